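# mechamap

Micromechanical analysis of AFM force maps on soft tissue: from raw
force–distance curves to hierarchical statistics of Young's moduli across
tissue types and clinical covariates.

## The problem

Colon tissue — like most soft tissue — is mechanically heterogeneous, and
tumor progression stiffens it. Colloidal-probe atomic force microscopy
(AFM) measures this directly: a cantilever carrying a ~10 µm silica bead
indents the tissue section at every pixel of a grid (typically 10 × 10
pixels over 50 × 50 µm), recording force versus piezo position. Each
approach curve yields a local Young's modulus *E* through the Hertz model
for a rigid sphere on an elastic half-space,

    F(δ) = (4/3) · E / (1 − ν²) · √R · δ^{3/2},

where δ is the indentation depth, R the bead radius and ν the Poisson
ratio. The depth couples to the cantilever deflection through the spring
constant k: δ = (z − z₀) − F/k, with z₀ the contact point. Ramps stop at a
2 nN force trigger so the indentation stays near 10% of the 20 µm section
thickness and the rigid substrate does not contaminate the modulus.

Per-pixel moduli are strongly right-skewed (gamma-like, with many values
near 0.1 kPa), and measurements are nested — pixels within maps, maps
within patients, several maps per tissue type. `mechamap` implements the
full chain:

1. **synthetic_cohort** — a generator of virtual patients, gamma-distributed
   ground-truth stiffness fields, and physically simulated force curves
   (including deliberately corrupted ones) so every stage is testable
   without instrument data;
2. **curve_processing** — baseline correction, contact-point detection,
   Hertz fitting, and the three classical curve-exclusion criteria
   (permanent contact, ill-defined contact point, excessive noise);
3. **map_qc** — a nearest-neighbour *coverage index* per map (mean distance
   from each valid pixel to its nearest valid neighbour, µm); maps above a
   threshold (default 8 µm at a 5 µm pitch) are discarded, and a weighted
   ANOVA checks coverage is not confounded with tissue type;
4. **stiffness_stats** — gamma generalized linear mixed models with log
   link, fitted by penalized quasi-likelihood (PQL), with patient / map /
   map×tissue random intercepts and Wald F tests using containment
   degrees of freedom; analyses cover intra-/inter-patient variability,
   tissue contrasts (normal epithelium vs tumor epithelium vs stroma vs
   mixed zones), and per-covariate clinical associations;
5. **io / cli** — a documented TSV force-curve dialect, CSV tables, YAML
   configs, and a `mechamap` command-line pipeline.

## Worked example

```python
import mechamap as mm

cfg = mm.AcquisitionConfig()          # 10.2 um bead, k = 0.2 N/m, 2 nN trigger
curve = mm.simulate_force_curve(1000.0, config=cfg, seed=0)
result = mm.process_curve(curve, cfg)
print(f"E = {result.fit.E:.1f} Pa, contact at z0 = {result.fit.z0*1e6:.3f} um, "
      f"QC pass = {result.qc.passed}")

obs, cohort = mm.simulate_observations(n_patients=20, maps_per_patient=4,
                                       points_per_map=56, seed=1)
table, fit = mm.tissue_contrasts(obs)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

prints

```
E = 1002.3 Pa, contact at z0 = 5.999 um, QC pass = True
reference           tissue  beta    sd      t     p
   normal            mixed 2.285 0.138 16.592 0.000
   normal           stroma 2.729 0.138 19.813 0.000
   normal tumor_epithelium 0.699 0.138  5.078 0.000
```

The first line is a single noisy curve on a 1 kPa half-space: the Hertz
fit recovers the modulus to 0.2% and the contact point to a few
nanometres, and the curve passes all three quality filters. The table is
the tissue-contrast analysis of a 20-patient synthetic cohort on the log
scale: at the default generator settings every tumor compartment is
significantly stiffer than pooled normal epithelium, stroma most of all
(e^2.73 ≈ 15-fold), with standard errors reflecting the map-to-map and
patient-to-patient variance structure. (These estimates include the
generator's clinical stiffening effects, which act on tumor tissue on top
of the pure tissue contrasts.)

The same pipeline runs from a shell:

```bash
mechamap run --seed 9 --out out/            # simulate -> process -> qc -> stats
mechamap simulate --patients 4 --maps-per-patient 2 --seed 1 --out sim/
mechamap process  --curves sim/ --manifest sim/manifest.csv --out proc/
mechamap qc       --pixels proc/pixels.csv --threshold-um 8 --out qc/
mechamap stats    --obs qc/pixels_retained.csv --cohort sim/cohort.csv \
                  --analysis describe --out stats/
```

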