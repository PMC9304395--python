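"""Synthetic cohorts, ground-truth stiffness fields, and raw force curves.

This module is the study-condition generator: every downstream stage
(curve processing, map QC, mixed-model statistics) is testable against data
whose ground truth is known. Three layers are provided:

* :func:`simulate_cohort` — virtual patients with the clinical/molecular
  covariate set of a colon-adenocarcinoma cohort (sex, age, location, stage,
  mucinous component, lymphovascular/perinervous infiltration, MSI status,
  KRAS/NRAS/BRAF mutations);
* :func:`simulate_stiffness_field` / :func:`simulate_observations` —
  per-pixel Young's moduli drawn from a gamma distribution with log-scale
  patient/map/tissue structure (the model the GLMM fitter must invert);
* :func:`simulate_force_curve` / :func:`simulate_force_map` — Hertzian
  approach/retract ramps with cantilever-deflection coupling, force trigger,
  Gaussian force noise, and deliberately corrupted curves that violate
  exactly one quality-control criterion each.

Determinism: identical inputs and seed give identical output; all entropy
flows through ``numpy.random.default_rng``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .curve_processing import APPROACH, RETRACT, ForceCurve
from .physics import force_at_travel, hertz_prefactor, indentation_at_force

TISSUE_TYPES = ("distal_normal", "proximal_normal", "tumor_epithelium",
                "stroma", "mixed")
ARTIFACT_KINDS = ("clean", "permanent_contact", "short_baseline",
                  "high_noise")

#: Table-1-style default marginal frequencies for the virtual cohort
DEFAULT_FREQUENCIES = {
    "female": 11 / 18,
    "right_colon": 10 / 18,
    "mucinous": 8 / 18,
    "lymphovascular": 10 / 18,
    "perinervous": 5 / 18,
    "stage": {"I": 1 / 18, "II": 10 / 18, "III": 3 / 18, "IV": 4 / 18},
    "msi": 9 / 18,
    "mutated": 12 / 18,
    # conditional on being mutated: which gene carries the hit
    "mutation_type": {"KRAS": 7 / 12, "NRAS": 1 / 12, "BRAF": 4 / 12},
    "second_hit": 1 / 12,
}

COHORT_COLUMNS = [
    "patient_id", "sex", "age", "location", "mucinous", "lymphovascular",
    "perinervous", "stage", "msi", "kras", "nras", "braf", "ras",
    "true_patient_effect",
]


#: per-kind default corruption scale; high_noise sits comfortably above the
#: c=0.25 decision boundary so flagging is deterministic, not coin-flip
DEFAULT_ARTIFACT_MAGNITUDE = {"clean": 1.0, "permanent_contact": 1.0,
                              "short_baseline": 1.0, "high_noise": 1.5}


@dataclass(frozen=True)
class ArtifactSpec:
    """Deliberate curve corruption targeting one QC criterion.

    ``magnitude`` scales the corruption: for ``high_noise`` the noise sd is
    ``magnitude * 0.25 * trigger`` (default 1.5 -> 0.75 nN at a 2 nN
    trigger); for ``short_baseline`` it is the flat pre-contact travel in
    units of 1 µm; for ``permanent_contact`` the initial indentation depth
    in units of 0.5 µm.
    """

    kind: str = "clean"
    magnitude: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.magnitude is None:
            object.__setattr__(self, "magnitude",
                               DEFAULT_ARTIFACT_MAGNITUDE[self.kind])


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect structure on the log-stiffness scale.

    The linear predictor of a pixel is (log Pa)

        eta = baseline + tissue_effect + [clinical effects, tumor tissue only]
              + b_patient + b_map + b_map_tissue + b_probe

    and the pixel modulus is Gamma(shape, mean=exp(eta)). Tissue and
    clinical magnitudes default to the effect sizes reported for colon
    tissue (stroma +2.18, tumor epithelium +0.192, mixed +1.75; stage
    +0.90, right-vs-left location −0.564, RAS +0.498 ...); clinical effects
    apply to tumor-derived tissue only, mirroring the tumor-restricted
    clinical analysis. Random-effect SDs and the gamma shape are generator
    choices (see docs/methods.md).
    """

    baseline_log_pa: float = float(np.log(80.0))  # normal mucosa ~0.08 kPa
    tissue_effects: dict = field(default_factory=lambda: {
        "distal_normal": 0.0,
        "proximal_normal": 0.0,
        "tumor_epithelium": 0.192,
        "stroma": 2.18,
        "mixed": 1.75,
    })
    clinical_effects: dict = field(default_factory=lambda: {
        "sex_male": -0.098,
        "location_right": -0.564,
        "age_per_year": -0.0128,
        "mucinous": -0.356,
        "lymphovascular": 0.268,
        "perinervous": 0.625,
        "stage_late": 0.90,
        "ras": 0.498,
        "mss": 0.291,
    })
    sd_patient: float = 0.5
    sd_map: float = 0.25
    sd_map_tissue: float = 0.0
    sd_probe: float = 0.0
    gamma_shape: float = 2.0

    @classmethod
    def null(cls) -> "EffectConfig":
        """All fixed effects zero; random structure and dispersion kept."""
        return cls(
            tissue_effects={t: 0.0 for t in TISSUE_TYPES},
            clinical_effects={k: 0.0
                              for k in cls().clinical_effects},
        )

    @classmethod
    def only(cls, tissue: Optional[dict] = None,
             clinical: Optional[dict] = None) -> "EffectConfig":
        """Isolate selected effects (all others zero) for recovery
        experiments; unspecified magnitudes fall back to the defaults."""
        base = cls()
        te = {t: 0.0 for t in TISSUE_TYPES}
        ce = {k: 0.0 for k in base.clinical_effects}
        for k, v in (tissue or {}).items():
            te[k] = base.tissue_effects[k] if v is True else float(v)
        for k, v in (clinical or {}).items():
            ce[k] = base.clinical_effects[k] if v is True else float(v)
        return cls(tissue_effects=te, clinical_effects=ce)


@dataclass
class StiffnessGroundTruth:
    """True generating state of one force map."""

    patient_id: str
    map_id: str
    tissue_type: str
    linear_predictor: float  # log(Pa)
    gamma_shape: float = 2.0

    def __post_init__(self):
        if self.tissue_type not in TISSUE_TYPES:
            raise ValueError(f"unknown tissue type {self.tissue_type!r}")
        if not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be positive")

    @classmethod
    def normal_mucosa(cls, patient_id: str = "P1",
                      map_id: str = "M1") -> "StiffnessGroundTruth":
        """Preset for soft normal colon mucosa (mean < 0.1 kPa)."""
        return cls(patient_id, map_id, "distal_normal",
                   EffectConfig().baseline_log_pa)


def simulate_cohort(n_patients: int, frequencies: Optional[dict] = None,
                    seed: int = 0,
                    effects: EffectConfig = EffectConfig()):
    """Draw a virtual patient table plus the ground-truth effect ledger.

    Covariates are sampled independently from the configured marginal
    frequencies. The returned frame also carries the true patient-level
    random intercept used by the stiffness generator; the second return
    value records every effect magnitude in force for downstream checks.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    freq = dict(DEFAULT_FREQUENCIES)
    if frequencies:
        freq.update(frequencies)
    rng = np.random.default_rng(seed)
    rows = []
    stages = list(freq["stage"].keys())
    p_stage = np.array(list(freq["stage"].values()), dtype=float)
    if p_stage.sum() <= 0:
        p_stage = np.array([1.0] + [0.0] * (len(stages) - 1))
    p_stage = p_stage / p_stage.sum()
    genes = list(freq["mutation_type"].keys())
    p_gene = np.array(list(freq["mutation_type"].values()), dtype=float)
    p_gene = p_gene / p_gene.sum() if p_gene.sum() > 0 else np.array(
        [1.0] + [0.0] * (len(genes) - 1))
    for i in range(n_patients):
        female = rng.random() < freq["female"]
        age = float(np.clip(np.round(rng.normal(67.6, 9.7)), 40, 95))
        right = rng.random() < freq["right_colon"]
        mucinous = rng.random() < freq["mucinous"]
        lymphovascular = rng.random() < freq["lymphovascular"]
        perinervous = rng.random() < freq["perinervous"]
        stage = stages[rng.choice(len(stages), p=p_stage)]
        msi = rng.random() < freq["msi"]
        kras = nras = braf = False
        if rng.random() < freq["mutated"]:
            hit = genes[rng.choice(len(genes), p=p_gene)]
            kras, nras, braf = (hit == "KRAS", hit == "NRAS", hit == "BRAF")
            if rng.random() < freq["second_hit"]:
                others = [g for g in genes if g != hit]
                second = others[rng.choice(len(others))]
                kras = kras or second == "KRAS"
                nras = nras or second == "NRAS"
                braf = braf or second == "BRAF"
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "sex": "F" if female else "M",
            "age": age,
            "location": "right" if right else "left",
            "mucinous": mucinous,
            "lymphovascular": lymphovascular,
            "perinervous": perinervous,
            "stage": stage,
            "msi": "MSI" if msi else "MSS",
            "kras": kras,
            "nras": nras,
            "braf": braf,
            "ras": kras or nras,
            "true_patient_effect": rng.normal(0.0, effects.sd_patient),
        })
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    ledger = {
        "baseline_log_pa": effects.baseline_log_pa,
        "tissue_effects": dict(effects.tissue_effects),
        "clinical_effects": dict(effects.clinical_effects),
        "sd_patient": effects.sd_patient,
        "sd_map": effects.sd_map,
        "sd_map_tissue": effects.sd_map_tissue,
        "gamma_shape": effects.gamma_shape,
    }
    return cohort, ledger


def demo_cohort() -> pd.DataFrame:
    """Deterministic 18-patient cohort realizing the default marginal counts
    exactly: 11 female / 7 male, 10 right / 8 left colon, stages
    1×I + 10×II + 3×III + 4×IV, 9 MSI / 9 MSS, and 12 mutated patients
    carrying 7 KRAS, 1 NRAS and 4 BRAF hits (so 8 RAS-mutated, of which
    7/8 = 87.5% are KRAS)."""
    n = 18
    rows = []
    stages = ["I"] + ["II"] * 10 + ["III"] * 3 + ["IV"] * 4
    genes = ["KRAS"] * 7 + ["NRAS"] + ["BRAF"] * 4 + [None] * 6
    for i in range(n):
        rows.append({
            "patient_id": f"P{i + 1:03d}",
            "sex": "F" if i < 11 else "M",
            "age": 65.0,
            "location": "right" if i < 10 else "left",
            "mucinous": i < 8,
            "lymphovascular": i < 10,
            "perinervous": i < 5,
            "stage": stages[i],
            "msi": "MSI" if i % 2 == 0 else "MSS",
            "kras": genes[i] == "KRAS",
            "nras": genes[i] == "NRAS",
            "braf": genes[i] == "BRAF",
            "ras": genes[i] in ("KRAS", "NRAS"),
            "true_patient_effect": 0.0,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_stiffness_field(truth: StiffnessGroundTruth, seed: int = 0,
                             config: AcquisitionConfig = AcquisitionConfig(),
                             correlation_length: float = 0.0) -> np.ndarray:
    """Per-pixel true moduli (Pa) for one map.

    Pixels are i.i.d. Gamma(shape, mean=exp(linear_predictor)). An optional
    correlated field (Gaussian-smoothed copula on the log scale, correlation
    length in pixels) exists for robustness experiments; the default is
    spatial independence.
    """
    if not truth.gamma_shape > 0:
        raise ValueError("gamma_shape must be positive")
    rng = np.random.default_rng(seed)
    n = config.grid_n
    mean = float(np.exp(truth.linear_predictor))
    shape = truth.gamma_shape
    if correlation_length <= 0:
        return rng.gamma(shape, scale=mean / shape, size=(n, n))
    # correlated field: smooth a Gaussian sheet, map through the gamma ppf
    from scipy.ndimage import gaussian_filter
    from scipy.stats import gamma as gamma_dist, norm
    g = gaussian_filter(rng.normal(size=(n, n)), sigma=correlation_length,
                        mode="wrap")
    g = (g - g.mean()) / max(g.std(), 1e-12)
    u = np.clip(norm.cdf(g), 1e-12, 1 - 1e-12)
    return gamma_dist.ppf(u, a=shape, scale=mean / shape)


def simulate_force_curve(E_true: float,
                         config: AcquisitionConfig = AcquisitionConfig(),
                         artifact: ArtifactSpec = ArtifactSpec(),
                         seed: int = 0, curve_id: str = "c000",
                         grid_row: int = 0, grid_col: int = 0,
                         with_retract: bool = True,
                         adhesion_force: float = 0.3e-9,
                         adhesion_width: float = 1.0e-6) -> ForceCurve:
    """Simulate one indentation cycle on a half-space of modulus ``E_true``.

    The approach is a flat zero-force baseline followed by Hertzian loading
    with deflection coupling; the ramp stops at the first sample at or above
    the force trigger, or when ``max_ramp`` is exhausted (curve flagged
    ``truncated``, not an error). The retract mirrors the approach with a
    single negative adhesion well just off contact; it exists so retract
    code paths are exercised but is never fitted. Gaussian force noise is
    added at the configured amplitude (``high_noise`` artifacts override it).
    """
    if not E_true > 0:
        raise ValueError("E_true must be positive")
    rng = np.random.default_rng(seed)
    dz = config.sample_spacing
    noise_sd = config.noise_sd

    if artifact.kind == "permanent_contact":
        start_offset = -0.5e-6 * artifact.magnitude  # start indented
    elif artifact.kind == "short_baseline":
        start_offset = 1.0e-6 * artifact.magnitude   # only ~1 µm baseline
    else:
        start_offset = config.pre_contact_travel
    if artifact.kind == "high_noise":
        noise_sd = artifact.magnitude * 0.25 * config.force_trigger

    z0 = max(start_offset, 0.0)
    z_start = z0 - start_offset  # 0 for baseline'd curves, >z0 for permanent

    # travel past contact needed to reach the trigger (depth + deflection)
    d_trig = indentation_at_force(config.force_trigger, E_true,
                                  config.bead_radius, config.poisson_ratio)
    s_trig = d_trig + config.force_trigger / config.spring_constant
    z_end = max(z0 + s_trig + 2 * dz, z_start + 10 * dz)
    z_end = min(z_end, z_start + config.max_ramp)
    z = np.arange(z_start, z_end + 0.5 * dz, dz)
    force = force_at_travel(z - z0, E_true, config.bead_radius,
                            config.poisson_ratio, config.spring_constant)
    # stop at the first sample reaching the trigger
    hit = np.nonzero(force >= config.force_trigger)[0]
    truncated = len(hit) == 0
    if not truncated:
        z = z[: hit[0] + 1]
        force = force[: hit[0] + 1]
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=len(force))

    if with_retract:
        z_r = z[::-1].copy()
        f_r = force_at_travel(z_r - z0, E_true, config.bead_radius,
                              config.poisson_ratio, config.spring_constant)
        well = -adhesion_force * np.exp(
            -((z_r - z0) / adhesion_width) ** 2)
        f_r = f_r + np.where(z_r <= z0 + 0.25 * adhesion_width, well, 0.0)
        if noise_sd > 0:
            f_r = f_r + rng.normal(0.0, noise_sd, size=len(f_r))
        z_all = np.concatenate([z, z_r])
        f_all = np.concatenate([force, f_r])
        seg = np.array([APPROACH] * len(z) + [RETRACT] * len(z_r))
    else:
        z_all, f_all = z, force
        seg = np.array([APPROACH] * len(z))
    return ForceCurve(z=z_all, force=f_all, segment=seg, curve_id=curve_id,
                      grid_row=grid_row, grid_col=grid_col, metadata=config,
                      truncated=truncated)


def simulate_force_map(truth: StiffnessGroundTruth,
                       config: AcquisitionConfig = AcquisitionConfig(),
                       artifact_fraction: float = 0.0,
                       seed: int = 0) -> tuple[list, np.ndarray, list]:
    """Simulate all curves of one force map.

    Returns (curves, true modulus grid in Pa, artifact kind per curve).
    Artifact kinds are cycled deterministically among corrupted pixels.
    """
    rng = np.random.default_rng(seed)
    field_seed = int(rng.integers(0, 2**31 - 1))
    E_grid = simulate_stiffness_field(truth, seed=field_seed, config=config)
    n = config.grid_n
    n_pix = n * n
    n_bad = int(round(artifact_fraction * n_pix))
    bad_idx = set(rng.choice(n_pix, size=n_bad, replace=False).tolist())
    bad_kinds = [k for k in ARTIFACT_KINDS if k != "clean"]
    curves, kinds = [], []
    j = 0
    for idx in range(n_pix):
        r, c = divmod(idx, n)
        if idx in bad_idx:
            kind = bad_kinds[j % len(bad_kinds)]
            j += 1
        else:
            kind = "clean"
        cseed = int(rng.integers(0, 2**31 - 1))
        curve = simulate_force_curve(
            float(E_grid[r, c]), config=config,
            artifact=ArtifactSpec(kind=kind), seed=cseed,
            curve_id=f"{truth.map_id}_r{r:02d}c{c:02d}",
            grid_row=r, grid_col=c)
        curves.append(curve)
        kinds.append(kind)
    return curves, E_grid, kinds


DEFAULT_TISSUE_ALLOCATION = ("distal_normal", "tumor_epithelium", "stroma",
                             "mixed")


def simulate_observations(n_patients: int = 20, maps_per_patient: int = 4,
                          points_per_map: int = 56,
                          effects: EffectConfig = EffectConfig(),
                          tissue_allocation: Sequence[str] =
                          DEFAULT_TISSUE_ALLOCATION,
                          frequencies: Optional[dict] = None,
                          seed: int = 0):
    """Observation-level generator for the mixed-model layer.

    Bypasses the force-curve physics: per-pixel moduli are drawn directly
    from the gamma/log-link hierarchy, which is what the GLMM inverts. Each
    patient receives ``maps_per_patient`` maps whose tissue types cycle
    through ``tissue_allocation``; each map contributes ``points_per_map``
    values (the study's median retained points per map). Returns a tidy
    observation frame (E_kPa, patient/map/tissue, clinical covariates) and
    the cohort table.
    """
    if n_patients < 1 or maps_per_patient < 1 or points_per_map < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    cohort, _ = simulate_cohort(n_patients, frequencies=frequencies,
                                seed=int(rng.integers(0, 2**31 - 1)),
                                effects=effects)
    ce = effects.clinical_effects
    obs = []
    for _, pat in cohort.iterrows():
        clin = (
            ce["sex_male"] * (pat.sex == "M")
            + ce["location_right"] * (pat.location == "right")
            + ce["age_per_year"] * (pat.age - 67.6)
            + ce["mucinous"] * pat.mucinous
            + ce["lymphovascular"] * pat.lymphovascular
            + ce["perinervous"] * pat.perinervous
            + ce["stage_late"] * (pat.stage in ("III", "IV"))
            + ce["ras"] * pat.ras
            + ce["mss"] * (pat.msi == "MSS")
        )
        for m in range(maps_per_patient):
            tissue = tissue_allocation[m % len(tissue_allocation)]
            is_tumor = tissue in ("tumor_epithelium", "stroma", "mixed")
            eta = (effects.baseline_log_pa
                   + effects.tissue_effects.get(tissue, 0.0)
                   + (clin if is_tumor else 0.0)
                   + pat.true_patient_effect
                   + rng.normal(0.0, effects.sd_map)
                   + rng.normal(0.0, effects.sd_map_tissue))
            mean_pa = np.exp(eta)
            e_pa = rng.gamma(effects.gamma_shape,
                             scale=mean_pa / effects.gamma_shape,
                             size=points_per_map)
            map_id = f"{pat.patient_id}_M{m + 1}"
            for v in e_pa:
                obs.append((pat.patient_id, map_id, tissue, v / 1000.0))
    frame = pd.DataFrame(obs, columns=["patient_id", "map_id", "tissue_type",
                                       "E_kPa"])
    frame = frame.merge(cohort.drop(columns=["true_patient_effect"]),
                        on="patient_id", how="left")
    return frame, cohort
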