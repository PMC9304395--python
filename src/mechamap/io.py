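"""File formats, configuration round-tripping, and the end-to-end pipeline.

Force curves travel as a documented UTF-8 tab-separated dialect with header
``curve_id\tsegment\tz_nm\tforce_pN`` — one sample per row, "." decimal
separator, z monotone within each segment (increasing on approach,
decreasing on retract). Units at file boundaries are human-scale (nm, pN,
µm, kPa); everything in memory is SI. Vendor binary force formats are out
of scope; a converter can target this dialect.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig, QCConfig, RunConfig
from .curve_processing import APPROACH, RETRACT, ForceCurve, process_map
from . import map_qc as mq
from . import stiffness_stats as st
from . import synthetic_cohort as sc

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["curve_id", "segment", "z_nm", "force_pN"]
MANIFEST_COLUMNS = ["curve_id", "patient_id", "slide_id", "map_id",
                    "probe_id", "tissue_type", "grid_row", "grid_col"]


def write_curves(curves: Sequence[ForceCurve], path) -> Path:
    """Write curves to one TSV file in the package dialect (nm / pN)."""
    path = Path(path)
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "curve_id": c.curve_id,
            "segment": c.segment,
            "z_nm": c.z * 1e9,
            "force_pN": c.force * 1e12,
        }))
    table = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=CURVE_COLUMNS)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_curves(path, config: Optional[AcquisitionConfig] = None
                ) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Read the TSV curve dialect; returns (curves, quarantine report).

    Curves are grouped by ``curve_id`` and converted to SI. Malformed rows
    quarantine the affected curve (with a reason) without failing the rest;
    a missing or wrong header is a hard error.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    curves: list[ForceCurve] = []
    problems: list[dict] = []
    for fp in files:
        with open(fp, "r", encoding="utf-8") as fh:
            header = fh.readline().strip().split("\t")
        if header != CURVE_COLUMNS:
            raise ValueError(f"{fp}: missing or malformed header "
                             f"{header!r}; expected {CURVE_COLUMNS}")
        raw = pd.read_csv(fp, sep="\t", dtype=str)
        for cid, grp in raw.groupby("curve_id", sort=False):
            try:
                z = grp["z_nm"].astype(float).to_numpy() * 1e-9
                f = grp["force_pN"].astype(float).to_numpy() * 1e-12
            except ValueError as exc:
                problems.append({"curve_id": cid, "file": str(fp),
                                 "reason": f"unparseable number: {exc}"})
                continue
            seg = grp["segment"].to_numpy()
            bad = ~np.isin(seg, [APPROACH, RETRACT])
            if bad.any():
                problems.append({"curve_id": cid, "file": str(fp),
                                 "reason": "unknown segment label"})
                continue
            ok = True
            for label, sign in ((APPROACH, 1.0), (RETRACT, -1.0)):
                zi = z[seg == label]
                if len(zi) >= 2 and np.any(sign * np.diff(zi) < 0):
                    problems.append({
                        "curve_id": cid, "file": str(fp),
                        "reason": f"non-monotone z in {label} segment"})
                    ok = False
                    break
            if not ok:
                continue
            if np.any(~np.isfinite(z)) or np.any(~np.isfinite(f)):
                problems.append({"curve_id": cid, "file": str(fp),
                                 "reason": "non-finite sample"})
                continue
            curves.append(ForceCurve(z=z, force=f, segment=seg,
                                     curve_id=str(cid), metadata=config))
    report = pd.DataFrame(problems, columns=["curve_id", "file", "reason"])
    return curves, report


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, dtype={"grid_row": int, "grid_col": int})
    missing = [c for c in MANIFEST_COLUMNS if c not in m.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dup = m.duplicated(subset=["map_id", "grid_row", "grid_col"])
    if dup.any():
        logger.warning("%d duplicate (map_id, grid) entries in manifest",
                       int(dup.sum()))
    bad = ~m["tissue_type"].isin(sc.TISSUE_TYPES)
    if bad.any():
        raise ValueError("unknown tissue types in manifest: "
                         f"{sorted(m.loc[bad, 'tissue_type'].unique())}")
    return m


def attach_manifest(curves: Sequence[ForceCurve],
                    manifest: pd.DataFrame) -> dict[str, list[ForceCurve]]:
    """Group curves by map_id, filling grid indices from the manifest."""
    info = manifest.set_index("curve_id")
    by_map: dict[str, list[ForceCurve]] = {}
    for c in curves:
        if c.curve_id not in info.index:
            logger.warning("curve %s absent from manifest; skipped",
                           c.curve_id)
            continue
        row = info.loc[c.curve_id]
        c.grid_row = int(row["grid_row"])
        c.grid_col = int(row["grid_col"])
        by_map.setdefault(str(row["map_id"]), []).append(c)
    return by_map


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_PIXEL_COLUMNS = ["patient_id", "map_id", "slide_id", "probe_id",
                  "tissue_type", "grid_row", "grid_col", "E_kPa", "valid"]


def maps_to_frame(maps: Sequence[mq.StiffnessMap]) -> pd.DataFrame:
    """Tidy per-pixel table: one row per pixel (map metadata repeated)."""
    if not maps:
        return pd.DataFrame(columns=_PIXEL_COLUMNS)
    rows = []
    for m in maps:
        nr, nc = m.values.shape
        for r in range(nr):
            for c in range(nc):
                rows.append({
                    "patient_id": m.patient_id, "map_id": m.map_id,
                    "slide_id": m.slide_id, "probe_id": m.probe_id,
                    "tissue_type": m.tissue_type, "grid_row": r,
                    "grid_col": c,
                    "E_kPa": m.values[r, c] if m.valid[r, c] else np.nan,
                    "valid": bool(m.valid[r, c]),
                })
    return pd.DataFrame(rows)


def observations_from_maps(maps: Sequence[mq.StiffnessMap]) -> pd.DataFrame:
    """Valid pixels of retained maps as a tidy observation table."""
    frame = maps_to_frame(maps)
    obs = frame[frame["valid"].astype(bool)].drop(columns=["valid"])
    return obs.reset_index(drop=True)


def write_results(out_dir, *, summary: dict,
                  tables: Optional[dict] = None,
                  overwrite: bool = False) -> dict:
    """Write result tables (CSV) and a JSON run summary with deterministic
    names. Refuses to clobber an existing summary unless ``overwrite``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "run_summary.json"
    if summary_path.exists() and not overwrite:
        raise FileExistsError(f"{summary_path} exists; pass overwrite=True")
    written = {}
    for name, table in (tables or {}).items():
        if table is None or (hasattr(table, "empty") and table.empty):
            continue
        p = out / f"{name}.csv"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True")
        table.to_csv(p, index=False)
        written[name] = str(p)
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    written["run_summary"] = str(summary_path)
    return written


def run_pipeline(config: RunConfig, out_dir,
                 overwrite: bool = False) -> dict:
    """simulate -> process -> qc -> stats -> report, all from one seed.

    Stages log their progress; a starved stage (e.g. every map filtered
    out) reports "no data" in the summary instead of failing.
    """
    rng = np.random.default_rng(config.seed)
    acq = config.acquisition
    effects = sc.EffectConfig()
    cohort, ledger = sc.simulate_cohort(
        config.n_patients, seed=int(rng.integers(0, 2**31 - 1)),
        effects=effects)
    logger.info("simulate: %d patients", len(cohort))

    allocation = sc.DEFAULT_TISSUE_ALLOCATION
    maps, all_results, injected = [], [], {"clean": 0}
    for _, pat in cohort.iterrows():
        for mi in range(config.maps_per_patient):
            tissue = allocation[mi % len(allocation)]
            truth = sc.StiffnessGroundTruth(
                patient_id=pat.patient_id,
                map_id=f"{pat.patient_id}_M{mi + 1}",
                tissue_type=tissue,
                linear_predictor=(effects.baseline_log_pa
                                  + effects.tissue_effects[tissue]
                                  + pat.true_patient_effect),
                gamma_shape=effects.gamma_shape)
            curves, _, kinds = sc.simulate_force_map(
                truth, config=acq,
                artifact_fraction=config.artifact_fraction,
                seed=int(rng.integers(0, 2**31 - 1)))
            for k in kinds:
                injected[k] = injected.get(k, 0) + 1
            smap, results = process_map(
                curves, acq, qc=config.qc, delta_max=config.delta_max,
                patient_id=pat.patient_id, map_id=truth.map_id,
                slide_id=f"{pat.patient_id}_S1", probe_id="probe1",
                tissue_type=tissue)
            maps.append(smap)
            all_results.extend(results)
    logger.info("process: %d maps, %d curves", len(maps), len(all_results))

    retained, coverage_report = mq.filter_maps(
        maps, threshold_um=config.qc.coverage_threshold_um)
    logger.info("qc: %d/%d maps retained", len(retained), len(maps))

    fits_table = pd.DataFrame([{
        "curve_id": r.curve_id, "E_kPa": r.fit.E / 1000.0,
        "z0_um": r.fit.z0 * 1e6 if np.isfinite(r.fit.z0) else np.nan,
        "rss": r.fit.rss, "n_fit": r.fit.n_fit,
        "converged": r.fit.converged,
        "permanent_contact": r.qc.permanent_contact,
        "ill_defined_contact": r.qc.ill_defined_contact,
        "too_noisy": r.qc.too_noisy, "passed": r.qc.passed,
    } for r in all_results])

    excluded = {k: int(sum(m.exclusion_counts.get(k, 0) for m in maps))
                for k in ("clean", "permanent_contact",
                          "ill_defined_contact", "too_noisy",
                          "non_converged")}

    tables = {
        "cohort": cohort,
        "curve_fits": fits_table,
        "pixels": maps_to_frame(maps),
        "coverage": coverage_report,
    }
    summary = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_patients": len(cohort),
        "n_maps": len(maps),
        "n_maps_retained": len(retained),
        "n_curves": len(all_results),
        "curves_by_outcome": excluded,
        "artifacts_injected": injected,
        "ground_truth": ledger,
    }

    obs = observations_from_maps(retained)
    if obs.empty or obs["map_id"].nunique() < 2:
        summary["stats"] = "no data"
        logger.info("stats: no data after QC")
    else:
        desc = st.descriptive_summary(cohort)
        tables["table_descriptive_age"] = desc["age"]
        tables["table_descriptive"] = desc["categorical"]
        try:
            if obs["tissue_type"].nunique() >= 2:
                contrasts, _ = st.tissue_contrasts(obs)
                tables["table_tissue"] = contrasts
            var_rows = []
            for tissue in sorted(obs["tissue_type"].unique()):
                sub = obs[obs["tissue_type"] == tissue]
                if sub["map_id"].nunique() >= 2:
                    var_rows.append(st.variability_analysis(obs, tissue))
            if var_rows:
                tables["table_variability"] = pd.concat(
                    var_rows, ignore_index=True)
            tables["table_clinical"] = st.clinical_associations(obs, cohort)
            summary["stats"] = "ok"
        except (ValueError, KeyError) as exc:
            summary["stats"] = f"degenerate design: {exc}"
            logger.warning("stats stage degraded: %s", exc)
        if len(retained) >= 2 and obs["tissue_type"].nunique() >= 2:
            try:
                F, p = mq.coverage_anova(
                    retained,
                    threshold_um=config.qc.coverage_threshold_um)
                summary["coverage_anova"] = {"F": F, "p": p}
            except ValueError:
                pass

    written = write_results(out_dir, summary=summary, tables=tables,
                            overwrite=overwrite)
    logger.info("report: wrote %d files to %s", len(written), out_dir)
    return {"summary": summary, "files": written, "maps": maps,
            "retained": retained, "observations": obs}
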