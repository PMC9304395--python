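"""Hierarchical gamma mixed-model analyses of per-pixel stiffness.

Observations are repeated Young's-modulus measurements (E, kPa) at many
pixels per map, several maps per patient, across tissue types. The layer
reproduces four analysis shapes:

* :func:`variability_analysis` — intra-patient (map factor) and
  inter-patient (patient factor) variability within one tissue type;
* :func:`tissue_contrasts` — tissue-type fixed effect with patient, map and
  map x tissue random intercepts, with the pooled groupings used for
  normal tissue (distal+proximal) and merged tumor compartments (T+S);
* :func:`clinical_associations` — tumor-restricted, one clinical or
  molecular covariate at a time with patient and map random intercepts;
* :func:`descriptive_summary` — cohort descriptives (counts/percentages,
  age statistics).

All models are gamma GLMMs with log link fitted by PQL
(:mod:`mechamap.glmm`). Wald F statistics use containment denominator
degrees of freedom: a fixed term is tested at the grouping level within
which it varies — between-patient terms against patient-level df,
between-map terms against map-level df, observation-level terms against
residual df.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist, t as t_dist

from .glmm import PQLFit, RandomTerm, fit_gamma_pql

logger = logging.getLogger(__name__)

RANDOM_TERM_CHOICES = ("patient", "map", "map_tissue")
TUMOR_TISSUES = ("tumor_epithelium", "stroma", "mixed")


@dataclass(frozen=True)
class MixedModelSpec:
    """Declarative model description: fixed terms (data columns),
    random intercept structure, gamma family with log link."""

    fixed_terms: tuple = ()
    random_terms: tuple = ("patient", "map")
    family: str = "gamma"
    link: str = "log"
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family != "gamma" or self.link != "log":
            raise ValueError("only the gamma family with log link is "
                             "supported")
        for rt in self.random_terms:
            if rt not in RANDOM_TERM_CHOICES:
                raise ValueError(f"unknown random term {rt!r}")


@dataclass
class MixedModelFit:
    """Fitted gamma GLMM: coefficient table, random variances, Wald tests."""

    params: pd.Series              # beta on the log scale
    se: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    df: pd.Series                  # containment df per coefficient
    cov_params: pd.DataFrame
    random_variances: dict
    dispersion: float
    wald: dict                     # term -> dict(F, df1, df2, p)
    converged: bool
    n_obs: int
    n_maps: int
    n_patients: int
    term_columns: dict
    dropped_random: list = field(default_factory=list)
    notes: list = field(default_factory=list)


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 reference_levels: Optional[dict] = None):
    """Fixed-effects design matrix with intercept; categoricals are
    treatment-coded against a reference level (default: first sorted)."""
    reference_levels = reference_levels or {}
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    term_columns: dict[str, list[int]] = {}
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"column {term!r} missing from data")
        s = data[term]
        idx = []
        if s.dtype == bool:
            cols.append(s.to_numpy(dtype=float))
            names.append(f"{term}[True]")
            idx.append(len(cols) - 1)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            ref = str(reference_levels.get(term, levels[0]))
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from {term!r}")
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{term}[{lv}]")
                idx.append(len(cols) - 1)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
            idx.append(len(cols) - 1)
        term_columns[term] = idx
    X = np.column_stack(cols)
    return X, names, term_columns


def _random_factor(data: pd.DataFrame, which: str) -> np.ndarray:
    if which == "patient":
        return data["patient_id"].to_numpy()
    if which == "map":
        return data["map_id"].to_numpy()
    if which == "map_tissue":
        return (data["map_id"].astype(str) + ":"
                + data["tissue_type"].astype(str)).to_numpy()
    return data[which].to_numpy()


def _containment_df(data: pd.DataFrame, X: np.ndarray, names: list,
                    term_columns: dict, groupings: list) -> dict:
    """Containment denominator df per design column.

    ``groupings``: list of (name, label array) ordered coarse -> fine,
    deduplicated. Level population sizes N_0=1 < N_1 < ... < N_L < n; a
    column constant within level-l units is estimated at level l and tested
    against df_l = N_l - N_{l-1} - p_l, where p_l counts the fixed-effect
    columns assigned to that level (intercept at the coarsest).
    """
    n = len(data)
    level_names = [g[0] for g in groupings] + ["obs"]
    level_sizes = [pd.unique(g[1]).size for g in groupings] + [n]
    col_level = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            col_level[j] = 0 if groupings else len(level_names) - 1
            continue
        assigned = len(level_names) - 1  # obs level by default
        for li, (gname, labels) in enumerate(groupings):
            nun = pd.Series(X[:, j]).groupby(
                pd.Series(labels)).nunique()
            if (nun <= 1).all():
                assigned = li
                break
        col_level[j] = assigned
    p_at = {li: 0 for li in range(len(level_names))}
    for j, li in col_level.items():
        p_at[li] += 1
    dfs = {}
    prev = 1
    df_level = {}
    for li, size in enumerate(level_sizes):
        df_level[li] = max(size - prev - p_at[li], 1)
        prev = size
    for j in col_level:
        dfs[j] = df_level[col_level[j]]
    return dfs


def fit_gamma_glmm(data: pd.DataFrame, spec: MixedModelSpec,
                   tol: float = 1e-6, max_iter: int = 100) -> MixedModelFit:
    """Fit a gamma/log GLMM by PQL per the spec.

    ``data`` must carry ``E_kPa`` (> 0), ``patient_id``, ``map_id`` and any
    fixed-term columns; each map must nest in exactly one patient.
    """
    if "E_kPa" not in data.columns:
        raise KeyError("data must contain an 'E_kPa' column")
    y = data["E_kPa"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("all stiffness values must be positive")
    nesting = data.groupby("map_id")["patient_id"].nunique()
    if (nesting > 1).any():
        bad = nesting[nesting > 1].index.tolist()
        raise ValueError(f"maps spanning several patients: {bad}")

    X, names, term_columns = build_design(data, spec.fixed_terms,
                                          spec.reference_levels)
    rterms = [RandomTerm.from_labels(rt, _random_factor(data, rt))
              for rt in spec.random_terms]
    pql = fit_gamma_pql(y, X, rterms, tol=tol, max_iter=max_iter)

    # grouping hierarchy for containment df: only terms kept in the model,
    # coarse -> fine, duplicate partitions collapsed
    partitions = []
    seen = set()
    for rt in spec.random_terms:
        if rt in pql.dropped_terms:
            continue
        labels = _random_factor(data, rt)
        key = tuple(pd.factorize(labels)[0])
        if key in seen:
            continue
        seen.add(key)
        partitions.append((rt, labels))
    partitions.sort(key=lambda g: pd.unique(g[1]).size)
    dfs = _containment_df(data, X, names, term_columns, partitions)

    se = np.sqrt(np.clip(np.diag(pql.cov_beta), 0.0, None))
    tvals = np.divide(pql.beta, se, out=np.zeros_like(pql.beta),
                      where=se > 0)
    pvals = np.array([2.0 * t_dist.sf(abs(tvals[j]), dfs[j])
                      for j in range(len(names))])
    wald = {}
    cov = pql.cov_beta
    for term, idx in term_columns.items():
        if not idx:
            continue
        C = np.zeros((len(idx), len(names)))
        for r, j in enumerate(idx):
            C[r, j] = 1.0
        wald[term] = _wald_from_contrast(pql.beta, cov, C,
                                         min(dfs[j] for j in idx))
    fit = MixedModelFit(
        params=pd.Series(pql.beta, index=names),
        se=pd.Series(se, index=names),
        t_values=pd.Series(tvals, index=names),
        p_values=pd.Series(pvals, index=names),
        df=pd.Series([dfs[j] for j in range(len(names))], index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        random_variances=pql.random_variances,
        dispersion=pql.dispersion_pearson,
        wald=wald,
        converged=pql.converged,
        n_obs=len(data),
        n_maps=int(data["map_id"].nunique()),
        n_patients=int(data["patient_id"].nunique()),
        term_columns=term_columns,
        dropped_random=pql.dropped_terms,
    )
    return fit


def _wald_from_contrast(beta, cov, C, ddf) -> dict:
    q = C.shape[0]
    cb = C @ beta
    M = C @ cov @ C.T
    try:
        sol = np.linalg.solve(M, cb)
    except np.linalg.LinAlgError:
        raise ValueError("rank-deficient contrast for Wald test")
    F = float(cb @ sol) / q
    F = max(F, 0.0)
    return {"F": F, "df1": q, "df2": int(ddf),
            "p": float(f_dist.sf(F, q, ddf))}


def wald_f_test(fit: MixedModelFit, term: str) -> tuple[float, float]:
    """Wald F test of all coefficients of one fixed term; returns (F, p)."""
    if term not in fit.term_columns:
        raise KeyError(f"{term!r} is not a fixed term of this model")
    w = fit.wald[term]
    return w["F"], w["p"]


def variability_analysis(data: pd.DataFrame, tissue_type: str,
                         preset: str = "legend") -> pd.DataFrame:
    """Intra-/inter-patient variability for one tissue type.

    Two single-factor gamma GLMMs: the *Map* row tests map-to-map
    differences, the *Patient* row patient-to-patient differences. Preset
    ``legend`` (default): Map as fixed effect with patient random, Patient
    as fixed effect with map random. Preset ``narrative`` swaps the roles
    (patient fixed / map random for the intra row). Patients contributing a
    single map are retained (their map effect is absorbed), and with a
    single patient the inter-patient row is reported as not estimable.
    """
    if preset not in ("legend", "narrative"):
        raise ValueError("preset must be 'legend' or 'narrative'")
    sub = data[data["tissue_type"] == tissue_type].copy()
    if sub.empty:
        raise ValueError(f"no observations for tissue {tissue_type!r}")
    rows = []

    def _row(factor, fixed_col, random_term):
        d = sub.copy()
        n_levels = d[fixed_col].nunique()
        if n_levels < 2:
            return {"tissue_type": tissue_type, "factor": factor,
                    "F": np.nan, "p": np.nan,
                    "note": f"single {factor.lower()}: not estimable"}
        d[fixed_col] = d[fixed_col].astype(str)
        spec = MixedModelSpec(fixed_terms=(fixed_col,),
                              random_terms=(random_term,))
        fit = fit_gamma_glmm(d, spec)
        F, p = wald_f_test(fit, fixed_col)
        return {"tissue_type": tissue_type, "factor": factor, "F": F,
                "p": p, "note": ""}

    if preset == "legend":
        rows.append(_row("Map", "map_id", "patient"))
        rows.append(_row("Patient", "patient_id", "map"))
    else:
        rows.append(_row("Patient", "patient_id", "map"))
        rows.append(_row("Map", "map_id", "patient"))
    return pd.DataFrame(rows)


def _pool_tissues(data: pd.DataFrame, pooling: Optional[str]) -> pd.DataFrame:
    d = data.copy()
    if pooling is None:
        return d
    if pooling == "normal":
        d["tissue_type"] = d["tissue_type"].replace(
            {"distal_normal": "normal", "proximal_normal": "normal"})
    elif pooling == "st_merged":
        d["tissue_type"] = d["tissue_type"].replace(
            {"distal_normal": "normal", "proximal_normal": "normal",
             "tumor_epithelium": "t_s_merged", "stroma": "t_s_merged"})
    else:
        raise ValueError("pooling must be None, 'normal' or 'st_merged'")
    return d


def tissue_contrasts(data: pd.DataFrame, reference: str = "normal",
                     pooling: Optional[str] = "normal",
                     random_terms: tuple = ("patient", "map", "map_tissue"),
                     ) -> tuple[pd.DataFrame, MixedModelFit]:
    """Tissue-type contrasts with the full random structure.

    Fits tissue as fixed effect with patient, map, and map x tissue random
    intercepts; reports beta (log scale), SD (standard error), t and p per
    non-reference tissue. ``pooling='normal'`` merges distal and proximal
    normal epithelium into one reference group; ``'st_merged'`` also merges
    tumor epithelium with stroma for the mixed-zone comparison.
    """
    d = _pool_tissues(data, pooling)
    present = set(d["tissue_type"].unique())
    if reference not in present:
        raise ValueError(f"reference tissue {reference!r} absent from data")
    if len(present) < 2:
        raise ValueError("need at least two tissue types")
    spec = MixedModelSpec(fixed_terms=("tissue_type",),
                          random_terms=random_terms,
                          reference_levels={"tissue_type": reference})
    fit = fit_gamma_glmm(d, spec)
    rows = []
    for name in fit.params.index:
        if not name.startswith("tissue_type["):
            continue
        level = name[len("tissue_type["):-1]
        rows.append({"reference": reference, "tissue": level,
                     "beta": fit.params[name], "sd": fit.se[name],
                     "t": fit.t_values[name], "p": fit.p_values[name]})
    return pd.DataFrame(rows), fit


#: covariate -> (column builder, reference description) for the clinical scan
def _clinical_columns(merged: pd.DataFrame) -> dict:
    return {
        "sex_male": (merged["sex"] == "M", "ref = F"),
        "location_right": (merged["location"] == "right", "ref = Left"),
        "age": (merged["age"].astype(float), "per year"),
        "mucinous": (merged["mucinous"].astype(bool), "ref = no"),
        "lymphovascular": (merged["lymphovascular"].astype(bool),
                           "ref = no"),
        "perinervous": (merged["perinervous"].astype(bool), "ref = no"),
        "stage_late": (merged["stage"].isin(["III", "IV"]),
                       "III+IV vs I+II"),
        "kras": (merged["kras"].astype(bool), "ref = WT"),
        "nras": (merged["nras"].astype(bool), "ref = WT"),
        "ras": (merged["ras"].astype(bool), "ref = WT"),
        "braf": (merged["braf"].astype(bool), "ref = WT"),
        "ras_braf": (merged["ras"].astype(bool)
                     | merged["braf"].astype(bool), "ref = WT"),
        "mss": (merged["msi"] == "MSS", "ref = MSI"),
    }


def clinical_associations(data: pd.DataFrame, cohort: pd.DataFrame,
                          covariates: Optional[Sequence[str]] = None,
                          tumor_only: bool = True) -> pd.DataFrame:
    """Clinical/molecular covariates vs tumor tissue stiffness.

    Tumor epithelium, stroma and mixed-zone observations are merged; each
    covariate is tested in its own gamma GLMM (covariate fixed; patient and
    map random). Covariates constant across the analysed patients are
    skipped with a notice. ``n`` is the number of maps at the non-reference
    level (blank for the continuous age term).
    """
    d = data.copy()
    if tumor_only:
        d = d[d["tissue_type"].isin(TUMOR_TISSUES)]
    if d.empty:
        raise ValueError("no tumor-tissue observations to analyse")
    keep = [c for c in cohort.columns if c != "true_patient_effect"]
    merged = d[["patient_id", "map_id", "tissue_type", "E_kPa"]].merge(
        cohort[keep], on="patient_id", how="inner")
    builders = _clinical_columns(merged)
    if covariates is None:
        covariates = list(builders)
    rows = []
    for cov in covariates:
        if cov not in builders:
            raise KeyError(f"unknown covariate {cov!r}")
        col, ref = builders[cov]
        frame = merged.copy()
        frame[cov] = col.to_numpy()
        if frame.groupby("patient_id")[cov].first().nunique() < 2:
            rows.append({"covariate": cov, "reference": ref, "n_maps": 0,
                         "beta": np.nan, "p": np.nan,
                         "note": "constant across patients: skipped"})
            continue
        spec = MixedModelSpec(fixed_terms=(cov,),
                              random_terms=("patient", "map"))
        fit = fit_gamma_glmm(frame, spec)
        cname = f"{cov}[True]" if frame[cov].dtype == bool else cov
        if frame[cov].dtype == bool:
            n_maps = int(frame.loc[frame[cov], "map_id"].nunique())
        else:
            n_maps = int(frame["map_id"].nunique())
        rows.append({"covariate": cov, "reference": ref, "n_maps": n_maps,
                     "beta": float(fit.params[cname]),
                     "p": float(fit.p_values[cname]), "note": ""})
    return pd.DataFrame(rows, columns=["covariate", "reference", "n_maps",
                                       "beta", "p", "note"])


_CATEGORICAL_SUMMARY = [
    ("sex", {"Male": lambda d: d["sex"] == "M",
             "Female": lambda d: d["sex"] == "F"}),
    ("location", {"Right colon": lambda d: d["location"] == "right",
                  "Left colon": lambda d: d["location"] == "left"}),
    ("mucinous", {"Yes": lambda d: d["mucinous"].astype(bool),
                  "No": lambda d: ~d["mucinous"].astype(bool)}),
    ("lymphovascular", {"Yes": lambda d: d["lymphovascular"].astype(bool),
                        "No": lambda d: ~d["lymphovascular"].astype(bool)}),
    ("perinervous", {"Yes": lambda d: d["perinervous"].astype(bool),
                     "No": lambda d: ~d["perinervous"].astype(bool)}),
    ("stage", {s: (lambda d, s=s: d["stage"] == s)
               for s in ("I", "II", "III", "IV")}),
    ("msi", {"MSS": lambda d: d["msi"] == "MSS",
             "MSI": lambda d: d["msi"] == "MSI"}),
    ("mutation", {"KRAS mutated": lambda d: d["kras"].astype(bool),
                  "NRAS mutated": lambda d: d["nras"].astype(bool),
                  "BRAF mutated": lambda d: d["braf"].astype(bool),
                  "RAS mutated": lambda d: d["ras"].astype(bool)}),
]

_REQUIRED_COHORT_COLUMNS = ("patient_id", "sex", "age", "location",
                            "mucinous", "lymphovascular", "perinervous",
                            "stage", "msi", "kras", "nras", "braf", "ras")


def descriptive_summary(cohort: pd.DataFrame) -> dict:
    """Cohort descriptives: age statistics plus count/percentage per level.

    Returns ``{"age": DataFrame, "categorical": DataFrame}``. Percentages
    are over all patients; an empty level reports count 0 and 0%.
    """
    missing = [c for c in _REQUIRED_COHORT_COLUMNS
               if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table missing columns: {missing}")
    n = len(cohort)
    age = cohort["age"].astype(float)
    age_table = pd.DataFrame([
        {"statistic": "mean", "value": float(age.mean())},
        {"statistic": "sd", "value": float(age.std(ddof=1))
         if n > 1 else 0.0},
        {"statistic": "median", "value": float(age.median())},
        {"statistic": "min", "value": float(age.min())},
        {"statistic": "max", "value": float(age.max())},
    ])
    rows = []
    for var, levels in _CATEGORICAL_SUMMARY:
        for level, pred in levels.items():
            count = int(pred(cohort).sum())
            rows.append({"variable": var, "level": level, "count": count,
                         "percentage": 100.0 * count / n if n else 0.0})
    return {"age": age_table,
            "categorical": pd.DataFrame(rows, columns=["variable", "level",
                                                       "count",
                                                       "percentage"])}


def kras_among_ras_fraction(cohort: pd.DataFrame) -> float:
    """Share of RAS-mutated patients whose RAS hit is in KRAS (%)."""
    ras = cohort["ras"].astype(bool)
    if ras.sum() == 0:
        return float("nan")
    return 100.0 * float(cohort.loc[ras, "kras"].astype(bool).sum()) \
        / float(ras.sum())
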