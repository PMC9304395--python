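"""Stiffness-map assembly and vetting.

A force map is retained only when its valid (QC-passing) pixels cover the
mapped region densely enough. Coverage is summarized by the *distance
index*: the mean, over valid pixels, of the Euclidean distance to the
nearest other valid pixel (µm). A fully covered regular grid scores exactly
the pixel pitch; sparse maps score higher; maps above a threshold (default
8 µm for a 5 µm pitch) are discarded. A weighted one-way ANOVA checks that
coverage does not differ systematically between tissue types, which would
confound stiffness contrasts with map quality.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import f as f_dist


@dataclass
class StiffnessMap:
    """Gridded per-pixel Young's moduli (kPa) with a validity mask."""

    patient_id: str
    map_id: str
    slide_id: str
    probe_id: str
    tissue_type: str
    pitch_um: float
    values: np.ndarray  # kPa, NaN where invalid
    valid: np.ndarray   # bool mask
    coverage_index: Optional[float] = None  # µm
    retained: Optional[bool] = None
    exclusion_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if np.any(self.values[self.valid] <= 0):
            raise ValueError("valid stiffness values must be positive")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def pixel_coordinates_um(self) -> np.ndarray:
        """(n_valid, 2) physical coordinates of valid pixel centres, µm.

        Pixel-centred convention: coordinate = (index + 0.5) * pitch.
        """
        rows, cols = np.nonzero(self.valid)
        return np.column_stack([(cols + 0.5) * self.pitch_um,
                                (rows + 0.5) * self.pitch_um])


@dataclass
class CoverageResult:
    map_id: str
    index: float  # µm; NaN when undefined (n_valid <= 1)
    n_valid: int
    retained: bool


def sqrt_display(values: np.ndarray) -> np.ndarray:
    """Element-wise square root for a readable colour scale on gamma-ish
    stiffness data; NaN (invalid) pixels propagate unchanged."""
    values = np.asarray(values, dtype=float)
    if np.any(values[~np.isnan(values)] < 0):
        raise ValueError("stiffness values must be non-negative")
    return np.sqrt(values)


def coverage_index(smap: StiffnessMap,
                   threshold_um: float = 8.0) -> CoverageResult:
    """Mean nearest-neighbour distance among valid pixels, µm.

    Higher index = poorer coverage. With fewer than two valid pixels the
    index is undefined (NaN) and the map is not retained.
    """
    pts = smap.pixel_coordinates_um()
    n = len(pts)
    if n <= 1:
        result = CoverageResult(smap.map_id, float("nan"), n, False)
    else:
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=2)
        index = float(np.mean(dists[:, 1]))
        result = CoverageResult(smap.map_id, index, n,
                                bool(index <= threshold_um))
    smap.coverage_index = result.index
    smap.retained = result.retained
    return result


def filter_maps(maps: Sequence[StiffnessMap], threshold_um: float = 8.0
                ) -> tuple[list[StiffnessMap], pd.DataFrame]:
    """Retain maps whose coverage index is at or below the threshold.

    Returns the retained subset and a report of all maps (one row each:
    map_id, index_um, n_valid, retained). Idempotent.
    """
    rows, retained = [], []
    for smap in maps:
        res = coverage_index(smap, threshold_um=threshold_um)
        rows.append({"map_id": smap.map_id, "index_um": res.index,
                     "n_valid": res.n_valid, "retained": res.retained})
        if res.retained:
            retained.append(smap)
    report = pd.DataFrame(rows, columns=["map_id", "index_um", "n_valid",
                                         "retained"])
    return retained, report


def weighted_anova(y: np.ndarray, groups: np.ndarray,
                   weights: np.ndarray) -> tuple[float, float]:
    """Weighted one-way ANOVA (WLS F test of the group factor).

    Observation i has weight w_i (variance assumed proportional to 1/w_i).
    Returns (F, p) with numerator df = k-1 and denominator df = n-k.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    groups = np.asarray(groups)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    labels = pd.unique(groups)
    k, n = len(labels), len(y)
    if k < 2:
        raise ValueError("weighted ANOVA needs at least two groups")
    if n - k < 1:
        raise ValueError("not enough observations for the ANOVA")
    grand = float(np.sum(w * y) / np.sum(w))
    ssb = ssw = 0.0
    for g in labels:
        m = groups == g
        wg = w[m]
        mu_g = float(np.sum(wg * y[m]) / np.sum(wg))
        ssb += float(np.sum(wg)) * (mu_g - grand) ** 2
        ssw += float(np.sum(wg * (y[m] - mu_g) ** 2))
    df1, df2 = k - 1, n - k
    if ssw <= 0:
        F = 0.0 if ssb <= 0 else np.inf
    else:
        F = (ssb / df1) / (ssw / df2)
    p = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return float(F), p


def coverage_anova(maps: Sequence[StiffnessMap],
                   threshold_um: float = 8.0) -> tuple[float, float]:
    """Weighted ANOVA of the coverage index across tissue types, weighting
    each map by its number of valid pixels."""
    ys, gs, ws = [], [], []
    for smap in maps:
        res = coverage_index(smap, threshold_um=threshold_um)
        if np.isnan(res.index):
            continue
        ys.append(res.index)
        gs.append(smap.tissue_type)
        ws.append(res.n_valid)
    return weighted_anova(np.array(ys), np.array(gs), np.array(ws))


def plot_map(smap: StiffnessMap, path, sqrt_scale: bool = True):
    """Optional heatmap of one stiffness map (sqrt colour scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = sqrt_display(smap.values) if sqrt_scale else smap.values
    fig, ax = plt.subplots(figsize=(4, 4))
    side = smap.pitch_um * smap.values.shape[0]
    im = ax.imshow(data, origin="lower", extent=(0, side, 0, side),
                   cmap="viridis")
    label = r"$\sqrt{E}$ ($\sqrt{\mathrm{kPa}}$)" if sqrt_scale \
        else "E (kPa)"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"{smap.map_id} ({smap.tissue_type})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
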