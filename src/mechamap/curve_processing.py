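"""Raw force–distance curves -> per-curve Young's moduli with quality filters.

The processing chain for one approach curve is

    baseline_correct -> detect_contact_point -> compute_indentation
    -> fit_hertz -> qc_curve

and :func:`process_map` runs it over a grid of curves to build a stiffness
map. Only the approach segment is ever fitted; the retract segment is carried
along for completeness but ignored by the model.

Quality control implements three exclusion criteria:

1. *permanent contact* — the tip never leaves the surface, so no pre-contact
   baseline exists;
2. *ill-defined contact point* — the baseline is not flat over at least 2 µm
   before mechanical contact;
3. *too noisy* — the force-channel noise is comparable with the trigger
   force (operationalized as sd(pre-contact force) >= c * trigger).

Criterion 2 is only evaluated when criterion 1 does not apply, so each
failure mode maps to exactly one flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import AcquisitionConfig, QCConfig
from .physics import hertz_prefactor

logger = logging.getLogger(__name__)

APPROACH = "approach"
RETRACT = "retract"

#: noise floor (N) standing in for sd = 0 on noiseless synthetic curves
_NOISE_FLOOR = 1e-13
#: multiple of the noise sd a force excursion must exceed to count as contact
_DETECT_FACTOR = 5.0
#: consecutive samples that must stay above threshold ("persistently")
_PERSIST = 10
#: minimal pre-contact z-extent below which no baseline is deemed to exist
_MIN_PRECONTACT = 0.2e-6


@dataclass
class ForceCurve:
    """One indentation cycle: piezo height vs cantilever force.

    ``z`` increases toward the sample on the approach. Units are SI (m, N).
    """

    z: np.ndarray
    force: np.ndarray
    segment: np.ndarray  # per-sample label: "approach" | "retract"
    curve_id: str = ""
    grid_row: int = 0
    grid_col: int = 0
    metadata: Optional[AcquisitionConfig] = None
    truncated: bool = False

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (len(self.z) == len(self.force) == len(self.segment)):
            raise ValueError("z, force and segment must have equal length")
        app = self.segment == APPROACH
        if app.any() and not app[: int(app.sum())].all():
            raise ValueError("approach samples must precede retract samples")

    @property
    def approach(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == APPROACH
        return self.z[m], self.force[m]

    @property
    def retract(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == RETRACT
        return self.z[m], self.force[m]


@dataclass
class BaselineResult:
    curve: ForceCurve
    slope: float  # N per m
    intercept: float  # N
    window_n: int
    identifiable: bool


@dataclass
class ContactPoint:
    z0: float
    index: int
    found: bool
    permanent: bool
    flat_ok: bool
    pre_contact_span: float  # m of baseline travel before contact
    noise_sd: float  # noise level actually used, N


@dataclass
class HertzFit:
    """Least-squares Hertz fit of one approach curve."""

    E: float  # Pa
    z0: float  # m, refined contact point
    F0: float  # N, residual baseline offset
    rss: float  # N^2
    n_fit: int
    converged: bool
    reason: str = ""


@dataclass
class CurveQC:
    permanent_contact: bool
    ill_defined_contact: bool
    too_noisy: bool

    @property
    def passed(self) -> bool:
        return not (self.permanent_contact or self.ill_defined_contact
                    or self.too_noisy)


def estimate_noise_sd(force: np.ndarray, fraction: float = 0.25) -> float:
    """Robust per-curve noise estimate, N.

    Median absolute successive difference over the earliest ``fraction`` of
    the approach, scaled to a Gaussian sd (MAD of a difference of two i.i.d.
    normals). Floored at a tiny positive value so noiseless synthetic data
    stay well-defined.
    """
    n = max(int(len(force) * fraction), 8)
    d = np.diff(force[:n])
    if len(d) == 0:
        return _NOISE_FLOOR
    sd = np.median(np.abs(d)) / (0.6744897501960817 * np.sqrt(2.0))
    return max(float(sd), _NOISE_FLOOR)


def baseline_correct(curve: ForceCurve,
                     window_fraction: float = 0.3) -> BaselineResult:
    """Remove a straight-line baseline from the whole curve.

    Two-pass scheme: a line is first fitted to the earliest
    ``window_fraction`` of approach samples (the putative pre-contact
    region), the contact point is located on the corrected curve, and the
    line is refitted on the actual pre-contact window. The flag
    ``identifiable`` is lowered when no pre-contact window could be found;
    it feeds QC criterion 1 rather than raising.
    """
    z_app, f_app = curve.approach
    if len(z_app) < 4:
        return BaselineResult(curve, 0.0, 0.0, 0, False)

    def _fit_line(z, f):
        A = np.vstack([z, np.ones_like(z)]).T
        coef, *_ = np.linalg.lstsq(A, f, rcond=None)
        return coef[0], coef[1]

    n0 = max(int(len(z_app) * window_fraction), 4)
    slope, icept = _fit_line(z_app[:n0], f_app[:n0])
    f_corr = f_app - (slope * z_app + icept)
    noise = estimate_noise_sd(f_corr)
    cp = _locate_contact(z_app, f_corr, noise)
    identifiable = not cp.permanent
    if identifiable and cp.index >= 4:
        slope, icept = _fit_line(z_app[: cp.index], f_app[: cp.index])
    corrected = ForceCurve(
        z=curve.z,
        force=curve.force - (slope * curve.z + icept),
        segment=curve.segment,
        curve_id=curve.curve_id,
        grid_row=curve.grid_row,
        grid_col=curve.grid_col,
        metadata=curve.metadata,
        truncated=curve.truncated,
    )
    return BaselineResult(corrected, float(slope), float(icept),
                          int(min(n0, len(z_app))), identifiable)


def _locate_contact(z: np.ndarray, f: np.ndarray, noise_sd: float,
                    persist: int = _PERSIST) -> ContactPoint:
    thresh = _DETECT_FACTOR * max(noise_sd, _NOISE_FLOOR)
    above = f > thresh
    # first index from which `persist` consecutive samples stay above
    run = np.convolve(above.astype(int), np.ones(persist, dtype=int),
                      mode="valid")
    hits = np.nonzero(run == persist)[0]
    if len(hits) == 0:
        return ContactPoint(np.nan, -1, False, False, True,
                            float(z[-1] - z[0]), noise_sd)
    i = int(hits[0])
    span = float(z[i] - z[0])
    permanent = (i < 4) or (span < _MIN_PRECONTACT)
    return ContactPoint(float(z[i]), i, True, permanent, True, span, noise_sd)


def is_permanent_contact(z: np.ndarray, f: np.ndarray,
                         noise_sd: float) -> bool:
    """Shape-based permanent-contact test on a raw approach segment.

    The absolute force zero of an AFM channel is arbitrary, so permanent
    contact cannot be read off the force level; its signature is the
    absence of any flat start: the slope over the first 0.5 µm is already a
    sizeable fraction of the slope just before the trigger, and the rise
    over that initial window clearly exceeds the noise.
    """
    if len(z) < 8:
        return True  # no room for any baseline at all
    w = 0.5e-6

    def _slope(zi, fi):
        if len(zi) < 4:
            return None
        A = np.vstack([zi, np.ones_like(zi)]).T
        coef, *_ = np.linalg.lstsq(A, fi, rcond=None)
        return float(coef[0])

    m1 = z <= z[0] + w
    m2 = z >= z[-1] - w
    s1 = _slope(z[m1], f[m1])
    s2 = _slope(z[m2], f[m2])
    if s1 is None or s2 is None or s2 <= 0:
        return False
    rise = s1 * min(w, float(z[-1] - z[0]))
    return (rise > 3.0 * max(noise_sd, _NOISE_FLOOR)) and (s1 > 0.1 * s2)


def detect_contact_point(curve: ForceCurve,
                         noise_sd: Optional[float] = None,
                         qc: QCConfig = QCConfig()) -> ContactPoint:
    """Locate the contact point on a baseline-corrected approach segment.

    Scans toward the surface for the first force excursion that persistently
    exceeds a multiple of the noise sd. The returned z0 is a seed estimate;
    :func:`fit_hertz` refines it as a free parameter. The ``flat_ok`` flag
    implements the "flat over at least 2 µm before contact" requirement:
    the window must exist and its local slope must stay below
    ``flat_slope_factor * noise_sd`` per µm.

    A curve in permanent contact yields a sentinel (``permanent=True``)
    consumed by QC criterion 1, not an exception.
    """
    z, f = curve.approach
    if noise_sd is None:
        noise_sd = estimate_noise_sd(f)
    noise_sd = max(noise_sd, _NOISE_FLOOR)
    if is_permanent_contact(z, f, noise_sd):
        return ContactPoint(np.nan, -1, False, True, False, 0.0, noise_sd)
    cp = _locate_contact(z, f, noise_sd)
    if (not cp.found) or cp.permanent:
        return cp
    # On soft samples the threshold crossing sits well past true contact;
    # back-extrapolate with the F^(2/3) linearization so the flatness
    # window is measured from the mechanical contact, not the crossing.
    z0, index = _refine_contact(z, f, cp.index, noise_sd)
    span = float(z0 - z[0])
    cp = ContactPoint(z0, index, True, False, True, span, noise_sd)
    flat_ok = cp.pre_contact_span >= qc.flat_window
    if flat_ok:
        # slope of the trailing flat_window before contact
        lo = np.searchsorted(z, cp.z0 - qc.flat_window)
        zi, fi = z[lo:cp.index], f[lo:cp.index]
        if len(zi) >= 4:
            A = np.vstack([zi, np.ones_like(zi)]).T
            coef, *_ = np.linalg.lstsq(A, fi, rcond=None)
            slope_per_um = abs(coef[0]) * 1e-6  # N per µm
            n_win = len(zi)
            # sampling error of the slope estimate shrinks with the window
            allowed = qc.flat_slope_factor * noise_sd * max(
                1.0, 3.5 / np.sqrt(n_win))
            flat_ok = slope_per_um < allowed
    return ContactPoint(cp.z0, cp.index, True, False, bool(flat_ok),
                        cp.pre_contact_span, noise_sd)


def _refine_contact(z: np.ndarray, f: np.ndarray, i_cross: int,
                    noise_sd: float) -> tuple[float, int]:
    """Back-extrapolated contact estimate from the low-force Hertz branch:
    F^(2/3) is linear in z near contact, so its z-intercept locates z0."""
    fmax = float(f[i_cross:].max(initial=0.0))
    lo_f = _DETECT_FACTOR * max(noise_sd, _NOISE_FLOOR)
    hi_f = max(0.5 * fmax, 2 * lo_f)
    sel = np.zeros(len(f), dtype=bool)
    sel[i_cross:] = (f[i_cross:] > lo_f) & (f[i_cross:] <= hi_f)
    if sel.sum() >= 5:
        u = f[sel] ** (2.0 / 3.0)
        A = np.vstack([z[sel], np.ones(sel.sum())]).T
        coef, *_ = np.linalg.lstsq(A, u, rcond=None)
        if coef[0] > 0:
            z0 = float(-coef[1] / coef[0])
            z0 = float(np.clip(z0, z[i_cross] - 1.0e-6, z[i_cross]))
            return z0, int(np.searchsorted(z, z0))
    return float(z[i_cross]), i_cross


def compute_indentation(curve: ForceCurve, z0: float,
                        k: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert (z, F) to (indentation delta, F) for post-contact samples.

    delta = (z - z0) - F/k, clipped to >= 0, ordered by increasing delta.
    """
    if k <= 0:
        raise ValueError("spring constant k must be positive")
    z, f = curve.approach
    m = z >= z0
    delta = (z[m] - z0) - f[m] / k
    delta = np.clip(delta, 0.0, None)
    order = np.argsort(delta, kind="stable")
    return delta[order], f[m][order]


def fit_hertz(delta: np.ndarray, force: np.ndarray, R: float, nu: float,
              delta_max: Optional[float] = None, z0_init: float = 0.0,
              min_samples: int = 5) -> HertzFit:
    """Least-squares Hertz fit over delta in (0, delta_max].

    Jointly refines (E, contact-point shift, force offset F0); the reported
    ``z0`` is ``z0_init`` plus the fitted shift. Samples beyond ``delta_max``
    (default: caller passes 10% of section thickness) are excluded so the
    rigid-substrate contribution stays negligible.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    if delta_max is None:
        delta_max = np.inf
    sel = (delta > 0) & (delta <= delta_max)  # window open at zero depth
    d, f = delta[sel], force[sel]
    if len(d) < min_samples:
        return HertzFit(0.0, z0_init, 0.0, np.nan, int(len(d)), False,
                        "fewer than %d usable samples" % min_samples)

    shape = np.sqrt(R) * (4.0 / 3.0) / (1.0 - nu**2)
    span = max(float(d.max()), 1e-9)
    E0, dz0 = _hertz_seed(d, f, shape)

    def resid(p):
        E, dz, F0 = p
        de = np.clip(d - dz, 0.0, None)
        return shape * E * de**1.5 + F0 - f

    res = least_squares(
        resid, x0=np.array([E0, dz0, 0.0]),
        bounds=([0.0, -span, -np.inf], [np.inf, 0.5 * span, np.inf]),
        method="trf", ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    E_hat, dz_hat, F0_hat = res.x
    flagged = ""
    if E_hat < 0:
        E_hat, flagged = 0.0, "negative modulus clipped to 0"
    return HertzFit(float(E_hat), float(z0_init + dz_hat), float(F0_hat),
                    float(np.sum(res.fun**2)), int(len(d)),
                    bool(res.success), flagged or ("" if res.success else
                                                  res.message))


def _hertz_seed(d: np.ndarray, f: np.ndarray,
                shape: float) -> tuple[float, float]:
    """Initial (E, contact shift) from the 2/3-power linearization:
    F^{2/3} = (shape*E)^{2/3} * (delta - dz), fitted on the upper part of
    the force range where noise matters least."""
    fmax = float(np.max(f))
    sel = f > 0.2 * fmax if fmax > 0 else np.zeros(len(f), dtype=bool)
    if sel.sum() >= 3:
        u = f[sel] ** (2.0 / 3.0)
        A = np.vstack([d[sel], np.ones(sel.sum())]).T
        coef, *_ = np.linalg.lstsq(A, u, rcond=None)
        slope, icept = coef
        if slope > 0:
            span = max(float(d.max()), 1e-9)
            dz0 = float(np.clip(-icept / slope, -0.9 * span, 0.4 * span))
            E0 = float(slope**1.5 / shape)
            return max(E0, 1e-3), dz0
    x = d**1.5
    denom = float(x @ x)
    E0 = max(float(x @ f) / denom / shape, 1e-3) if denom > 0 else 1.0
    return E0, 0.0


def qc_curve(curve: ForceCurve, contact: ContactPoint,
             trigger: float, qc: QCConfig = QCConfig()) -> CurveQC:
    """Apply the three exclusion criteria to a baseline-corrected curve.

    1. permanent contact  <=> no pre-contact window exists;
    2. ill-defined contact <=> a window exists but the flat stretch is
       shorter than the 2 µm requirement (evaluated only when 1 is false);
    3. too noisy          <=> sd(pre-contact force) >= c * trigger.
    """
    permanent = (not contact.found and _is_everywhere_loaded(curve)) \
        or contact.permanent
    ill_defined = False
    if not permanent and contact.found:
        ill_defined = not contact.flat_ok
    too_noisy = False
    z, f = curve.approach
    if contact.found and not permanent:
        pre = f[: contact.index]
    else:
        pre = f
    if len(pre) >= 4:
        too_noisy = bool(np.std(pre, ddof=1) >= qc.noise_factor_c * trigger)
    return CurveQC(bool(permanent), bool(ill_defined), bool(too_noisy))


def _is_everywhere_loaded(curve: ForceCurve) -> bool:
    """True when the force channel never returns to baseline (monotone,
    nonzero force everywhere) — the permanent-contact signature when no
    threshold crossing could even be located."""
    _, f = curve.approach
    if len(f) == 0:
        return False
    return bool(np.min(f) > 0)


@dataclass
class ProcessedCurve:
    curve_id: str
    grid_row: int
    grid_col: int
    fit: HertzFit
    qc: CurveQC
    baseline: BaselineResult
    contact: ContactPoint


def process_curve(curve: ForceCurve, config: AcquisitionConfig,
                  qc: QCConfig = QCConfig(),
                  delta_max: Optional[float] = None) -> ProcessedCurve:
    """Run the full chain on a single curve."""
    if delta_max is None:
        delta_max = config.delta_max
    z_raw, f_raw = curve.approach
    noise_raw = estimate_noise_sd(f_raw)
    base = baseline_correct(curve)
    if is_permanent_contact(z_raw, f_raw, noise_raw):
        # baseline subtraction would mask the signature; decide on raw data
        contact = ContactPoint(np.nan, -1, False, True, False, 0.0,
                               noise_raw)
    else:
        contact = detect_contact_point(base.curve, qc=qc)
    if contact.found and not contact.permanent:
        delta, force = compute_indentation(base.curve, contact.z0,
                                           config.spring_constant)
        fit = fit_hertz(delta, force, config.bead_radius,
                        config.poisson_ratio, delta_max=delta_max,
                        z0_init=contact.z0, min_samples=qc.min_fit_samples)
    else:
        fit = HertzFit(0.0, np.nan, 0.0, np.nan, 0, False,
                       "no contact point")
    verdict = qc_curve(base.curve, contact, config.force_trigger, qc=qc)
    return ProcessedCurve(curve.curve_id, curve.grid_row, curve.grid_col,
                          fit, verdict, base, contact)


def process_map(curves: Sequence[ForceCurve], config: AcquisitionConfig,
                qc: QCConfig = QCConfig(),
                delta_max: Optional[float] = None,
                patient_id: str = "", map_id: str = "", slide_id: str = "",
                probe_id: str = "", tissue_type: str = ""):
    """Process all curves of one force map into a StiffnessMap (values kPa).

    A pixel is valid when its curve passes QC and the fit converged.
    Duplicate grid indices: the latest curve wins (logged). Returns the map
    plus the list of per-curve results.
    """
    from .map_qc import StiffnessMap  # local import: keeps modules acyclic

    n = config.grid_n
    values = np.full((n, n), np.nan)
    valid = np.zeros((n, n), dtype=bool)
    seen: dict[tuple[int, int], str] = {}
    counts = {"clean": 0, "permanent_contact": 0, "ill_defined_contact": 0,
              "too_noisy": 0, "non_converged": 0}
    results = []
    for curve in curves:
        r, c = curve.grid_row, curve.grid_col
        if not (0 <= r < n and 0 <= c < n):
            raise ValueError(f"grid index ({r},{c}) outside {n}x{n} grid")
        if (r, c) in seen:
            logger.warning("duplicate grid index (%d,%d): curve %s replaces "
                           "%s", r, c, curve.curve_id, seen[(r, c)])
        seen[(r, c)] = curve.curve_id
        pc = process_curve(curve, config, qc=qc, delta_max=delta_max)
        results.append(pc)
        if pc.qc.permanent_contact:
            counts["permanent_contact"] += 1
        elif pc.qc.ill_defined_contact:
            counts["ill_defined_contact"] += 1
        elif pc.qc.too_noisy:
            counts["too_noisy"] += 1
        elif not pc.fit.converged:
            counts["non_converged"] += 1
        else:
            counts["clean"] += 1
        ok = pc.qc.passed and pc.fit.converged
        values[r, c] = pc.fit.E / 1000.0 if ok else np.nan  # Pa -> kPa
        valid[r, c] = ok
    smap = StiffnessMap(
        patient_id=patient_id, map_id=map_id, slide_id=slide_id,
        probe_id=probe_id, tissue_type=tissue_type,
        pitch_um=config.pitch * 1e6, values=values, valid=valid,
        exclusion_counts=counts,
    )
    return smap, results
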