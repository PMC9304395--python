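"""Acquisition and run configuration.

All physical quantities are stored in SI units (m, N, N/m, s). Helper
properties expose the derived geometry (bead radius, grid pitch, fit window).
File formats at the package boundary use human-scale units (nm, pN, µm, kPa);
conversion happens in :mod:`mechamap.io`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

#: tolerance on the incompressibility bound for the Poisson ratio
_NU_TOL = 1e-9


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument and protocol settings for one force-map acquisition.

    Defaults mirror a colloidal-probe AFM protocol for soft tissue sections:
    a 10.2 µm silica bead on a soft cantilever (0.15–0.24 N/m), 2 nN force
    trigger, 2 µm/s ramps of up to 50 µm, a 10 × 10 grid over 50 × 50 µm, and
    20 µm thick sections so that indentation is capped at 10% of thickness.

    Parameters
    ----------
    bead_diameter : float
        Colloidal bead diameter, m.
    spring_constant : float
        Calibrated cantilever spring constant k, N/m.
    force_trigger : float
        Maximum (setpoint) force terminating the approach ramp, N.
    approach_speed : float
        Piezo loading rate, m/s.
    max_ramp : float
        Maximum piezo travel of one indentation cycle, m.
    grid_n : int
        Pixels per side of the square force map.
    map_side : float
        Physical side length of the mapped region, m.
    section_thickness : float
        Tissue section thickness, m; the default fit window is 10% of it.
    poisson_ratio : float
        Poisson ratio ν of the sample (0.5 = incompressible).
    sample_spacing : float
        z-distance between consecutive samples along the ramp, m.
    noise_sd : float
        Standard deviation of additive Gaussian force noise, N.
    pre_contact_travel : float
        Baseline (non-contact) travel simulated before the contact point on a
        clean curve, m. Must exceed the 2 µm flatness window used by QC.
    """

    bead_diameter: float = 10.2e-6
    spring_constant: float = 0.2
    force_trigger: float = 2e-9
    approach_speed: float = 2e-6
    max_ramp: float = 50e-6
    grid_n: int = 10
    map_side: float = 50e-6
    section_thickness: float = 20e-6
    poisson_ratio: float = 0.5
    sample_spacing: float = 5e-9
    noise_sd: float = 20e-12
    pre_contact_travel: float = 6e-6

    def __post_init__(self) -> None:
        positive = (
            "bead_diameter", "spring_constant", "force_trigger",
            "approach_speed", "max_ramp", "map_side", "section_thickness",
            "sample_spacing", "pre_contact_travel",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if not (0.0 <= self.poisson_ratio < 0.5 + _NU_TOL):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def bead_radius(self) -> float:
        """Indenter radius R, m."""
        return self.bead_diameter / 2.0

    @property
    def pitch(self) -> float:
        """Distance between adjacent pixel centres, m (pixel-centred grid)."""
        return self.map_side / self.grid_n

    @property
    def delta_max(self) -> float:
        """Default Hertz fit window: 10% of the section thickness, m."""
        return 0.1 * self.section_thickness

    def replace(self, **kwargs) -> "AcquisitionConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class QCConfig:
    """Constants operationalizing the three curve-exclusion criteria and the
    map-coverage filter.

    ``noise_factor_c`` turns "noise comparable with the trigger force" into
    the decision rule ``sd(pre-contact force) >= c * trigger``. ``flat_window``
    is the minimum flat pre-contact stretch required for a well-defined
    contact point. ``coverage_threshold`` is the retention bound on the mean
    nearest-neighbour distance index (µm semantics: stored in m here).
    """

    noise_factor_c: float = 0.25
    flat_window: float = 2e-6
    flat_slope_factor: float = 2.0
    coverage_threshold_um: float = 8.0
    min_fit_samples: int = 5

    def __post_init__(self) -> None:
        if self.noise_factor_c <= 0:
            raise ValueError("noise_factor_c must be positive")
        if self.flat_window <= 0:
            raise ValueError("flat_window must be positive")
        if self.coverage_threshold_um <= 0:
            raise ValueError("coverage_threshold_um must be positive")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    seed: int = 0
    n_patients: int = 4
    maps_per_patient: int = 2
    artifact_fraction: float = 0.0
    spacing_mode: str = "centered"  # or "endpoint": pitch = side/(n-1)
    delta_max: Optional[float] = None  # override of acquisition.delta_max, m

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["acquisition"] = AcquisitionConfig(**d.get("acquisition", {}))
        d["qc"] = QCConfig(**d.get("qc", {}))
        return cls(**d)
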