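"""Core data containers shared across the pipeline.

Conventions
-----------
* Force curves store piezo position and cantilever deflection in nanometres
  (the table dialect's units); analysis code converts to SI internally.
* The approach segment is stored with strictly increasing piezo z (probe
  moving towards the sample); the withdrawal segment is stored in
  acquisition order, i.e. strictly decreasing z.
* Force is always ``k * deflection`` (cantilever spring constant times
  deflection), so the deflection column fully determines the force column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

AGE_LEVELS = ("young", "aged")
VOLUME_LEVELS = ("RV", "FV")


@dataclass
class ForceCurve:
    """One indentation record: approach + withdrawal segments plus probe constants.

    Attributes
    ----------
    z_app_nm, defl_app_nm : approach-segment piezo position / deflection (nm).
    z_ret_nm, defl_ret_nm : withdrawal segment in acquisition order (z decreasing).
    k : cantilever spring constant (N/m).
    R_um : indenter bead radius (µm).
    metadata : free-form key/value pairs (ramp speed, sample labels, ...).
    """

    curve_id: str
    z_app_nm: np.ndarray
    defl_app_nm: np.ndarray
    z_ret_nm: np.ndarray
    defl_ret_nm: np.ndarray
    k: float
    R_um: float
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_app_nm = np.asarray(self.z_app_nm, dtype=float)
        self.defl_app_nm = np.asarray(self.defl_app_nm, dtype=float)
        self.z_ret_nm = np.asarray(self.z_ret_nm, dtype=float)
        self.defl_ret_nm = np.asarray(self.defl_ret_nm, dtype=float)

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError(f"{self.curve_id}: spring constant k must be > 0, got {self.k}")
        if self.R_um <= 0:
            raise ValueError(f"{self.curve_id}: bead radius R must be > 0, got {self.R_um}")
        for name, z, d in (
            ("approach", self.z_app_nm, self.defl_app_nm),
            ("withdrawal", self.z_ret_nm, self.defl_ret_nm),
        ):
            if z.size == 0:
                raise ValueError(f"{self.curve_id}: empty {name} segment")
            if z.shape != d.shape:
                raise ValueError(f"{self.curve_id}: {name} z/deflection length mismatch")
        if not np.all(np.diff(self.z_app_nm) > 0):
            raise ValueError(f"{self.curve_id}: approach z must be strictly increasing")
        if not np.all(np.diff(self.z_ret_nm) < 0):
            raise ValueError(f"{self.curve_id}: withdrawal z must be strictly decreasing")

    # SI accessors used by the mechanics code --------------------------------
    @property
    def R_m(self) -> float:
        return self.R_um * 1e-6

    def force_app_N(self) -> np.ndarray:
        return self.k * self.defl_app_nm * 1e-9

    def force_ret_N(self) -> np.ndarray:
        return self.k * self.defl_ret_nm * 1e-9

    def z_app_m(self) -> np.ndarray:
        return self.z_app_nm * 1e-9

    def z_ret_m(self) -> np.ndarray:
        return self.z_ret_nm * 1e-9


@dataclass
class CurveGroundTruth:
    """True generative parameters stored alongside each synthetic curve."""

    curve_id: str
    E_true: float            # Pa
    z0_true: float           # m, contact point in piezo coordinates
    nu: float
    k: float                 # N/m
    R: float                 # m
    adhesion_depth: float    # N
    adhesion_center: float   # m (piezo z of the pull-off well minimum)
    adhesion_width: float    # m
    hysteresis_factor: float
    baseline_slope: float    # N/m
    noise_sd: float          # N
    seed_key: tuple[int, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["seed_key"] = list(self.seed_key)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "CurveGroundTruth":
        d = json.loads(s)
        d["seed_key"] = tuple(d.get("seed_key", ()))
        return cls(**d)


@dataclass
class CurveRecord:
    """One curve within the replicate -> point -> region -> sample nesting."""

    sample: str
    region: int
    point: int
    replicate: int
    curve: ForceCurve
    truth: CurveGroundTruth | None = None


@dataclass
class CurveBatch:
    """All curves measured on one sample, with its group labels."""

    sample: str
    records: list[CurveRecord]
    age: str | None = None
    volume: str | None = None

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IndentationResult:
    """Hertz-fit output for a single curve."""

    curve_id: str
    z0: float                 # m
    baseline_offset: float    # N
    baseline_slope: float     # N/m
    E: float                  # Pa
    nu_assumed: float
    r_squared: float
    fit_range: tuple[float, float]  # indentation interval used (m)
    n_fit_points: int
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class ViscosityIndex:
    """Approach/withdrawal hysteresis ratio, a dimensionless viscous-dissipation proxy."""

    curve_id: str
    hysteresis_ratio: float
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class AdhesionMeasure:
    """Magnitude of the most negative baseline-corrected withdrawal force."""

    curve_id: str
    F_adh_nN: float


@dataclass
class IntensityProfile:
    """KDE summary of one single-channel image's pixel intensities."""

    kde_grid: np.ndarray
    density: np.ndarray
    peak_intensity: float
    weak_area: float
    intense_area: float
    activated_fraction: float
    thresholds: tuple[float, float]
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class NucleusRegion:
    label: int
    area: float
    major_axis_length: float
    centroid: tuple[float, float]
    equivalent_diameter: float


@dataclass
class CellQuantResult:
    """Per-field cell quantification: nuclei count, Ki67 fraction, viability."""

    field_id: str
    n_nuclei: int
    n_ki67_pos: int
    ki67_fraction: float | None   # percent; None when n_nuclei == 0
    n_live: int
    n_dead: int
    viability: float | None       # percent; None when live + dead == 0


@dataclass
class GroupSummary:
    group: Any
    n: int
    mean: float
    se: float | None   # None when n == 1


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False
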