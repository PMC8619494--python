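"""Fixed-intercept nSSC calibration and the size-dependent slope model.

The calibration rests on one physical anchor: an unexposed control has
nSSC = 1 and zero cell-associated particles, so every per-size calibration
line is forced through (nSSC, c-Ag) = (1, 0):

    c-Ag = m_d · (nSSC − 1)

The forced-origin least-squares slope has the closed form
m = Σ xᵢyᵢ / Σ xᵢ² with xᵢ = nSSCᵢ − 1 and yᵢ = c-Agᵢ.

Per-size slopes fall steeply with core diameter — small particles are taken
up in larger numbers but each scatters less — and are summarized by a
three-parameter exponential,

    m(d) = a + b·e^(−k·d)

which merges the per-size lines into a single size-aware estimator
c-Ag = m(d)·(nSSC − 1). Published coefficients for bPEI-coated silver
nanoparticles (40–200 nm) on A549 cells are packaged as
:data:`AG_BPEI_A549_SLOPES` and :data:`AG_BPEI_A549_SIZE_MODEL`.

A note on R² for a forced-intercept fit: there is no universally agreed
definition. This package uses the centered convention
R² = 1 − SS_res/Σ(y − ȳ)², which is the most conservative (it can be
negative when the forced line fits worse than the mean).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .cytometry import ExposureCondition
from .errors import (
    CoverageError,
    DegenerateRegressorError,
    DomainError,
    FitFailureError,
    IdentifiabilityError,
)

#: Published per-size calibration slopes (particles/cell per unit nSSC) for
#: bPEI-coated Ag nanoparticles on A549 cells, keyed by core diameter in nm.
AG_BPEI_A549_SLOPES: dict[float, float] = {
    40.0: 9423.0,
    60.0: 2301.0,
    80.0: 967.0,
    100.0: 204.0,
    200.0: 159.0,
}

#: Default ceiling of the validated working range of the method.
MAX_CALIBRATED_NSSC = 23.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One paired (nSSC, c-Ag) observation."""

    nssc: float
    c_ag: float
    condition: ExposureCondition | None = None
    split: str = "train"  # "train" | "validation"

    def __post_init__(self) -> None:
        if self.nssc <= 0:
            raise DomainError(f"nssc must be > 0, got {self.nssc}")
        if self.c_ag < 0:
            raise DomainError(f"c_ag must be >= 0, got {self.c_ag}")
        if self.split not in ("train", "validation"):
            raise DomainError(f"split must be train|validation, got {self.split!r}")

    @property
    def core_diameter(self) -> float | None:
        return self.condition.core_diameter if self.condition else None


@dataclass(frozen=True)
class SizeCalibration:
    """Fitted fixed-intercept line for one core diameter."""

    core_diameter: float
    slope: float  # particles/cell per unit nSSC
    r_squared: float  # may be NaN (undefined) or negative
    n_points: int


@dataclass(frozen=True)
class SlopeSizeModel:
    """Exponential slope-vs-diameter model m(d) = a + b·e^(−k·d).

    ``a`` is the large-diameter asymptote, ``b`` the amplitude at d = 0 and
    ``k`` the decay rate (1/nm). With b, k > 0 the slope is strictly
    decreasing in diameter with limit ``a``.
    """

    a: float
    b: float
    k: float
    rss: float = float("nan")  # residual sum of squares of the fit

    def slope(self, diameter: float) -> float:
        if diameter <= 0:
            raise DomainError(f"diameter must be > 0, got {diameter}")
        return self.a + self.b * math.exp(-self.k * diameter)


#: Published coefficients of the exponential size model for bPEI-Ag on A549.
AG_BPEI_A549_SIZE_MODEL = SlopeSizeModel(a=199.0, b=161933.0, k=0.072)


@dataclass(frozen=True)
class EstimationResult:
    """A c-Ag estimate from a single nSSC value."""

    nssc: float
    c_ag_est: float
    model_used: str  # "per_size" | "combined"
    core_diameter: float | None = None
    sub_control: bool = False  # nssc < 1 → negative estimate, flagged
    out_of_domain: bool = False  # nssc above the calibrated range


def _xy(points: Sequence[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.nssc - 1.0 for p in points], dtype=float)
    y = np.array([p.c_ag for p in points], dtype=float)
    return x, y


def fit_size_calibration(
    points: Sequence[CalibrationPoint], diameter: float
) -> SizeCalibration:
    """Least-squares slope of c-Ag on (nSSC − 1), forced through (1, 0).

    All points must share ``diameter`` (when their conditions carry one);
    at least one point must have nSSC ≠ 1, otherwise the regressor is
    degenerate.
    """
    if not points:
        raise DegenerateRegressorError("no calibration points")
    for p in points:
        if p.core_diameter is not None and p.core_diameter != diameter:
            raise DomainError(
                f"point with diameter {p.core_diameter} nm in a {diameter} nm fit"
            )
    x, y = _xy(points)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateRegressorError(
            "all points sit at nSSC = 1; the forced-origin slope is undefined"
        )
    slope = float(x @ y) / sxx
    r2 = r_squared_forced(points, slope) if len(points) >= 2 else float("nan")
    return SizeCalibration(
        core_diameter=diameter, slope=slope, r_squared=r2, n_points=len(points)
    )


def r_squared_forced(points: Sequence[CalibrationPoint], slope: float) -> float:
    """Centered R² of the forced-intercept line c-Ag = slope·(nSSC − 1).

    Returns 1 − SS_res/SS_tot with SS_tot about the mean of y. Can be
    negative. When all y are equal, SS_tot = 0 and R² is undefined: NaN is
    returned as a sentinel rather than raising.
    """
    if len(points) < 2:
        raise DomainError("R² needs at least two points")
    x, y = _xy(points)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_slope_size_model(
    calibrations: Iterable[SizeCalibration],
    k_starts: Sequence[float] = tuple(np.linspace(0.01, 0.2, 20)),
) -> SlopeSizeModel:
    """Fit m(d) = a + b·e^(−k·d) to per-size slopes by multi-start least squares.

    The joint (b, k) objective is nearly flat along a ridge, so a single
    local fit is unreliable: Levenberg–Marquardt is launched from a grid of
    decay rates k, with a ∈ {0, min slope} and b solved from the
    smallest-diameter point at each start. The best converged solution (the
    one whose residual sum of squares is no worse than every start) is
    returned. Unweighted: every per-size slope counts equally.
    """
    cals = sorted(calibrations, key=lambda c: c.core_diameter)
    d = np.array([c.core_diameter for c in cals], dtype=float)
    s = np.array([c.slope for c in cals], dtype=float)
    if len(np.unique(d)) < 3:
        raise IdentifiabilityError(
            f"need >= 3 distinct diameters to identify (a, b, k), got {np.unique(d)}"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, k = theta
        return a + b * np.exp(-k * d) - s

    best = None
    s_min = float(s.min())
    for k0 in k_starts:
        for a0 in (0.0, s_min):
            b0 = (s[0] - a0) / math.exp(-k0 * d[0])
            if b0 <= 0:
                b0 = max(s[0], 1.0)
            try:
                sol = least_squares(
                    residuals, x0=[a0, b0, k0], method="lm", max_nfev=20_000
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError(
            f"exponential size-model fit failed from all {2 * len(k_starts)} "
            f"starts (diameters {d.tolist()}, slopes {s.tolist()})"
        )
    a, b, k = (float(v) for v in best.x)
    return SlopeSizeModel(a=a, b=b, k=k, rss=float(2.0 * best.cost))


def combined_slope(model: SlopeSizeModel, diameter: float) -> float:
    """Evaluate the size model: a + b·e^(−k·diameter)."""
    return model.slope(diameter)


def estimate_c_ag(
    nssc: float,
    slope: float,
    core_diameter: float | None = None,
    model_used: str = "per_size",
    max_nssc: float = MAX_CALIBRATED_NSSC,
    clamp: bool = False,
) -> EstimationResult:
    """Estimate c-Ag = slope·(nSSC − 1) particles/cell.

    nSSC < 1 yields a negative estimate; it is returned as-is but flagged
    ``sub_control`` (clamping would bias downstream averages; pass
    ``clamp=True`` to floor at zero for reporting). nSSC above ``max_nssc``
    is flagged ``out_of_domain`` — the calibration was never exercised there.
    """
    if nssc <= 0:
        raise DomainError(f"nssc must be > 0, got {nssc}")
    if slope <= 0:
        raise DomainError(f"slope must be > 0, got {slope}")
    est = slope * (nssc - 1.0)
    sub = nssc < 1.0
    if clamp and sub:
        est = 0.0
    return EstimationResult(
        nssc=nssc,
        c_ag_est=est,
        model_used=model_used,
        core_diameter=core_diameter,
        sub_control=sub,
        out_of_domain=nssc > max_nssc,
    )


@dataclass
class CalibrationModel:
    """A full calibration artifact: per-size lines plus the size model."""

    per_size: dict[float, SizeCalibration] = field(default_factory=dict)
    size_model: SlopeSizeModel | None = None

    @classmethod
    def fit(
        cls, points: Sequence[CalibrationPoint], fit_size_model: bool = True
    ) -> "CalibrationModel":
        """Group training points by core diameter and fit everything.

        Points pool all configurations and media heights into one line per
        size; only points whose condition carries a diameter participate.
        """
        by_d: dict[float, list[CalibrationPoint]] = {}
        for p in points:
            if p.core_diameter is None:
                raise DomainError("calibration points need a condition with a diameter")
            by_d.setdefault(p.core_diameter, []).append(p)
        per_size = {
            d: fit_size_calibration(pts, d) for d, pts in sorted(by_d.items())
        }
        size_model = None
        if fit_size_model and len(per_size) >= 3:
            size_model = fit_slope_size_model(per_size.values())
        return cls(per_size=per_size, size_model=size_model)

    def slope_for(self, diameter: float, mode: str = "per_size") -> float:
        if mode == "per_size":
            if diameter not in self.per_size:
                raise CoverageError(
                    f"no per-size calibration at {diameter} nm; "
                    f"calibrated sizes: {sorted(self.per_size)}"
                )
            return self.per_size[diameter].slope
        if mode == "combined":
            if self.size_model is None:
                raise CoverageError("no size model fitted")
            return self.size_model.slope(diameter)
        raise DomainError(f"mode must be per_size|combined, got {mode!r}")

    def estimate(
        self, nssc: float, diameter: float, mode: str = "per_size", **kwargs
    ) -> EstimationResult:
        slope = self.slope_for(diameter, mode)
        return estimate_c_ag(
            nssc, slope, core_diameter=diameter, model_used=mode, **kwargs
        )

    def to_dict(self) -> dict:
        from . import __version__

        out: dict = {
            "per_size": [
                {
                    "core_diameter_nm": c.core_diameter,
                    "slope": c.slope,
                    "r_squared": None if math.isnan(c.r_squared) else c.r_squared,
                    "n_points": c.n_points,
                }
                for c in self.per_size.values()
            ],
            "size_model": None,
            "software_version": __version__,
        }
        if self.size_model is not None:
            out["size_model"] = {
                "a": self.size_model.a,
                "b": self.size_model.b,
                "k": self.size_model.k,
                "rss": None
                if math.isnan(self.size_model.rss)
                else self.size_model.rss,
            }
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        blob = json.loads(Path(path).read_text())
        per_size = {
            row["core_diameter_nm"]: SizeCalibration(
                core_diameter=row["core_diameter_nm"],
                slope=row["slope"],
                r_squared=float("nan")
                if row["r_squared"] is None
                else row["r_squared"],
                n_points=row["n_points"],
            )
            for row in blob["per_size"]
        }
        size_model = None
        if blob.get("size_model"):
            sm = blob["size_model"]
            size_model = SlopeSizeModel(
                a=sm["a"],
                b=sm["b"],
                k=sm["k"],
                rss=float("nan") if sm.get("rss") is None else sm["rss"],
            )
        return cls(per_size=per_size, size_model=size_model)


def reference_model() -> CalibrationModel:
    """The packaged published calibration for bPEI-Ag nanoparticles on A549."""
    per_size = {
        d: SizeCalibration(
            core_diameter=d, slope=m, r_squared=float("nan"), n_points=0
        )
        for d, m in AG_BPEI_A549_SLOPES.items()
    }
    return CalibrationModel(per_size=per_size, size_model=AG_BPEI_A549_SIZE_MODEL)


__all__ = [
    "AG_BPEI_A549_SIZE_MODEL",
    "AG_BPEI_A549_SLOPES",
    "MAX_CALIBRATED_NSSC",
    "CalibrationModel",
    "CalibrationPoint",
    "EstimationResult",
    "SizeCalibration",
    "SlopeSizeModel",
    "combined_slope",
    "estimate_c_ag",
    "fit_size_calibration",
    "fit_slope_size_model",
    "r_squared_forced",
    "reference_model",
]
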