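"""Train/validation splitting, RMSE, and the outlier-size exclusion workflow.

Validation compares ICPMS-measured c-Ag against the value estimated from
nSSC alone, per point, and condenses the deviation into a root-mean-squared
error. Two estimation modes are compared: ``per_size`` (each diameter uses
its own fitted line) and ``combined`` (one size-aware exponential model for
all diameters). A diameter whose group RMSE is grossly out of line with the
others — the hallmark of anomalous agglomeration, seen for 40 nm particles —
can be excluded; inclusive and exclusive RMSEs are always reported side by
side so exclusion never hides data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationModel, CalibrationPoint
from .cytometry import ExposureCondition
from .errors import DomainError, EmptySampleError, ShapeError, SplitError


@dataclass(frozen=True)
class ValidationPair:
    measured: float  # particles/cell, from ICPMS
    estimated: float  # particles/cell, from nSSC
    condition: ExposureCondition | None = None
    excluded: bool = False

    @property
    def core_diameter(self) -> float | None:
        return self.condition.core_diameter if self.condition else None


@dataclass
class ValidationReport:
    """Measured-vs-estimated comparison for one model/mode.

    ``rmse`` is computed after dropping excluded diameters; ``rmse_all``
    keeps every pair. ``n_pairs`` counts all pairs, ``n_used`` those that
    survived exclusion.
    """

    pairs: list[ValidationPair]
    rmse: float
    rmse_all: float
    model_used: str
    excluded_diameters: list[float] = field(default_factory=list)
    split_seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_used(self) -> int:
        return sum(not p.excluded for p in self.pairs)

    def group_rmse(self) -> dict[float, float]:
        """RMSE per core diameter, over all pairs (no exclusion applied)."""
        by_d: dict[float, list[ValidationPair]] = {}
        for p in self.pairs:
            if p.core_diameter is not None:
                by_d.setdefault(p.core_diameter, []).append(p)
        return {
            d: rmse([p.measured for p in ps], [p.estimated for p in ps])
            for d, ps in sorted(by_d.items())
        }

    def to_dict(self) -> dict:
        return {
            "model_used": self.model_used,
            "rmse": self.rmse,
            "rmse_all": self.rmse_all,
            "n_pairs": self.n_pairs,
            "n_used": self.n_used,
            "excluded_diameters": list(self.excluded_diameters),
            "group_rmse": {str(d): v for d, v in self.group_rmse().items()},
            "split_seed": self.split_seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def split_points(
    points: Sequence[CalibrationPoint], fraction_train: float, seed: int
) -> tuple[list[CalibrationPoint], list[CalibrationPoint]]:
    """Stratified-by-diameter random train/validation split.

    Each diameter stratum is shuffled with a seeded generator and cut so
    that both sides are non-empty; the union is the input and the
    intersection empty. Deterministic for a fixed seed.
    """
    if not 0.0 < fraction_train < 1.0:
        raise DomainError(f"fraction_train must be in (0, 1), got {fraction_train}")
    by_d: dict[float, list[CalibrationPoint]] = {}
    for p in points:
        d = p.core_diameter
        if d is None:
            raise DomainError("points need a condition with a diameter to stratify")
        by_d.setdefault(d, []).append(p)

    rng = np.random.default_rng(seed)
    train: list[CalibrationPoint] = []
    validation: list[CalibrationPoint] = []
    for d, stratum in sorted(by_d.items()):
        n = len(stratum)
        if n < 2:
            raise SplitError(
                f"stratum at {d} nm has {n} point(s); need >= 2 to split"
            )
        n_train = int(round(fraction_train * n))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        for rank, idx in enumerate(order):
            p = stratum[idx]
            if rank < n_train:
                train.append(replace_split(p, "train"))
            else:
                validation.append(replace_split(p, "validation"))
    return train, validation


def replace_split(point: CalibrationPoint, split: str) -> CalibrationPoint:
    return CalibrationPoint(
        nssc=point.nssc, c_ag=point.c_ag, condition=point.condition, split=split
    )


def rmse(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """Root-mean-squared error between paired vectors, in particles/cell."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ShapeError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size == 0:
        raise EmptySampleError("RMSE of empty vectors is undefined")
    return float(np.sqrt(np.mean((m - e) ** 2)))


def validate_model(
    model: CalibrationModel,
    points: Sequence[CalibrationPoint],
    mode: str = "per_size",
    excluded_diameters: Sequence[float] = (),
    split_seed: int | None = None,
) -> ValidationReport:
    """Estimate every validation point from its nSSC and report RMSE.

    ``mode`` selects the per-size line or the combined size model. Pairs at
    excluded diameters are kept in the report (flagged) but dropped from the
    headline RMSE; ``rmse_all`` retains them.
    """
    if not points:
        raise EmptySampleError("no validation points")
    excluded = set(float(d) for d in excluded_diameters)
    pairs: list[ValidationPair] = []
    for p in points:
        d = p.core_diameter
        if d is None:
            raise DomainError("validation points need a condition with a diameter")
        est = model.estimate(p.nssc, d, mode=mode)
        pairs.append(
            ValidationPair(
                measured=p.c_ag,
                estimated=est.c_ag_est,
                condition=p.condition,
                excluded=d in excluded,
            )
        )
    rmse_all = rmse([p.measured for p in pairs], [p.estimated for p in pairs])
    kept = [p for p in pairs if not p.excluded]
    rmse_kept = (
        rmse([p.measured for p in kept], [p.estimated for p in kept])
        if kept
        else float("nan")
    )
    return ValidationReport(
        pairs=pairs,
        rmse=rmse_kept,
        rmse_all=rmse_all,
        model_used=mode,
        excluded_diameters=sorted(excluded),
        split_seed=split_seed,
    )


def flag_outlier_diameters(
    report: ValidationReport, threshold: float = 3.0
) -> list[float]:
    """Diameters whose group RMSE exceeds ``threshold`` × the median group RMSE.

    Quantifies the visual outlier-exclusion judgment: a size whose errors are
    grossly inflated relative to its peers is a candidate for exclusion.
    """
    groups = report.group_rmse()
    if len(groups) < 2:
        raise DomainError("need >= 2 diameters to flag outliers")
    median = float(np.median(list(groups.values())))
    if median == 0.0:
        return [d for d, v in groups.items() if v > 0.0]
    return [d for d, v in groups.items() if v > threshold * median]


def pairs_to_csv(report: ValidationReport, path: str | Path) -> None:
    """Write (measured, estimated, diameter, configuration, height, excluded)."""
    import pandas as pd

    rows = []
    for p in report.pairs:
        c = p.condition
        rows.append(
            {
                "measured_c_ag": p.measured,
                "estimated_c_ag": p.estimated,
                "core_diameter_nm": c.core_diameter if c else "",
                "configuration": c.configuration if c else "",
                "media_height_mm": c.media_height if c else "",
                "excluded": p.excluded,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def plot_validation(report: ValidationReport, path: str | Path) -> None:
    """Scatter of measured vs estimated c-Ag with the identity diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    kept = [p for p in report.pairs if not p.excluded]
    out = [p for p in report.pairs if p.excluded]
    ax.scatter(
        [p.measured for p in kept], [p.estimated for p in kept], s=18, label="included"
    )
    if out:
        ax.scatter(
            [p.measured for p in out],
            [p.estimated for p in out],
            s=18,
            marker="x",
            color="crimson",
            label="excluded",
        )
    lim = max(
        [p.measured for p in report.pairs] + [p.estimated for p in report.pairs] + [1]
    )
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("measured c-Ag (NPs/cell)")
    ax.set_ylabel("estimated c-Ag (NPs/cell)")
    ax.set_title(f"{report.model_used}: RMSE {report.rmse:.1f} (all: {report.rmse_all:.1f})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "ValidationPair",
    "ValidationReport",
    "flag_outlier_diameters",
    "pairs_to_csv",
    "plot_validation",
    "rmse",
    "split_points",
    "validate_model",
]
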