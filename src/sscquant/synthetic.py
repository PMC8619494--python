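"""Synthetic paired FCM/ICPMS study generator.

Emulates the experiment the calibration assumes: adherent lung epithelial
cells exposed to bPEI-coated silver nanoparticles of five core sizes in two
plate configurations (upright — sedimentation plus diffusion — and inverted
— diffusion only) at three media heights, three replicates each, with
matched unexposed controls per batch, read out both by flow cytometry
(side-scatter event distributions) and by ICPMS (total silver mass over a
counted cell pellet).

The effect model is deliberately simple and fully deterministic given a
condition:

* uptake falls with core diameter (small particles are more numerous at
  equal mass dose), rises with media height (more particles available above
  the cells), and is higher upright than inverted;
* the smallest size (40 nm by default) gets a multiplicative uptake boost,
  reproducing the anomalously high association of heavily agglomerating
  small particles so the outlier-exclusion workflow has something to find.

The cytometry read-out inverts the estimator exactly: a sample's mean SSC is
the control mean times (1 + c/m(d)), so a zero-noise study round-trips to
the generating slopes identically — the core test oracle of the package.
Event-level SSC is log-normal (right-skewed, strictly positive, the standard
shape for cytometry intensity data); only its mean matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import fcs
from .calibration import AG_BPEI_A549_SLOPES
from .cytometry import EventTable, ExposureCondition
from .errors import DesignError, DomainError
from .icpms import NG_PER_FG, SILVER_DENSITY_G_CM3, IcpmsMeasurement, mass_per_particle

_INVERTED_FACTOR = 0.4  # diffusion-only delivery relative to upright
_SIZE_EXPONENT = 1.5  # uptake ~ (d_ref/d)^1.5 across the size series


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and noise levels for the generator.

    Defaults encode the study conditions the calibration was built for:
    five core sizes spanning 40–200 nm with the published per-size slopes as
    generating truth, upright and inverted configurations, 3/6/9 mm media
    heights, three replicates, and an anomalous 4× uptake boost at 40 nm.
    ``uptake_base`` (11,000 NPs/cell) places the design maximum (40 nm,
    upright, 9 mm, boosted) at 66,000 NPs/cell and the maximum nSSC near
    21.5 — inside the method's validated working range (~80,000 NPs/cell,
    ~23 nSSC).
    """

    diameters: tuple[float, ...] = (40.0, 60.0, 80.0, 100.0, 200.0)
    generating_slopes: Mapping[float, float] = field(
        default_factory=lambda: dict(AG_BPEI_A549_SLOPES)
    )
    configurations: tuple[str, ...] = ("upright", "inverted")
    media_heights: tuple[float, ...] = (3.0, 6.0, 9.0)
    replicates: int = 3
    dose: float = 10.0  # µg/mL
    duration: float = 24.0  # h
    uptake_base: float = 11_000.0  # NPs/cell at the reference condition
    anomalous_diameter: float | None = 40.0
    anomaly_multiplier: float = 4.0
    control_ssc_mean: float = 1.0e5  # arbitrary cytometer units
    control_ssc_cv: float = 0.35  # event-level spread of cellular SSC
    fcm_cv: float = 0.05  # sample-level replicate variation of the mean
    icpms_cv: float = 0.10  # relative error of the mass read-out
    events_per_sample: int = 5_000
    cell_count: float = 1.0e6  # cells per ICPMS pellet
    density: float = SILVER_DENSITY_G_CM3
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in (self.control_ssc_cv, self.fcm_cv, self.icpms_cv):
            if cv < 0:
                raise DomainError("noise CVs must be >= 0")
        for d in self.diameters:
            if d not in self.generating_slopes:
                raise DomainError(f"no generating slope for {d} nm")
            if self.generating_slopes[d] <= 0:
                raise DomainError(f"generating slope for {d} nm must be > 0")

    def zero_noise(self) -> "SyntheticConfig":
        """The same design with every noise source switched off."""
        return replace(self, control_ssc_cv=0.0, fcm_cv=0.0, icpms_cv=0.0)


@dataclass
class SampleDesign:
    sample_id: str
    control_id: str
    batch_id: str
    condition: ExposureCondition | None  # None for controls


@dataclass
class SyntheticStudy:
    event_tables: list[EventTable]
    icpms_table: list[IcpmsMeasurement]
    design: list[SampleDesign]
    truth: dict[str, float]  # sample_id -> true c-Ag
    config: SyntheticConfig

    def table(self, sample_id: str) -> EventTable:
        for t in self.event_tables:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)


def true_uptake(condition: ExposureCondition, config: SyntheticConfig) -> float:
    """Deterministic expected c-Ag (NPs/cell) for a design condition.

    base × (d_ref/d)^1.5 × (h/mean height) × configuration factor
    (upright 1, inverted 0.4) × anomaly multiplier at the anomalous size.
    """
    if condition.core_diameter not in config.diameters:
        raise DesignError(
            f"diameter {condition.core_diameter} nm outside design {config.diameters}"
        )
    if condition.configuration not in config.configurations:
        raise DesignError(f"configuration {condition.configuration!r} outside design")
    if condition.media_height not in config.media_heights:
        raise DesignError(
            f"media height {condition.media_height} mm outside design "
            f"{config.media_heights}"
        )
    d_ref = min(config.diameters)
    size_factor = (d_ref / condition.core_diameter) ** _SIZE_EXPONENT
    height_factor = condition.media_height / (
        sum(config.media_heights) / len(config.media_heights)
    )
    config_factor = 1.0 if condition.configuration == "upright" else _INVERTED_FACTOR
    c = config.uptake_base * size_factor * height_factor * config_factor
    if condition.core_diameter == config.anomalous_diameter:
        c *= config.anomaly_multiplier
    return c


def _lognormal(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV (exact at cv=0)."""
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def simulate_fcm_sample(
    true_c_ag: float,
    slope: float,
    config: SyntheticConfig,
    seed: int | np.random.Generator,
    sample_id: str = "sample",
) -> EventTable:
    """Draw one sample's event table (FSC-A, SSC-A).

    The sample-level mean SSC is control_ssc_mean × (1 + c/m), perturbed by
    a Gaussian of CV ``fcm_cv`` (replicate-to-replicate biology and
    instrument drift); events are then log-normal about that mean with
    event-level CV ``control_ssc_cv``. FSC-A is uptake-independent and only
    exists so gating has a second channel.
    """
    if slope <= 0:
        raise DomainError(f"slope must be > 0, got {slope}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    target = config.control_ssc_mean * (1.0 + true_c_ag / slope)
    if config.fcm_cv > 0:
        target *= max(1.0 + config.fcm_cv * rng.standard_normal(), 1e-6)
    ssc = _lognormal(rng, target, config.control_ssc_cv, config.events_per_sample)
    fsc = _lognormal(rng, 5.0e5, 0.30, config.events_per_sample)
    frame = pd.DataFrame({"FSC-A": fsc, "SSC-A": ssc})
    return EventTable(sample_id=sample_id, events=frame)


def simulate_icpms(
    true_c_ag: float,
    cell_count: float,
    diameter: float,
    config: SyntheticConfig,
    seed: int | np.random.Generator,
    sample_id: str = "sample",
    condition: ExposureCondition | None = None,
) -> IcpmsMeasurement:
    """Draw the ICPMS mass read-out for one pellet.

    total mass = c × m_particle × n_cells × (1 + ε), ε ~ N(0, icpms_cv),
    truncated at zero so no negative masses are ever reported.
    """
    if cell_count <= 0:
        raise DomainError(f"cell_count must be > 0, got {cell_count}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mpp = mass_per_particle(diameter, config.density)  # fg
    mass_fg = true_c_ag * mpp * cell_count
    if config.icpms_cv > 0:
        mass_fg *= 1.0 + config.icpms_cv * rng.standard_normal()
    mass_fg = max(mass_fg, 0.0)
    return IcpmsMeasurement(
        sample_id=sample_id,
        total_mass=mass_fg * NG_PER_FG,
        cell_count=cell_count,
        condition=condition,
    )


def sample_calibration_points(
    slope: float,
    diameter: float,
    n: int,
    seed: int | np.random.Generator,
    nssc_range: tuple[float, float] = (1.5, 23.0),
    cv: float = 0.10,
    configuration: str = "upright",
    media_height: float = 6.0,
) -> list:
    """Draw paired (nSSC, c-Ag) points straight from the linear response.

    nSSC is uniform on ``nssc_range`` and c-Ag = slope·(nSSC − 1) under
    multiplicative Gaussian noise of the given CV (truncated at zero). This
    bypasses the event-level machinery for fast slope-recovery experiments.
    """
    from .calibration import CalibrationPoint

    if slope <= 0:
        raise DomainError(f"slope must be > 0, got {slope}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cond = ExposureCondition(
        core_diameter=diameter, configuration=configuration, media_height=media_height
    )
    nssc = rng.uniform(*nssc_range, size=n)
    noise = 1.0 + cv * rng.standard_normal(n) if cv > 0 else np.ones(n)
    c_ag = np.maximum(slope * (nssc - 1.0) * noise, 0.0)
    return [
        CalibrationPoint(nssc=float(x), c_ag=float(y), condition=cond)
        for x, y in zip(nssc, c_ag)
    ]


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate a full in-memory study: events, ICPMS table, design, truth.

    One batch per (configuration, media height, replicate), each with its
    own unexposed control; every exposed sample names its same-batch
    control. Fully deterministic for a fixed ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    event_tables: list[EventTable] = []
    icpms_table: list[IcpmsMeasurement] = []
    design: list[SampleDesign] = []
    truth: dict[str, float] = {}

    ref_slope = config.generating_slopes[min(config.diameters)]
    for conf in config.configurations:
        for h in config.media_heights:
            for rep in range(1, config.replicates + 1):
                batch = f"{conf}_h{h:g}_r{rep}"
                control_id = f"ctrl_{batch}"
                ctrl = simulate_fcm_sample(
                    0.0, ref_slope, config, rng, sample_id=control_id
                )
                event_tables.append(ctrl)
                design.append(SampleDesign(control_id, control_id, batch, None))
                truth[control_id] = 0.0
                for d in config.diameters:
                    cond = ExposureCondition(
                        core_diameter=d,
                        configuration=conf,
                        media_height=h,
                        dose=config.dose,
                        duration=config.duration,
                    )
                    c = true_uptake(cond, config)
                    sid = f"Ag{d:g}_{batch}"
                    event_tables.append(
                        simulate_fcm_sample(
                            c,
                            config.generating_slopes[d],
                            config,
                            rng,
                            sample_id=sid,
                        )
                    )
                    icpms_table.append(
                        simulate_icpms(
                            c,
                            config.cell_count,
                            d,
                            config,
                            rng,
                            sample_id=sid,
                            condition=cond,
                        )
                    )
                    design.append(SampleDesign(sid, control_id, batch, cond))
                    truth[sid] = c
    return SyntheticStudy(
        event_tables=event_tables,
        icpms_table=icpms_table,
        design=design,
        truth=truth,
        config=config,
    )


def write_study(
    study: SyntheticStudy, out_dir: str | Path, event_format: str = "csv"
) -> Path:
    """Write a study to disk: events/, icpms.csv, design.csv, truth.csv.

    ``event_format`` is ``"csv"`` (text, byte-deterministic) or ``"fcs"``
    (FCS 3.1 float32). Returns the output directory.
    """
    if event_format not in ("csv", "fcs"):
        raise DomainError(f"event_format must be csv|fcs, got {event_format!r}")
    out = Path(out_dir)
    events_dir = out / "events"
    events_dir.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    for t in study.event_tables:
        fname = f"{t.sample_id}.{event_format}"
        fpath = events_dir / fname
        if event_format == "csv":
            t.events.to_csv(fpath, index=False, float_format="%.6f")
        else:
            fcs.write_fcs(fpath, t.events, extra_keywords={"$SRC": t.sample_id})
        files[t.sample_id] = str(Path("events") / fname)

    icpms_rows = []
    for m in study.icpms_table:
        c = m.condition
        icpms_rows.append(
            {
                "sample_id": m.sample_id,
                "total_mass_ng": m.total_mass,
                "cell_count": m.cell_count,
                "core_diameter_nm": c.core_diameter if c else "",
                "configuration": c.configuration if c else "",
                "media_height_mm": c.media_height if c else "",
            }
        )
    pd.DataFrame(icpms_rows).to_csv(out / "icpms.csv", index=False)

    design_rows = []
    for s in study.design:
        c = s.condition
        design_rows.append(
            {
                "sample_id": s.sample_id,
                "control_id": s.control_id,
                "batch_id": s.batch_id,
                "file": files[s.sample_id],
                "is_control": c is None,
                "core_diameter_nm": c.core_diameter if c else "",
                "configuration": c.configuration if c else "",
                "media_height_mm": c.media_height if c else "",
                "dose_ug_ml": c.dose if c else "",
                "duration_h": c.duration if c else "",
            }
        )
    pd.DataFrame(design_rows).to_csv(out / "design.csv", index=False)

    pd.DataFrame(
        [{"sample_id": k, "true_c_ag": v} for k, v in study.truth.items()]
    ).to_csv(out / "truth.csv", index=False)
    return out


__all__ = [
    "SampleDesign",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_study",
    "sample_calibration_points",
    "simulate_fcm_sample",
    "simulate_icpms",
    "true_uptake",
    "write_study",
]
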