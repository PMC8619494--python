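"""ICPMS elemental mass to particles-per-cell conversion.

ICPMS (inductively coupled plasma mass spectrometry) measures the total
elemental silver mass in a digested cell pellet. Combined with a
hemocytometer cell count and a solid-sphere particle mass model, this yields
c-Ag, the number of cell-associated nanoparticles per cell — the reference
quantity against which the side-scatter calibration is trained.

Unit conventions: element masses are carried in femtograms internally and in
nanograms at file boundaries; ICPMS standard concentrations are µg/L.

The particle mass model is a solid sphere of the *nominal* core diameter at
bulk density (10.49 g/cm³ for silver). Hydrodynamic diameter is never used
for mass: protein corona and agglomeration change the scattering size, not
the silver content. No dissolved-ion correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cytometry import ExposureCondition
from .errors import DomainError, RankError

SILVER_DENSITY_G_CM3 = 10.49
NG_PER_FG = 1e-6


@dataclass(frozen=True)
class IcpmsStandard:
    """One point of the instrument calibration line."""

    concentration: float  # µg/L
    signal: float  # counts

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.signal < 0:
            raise DomainError("standard concentration and signal must be >= 0")


@dataclass(frozen=True)
class IcpmsMeasurement:
    """Total elemental mass and cell count for one digested sample."""

    sample_id: str
    total_mass: float  # ng of element
    cell_count: float  # cells
    condition: ExposureCondition | None = None

    def __post_init__(self) -> None:
        if self.total_mass < 0:
            raise DomainError(f"{self.sample_id}: total_mass must be >= 0")
        if self.cell_count <= 0:
            raise DomainError(f"{self.sample_id}: cell_count must be > 0")


@dataclass(frozen=True)
class ParticleCountResult:
    """Particles per cell derived from an ICPMS measurement."""

    sample_id: str
    c_ag: float  # particles/cell
    mass_per_cell: float  # fg/cell
    mass_per_particle: float  # fg/particle
    condition: ExposureCondition | None = None


@dataclass(frozen=True)
class IcpmsLine:
    """OLS instrument calibration: signal = slope * concentration + intercept."""

    slope: float
    intercept: float

    def predict_signal(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def concentration(self, signal: float) -> float:
        """Inverse prediction of an unknown's concentration (µg/L)."""
        return (signal - self.intercept) / self.slope


def fit_icpms_line(standards: list[IcpmsStandard]) -> IcpmsLine:
    """Fit the instrument calibration line by ordinary least squares."""
    conc = np.array([s.concentration for s in standards], dtype=float)
    sig = np.array([s.signal for s in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise RankError(
            f"need >= 2 distinct standard concentrations, got {np.unique(conc)}"
        )
    slope, intercept = np.polyfit(conc, sig, 1)
    return IcpmsLine(slope=float(slope), intercept=float(intercept))


def mass_per_particle(
    diameter: float, density: float = SILVER_DENSITY_G_CM3
) -> float:
    """Mass of a solid sphere, in femtograms.

    ``diameter`` in nm, ``density`` in g/cm³. m = ρ·(π/6)·d³, which in these
    units reduces to ρ·(π/6)·d³·1e−6 fg.
    """
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    if density <= 0:
        raise DomainError(f"density must be > 0, got {density}")
    return density * (np.pi / 6.0) * diameter**3 * 1e-6


def cellular_np_count(
    measurement: IcpmsMeasurement,
    diameter: float,
    density: float = SILVER_DENSITY_G_CM3,
) -> ParticleCountResult:
    """Convert an ICPMS measurement to particles per cell (c-Ag).

    mass_per_cell = total_mass / cell_count (fg/cell);
    c_ag = mass_per_cell / mass_per_particle(diameter, density).
    """
    mpp = mass_per_particle(diameter, density)
    mass_per_cell_fg = measurement.total_mass / NG_PER_FG / measurement.cell_count
    return ParticleCountResult(
        sample_id=measurement.sample_id,
        c_ag=mass_per_cell_fg / mpp,
        mass_per_cell=mass_per_cell_fg,
        mass_per_particle=mpp,
        condition=measurement.condition,
    )


__all__ = [
    "NG_PER_FG",
    "SILVER_DENSITY_G_CM3",
    "IcpmsLine",
    "IcpmsMeasurement",
    "IcpmsStandard",
    "ParticleCountResult",
    "cellular_np_count",
    "fit_icpms_line",
    "mass_per_particle",
]
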