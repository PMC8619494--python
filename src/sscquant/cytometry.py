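"""Flow-cytometry ingestion, gating and side-scatter normalization.

The quantity this package is built around is the normalized side-scatter
intensity

    nSSC = (SSC)_i / (SSC)_o

where (SSC)_i is the mean side-scatter intensity of cells exposed to
nanoparticles and (SSC)_o that of unexposed control cells from the same
batch. Side scatter proxies intracellular granularity, so metal
nanoparticles taken up by (or bound to) cells raise it in proportion to the
cellular particle load; dividing by the same-batch control cancels
instrument drift and batch-to-batch biological variation, pinning controls
at nSSC = 1.

No gating is applied by default — the summary statistic is the arithmetic
mean SSC over all acquired events. An optional rectangular gate (e.g. a
debris cut on FSC/SSC lower bounds) is available via :func:`gate_events`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import fcs
from .errors import (
    BatchMismatchError,
    ChannelError,
    DegenerateControlError,
    DomainError,
    EmptySampleError,
    FormatError,
)

CONFIGURATIONS = ("upright", "inverted")


@dataclass(frozen=True)
class ExposureCondition:
    """One cell of the exposure design.

    Parameters
    ----------
    core_diameter : float
        Nominal metallic core diameter in nm (distinct from hydrodynamic
        diameter, which includes corona and agglomerates).
    configuration : str
        ``"upright"`` (cells face up; sedimentation plus diffusion deliver
        particles) or ``"inverted"`` (cells face down on spacers; diffusion
        only).
    media_height : float
        Culture-medium column height above/below the cells, mm.
    dose : float
        Administered dose, µg/mL.
    duration : float
        Exposure duration, hours.
    """

    core_diameter: float
    configuration: str
    media_height: float
    dose: float = 10.0
    duration: float = 24.0

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise DomainError(f"core_diameter must be > 0, got {self.core_diameter}")
        if self.configuration not in CONFIGURATIONS:
            raise DomainError(
                f"configuration must be one of {CONFIGURATIONS}, "
                f"got {self.configuration!r}"
            )
        if self.media_height <= 0:
            raise DomainError(f"media_height must be > 0, got {self.media_height}")
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")
        if self.duration <= 0:
            raise DomainError(f"duration must be > 0, got {self.duration}")


@dataclass
class EventTable:
    """Per-event channel intensities for one acquired sample."""

    sample_id: str
    events: pd.DataFrame
    acquisition_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.events.to_numpy(dtype=float) if len(self.events) else None
        if values is not None and not np.isfinite(values).all():
            raise DomainError(
                f"{self.sample_id}: event table contains non-finite intensities"
            )

    @property
    def channel_names(self) -> list[str]:
        return [str(c) for c in self.events.columns]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def require_channel(self, channel: str) -> None:
        if channel not in self.channel_names:
            raise ChannelError(channel, self.channel_names)


@dataclass(frozen=True)
class SSCSummary:
    """Mean side-scatter intensity of one sample (houses (SSC)_i / (SSC)_o)."""

    sample_id: str
    mean_ssc: float
    n_events: int
    gate_id: str = "ungated"
    batch_id: str = ""


@dataclass(frozen=True)
class NormalizedSample:
    """A sample's nSSC with the control it was normalized against."""

    sample_id: str
    control_id: str
    nssc: float
    batch_id: str = ""
    condition: ExposureCondition | None = None


def read_events(
    path: str | Path, ssc_channel: str, sample_id: str | None = None
) -> EventTable:
    """Read an FCS 3.0/3.1 file or a CSV event table.

    CSV files need a header row of channel names and one row per event.
    The designated SSC channel must be present; event order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sid = sample_id if sample_id is not None else path.stem

    head = b""
    with open(path, "rb") as fh:
        head = fh.read(6)
    if head.startswith(b"FCS"):
        frame, text = fcs.read_fcs(path)
        meta = {k: v for k, v in text.items() if not k.startswith("$P")}
        table = EventTable(sample_id=sid, events=frame, acquisition_meta=meta)
    else:
        try:
            frame = pd.read_csv(path)
            frame = frame.astype(float)
        except (ValueError, pd.errors.ParserError, UnicodeDecodeError) as exc:
            raise FormatError(f"{path}: not a numeric CSV event table ({exc})") from exc
        table = EventTable(sample_id=sid, events=frame)
    table.require_channel(ssc_channel)
    return table


def gate_events(
    table: EventTable, gate: Mapping[str, tuple[float, float]], gate_id: str = "rect"
) -> EventTable:
    """Keep events inside a closed rectangular gate.

    ``gate`` maps channel name -> (low, high); an event survives only if it
    lies inside every interval. An empty result is legal.
    """
    mask = np.ones(table.n_events, dtype=bool)
    for channel, (low, high) in gate.items():
        table.require_channel(channel)
        values = table.events[channel].to_numpy(dtype=float)
        mask &= (values >= low) & (values <= high)
    gated = table.events.loc[mask].reset_index(drop=True)
    meta = dict(table.acquisition_meta)
    meta["gate"] = gate_id
    return EventTable(sample_id=table.sample_id, events=gated, acquisition_meta=meta)


def summarize_ssc(
    table: EventTable,
    ssc_channel: str,
    statistic: str = "mean",
    batch_id: str = "",
) -> SSCSummary:
    """Summarize a sample's SSC channel.

    ``statistic`` is ``"mean"`` (the default and the definition used by the
    nSSC calibration) or ``"median"``.
    """
    table.require_channel(ssc_channel)
    if table.n_events == 0:
        raise EmptySampleError(f"{table.sample_id}: no events to summarize")
    values = table.events[ssc_channel].to_numpy(dtype=float)
    if statistic == "mean":
        stat = float(np.mean(values))
    elif statistic == "median":
        stat = float(np.median(values))
    else:
        raise DomainError(f"unknown statistic {statistic!r}")
    return SSCSummary(
        sample_id=table.sample_id,
        mean_ssc=stat,
        n_events=table.n_events,
        gate_id=table.acquisition_meta.get("gate", "ungated"),
        batch_id=batch_id,
    )


def normalize_ssc(
    sample: SSCSummary,
    control: SSCSummary,
    condition: ExposureCondition | None = None,
    allow_cross_batch: bool = False,
) -> NormalizedSample:
    """Compute nSSC = sample.mean_ssc / control.mean_ssc.

    Sample and control must come from the same batch; normalizing across
    batches defeats the purpose of the ratio and is only allowed with
    ``allow_cross_batch=True`` (a warning is emitted).
    """
    if control.mean_ssc <= 0:
        raise DegenerateControlError(
            f"control {control.sample_id!r} has mean SSC {control.mean_ssc} <= 0"
        )
    if sample.batch_id != control.batch_id:
        if not allow_cross_batch:
            raise BatchMismatchError(
                f"sample batch {sample.batch_id!r} != control batch "
                f"{control.batch_id!r}; pass allow_cross_batch=True to override"
            )
        warnings.warn(
            f"normalizing {sample.sample_id!r} against control "
            f"{control.sample_id!r} from a different batch",
            stacklevel=2,
        )
    return NormalizedSample(
        sample_id=sample.sample_id,
        control_id=control.sample_id,
        nssc=sample.mean_ssc / control.mean_ssc,
        batch_id=sample.batch_id,
        condition=condition,
    )


def concat_tables(tables: list[EventTable], sample_id: str) -> EventTable:
    """Concatenate event tables that share a channel layout."""
    if not tables:
        raise EmptySampleError("nothing to concatenate")
    cols = tables[0].channel_names
    for t in tables[1:]:
        if t.channel_names != cols:
            raise ChannelError(str(t.channel_names), cols)
    frame = pd.concat([t.events for t in tables], ignore_index=True)
    return EventTable(sample_id=sample_id, events=frame)


__all__ = [
    "CONFIGURATIONS",
    "EventTable",
    "ExposureCondition",
    "NormalizedSample",
    "SSCSummary",
    "concat_tables",
    "gate_events",
    "normalize_ssc",
    "read_events",
    "summarize_ssc",
]
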