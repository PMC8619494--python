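"""Exception hierarchy for sscquant.

All package-specific failures derive from :class:`SscquantError` so callers can
catch one base class; subclasses also derive from the matching builtin
(``ValueError`` / ``IOError``) where that is the natural Python idiom.
"""


class SscquantError(Exception):
    """Base class for all sscquant errors."""


class FormatError(SscquantError, IOError):
    """A file could not be parsed as FCS or as a CSV event table."""


class ChannelError(SscquantError, KeyError):
    """A requested cytometry channel is not present."""

    def __init__(self, channel: str, available: list[str]):
        self.channel = channel
        self.available = list(available)
        super().__init__(
            f"channel {channel!r} not found; available channels: {self.available}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class EmptySampleError(SscquantError, ValueError):
    """An operation that needs at least one event received none."""


class DegenerateControlError(SscquantError, ValueError):
    """Control mean SSC is non-positive; normalization undefined."""


class BatchMismatchError(SscquantError, ValueError):
    """Sample and control come from different batches (override available)."""


class RankError(SscquantError, ValueError):
    """Too few distinct x-values to fit a line."""


class DomainError(SscquantError, ValueError):
    """An argument is outside its physical domain (e.g. diameter <= 0)."""


class DegenerateRegressorError(SscquantError, ValueError):
    """All calibration points sit at nSSC = 1; the forced-origin slope is undefined."""


class IdentifiabilityError(SscquantError, ValueError):
    """Too few distinct diameters to identify the three-parameter size model."""


class FitFailureError(SscquantError, RuntimeError):
    """Nonlinear fit failed to converge from every start point."""


class SplitError(SscquantError, ValueError):
    """A diameter stratum is too small to split into train and validation."""


class CoverageError(SscquantError, ValueError):
    """A validation point's diameter has no per-size calibration."""


class DesignError(SscquantError, ValueError):
    """An exposure condition falls outside the synthetic study design."""


class ShapeError(SscquantError, ValueError):
    """Paired vectors have mismatched lengths."""
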