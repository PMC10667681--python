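"""Exception types shared across the package."""

from __future__ import annotations


class MeltplexError(Exception):
    """Base class for all package-specific errors."""


class PanelValidationError(MeltplexError):
    """A panel configuration violates one or more invariants.

    Carries the list of :class:`~meltplex.panel.Violation` records that
    triggered the failure.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(v.message for v in self.violations)
        super().__init__(f"invalid panel configuration: {msg}")


class PartitionTableError(MeltplexError):
    """A partition summary table is malformed or fails validation."""


class ResultsTableError(MeltplexError):
    """A results table violates its invariants."""


class ZeroDenominatorError(MeltplexError):
    """Ratio denominators at or below the configured floor.

    ``partition_indices`` lists the offending 0-based partition indices.
    """

    def __init__(self, partition_indices, floor):
        self.partition_indices = list(partition_indices)
        self.floor = floor
        shown = ", ".join(str(i) for i in self.partition_indices[:20])
        more = "" if len(self.partition_indices) <= 20 else ", ..."
        super().__init__(
            f"{len(self.partition_indices)} partition(s) with ratio denominator "
            f"<= {floor} RFU at indices: {shown}{more}"
        )


class NormalizationError(MeltplexError):
    """Rolling-window normalization cannot be computed."""


class SaturatedWellError(MeltplexError):
    """All partitions positive for a probe: lambda is inestimable.

    Quantification is impossible; the sample should be re-diluted.
    """

    def __init__(self, probe_id=None):
        self.probe_id = probe_id
        what = f"probe {probe_id!r}" if probe_id else "target"
        super().__init__(
            f"all partitions positive for {what}: copy number is inestimable "
            "(saturated well, re-dilution required)"
        )


class QuantificationError(MeltplexError):
    """A quantification operation received inconsistent inputs."""
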