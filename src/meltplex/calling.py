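"""Raw fluorescence → per-probe positive/negative calls.

The discrete-melt readout for a probe sitting in melt window ``w`` of
channel ``c`` is the ratio of the channel's fluorescence at the window's
upper imaging temperature to its value at the lower one:

    r[p, c, w] = F[p, c, T_{w+1}] / F[p, c, T_w]

A cleaved (target-positive) probe is quenched below its hairpin melt
temperature, so its ratio rises well above 1; untouched probes give ratios
near 1.  Raw ratios are baseline-corrected with a rolling-window statistic
computed independently per (channel, window) track along partition order,
then compared strictly against per-probe thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import NormalizationError, ZeroDenominatorError
from .io import PartitionTable
from .panel import CHANNELS, N_WINDOWS, NormalizationConfig, PanelConfig

__all__ = [
    "CallTable",
    "QCCheck",
    "QCReport",
    "RatioTable",
    "call_partitions",
    "compute_ratios",
    "normalize_ratios",
    "qc_well",
    "ratio_debug_frame",
]

#: Default floor below which a ratio denominator is treated as zero.
DENOMINATOR_FLOOR = 1e-9


@dataclass
class RatioTable:
    """Per-partition melt-window ratios for one well.

    ``raw`` and ``norm`` have shape ``(n_partitions, 4 channels, 3 windows)``;
    ``valid`` marks partitions whose denominators were all above the floor
    (invalid partitions hold NaN ratios and are excluded downstream).
    """

    well_id: str
    raw: np.ndarray
    preliminary_negative: np.ndarray
    valid: np.ndarray
    norm: Optional[np.ndarray] = None

    @property
    def n_partitions(self) -> int:
        return self.raw.shape[0]


def compute_ratios(
    table: PartitionTable,
    panel: PanelConfig,
    *,
    denominator_floor: float = DENOMINATOR_FLOOR,
    on_zero_denominator: str = "raise",
) -> RatioTable:
    """Window ratios ``F[T_{w+1}]/F[T_w]`` for every partition × channel × window.

    ``on_zero_denominator``: ``"raise"`` (default) raises
    :class:`ZeroDenominatorError` listing offending partition indices;
    ``"exclude"`` marks them invalid (NaN) so downstream stages drop them
    from the analyzed count.
    """
    if on_zero_denominator not in ("raise", "exclude"):
        raise ValueError("on_zero_denominator must be 'raise' or 'exclude'")
    F = table.fluorescence
    denom = F[:, :, :N_WINDOWS]
    bad = (denom <= denominator_floor).any(axis=(1, 2))
    if bad.any() and on_zero_denominator == "raise":
        raise ZeroDenominatorError(np.flatnonzero(bad), denominator_floor)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = F[:, :, 1:] / denom
    valid = ~bad
    raw[bad] = np.nan

    cutoff = panel.normalization.preliminary_negative_cutoff
    prelim_neg = np.zeros_like(raw, dtype=bool)
    prelim_neg[valid] = raw[valid] <= cutoff
    return RatioTable(
        well_id=table.well_id, raw=raw, preliminary_negative=prelim_neg, valid=valid
    )


# ---------------------------------------------------------------------------
# rolling-window normalization


def _symmetric_half_widths(n: int, window_size: int) -> np.ndarray:
    # centered window shrinks symmetrically at the edges
    k = window_size // 2
    i = np.arange(n)
    return np.minimum(k, np.minimum(i, n - 1 - i))


def _rolling_median(x: np.ndarray, window_size: int) -> np.ndarray:
    """Centered rolling median with symmetric shrinkage at the edges.

    NaN entries (excluded partitions) are ignored.
    """
    n = x.size
    k = window_size // 2
    has_nan = bool(np.isnan(x).any())
    med = np.nanmedian if has_nan else np.median
    out = np.empty(n)
    if n >= window_size:
        # interior: pandas skiplist rolling median is O(n log w) and skips NaN
        s = pd.Series(x).rolling(window_size, center=True, min_periods=1).median()
        out[:] = s.to_numpy()
        edge = list(range(k)) + list(range(n - k, n))
    else:
        edge = list(range(n))
    for i in edge:
        h = min(k, i, n - 1 - i)
        out[i] = med(x[i - h : i + h + 1])
    return out


def _rolling_mean_of_negatives(
    x: np.ndarray, window_size: int, cutoff: float, track: str
) -> np.ndarray:
    finite = np.isfinite(x)
    mask = finite & (x <= cutoff)
    vals = np.where(mask, x, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    n = x.size
    h = _symmetric_half_widths(n, window_size)
    i = np.arange(n)
    lo, hi = i - h, i + h
    counts = cn[hi + 1] - cn[lo]
    if (counts == 0).any():
        raise NormalizationError(
            f"track {track}: no preliminary-negative partitions in the rolling "
            f"window around index {int(np.flatnonzero(counts == 0)[0])}; "
            "mean-of-negatives baseline is undefined"
        )
    return (cs[hi + 1] - cs[lo]) / counts


#: Minimum fraction of preliminary-negative partitions a track needs before
#: the rolling median is trusted as a baseline.  A (nearly) saturated track
#: has no negative cloud at 1: dividing by its median would flatten every
#: positive to ~1 and silently report zero copies, so such tracks are left
#: unnormalized and saturation surfaces downstream as positives == analyzed.
MIN_NEGATIVE_FRACTION = 0.02


def normalize_ratios(
    ratios: RatioTable,
    cfg: NormalizationConfig,
    *,
    min_negative_fraction: float = MIN_NEGATIVE_FRACTION,
) -> RatioTable:
    """Divide each (channel, window) track by its rolling baseline.

    Tracks are normalized independently; partition order is the file row
    order.  Returns a new :class:`RatioTable` with ``norm`` filled in.
    """
    n = ratios.n_partitions
    if cfg.window_size > n:
        raise NormalizationError(
            f"window_size {cfg.window_size} exceeds partition count {n}"
        )
    norm = np.full_like(ratios.raw, np.nan)
    for ci, channel in enumerate(CHANNELS):
        for w in range(N_WINDOWS):
            x = ratios.raw[:, ci, w]
            if cfg.statistic == "rolling_median":
                finite = np.isfinite(x)
                neg_frac = (
                    float((x[finite] <= cfg.preliminary_negative_cutoff).mean())
                    if finite.any()
                    else 0.0
                )
                if neg_frac < min_negative_fraction:
                    norm[:, ci, w] = x
                    continue
                baseline = _rolling_median(x, cfg.window_size)
            else:
                baseline = _rolling_mean_of_negatives(
                    x,
                    cfg.window_size,
                    cfg.preliminary_negative_cutoff,
                    track=f"({channel}, window {w + 1})",
                )
            if np.any(baseline[np.isfinite(x)] <= 0):
                raise NormalizationError(
                    f"track ({channel}, window {w + 1}): non-positive rolling baseline"
                )
            norm[:, ci, w] = x / baseline
    return replace(ratios, norm=norm)


# ---------------------------------------------------------------------------
# threshold calling


@dataclass
class CallTable:
    """Boolean positivity per partition per probe, plus per-probe counts.

    ``calls`` has shape ``(n_partitions, n_probes)`` in panel probe order;
    invalid (zero-denominator) partitions are never positive and are
    excluded from ``analyzed``.
    """

    well_id: str
    probe_ids: List[str]
    calls: np.ndarray
    valid: np.ndarray

    @property
    def analyzed(self) -> int:
        return int(self.valid.sum())

    @property
    def positives(self) -> np.ndarray:
        return self.calls[self.valid].sum(axis=0).astype(int)

    def positives_for(self, probe_id: str) -> int:
        return int(self.positives[self.probe_ids.index(probe_id)])


def call_partitions(ratios: RatioTable, panel: PanelConfig) -> CallTable:
    """Positive iff the probe's normalized window ratio strictly exceeds its
    threshold (ties are negative)."""
    if ratios.norm is None:
        raise ValueError("ratios must be normalized before calling (norm is None)")
    n = ratios.n_partitions
    probe_ids = panel.probe_ids()
    calls = np.zeros((n, len(probe_ids)), dtype=bool)
    for j, probe in enumerate(panel.probes):
        ci, wi = panel.slot_of(probe.probe_id)
        track = ratios.norm[:, ci, wi]
        with np.errstate(invalid="ignore"):
            calls[:, j] = track > probe.threshold
    calls[~ratios.valid, :] = False
    return CallTable(
        well_id=ratios.well_id, probe_ids=probe_ids, calls=calls, valid=ratios.valid.copy()
    )


def ratio_debug_frame(ratios: RatioTable, calls: Optional[CallTable] = None,
                      panel: Optional[PanelConfig] = None) -> pd.DataFrame:
    """Long-format per-partition ratio export for scatter-style plotting."""
    rows = []
    slot_probe = {}
    if panel is not None:
        for p in panel.probes:
            slot_probe[panel.slot_of(p.probe_id)] = p.probe_id
    for ci, channel in enumerate(CHANNELS):
        for w in range(N_WINDOWS):
            probe_id = slot_probe.get((ci, w))
            call_col = None
            if calls is not None and probe_id is not None:
                call_col = calls.calls[:, calls.probe_ids.index(probe_id)]
            for p in range(ratios.n_partitions):
                rows.append(
                    {
                        "partition": p,
                        "channel": channel,
                        "window": w + 1,
                        "raw_ratio": ratios.raw[p, ci, w],
                        "norm_ratio": np.nan if ratios.norm is None else ratios.norm[p, ci, w],
                        "call": bool(call_col[p]) if call_col is not None else None,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# well-level QC


@dataclass(frozen=True)
class QCCheck:
    name: str
    passed: bool
    message: str


@dataclass
class QCReport:
    well_id: str
    checks: List[QCCheck] = field(default_factory=list)
    reference_channel: str = "red"

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def qc_well(
    table: PartitionTable,
    panel: PanelConfig,
    *,
    reference_channel: str = "red",
    min_reference_median: float = 1.0,
    denominator_floor: float = DENOMINATOR_FLOOR,
    max_zero_denominator_fraction: float = 0.01,
) -> QCReport:
    """Well-level data-quality checks; failures are reported, never raised."""
    checks: List[QCCheck] = []
    n = table.n_partitions

    expected = panel.partitions_per_well
    checks.append(
        QCCheck(
            "partition_count",
            n == expected,
            f"{n} partitions (expected {expected})",
        )
    )

    finite = bool(np.isfinite(table.fluorescence).all())
    checks.append(QCCheck("finite_fluorescence", finite, "all fluorescence finite"
                          if finite else "non-finite fluorescence present"))

    ci = CHANNELS.index(reference_channel)
    ref_median = float(np.median(table.fluorescence[:, ci, 0]))
    checks.append(
        QCCheck(
            "reference_channel_signal",
            ref_median > min_reference_median,
            f"{reference_channel} channel median T1 fluorescence {ref_median:.4g} "
            f"(floor {min_reference_median:.4g})",
        )
    )

    denom = table.fluorescence[:, :, :N_WINDOWS]
    zero_frac = float((denom <= denominator_floor).any(axis=(1, 2)).mean())
    checks.append(
        QCCheck(
            "zero_denominator_fraction",
            zero_frac < max_zero_denominator_fraction,
            f"{zero_frac:.2%} of partitions with near-zero ratio denominators "
            f"(limit {max_zero_denominator_fraction:.2%})",
        )
    )

    return QCReport(well_id=table.well_id, checks=checks, reference_channel=reference_channel)
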