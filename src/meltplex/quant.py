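"""Poisson absolute quantification, allele fractions, LoB/LoD, replicate stats.

Partition occupancy is Poisson, so the mean copies per partition is
estimated from the fraction of negative partitions: λ̂ = −ln(m/N) with
``m`` negatives out of ``N`` analyzed.  The 95% CI uses the delta-method
standard error √((N−m)/(N·m)) on λ̂; a well with zero positives reports
the one-sided rule-of-three upper bound 3/N.

Detection limits follow the blank-replicate construction: with per-replicate
false-positive partition counts, LoB = mean + 1.645·SD and the analytical
LoD = LoB + 1.645·SD, each also expressed as a percentage of the total
copies put into the reaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calling import CallTable
from .errors import QuantificationError, SaturatedWellError
from .panel import PanelConfig

__all__ = [
    "ConcordanceResult",
    "DetectionLimits",
    "LocusSummary",
    "TargetQuantification",
    "allele_fractions",
    "concordance",
    "estimate_lambda",
    "frequency_pct",
    "limit_of_blank",
    "limit_of_detection",
    "quantify_targets",
    "replicate_stats",
    "round_half_away",
]

#: z-value mapping SD to the 95th percentile of a normal distribution,
#: used by the LoB/LoD constructions.
LOB_Z = 1.645

Z95 = 1.96


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 → 0.01, −0.005 → −0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def frequency_pct(partitions: float, total_copies: float) -> float:
    """Detection-limit frequency: partitions as a percentage of total copies."""
    if total_copies <= 0:
        raise QuantificationError("total_copies must be positive")
    return partitions / total_copies * 100.0


# ---------------------------------------------------------------------------
# lambda estimation


def estimate_lambda(positives: int, analyzed: int) -> Tuple[float, Tuple[float, float]]:
    """Estimate mean copies/partition and a 95% CI from positive counts.

    Returns ``(lambda_hat, (ci_low, ci_high))``.  ``positives == 0`` gives
    ``(0, (0, 3/analyzed))``; ``positives == analyzed`` raises
    :class:`SaturatedWellError` (copy number inestimable; re-dilute).
    """
    if analyzed < 1:
        raise QuantificationError("analyzed must be >= 1")
    if not 0 <= positives <= analyzed:
        raise QuantificationError(
            f"positives {positives} outside [0, analyzed={analyzed}]"
        )
    if positives == 0:
        return 0.0, (0.0, 3.0 / analyzed)
    if positives == analyzed:
        raise SaturatedWellError()
    m = analyzed - positives  # negatives
    lam = -math.log(m / analyzed)
    se = math.sqrt((analyzed - m) / (analyzed * m))
    return lam, (max(0.0, lam - Z95 * se), lam + Z95 * se)


@dataclass
class TargetQuantification:
    """Absolute quantification for one probe in one well."""

    probe_id: str
    positives: int
    analyzed: int
    lambda_hat: float
    lambda_ci95: Tuple[float, float]
    copies_per_uL: float
    total_copies: float
    total_ci95: Tuple[float, float]
    saturated: bool = False


def quantify_targets(calls: CallTable, panel: PanelConfig) -> List[TargetQuantification]:
    """Per-probe copy numbers scaled to the full (undigitized) assay input.

    total_copies = λ̂·analyzed / loaded_fraction; saturated probes are
    reported with NaN estimates and ``saturated=True`` rather than aborting
    the other probes.
    """
    out: List[TargetQuantification] = []
    analyzed = calls.analyzed
    positives = calls.positives
    scale = analyzed / panel.loaded_fraction
    for j, probe_id in enumerate(calls.probe_ids):
        pos = int(positives[j])
        try:
            lam, (lo, hi) = estimate_lambda(pos, analyzed)
        except SaturatedWellError:
            nan = float("nan")
            out.append(
                TargetQuantification(
                    probe_id=probe_id,
                    positives=pos,
                    analyzed=analyzed,
                    lambda_hat=nan,
                    lambda_ci95=(nan, nan),
                    copies_per_uL=nan,
                    total_copies=nan,
                    total_ci95=(nan, nan),
                    saturated=True,
                )
            )
            continue
        total = lam * scale
        out.append(
            TargetQuantification(
                probe_id=probe_id,
                positives=pos,
                analyzed=analyzed,
                lambda_hat=lam,
                lambda_ci95=(lo, hi),
                copies_per_uL=total / panel.reaction_volume_uL,
                total_copies=total,
                total_ci95=(lo * scale, hi * scale),
            )
        )
    return out


@dataclass
class LocusSummary:
    """Both alleles of one biallelic locus."""

    locus_id: str
    copies_A: float
    copies_B: float
    allele_fraction_A: float
    minor_fraction: float


def allele_fractions(
    quants: Sequence[TargetQuantification],
    panel: PanelConfig,
    *,
    on_undefined: str = "raise",
) -> List[LocusSummary]:
    """Per-locus allele fraction AF_A = c_A/(c_A + c_B) and minor fraction.

    Loci with a saturated allele or zero total copies raise
    :class:`QuantificationError` naming the locus (``on_undefined="skip"``
    drops them instead, e.g. for blank wells).
    """
    if on_undefined not in ("raise", "skip"):
        raise ValueError("on_undefined must be 'raise' or 'skip'")
    by_probe: Dict[str, TargetQuantification] = {q.probe_id: q for q in quants}
    loci: Dict[str, Dict[str, TargetQuantification]] = {}
    for p in panel.probes:
        if p.probe_id in by_probe:
            loci.setdefault(p.locus_id, {})[p.allele] = by_probe[p.probe_id]
    out: List[LocusSummary] = []
    for locus_id, alleles in loci.items():
        if set(alleles) != {"A", "B"}:
            continue  # locus not fully quantified
        qa, qb = alleles["A"], alleles["B"]
        if qa.saturated or qb.saturated:
            if on_undefined == "skip":
                continue
            raise QuantificationError(
                f"locus {locus_id!r}: allele fraction undefined (saturated allele)"
            )
        total = qa.total_copies + qb.total_copies
        if total == 0:
            if on_undefined == "skip":
                continue
            raise QuantificationError(
                f"locus {locus_id!r}: allele fraction undefined (zero copies for both alleles)"
            )
        af = qa.total_copies / total
        out.append(
            LocusSummary(
                locus_id=locus_id,
                copies_A=qa.total_copies,
                copies_B=qb.total_copies,
                allele_fraction_A=af,
                minor_fraction=min(af, 1.0 - af),
            )
        )
    return out


# ---------------------------------------------------------------------------
# detection limits


@dataclass
class DetectionLimits:
    """LoB/LoD for one probe, in partitions and as % of input copies."""

    probe_id: str
    n_replicates: int
    fp_mean: float
    fp_sd: float
    total_copies_denominator: float
    lob_partitions: float
    lob_frequency_pct: float
    lod_partitions: Optional[float] = None
    lod_frequency_pct: Optional[float] = None

    @property
    def lob_frequency_pct_rounded(self) -> float:
        return round_half_away(self.lob_frequency_pct, 2)

    @property
    def lod_frequency_pct_rounded(self) -> Optional[float]:
        if self.lod_frequency_pct is None:
            return None
        return round_half_away(self.lod_frequency_pct, 2)


def limit_of_blank(
    fp_counts: Sequence[float], total_copies: float, probe_id: str = ""
) -> DetectionLimits:
    """LoB = mean + 1.645·SD of per-replicate false-positive partition counts.

    ``total_copies`` is the denominator for the frequency (% of input
    copies); SD is the n−1 sample SD.  Non-integer counts are permitted
    (normalization can yield partial partitions) but warned about.
    """
    counts = np.asarray(fp_counts, dtype=float)
    if counts.size < 2:
        raise QuantificationError("limit_of_blank requires at least 2 replicates")
    if (counts < 0).any():
        raise QuantificationError("false-positive counts must be >= 0")
    if not np.allclose(counts, np.round(counts)):
        warnings.warn("non-integer false-positive counts supplied", stacklevel=2)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    lob = mean + LOB_Z * sd
    return DetectionLimits(
        probe_id=probe_id,
        n_replicates=int(counts.size),
        fp_mean=mean,
        fp_sd=sd,
        total_copies_denominator=float(total_copies),
        lob_partitions=lob,
        lob_frequency_pct=frequency_pct(lob, total_copies),
    )


def limit_of_detection(lob: DetectionLimits) -> DetectionLimits:
    """Analytical LoD = LoB + 1.645·SD, with its frequency (% of input copies)."""
    lod = lob.lob_partitions + LOB_Z * lob.fp_sd
    return replace(
        lob,
        lod_partitions=lod,
        lod_frequency_pct=frequency_pct(lod, lob.total_copies_denominator),
    )


# ---------------------------------------------------------------------------
# replicate / concordance statistics


def replicate_stats(values: Sequence[float]) -> Tuple[float, float, float, Tuple[float, float]]:
    """(mean, sample SD, CV%, 95% CI of the mean) for replicate measurements."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise QuantificationError("replicate_stats requires at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0:
        raise QuantificationError("CV undefined for zero mean")
    cv = sd / mean * 100.0
    half = Z95 * sd / math.sqrt(arr.size)
    return mean, sd, cv, (mean - half, mean + half)


@dataclass
class ConcordanceResult:
    """Agreement between two series of copy-number measurements (log10 scale)."""

    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    cv_pct: Optional[Dict[str, float]] = None


def concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Pearson r and OLS fit of log10(y) on log10(x)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise QuantificationError("x and y must have equal length")
    if xa.size < 3:
        raise QuantificationError("concordance requires at least 3 paired values")
    if (xa <= 0).any() or (ya <= 0).any():
        raise QuantificationError("all copy numbers must be positive (log10 applied)")
    lx, ly = np.log10(xa), np.log10(ya)
    if np.allclose(lx, lx[0]):
        raise QuantificationError("zero variance in x: regression undefined")
    fit = stats.linregress(lx, ly)
    r = float(fit.rvalue)
    return ConcordanceResult(
        n=int(xa.size),
        pearson_r=r,
        r_squared=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
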