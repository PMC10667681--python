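"""Ground-truthed synthetic wells: Poisson loading + phenomenological melt model.

Each probe's target copies are distributed over partitions as
Poisson(copies·loaded_fraction/N).  A partition that received at least one
copy has that probe fully cleaved (endpoint plateau); cleaved probes are
quenched below their final-hairpin melt temperature and recover fluorescence
above it, so their window ratio rises well above 1.  Channel fluorescence at
imaging temperature T is the sum over the channel's probes:

    F[p, c](T) = sum_k A[p, k] * (q + (1-q)·sigmoid((T - Tm_k)/s)  if cleaved
                                  else 1)            * (1 + eps[p, c](T))

with per-partition amplitudes A, residual quench q, melt steepness s, and
multiplicative Gaussian read noise eps.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .calling import call_partitions, compute_ratios, normalize_ratios
from .errors import MeltplexError, PanelValidationError
from .io import PartitionTable
from .panel import CHANNELS, PanelConfig, validate_panel

__all__ = [
    "GroundTruth",
    "MixtureWell",
    "SimulationConfig",
    "genotype_doses",
    "simulate_blank_replicates",
    "simulate_mixture_series",
    "simulate_well",
]


class SimulationConfig(BaseModel):
    """Inputs and nuisance parameters for one simulated well.

    Noise magnitudes are plausibility defaults, not instrument
    measurements; they are chosen so that negative-partition ratios sit at
    1 with a spread far below the smallest calling threshold.
    """

    model_config = ConfigDict(extra="forbid")

    panel: PanelConfig
    copies_per_target: Dict[str, float] = Field(default_factory=dict)
    noise_sd_frac: float = Field(default=0.005, ge=0.0)
    amplitude_cv: float = Field(default=0.05, ge=0.0)
    residual_quench: float = Field(default=0.05, ge=0.0, lt=1.0)
    melt_steepness: float = Field(default=0.8, gt=0.0)
    false_positive_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    cleavage_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    background_rfu: float = Field(default=100.0, ge=0.0)
    seed: int = 0


@dataclass
class GroundTruth:
    """Simulator truth for recovery tests.

    ``occupancy`` has shape (n_partitions, n_probes) in panel probe order;
    digitized copies are its per-probe column sums, exactly.
    """

    probe_ids: List[str]
    true_copies_input: np.ndarray
    occupancy: np.ndarray
    seed: Optional[int] = None

    @property
    def true_copies_digitized(self) -> np.ndarray:
        return self.occupancy.sum(axis=0)

    def input_copies_for(self, probe_id: str) -> float:
        return float(self.true_copies_input[self.probe_ids.index(probe_id)])

    def to_dict(self) -> dict:
        dig = self.true_copies_digitized
        return {
            "seed": self.seed,
            "probes": {
                pid: {
                    "input_copies": float(self.true_copies_input[j]),
                    "digitized_copies": int(dig[j]),
                }
                for j, pid in enumerate(self.probe_ids)
            },
        }


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_well(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "W01",
) -> tuple:
    """Generate one well; returns ``(PartitionTable, GroundTruth)``.

    Unknown probe ids in ``copies_per_target`` are an error; probes not
    mentioned get zero copies.  The RNG draw order is fixed (occupancy,
    spontaneous cleavage, amplitudes, read noise) so identical configs and
    seeds give byte-identical tables.
    """
    panel = cfg.panel
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    known = set(panel.probe_ids())
    unknown = sorted(set(cfg.copies_per_target) - known)
    if unknown:
        raise MeltplexError(f"copies_per_target references unknown probe(s): {unknown}")

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N = panel.partitions_per_well
    probes = panel.probes
    K = len(probes)

    copies = np.array(
        [float(cfg.copies_per_target.get(p.probe_id, 0.0)) for p in probes]
    )
    if (copies < 0).any():
        raise MeltplexError("copies_per_target values must be >= 0")
    lam = copies * panel.loaded_fraction / N
    occupancy = rng.poisson(lam, size=(N, K))

    cleaved = occupancy >= 1
    if cfg.false_positive_rate > 0:
        cleaved |= rng.random((N, K)) < cfg.false_positive_rate

    amps = np.array([p.amplitude for p in probes])
    A = amps * (1.0 + rng.normal(0.0, cfg.amplitude_cv, size=(N, K)))
    # resample non-positive amplitudes (pathological only at large CV)
    bad = A <= 0
    while bad.any():
        A[bad] = amps[np.nonzero(bad)[1]] * (
            1.0 + rng.normal(0.0, cfg.amplitude_cv, size=int(bad.sum()))
        )
        bad = A <= 0

    temps = np.asarray(panel.temperatures)
    tms = np.array([p.tm_final_hairpin for p in probes])
    q, s, pc = cfg.residual_quench, cfg.melt_steepness, cfg.cleavage_fraction
    melt = q + (1.0 - q) * _logistic((temps[None, :] - tms[:, None]) / s)  # (K, 4)
    # partial cleavage mixes melted and intact probe signal
    cleaved_shape = pc * melt + (1.0 - pc)  # (K, 4)

    shape = np.where(
        cleaved[:, :, None], cleaved_shape[None, :, :], 1.0
    )  # (N, K, 4)
    contrib = A[:, :, None] * shape

    F = np.full((N, len(CHANNELS), len(temps)), cfg.background_rfu, dtype=float)
    for j, p in enumerate(probes):
        ci = CHANNELS.index(p.channel)
        F[:, ci, :] += contrib[:, j, :]

    if cfg.noise_sd_frac > 0:
        F *= 1.0 + rng.normal(0.0, cfg.noise_sd_frac, size=F.shape)
    np.maximum(F, 0.0, out=F)

    table = PartitionTable(well_id=well_id, fluorescence=F)
    truth = GroundTruth(
        probe_ids=[p.probe_id for p in probes],
        true_copies_input=copies,
        occupancy=occupancy,
        seed=cfg.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# mixtures


def genotype_doses(genotype: Dict[str, str]) -> Dict[str, Dict[str, float]]:
    """Expand locus → genotype strings to per-allele dose maps.

    ``"A"``/``"B"`` are homozygous (dose 1.0 on that allele); ``"AB"`` is
    heterozygous (0.5 each).  Doses sum to one copy per hge per locus.
    """
    out: Dict[str, Dict[str, float]] = {}
    for locus, g in genotype.items():
        if g == "A":
            out[locus] = {"A": 1.0, "B": 0.0}
        elif g == "B":
            out[locus] = {"A": 0.0, "B": 1.0}
        elif g in ("AB", "BA"):
            out[locus] = {"A": 0.5, "B": 0.5}
        else:
            raise MeltplexError(f"locus {locus!r}: genotype must be 'A', 'B' or 'AB', got {g!r}")
    return out


@dataclass
class MixtureWell:
    """One simulated well of a mixture series."""

    fraction: float
    replicate: int
    table: PartitionTable
    truth: GroundTruth


def mixture_copies(
    panel: PanelConfig,
    genotype_major: Dict[str, str],
    genotype_minor: Dict[str, str],
    total_hge: float,
    fraction: float,
) -> Dict[str, float]:
    """Per-probe copies for a two-genotype mixture at a given minor fraction.

    One hge contributes one allele copy per locus: copies of allele ``a``
    at locus ``L`` = total_hge·[(1−f)·dose_major(L,a) + f·dose_minor(L,a)].
    """
    if not 0.0 <= fraction <= 1.0:
        raise MeltplexError(f"minor fraction must be in [0, 1], got {fraction}")
    dmaj = genotype_doses(genotype_major)
    dmin = genotype_doses(genotype_minor)
    copies: Dict[str, float] = {}
    for p in panel.probes:
        for name, doses in (("major", dmaj), ("minor", dmin)):
            if p.locus_id not in doses:
                raise MeltplexError(
                    f"locus {p.locus_id!r} missing from {name} genotype"
                )
        copies[p.probe_id] = total_hge * (
            (1.0 - fraction) * dmaj[p.locus_id][p.allele]
            + fraction * dmin[p.locus_id][p.allele]
        )
    return copies


def simulate_mixture_series(
    panel: PanelConfig,
    genotype_major: Dict[str, str],
    genotype_minor: Dict[str, str],
    total_hge: float,
    fractions: Sequence[float],
    replicates: int,
    seed: int,
    **sim_kwargs,
) -> List[MixtureWell]:
    """Wells for every (minor fraction × replicate) design point.

    Each well gets an independent child RNG stream spawned from ``seed``;
    extra keyword arguments are forwarded to :class:`SimulationConfig`.
    """
    if replicates < 1:
        raise MeltplexError("replicates must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(len(fractions) * replicates)
    wells: List[MixtureWell] = []
    i = 0
    for f in fractions:
        copies = mixture_copies(panel, genotype_major, genotype_minor, total_hge, f)
        for rep in range(replicates):
            cfg = SimulationConfig(
                panel=panel, copies_per_target=copies, seed=seed, **sim_kwargs
            )
            rng = np.random.default_rng(seeds[i])
            table, truth = simulate_well(
                cfg, rng=rng, well_id=f"f{f:g}_r{rep + 1}"
            )
            wells.append(MixtureWell(fraction=f, replicate=rep + 1, table=table, truth=truth))
            i += 1
    return wells


# ---------------------------------------------------------------------------
# blanks


def simulate_blank_replicates(
    panel: PanelConfig,
    n: int,
    false_positive_rate: float,
    seed: int,
    *,
    full_pipeline: bool = False,
    **sim_kwargs,
) -> Dict[str, List[int]]:
    """False-positive partition counts from ``n`` blank (zero-target) wells.

    By default counts spontaneously cleaved partitions directly (binomial
    per probe), which is what noise-free thresholding recovers; with
    ``full_pipeline=True`` each well is pushed through
    ratio/normalize/call so threshold-level noise can also contribute.
    """
    if n < 2:
        raise MeltplexError("simulate_blank_replicates requires n >= 2 wells")
    probe_ids = panel.probe_ids()
    rng = np.random.default_rng(seed)
    counts: Dict[str, List[int]] = {pid: [] for pid in probe_ids}
    if not full_pipeline:
        draws = rng.binomial(panel.partitions_per_well, false_positive_rate, size=(n, len(probe_ids)))
        for j, pid in enumerate(probe_ids):
            counts[pid] = [int(c) for c in draws[:, j]]
        return counts
    seeds = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        cfg = SimulationConfig(
            panel=panel,
            copies_per_target={},
            false_positive_rate=false_positive_rate,
            seed=seed,
            **sim_kwargs,
        )
        table, _ = simulate_well(cfg, rng=np.random.default_rng(seeds[i]), well_id=f"blank_{i + 1}")
        ratios = normalize_ratios(compute_ratios(table, panel), panel.normalization)
        calls = call_partitions(ratios, panel)
        for pid in probe_ids:
            counts[pid].append(calls.positives_for(pid))
    return counts
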