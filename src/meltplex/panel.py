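"""Assay/platform data model: probes, channels, melt windows, thresholds.

The panel describes everything the calling and quantification stages need to
know about an assay: the four imaging temperatures, the probe→(channel,
melt window) assignment, per-probe positivity thresholds, and platform
constants (partitions per well, loaded fraction, volumes).  A melt window
``w`` spans the interval between imaging temperatures ``T_w`` and
``T_{w+1}``, so four temperatures give three windows per optical channel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import PanelValidationError

__all__ = [
    "CHANNELS",
    "Channel",
    "NormalizationConfig",
    "PanelConfig",
    "ProbeSpec",
    "Violation",
    "default_prototype_panel",
    "load_panel_config",
    "save_panel_config",
    "validate_panel",
]

Channel = Literal["blue", "green", "yellow", "red"]

#: Optical channel order used for array layouts throughout the package.
CHANNELS: tuple = ("blue", "green", "yellow", "red")

#: Number of melt windows per channel (four imaging temperatures).
N_WINDOWS = 3


class NormalizationConfig(BaseModel):
    """Rolling-window baseline normalization settings.

    ``rolling_median`` (default) takes the median of all raw ratios in a
    centered window; ``rolling_mean_of_preliminary_negatives`` takes the
    mean of raw ratios at or below ``preliminary_negative_cutoff``.
    """

    model_config = ConfigDict(extra="forbid")

    window_size: int = 1001
    statistic: Literal[
        "rolling_median", "rolling_mean_of_preliminary_negatives"
    ] = "rolling_median"
    preliminary_negative_cutoff: float = 1.0

    @field_validator("window_size")
    @classmethod
    def _odd_and_at_least_three(cls, v: int) -> int:
        if v < 3 or v % 2 == 0:
            raise ValueError("window_size must be an odd integer >= 3")
        return v


class ProbeSpec(BaseModel):
    """One allele-specific probe: optical channel, melt window, threshold.

    ``tm_final_hairpin`` and ``amplitude`` parameterize the simulator only;
    calling depends solely on (channel, melt_window, threshold).
    """

    model_config = ConfigDict(extra="forbid")

    probe_id: str
    locus_id: str
    allele: Literal["A", "B"]
    channel: Channel
    melt_window: int = Field(ge=1, le=N_WINDOWS)
    threshold: float = Field(gt=1.0, description="positivity ratio cutoff (strict >)")
    tm_final_hairpin: float = Field(gt=0.0)
    amplitude: float = Field(default=1000.0, gt=0.0)


class PanelConfig(BaseModel):
    """A complete assay definition plus platform constants."""

    model_config = ConfigDict(extra="forbid")

    temperatures: List[float] = Field(min_length=4, max_length=4)
    probes: List[ProbeSpec]
    partitions_per_well: int = Field(default=20480, ge=1)
    loaded_fraction: float = Field(default=0.9, gt=0.0, le=1.0)
    reaction_volume_uL: float = Field(default=10.0, gt=0.0)
    dna_input_uL: float = Field(default=4.0, gt=0.0)
    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)

    @model_validator(mode="after")
    def _temperatures_increasing(self) -> "PanelConfig":
        t = self.temperatures
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be strictly increasing")
        return self

    # -- convenience accessors -------------------------------------------

    def window_bounds(self, window: int) -> tuple:
        """(lower, upper) imaging temperature of melt window ``window`` (1-based)."""
        if not 1 <= window <= N_WINDOWS:
            raise ValueError(f"melt window must be in 1..{N_WINDOWS}, got {window}")
        return self.temperatures[window - 1], self.temperatures[window]

    def probe(self, probe_id: str) -> ProbeSpec:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def probe_ids(self) -> List[str]:
        return [p.probe_id for p in self.probes]

    def slot_of(self, probe_id: str) -> tuple:
        """(channel index, window index) of a probe, both 0-based."""
        p = self.probe(probe_id)
        return CHANNELS.index(p.channel), p.melt_window - 1

    def panel_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form of the panel."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_panel`."""

    rule: str
    message: str
    probe_id: Optional[str] = None


def validate_panel(panel: PanelConfig) -> List[Violation]:
    """Check cross-field invariants; return violations instead of raising.

    Field-level constraints (threshold > 1, window in 1..3, ...) are
    enforced at construction time by pydantic; this checks everything that
    spans probes or couples probes to the temperature ladder.
    """
    violations: List[Violation] = []

    if len(panel.probes) > len(CHANNELS) * N_WINDOWS:
        violations.append(
            Violation(
                rule="capacity",
                message=(
                    f"{len(panel.probes)} probes exceed capacity of "
                    f"{len(CHANNELS) * N_WINDOWS} (channels x windows)"
                ),
            )
        )

    seen: dict = {}
    for p in panel.probes:
        slot = (p.channel, p.melt_window)
        if slot in seen:
            violations.append(
                Violation(
                    rule="duplicate_slot",
                    probe_id=p.probe_id,
                    message=(
                        f"probes {seen[slot]!r} and {p.probe_id!r} both assigned "
                        f"to channel {p.channel!r} window {p.melt_window}"
                    ),
                )
            )
        else:
            seen[slot] = p.probe_id

    for p in panel.probes:
        lo, hi = panel.window_bounds(p.melt_window)
        if not (lo < p.tm_final_hairpin < hi):
            violations.append(
                Violation(
                    rule="tm_outside_window",
                    probe_id=p.probe_id,
                    message=(
                        f"probe {p.probe_id!r}: tm_final_hairpin "
                        f"{p.tm_final_hairpin} not strictly inside window "
                        f"{p.melt_window} ({lo}, {hi})"
                    ),
                )
            )

    by_locus: dict = {}
    for p in panel.probes:
        by_locus.setdefault(p.locus_id, []).append(p)
    for locus, probes in by_locus.items():
        alleles = [p.allele for p in probes]
        if len(probes) > 2 or len(set(alleles)) != len(alleles):
            violations.append(
                Violation(
                    rule="locus_alleles",
                    probe_id=probes[0].probe_id,
                    message=(
                        f"locus {locus!r} must have at most one probe per allele "
                        f"(got alleles {alleles})"
                    ),
                )
            )

    return violations


# ---------------------------------------------------------------------------
# prototype 12-plex panel

_PROTOTYPE_THRESHOLDS = {
    "P1-A": 1.075,
    "P1-B": 1.1,
    "P2-A": 1.06,
    "P2-B": 1.11,
    "P3-A": 1.08,
    "P3-B": 1.12,
    "P4-A": 1.07,
    "P4-B": 1.1,
    "P5-A": 1.085,
    "P5-B": 1.1,
    "P6-A": 1.08,
    "P6-B": 1.075,
}

# Probe -> slot assignment is a documented, overridable convention: results
# depend only on thresholds and window membership, not on which named probe
# occupies which slot.
_PROTOTYPE_SLOTS = {
    "P1-A": ("blue", 1),
    "P1-B": ("blue", 2),
    "P2-A": ("blue", 3),
    "P2-B": ("green", 1),
    "P3-A": ("green", 2),
    "P3-B": ("green", 3),
    "P4-A": ("yellow", 1),
    "P4-B": ("yellow", 2),
    "P5-A": ("yellow", 3),
    "P5-B": ("red", 1),
    "P6-A": ("red", 2),
    "P6-B": ("red", 3),
}

_PROTOTYPE_TEMPERATURES = [60.0, 72.0, 81.0, 92.0]

# Simulator hairpin Tm defaults: window midpoints, for maximal ratio
# contrast at both bracketing imaging temperatures.
_WINDOW_MID_TM = {1: 66.0, 2: 76.5, 3: 86.5}


def default_prototype_panel() -> PanelConfig:
    """The 12-probe prototype panel: 3 probes per channel, 20,480 partitions."""
    probes = []
    for probe_id, threshold in _PROTOTYPE_THRESHOLDS.items():
        channel, window = _PROTOTYPE_SLOTS[probe_id]
        locus_id, allele = probe_id.split("-")
        probes.append(
            ProbeSpec(
                probe_id=probe_id,
                locus_id=locus_id,
                allele=allele,
                channel=channel,
                melt_window=window,
                threshold=threshold,
                tm_final_hairpin=_WINDOW_MID_TM[window],
            )
        )
    return PanelConfig(temperatures=list(_PROTOTYPE_TEMPERATURES), probes=probes)


def default_panel_path() -> Path:
    """Path of the shipped YAML copy of the prototype panel."""
    return Path(__file__).parent / "data" / "prototype_panel.yaml"


# ---------------------------------------------------------------------------
# config file I/O

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("yaml", "json"):
            raise ValueError(f"unsupported panel config format {format!r}")
        return format
    return "json" if path.suffix.lower() == ".json" else "yaml"


def load_panel_config(path, format: Optional[str] = None) -> PanelConfig:
    """Load and fully validate a panel config from YAML (default) or JSON.

    Raises ``FileNotFoundError``, a parse error, a pydantic
    ``ValidationError`` for field-level schema violations, or
    :class:`PanelValidationError` for cross-field invariant violations
    (duplicate slots, Tm outside window, capacity, locus/allele structure).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise PanelValidationError(
            [Violation(rule="schema", message=f"{path}: top level must be a mapping")]
        )
    panel = PanelConfig.model_validate(data)
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


def save_panel_config(panel: PanelConfig, path, format: Optional[str] = None) -> None:
    """Write a panel config; ``load_panel_config`` round-trips it exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data = panel.model_dump(mode="json")
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
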