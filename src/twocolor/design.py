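"""Hybridization designs for dual-color (two-channel) microarrays.

A dual-color array co-hybridizes two samples, one labeled Cy3 and one Cy5,
so every array contributes exactly two intensity channels.  A
:class:`HybridizationDesign` maps each channel to the sample measured in it
and to that sample's factor levels: the treatment (or group) of biological
interest, the experimental unit it came from (a cell line or a human
subject), and optionally a technical replicate set.

The module also splits a technically replicated design into two
biologically identical halves, which downstream reproducibility analyses
compare.  Two rules are supported:

``by-replicate-set``
    Channels carry an explicit replicate-set label (1 or 2); each array's
    two channels share a label and land in the same half.  This is the
    natural split for a fully replicated factorial experiment.

``once-per-subject``
    Every unit (subject) was hybridized exactly twice; each half receives
    one of its two channels.  Because co-hybridization links units into
    cycles, the split walks each cycle and alternates whole arrays between
    the halves, so that as many within-array sample pairs as possible stay
    intact inside a half (at most one array per odd cycle is torn apart).
    This keeps the with-array-effect model estimable within each half.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DYES = ("Cy3", "Cy5")

SPLIT_BY_REPLICATE_SET = "by-replicate-set"
SPLIT_ONCE_PER_SUBJECT = "once-per-subject"


@dataclass(frozen=True, order=True)
class ChannelKey:
    """One of the two dye channels of one array."""

    array_id: str
    dye: str

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise ValueError(f"dye must be one of {DYES}, got {self.dye!r}")

    def __str__(self) -> str:
        return f"{self.array_id}:{self.dye}"

    @classmethod
    def parse(cls, text: str) -> "ChannelKey":
        """Parse an ``array:dye`` label such as ``"A01:Cy3"``."""
        array_id, sep, dye = text.rpartition(":")
        if not sep or not array_id:
            raise ValueError(f"cannot parse channel label {text!r}")
        return cls(array_id, _normalize_dye(dye))


def _normalize_dye(dye: str) -> str:
    for d in DYES:
        if dye.lower() == d.lower():
            return d
    raise ValueError(f"unknown dye {dye!r}; expected Cy3 or Cy5")


@dataclass(frozen=True)
class DesignRow:
    """Mapping of one channel to its sample and factor levels."""

    channel: ChannelKey
    sample_id: str
    treatment: str
    unit: str
    replicate_set: int | None = None


class HybridizationDesign:
    """Ordered collection of :class:`DesignRow` describing an experiment."""

    def __init__(self, rows: Iterable[DesignRow]):
        self.rows: list[DesignRow] = list(rows)
        if not self.rows:
            raise ValueError("design must contain at least one channel")
        self._by_channel = {r.channel: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, HybridizationDesign) and self.rows == other.rows

    @property
    def channels(self) -> list[ChannelKey]:
        return [r.channel for r in self.rows]

    @property
    def arrays(self) -> list[str]:
        return _ordered_unique(r.channel.array_id for r in self.rows)

    @property
    def treatments(self) -> list[str]:
        return _ordered_unique(r.treatment for r in self.rows)

    @property
    def units(self) -> list[str]:
        return _ordered_unique(r.unit for r in self.rows)

    def row_for(self, channel: ChannelKey) -> DesignRow:
        return self._by_channel[channel]

    def subset(self, channels: Sequence[ChannelKey]) -> "HybridizationDesign":
        """Sub-design containing ``channels``, in this design's row order."""
        wanted = set(channels)
        missing = wanted - set(self._by_channel)
        if missing:
            raise KeyError(f"channels not in design: {sorted(map(str, missing))}")
        return HybridizationDesign(r for r in self.rows if r.channel in wanted)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [r.channel.array_id for r in self.rows],
                "dye": [r.channel.dye for r in self.rows],
                "sample_id": [r.sample_id for r in self.rows],
                "treatment": [r.treatment for r in self.rows],
                "unit": [r.unit for r in self.rows],
                "replicate_set": [r.replicate_set for r in self.rows],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HybridizationDesign":
        required = {"array_id", "dye", "sample_id", "treatment", "unit"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        rows = []
        for rec in frame.to_dict("records"):
            rep = rec.get("replicate_set")
            if rep is None or (isinstance(rep, float) and np.isnan(rep)):
                rep = None
            else:
                rep = int(rep)
            rows.append(
                DesignRow(
                    channel=ChannelKey(str(rec["array_id"]), _normalize_dye(str(rec["dye"]))),
                    sample_id=str(rec["sample_id"]),
                    treatment=str(rec["treatment"]),
                    unit=str(rec["unit"]),
                    replicate_set=rep,
                )
            )
        return cls(rows)

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        if frame["replicate_set"].isna().all():
            frame = frame.drop(columns=["replicate_set"])
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "HybridizationDesign":
        frame = pd.read_csv(path, sep="\t", comment="#")
        if "replicate_set" not in frame.columns:
            frame["replicate_set"] = None
        return cls.from_frame(frame)


@dataclass(frozen=True)
class ReplicateSplit:
    """Two disjoint, jointly exhaustive channel sets (dataset-1/dataset-2)."""

    half1: tuple[ChannelKey, ...]
    half2: tuple[ChannelKey, ...]
    rule: str

    def __post_init__(self) -> None:
        if set(self.half1) & set(self.half2):
            raise ValueError("split halves overlap")


def validate_design(design: HybridizationDesign) -> list[str]:
    """Report structural violations of a design; empty list means well-formed.

    Checks: duplicate channels, a duplicated dye on one array, arrays missing
    their dye partner or carrying extra channels, blank factor levels, samples
    with inconsistent factor levels, and per-treatment dye imbalance.  The
    caller decides which violations are fatal.
    """
    violations: list[str] = []

    channel_counts = Counter(r.channel for r in design.rows)
    for ch, n in channel_counts.items():
        if n > 1:
            violations.append(f"duplicate channel {ch} listed {n} times")

    by_array: dict[str, list[DesignRow]] = {}
    for r in design.rows:
        by_array.setdefault(r.channel.array_id, []).append(r)
    for array_id, rows in by_array.items():
        dyes = [r.channel.dye for r in rows]
        for dye, n in Counter(dyes).items():
            if n > 1:
                violations.append(f"duplicate dye on array {array_id}: {dye} appears {n} times")
        if len(rows) < 2:
            violations.append(f"array {array_id} missing dye partner ({dyes[0]} only)")
        elif len(rows) > 2:
            violations.append(f"array {array_id} has {len(rows)} channels; expected 2")

    for r in design.rows:
        for field_name in ("sample_id", "treatment", "unit"):
            if not str(getattr(r, field_name)).strip():
                violations.append(f"channel {r.channel} has empty {field_name}")

    sample_levels: dict[str, tuple[str, str]] = {}
    for r in design.rows:
        levels = (r.treatment, r.unit)
        prev = sample_levels.setdefault(r.sample_id, levels)
        if prev != levels:
            violations.append(
                f"sample {r.sample_id} has inconsistent factor levels: {prev} vs {levels}"
            )

    for treatment in design.treatments:
        n_cy3 = sum(
            1 for r in design.rows if r.treatment == treatment and r.channel.dye == "Cy3"
        )
        n_cy5 = sum(
            1 for r in design.rows if r.treatment == treatment and r.channel.dye == "Cy5"
        )
        if n_cy3 != n_cy5:
            violations.append(
                f"dye imbalance for treatment {treatment}: {n_cy3} Cy3 vs {n_cy5} Cy5"
            )

    return violations


def split_technical_replicates(
    design: HybridizationDesign,
    rule: str = SPLIT_BY_REPLICATE_SET,
    seed: int | None = None,
) -> ReplicateSplit:
    """Split a design into two biologically identical channel sets.

    Parameters
    ----------
    design
        The full design.
    rule
        ``"by-replicate-set"`` or ``"once-per-subject"`` (see module docs).
    seed
        Only used by ``once-per-subject``.  ``None`` gives the deterministic
        split (cycle walk starting at each cycle's first-listed array); an
        integer seed randomizes the per-cycle parity, producing one of the
        other valid splits for robustness studies.
    """
    if rule == SPLIT_BY_REPLICATE_SET:
        return _split_by_replicate_set(design)
    if rule == SPLIT_ONCE_PER_SUBJECT:
        return _split_once_per_subject(design, seed)
    raise ValueError(f"unknown split rule {rule!r}")


def _split_by_replicate_set(design: HybridizationDesign) -> ReplicateSplit:
    labels = {r.replicate_set for r in design.rows}
    if None in labels:
        raise ValueError("by-replicate-set split requires replicate_set on every channel")
    if labels != {1, 2}:
        raise ValueError(f"replicate_set labels must be exactly {{1, 2}}, got {sorted(labels)}")
    for array_id in design.arrays:
        sets = {r.replicate_set for r in design.rows if r.channel.array_id == array_id}
        if len(sets) != 1:
            raise ValueError(f"array {array_id} spans both replicate sets")
    half1 = tuple(r.channel for r in design.rows if r.replicate_set == 1)
    half2 = tuple(r.channel for r in design.rows if r.replicate_set == 2)
    return ReplicateSplit(half1, half2, SPLIT_BY_REPLICATE_SET)


def _split_once_per_subject(
    design: HybridizationDesign, seed: int | None
) -> ReplicateSplit:
    unit_channels: dict[str, list[DesignRow]] = {}
    for r in design.rows:
        unit_channels.setdefault(r.unit, []).append(r)
    for unit, rows in unit_channels.items():
        if len(rows) != 2:
            raise ValueError(
                f"once-per-subject split requires every unit on exactly 2 channels; "
                f"unit {unit!r} appears {len(rows)} time(s)"
            )

    by_array: dict[str, list[DesignRow]] = {}
    for r in design.rows:
        by_array.setdefault(r.channel.array_id, []).append(r)

    rng = np.random.default_rng(seed) if seed is not None else None
    assignment: dict[ChannelKey, int] = {}
    visited: set[str] = set()

    for start_array in design.arrays:
        if start_array in visited:
            continue
        rows = by_array[start_array]
        if len(rows) == 2 and rows[0].unit == rows[1].unit:
            # self-pair: the subject's two labelings co-hybridized on one array
            visited.add(start_array)
            flip = bool(rng.integers(2)) if rng is not None else False
            assignment[rows[0].channel] = 2 if flip else 1
            assignment[rows[1].channel] = 1 if flip else 2
            continue

        # walk the co-hybridization cycle: arrays are edges, units vertices
        cycle_units: list[str] = []
        cycle_arrays: list[str] = []
        current_array = start_array
        entry_unit = by_array[start_array][0].unit
        while True:
            visited.add(current_array)
            cycle_arrays.append(current_array)
            cycle_units.append(entry_unit)
            exit_unit = next(
                r.unit for r in by_array[current_array] if r.unit != entry_unit
            )
            if exit_unit == cycle_units[0]:
                break  # cycle closed
            candidates = [
                r.channel.array_id
                for r in unit_channels[exit_unit]
                if r.channel.array_id != current_array
            ]
            if not candidates:
                raise ValueError(f"unit {exit_unit!r} has both channels on one array")
            current_array = candidates[0]
            entry_unit = exit_unit

        flip = bool(rng.integers(2)) if rng is not None else False
        m = len(cycle_units)
        for t, unit in enumerate(cycle_units):
            h = 1 if (t % 2 == 0) != flip else 2
            other = 2 if h == 1 else 1
            prev_array = cycle_arrays[t - 1] if t > 0 else cycle_arrays[m - 1]
            cur_array = cycle_arrays[t]
            for r in unit_channels[unit]:
                if r.channel.array_id == prev_array and r.channel not in assignment:
                    assignment[r.channel] = h
                elif r.channel.array_id == cur_array and r.channel not in assignment:
                    assignment[r.channel] = other

    half1 = tuple(r.channel for r in design.rows if assignment[r.channel] == 1)
    half2 = tuple(r.channel for r in design.rows if assignment[r.channel] == 2)
    return ReplicateSplit(half1, half2, SPLIT_ONCE_PER_SUBJECT)


def _ordered_unique(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for item in items:
        seen.setdefault(item, None)
    return list(seen)
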