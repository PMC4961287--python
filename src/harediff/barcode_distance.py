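"""Barcode distances and molecular-clock arithmetic.

Uncorrected p-distance over aligned sequences (proportion of compared
columns that differ), with pairwise deletion: any column where either
sequence carries a gap or an ambiguous base is dropped for that pair.
Group means average the pairwise distances over all between-group pairs,
or all unordered within-group pairs when the two groups coincide.

The clock conversion is the plain linear one used for Cytb calibrations:
divergence (%) divided by rate (% per Myr) gives the split age in Myr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from os import PathLike
from typing import IO, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

COMPARABLE = frozenset("ACGT")


@dataclass(frozen=True)
class BarcodeGroup:
    """A labelled group of aligned sequences (species or lineage)."""

    label: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"group {self.label!r} has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"group {self.label!r}: unequal alignment lengths {sorted(lengths)}"
            )
        object.__setattr__(
            self, "sequences", tuple(s.upper() for s in self.sequences)
        )


@dataclass(frozen=True)
class ClockParams:
    """Divergence (%) and substitution rate (% per Myr)."""

    divergence_percent: float
    rate_percent_per_myr: float

    def __post_init__(self) -> None:
        if self.rate_percent_per_myr <= 0:
            raise ValueError("clock rate must be > 0")
        if self.divergence_percent < 0:
            raise ValueError("divergence must be >= 0")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of comparable aligned columns that differ.

    Columns where either sequence has a gap or a non-ACGT symbol are
    excluded from both numerator and denominator; an alignment with no
    comparable column yields ``nan``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = seq_a.upper(), seq_b.upper()
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in COMPARABLE and y in COMPARABLE:
            compared += 1
            if x != y:
                mismatches += 1
    return mismatches / compared if compared else math.nan


def group_mean_distance(group_a: BarcodeGroup, group_b: BarcodeGroup) -> float:
    """Mean pairwise p-distance between (or within) groups.

    For ``group_a == group_b`` the mean runs over unordered within-group
    pairs and needs at least two sequences; a singleton yields ``nan``.
    """
    if group_a == group_b:
        if len(group_a.sequences) < 2:
            return math.nan
        pairs = list(combinations(group_a.sequences, 2))
    else:
        pairs = list(product(group_a.sequences, group_b.sequences))
    distances = [p_distance(x, y) for x, y in pairs]
    distances = [d for d in distances if not math.isnan(d)]
    return sum(distances) / len(distances) if distances else math.nan


def distance_matrix(groups: Sequence[BarcodeGroup]) -> pd.DataFrame:
    """Symmetric matrix of within/between group mean distances."""
    labels = [g.label for g in groups]
    data = [
        [group_mean_distance(ga, gb) for gb in groups]
        for ga in groups
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


def mean_between_groups(groups: Sequence[BarcodeGroup]) -> float:
    """Average of all pairwise between-group mean distances."""
    vals = [
        group_mean_distance(a, b) for a, b in combinations(groups, 2)
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else math.nan


def divergence_time(clock: ClockParams) -> float:
    """Split age in Myr under a linear molecular clock."""
    return clock.divergence_percent / clock.rate_percent_per_myr


def read_barcode_groups(
    fasta_source: str | PathLike | IO,
    labels: str | PathLike | IO | Mapping[str, str] | pd.DataFrame,
) -> list[BarcodeGroup]:
    """Aligned FASTA plus a (sequence_id, group) table -> barcode groups.

    ``labels`` may be a TSV path with columns ``sequence_id`` and ``group``,
    a DataFrame of the same shape, or a plain id -> group mapping.
    """
    if isinstance(labels, pd.DataFrame):
        mapping = dict(zip(labels["sequence_id"], labels["group"]))
    elif isinstance(labels, Mapping):
        mapping = dict(labels)
    else:
        table = pd.read_csv(labels, sep="\t")
        mapping = dict(zip(table["sequence_id"], table["group"]))

    buckets: dict[str, list[str]] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        group = mapping.get(rec.id)
        if group is None:
            raise ValueError(f"sequence {rec.id!r} has no group label")
        buckets.setdefault(group, []).append(str(rec.seq))
    return [
        BarcodeGroup(label=label, sequences=tuple(seqs))
        for label, seqs in sorted(buckets.items())
    ]
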