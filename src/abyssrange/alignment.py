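"""Aligned-sequence input, site filtering and haplotype collapsing.

All downstream genetic computation (diversity statistics, distances,
networks) operates on an :class:`Alignment` plus a :class:`SiteFilter`
selecting the columns admitted to the analysis.

The default filtering convention is *complete deletion*: a column is retained
only if every sequence carries an unambiguous base (A/C/G/T) there.
Ambiguity codes (R, Y, S, W, ...) and N are treated as missing, not expanded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AlignmentFormatError, ValidationError

UNAMBIGUOUS = frozenset("ACGT")
#: IUPAC symbols accepted on input; anything else becomes N with a warning
KNOWN_SYMBOLS = frozenset("ACGTRYSWKMBDHVN-")

LOCI = ("16S", "COI", "28S", "other")


@dataclass
class Alignment:
    """Equal-length sequences with ids and optional per-sequence locality.

    ``matrix`` is an ``(n, L)`` array of single-character strings, uppercase.
    """

    ids: list[str]
    matrix: np.ndarray
    locus: str = "other"
    locality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise AlignmentFormatError("matrix shape does not match id count")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentFormatError("duplicate sequence ids")
        if len(self.ids) < 1:
            raise AlignmentFormatError("alignment must contain at least one sequence")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, seq_id: str) -> str:
        return "".join(self.matrix[self.ids.index(seq_id)])

    @classmethod
    def from_sequences(
        cls,
        pairs: list[tuple[str, str]],
        locus: str = "other",
        locality: dict[str, str] | None = None,
    ) -> "Alignment":
        """Build an alignment from (id, sequence) pairs (testing/simulation)."""
        if not pairs:
            raise AlignmentFormatError("no sequences given")
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged sequence lengths: {sorted(lengths)}")
        ids = [i for i, _ in pairs]
        mat = np.array([list(_clean(s)) for _, s in pairs], dtype="U1")
        return cls(ids=ids, matrix=mat, locus=locus, locality=dict(locality or {}))


def _clean(seq: str) -> str:
    seq = seq.upper()
    unknown = set(seq) - KNOWN_SYMBOLS
    if unknown:
        warnings.warn(
            f"unknown symbols {sorted(unknown)} mapped to N", stacklevel=3
        )
        seq = "".join(c if c in KNOWN_SYMBOLS else "N" for c in seq)
    return seq


def read_alignment(
    path: str | Path,
    locus: str = "other",
    locality_map: dict[str, str] | None = None,
) -> Alignment:
    """Read an aligned FASTA file.

    All records must have equal length; symbols are uppercased and anything
    outside the IUPAC alphabet is mapped to N with a warning.
    """
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    seen = set()
    for rid, _ in pairs:
        if rid in seen:
            raise AlignmentFormatError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
    return Alignment.from_sequences(pairs, locus=locus, locality=locality_map)


@dataclass(frozen=True)
class SiteFilter:
    """Ordered 0-based indices of alignment columns retained for analysis."""

    retained_columns: tuple[int, ...]
    source_length: int

    def __post_init__(self):
        cols = self.retained_columns
        if any(c < 0 or c >= self.source_length for c in cols):
            raise ValidationError("retained column index out of range")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValidationError("retained columns must be strictly increasing")

    @property
    def L_retained(self) -> int:
        return len(self.retained_columns)

    def apply(self, alignment: Alignment) -> np.ndarray:
        """Sub-matrix of the alignment restricted to the retained columns."""
        return alignment.matrix[:, list(self.retained_columns)]


def complete_deletion(alignment: Alignment) -> SiteFilter:
    """Retain exactly the columns where every sequence has an A/C/G/T base.

    Raises
    ------
    ValidationError
        If no column survives (all statistics would be undefined).
    """
    ok = np.isin(alignment.matrix, list(UNAMBIGUOUS)).all(axis=0)
    cols = tuple(int(i) for i in np.flatnonzero(ok))
    if not cols:
        raise ValidationError(
            "complete deletion removed every column; statistics undefined"
        )
    return SiteFilter(retained_columns=cols, source_length=alignment.length)


def all_columns(alignment: Alignment) -> SiteFilter:
    """Identity filter retaining every column (no deletion)."""
    return SiteFilter(
        retained_columns=tuple(range(alignment.length)),
        source_length=alignment.length,
    )


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str  # over retained columns
    frequency: int
    members: tuple[str, ...]
    localities: frozenset[str]


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]
    n: int

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    @property
    def frequencies(self) -> list[int]:
        return [h.frequency for h in self.haplotypes]

    def __post_init__(self):
        if sum(h.frequency for h in self.haplotypes) != self.n:
            raise ValidationError("haplotype frequencies do not sum to n")
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValidationError("haplotype representatives are not distinct")


def collapse_haplotypes(alignment: Alignment, site_filter: SiteFilter) -> HaplotypeTable:
    """Group sequences identical on the retained columns into haplotypes.

    Haplotype ids H1..Hk are assigned in lexicographic order of the
    representative sequence so that the labelling is independent of input row
    order (frequencies and memberships are order-free regardless).
    """
    sub = site_filter.apply(alignment)
    keyed: dict[str, list[str]] = {}
    for row, seq_id in zip(sub, alignment.ids):
        keyed.setdefault("".join(row), []).append(seq_id)
    haplotypes = []
    for k, (seq, members) in enumerate(sorted(keyed.items()), start=1):
        locs = frozenset(
            alignment.locality[m] for m in members if m in alignment.locality
        )
        haplotypes.append(
            Haplotype(
                haplotype_id=f"H{k}",
                sequence=seq,
                frequency=len(members),
                members=tuple(sorted(members)),
                localities=locs,
            )
        )
    return HaplotypeTable(haplotypes=tuple(haplotypes), n=alignment.n)


def write_haplotype_csv(table: HaplotypeTable, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["haplotype_id", "frequency", "localities", "members"])
        for h in table.haplotypes:
            w.writerow(
                [
                    h.haplotype_id,
                    h.frequency,
                    ";".join(sorted(h.localities)),
                    ";".join(h.members),
                ]
            )
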