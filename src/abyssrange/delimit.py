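"""Distance-threshold species partitioning with a barcode-gap score.

A single-linkage sweep over a pairwise distance matrix yields one candidate
partition per merge height (plus the all-singleton and one-group extremes).
Each partition is scored by its barcode gap — the margin between the
smallest between-group distance and the largest within-group distance.

This is a deliberately simple stand-in for full automatic-partitioning
tools: it ranks candidate splits by raw gap width only and does not compute
any panmixia probability or composite score.  Reports carry that caveat.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix
from .errors import UndefinedStatisticError, ValidationError

CAVEAT = (
    "Partitions are ranked by raw barcode-gap width from a single-linkage "
    "sweep; this is a simpler criterion than automatic-partitioning tools "
    "and computes no panmixia probability."
)


@dataclass(frozen=True)
class Partition:
    """One candidate assignment of sequences to groups at a merge height."""

    threshold: float
    groups: tuple[tuple[str, ...], ...]  # each group: sorted member ids
    max_intra: float
    min_inter: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def gap(self) -> float:
        return self.min_inter - self.max_intra

    def labels(self) -> dict[str, int]:
        return {m: gi for gi, grp in enumerate(self.groups) for m in grp}


@dataclass(frozen=True)
class PartitionSweep:
    partitions: tuple[Partition, ...]
    caveat: str = CAVEAT


@dataclass(frozen=True)
class RankedPartition:
    partition: Partition
    rank: int
    no_gap_warning: bool = False


def _score(values: np.ndarray, ids: tuple[str, ...], membership: np.ndarray,
           threshold: float) -> Partition:
    n = len(ids)
    same = membership[:, None] == membership[None, :]
    iu = np.triu_indices(n, k=1)
    intra = values[iu][same[iu]]
    inter = values[iu][~same[iu]]
    # a barcode gap needs both within- and between-group pairs; the
    # all-singleton and one-group extremes therefore have undefined gap
    max_intra = float(intra.max()) if intra.size else np.nan
    min_inter = float(inter.min()) if inter.size else np.nan
    groups = {}
    for i, m in enumerate(membership):
        groups.setdefault(int(m), []).append(ids[i])
    grp_tuples = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=lambda g: sorted(g)[0])
    )
    return Partition(
        threshold=threshold,
        groups=grp_tuples,
        max_intra=max_intra,
        min_inter=min_inter,
    )


def linkage_sweep(matrix: DistanceMatrix) -> PartitionSweep:
    """Single-linkage dendrogram sweep over a complete distance matrix.

    Emits one partition per distinct merge height, plus the all-singleton
    partition below the smallest distance and the one-group partition at the
    top.  A partition at threshold t equals the connected components of the
    graph whose edges join pairs at distance <= t.

    Raises
    ------
    ValidationError
        If the matrix contains missing (NaN) entries — recompute the
        distances under complete deletion first.
    """
    if not np.all(np.isfinite(matrix.values)):
        raise ValidationError(
            "distance matrix has missing entries; use complete-deletion distances"
        )
    ids = matrix.ids
    n = matrix.n
    if n == 1:
        only = Partition(
            threshold=0.0, groups=((ids[0],),), max_intra=0.0, min_inter=np.nan
        )
        return PartitionSweep(partitions=(only,))

    condensed = squareform(matrix.values, checks=False)
    z = linkage(condensed, method="single")
    heights = sorted(set(float(h) for h in z[:, 2]))

    partitions: list[Partition] = []
    # all-singleton partition (threshold just below the smallest merge)
    singleton = np.arange(n)
    partitions.append(_score(matrix.values, ids, singleton, threshold=-np.inf))
    seen_memberships = {tuple(singleton)}
    for h in heights:
        membership = fcluster(z, t=h, criterion="distance")
        key = tuple(int(x) for x in membership)
        if key in seen_memberships:
            continue
        seen_memberships.add(key)
        partitions.append(_score(matrix.values, ids, np.asarray(membership), h))
    # ensure the one-group partition is present even with tied top merges
    if partitions[-1].n_groups != 1:
        membership = np.zeros(n, dtype=int)
        partitions.append(
            _score(matrix.values, ids, membership, threshold=float(heights[-1]))
        )
    return PartitionSweep(partitions=tuple(partitions))


def best_partition(sweep: PartitionSweep) -> tuple[RankedPartition, list[RankedPartition]]:
    """Rank the sweep's partitions by descending gap (ties: fewer groups).

    Returns the top-ranked partition and the full ranked list; callers must
    surface the whole list, never a single silent answer.  When no partition
    has a positive gap the one-group partition is returned with a warning
    flag.
    """
    if not sweep.partitions:
        raise UndefinedStatisticError("empty partition sweep")
    finite_gap = [p for p in sweep.partitions if np.isfinite(p.gap)]
    undefined_gap = [p for p in sweep.partitions if not np.isfinite(p.gap)]
    order = sorted(finite_gap, key=lambda p: (-p.gap, p.n_groups, p.threshold))
    order += sorted(undefined_gap, key=lambda p: p.n_groups)
    ranked = [RankedPartition(partition=p, rank=r + 1) for r, p in enumerate(order)]
    if not finite_gap or max(p.gap for p in finite_gap) <= 0:
        one_group = min(sweep.partitions, key=lambda p: p.n_groups)
        return (
            RankedPartition(partition=one_group, rank=1, no_gap_warning=True),
            ranked,
        )
    return ranked[0], ranked


def write_sweep_csv(sweep: PartitionSweep, ranked: list[RankedPartition], path) -> None:
    rank_of = {id(rp.partition): rp.rank for rp in ranked}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["# " + sweep.caveat])
        w.writerow(["threshold", "n_groups", "max_intra", "min_inter", "gap", "rank"])
        for p in sweep.partitions:
            w.writerow(
                [p.threshold, p.n_groups, p.max_intra, p.min_inter, p.gap,
                 rank_of.get(id(p), "")]
            )


def write_membership_csv(partition: Partition, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "group"])
        for gi, grp in enumerate(partition.groups, start=1):
            for m in grp:
                w.writerow([m, gi])
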