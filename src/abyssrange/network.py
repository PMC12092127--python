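"""Statistical-parsimony haplotype networks.

The connection limit — the largest mutational step count that is still
parsimoniously interpretable at a probability threshold (conventionally
95%) — is estimated with a seed-deterministic Monte-Carlo scheme:

    P_pars(j) = w_j / sum_{k >= j} w_k

where w_k is the Monte-Carlo probability that k substitutions, placed
uniformly over L sites with each substitution drawing a uniformly chosen
different base, produce exactly j observed differences from the starting
sequence.  The tail over k is truncated once a term's contribution falls
below 1e-4.

Networks are minimum spanning networks over haplotype Hamming distances:
edges are added in increasing (distance, lexicographic id-pair) order and an
edge is kept when it joins two components that were distinct when its
distance class began (so tied alternative connections are retained as
reticulations).  Accepted multi-step edges are expanded through latent
(unsampled, frequency-0) intermediate nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .alignment import HaplotypeTable
from .errors import ValidationError

TAIL_CUTOFF = 1e-4


@dataclass(frozen=True)
class ParsimonyEstimate:
    j: int
    L: int
    P_pars: float
    mc_reps: int
    seed: int


def _mc_weight(k: int, j: int, L: int, reps: int, rng: np.random.Generator) -> float:
    """Probability that k uniform substitutions leave exactly j sites changed."""
    if k == 0:
        return 1.0 if j == 0 else 0.0
    if k < j:
        return 0.0
    # per-site state 0..3 relative to the start; 0 means 'matches start';
    # adding a uniform 1..3 step mod 4 draws a uniformly different base
    sites = rng.integers(0, L, size=(reps, k))
    steps = rng.integers(1, 4, size=(reps, k))
    count = np.zeros(reps, dtype=np.int64)
    for r in range(reps):
        st: dict[int, int] = {}
        row_sites = sites[r]
        row_steps = steps[r]
        for s, inc in zip(row_sites, row_steps):
            nxt = (st.get(s, 0) + inc) % 4
            if nxt == 0:
                st.pop(s, None)
            else:
                st[s] = nxt
        count[r] = len(st)
    return float(np.mean(count == j))


def parsimony_probability(
    j: int, L: int, mc_reps: int = 10000, seed: int = 0
) -> ParsimonyEstimate:
    """Estimate the parsimony probability of a j-step difference over L sites.

    Deterministic for a given seed.  j=0 returns exactly 1 (no substitutions
    are required, and the k=1 term vanishes, truncating the tail).
    """
    if not 0 <= j <= L:
        raise ValidationError(f"step count j={j} outside [0, L={L}]")
    if mc_reps < 1000:
        raise ValidationError("mc_reps must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    w_j = _mc_weight(j, j, L, mc_reps, rng)
    total = w_j
    k = j + 1
    while True:
        w_k = _mc_weight(k, j, L, mc_reps, rng)
        if w_k < TAIL_CUTOFF:
            break
        total += w_k
        k += 1
        if k > L:
            break
    p = w_j / total if total > 0 else 0.0
    return ParsimonyEstimate(j=j, L=L, P_pars=p, mc_reps=mc_reps, seed=seed)


def connection_limit(
    L: int, threshold: float = 0.95, mc_reps: int = 10000, seed: int = 0
) -> int:
    """Largest step count whose parsimony probability meets the threshold.

    Returns at least 1.  Scans j upward and stops at the first estimate
    falling below the threshold (P_pars is non-increasing in j up to
    Monte-Carlo noise).
    """
    if L < 1:
        raise ValidationError("alignment length must be >= 1")
    if threshold <= 0:
        return L  # every j qualifies: P_pars >= 0 always
    j = 1
    while j <= L:
        est = parsimony_probability(j, L, mc_reps=mc_reps, seed=seed)
        if est.P_pars < threshold:
            break
        j += 1
    return max(1, j - 1)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(table: HaplotypeTable, limit: float) -> nx.Graph:
    """Minimum spanning network over the haplotype table.

    Nodes carry ``frequency``, ``localities`` (sorted tuple) and ``latent``
    attributes; edges carry ``steps=1`` after latent expansion.  Components
    whose mutual distances all exceed ``limit`` stay disconnected.
    """
    g = nx.Graph()
    haps = sorted(table.haplotypes, key=lambda h: h.haplotype_id)
    for h in haps:
        g.add_node(
            h.haplotype_id,
            frequency=h.frequency,
            localities=tuple(sorted(h.localities)),
            latent=False,
        )
    if len(haps) < 2:
        return g

    edges = []
    for ha, hb in itertools.combinations(haps, 2):
        d = _hamming(ha.sequence, hb.sequence)
        a, b = sorted((ha.haplotype_id, hb.haplotype_id))
        edges.append((d, a, b))
    edges.sort()

    # union-find over sampled nodes; snapshot components per distance class
    parent = {h.haplotype_id: h.haplotype_id for h in haps}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted: list[tuple[int, str, str]] = []
    for d, group in itertools.groupby(edges, key=lambda e: e[0]):
        if d > limit:
            break
        snapshot = {node: find(node) for node in parent}
        to_union = []
        for _, a, b in group:
            if snapshot[a] != snapshot[b]:
                accepted.append((d, a, b))
                to_union.append((a, b))
        for a, b in to_union:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    for d, a, b in accepted:
        if d == 1:
            g.add_edge(a, b, steps=1)
        else:
            prev = a
            for k in range(1, d):
                latent = f"{a}-{b}-step-{k}"
                g.add_node(latent, frequency=0, localities=(), latent=True)
                g.add_edge(prev, latent, steps=1)
                prev = latent
            g.add_edge(prev, b, steps=1)
    return g


def classify_haplotypes(table: HaplotypeTable) -> dict[str, str]:
    """Label each haplotype 'private' (one locality) or 'shared' (several)."""
    missing = [
        h.haplotype_id for h in table.haplotypes if len(h.localities) == 0
    ]
    if missing:
        members = {
            h.haplotype_id: h.members for h in table.haplotypes if h.haplotype_id in missing
        }
        raise ValidationError(
            f"haplotypes without locality labels: {members}"
        )
    return {
        h.haplotype_id: ("private" if len(h.localities) == 1 else "shared")
        for h in table.haplotypes
    }


def write_graphml(g: nx.Graph, path) -> None:
    out = g.copy()
    for _, data in out.nodes(data=True):
        data["localities"] = ";".join(data.get("localities", ()))
    nx.write_graphml(out, path)


def write_edge_csv(g: nx.Graph, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["node1", "node2", "steps"])
        for a, b, data in sorted(g.edges(data=True)):
            w.writerow([a, b, data.get("steps", 1)])
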