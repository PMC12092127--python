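"""Pairwise genetic distances: uncorrected p, JC69 and F81 corrections.

Base frequencies for F81 are supplied, not estimated, matching workflows
where published frequency values are fixed for the correction
(``BaseFrequencies.from_alignment`` offers empirical estimation as an
option).  Saturated pairs, where the log correction is undefined, become NaN
with a warning rather than infinity so downstream summaries can skip them.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import UNAMBIGUOUS, Alignment, SiteFilter, complete_deletion
from .errors import ConfigurationError, UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class BaseFrequencies:
    piA: float
    piC: float
    piG: float
    piT: float

    def __post_init__(self):
        vals = (self.piA, self.piC, self.piG, self.piT)
        if any(not 0 < v < 1 for v in vals):
            raise ValidationError("base frequencies must lie in (0, 1)")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            # published frequency tables are often rounded to 3 decimals and
            # may miss 1 by a few thousandths: renormalize, do not reject
            if abs(total - 1.0) > 5e-3:
                raise ValidationError(f"base frequencies sum to {total}, not 1")
            warnings.warn(
                f"base frequencies sum to {total}; renormalizing", stacklevel=2
            )
            for name, v in zip(("piA", "piC", "piG", "piT"), vals):
                object.__setattr__(self, name, v / total)

    @property
    def B(self) -> float:
        """1 - sum(pi_i^2), the F81 saturation ceiling."""
        return 1.0 - (self.piA**2 + self.piC**2 + self.piG**2 + self.piT**2)

    @classmethod
    def uniform(cls) -> "BaseFrequencies":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_alignment(cls, alignment: Alignment) -> "BaseFrequencies":
        """Empirical frequencies over unambiguous bases in the alignment."""
        flat = alignment.matrix.ravel()
        counts = {b: int(np.count_nonzero(flat == b)) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            raise ValidationError("alignment contains no unambiguous bases")
        return cls(*(counts[b] / total for b in "ACGT"))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, NaN marks missing/saturated entries
    model: str  # raw | JC69 | F81
    deletion_mode: str  # complete | pairwise
    freqs: BaseFrequencies | None = None

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(np.diagonal(v), 0.0, equal_nan=False):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def p_distance_matrix(
    alignment: Alignment,
    deletion_mode: str = "complete",
    site_filter: SiteFilter | None = None,
) -> DistanceMatrix:
    """Uncorrected p-distances: differing sites / compared sites per pair.

    ``complete`` mode compares all pairs over one shared set of gap/N-free
    columns (``site_filter`` defaults to complete deletion).  ``pairwise``
    mode compares each pair over the columns where both members are
    unambiguous; a pair with zero comparable sites gets NaN with a warning.
    """
    if alignment.n < 2:
        raise UndefinedStatisticError("distance matrix needs >= 2 sequences")
    n = alignment.n
    out = np.zeros((n, n))
    if deletion_mode == "complete":
        sf = site_filter or complete_deletion(alignment)
        sub = sf.apply(alignment)
        L = sf.L_retained
        for i in range(n - 1):
            diffs = (sub[i] != sub[i + 1 :]).sum(axis=1) / L
            out[i, i + 1 :] = diffs
            out[i + 1 :, i] = diffs
    elif deletion_mode == "pairwise":
        good = np.isin(alignment.matrix, list(UNAMBIGUOUS))
        mat = alignment.matrix
        for i in range(n - 1):
            for j in range(i + 1, n):
                both = good[i] & good[j]
                m = int(both.sum())
                if m == 0:
                    warnings.warn(
                        f"no comparable sites for pair ({alignment.ids[i]}, "
                        f"{alignment.ids[j]}); entry set to NaN",
                        stacklevel=2,
                    )
                    out[i, j] = out[j, i] = np.nan
                else:
                    d = int((mat[i, both] != mat[j, both]).sum()) / m
                    out[i, j] = out[j, i] = d
    else:
        raise ConfigurationError(f"unknown deletion mode {deletion_mode!r}")
    return DistanceMatrix(
        ids=tuple(alignment.ids),
        values=out,
        model="raw",
        deletion_mode=deletion_mode,
    )


def correct_distances(
    matrix: DistanceMatrix,
    model: str,
    freqs: BaseFrequencies | None = None,
) -> DistanceMatrix:
    """Apply a JC69 or F81 multiple-hit correction to a raw p-distance matrix.

    JC69: d = -(3/4) ln(1 - 4p/3).  F81: d = -B ln(1 - p/B) with
    B = 1 - sum(pi_i^2).  Entries at or beyond saturation (log argument <= 0)
    become NaN with a warning.
    """
    if matrix.model != "raw":
        raise ConfigurationError(
            f"corrections apply to raw p-distances, got model {matrix.model!r}"
        )
    if model == "JC69":
        ceiling = 0.75
    elif model == "F81":
        if freqs is None:
            raise ConfigurationError("F81 correction requires base frequencies")
        ceiling = freqs.B
    else:
        raise ConfigurationError(f"unknown correction model {model!r}")

    p = matrix.values
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - p / ceiling
        d = np.where(arg > 0, -ceiling * np.log(np.maximum(arg, np.finfo(float).tiny)), np.nan)
    np.fill_diagonal(d, 0.0)
    n_sat = int(np.isnan(d[np.triu_indices(matrix.n, k=1)]).sum() - np.isnan(
        p[np.triu_indices(matrix.n, k=1)]
    ).sum())
    if n_sat > 0:
        warnings.warn(
            f"{n_sat} saturated pair(s) (p >= {ceiling:.4f}) set to NaN",
            stacklevel=2,
        )
    return DistanceMatrix(
        ids=matrix.ids,
        values=d,
        model=model,
        deletion_mode=matrix.deletion_mode,
        freqs=freqs if model == "F81" else None,
    )


def distance_range(matrix: DistanceMatrix) -> tuple[float, float]:
    """(min, max) over off-diagonal entries, skipping missing/saturated ones."""
    if matrix.n < 2:
        raise UndefinedStatisticError("distance range needs >= 2 sequences")
    off = matrix.offdiagonal()
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValidationError("all off-diagonal distances are missing")
    return float(finite.min()), float(finite.max())


def write_matrix_csv(matrix: DistanceMatrix, path: str | Path) -> None:
    """Square CSV with ids as header row/column; NaN written as empty cell."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *matrix.ids])
        for i, rid in enumerate(matrix.ids):
            row = [
                "" if not np.isfinite(v) else repr(float(v))
                for v in matrix.values[i]
            ]
            w.writerow([rid, *row])


def write_long_csv(matrix: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id1", "id2", "model", "distance"])
        for i in range(matrix.n - 1):
            for j in range(i + 1, matrix.n):
                v = matrix.values[i, j]
                w.writerow(
                    [
                        matrix.ids[i],
                        matrix.ids[j],
                        matrix.model,
                        "" if not np.isfinite(v) else repr(float(v)),
                    ]
                )
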