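"""Exact Fisher–Freeman–Halton test for r x c contingency tables.

Used on the confirmation-genotyping table (animal status x genotype) to
test association between genotype and survival.  The two-sided p-value is
the probability-mass criterion: the sum of conditional (multivariate
hypergeometric) probabilities of every table with the observed margins
whose probability does not exceed that of the observed table.  Tables are
enumerated exhaustively with margin-feasibility pruning; probabilities are
computed in log space from log-factorials, so the enumeration is exact up
to floating error, with a small relative tolerance on the "as or less
probable" comparison to absorb it.  A Monte-Carlo fallback handles tables
too large to enumerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["ContingencyTable", "fisher_exact_rxc", "fisher_monte_carlo"]

_MAX_ENUMERATION_N = 200


@dataclass
class ContingencyTable:
    """Non-negative integer counts with optional row/column labels."""

    counts: np.ndarray
    row_labels: Sequence[str] = field(default_factory=list)
    col_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("table must be two-dimensional")
        if (self.counts < 0).any():
            raise ValueError("table entries must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table is all zero")

    @classmethod
    def parse(cls, text: str) -> "ContingencyTable":
        """Parse ``"4,2,7;0,6,0;13,9,0"`` (rows separated by ``;``)."""
        rows = [
            [int(x) for x in row.split(",")] for row in text.split(";") if row
        ]
        return cls(np.array(rows))

    def trimmed(self) -> np.ndarray:
        """Counts with all-zero rows and columns removed (they are inert)."""
        c = self.counts
        c = c[c.sum(axis=1) > 0][:, c.sum(axis=0) > 0]
        return c


def _log_table_prob(flat: Sequence[int], log_const: float) -> float:
    return log_const - sum(math.lgamma(n + 1) for n in flat)


def _enumerate_pvalue(
    counts: np.ndarray, rel_tol: float
) -> tuple[float, float]:
    """Returns (p_value, total_probability) over all margin-preserving tables."""
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    log_const = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n + 1)
    )
    logp_obs = _log_table_prob(counts.ravel(), log_const)
    cutoff = logp_obs + math.log1p(rel_tol)
    r, c = counts.shape

    p_sum = 0.0
    total = 0.0
    cells = [0] * (r * c)

    def fill(i: int, j: int, row_left: int, col_left: tuple) -> None:
        nonlocal p_sum, total
        if i == r - 1:
            # last row forced
            for jj in range(c):
                cells[i * c + jj] = col_left[jj]
            logp = _log_table_prob(cells, log_const)
            p = math.exp(logp)
            total += p
            if logp <= cutoff:
                p_sum += p
            return
        if j == c - 1:
            v = row_left
            if v > col_left[j]:
                return
            cells[i * c + j] = v
            new_col = col_left[:j] + (col_left[j] - v,)
            fill(i + 1, 0, int(row_sums[i + 1]), new_col)
            return
        # remaining capacity of later columns bounds v from below
        later = sum(col_left[j + 1 :])
        vmin = max(0, row_left - later)
        vmax = min(row_left, col_left[j])
        for v in range(vmin, vmax + 1):
            cells[i * c + j] = v
            fill(
                i,
                j + 1,
                row_left - v,
                col_left[:j] + (col_left[j] - v,) + col_left[j + 1 :],
            )

    if r == 1 or c == 1:
        return 1.0, 1.0
    fill(0, 0, int(row_sums[0]), tuple(int(x) for x in col_sums))
    return min(p_sum, 1.0), total


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    rel_tol: float = 1e-7,
) -> float:
    """Two-sided Fisher–Freeman–Halton p-value by full enumeration.

    Raises for tables with total count above 200, where enumeration may be
    impractical — use :func:`fisher_monte_carlo` there instead.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.trimmed()
    n = int(counts.sum())
    if n > _MAX_ENUMERATION_N:
        raise ValueError(
            f"table total {n} > {_MAX_ENUMERATION_N}: enumeration impractical; "
            "use fisher_monte_carlo"
        )
    p, total = _enumerate_pvalue(counts, rel_tol)
    if not math.isclose(total, 1.0, abs_tol=1e-8):
        raise AssertionError(
            f"enumerated probabilities sum to {total}, not 1"
        )  # pragma: no cover - internal consistency
    return p


def enumerated_probability_total(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
) -> float:
    """Sum of probabilities over all margin-preserving tables (should be 1)."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    _, total = _enumerate_pvalue(table.trimmed(), 1e-7)
    return total


def fisher_monte_carlo(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    n_samples: int = 100_000,
    seed: Optional[int] = None,
    rel_tol: float = 1e-7,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the Freeman–Halton p-value.

    Samples margin-preserving tables row by row from the multivariate
    hypergeometric distribution and applies the same probability-mass
    criterion.  Returns ``(p_estimate, standard_error)``; the estimate uses
    the (k+1)/(B+1) correction so it is never exactly zero.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.trimmed()
    rng = np.random.default_rng(seed)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    log_const = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n + 1)
    )
    logp_obs = _log_table_prob(counts.ravel(), log_const)
    cutoff = logp_obs + math.log1p(rel_tol)
    hits = 0
    for _ in range(n_samples):
        remaining = col_sums.copy()
        flat: list[int] = []
        for i in range(len(row_sums) - 1):
            row = rng.multivariate_hypergeometric(remaining, int(row_sums[i]))
            remaining = remaining - row
            flat.extend(int(x) for x in row)
        flat.extend(int(x) for x in remaining)
        if _log_table_prob(flat, log_const) <= cutoff:
            hits += 1
    p = (hits + 1) / (n_samples + 1)
    se = math.sqrt(p * (1 - p) / n_samples)
    return p, se
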