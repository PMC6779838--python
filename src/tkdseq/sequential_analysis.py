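"""Lag-k sequential analysis of coded event streams.

The analysis treats each event at lag 0 as the *focal* behavior and the event
k positions later (within the same bout — pairs never span bouts) as the
*conditioned* behavior.  The resulting k x k transition table is tested
against the independence model with Pearson's chi-square and the
likelihood-ratio G-test, and each cell receives a Haberman adjusted residual

    z_ij = (O_ij - E_ij) / sqrt(E_ij (1 - n_i./N) (1 - n_.j/N)),

which is asymptotically standard normal under independence.  Cells with
z above the two-sided critical value are *excitatory* transitions (the
conditioned behavior follows the focal one more often than chance); cells
below the negative critical value are *inhibitory*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .event_data import Corpus

__all__ = [
    "TransitionTable",
    "TestResult",
    "SequentialAnalysisResult",
    "transition_counts",
    "expected_frequencies",
    "pearson_chi_square",
    "g_test",
    "adjusted_residuals",
    "standardized_residuals",
    "significance_masks",
    "analyze",
]


@dataclass(frozen=True)
class TransitionTable:
    """Lag-k pair counts: rows are focal (lag-0) codes, columns conditioned."""

    observed: np.ndarray
    codes: tuple[str, ...]
    lag: int

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed)
        k = len(self.codes)
        if obs.shape != (k, k):
            raise ValueError(f"observed must be {k}x{k}, got {obs.shape}")
        if (obs < 0).any():
            raise ValueError("negative cell count")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        object.__setattr__(self, "observed", obs.astype(np.int64))

    @property
    def k(self) -> int:
        return len(self.codes)

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def n_pairs(self) -> int:
        return int(self.observed.sum())


class TestResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SequentialAnalysisResult:
    """Full output of :func:`analyze` for one corpus at one lag."""

    table: TransitionTable
    expected: np.ndarray
    chi2: float
    g2: float
    df: int
    p_chi2: float
    p_g2: float
    z: np.ndarray
    alpha: float
    z_threshold: float
    excitatory: np.ndarray
    inhibitory: np.ndarray

    @property
    def codes(self) -> tuple[str, ...]:
        return self.table.codes


def transition_counts(corpus: Corpus, lag: int = 1) -> TransitionTable:
    """Count focal -> conditioned pairs at the given lag.

    ``O[i, j]`` is the number of positions ``t`` with event ``i`` at ``t``
    and event ``j`` at ``t + lag`` within one sequence; boundaries between
    sequences contribute no pairs.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    alphabet = corpus.alphabet
    k = len(alphabet)
    observed = np.zeros((k, k), dtype=np.int64)
    for seq in corpus:
        if len(seq) <= lag:
            continue
        idx = np.fromiter(
            (alphabet.index(s) for s in seq.events), dtype=np.intp, count=len(seq)
        )
        np.add.at(observed, (idx[:-lag], idx[lag:]), 1)
    if observed.sum() == 0:
        warnings.warn(
            f"no lag-{lag} pairs: every sequence is shorter than lag + 1",
            stacklevel=2,
        )
    return TransitionTable(observed, alphabet.codes, lag)


def expected_frequencies(table: TransitionTable) -> np.ndarray:
    """Independence-model expectations E_ij = n_i. * n_.j / N."""
    n = table.n_pairs
    if n == 0:
        raise ValueError("empty transition table")
    return np.outer(table.row_totals, table.col_totals) / n


def pearson_chi_square(table: TransitionTable, expected: np.ndarray) -> TestResult:
    """Pearson chi-square omnibus test of the lag-k independence model."""
    if table.n_pairs == 0:
        raise ValueError("empty transition table")
    o = table.observed.astype(float)
    e = np.asarray(expected, dtype=float)
    mask = e > 0
    stat = float(((o[mask] - e[mask]) ** 2 / e[mask]).sum())
    df = (table.k - 1) ** 2
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


def g_test(table: TransitionTable, expected: np.ndarray) -> TestResult:
    """Likelihood-ratio G-test: G2 = 2 sum O ln(O/E), with 0 ln 0 := 0."""
    if table.n_pairs == 0:
        raise ValueError("empty transition table")
    o = table.observed.astype(float)
    e = np.asarray(expected, dtype=float)
    if ((o > 0) & (e == 0)).any():
        raise ValueError("observed count in a cell with zero expectation")
    mask = o > 0
    stat = float(2.0 * (o[mask] * np.log(o[mask] / e[mask])).sum())
    df = (table.k - 1) ** 2
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


def adjusted_residuals(table: TransitionTable, expected: np.ndarray) -> np.ndarray:
    """Haberman adjusted residuals, ~N(0,1) per cell under independence.

    Cells whose variance estimate is zero (a zero row or column marginal,
    or a marginal equal to N) are degenerate and reported as z = 0.
    """
    n = table.n_pairs
    if n == 0:
        raise ValueError("empty transition table")
    o = table.observed.astype(float)
    e = np.asarray(expected, dtype=float)
    var = e * np.outer(1.0 - table.row_totals / n, 1.0 - table.col_totals / n)
    z = np.zeros_like(e)
    ok = var > 0
    z[ok] = (o[ok] - e[ok]) / np.sqrt(var[ok])
    return z


def standardized_residuals(table: TransitionTable, expected: np.ndarray) -> np.ndarray:
    """Unadjusted residuals (O - E)/sqrt(E); zero-expectation cells get 0."""
    if table.n_pairs == 0:
        raise ValueError("empty transition table")
    o = table.observed.astype(float)
    e = np.asarray(expected, dtype=float)
    z = np.zeros_like(e)
    ok = e > 0
    z[ok] = (o[ok] - e[ok]) / np.sqrt(e[ok])
    return z


def significance_masks(
    z: np.ndarray, z_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of excitatory (z > t) and inhibitory (z < -t) cells.

    Both inequalities are strict, so a cell exactly at the threshold is in
    neither mask; the masks are disjoint.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    z = np.asarray(z)
    return z > z_threshold, z < -z_threshold


def analyze(
    corpus: Corpus,
    lag: int = 1,
    alpha: float = 0.05,
    residual: str = "adjusted",
) -> SequentialAnalysisResult:
    """Run the full lag-k sequential analysis of a corpus.

    The significance threshold is the upper alpha/2 standard-normal
    quantile (1.96 at alpha = 0.05, the conventional two-sided cutoff).
    ``residual`` selects ``"adjusted"`` (Haberman, the sequential-analysis
    standard) or ``"standardized"`` ((O-E)/sqrt(E)).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    table = transition_counts(corpus, lag)
    unused = [c for c, t in zip(table.codes, table.row_totals + table.col_totals) if t == 0]
    if unused:
        warnings.warn(f"codes never observed in any pair: {unused}", stacklevel=2)
    expected = expected_frequencies(table)
    chi2 = pearson_chi_square(table, expected)
    g2 = g_test(table, expected)
    if residual == "adjusted":
        z = adjusted_residuals(table, expected)
    elif residual == "standardized":
        z = standardized_residuals(table, expected)
    else:
        raise ValueError("residual must be 'adjusted' or 'standardized'")
    z_threshold = float(stats.norm.ppf(1.0 - alpha / 2.0))
    excitatory, inhibitory = significance_masks(z, z_threshold)
    return SequentialAnalysisResult(
        table=table,
        expected=expected,
        chi2=chi2.statistic,
        g2=g2.statistic,
        df=chi2.df,
        p_chi2=chi2.p_value,
        p_g2=g2.p_value,
        z=z,
        alpha=alpha,
        z_threshold=z_threshold,
        excitatory=excitatory,
        inhibitory=inhibitory,
    )
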