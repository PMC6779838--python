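"""Seeded first-order Markov corpus generator.

The lag-1 sequential analysis detects exactly first-order Markov structure,
so the generator plants exactly that: each bout is a chain whose first event
is drawn from an initial distribution and every later event from the row of
a transition matrix P indexed by the previous event.  Specs can be built
three ways: directly, by boosting chosen cells of a base matrix
(:func:`planted_pattern_spec`), or calibrated to the published per-sex
marginal action counts (:func:`paper_like_spec`).

Every simulation takes its randomness from a single seeded
:class:`numpy.random.Generator`; no global RNG state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .event_data import Alphabet, Corpus, EventSequence, TKDOT
from . import fixtures_io
from .sequential_analysis import transition_counts

__all__ = [
    "SimulationSpec",
    "make_spec",
    "simulate_corpus",
    "estimate_transition_matrix",
    "planted_pattern_spec",
    "paper_like_spec",
]

_STOCHASTIC_TOL = 1e-12


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one corpus reproducibly.

    ``lengths`` gives the per-sequence event counts; use
    :meth:`with_uniform_lengths` or the factory helpers to build one from a
    fixed length or a (min, max) range.
    """

    alphabet: Alphabet
    initial_distribution: np.ndarray
    transition_matrix: np.ndarray
    lengths: tuple[int, ...]
    seed: int
    sex_label: str | None = None

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        pi = np.asarray(self.initial_distribution, dtype=float)
        p = np.asarray(self.transition_matrix, dtype=float)
        if pi.shape != (k,):
            raise ValueError(f"initial_distribution must have length {k}")
        if p.shape != (k, k):
            raise ValueError(f"transition_matrix must be {k}x{k}")
        if (pi < 0).any() or (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > _STOCHASTIC_TOL:
            raise ValueError("initial_distribution must sum to 1")
        bad = np.abs(p.sum(axis=1) - 1.0) > _STOCHASTIC_TOL
        if bad.any():
            raise ValueError(
                f"transition matrix rows not stochastic: "
                f"{[self.alphabet.codes[i] for i in np.flatnonzero(bad)]}"
            )
        if not self.lengths or any(l < 1 for l in self.lengths):
            raise ValueError("each sequence length must be >= 1")
        object.__setattr__(self, "initial_distribution", pi)
        object.__setattr__(self, "transition_matrix", p)
        object.__setattr__(self, "lengths", tuple(int(l) for l in self.lengths))

    @property
    def n_sequences(self) -> int:
        return len(self.lengths)

    @property
    def total_events(self) -> int:
        return sum(self.lengths)


def _lengths_from(n_sequences: int, length, rng: np.random.Generator | None):
    """Expand a fixed length or (min, max) range into per-sequence lengths."""
    if isinstance(length, tuple):
        lo, hi = length
        if rng is None:
            raise ValueError("a length range requires an RNG")
        return tuple(int(x) for x in rng.integers(lo, hi + 1, size=n_sequences))
    return (int(length),) * n_sequences


def make_spec(
    alphabet: Alphabet,
    initial_distribution,
    transition_matrix,
    n_sequences: int,
    length,
    seed: int,
    sex_label: str | None = None,
) -> SimulationSpec:
    """Build a spec from a fixed length or a (min, max) uniform range.

    A ranged length draws the per-sequence lengths from an RNG seeded with
    ``seed``, so the spec itself stays fully determined by its arguments.
    """
    rng = np.random.default_rng(seed) if isinstance(length, tuple) else None
    return SimulationSpec(
        alphabet=alphabet,
        initial_distribution=np.asarray(initial_distribution, dtype=float),
        transition_matrix=np.asarray(transition_matrix, dtype=float),
        lengths=_lengths_from(n_sequences, length, rng),
        seed=seed,
        sex_label=sex_label,
    )


def simulate_corpus(spec: SimulationSpec) -> Corpus:
    """Sample a corpus from a first-order Markov chain.

    Identical specs (including seed) give byte-identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    codes = spec.alphabet.codes
    cum_init = np.cumsum(spec.initial_distribution)
    cum_rows = np.cumsum(spec.transition_matrix, axis=1)
    # guard against cumulative rounding leaving the last bin slightly < 1
    cum_init[-1] = 1.0
    cum_rows[:, -1] = 1.0

    sequences = []
    for b, length in enumerate(spec.lengths, start=1):
        u = rng.random(length)
        states = np.empty(length, dtype=np.intp)
        state = int(np.searchsorted(cum_init, u[0], side="right"))
        states[0] = state
        for t in range(1, length):
            state = int(np.searchsorted(cum_rows[state], u[t], side="right"))
            states[t] = state
        sequences.append(
            EventSequence(
                bout_id=str(b),
                events=tuple(codes[s] for s in states),
                sex=spec.sex_label,
            )
        )
    return Corpus(tuple(sequences), spec.alphabet)


def estimate_transition_matrix(corpus: Corpus) -> np.ndarray:
    """Maximum-likelihood transition matrix from lag-1 pair counts.

    Rows with no observed pairs cannot be estimated; they are filled with
    the uniform distribution and reported in a warning.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    table = transition_counts(corpus, lag=1)
    counts = table.observed.astype(float)
    totals = table.row_totals.astype(float)
    k = table.k
    p = np.full((k, k), 1.0 / k)
    observed_rows = totals > 0
    p[observed_rows] = counts[observed_rows] / totals[observed_rows, None]
    if not observed_rows.all():
        unseen = [table.codes[i] for i in np.flatnonzero(~observed_rows)]
        warnings.warn(
            f"rows with no observed pairs set to uniform: {unseen}",
            stacklevel=2,
        )
    return p


def planted_pattern_spec(
    boosts: list[tuple[str, str, float]],
    base: np.ndarray | None = None,
    alphabet: Alphabet = TKDOT,
    n_sequences: int = 150,
    length=75,
    seed: int = 0,
    sex_label: str | None = None,
    initial_distribution: np.ndarray | None = None,
) -> SimulationSpec:
    """A spec whose transition matrix has chosen cells set to target values.

    Starting from ``base`` (uniform if omitted), each boost
    ``(focal, conditioned, target)`` pins P[focal, conditioned] to the
    target probability and rescales the rest of that row proportionally so
    it stays stochastic.
    """
    k = len(alphabet)
    p = (np.full((k, k), 1.0 / k) if base is None
         else np.array(base, dtype=float))
    by_row: dict[int, list[tuple[int, float]]] = {}
    for focal, conditioned, target in boosts:
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target probability {target} outside [0, 1]")
        by_row.setdefault(alphabet.index(focal), []).append(
            (alphabet.index(conditioned), target)
        )
    for i, row_boosts in by_row.items():
        boosted_cols = [j for j, _ in row_boosts]
        boosted_mass = sum(t for _, t in row_boosts)
        if boosted_mass > 1.0 + _STOCHASTIC_TOL:
            raise ValueError(
                f"boosts for row {alphabet.codes[i]!r} total {boosted_mass} > 1"
            )
        rest = np.setdiff1d(np.arange(k), boosted_cols)
        rest_mass = p[i, rest].sum()
        if rest_mass <= 0 and boosted_mass < 1.0 - _STOCHASTIC_TOL:
            raise ValueError(
                f"row {alphabet.codes[i]!r}: no residual mass to redistribute"
            )
        for j, target in row_boosts:
            p[i, j] = target
        if rest_mass > 0:
            p[i, rest] *= (1.0 - boosted_mass) / rest_mass
    init = (np.full(k, 1.0 / k) if initial_distribution is None
            else np.asarray(initial_distribution, dtype=float))
    return make_spec(alphabet, init, p, n_sequences, length, seed, sex_label)


def paper_like_spec(
    sex: str,
    seed: int = 0,
    boosts: list[tuple[str, str, float]] | None = None,
) -> SimulationSpec:
    """A spec calibrated to the published per-sex marginal action counts.

    The initial distribution and every row of the base transition matrix
    equal the published per-code proportions (the independence model on
    those marginals), which also makes the chain stationary at exactly
    those frequencies.  Corpus size matches the study: one sequence per
    bout (75 male / 76 female), lengths chosen so the total event count
    equals the published per-sex total (11,474 male / 12,980 female).
    Optional ``boosts`` plant excitatory cells on top of the base.
    """
    marginals = fixtures_io.load_marginals(sex)
    total = int(marginals.sum())
    probs = marginals.to_numpy(dtype=float) / total
    n_bouts = 75 if sex == "male" else 76
    base_len, remainder = divmod(total, n_bouts)
    lengths = (base_len + 1,) * remainder + (base_len,) * (n_bouts - remainder)
    k = len(TKDOT)
    base = np.tile(probs, (k, 1))
    if boosts:
        spec = planted_pattern_spec(
            boosts, base=base, alphabet=TKDOT, n_sequences=n_bouts,
            length=base_len, seed=seed, sex_label=sex,
            initial_distribution=probs,
        )
        return SimulationSpec(
            alphabet=TKDOT,
            initial_distribution=probs,
            transition_matrix=spec.transition_matrix,
            lengths=lengths,
            seed=seed,
            sex_label=sex,
        )
    return SimulationSpec(
        alphabet=TKDOT,
        initial_distribution=probs,
        transition_matrix=base,
        lengths=lengths,
        seed=seed,
        sex_label=sex,
    )
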