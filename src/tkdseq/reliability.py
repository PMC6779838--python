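"""Inter- and intra-observer reliability via Cohen's kappa.

Two observers code the same bout event by event; the position-aligned
codings form a k x k confusion matrix from which chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e)

is computed, with p_o the observed agreement (trace / N) and p_e the
agreement expected by chance from the marginals.  The value is mapped to
five conformity bands: weak (0-0.20), distant (0.21-0.40), moderate
(0.41-0.60), strong (0.61-0.80) and almost perfect (0.81-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .event_data import Alphabet, EventSequence, TKDOT

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "confusion_from_codings",
    "cohens_kappa",
    "band_label",
    "kappa_report",
]

BANDS = ("weak", "distant", "moderate", "strong", "almost perfect")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Event-aligned coding tallies: rows observer A, columns observer B."""

    counts: np.ndarray
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.codes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() < 1:
            raise ValueError("confusion matrix must contain at least one event")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.codes != other.codes:
            raise ValueError("cannot pool confusion matrices over different alphabets")
        return ConfusionMatrix(self.counts + other.counts, self.codes)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    chance_agreement: float
    band: str
    below_chance: bool = False


def confusion_from_codings(
    a: EventSequence, b: EventSequence, alphabet: Alphabet = TKDOT
) -> ConfusionMatrix:
    """Tally two position-aligned codings of the same bout.

    No alignment heuristics are applied: codings of different length are
    rejected outright.
    """
    if len(a) != len(b):
        raise ValueError(
            f"codings differ in length: observer A has {len(a)} events, "
            f"observer B has {len(b)}"
        )
    k = len(alphabet)
    counts = np.zeros((k, k), dtype=np.int64)
    for ca, cb in zip(a.events, b.events):
        counts[alphabet.index(ca), alphabet.index(cb)] += 1
    return ConfusionMatrix(counts, alphabet.codes)


def cohens_kappa(m: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement from a confusion matrix."""
    counts = m.counts.astype(float)
    n = counts.sum()
    p_o = float(np.trace(counts) / n)
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / n**2)
    if p_e >= 1.0:
        # All mass in one category for both observers: agreement is either
        # trivially perfect or kappa has no defined value.
        if p_o == 1.0:
            kappa = 1.0
        else:
            raise ValueError("undefined kappa: chance agreement is 1")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=kappa,
        observed_agreement=p_o,
        chance_agreement=p_e,
        band=band_label(kappa),
        below_chance=kappa < 0,
    )


def band_label(kappa: float) -> str:
    """Map a kappa value to its conformity band.

    Band edges are stated at two-decimal resolution, so the value is
    rounded to two decimals before banding; negative values fall in the
    weak band (callers flag below-chance agreement separately).
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    r = round(kappa, 2)
    if r <= 0.20:
        return "weak"
    if r <= 0.40:
        return "distant"
    if r <= 0.60:
        return "moderate"
    if r <= 0.80:
        return "strong"
    return "almost perfect"


def kappa_report(
    pairs: Iterable[tuple[EventSequence, EventSequence]],
    alphabet: Alphabet = TKDOT,
) -> dict:
    """Pooled and per-bout kappa for a set of doubly coded bouts.

    The pooled value sums all confusion matrices before computing kappa;
    per-bout values are reported alongside because the two conventions can
    differ when bouts have unequal lengths or marginals.
    """
    matrices = [confusion_from_codings(a, b, alphabet) for a, b in pairs]
    if not matrices:
        raise ValueError("no coding pairs supplied")
    pooled = matrices[0]
    for m in matrices[1:]:
        pooled = pooled + m
    pooled_result = cohens_kappa(pooled)
    return {
        "pooled": pooled_result,
        "per_bout": [cohens_kappa(m) for m in matrices],
    }
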