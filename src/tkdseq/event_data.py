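"""Coding alphabet and corpus data model for coded tactical-action sequences.

A bout is coded as one totally ordered stream of 3-letter action codes drawn
from the 9-category TKDOT alphabet (openings, direct/indirect attacks, the
three counterattack types, and blocks, dodges, and cuts).  This module defines
the alphabet, the per-bout :class:`EventSequence`, the :class:`Corpus`
container, and readers/writers for two plain-text representations:

* an SDIS-style event text format (``%key=value`` metadata directives,
  whitespace-separated code tokens, ``/`` sequence terminator, ``#`` comments);
* a long-format CSV with columns ``bout_id, sex, order_index, code``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "ActionCode",
    "Alphabet",
    "TKDOT",
    "EventSequence",
    "Corpus",
    "CodeFrequencyTable",
    "ParseError",
    "SEXES",
    "parse_event_text",
    "write_event_text",
    "read_long_csv",
    "write_long_csv",
    "corpus_summary",
]

SEXES = ("male", "female")

TACTICAL_CLASSES = ("attack", "counterattack", "defense")


class ParseError(ValueError):
    """Raised when an event-text or CSV source violates the format contract."""


@dataclass(frozen=True)
class ActionCode:
    """One category of the coding scheme.

    Parameters
    ----------
    code:
        Three-letter symbol (e.g. ``"SCA"``), the token used in data files.
    label:
        Full category name (e.g. ``"Simultaneous counterattack"``).
    tactical_class:
        One of ``"attack"`` (attack-initiation actions), ``"counterattack"``,
        or ``"defense"``.
    """

    code: str
    label: str
    tactical_class: str

    def __post_init__(self) -> None:
        if self.tactical_class not in TACTICAL_CLASSES:
            raise ValueError(
                f"tactical_class {self.tactical_class!r} not in {TACTICAL_CLASSES}"
            )


class Alphabet:
    """An ordered, immutable set of :class:`ActionCode` categories."""

    def __init__(self, codes: Iterable[ActionCode]):
        self._codes: tuple[ActionCode, ...] = tuple(codes)
        if len({c.code for c in self._codes}) != len(self._codes):
            raise ValueError("duplicate code symbols in alphabet")
        self._index: dict[str, int] = {c.code: i for i, c in enumerate(self._codes)}

    @property
    def codes(self) -> tuple[str, ...]:
        """Code symbols in canonical order."""
        return tuple(c.code for c in self._codes)

    @property
    def action_codes(self) -> tuple[ActionCode, ...]:
        return self._codes

    def __len__(self) -> int:
        return len(self._codes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __iter__(self) -> Iterator[ActionCode]:
        return iter(self._codes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alphabet) and self._codes == other._codes

    def __hash__(self) -> int:
        return hash(self._codes)

    def index(self, symbol: str) -> int:
        """Position of ``symbol`` in canonical order."""
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"unknown code {symbol!r}") from None

    def tactical_class(self, symbol: str) -> str:
        return self._codes[self.index(symbol)].tactical_class

    def by_class(self, tactical_class: str) -> tuple[str, ...]:
        return tuple(
            c.code for c in self._codes if c.tactical_class == tactical_class
        )


#: The 9-category taekwondo observational tool (TKDOT) alphabet.  The opening
#: (OPE) is classified with the attack-initiation block because sequences it
#: starts behave tactically as attack initiations, even though the action
#: itself is a distance-control movement.
TKDOT = Alphabet(
    [
        ActionCode("OPE", "Opening", "attack"),
        ActionCode("DIA", "Direct attack", "attack"),
        ActionCode("INA", "Indirect attack", "attack"),
        ActionCode("ACA", "Anticipated counterattack", "counterattack"),
        ActionCode("SCA", "Simultaneous counterattack", "counterattack"),
        ActionCode("PCA", "Posterior counterattack", "counterattack"),
        ActionCode("BLO", "Block", "defense"),
        ActionCode("DOD", "Dodge", "defense"),
        ActionCode("CUT", "Cut", "defense"),
    ]
)


@dataclass(frozen=True)
class EventSequence:
    """One bout's ordered stream of action codes."""

    bout_id: str
    events: tuple[str, ...]
    sex: str | None = None

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError(f"bout {self.bout_id!r}: empty event stream")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(
                f"bout {self.bout_id!r}: sex {self.sex!r} not in {list(SEXES)}"
            )
        object.__setattr__(self, "events", tuple(self.events))

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class Corpus:
    """A collection of coded bouts sharing one alphabet."""

    sequences: tuple[EventSequence, ...]
    alphabet: Alphabet = TKDOT

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        for seq in self.sequences:
            for symbol in seq.events:
                if symbol not in self.alphabet:
                    raise ValueError(
                        f"bout {seq.bout_id!r}: code {symbol!r} not in alphabet"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[EventSequence]:
        return iter(self.sequences)

    @property
    def n_events(self) -> int:
        return sum(len(s) for s in self.sequences)

    def filter_sex(self, sex: str) -> "Corpus":
        """A new corpus containing only bouts of the given sex group."""
        if sex not in SEXES:
            raise ValueError(f"sex {sex!r} not in {list(SEXES)}")
        return Corpus(
            tuple(s for s in self.sequences if s.sex == sex), self.alphabet
        )


@dataclass(frozen=True)
class CodeFrequencyTable:
    """Per-code event counts over a corpus."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, code: str) -> int:
        return self.counts[code]

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.counts), name="count")


# ---------------------------------------------------------------------------
# SDIS-style event text
# ---------------------------------------------------------------------------

def parse_event_text(text: str, alphabet: Alphabet = TKDOT) -> Corpus:
    """Parse SDIS-style event text into a :class:`Corpus`.

    Dialect: ``#`` starts a comment line; ``%key=value`` directives set
    metadata for the *following* sequence (``%sex`` is sticky across
    sequences, ``%bout`` applies once and subsequent bouts auto-number);
    code tokens are whitespace separated and upper-cased on read; ``/``
    terminates a sequence.

    Raises
    ------
    ParseError
        On an unknown code token (named with line and column), an empty
        stream between terminators, or a missing final terminator.
    """
    sequences: list[EventSequence] = []
    current: list[str] = []
    sex: str | None = None
    pending_bout: str | None = None
    auto_bout = 1
    saw_tokens = False  # tokens since last terminator (or start)

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0]
        pos = 0
        for token in line.split():
            start = line.index(token, pos)
            pos = start + len(token)
            col = start + 1
            if token.startswith("%"):
                if "=" not in token:
                    raise ParseError(
                        f"line {lineno}, col {col}: malformed directive {token!r}"
                    )
                key, value = token[1:].split("=", 1)
                if key == "bout":
                    pending_bout = value
                elif key == "sex":
                    if value not in SEXES:
                        raise ParseError(
                            f"line {lineno}, col {col}: sex {value!r} "
                            f"not one of {list(SEXES)}"
                        )
                    sex = value
                else:
                    raise ParseError(
                        f"line {lineno}, col {col}: unknown directive %{key}"
                    )
            elif token == "/":
                if not current:
                    raise ParseError(
                        f"line {lineno}, col {col}: empty stream before '/'"
                    )
                bout_id = pending_bout if pending_bout is not None else str(auto_bout)
                sequences.append(EventSequence(bout_id, tuple(current), sex))
                try:
                    auto_bout = int(bout_id) + 1
                except ValueError:
                    auto_bout += 1
                pending_bout = None
                current = []
                saw_tokens = False
            else:
                symbol = token.upper()
                if symbol not in alphabet:
                    raise ParseError(
                        f"line {lineno}, col {col}: unknown code {token!r}"
                    )
                current.append(symbol)
                saw_tokens = True

    if saw_tokens or current:
        raise ParseError("missing final '/' terminator")
    return Corpus(tuple(sequences), alphabet)


def write_event_text(corpus: Corpus) -> str:
    """Serialize a corpus to canonical event text.

    Sequences appear in corpus order, each preceded by its metadata
    directive line; codes are single-space separated and terminated by
    ``' /'``.  ``parse_event_text(write_event_text(c))`` reproduces ``c``.
    """
    out = io.StringIO()
    out.write("# tkdseq event text\n")
    for seq in corpus:
        meta = [f"%bout={seq.bout_id}"]
        if seq.sex is not None:
            meta.append(f"%sex={seq.sex}")
        out.write(" ".join(meta) + "\n")
        out.write(" ".join(seq.events) + " /\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Long CSV
# ---------------------------------------------------------------------------

LONG_CSV_COLUMNS = ("bout_id", "sex", "order_index", "code")


def read_long_csv(source, alphabet: Alphabet = TKDOT) -> Corpus:
    """Read a long-format CSV (``bout_id, sex, order_index, code``).

    Events are sorted by ``order_index`` within each bout.  Duplicate
    ``(bout_id, order_index)`` pairs are an error; non-contiguous indices
    produce a warning but the sorted order is kept.
    """
    df = pd.read_csv(source, dtype={"bout_id": str, "sex": str, "code": str})
    missing = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")

    dupes = df.duplicated(subset=["bout_id", "order_index"])
    if dupes.any():
        pair = df.loc[dupes.idxmax(), ["bout_id", "order_index"]]
        raise ParseError(
            f"duplicate (bout_id, order_index): "
            f"({pair['bout_id']!r}, {pair['order_index']})"
        )
    bad_sex = set(df["sex"].dropna()) - set(SEXES)
    if bad_sex:
        raise ParseError(
            f"invalid sex value(s) {sorted(bad_sex)}; allowed: {list(SEXES)}"
        )
    bad_codes = set(df["code"].str.upper()) - set(alphabet.codes)
    if bad_codes:
        raise ParseError(f"unknown code(s): {sorted(bad_codes)}")

    sequences = []
    for bout_id, group in df.groupby("bout_id", sort=False):
        group = group.sort_values("order_index")
        idx = group["order_index"].to_numpy()
        if len(idx) > 1 and not (idx[1:] - idx[:-1] == 1).all():
            warnings.warn(
                f"bout {bout_id!r}: non-contiguous order_index; "
                "order preserved by sort",
                stacklevel=2,
            )
        sexes = group["sex"].dropna().unique()
        if len(sexes) > 1:
            raise ParseError(f"bout {bout_id!r}: conflicting sex values {list(sexes)}")
        sequences.append(
            EventSequence(
                str(bout_id),
                tuple(group["code"].str.upper()),
                sexes[0] if len(sexes) else None,
            )
        )
    return Corpus(tuple(sequences), alphabet)


def write_long_csv(corpus: Corpus, target) -> None:
    """Write a corpus as long-format CSV to a path or file-like object."""
    rows = [
        (seq.bout_id, seq.sex, i + 1, code)
        for seq in corpus
        for i, code in enumerate(seq.events)
    ]
    pd.DataFrame(rows, columns=LONG_CSV_COLUMNS).to_csv(target, index=False)


def corpus_summary(corpus: Corpus) -> CodeFrequencyTable:
    """Count every event occurrence per code over the whole corpus."""
    counts = {code: 0 for code in corpus.alphabet.codes}
    for seq in corpus:
        for symbol in seq.events:
            counts[symbol] += 1
    return CodeFrequencyTable(counts)
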