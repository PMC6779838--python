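"""Significant transition patterns and the three-level tactical model.

A *pattern* is an excitatory focal -> conditioned transition: the conditioned
action follows the focal action significantly more often than the
independence model predicts.  Patterns are grouped by the focal action's
tactical block (attack / counterattack / defense) and ranked within each
block by observed pair count, mirroring the published per-sex pattern
tables.  The per-sex pattern sets merge into a directed *tactical model*
graph in which attack-initiated edges form level 1 -> 2 of the
offensive-defensive scheme (attacker acts, opponent responds) and
counterattack- or defense-initiated edges form level 2 -> 3 (the original
attacker responds in turn).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from . import fixtures_io
from .event_data import Alphabet, SEXES, TKDOT
from .sequential_analysis import SequentialAnalysisResult

__all__ = [
    "PatternRecord",
    "TacticalModel",
    "DiffReport",
    "extract_patterns",
    "rank_patterns",
    "pattern_totals",
    "build_tactical_model",
    "export_graph",
    "compare_to_reference",
    "reference_patterns",
    "patterns_to_frame",
]

GRAPH_FORMATS = ("dot", "graphml", "csv")

#: Block order used for reporting: attack-initiated patterns first, then
#: counterattack- and defense-initiated ones.
BLOCK_ORDER = ("attack", "counterattack", "defense")


@dataclass(frozen=True)
class PatternRecord:
    """One significant (excitatory) focal -> conditioned transition."""

    focal: str
    conditioned: str
    count: int
    z: float
    sex: str
    focal_block: str
    order: int | None = None


@dataclass(frozen=True)
class DiffReport:
    """Difference between a generated pattern set and a reference set."""

    missing: tuple[tuple[str, str], ...]   # in reference only
    extra: tuple[tuple[str, str], ...]     # in generated only
    count_mismatches: tuple[tuple[str, str, int, int], ...]  # pair, got, want
    order_mismatches: tuple[tuple[str, str, int, int], ...]

    @property
    def is_empty(self) -> bool:
        return not (
            self.missing or self.extra or self.count_mismatches or self.order_mismatches
        )

    @property
    def overlap_rate(self) -> float:
        """Jaccard overlap of the two pair sets."""
        n_common = len(self._reference_pairs() & self._generated_pairs())
        n_union = len(self._reference_pairs() | self._generated_pairs())
        return n_common / n_union if n_union else 1.0

    def _reference_pairs(self) -> set[tuple[str, str]]:
        return set(self.missing) | (self._generated_pairs() - set(self.extra))

    def _generated_pairs(self) -> set[tuple[str, str]]:
        return set(self._gen_pairs)

    # stored at construction by compare_to_reference
    _gen_pairs: tuple[tuple[str, str], ...] = field(default=(), repr=False)


class TacticalModel:
    """Directed graph of significant transitions merged across sex groups.

    Thin wrapper over a :class:`networkx.DiGraph`; node attributes carry the
    tactical class, edge attributes carry per-sex counts and z values plus a
    ``presence`` flag (``"both"``, ``"male_only"``, ``"female_only"``) — the
    straight / discontinuous / dotted arrow distinction of the published
    figures encoded as data.
    """

    def __init__(self, graph: nx.DiGraph, alphabet: Alphabet = TKDOT):
        self.graph = graph
        self.alphabet = alphabet

    @property
    def edges(self):
        return self.graph.edges(data=True)

    def edges_present_in(self, presence: str) -> list[tuple[str, str]]:
        return sorted(
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["presence"] == presence
        )


def extract_patterns(
    result: SequentialAnalysisResult, sex: str
) -> list[PatternRecord]:
    """One unranked record per excitatory-significant cell of an analysis.

    Counts come from the observed transition table; the focal block from
    the alphabet's tactical classes.  Call :func:`rank_patterns` to assign
    within-block orders.
    """
    codes = result.codes
    records = []
    for i, focal in enumerate(codes):
        for j, conditioned in enumerate(codes):
            if result.excitatory[i, j]:
                records.append(
                    PatternRecord(
                        focal=focal,
                        conditioned=conditioned,
                        count=int(result.table.observed[i, j]),
                        z=float(result.z[i, j]),
                        sex=sex,
                        focal_block=TKDOT.tactical_class(focal),
                    )
                )
    return records


def rank_patterns(records: list[PatternRecord]) -> list[PatternRecord]:
    """Assign within-block orders 1..n, descending by count.

    Ties break by larger z, then lexicographic (focal, conditioned).  The
    returned list is sorted block by block (attack, counterattack, defense)
    in rank order.
    """
    sexes = {r.sex for r in records}
    if len(sexes) > 1:
        raise ValueError(f"records mix sex groups: {sorted(sexes)}")
    ranked: list[PatternRecord] = []
    for block in BLOCK_ORDER:
        block_records = sorted(
            (r for r in records if r.focal_block == block),
            key=lambda r: (-r.count, -r.z, r.focal, r.conditioned),
        )
        ranked.extend(
            replace(r, order=i + 1) for i, r in enumerate(block_records)
        )
    return ranked


def pattern_totals(records: list[PatternRecord]) -> tuple[int, int, dict[str, int]]:
    """(number of patterns, total pair occurrences, per-block pattern counts)."""
    per_block = {block: 0 for block in BLOCK_ORDER}
    for r in records:
        per_block[r.focal_block] += 1
    return len(records), sum(r.count for r in records), per_block


def build_tactical_model(
    records_by_sex: dict[str, list[PatternRecord]],
    alphabet: Alphabet = TKDOT,
) -> TacticalModel:
    """Merge per-group pattern sets into one annotated directed graph.

    Groups are normally the two sexes (yielding the ``both`` /
    ``male_only`` / ``female_only`` presence semantics), but any single
    label works for an ungrouped analysis.
    """
    graph = nx.DiGraph()
    for code in alphabet:
        graph.add_node(code.code, tactical_class=code.tactical_class)

    for sex, records in records_by_sex.items():
        for r in records:
            if r.focal not in alphabet or r.conditioned not in alphabet:
                raise ValueError(
                    f"pattern {r.focal}->{r.conditioned} uses a code "
                    "outside the alphabet"
                )
            if not graph.has_edge(r.focal, r.conditioned):
                # Attack-initiated transitions are the scheme's first level
                # (attacker -> opponent response); counterattack- and
                # defense-initiated ones are the second (opponent -> attacker).
                level = 1 if r.focal_block == "attack" else 2
                graph.add_edge(r.focal, r.conditioned, level=level)
            edge = graph.edges[r.focal, r.conditioned]
            edge[f"count_{sex}"] = r.count
            edge[f"z_{sex}"] = r.z
            edge[f"order_{sex}"] = r.order

    for u, v, data in graph.edges(data=True):
        present = sorted(g for g in records_by_sex if f"count_{g}" in data)
        data["presence"] = (
            "both" if {"male", "female"} <= set(present)
            else f"{present[0]}_only" if len(present) == 1
            else "+".join(present)
        )
    return TacticalModel(graph, alphabet)


def export_graph(model: TacticalModel, format: str = "dot") -> str:
    """Serialize a tactical model deterministically.

    Supported formats: ``dot`` (Graphviz), ``graphml``, ``csv`` (edge list
    with per-sex counts and z values).
    """
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {GRAPH_FORMATS}")
    if format == "csv":
        return _export_edge_csv(model)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(_ordered_copy(model))) + "\n"
    return _export_dot(model)


def _ordered_copy(model: TacticalModel) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in sorted(model.graph.nodes):
        g.add_node(node, **model.graph.nodes[node])
    for u, v in sorted(model.graph.edges):
        g.add_edge(u, v, **{k: model.graph.edges[u, v][k]
                            for k in sorted(model.graph.edges[u, v])
                            if model.graph.edges[u, v][k] is not None})
    return g


def _export_dot(model: TacticalModel) -> str:
    out = io.StringIO()
    out.write("digraph tactical_model {\n")
    for node in sorted(model.graph.nodes):
        cls = model.graph.nodes[node]["tactical_class"]
        out.write(f'  {node} [tactical_class="{cls}"];\n')
    style = {"both": "solid", "male_only": "dashed", "female_only": "dotted"}
    for u, v in sorted(model.graph.edges):
        d = model.graph.edges[u, v]
        attrs = [f'style="{style.get(d["presence"], "solid")}"',
                 f'presence="{d["presence"]}"',
                 f'level="{d["level"]}"']
        for key in ("count_male", "count_female", "z_male", "z_female"):
            if d.get(key) is not None:
                attrs.append(f'{key}="{d[key]}"')
        out.write(f"  {u} -> {v} [{', '.join(attrs)}];\n")
    out.write("}\n")
    return out.getvalue()


def _export_edge_csv(model: TacticalModel) -> str:
    value_keys = sorted(
        {
            k
            for _, _, d in model.graph.edges(data=True)
            for k in d
            if k.startswith(("count_", "z_")) and d[k] is not None
        }
    )
    rows = []
    for u, v in sorted(model.graph.edges):
        d = model.graph.edges[u, v]
        row = {"focal": u, "conditioned": v, "level": d["level"]}
        row.update({k: d.get(k) for k in value_keys})
        row["presence"] = d["presence"]
        rows.append(row)
    columns = ["focal", "conditioned", "level", *value_keys, "presence"]
    return pd.DataFrame(rows, columns=columns).to_csv(index=False)


def patterns_to_frame(records: list[PatternRecord]) -> pd.DataFrame:
    """Tabulate ranked records (one row per pattern, published-table shape)."""
    return pd.DataFrame(
        [
            {
                "focal": r.focal,
                "conditioned": r.conditioned,
                "focal_block": r.focal_block,
                "count": r.count,
                "z": r.z,
                "order": r.order,
                "sex": r.sex,
            }
            for r in records
        ]
    )


def reference_patterns(sex: str) -> list[PatternRecord]:
    """Ranked pattern records reconstructed from the packaged reference tables.

    Counts and orders come from the pattern fixture; z values from the
    z-score fixture.
    """
    table = fixtures_io.load_patterns(sex)
    zmat = fixtures_io.load_zscores(sex)
    records = [
        PatternRecord(
            focal=r.focal,
            conditioned=r.conditioned,
            count=int(r.count),
            z=float(zmat.loc[r.focal, r.conditioned]),
            sex=sex,
            focal_block=TKDOT.tactical_class(r.focal),
            order=int(r.order),
        )
        for r in table.itertuples()
    ]
    # keep block-by-block rank order for readability
    return sorted(
        records, key=lambda r: (BLOCK_ORDER.index(r.focal_block), r.order)
    )


def compare_to_reference(
    records: list[PatternRecord], reference: list[PatternRecord]
) -> DiffReport:
    """Diff a generated pattern set against a reference set of the same sex.

    Reports pairs present on only one side, count mismatches, and order
    mismatches; an empty diff means exact reproduction.
    """
    gen = {(r.focal, r.conditioned): r for r in records}
    ref = {(r.focal, r.conditioned): r for r in reference}
    missing = tuple(sorted(set(ref) - set(gen)))
    extra = tuple(sorted(set(gen) - set(ref)))
    count_mismatches = []
    order_mismatches = []
    for pair in sorted(set(gen) & set(ref)):
        g, r = gen[pair], ref[pair]
        if g.count != r.count:
            count_mismatches.append((*pair, g.count, r.count))
        if g.order is not None and r.order is not None and g.order != r.order:
            order_mismatches.append((*pair, g.order, r.order))
    return DiffReport(
        missing=missing,
        extra=extra,
        count_mismatches=tuple(count_mismatches),
        order_mismatches=tuple(order_mismatches),
        _gen_pairs=tuple(sorted(gen)),
    )
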