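"""Dyadic sampling counts and association-index matrices.

For each unordered dyad (A, B) the daily records partition the relevant
sampling days into x (both identified and associated), y_AB (both identified,
not associated), y_A (only A identified) and y_B (only B identified).  The
twice-weight association index

    AI = x / (x + 2*y_AB + y_A + y_B)

down-weights joint-identification-without-association days twice, which is the
least biased choice when associated individuals are more likely to be observed
than lone ones.  Half-weight and simple-ratio variants are provided for
sensitivity analysis.  Dyads whose denominator is zero (never co-sampled) are
*missing*, not zero: zero asserts observed non-association.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DailyRecord

INDEX_KINDS = ("twice_weight", "half_weight", "simple_ratio")


@dataclasses.dataclass(frozen=True)
class DyadCounts:
    """Day-partition counts for one unordered dyad."""

    id_a: str
    id_b: str
    x: int
    y_a: int
    y_b: int
    y_ab: int

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("a dyad needs two distinct individuals")
        if min(self.x, self.y_a, self.y_b, self.y_ab) < 0:
            raise ValueError("dyad counts must be nonnegative")


def dyad_counts(daily: Iterable[DailyRecord], id_a: str, id_b: str) -> DyadCounts:
    """Classify each daily record into the dyad's day-partition cells."""
    if id_a == id_b:
        raise ValueError("a dyad needs two distinct individuals")
    pair = (id_a, id_b) if id_a < id_b else (id_b, id_a)
    x = y_a = y_b = y_ab = 0
    for rec in daily:
        a_in = id_a in rec.identified_ids
        b_in = id_b in rec.identified_ids
        if a_in and b_in:
            if pair in rec.associated_dyads:
                x += 1
            else:
                y_ab += 1
        elif a_in:
            y_a += 1
        elif b_in:
            y_b += 1
    return DyadCounts(id_a=id_a, id_b=id_b, x=x, y_a=y_a, y_b=y_b, y_ab=y_ab)


def twice_weight_ai(counts: DyadCounts) -> float:
    """x / (x + 2*y_AB + y_A + y_B); NaN when the dyad was never sampled."""
    denom = counts.x + 2 * counts.y_ab + counts.y_a + counts.y_b
    return counts.x / denom if denom > 0 else float("nan")


def half_weight_ai(counts: DyadCounts) -> float:
    """x / (x + y_AB + (y_A + y_B)/2); NaN when the dyad was never sampled."""
    denom = counts.x + counts.y_ab + 0.5 * (counts.y_a + counts.y_b)
    return counts.x / denom if denom > 0 else float("nan")


def simple_ratio_ai(counts: DyadCounts) -> float:
    """x / (x + y_AB + y_A + y_B); NaN when the dyad was never sampled."""
    denom = counts.x + counts.y_ab + counts.y_a + counts.y_b
    return counts.x / denom if denom > 0 else float("nan")


_INDEX_FUNCS = {
    "twice_weight": twice_weight_ai,
    "half_weight": half_weight_ai,
    "simple_ratio": simple_ratio_ai,
}


class AssociationMatrix:
    """Symmetric association-index matrix over an ordered list of individuals.

    ``values`` is a float array with NaN for missing dyads; the diagonal is
    always NaN (self-association is undefined).
    """

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray,
        behaviour: str = "",
        index_kind: str = "twice_weight",
    ):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match the individual list")
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate individual ids")
        finite = np.isfinite(values)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            values[finite & finite.T], values.T[finite & finite.T]
        ):
            raise ValueError("association matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(values, initial=0.0) < -1e-12 or np.nanmax(
                values, initial=0.0
            ) > 1.0 + 1e-12:
                raise ValueError("association indices must lie in [0, 1]")
        values = values.copy()
        np.fill_diagonal(values, np.nan)
        self.ids = ids
        self.values = values
        self.behaviour = behaviour
        self.index_kind = index_kind
        self._pos = {i: k for k, i in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Dense copy with missing entries and the diagonal set to ``fill``."""
        out = self.values.copy()
        out[~np.isfinite(out)] = fill
        np.fill_diagonal(out, fill)
        return out

    def reorder(self, ids: Sequence[str]) -> "AssociationMatrix":
        idx = [self._pos[i] for i in ids]
        return AssociationMatrix(
            ids, self.values[np.ix_(idx, idx)], self.behaviour, self.index_kind
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, behaviour: str = "", index_kind: str = "twice_weight"):
        frame = pd.read_csv(path, index_col="id")
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(list(frame.index), frame.to_numpy(), behaviour, index_kind)

    def to_graphml(self, path, node_attrs: pd.DataFrame | None = None) -> None:
        """Edge-weight export for external network tools (missing edges omitted)."""
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                w = self.values[i, j]
                if np.isfinite(w) and w > 0:
                    graph.add_edge(self.ids[i], self.ids[j], weight=float(w))
        if node_attrs is not None:
            for col in node_attrs.columns:
                nx.set_node_attributes(
                    graph,
                    {i: v for i, v in node_attrs[col].items() if not pd.isna(v)},
                    name=str(col),
                )
        nx.write_graphml(graph, path)


def build_matrix(
    daily: Iterable[DailyRecord],
    individuals: Sequence[str],
    index_kind: str = "twice_weight",
    group_of: Mapping[str, str] | None = None,
) -> AssociationMatrix:
    """Association-index matrix over ``individuals`` from daily records.

    Individuals never identified get all-missing rows.  When ``group_of`` is
    supplied, cross-group dyads are masked as missing: groups are closed
    networks and between-group association is undefined, not zero.
    """
    individuals = list(individuals)
    if not individuals:
        raise ValueError("empty individual list")
    if index_kind not in _INDEX_FUNCS:
        raise ValueError(f"unknown index kind {index_kind!r}")
    n = len(individuals)
    pos = {ind: k for k, ind in enumerate(individuals)}
    x = np.zeros((n, n))
    y_ab = np.zeros((n, n))
    only_row = np.zeros((n, n))  # only_row[i, j]: days i identified, j not
    behaviour = ""
    for rec in daily:
        behaviour = behaviour or rec.behaviour
        ident = np.zeros(n, dtype=bool)
        for ind in rec.identified_ids:
            k = pos.get(ind)
            if k is not None:
                ident[k] = True
        both = np.logical_and.outer(ident, ident)
        assoc = np.zeros((n, n), dtype=bool)
        for a, b in rec.associated_dyads:
            ia, ib = pos.get(a), pos.get(b)
            if ia is not None and ib is not None:
                assoc[ia, ib] = assoc[ib, ia] = True
        x += assoc
        y_ab += both & ~assoc
        only_row += np.logical_and.outer(ident, ~ident)
    y_a, y_b = only_row, only_row.T
    if index_kind == "twice_weight":
        denom = x + 2.0 * y_ab + y_a + y_b
    elif index_kind == "half_weight":
        denom = x + y_ab + 0.5 * (y_a + y_b)
    else:
        denom = x + y_ab + y_a + y_b
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.nan)
    if group_of is not None:
        groups = np.array([group_of[i] for i in individuals], dtype=object)
        values[~np.equal.outer(groups, groups)] = np.nan
    np.fill_diagonal(values, np.nan)
    return AssociationMatrix(individuals, values, behaviour, index_kind)
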