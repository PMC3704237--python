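"""Numerator relationship matrix from pedigree (tabular method).

The numerator relationship a_ij is twice the kinship coefficient; the
diagonal is 1 plus the inbreeding coefficient.  Unknown parents are
treated as unrelated, non-inbred founders.  The matrix is assembled over
the pedigree closure of the requested ids and then restricted, keeping
memory proportional to the relevant pedigree only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError

UNKNOWN = {"0", "", "nan", "None", None}


def _clean_parent(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value)
    return None if value in UNKNOWN else value


def normalize_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Coerce a 3-column (id, sire, dam) table to strings with None for unknown."""
    cols = list(pedigree.columns[:3])
    out = pd.DataFrame(
        {
            "id": pedigree[cols[0]].astype(str),
            "sire": [_clean_parent(v) for v in pedigree[cols[1]]],
            "dam": [_clean_parent(v) for v in pedigree[cols[2]]],
        }
    )
    if out["id"].duplicated().any():
        dup = out.loc[out["id"].duplicated(), "id"].iloc[0]
        raise PedigreeError(f"duplicate pedigree entry for {dup!r}")
    return out


@dataclass
class RelationshipMatrix:
    """Symmetric numerator relationship matrix over an ordered id list."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")

    def restrict(self, ids) -> "RelationshipMatrix":
        index = {v: i for i, v in enumerate(self.ids)}
        try:
            rows = np.array([index[str(i)] for i in ids])
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc
        return RelationshipMatrix([str(i) for i in ids], self.values[np.ix_(rows, rows)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _topological_order(parents: dict) -> list:
    """Kahn topological sort (parents before offspring); cycles are fatal."""
    children = {i: [] for i in parents}
    indegree = {i: 0 for i in parents}
    for ind, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(ind)
                indegree[ind] += 1
    queue = sorted(i for i, deg in indegree.items() if deg == 0)
    order = []
    while queue:
        node = queue.pop()
        order.append(node)
        for child in children[node]:
            indegree[child] -= 1
            if indegree[child] == 0:
                queue.append(child)
    if len(order) != len(parents):
        raise PedigreeError("pedigree contains a cycle (an individual is its own ancestor)")
    return order


def build_numerator_relationship(pedigree: pd.DataFrame, ids) -> RelationshipMatrix:
    """Tabular-method A matrix restricted to ``ids`` (in the given order).

    Recursion: a_ii = 1 + a(sire_i, dam_i)/2 and, for j preceding i,
    a_ij = (a(j, sire_i) + a(j, dam_i))/2 with unknown parents
    contributing 0.
    """
    ped = normalize_pedigree(pedigree)
    parents = {row.id: (row.sire, row.dam) for row in ped.itertuples(index=False)}
    ids = [str(i) for i in ids]

    # pedigree closure of the requested ids; parents without their own
    # record are treated as founders
    requested = set(ids)
    needed = set()
    stack = list(ids)
    while stack:
        ind = stack.pop()
        if ind in needed:
            continue
        if ind not in parents:
            if ind in requested:
                raise PedigreeError(f"requested id {ind!r} absent from pedigree")
            parents[ind] = (None, None)
        needed.add(ind)
        for p in parents[ind]:
            if p is not None:
                stack.append(p)

    closure = {i: parents[i] for i in needed}
    order = _topological_order(closure)
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = closure[ind]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * a[si, :i]
        if di is not None:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        inbreeding = 0.5 * a[si, di] if (si is not None and di is not None) else 0.0
        a[i, i] = 1.0 + inbreeding
    full = RelationshipMatrix(order, a)
    return full.restrict(ids)
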