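"""Observation streams: group-by-individual data and its serialization.

A stream is the raw material of "gambit of the group" sampling: an ordered
sequence of sampling units, each recording which individuals were seen
together.  Two unit flavours are supported:

* ``group`` mode — each unit is a set of individual IDs observed in the
  same group (flock, herd); everyone in the group is assumed associated.
* ``period`` mode — each unit is a symmetric 0/1 dyadic matrix over the
  full roster, recording which pairs were observed associating during one
  sampling window (the representation produced by the simulator).

The stream is the resampling unit for the bootstrap and the swap substrate
for the data-stream permutation, so unit order is preserved exactly by all
readers and writers.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

Mode = Literal["group", "period"]


@dataclass(frozen=True)
class ObservationStream:
    """An ordered collection of sampling units over a fixed roster.

    Parameters
    ----------
    units
        Group mode: sequence of non-empty frozensets of IDs.
        Period mode: sequence of symmetric 0/1 ``(n, n)`` arrays with zero
        diagonal, indexed by roster order.
    roster
        All individual IDs, in a stable order. Every ID occurring in a
        unit must be in the roster.
    mode
        ``"group"`` or ``"period"``.
    """

    units: tuple
    roster: tuple
    mode: Mode = "group"

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "roster", tuple(str(r) for r in self.roster))
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate IDs in roster")
        if self.mode == "group":
            units = tuple(frozenset(str(i) for i in u) for u in self.units)
            object.__setattr__(self, "units", units)
            roster_set = set(self.roster)
            for u in units:
                if not u:
                    raise ValueError("group-mode units must be non-empty")
                if not u <= roster_set:
                    raise ValueError(f"IDs {sorted(u - roster_set)} not in roster")
        elif self.mode == "period":
            n = len(self.roster)
            mats = []
            for m in self.units:
                a = np.asarray(m)
                if a.shape != (n, n):
                    raise ValueError(f"period matrix shape {a.shape} != ({n}, {n})")
                a = (a != 0).astype(np.uint8)
                if not np.array_equal(a, a.T) or np.any(np.diag(a)):
                    raise ValueError("period matrices must be symmetric with zero diagonal")
                a.setflags(write=False)
                mats.append(a)
            object.__setattr__(self, "units", tuple(mats))
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- basic queries -------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_individuals(self) -> int:
        return len(self.roster)

    def presence_matrix(self) -> np.ndarray:
        """0/1 array of shape (n_units, n_individuals): who was observed in
        each unit.  In period mode an individual counts as observed in a
        period iff it has at least one association in it."""
        n_u, n = self.n_units, self.n_individuals
        out = np.zeros((n_u, n), dtype=np.uint8)
        if self.mode == "group":
            index = {ind: k for k, ind in enumerate(self.roster)}
            for t, u in enumerate(self.units):
                for ind in u:
                    out[t, index[ind]] = 1
        else:
            for t, m in enumerate(self.units):
                out[t] = m.any(axis=1)
        return out

    def association_counts(self) -> np.ndarray:
        """n×n counts of units in which each dyad was observed associating."""
        n = self.n_individuals
        if self.mode == "group":
            pres = self.presence_matrix().astype(np.int64)
            x = pres.T @ pres
        else:
            x = np.zeros((n, n), dtype=np.int64)
            for m in self.units:
                x += m
        np.fill_diagonal(x, 0)
        return x

    def observation_counts(self) -> dict:
        """Units in which each individual was observed (flock-level counts)."""
        pres = self.presence_matrix()
        totals = pres.sum(axis=0)
        return {ind: int(totals[k]) for k, ind in enumerate(self.roster)}

    def subset_units(self, indices: Sequence[int], restrict_roster: bool = True) -> "ObservationStream":
        """New stream keeping the units at ``indices`` (in that order).

        With ``restrict_roster`` the roster shrinks to individuals actually
        observed in the kept units (original roster order); period matrices
        are sliced accordingly.
        """
        indices = list(indices)
        units = [self.units[i] for i in indices]
        if not restrict_roster:
            return ObservationStream(units, self.roster, self.mode)
        if self.mode == "group":
            seen = set().union(*units) if units else set()
            roster = tuple(r for r in self.roster if r in seen)
            return ObservationStream(units, roster, "group")
        present = np.zeros(self.n_individuals, dtype=bool)
        for m in units:
            present |= m.any(axis=1)
        keep = np.flatnonzero(present)
        roster = tuple(self.roster[k] for k in keep)
        mats = [m[np.ix_(keep, keep)] for m in units]
        return ObservationStream(mats, roster, "period")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationStream):
            return NotImplemented
        if self.mode != other.mode or self.roster != other.roster:
            return False
        if self.mode == "group":
            return self.units == other.units
        return len(self.units) == len(other.units) and all(
            np.array_equal(a, b) for a, b in zip(self.units, other.units)
        )

    __hash__ = None


@dataclass(frozen=True)
class AssociationNetwork:
    """Undirected weighted network of association indices in [0, 1]."""

    roster: tuple
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "roster", tuple(str(r) for r in self.roster))
        w = np.array(self.weights, dtype=float)
        n = len(self.roster)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.roster)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationNetwork):
            return NotImplemented
        return self.roster == other.roster and np.allclose(self.weights, other.weights)

    __hash__ = None


# ---------------------------------------------------------------------------
# CSV / GraphML I/O
# ---------------------------------------------------------------------------

def read_gbi(path: Union[str, Path], format: Literal["wide", "long"] = "wide") -> ObservationStream:
    """Read a group-by-individual observation file into a group-mode stream.

    ``wide``: CSV whose header lists individual IDs and whose rows are
    groups, cells 0/1.  Roster order = column order; all-zero rows (empty
    groups) are dropped with a warning.

    ``long``: CSV with columns ``group_id, individual_id``, one row per
    observation.  Group order and roster order follow first appearance in
    the file; duplicate (group, individual) rows are collapsed with a
    warning.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header, body = rows[0], rows[1:]

    if format == "wide":
        roster = [c.strip() for c in header]
        units = []
        for lineno, row in enumerate(body, start=2):
            if len(row) != len(roster):
                raise ValueError(f"{path}:{lineno}: expected {len(roster)} cells, got {len(row)}")
            members = set()
            for ind, cell in zip(roster, row):
                v = cell.strip()
                if v not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: non-binary cell {cell!r}")
                if v == "1":
                    members.add(ind)
            if members:
                units.append(frozenset(members))
            else:
                warnings.warn(f"{path}:{lineno}: empty group row dropped", stacklevel=2)
        return ObservationStream(units, roster, "group")

    if format == "long":
        cols = [c.strip().lower() for c in header]
        try:
            gi, ii = cols.index("group_id"), cols.index("individual_id")
        except ValueError as exc:
            raise ValueError(f"{path}: long format needs group_id and individual_id columns") from exc
        groups: dict = {}
        roster: list = []
        n_dup = 0
        for lineno, row in enumerate(body, start=2):
            if len(row) <= max(gi, ii):
                raise ValueError(f"{path}:{lineno}: short row")
            g, ind = row[gi].strip(), row[ii].strip()
            members = groups.setdefault(g, set())
            if ind in members:
                n_dup += 1
            members.add(ind)
            if ind not in roster:
                roster.append(ind)
        if n_dup:
            warnings.warn(f"{path}: collapsed {n_dup} duplicate (group, individual) rows", stacklevel=2)
            logger.warning("%s: collapsed %d duplicate observation rows", path, n_dup)
        units = [frozenset(groups[g]) for g in groups]  # dicts preserve insertion order
        return ObservationStream(units, roster, "group")

    raise ValueError(f"unknown GBI format {format!r}")


def write_gbi(stream: ObservationStream, path: Union[str, Path], format: Literal["wide", "long"] = "wide") -> None:
    """Serialize a group-mode stream; round-trips exactly through read_gbi."""
    if stream.mode != "group":
        raise ValueError("write_gbi requires a group-mode stream")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if format == "wide":
            w.writerow(stream.roster)
            for u in stream.units:
                w.writerow([1 if ind in u else 0 for ind in stream.roster])
        elif format == "long":
            w.writerow(["group_id", "individual_id"])
            order = {ind: k for k, ind in enumerate(stream.roster)}
            for g, u in enumerate(stream.units, start=1):
                for ind in sorted(u, key=order.__getitem__):
                    w.writerow([f"g{g}", ind])
        else:
            raise ValueError(f"unknown GBI format {format!r}")


def write_network(
    net: AssociationNetwork,
    path: Union[str, Path],
    format: Literal["edgelist_csv", "graphml"] = "edgelist_csv",
    labels: dict | None = None,
) -> None:
    """Write a network as an edge-list CSV (``id_i, id_j, weight``, i < j in
    roster order, zero-weight pairs omitted) or as GraphML with a ``weight``
    edge attribute and an optional ``community`` node attribute."""
    path = Path(path)
    if format == "edgelist_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id_i", "id_j", "weight"])
            for i in range(net.n):
                for j in range(i + 1, net.n):
                    if net.weights[i, j] > 0:
                        w.writerow([net.roster[i], net.roster[j], repr(float(net.weights[i, j]))])
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for ind in net.roster:
            if labels is not None and ind in labels:
                g.add_node(ind, community=int(labels[ind]))
            else:
                g.add_node(ind)
        for i in range(net.n):
            for j in range(i + 1, net.n):
                if net.weights[i, j] > 0:
                    g.add_edge(net.roster[i], net.roster[j], weight=float(net.weights[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(
    path: Union[str, Path],
    format: Literal["edgelist_csv", "graphml"] = "edgelist_csv",
    roster: Iterable | None = None,
) -> AssociationNetwork:
    """Inverse of :func:`write_network`.

    Edge-list CSVs omit zero-weight pairs, so isolated individuals are
    recoverable only if ``roster`` is supplied; by default the roster is
    taken as the order of first appearance in the file.
    """
    path = Path(path)
    if format == "edgelist_csv":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        if not rows or [c.strip() for c in rows[0]] != ["id_i", "id_j", "weight"]:
            raise ValueError(f"{path}: expected header id_i,id_j,weight")
        edges = [(a.strip(), b.strip(), float(wt)) for a, b, wt in rows[1:]]
        if roster is None:
            seen: list = []
            for a, b, _ in edges:
                for ind in (a, b):
                    if ind not in seen:
                        seen.append(ind)
            roster = seen
        roster = list(roster)
        index = {ind: k for k, ind in enumerate(roster)}
        w = np.zeros((len(roster), len(roster)))
        for a, b, wt in edges:
            w[index[a], index[b]] = wt
            w[index[b], index[a]] = wt
        return AssociationNetwork(roster, w)
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        roster = list(roster) if roster is not None else list(g.nodes)
        index = {ind: k for k, ind in enumerate(roster)}
        w = np.zeros((len(roster), len(roster)))
        for a, b, data in g.edges(data=True):
            w[index[a], index[b]] = data.get("weight", 1.0)
            w[index[b], index[a]] = data.get("weight", 1.0)
        return AssociationNetwork(roster, w)
    raise ValueError(f"unknown network format {format!r}")


def filter_rare_individuals(stream: ObservationStream, min_obs: int) -> ObservationStream:
    """Drop individuals observed in fewer than ``min_obs`` sampling units.

    Counts are at the unit (flock) level: being in a unit once counts once
    regardless of how many associations it contains.  Units left empty are
    removed.  The input stream is untouched.
    """
    if min_obs < 0:
        raise ValueError("min_obs must be >= 0")
    counts = stream.observation_counts()
    keep = {ind for ind, c in counts.items() if c >= min_obs}
    roster = tuple(r for r in stream.roster if r in keep)
    if stream.mode == "group":
        units = []
        for u in stream.units:
            trimmed = u & keep
            if trimmed:
                units.append(trimmed)
        return ObservationStream(units, roster, "group")
    idx = np.array([k for k, r in enumerate(stream.roster) if r in keep], dtype=int)
    mats = []
    for m in stream.units:
        sub = m[np.ix_(idx, idx)]
        if sub.any():
            mats.append(sub)
    return ObservationStream(mats, roster, "period")
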