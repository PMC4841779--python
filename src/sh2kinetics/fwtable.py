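"""Far-Western band-table analytics.

Probes (SH2/PTB domains) x (protein band, time point) intensity matrices:
per-replicate max normalization, per-lane relative-specificity differences
against anti-phosphotyrosine blots, and average-linkage hierarchical
clustering on the uncentered correlation (cosine) similarity,

    sim(x, y) = sum(x_i y_i) / sqrt(sum(x_i^2) * sum(y_i^2)),

with flat probe clusters read off at a similarity cutoff (default 0.85).
The agglomeration is implemented directly (naive O(n^3) average linkage with
lexicographic tie-breaking on leaf labels) so merge order is deterministic —
the classic desktop clustering tools do not document their tie behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 0.85

LONG_COLUMNS = ["probe", "replicate", "protein", "time_min", "intensity"]


# ----------------------------------------------------------------------
# Band table I/O and normalization
# ----------------------------------------------------------------------

def load_band_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format band CSV (probe, replicate, protein, time_min,
    intensity) into a wide table: rows (probe, replicate), columns
    (protein, time_min)."""
    long = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(long.columns)
    if missing:
        raise ValueError(f"band table missing columns {sorted(missing)}")
    wide = long.pivot_table(
        index=["probe", "replicate"],
        columns=["protein", "time_min"],
        values="intensity",
        aggfunc="mean",
    ).fillna(0.0)
    return wide.sort_index(axis=1)


def normalize_to_probe_max(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate max normalization, then replicate averaging per probe.

    Each replicate row is divided by its own maximum over all bands and time
    points (so its max is exactly 1), then replicate rows of the same probe
    are averaged.  Idempotent on already-normalized single-replicate data and
    invariant to per-replicate intensity scaling.

    ``table`` rows are indexed by (probe, replicate) or plain probe; values
    must be non-negative with at least one positive value per row.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("band intensities must be non-negative")
    row_max = values.max(axis=1)
    zero_rows = np.flatnonzero(row_max == 0)
    if len(zero_rows):
        label = table.index[zero_rows[0]]
        probe = label[0] if isinstance(label, tuple) else label
        raise ValueError(f"probe {probe!r} has an all-zero replicate row")
    normalized = table.div(row_max, axis=0)
    if isinstance(table.index, pd.MultiIndex):
        return normalized.groupby(level=0, sort=False).mean()
    return normalized


# ----------------------------------------------------------------------
# Relative specificity
# ----------------------------------------------------------------------

def lane_fractions(row: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Express band intensities as fraction of the per-lane (time point)
    total.  Expects a (protein, time) column MultiIndex; every lane must
    have positive total signal."""
    df = row.to_frame().T if isinstance(row, pd.Series) else row
    totals = df.T.groupby(level="time_min").transform("sum").T
    if (totals.to_numpy() <= 0).any():
        raise ValueError("every lane must have positive total intensity")
    frac = df / totals
    return frac.iloc[0] if isinstance(row, pd.Series) else frac


def relative_specificity(
    sh2_row: pd.Series, py_row: pd.Series, tol: float = 1e-6
) -> pd.Series:
    """Per-band relative specificity: SH2 lane fraction minus anti-pY lane
    fraction.

    Both inputs must already be fractions of lane total (each lane sums to
    1 within ``tol``).  Positive values mark binding above the
    motif-independent expectation set by total phosphorylation; by
    construction the values sum to zero within each lane.
    """
    if not sh2_row.index.equals(py_row.index):
        raise ValueError("rows must share the same (protein, time) bands")
    for name, row in (("sh2", sh2_row), ("py", py_row)):
        lane_sums = row.groupby(level="time_min").sum()
        if np.any(np.abs(lane_sums.to_numpy() - 1.0) > tol):
            raise ValueError(
                f"{name} lane totals deviate from 1 by more than {tol}"
            )
    return sh2_row - py_row


# ----------------------------------------------------------------------
# Uncentered-correlation hierarchical clustering
# ----------------------------------------------------------------------

def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-like similarity without mean subtraction, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.sqrt(np.sum(x**2))
    ny = np.sqrt(np.sum(y**2))
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm row has undefined uncentered correlation")
    return float(np.dot(x, y) / (nx * ny))


def similarity_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    norms = np.sqrt(np.sum(matrix**2, axis=1))
    if np.any(norms == 0):
        raise ValueError("zero-norm row has undefined uncentered correlation")
    unit = matrix / norms[:, None]
    return np.clip(unit @ unit.T, -1.0, 1.0)


@dataclass
class Merge:
    """One agglomeration step: the two merged subtrees (by node id) and the
    average pairwise similarity between their leaves."""

    node_id: int
    left: int
    right: int
    similarity: float


@dataclass
class Dendrogram:
    """Binary merge tree over probe rows.

    Leaves are node ids 0..n-1 (in input row order); internal nodes n..2n-2
    in merge order.  ``flat_clusters(cutoff)`` returns the maximal subtrees
    whose internal merge similarities all exceed the cutoff, as frozensets
    of leaf labels.
    """

    labels: list
    merges: list
    _members: dict = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node_id: int) -> frozenset:
        if node_id < self.n_leaves:
            return frozenset([self.labels[node_id]])
        return self._members[node_id]

    def flat_clusters(self, cutoff: float = DEFAULT_CUTOFF) -> list:
        """Maximal subtrees whose merges all exceed ``cutoff``; singletons
        for leaves that never merge that tightly.  Returned as a list of
        frozensets of labels, sorted for determinism."""
        n = self.n_leaves
        min_sim = {}
        children = {}
        for m in self.merges:
            lo = min(
                m.similarity,
                min_sim.get(m.left, np.inf),
                min_sim.get(m.right, np.inf),
            )
            min_sim[m.node_id] = lo
            children[m.node_id] = (m.left, m.right)

        clusters: list = []

        def descend(node: int) -> None:
            if node < n:
                clusters.append(frozenset([self.labels[node]]))
            elif min_sim[node] > cutoff:
                clusters.append(self.members(node))
            else:
                left, right = children[node]
                descend(left)
                descend(right)

        root = self.merges[-1].node_id if self.merges else 0
        if self.merges:
            descend(root)
        else:
            clusters = [frozenset([lab]) for lab in self.labels]
        return sorted(clusters, key=lambda c: sorted(c))

    # ------------------------------------------------------------------
    def to_nested(self) -> list:
        """Nested-list representation: [left, right, similarity] with leaves
        as their labels."""

        def build(node: int):
            if node < self.n_leaves:
                return self.labels[node]
            m = next(mm for mm in self.merges if mm.node_id == node)
            return [build(m.left), build(m.right), m.similarity]

        if not self.merges:
            return list(self.labels)
        return build(self.merges[-1].node_id)

    def to_json(self) -> str:
        return json.dumps(self.to_nested())

    def to_newick(self) -> str:
        """Newick string with merge similarities as internal node labels."""

        def esc(label) -> str:
            s = str(label)
            return s.replace(" ", "_").replace("(", "").replace(")", "")

        def build(node: int) -> str:
            if node < self.n_leaves:
                return esc(self.labels[node])
            m = next(mm for mm in self.merges if mm.node_id == node)
            return f"({build(m.left)},{build(m.right)}){m.similarity:.6f}"

        if not self.merges:
            return ";".join([]) or f"({','.join(esc(l) for l in self.labels)});"
        return build(self.merges[-1].node_id) + ";"


def hcluster_uncentered(
    matrix: pd.DataFrame | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> Dendrogram:
    """Average-linkage agglomeration on uncentered-correlation similarity.

    At each step the pair of clusters with the highest average pairwise leaf
    similarity merges; ties are broken by the lexicographically smallest
    (sorted-leaf-label) pair so row order never changes the result.  The
    ``cutoff`` is stored implicitly — call ``flat_clusters`` on the returned
    Dendrogram (default cutoff 0.85).
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = list(range(len(data)))
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    S = similarity_matrix(data)

    # cluster bookkeeping: node id -> set of leaf indices
    active: dict[int, set] = {i: {i} for i in range(n)}
    members_out: dict[int, frozenset] = {}
    merges: list[Merge] = []

    def avg_sim(ci: set, cj: set) -> float:
        rows = np.fromiter(ci, dtype=int)
        cols = np.fromiter(cj, dtype=int)
        return float(S[np.ix_(rows, cols)].mean())

    def sort_key(node: int) -> tuple:
        return tuple(sorted(str(labels[i]) for i in active[node]))

    next_id = n
    while len(active) > 1:
        best = None
        ids = sorted(active, key=sort_key)
        for ii, a_id in enumerate(ids):
            for b_id in ids[ii + 1 :]:
                sim = avg_sim(active[a_id], active[b_id])
                if best is None or sim > best[0] + 1e-15:
                    best = (sim, a_id, b_id)
        sim, a_id, b_id = best
        active[next_id] = active.pop(a_id) | active.pop(b_id)
        members_out[next_id] = frozenset(labels[i] for i in active[next_id])
        merges.append(Merge(node_id=next_id, left=a_id, right=b_id, similarity=sim))
        next_id += 1

    return Dendrogram(labels=labels, merges=merges, _members=members_out)
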