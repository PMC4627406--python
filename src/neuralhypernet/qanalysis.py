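"""Q-analysis of the patient-descriptor relation.

Each descriptor is a simplex whose vertices are the patients exhibiting it;
a descriptor observed in *n* patients is an (n-1)-dimensional simplex.  Two
descriptors are *q-near* when they share a face of dimension >= q, i.e. at
least q+1 common patients, and *q-connected* when a chain of pairwise q-near
simplices links them.  Sweeping q from the maximal simplex dimension down to
zero traces how the complex assembles: the profile of the maximal
q-connected component exposes a high-dimensional *backcloth* of descriptors
shared by very many patients, and a *plateau* — a q-interval over which the
component containing a chosen anchor (typically the positive-diagnosis
descriptor) keeps exactly the same membership — marks its stability zone.

The plateau members minus the diagnosis pair form the "connected
higher-dimensional set"; the remaining feature descriptors form the
"unconnected" set.  Because backcloth membership only says a descriptor is
common, not that it discriminates, the two sets are handed to the classifier
separately downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import AugmentedIncidence
from .schema import LABEL_COLUMN, descriptor_name

__all__ = [
    "SharedFaceMatrix",
    "QLevel",
    "QProfile",
    "PlateauReport",
    "shared_face_matrix",
    "q_components",
    "structure_profile",
    "find_plateau",
    "split_feature_sets",
    "cluster_shared_faces",
]

_DIAGNOSIS_DESCRIPTORS = frozenset(
    {descriptor_name(LABEL_COLUMN, 0), descriptor_name(LABEL_COLUMN, 1)}
)


@dataclass
class SharedFaceMatrix:
    """Pairwise shared-face dimensions between descriptor simplices.

    ``S[i, j]`` = (number of patients exhibiting both descriptors i and j) - 1;
    the diagonal holds each simplex's own dimension (occurrences - 1) and an
    off-diagonal -1 means the two descriptors share no patient.
    """

    descriptors: list[str]
    S: np.ndarray  # symmetric int matrix

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        if self.S.shape != (len(self.descriptors), len(self.descriptors)):
            raise ValueError("S shape inconsistent with descriptor list")

    @property
    def q_max(self) -> int:
        return int(self.S.diagonal().max())

    def dimension(self, descriptor: str) -> int:
        return int(self.S[self.descriptors.index(descriptor), self.descriptors.index(descriptor)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.descriptors, columns=self.descriptors)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="descriptor")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SharedFaceMatrix":
        df = pd.read_csv(path, index_col="descriptor")
        return cls(descriptors=list(df.index), S=df.to_numpy())


def shared_face_matrix(incidence: AugmentedIncidence) -> SharedFaceMatrix:
    """Shared-face dimensions from boolean column co-occurrence counts."""
    if incidence.matrix.size == 0:
        raise ValueError("empty incidence matrix")
    M = incidence.matrix.astype(np.int64)
    S = M.T @ M - 1
    return SharedFaceMatrix(descriptors=list(incidence.descriptors), S=S)


def q_components(sfm: SharedFaceMatrix, q: int) -> list[frozenset[str]]:
    """q-connected components, by explicit graph construction.

    Vertices are the descriptors whose simplex dimension is at least q;
    edges join pairs sharing a face of dimension >= q.  Descriptors with no
    q-near neighbour appear as singleton components.
    """
    if not 0 <= q <= sfm.q_max:
        raise ValueError(f"q={q} outside the valid range [0, {sfm.q_max}]")
    diag = sfm.S.diagonal()
    alive = [i for i in range(len(sfm.descriptors)) if diag[i] >= q]
    G = nx.Graph()
    G.add_nodes_from(alive)
    for a, i in enumerate(alive):
        for j in alive[a + 1 :]:
            if sfm.S[i, j] >= q:
                G.add_edge(i, j)
    return [
        frozenset(sfm.descriptors[i] for i in comp) for comp in nx.connected_components(G)
    ]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass(frozen=True)
class QLevel:
    q: int
    components: tuple[frozenset[str], ...]
    n_components: int
    max_component_size: int
    max_component_members: frozenset[str]


@dataclass
class QProfile:
    """Component structure at every q from 0 to the maximal dimension."""

    levels: list[QLevel] = field(default_factory=list)

    def level(self, q: int) -> QLevel:
        lv = self.levels[q]
        assert lv.q == q
        return lv

    @property
    def q_max(self) -> int:
        return self.levels[-1].q

    def to_frame(self, anchor: str | None = None) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            row = {
                "q": lv.q,
                "n_components": lv.n_components,
                "max_component_size": lv.max_component_size,
            }
            if anchor is not None:
                members = next((c for c in lv.components if anchor in c), frozenset())
                row["anchor_component"] = "|".join(sorted(members))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, anchor: str | None = None) -> None:
        self.to_frame(anchor=anchor).to_csv(path, index=False)


def _max_component(components: list[frozenset[str]]) -> tuple[int, frozenset[str]]:
    if not components:
        return 0, frozenset()
    # deterministic tie-break: largest size, then lexicographically first
    best = min(components, key=lambda c: (-len(c), sorted(c)))
    return len(best), best


def structure_profile(sfm: SharedFaceMatrix) -> QProfile:
    """Evaluate the q-connected components at every level in one sweep.

    Edges and vertices activate as q decreases (a simplex enters at its own
    dimension, an edge at its shared-face value), so a single union-find
    accumulates the structure top-down; the result is identical to calling
    :func:`q_components` level by level.
    """
    n = len(sfm.descriptors)
    diag = sfm.S.diagonal()
    q_max = sfm.q_max
    if q_max < 0:
        return QProfile(levels=[])

    vertices_at = [[] for _ in range(q_max + 1)]
    for i in range(n):
        if diag[i] >= 0:
            vertices_at[min(diag[i], q_max)].append(i)
    edges_at = [[] for _ in range(q_max + 1)]
    for i in range(n):
        for j in range(i + 1, n):
            if sfm.S[i, j] >= 0:
                edges_at[sfm.S[i, j]].append((i, j))

    uf = _UnionFind(n)
    active: list[int] = []
    levels_desc: list[QLevel] = []
    for q in range(q_max, -1, -1):
        active.extend(vertices_at[q])
        for i, j in edges_at[q]:
            uf.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in active:
            groups.setdefault(uf.find(i), []).append(i)
        comps = [frozenset(sfm.descriptors[i] for i in g) for g in groups.values()]
        comps.sort(key=lambda c: sorted(c))
        size, members = _max_component(comps)
        levels_desc.append(
            QLevel(
                q=q,
                components=tuple(comps),
                n_components=len(comps),
                max_component_size=size,
                max_component_members=members,
            )
        )
    return QProfile(levels=list(reversed(levels_desc)))


@dataclass(frozen=True)
class PlateauReport:
    """The anchor's stability zone: a maximal q-interval of constant
    component membership (component size >= 2)."""

    q_lo: int
    q_hi: int
    members: frozenset[str]
    contains_positive_diagnosis: bool

    @property
    def is_empty(self) -> bool:
        return not self.members


def find_plateau(profile: QProfile, anchor: str) -> PlateauReport:
    """Longest q-interval over which the anchor's component is unchanged.

    Only levels where the anchor sits in a component of size >= 2 count;
    among equally long intervals the one at higher q wins (the stability
    zone of interest is the high-dimensional one).  An anchor that is
    everywhere isolated yields an empty, flagged report.
    """
    memberships: list[tuple[int, frozenset[str]]] = []
    for lv in profile.levels:
        comp = next((c for c in lv.components if anchor in c), None)
        if comp is not None and len(comp) >= 2:
            memberships.append((lv.q, comp))
    if not memberships:
        warnings.warn(f"anchor {anchor!r} is never in a component of size >= 2")
        return PlateauReport(q_lo=-1, q_hi=-1, members=frozenset(), contains_positive_diagnosis=False)

    best: tuple[int, int, frozenset[str]] | None = None  # (length, q_lo, members)
    run_start = 0
    for k in range(1, len(memberships) + 1):
        end_of_run = (
            k == len(memberships)
            or memberships[k][0] != memberships[k - 1][0] + 1
            or memberships[k][1] != memberships[k - 1][1]
        )
        if end_of_run:
            q_lo, members = memberships[run_start]
            q_hi = memberships[k - 1][0]
            length = q_hi - q_lo + 1
            # ties broken toward the higher q-interval (>= on equal length)
            if best is None or length >= best[0]:
                best = (length, q_lo, members)
            run_start = k
    assert best is not None
    length, q_lo, members = best
    return PlateauReport(
        q_lo=q_lo,
        q_hi=q_lo + length - 1,
        members=members,
        contains_positive_diagnosis=descriptor_name(LABEL_COLUMN, 1) in members,
    )


def split_feature_sets(
    report: PlateauReport, all_descriptors: list[str]
) -> tuple[list[str], list[str]]:
    """Partition the feature descriptors by plateau membership.

    Returns ``(connected, unconnected)``: plateau members minus the
    diagnosis pair, and the remaining feature descriptors.  Order follows
    *all_descriptors*.
    """
    features = [d for d in all_descriptors if d not in _DIAGNOSIS_DESCRIPTORS]
    connected = [d for d in features if d in report.members]
    unconnected = [d for d in features if d not in report.members]
    return connected, unconnected


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaves: list[str]
    method: str


def cluster_shared_faces(sfm: SharedFaceMatrix, method: str = "average") -> ClusterResult:
    """Hierarchical agglomerative clustering of the shared-face rows.

    Descriptor rows of S are clustered under Euclidean distance (average
    linkage by default); the leaf ordering is what a clustered heatmap of
    the matrix is rendered with.
    """
    Z = linkage(sfm.S.astype(float), method=method, metric="euclidean")
    order = leaves_list(Z)
    return ClusterResult(
        linkage=Z, leaves=[sfm.descriptors[i] for i in order], method=method
    )


def plot_profile(profile: QProfile, path: str | Path) -> None:
    """Maximal connected-component size as a function of q."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qs = [lv.q for lv in profile.levels]
    sizes = [lv.max_component_size for lv in profile.levels]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.step(qs, sizes, where="post")
    ax.set_xlabel("q")
    ax.set_ylabel("size of maximal q-connected component")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shared_face_heatmap(
    sfm: SharedFaceMatrix, path: str | Path, method: str = "average"
) -> None:
    """Heatmap of S with rows/columns in clustered leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = cluster_shared_faces(sfm, method=method)
    idx = [sfm.descriptors.index(d) for d in res.leaves]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(sfm.S[np.ix_(idx, idx)], cmap="viridis")
    ax.set_xticks(range(len(idx)), res.leaves, rotation=90, fontsize=6)
    ax.set_yticks(range(len(idx)), res.leaves, fontsize=6)
    fig.colorbar(im, ax=ax, label="shared-face dimension")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class QConnectivitySelector(TransformerMixin, BaseEstimator):
    """Feature selection by backcloth membership, as an sklearn transformer.

    ``fit`` appends the diagnosis descriptor pair to the descriptor frame,
    runs the q-sweep, finds the plateau anchored at the positive-diagnosis
    descriptor and splits the feature descriptors into the connected and
    unconnected higher-dimensional sets; ``transform`` keeps the chosen set.

    Parameters
    ----------
    feature_set : {"connected", "unconnected", "union"}
        Which side of the split to select ("union" keeps every feature
        descriptor and uses the split only for reporting).
    anchor : str or None
        Anchor descriptor for the plateau search; defaults to the positive
        final-diagnosis descriptor.
    """

    def __init__(self, feature_set: str = "union", anchor: str | None = None):
        self.feature_set = feature_set
        self.anchor = anchor

    def fit(self, X: pd.DataFrame, y) -> "QConnectivitySelector":
        if self.feature_set not in ("connected", "unconnected", "union"):
            raise ValueError(
                f"feature_set must be 'connected', 'unconnected' or 'union', "
                f"got {self.feature_set!r}"
            )
        if not isinstance(X, pd.DataFrame):
            raise TypeError("QConnectivitySelector expects a descriptor DataFrame")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("y must align with the rows of X")
        full = X.copy()
        full[descriptor_name(LABEL_COLUMN, 0)] = (y == 0).astype(int)
        full[descriptor_name(LABEL_COLUMN, 1)] = (y == 1).astype(int)
        inc = AugmentedIncidence(
            patients=[str(p) for p in full.index],
            descriptors=list(full.columns),
            matrix=full.to_numpy().astype(bool),
            labels=np.asarray(y, dtype=float),
        )
        self.shared_face_ = shared_face_matrix(inc)
        self.profile_ = structure_profile(self.shared_face_)
        anchor = self.anchor or descriptor_name(LABEL_COLUMN, 1)
        self.plateau_ = find_plateau(self.profile_, anchor)
        self.connected_, self.unconnected_ = split_feature_sets(
            self.plateau_, list(full.columns)
        )
        if self.feature_set == "connected":
            self.selected_ = list(self.connected_)
        elif self.feature_set == "unconnected":
            self.selected_ = list(self.unconnected_)
        else:
            self.selected_ = [
                d for d in X.columns if d not in _DIAGNOSIS_DESCRIPTORS
            ]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_"):
            raise ValueError("QConnectivitySelector is not fitted yet")
        return X[self.selected_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.selected_, dtype=object)
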