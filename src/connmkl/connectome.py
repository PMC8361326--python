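"""Multi-weight structural connectomes and their edge-feature representation.

A subject's white-matter network is represented three times over the same
binary topology: edges weighted by streamline count (FN), by the mean
fractional anisotropy (FA) of the voxels the connecting streamlines traverse,
and by the mean diffusivity (MD) of those voxels.  For classification each
subject is flattened into one row of ``M * n(n-1)/2`` edge features (M = 3
networks) in a fixed, documented column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aal import default_node_labels

logger = logging.getLogger(__name__)

#: Canonical network block order used everywhere downstream.
NETWORK_KINDS: tuple[str, str, str] = ("FN", "FA", "MD")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultiWeightConnectome:
    """Three co-topological weighted adjacency matrices for one subject.

    Parameters
    ----------
    fn, fa, md
        Square symmetric matrices with zero diagonal sharing one binary
        support: ``fn[i, j] > 0`` iff ``fa[i, j] > 0`` iff ``md[i, j] > 0``.
        FN entries are non-negative integers (streamline counts), FA entries
        lie in (0, 1] on the support, MD entries are strictly positive on the
        support (mm^2/s scale, around 0.7e-3 for healthy white matter).
    node_labels
        Region names in atlas order; defaults to AAL-90 names for 90 nodes.
    """

    fn: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.fn = np.asarray(self.fn, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        self.md = np.asarray(self.md, dtype=float)
        if not self.node_labels:
            self.node_labels = default_node_labels(self.fn.shape[0])
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.fn.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Boolean adjacency shared by the three weightings."""
        return self.fn > 0

    def matrices(self) -> dict[str, np.ndarray]:
        return {"FN": self.fn, "FA": self.fa, "MD": self.md}

    def validate(self) -> None:
        n = self.fn.shape[0]
        for name, m in self.matrices().items():
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix is not {n}x{n}")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} matrix is not symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} matrix has a non-zero diagonal")
            if np.any(m < 0):
                raise ValueError(f"{name} matrix has negative entries")
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match matrix size")
        sup = self.fn > 0
        if not (np.array_equal(sup, self.fa > 0) and np.array_equal(sup, self.md > 0)):
            raise ValueError("FN/FA/MD do not share one binary topology")
        if np.any(self.fn[sup] != np.round(self.fn[sup])):
            raise ValueError("FN entries must be integers (streamline counts)")
        if np.any(self.fa[sup] > 1.0):
            raise ValueError("FA entries must lie in (0, 1] on the support")


@dataclass
class StreamlinePhantom:
    """Labelled volume plus streamlines, the raw material for network building.

    ``label_volume`` holds 0 for background and 1..R for regions; ``fa_volume``
    and ``md_volume`` are scalar maps of the same shape.  Each streamline is an
    ordered ``(L, 3)`` integer array of voxel indices, L >= 2.
    """

    label_volume: np.ndarray
    fa_volume: np.ndarray
    md_volume: np.ndarray
    streamlines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume, dtype=int)
        self.fa_volume = np.asarray(self.fa_volume, dtype=float)
        self.md_volume = np.asarray(self.md_volume, dtype=float)
        self.streamlines = [np.asarray(s, dtype=int) for s in self.streamlines]
        self.validate()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    @property
    def n_regions(self) -> int:
        return int(self.label_volume.max(initial=0))

    def validate(self) -> None:
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.fa_volume.shape != self.shape or self.md_volume.shape != self.shape:
            raise ValueError("FA/MD volumes must match the label volume shape")
        if np.any(self.label_volume < 0):
            raise ValueError("label volume has negative labels")
        bounds = np.array(self.shape)
        for k, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {k} is not an (L>=2, 3) index array")
            if np.any(s < 0) or np.any(s >= bounds):
                raise ValueError(f"streamline {k} leaves the volume")


@dataclass
class FeatureTable:
    """Subjects x edge-feature matrix with per-column provenance.

    Columns are ordered FN block, FA block, MD block; within each block the
    upper-triangle node pairs (i, j), i < j, 1-based, in lexicographic order.
    """

    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    n_nodes: int
    node_labels: tuple[str, ...]
    provenance: list[tuple[str, tuple[int, int]]]

    M: int = 3

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        p = self.M * self.n_nodes * (self.n_nodes - 1) // 2
        if self.features.shape != (len(self.subject_ids), p):
            raise ValueError("feature matrix shape does not match subjects x features")
        if len(self.provenance) != p:
            raise ValueError("provenance length does not match feature count")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be -1 or +1")

    # -- column bookkeeping -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def network_columns(self, kind: str) -> np.ndarray:
        """Column indices of one network block, in canonical order."""
        k = NETWORK_KINDS.index(kind)
        return np.arange(k * self.n_pairs, (k + 1) * self.n_pairs)

    def column_kind(self, j: int) -> str:
        return self.provenance[j][0]

    def column_names(self) -> list[str]:
        names = []
        for kind, (i, j) in self.provenance:
            names.append(f"{kind}:{self.node_labels[i - 1]}-{self.node_labels[j - 1]}")
        return names

    # -- round trip ---------------------------------------------------------

    def to_connectome(self, row: int) -> MultiWeightConnectome:
        """Rebuild one subject's three matrices from its feature row."""
        mats = {k: np.zeros((self.n_nodes, self.n_nodes)) for k in NETWORK_KINDS}
        x = self.features[row]
        for col, (kind, (i, j)) in enumerate(self.provenance):
            mats[kind][i - 1, j - 1] = x[col]
            mats[kind][j - 1, i - 1] = x[col]
        return MultiWeightConnectome(
            fn=mats["FN"], fa=mats["FA"], md=mats["MD"], node_labels=self.node_labels
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.column_names())
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_nodes: int | None = None,
                 node_labels: Sequence[str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        p = df.shape[1] - 2
        if n_nodes is None:
            # p = 3 n(n-1)/2  ->  n = (1 + sqrt(1 + 8p/3)) / 2
            n_nodes = int(round((1 + np.sqrt(1 + 8 * p / 3)) / 2))
        labels_tuple = tuple(node_labels) if node_labels else default_node_labels(n_nodes)
        prov = canonical_provenance(n_nodes)
        table = cls(
            features=df.iloc[:, 2:].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            subject_ids=df["subject_id"].astype(str).tolist(),
            n_nodes=n_nodes,
            node_labels=labels_tuple,
            provenance=prov,
        )
        if list(df.columns[2:]) != table.column_names():
            raise ValueError("CSV columns are not in canonical feature order")
        return table


def canonical_provenance(n_nodes: int) -> list[tuple[str, tuple[int, int]]]:
    """(network kind, 1-based node pair) for every canonical column."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    pairs = [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]
    return [(kind, pair) for kind in NETWORK_KINDS for pair in pairs]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_networks(phantom: StreamlinePhantom, n_nodes: int,
                   voxel_multiset: bool = False) -> MultiWeightConnectome:
    """Construct FN/FA/MD-weighted networks from labelled streamlines.

    A node pair (i, j), i != j, is connected if at least one streamline has
    its two endpoint voxels in regions i and j.  The FN weight is the count
    of such streamlines; the FA (MD) weight is the mean of the FA (MD) volume
    over the voxels traversed by all streamlines of that pair.  By default
    traversed voxels are deduplicated (a voxel visited twice counts once);
    ``voxel_multiset=True`` weights voxels by visit count instead.

    Streamlines with an endpoint in background (label 0) are skipped and
    counted in a log message; streamlines with both endpoints in one region
    are skipped (the diagonal is structurally zero).
    """
    if n_nodes < phantom.n_regions:
        raise ValueError(
            f"n_nodes={n_nodes} is smaller than the largest region id "
            f"{phantom.n_regions}"
        )
    counts: dict[tuple[int, int], int] = {}
    voxels: dict[tuple[int, int], list] = {}
    n_background = 0
    n_self = 0
    lab = phantom.label_volume
    for s in phantom.streamlines:
        r0 = int(lab[tuple(s[0])])
        r1 = int(lab[tuple(s[-1])])
        if r0 == 0 or r1 == 0:
            n_background += 1
            continue
        if r0 == r1:
            n_self += 1
            continue
        pair = (min(r0, r1), max(r0, r1))
        counts[pair] = counts.get(pair, 0) + 1
        voxels.setdefault(pair, []).append(s)
    if n_background:
        logger.info("skipped %d streamline(s) with endpoint in background", n_background)
    if n_self:
        logger.info("skipped %d self-connecting streamline(s)", n_self)

    fn = np.zeros((n_nodes, n_nodes))
    fa = np.zeros((n_nodes, n_nodes))
    md = np.zeros((n_nodes, n_nodes))
    for (i, j), streams in voxels.items():
        stacked = np.vstack(streams)
        if not voxel_multiset:
            stacked = np.unique(stacked, axis=0)
        idx = tuple(stacked.T)
        a, b = i - 1, j - 1
        fn[a, b] = fn[b, a] = counts[(i, j)]
        fa[a, b] = fa[b, a] = float(np.mean(phantom.fa_volume[idx]))
        md[a, b] = md[b, a] = float(np.mean(phantom.md_volume[idx]))
    return MultiWeightConnectome(fn=fn, fa=fa, md=md,
                                 node_labels=default_node_labels(n_nodes))


def vectorize(cohort: Iterable[tuple[MultiWeightConnectome, int]],
              subject_ids: Sequence[str] | None = None) -> FeatureTable:
    """Flatten a labelled cohort into the canonical edge-feature table.

    Every connectome must share ``n_nodes`` and node labels; labels must be
    -1 or +1 with at least one subject per class.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    n = cohort[0][0].n_nodes
    node_labels = cohort[0][0].node_labels
    labels = []
    rows = []
    iu, ju = np.triu_indices(n, k=1)
    for conn, y in cohort:
        if conn.n_nodes != n or conn.node_labels != node_labels:
            raise ValueError("connectomes in a cohort must share nodes and labels")
        if y not in (-1, 1):
            raise ValueError(f"label {y!r} is not -1 or +1")
        rows.append(np.concatenate([conn.fn[iu, ju], conn.fa[iu, ju], conn.md[iu, ju]]))
        labels.append(int(y))
    if len(set(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    if subject_ids is None:
        subject_ids = [f"sub-{k + 1:03d}" for k in range(len(cohort))]
    return FeatureTable(
        features=np.vstack(rows),
        labels=np.asarray(labels),
        subject_ids=list(subject_ids),
        n_nodes=n,
        node_labels=node_labels,
        provenance=canonical_provenance(n),
    )
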