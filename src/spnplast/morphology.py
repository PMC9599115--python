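"""Reduced dendritic morphology, explicit spines, and train-to-spine mappings.

The morphology is a tree of cylindrical segments rooted at the soma: by
default 4 primary dendrites, each splitting once into 2 secondary branches,
with SPN-like tapering and ~200 µm soma-to-tip path length.  Explicit spines
(cylindrical head 0.5x0.5 µm, neck 0.12x0.5 µm) are placed at a configurable
density on dendrite more than 25 µm from the soma.  Spike trains are assigned
to spines either as a random matching or in clusters parameterised by spines
per cluster and cluster length (the dendritic path distance between the most
separated pair of spines in a cluster).  All distances are path distances
along the dendrite, never Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Morphology",
    "SpineSet",
    "ClusterConfig",
    "ClusterMapping",
    "InfeasibleClusterError",
    "build_default_morphology",
    "place_spines",
    "assign_clusters",
    "spine_distance_matrix",
]

SPINE_HEAD_DIAM = 0.5   # µm
SPINE_HEAD_LEN = 0.5    # µm
SPINE_NECK_DIAM = 0.12  # µm
SPINE_NECK_LEN = 0.5    # µm


@dataclass(frozen=True)
class Morphology:
    """Tree of cylindrical segments; index 0 is the soma (root, parent = -1).

    ``length``/``diameter`` are µm.  ``proximal_distance[i]`` is the path
    distance (µm) from the soma to the proximal end of segment i (the soma
    itself contributes zero length to dendritic path distances).
    """

    parent: np.ndarray    # int, parent[0] == -1
    length: np.ndarray    # µm
    diameter: np.ndarray  # µm

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=int)
        length = np.asarray(self.length, dtype=float)
        diameter = np.asarray(self.diameter, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "diameter", diameter)
        if parent[0] != -1 or np.any(parent[1:] >= np.arange(1, parent.size)):
            raise ValueError("segments must be topologically ordered with root 0")
        if np.any(length <= 0) or np.any(diameter <= 0):
            raise ValueError("lengths and diameters must be positive")
        prox = np.zeros(parent.size)
        for i in range(1, parent.size):
            p = parent[i]
            prox[i] = 0.0 if p == 0 else prox[p] + length[p]
        object.__setattr__(self, "_proximal", prox)

    @property
    def n_segments(self) -> int:
        return int(self.parent.size)

    @property
    def proximal_distance(self) -> np.ndarray:
        return self._proximal

    @property
    def midpoint_distance(self) -> np.ndarray:
        """Path distance soma -> segment midpoint (soma midpoint = 0)."""
        mid = self._proximal + self.length / 2.0
        mid[0] = 0.0
        return mid

    def ancestors(self, seg: int) -> list[int]:
        """Chain of segments from `seg` up to (and including) the root."""
        chain = [seg]
        while self.parent[chain[-1]] != -1:
            chain.append(int(self.parent[chain[-1]]))
        return chain

    def point_distance(self, seg_a: int, x_a: float, seg_b: int, x_b: float) -> float:
        """Dendritic path distance (µm) between arc points on two segments."""
        da = self._proximal[seg_a] + x_a
        db = self._proximal[seg_b] + x_b
        if seg_a == seg_b:
            return abs(x_a - x_b)
        anc_a = self.ancestors(seg_a)
        anc_b = self.ancestors(seg_b)
        set_a, set_b = set(anc_a), set(anc_b)
        # one segment on the other's root path: route runs along the ancestor
        # segment, so the path distance is the difference of soma distances
        if (seg_b in set_a and seg_b != 0) or (seg_a in set_b and seg_a != 0):
            return abs(da - db)
        # lowest common ancestor: deepest shared segment on both chains
        lca = next(s for s in anc_a if s in set_b)
        branch = 0.0 if lca == 0 else self._proximal[lca] + self.length[lca]
        return (da - branch) + (db - branch)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": np.arange(self.n_segments),
                "parent_id": self.parent,
                "length_um": self.length,
                "diameter_um": self.diameter,
            }
        )

    @classmethod
    def from_table(cls, df) -> "Morphology":
        df = df.sort_values("segment_id")
        return cls(
            df["parent_id"].to_numpy(int),
            df["length_um"].to_numpy(float),
            df["diameter_um"].to_numpy(float),
        )


@dataclass(frozen=True)
class SpineSet:
    """Explicit spines: attachment segment and arc position along it (µm)."""

    segment: np.ndarray   # int, attachment segment per spine
    position: np.ndarray  # µm arc position along the segment
    morph: Morphology

    def __post_init__(self):
        seg = np.asarray(self.segment, dtype=int)
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "segment", seg)
        object.__setattr__(self, "position", pos)
        if np.any(pos < 0) or np.any(pos > self.morph.length[seg]):
            raise ValueError("spine arc positions must lie within their segment")

    @property
    def n_spines(self) -> int:
        return int(self.segment.size)

    @property
    def path_distance(self) -> np.ndarray:
        """Path distance soma -> spine attachment point (µm)."""
        return self.morph.proximal_distance[self.segment] + self.position


@dataclass(frozen=True)
class ClusterConfig:
    spines_per_cluster: int
    cluster_length: float  # µm, max pairwise dendritic distance within a cluster
    n_mappings: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.spines_per_cluster < 1:
            raise ValueError("spines_per_cluster must be >= 1")
        if self.cluster_length < 0:
            raise ValueError("cluster_length must be >= 0")


@dataclass(frozen=True)
class ClusterMapping:
    """Injective assignment train -> spine with a cluster id per assigned spine."""

    train_ids: np.ndarray   # assigned trains
    spine_ids: np.ndarray   # matching spine per train (injective)
    cluster_ids: np.ndarray  # cluster of each assigned spine
    spines: SpineSet

    def __post_init__(self):
        if len(set(self.spine_ids.tolist())) != len(self.spine_ids):
            raise ValueError("assignment must be injective over spines")

    @property
    def n_assigned(self) -> int:
        return int(self.train_ids.size)

    def spine_of_train(self, train_id: int) -> int:
        idx = np.nonzero(self.train_ids == train_id)[0]
        return int(self.spine_ids[idx[0]])

    def train_of_spine(self, spine_id: int) -> int:
        idx = np.nonzero(self.spine_ids == spine_id)[0]
        return int(self.train_ids[idx[0]])

    def realized_cluster_lengths(self) -> dict[int, float]:
        D = spine_distance_matrix(self.spines)
        out = {}
        for cid in np.unique(self.cluster_ids):
            members = self.spine_ids[self.cluster_ids == cid]
            out[int(cid)] = float(D[np.ix_(members, members)].max()) if members.size > 1 else 0.0
        return out

    def nearest_neighbors(self, spine_id: int, k: int) -> np.ndarray:
        """The k nearest ASSIGNED spines by dendritic path distance (ties by id)."""
        D = spine_distance_matrix(self.spines)
        others = self.spine_ids[self.spine_ids != spine_id]
        order = np.lexsort((others, D[spine_id, others]))
        return others[order[:k]]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "train_id": self.train_ids,
                "spine_id": self.spine_ids,
                "cluster_id": self.cluster_ids,
            }
        )


class InfeasibleClusterError(RuntimeError):
    pass


def build_default_morphology(
    n_primary: int = 4,
    segments_per_branch: int = 4,
    seg_length: float = 20.0,
    n_secondary: int = 2,
    secondary_segments: int = 6,
    primary_diameter: tuple[float, float] = (2.25, 1.5),
    secondary_diameter: tuple[float, float] = (1.0, 0.65),
    soma_diameter: float = 14.0,
) -> Morphology:
    """Deterministic reduced morphology: soma + primary branches, each
    splitting into ``n_secondary`` secondary branches (0 = unbranched)."""
    parent = [-1]
    length = [soma_diameter]
    diameter = [soma_diameter]

    def taper(n, d0, d1):
        return np.linspace(d0, d1, n)

    for _ in range(n_primary):
        prim_ids = []
        prev = 0
        for j, d in enumerate(taper(segments_per_branch, *primary_diameter)):
            parent.append(prev)
            length.append(seg_length)
            diameter.append(float(d))
            prev = len(parent) - 1
            prim_ids.append(prev)
        tip = prim_ids[-1]
        for _b in range(n_secondary):
            prev = tip
            for d in taper(secondary_segments, *secondary_diameter):
                parent.append(prev)
                length.append(seg_length)
                diameter.append(float(d))
                prev = len(parent) - 1
    return Morphology(np.array(parent), np.array(length), np.array(diameter))


def place_spines(
    morph: Morphology,
    density_per_um: float = 0.1,
    min_distance_um: float = 25.0,
    seed: int = 0,
    segments: np.ndarray | None = None,
) -> SpineSet:
    """Place spines uniformly over eligible arc length.

    Eligible arc length is every dendritic point with path distance to the
    soma greater than ``min_distance_um`` (restricted to ``segments`` when
    given, emulating elevated densities on a subset of branches).  The spine
    count is the deterministically rounded ``density x eligible length``;
    positions are a uniform sample of the pooled eligible arc length.
    """
    if density_per_um < 0:
        raise ValueError("density must be >= 0")
    segs, starts, lens = [], [], []
    candidates = range(1, morph.n_segments) if segments is None else segments
    for s in candidates:
        s = int(s)
        prox = morph.proximal_distance[s]
        lo = max(0.0, min_distance_um - prox)
        if lo < morph.length[s]:
            segs.append(s)
            starts.append(lo)
            lens.append(morph.length[s] - lo)
    total = float(np.sum(lens))
    n = int(round(density_per_um * total))
    if n == 0 or total == 0:
        return SpineSet(np.empty(0, int), np.empty(0), morph)
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, total, size=n))
    edges = np.concatenate(([0.0], np.cumsum(lens)))
    which = np.searchsorted(edges, u, side="right") - 1
    which = np.clip(which, 0, len(segs) - 1)
    seg_arr = np.array([segs[i] for i in which], int)
    pos_arr = np.array([starts[i] for i in which]) + (u - edges[which])
    order = np.lexsort((pos_arr, seg_arr))
    return SpineSet(seg_arr[order], pos_arr[order], morph)


def _segment_relations(morph: Morphology):
    """Per segment-pair: shared-root-path flag and LCA branch-point distance."""
    n = morph.n_segments
    anc = [set(morph.ancestors(s)) for s in range(n)]
    samepath = np.zeros((n, n), dtype=bool)
    branch = np.zeros((n, n))
    distal = morph.proximal_distance + morph.length
    for s in range(n):
        chain = morph.ancestors(s)
        for t in range(n):
            if s == t or s in anc[t] or t in anc[s]:
                samepath[s, t] = True
            else:
                lca = next(a for a in chain if a in anc[t])
                branch[s, t] = 0.0 if lca == 0 else distal[lca]
    return samepath, branch


def spine_distance_matrix(spines: SpineSet) -> np.ndarray:
    """Pairwise dendritic path distances (µm) between spine attachment points.

    Cached on the SpineSet (the geometry is immutable)."""
    cached = getattr(spines, "_distance_matrix", None)
    if cached is not None:
        return cached
    samepath, branch = _segment_relations(spines.morph)
    d = spines.path_distance
    sa = spines.segment
    D = np.where(
        samepath[np.ix_(sa, sa)],
        np.abs(d[:, None] - d[None, :]),
        d[:, None] + d[None, :] - 2.0 * branch[np.ix_(sa, sa)],
    )
    object.__setattr__(spines, "_distance_matrix", D)
    return D


def assign_clusters(
    spines: SpineSet,
    train_ids,
    cfg: ClusterConfig,
    seed: int | None = None,
) -> ClusterMapping:
    """Group spines into clusters and assign one train per cluster spine.

    Cluster anchors are seeded uniformly over eligible (unassigned) spines.
    Each cluster is built to approximately REALISE the requested length: the
    anchor is paired with the unassigned spine whose path distance to it is
    largest but still within ``cluster_length``, and the remaining members are
    drawn at random from spines compatible (pairwise) with the cluster so far.
    Trains are shuffled and dealt to cluster spines; leftover trains (fewer
    than a full cluster) stay unassigned.
    """
    train_ids = np.asarray(train_ids, dtype=int)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spc = cfg.spines_per_cluster
    n_clusters = train_ids.size // spc
    if n_clusters == 0:
        raise InfeasibleClusterError("fewer trains than spines_per_cluster")
    if n_clusters * spc > spines.n_spines:
        raise InfeasibleClusterError(
            f"need {n_clusters * spc} spines for {n_clusters} clusters of "
            f"{spc}, only {spines.n_spines} placed"
        )
    D = spine_distance_matrix(spines)
    unassigned = set(range(spines.n_spines))
    clusters: list[list[int]] = []
    tol = 1e-9
    for _ in range(n_clusters):
        anchors = rng.permutation(sorted(unassigned))
        built = None
        for anchor in anchors:
            anchor = int(anchor)
            if spc == 1:
                built = [anchor]
                break
            pool = np.array(sorted(unassigned - {anchor}), dtype=int)
            within = pool[D[anchor, pool] <= cfg.cluster_length + tol]
            if within.size < spc - 1:
                continue
            # realise the span: farthest compatible spine joins first
            far = int(within[np.argmax(D[anchor, within])])
            members = [anchor, far]
            cand = [int(c) for c in rng.permutation(within) if int(c) != far]
            while len(members) < spc and cand:
                c = cand.pop()
                if all(D[c, m] <= cfg.cluster_length + tol for m in members):
                    members.append(c)
            if len(members) == spc:
                built = members
                break
        if built is None:
            raise InfeasibleClusterError(
                f"cannot form a cluster of {spc} spines within "
                f"cluster_length={cfg.cluster_length} µm at the placed spine "
                "density; increase cluster_length or spine density"
            )
        clusters.append(built)
        unassigned -= set(built)

    spine_order = np.array([s for cl in clusters for s in cl], int)
    cluster_of = np.array(
        [ci for ci, cl in enumerate(clusters) for _ in cl], int
    )
    trains = rng.permutation(train_ids)[: spine_order.size]
    return ClusterMapping(trains, spine_order, cluster_of, spines)


def write_morphology(path, morph: Morphology) -> None:
    morph.to_table().to_csv(path, sep="\t", index=False)


def read_morphology(path) -> Morphology:
    import pandas as pd

    return Morphology.from_table(pd.read_csv(path, sep="\t"))
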