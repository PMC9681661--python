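"""Clustering and metacluster annotation.

Events are clustered by community detection (Leiden) on a k-nearest-neighbor
graph built from a named marker panel — the backend is pluggable behind
:func:`cluster_events`. Fine clusters are then merged into lineage-level
metaclusters by agglomerative linkage on their median profiles, with explicit
replayable merge/split/exclude rules; contaminant clusters (broad-positive
"doublet-like" or all-negative) are excluded by scaled-median rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .events import ConfigurationError, EventTable

logger = logging.getLogger(__name__)


@dataclass
class ClusteringSpec:
    """Marker panel and graph-clustering parameters."""

    markers: tuple[str, ...]
    n_neighbors: int = 20
    resolution: float = 1.0
    backend: str = "leiden"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ConfigurationError("neighbor count must be >= 2")
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError("duplicate markers in clustering panel")


def _leiden_backend(values: np.ndarray, spec: ClusteringSpec) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    knn = kneighbors_graph(values, n_neighbors=spec.n_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()  # symmetrize
    edges = [(int(i), int(j)) for i, j in zip(knn.row, knn.col) if i < j]
    graph = igraph.Graph(n=values.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=spec.resolution,
        seed=spec.seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


_BACKENDS = {"leiden": _leiden_backend}


def register_backend(name: str, fn) -> None:
    """Register an alternative clustering backend (values, spec) -> labels."""
    _BACKENDS[name] = fn


def cluster_events(events: EventTable | pd.DataFrame, spec: ClusteringSpec) -> np.ndarray:
    """Integer cluster labels from kNN-graph community detection.

    Deterministic under a fixed seed and backend.
    """
    data = events.data if isinstance(events, EventTable) else events
    if isinstance(events, EventTable) and not events.transformed:
        raise ConfigurationError("cluster on arcsinh-transformed events")
    missing = [m for m in spec.markers if m not in data.columns]
    if missing:
        raise ConfigurationError(f"panel markers missing from events: {missing}")
    if len(data) <= spec.n_neighbors:
        raise ConfigurationError(
            f"{len(data)} events is not enough for {spec.n_neighbors} neighbors"
        )
    values = data[list(spec.markers)].to_numpy(dtype=float)
    backend = _BACKENDS.get(spec.backend)
    if backend is None:
        raise ConfigurationError(f"unknown clustering backend {spec.backend!r}")
    return backend(values, spec)


@dataclass
class ClusterProfile:
    """Per-cluster marker medians (arcsinh scale) and a scaled display matrix."""

    medians: pd.DataFrame  # clusters × markers
    counts: pd.Series
    scaled: pd.DataFrame
    degenerate_markers: tuple[str, ...] = field(default_factory=tuple)


def min_max_scale(medians: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """(x − min)/(max − min) per marker across clusters; a constant marker is
    defined as 0 and flagged degenerate."""
    lo = medians.min(axis=0)
    hi = medians.max(axis=0)
    span = hi - lo
    degenerate = tuple(span.index[span == 0])
    span = span.replace(0, 1.0)
    scaled = (medians - lo) / span
    scaled[list(degenerate)] = 0.0
    return scaled, degenerate


def compute_cluster_profiles(
    events: EventTable | pd.DataFrame,
    labels: np.ndarray,
    markers: list[str] | None = None,
    scaling: str = "min-max",
) -> ClusterProfile:
    """Per-cluster per-marker medians with min-max scaled display values."""
    data = events.data if isinstance(events, EventTable) else events
    if markers is not None:
        data = data[list(markers)]
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ConfigurationError("labels do not cover all events")
    grouped = data.groupby(labels)
    counts = grouped.size()
    if (counts == 0).any():
        raise ConfigurationError("empty cluster")
    medians = grouped.median()
    if scaling == "min-max":
        scaled, degenerate = min_max_scale(medians)
    elif scaling == "none":
        scaled, degenerate = medians.copy(), ()
    else:
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    return ClusterProfile(medians=medians, counts=counts, scaled=scaled,
                          degenerate_markers=degenerate)


@dataclass
class MetaclusterMap:
    """Cluster → metacluster label mapping plus replayable rule records."""

    mapping: dict[int, str]
    excluded: dict[int, str] = field(default_factory=dict)
    rules: list[dict] = field(default_factory=list)

    def apply(self, labels: np.ndarray) -> np.ndarray:
        """Translate fine cluster labels into metacluster labels
        (excluded clusters become "excluded")."""
        out = np.empty(len(labels), dtype=object)
        for i, lab in enumerate(labels):
            lab = int(lab)
            if lab in self.excluded:
                out[i] = "excluded"
            else:
                out[i] = self.mapping.get(lab, f"MC{lab}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rules)


def metacluster(
    profiles: ClusterProfile,
    metric: str = "euclidean",
    linkage_method: str = "average",
    cut_height: float = 1.0,
    manual_rules: list[dict] | None = None,
    exclude_high: float = 0.9,
    exclude_low: float = 0.1,
) -> MetaclusterMap:
    """Merge fine clusters into metaclusters by profile similarity.

    Exclusion rules run first: a cluster whose scaled medians are all above
    ``exclude_high`` is dropped as doublet-like (broad expression of every
    lineage marker); one with all scaled medians below ``exclude_low`` is
    dropped as all-negative. Remaining cluster median profiles are
    agglomeratively linked (``metric`` = "euclidean" or "correlation") and cut
    at ``cut_height``; then manual rules are applied in order:
    ``{"rule": "merge", "clusters": [...], "label": ...}``,
    ``{"rule": "exclude", "cluster": id, "reason": ...}``,
    ``{"rule": "label", "cluster": id, "label": ...}``.
    """
    if len(profiles.medians) == 0:
        raise ConfigurationError("no cluster profiles")
    rules: list[dict] = []
    scaled = profiles.scaled
    excluded: dict[int, str] = {}
    for cid in scaled.index:
        row = scaled.loc[cid]
        if (row > exclude_high).all():
            excluded[int(cid)] = "doublet-like (broad positive)"
        elif (row < exclude_low).all():
            excluded[int(cid)] = "all-negative"
    for cid, reason in excluded.items():
        rules.append({"rule": "exclude", "cluster": cid, "reason": reason})

    kept = [int(c) for c in profiles.medians.index if int(c) not in excluded]
    mapping: dict[int, str] = {}
    if len(kept) == 1:
        mapping[kept[0]] = "MC1"
    elif kept:
        prof = profiles.medians.loc[kept].to_numpy(dtype=float)
        dist = pdist(prof, metric=metric)
        dist = np.nan_to_num(dist, nan=0.0)
        tree = linkage(dist, method=linkage_method)
        groups = fcluster(tree, t=cut_height, criterion="distance")
        for cid, g in zip(kept, groups):
            mapping[cid] = f"MC{int(g)}"
        for g in np.unique(groups):
            members = [c for c, gg in zip(kept, groups) if gg == g]
            rules.append({"rule": "merge", "clusters": members, "label": f"MC{int(g)}"})

    for rule in manual_rules or []:
        kind = rule.get("rule")
        if kind == "merge":
            label = rule["label"]
            for cid in rule["clusters"]:
                cid = int(cid)
                if cid in mapping and any(
                    r.get("rule") == "merge" and cid in r.get("clusters", [])
                    and r["label"] != label
                    for r in (manual_rules or []) if r is not rule
                ):
                    raise ConfigurationError(
                        f"conflicting manual rules: cluster {cid} merged into two labels"
                    )
                mapping[cid] = label
                excluded.pop(cid, None)
        elif kind == "exclude":
            cid = int(rule["cluster"])
            excluded[cid] = rule.get("reason", "manual")
            mapping.pop(cid, None)
        elif kind == "label":
            mapping[int(rule["cluster"])] = rule["label"]
        else:
            raise ConfigurationError(f"unknown manual rule {rule!r}")
        rules.append(dict(rule))

    return MetaclusterMap(mapping=mapping, excluded=excluded, rules=rules)


def split_by_threshold(
    events: EventTable | pd.DataFrame,
    labels: np.ndarray,
    cluster: int | str,
    marker: str,
    cutoff: float = 1.0,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> pd.Series:
    """Partition one cluster at a marker cutoff (≥ cutoff ⇒ positive branch).

    The default cutoff of 1.0 matches the FcεRI rule splitting a mixed
    basophil/eosinophil cluster: FcεRI-positive cells are basophils.
    """
    data = events.data if isinstance(events, EventTable) else events
    labels = np.asarray(labels)
    out = pd.Series(labels.astype(object), index=data.index, name="label")
    in_cluster = labels == cluster
    values = data[marker].to_numpy()
    out[in_cluster & (values >= cutoff)] = positive_label
    out[in_cluster & (values < cutoff)] = negative_label
    return out


def classify_monocytes_canonical(
    ly6c_values: np.ndarray | pd.Series,
    classical_cut: float = 4.5,
    intermediate_cut: float = 3.0,
) -> pd.Series:
    """Canonical monocyte classes from Ly-6C (arcsinh, cofactor 5):
    ≥ 4.5 classical; ≥ 3 and < 4.5 intermediate; < 3 non-classical.
    Both boundaries are inclusive on the higher class."""
    v = np.asarray(ly6c_values, dtype=float)
    out = np.where(
        v >= classical_cut, "classical",
        np.where(v >= intermediate_cut, "intermediate", "non-classical"),
    )
    return pd.Series(out, name="monocyte_class")
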