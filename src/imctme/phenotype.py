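"""Per-cell marker quantification, z-scoring, and multi-round clustering.

Quantification averages each marker's raw pixel intensity over every cell's
mask.  Marker intensities are then z-scored *within each image*: for marker
j and cell k of image m, ``z = (I - mu_j^m) / sigma_j^m`` with the mean and
population standard deviation taken over all cells of that image, so
expression is relative to the cells on the same slide.

Clustering follows the PhenoGraph construction: a k-nearest-neighbor graph
on z-scored marker vectors (Euclidean), edges re-weighted by the Jaccard
overlap of the endpoints' neighbor sets, then Louvain community detection
with a fixed seed.  A multi-round protocol first under-clusters to separate
the major populations (large k), keeps clusters matching a rule on their
median marker z-scores, pools the rest, and re-clusters the pool with a
round-specific marker list and k — repeating as configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from sklearn.neighbors import NearestNeighbors

from .stacks import ImageStack, LabelMask

__all__ = [
    "quantify_cells",
    "zscore_normalize",
    "cluster_round",
    "ClusteringRound",
    "ClusteringProtocol",
    "run_protocol",
    "annotate_subtypes",
    "protocol_from_dict",
]


def quantify_cells(mask: LabelMask, stack: ImageStack, sample_id: str = "sample") -> pd.DataFrame:
    """One row per mask label: centroid (um), area (px), raw marker means.

    The centroid is the unweighted mean of member-pixel coordinates; x is
    the column axis and y the row axis, origin at the top-left corner.
    """
    if mask.shape != stack.shape:
        raise ValueError("mask and stack spatial shapes differ")
    ids = mask.cell_ids
    cols = {"sample_id": sample_id, "cell_id": ids}
    if ids.size == 0:
        empty = {"sample_id": [], "cell_id": [], "x_um": [], "y_um": [], "area_px": []}
        empty.update({f"raw_{m}": [] for m in stack.markers})
        return pd.DataFrame(empty)
    centroids = ndi.center_of_mass(np.ones(mask.shape), labels=mask.labels, index=ids)
    centroids = np.asarray(centroids)  # (n, 2) as (row, col)
    areas = ndi.sum_labels(np.ones(mask.shape), labels=mask.labels, index=ids)
    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": ids,
            "x_um": centroids[:, 1] * stack.pixel_size_um,
            "y_um": centroids[:, 0] * stack.pixel_size_um,
            "area_px": areas.astype(int),
        }
    )
    for ci, marker in enumerate(stack.markers):
        table[f"raw_{marker}"] = ndi.mean(stack.pixels[ci], labels=mask.labels, index=ids)
    return table


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``z_<marker>`` columns: per-sample, per-marker z-scores.

    Uses the population standard deviation (divisor N) over the cells of
    each sample.  Markers constant within a sample get z = 0 so they carry
    no weight in marker-space distances.
    """
    if table.empty:
        raise ValueError("cannot z-score an empty cell table")
    table = table.copy()
    raw_cols = [c for c in table.columns if c.startswith("raw_")]
    for col in raw_cols:
        zcol = "z_" + col[len("raw_"):]
        grouped = table.groupby("sample_id")[col]
        mu = grouped.transform("mean")
        sigma = grouped.transform(lambda x: x.std(ddof=0))
        z = (table[col] - mu) / sigma
        table[zcol] = z.where(sigma > 0, 0.0).fillna(0.0)
    return table


def _phenograph_graph(X: np.ndarray, k: int) -> nx.Graph:
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row[1:]) for row in idx]  # drop self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in neighbor_sets[i]:
            j = int(j)
            if g.has_edge(i, j):
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            wt = inter / union if union else 0.0
            if wt > 0:
                g.add_edge(i, j, weight=wt)
    return g


def cluster_round(
    table: pd.DataFrame, markers: Sequence[str], k: int, seed: int = 0
) -> pd.Series:
    """PhenoGraph-style clustering of cells in z-scored marker space.

    Builds a Jaccard-weighted kNN graph and runs Louvain with a fixed seed.
    Cells are canonically ordered by (sample_id, cell_id) before graph
    construction so the result is invariant to input row order.
    Returns integer cluster labels indexed like ``table``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(table) < k + 1:
        raise ValueError(f"need more than k+1 = {k + 1} cells, got {len(table)}")
    zcols = [f"z_{m}" for m in markers]
    missing = [c for c in zcols if c not in table.columns]
    if missing:
        raise KeyError(f"markers without z-score columns: {missing}")
    order = table.sort_values(["sample_id", "cell_id"]).index
    X = table.loc[order, zcols].to_numpy(dtype=float)
    g = _phenograph_graph(X, k)
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: min(c))
    labels = np.empty(len(order), dtype=int)
    for ci, comm in enumerate(communities):
        labels[list(comm)] = ci
    return pd.Series(labels, index=order).reindex(table.index)


@dataclass
class ClusteringRound:
    """One protocol round: which cells, which markers, which k.

    ``subset`` is ``"all"`` for the first round or the name of a pool
    created by an earlier round's rule.  ``pool_rules`` assign whole
    clusters (by their median marker z-scores) to named pools for later
    rounds; clusters matching no rule are kept as final.
    Each rule is ``{"pool": name, "when": [[marker, op, value], ...]}``
    with op in {">", ">=", "<", "<="} and all conditions required.
    """

    markers: list[str]
    k: int
    subset: str = "all"
    pool_rules: list[dict] = field(default_factory=list)


@dataclass
class ClusteringProtocol:
    rounds: list[ClusteringRound]
    seed: int = 0


_OPS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


def _rule_matches(medians: pd.Series, conditions: list) -> bool:
    for marker, op, value in conditions:
        if op not in _OPS:
            raise ValueError(f"unknown comparison {op!r}")
        if not _OPS[op](medians[f"z_{marker}"], value):
            return False
    return True


def run_protocol(table: pd.DataFrame, protocol: ClusteringProtocol) -> pd.DataFrame:
    """Execute a multi-round clustering protocol.

    Adds ``cluster_r<i>`` columns per executed round and a final
    ``subtype_cluster`` column naming each cell's terminal cluster as
    ``r<round>_c<cluster>``.  Rounds whose subset is empty (or too small
    for their k) are skipped with a warning; their cells keep the pool
    name as terminal label.  No cells are ever added or dropped.
    """
    table = table.copy()
    table["subtype_cluster"] = pd.Series(pd.NA, index=table.index, dtype="object")
    pools: dict[str, pd.Index] = {"all": table.index}
    for ri, rnd in enumerate(protocol.rounds, start=1):
        if rnd.subset not in pools:
            warnings.warn(f"round {ri}: subset {rnd.subset!r} was never populated; skipped")
            continue
        subset_idx = pools[rnd.subset]
        if len(subset_idx) == 0:
            warnings.warn(f"round {ri}: subset {rnd.subset!r} is empty; skipped")
            continue
        if len(subset_idx) < rnd.k + 1:
            warnings.warn(
                f"round {ri}: subset {rnd.subset!r} has {len(subset_idx)} cells, "
                f"fewer than k+1 = {rnd.k + 1}; skipped"
            )
            continue
        sub = table.loc[subset_idx]
        labels = cluster_round(sub, rnd.markers, rnd.k, seed=protocol.seed + ri)
        table.loc[subset_idx, f"cluster_r{ri}"] = labels
        zcols = [c for c in table.columns if c.startswith("z_")]
        for cluster_id in sorted(labels.unique()):
            members = subset_idx[labels == cluster_id]
            medians = table.loc[members, zcols].median()
            pooled = False
            for rule in rnd.pool_rules:
                if _rule_matches(medians, rule["when"]):
                    pool_name = rule["pool"]
                    pools.setdefault(pool_name, pd.Index([], dtype=subset_idx.dtype))
                    pools[pool_name] = pools[pool_name].append(members)
                    table.loc[members, "subtype_cluster"] = pool_name  # provisional
                    pooled = True
                    break
            if not pooled:
                table.loc[members, "subtype_cluster"] = f"r{ri}_c{cluster_id}"
    return table


def annotate_subtypes(table: pd.DataFrame, rules: Sequence[Mapping]) -> pd.DataFrame:
    """Name terminal clusters by threshold rules on their median z-scores.

    Each rule is ``{"name": subtype, "when": [[marker, op, value], ...]}``;
    rules are tried in order and the first match wins.  Every terminal
    cluster must match some rule — unnamed clusters raise, with their
    median z-scores in the message.  A final catch-all rule (empty
    ``when``) is allowed.
    """
    table = table.copy()
    zcols = [c for c in table.columns if c.startswith("z_")]
    table["subtype"] = pd.Series(pd.NA, index=table.index, dtype="object")
    for cluster_name, members in table.groupby("subtype_cluster").groups.items():
        medians = table.loc[members, zcols].median()
        name = None
        for rule in rules:
            if _rule_matches(medians, rule.get("when", [])):
                name = rule["name"]
                break
        if name is None:
            summary = ", ".join(f"{c}={medians[c]:.2f}" for c in zcols)
            raise ValueError(
                f"cluster {cluster_name!r} matches no annotation rule; medians: {summary}"
            )
        table.loc[members, "subtype"] = name
    return table


def protocol_from_dict(cfg: Mapping) -> ClusteringProtocol:
    """Build a protocol from a plain dict (e.g. parsed YAML).

    Expected keys: ``seed`` (optional) and ``rounds``, a list of
    ``{markers, k, subset?, pool_rules?}`` entries.
    """
    rounds = [
        ClusteringRound(
            markers=list(r["markers"]),
            k=int(r["k"]),
            subset=r.get("subset", "all"),
            pool_rules=[
                {"pool": pr["pool"], "when": [list(c) for c in pr["when"]]}
                for pr in r.get("pool_rules", [])
            ],
        )
        for r in cfg["rounds"]
    ]
    return ClusteringProtocol(rounds=rounds, seed=int(cfg.get("seed", 0)))
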