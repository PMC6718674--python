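"""Weighted co-methylation / co-expression networks and differential connectivity.

Networks are built separately in the depressed and non-depressed twin
groups from nominally associated features (raw p below a cutoff; region
nodes carry the mean beta of their probes per sample). The adjacency is
unsigned WGCNA-style, |Pearson r|^beta with the soft power chosen as the
smallest integer in 1..12 whose degree distribution satisfies a scale-free
fit R^2 >= 0.8 (fallback 6). Module detection is average-linkage
hierarchical clustering of topological-overlap dissimilarity with a static
tree cut; hubs maximize mean adjacency to their module (module membership).

Differential connectivity of a node set compares mean binary degree
(adjacency >= edge cutoff) between the groups; its null distribution flips,
independently within each twin pair, which member counts as depressed, and
rebuilds both group networks per permutation, respecting the paired design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from cotwin.errors import ValidationError
from cotwin.io import log

__all__ = [
    "GroupNetwork",
    "select_nominal_features",
    "region_node_matrix",
    "pick_soft_power",
    "build_group_network",
    "topological_overlap",
    "detect_modules",
    "differential_connectivity",
    "differential_connectivity_scan",
]


@dataclass
class GroupNetwork:
    """An unsigned weighted network for one twin group."""

    group: str
    nodes: list[str]
    power: int
    adjacency: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    tom: np.ndarray  # topological-overlap similarity
    edge_cutoff: float

    @property
    def degree(self) -> np.ndarray:
        """Binary degree at the stated adjacency cutoff."""
        return (self.adjacency >= self.edge_cutoff).sum(axis=1)


def select_nominal_features(results: pd.DataFrame, p_max: float = 0.001) -> list[str]:
    """Feature ids with raw p strictly below ``p_max``."""
    hit = results[results["p"] < p_max]
    if hit.empty:
        log.warning("no features at p < %g; downstream network will be empty", p_max)
    return list(hit["feature_id"])


def region_node_matrix(
    regions: pd.DataFrame, betas: pd.DataFrame, sample_ids: list[str]
) -> pd.DataFrame:
    """Region-level node values: mean beta of the region's probes per sample."""
    rows = {}
    for _, r in regions.iterrows():
        name = f"{r['chrom']}:{r['start']}-{r['end']}"
        rows[name] = betas.loc[r["probe_ids"], sample_ids].mean(axis=0)
    return pd.DataFrame(rows).T


def _adjacency(values: np.ndarray, power: int) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)  # constant nodes: zero row
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k for the weighted connectivity distribution."""
    k = adj.sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return 0.0
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2) if r < 0 else 0.0  # scale-free fit requires a negative slope


def pick_soft_power(values: np.ndarray, r2_target: float = 0.8, fallback: int = 6) -> int:
    """Smallest power in 1..12 reaching the scale-free fit target, else fallback."""
    for power in range(1, 13):
        if _scale_free_r2(_adjacency(values, power)) >= r2_target:
            return power
    return fallback


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap similarity of a weighted adjacency."""
    k = adj.sum(axis=1)
    shared = adj @ adj
    num = shared + adj
    den = np.minimum.outer(k, k) + 1.0 - adj
    tom = num / np.maximum(den, 1e-300)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_group_network(
    node_values: pd.DataFrame,
    group: str = "",
    power: int | None = None,
    edge_cutoff: float = 0.1,
) -> GroupNetwork:
    """Build the unsigned weighted network for one group's node matrix
    (nodes x samples of that group)."""
    values = node_values.to_numpy(float)
    if values.shape[0] < 3:
        raise ValidationError("need at least 3 nodes to build a network")
    if power is None:
        power = pick_soft_power(values)
        log.info("group %s: soft power %d", group or "?", power)
    adj = _adjacency(values, power)
    return GroupNetwork(
        group=group,
        nodes=list(node_values.index),
        power=power,
        adjacency=adj,
        tom=topological_overlap(adj),
        edge_cutoff=edge_cutoff,
    )


def detect_modules(network: GroupNetwork, min_size: int = 50, cut_height: float = 0.99) -> pd.DataFrame:
    """Modules by average-linkage clustering of TOM dissimilarity.

    The tree is cut statically at ``cut_height`` (default 0.99, the usual
    static-cut level for TOM dendrograms, whose dissimilarities concentrate
    near 1); clusters smaller than ``min_size`` are dissolved to
    unassigned. The hub is the member with the highest mean adjacency to
    its module; ties break by node id order.
    """
    dissim = 1.0 - network.tom
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    labels = fcluster(link, t=cut_height, criterion="distance")
    rows = []
    module_id = 0
    for lab in sorted(set(labels)):
        members = [network.nodes[i] for i in np.where(labels == lab)[0]]
        if len(members) < min_size:
            continue
        idx = np.where(labels == lab)[0]
        membership = network.adjacency[np.ix_(idx, idx)].mean(axis=1)
        order = np.lexsort((np.array(members), -membership))
        module_id += 1
        rows.append(
            {
                "module_id": f"M{module_id}",
                "n_nodes": len(members),
                "members": members,
                "hub": members[int(order[0])],
            }
        )
    if not rows:
        log.warning("no module reached min size %d", min_size)
    return pd.DataFrame(rows, columns=["module_id", "n_nodes", "members", "hub"])


def _group_matrices(
    node_values_dep: pd.DataFrame, node_values_ctrl: pd.DataFrame, flips: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Swap, per pair, which column counts as depressed according to flips."""
    dep = node_values_dep.to_numpy(float)
    ctrl = node_values_ctrl.to_numpy(float)
    a = np.where(flips[None, :], ctrl, dep)
    b = np.where(flips[None, :], dep, ctrl)
    return a, b


def differential_connectivity(
    node_sets: dict[str, list[str]] | list[str],
    node_values_dep: pd.DataFrame,
    node_values_ctrl: pd.DataFrame,
    B_perm: int = 200,
    edge_cutoff: float = 0.1,
    seed: int = 0,
    power: int | None = None,
) -> pd.DataFrame:
    """Permutation test of group difference in mean binary node-set degree.

    ``node_values_dep`` and ``node_values_ctrl`` are nodes x pairs matrices
    with aligned columns (one per twin pair). The observed statistic is
    mean degree of the set in the depressed-group network minus the
    non-depressed-group network; the null flips pair labels at random
    (each pair independently) and rebuilds both networks. Multiple node
    sets share the same permutation draws. Two-sided p =
    (1 + #{|null| >= |observed|}) / (B_perm + 1).
    """
    single = not isinstance(node_sets, dict)
    sets = {"set": list(node_sets)} if single else {k: list(v) for k, v in node_sets.items()}
    nodes = list(node_values_dep.index)
    if list(node_values_ctrl.index) != nodes:
        raise ValidationError("group matrices must share node order")
    for name, members in sets.items():
        if not members:
            raise ValidationError(f"node set {name!r} is empty")
        missing = set(members) - set(nodes)
        if missing:
            raise ValidationError(f"node set {name!r} has unknown nodes: {sorted(missing)[:3]}")
    if node_values_dep.shape[1] != node_values_ctrl.shape[1]:
        raise ValidationError("paired design requires equal group sample counts")

    node_pos = {n: i for i, n in enumerate(nodes)}
    set_idx = {name: np.array([node_pos[m] for m in members]) for name, members in sets.items()}

    def stats_for(flips: np.ndarray) -> dict[str, tuple[float, float, float]]:
        a, b = _group_matrices(node_values_dep, node_values_ctrl, flips)
        net_a = build_group_network(pd.DataFrame(a, index=nodes), "A", power=power, edge_cutoff=edge_cutoff)
        net_b = build_group_network(pd.DataFrame(b, index=nodes), "B", power=power, edge_cutoff=edge_cutoff)
        deg_a, deg_b = net_a.degree, net_b.degree
        return {
            name: (float(deg_a[idx].mean()), float(deg_b[idx].mean()))
            for name, idx in set_idx.items()
        }

    n_pairs = node_values_dep.shape[1]
    rng = np.random.default_rng(seed)
    observed = stats_for(np.zeros(n_pairs, dtype=bool))
    exceed = {name: 0 for name in sets}
    for _ in range(B_perm):
        flips = rng.random(n_pairs) < 0.5
        null = stats_for(flips)
        for name in sets:
            obs_stat = observed[name][0] - observed[name][1]
            null_stat = null[name][0] - null[name][1]
            if abs(null_stat) >= abs(obs_stat) - 1e-12:
                exceed[name] += 1
    rows = [
        {
            "node_set": name,
            "mean_degree_depressed": observed[name][0],
            "mean_degree_nondepressed": observed[name][1],
            "p": (1 + exceed[name]) / (B_perm + 1),
        }
        for name in sets
    ]
    return pd.DataFrame(rows)


def differential_connectivity_scan(
    node_sets: dict[str, list[str]],
    node_values_dep: pd.DataFrame,
    node_values_ctrl: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Alias of :func:`differential_connectivity` for multiple node sets."""
    return differential_connectivity(node_sets, node_values_dep, node_values_ctrl, **kwargs)
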