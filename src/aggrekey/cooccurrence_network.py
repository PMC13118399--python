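"""Multi-kingdom co-occurrence network and module detection.

The bacterial, non-AMF-fungal and AMF genus tables are pooled (each on its
own compositional scale — marker sets are not quantitatively comparable)
and all pairwise Spearman correlations, within and across kingdoms, are
tested jointly.  Edges are kept when |rho| exceeds the configured threshold
and the Benjamini-Hochberg-adjusted p-value, computed once over the whole
pair set, is below the edge alpha.  Isolated genera are dropped from the
graph.

Modules are detected with random-walk (walktrap) community detection on
|rho| edge weights, cut at maximum modularity, and labelled by descending
size with roman numerals (I, II, ...).  "Major" modules hold strictly more
than a configured fraction (default 10%) of the drawn graph's nodes.  Each
module's per-sample accumulated relative abundance, z-scored across
samples, is the module abundance profile used by keystone selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .community_ecology import AbundanceTable
from .group_stats import bh_adjust


def _roman(k: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
                (100, "C"), (90, "XC"), (50, "L"), (40, "XL"), (10, "X"),
                (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for val, sym in numerals:
        while k >= val:
            out += sym
            k -= val
    return out


@dataclass
class CoocNetwork:
    """Filtered correlation graph over pooled dominant genera."""

    nodes: pd.DataFrame        # index genus; columns kingdom, degree
    edges: pd.DataFrame        # source, target, rho, p_adj, sign
    abundances: pd.DataFrame   # genus x sample relative abundances (pooled)
    n_tested_pairs: int
    modules: pd.Series | None = None       # genus -> module label
    major: tuple[str, ...] | None = None   # labels of major modules

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_density(self) -> float:
        """Retained edges over all tested pairs."""
        return len(self.edges) / self.n_tested_pairs


def build_network(tables: list[AbundanceTable], config) -> CoocNetwork:
    """All-pairs Spearman network over the pooled genus set.

    ``tables`` must be relative-abundance tables (dominant filter already
    applied) sharing an identical sample set.
    """
    if not tables:
        raise ValueError("no abundance tables given")
    samples = tables[0].samples
    for t in tables[1:]:
        if t.samples != samples:
            raise ValueError("tables must share an identical sample set")
    if len(samples) < 4:
        raise ValueError("need >= 4 samples for stable correlations")

    pooled = pd.concat([t.data for t in tables], axis=0)
    if pooled.index.has_duplicates:
        dups = pooled.index[pooled.index.duplicated()].tolist()
        raise ValueError(f"duplicate genus ids across kingdoms: {dups}")
    kingdom = pd.Series(
        {g: t.kingdom for t in tables for g in t.genera}, name="kingdom")

    x = pooled.to_numpy().T  # samples x genera
    m = x.shape[1]
    rho, pval = stats.spearmanr(x)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(m, 1)
    p_adj_flat = bh_adjust(pval[iu])

    keep = (np.abs(rho[iu]) > config.correlation_threshold) & \
           (p_adj_flat < config.edge_alpha)
    genera = pooled.index.to_numpy()
    src, dst = genera[iu[0][keep]], genera[iu[1][keep]]
    rho_kept = rho[iu][keep]
    edges = pd.DataFrame({
        "source": src, "target": dst,
        "rho": rho_kept, "p_adj": p_adj_flat[keep],
        "sign": np.where(rho_kept >= 0, "+", "-")})
    edges = edges.sort_values(["source", "target"]).reset_index(drop=True)

    degree = pd.Series(0, index=pooled.index, dtype=int)
    for col in ("source", "target"):
        degree = degree.add(edges[col].value_counts(), fill_value=0)
    connected = degree[degree > 0].index
    nodes = pd.DataFrame({"kingdom": kingdom.loc[connected],
                          "degree": degree.loc[connected].astype(int)})
    nodes.index.name = "genus"
    return CoocNetwork(nodes=nodes, edges=edges,
                       abundances=pooled.loc[connected],
                       n_tested_pairs=len(iu[0]))


def detect_modules(network: CoocNetwork, walk_length: int = 4) -> pd.Series:
    """Random-walk community detection, cut at maximum modularity.

    Deterministic for a fixed node ordering.  Returns genus -> module label,
    labels ordered by descending module size (ties by first member), and
    stores the partition on the network.
    """
    if len(network.edges) == 0:
        raise ValueError("network has no edges")
    genera = list(network.nodes.index)
    index = {g: i for i, g in enumerate(genera)}
    es = [(index[s], index[t]) for s, t in
          zip(network.edges["source"], network.edges["target"])]
    g = ig.Graph(n=len(genera), edges=es)
    g.es["weight"] = np.abs(network.edges["rho"].to_numpy()).tolist()
    dendro = g.community_walktrap(weights="weight", steps=walk_length)
    clustering = dendro.as_clustering()
    membership = np.asarray(clustering.membership)

    sizes = pd.Series(membership).value_counts()
    order = sorted(sizes.index,
                   key=lambda c: (-sizes[c], int(np.argmax(membership == c))))
    relabel = {c: _roman(i + 1) for i, c in enumerate(order)}
    modules = pd.Series([relabel[c] for c in membership],
                        index=pd.Index(genera, name="genus"), name="module")
    network.modules = modules
    return modules


def major_modules(network: CoocNetwork,
                  node_fraction: float = 0.10) -> tuple[str, ...]:
    """Module labels holding strictly more than ``node_fraction`` of the
    drawn graph's nodes (isolated genera were never part of the graph)."""
    if network.modules is None:
        raise ValueError("modules not detected yet")
    sizes = network.modules.value_counts()
    threshold = node_fraction * network.n_nodes
    major = tuple(sorted(sizes.index[sizes > threshold],
                         key=lambda lab: -sizes[lab]))
    network.major = major
    return major


def write_graphml(network: CoocNetwork, path) -> None:
    """Export the filtered graph (kingdom, module, edge rho/sign) as
    GraphML for external viewers."""
    genera = list(network.nodes.index)
    index = {g: i for i, g in enumerate(genera)}
    g = ig.Graph(
        n=len(genera),
        edges=[(index[s], index[t]) for s, t in
               zip(network.edges["source"], network.edges["target"])])
    g.vs["name"] = genera
    g.vs["kingdom"] = list(network.nodes["kingdom"])
    if network.modules is not None:
        g.vs["module"] = [network.modules.get(x, "") for x in genera]
    g.es["rho"] = network.edges["rho"].tolist()
    g.es["sign"] = network.edges["sign"].tolist()
    g.write_graphml(str(path))


def module_abundance(network: CoocNetwork,
                     modules: pd.Series | None = None) -> pd.DataFrame:
    """Per-module, per-sample accumulated relative abundance, z-scored.

    Member relative abundances (each on its kingdom's own compositional
    scale) are summed per sample, then each module's vector is centered and
    scaled to unit SD across samples.
    """
    modules = modules if modules is not None else network.modules
    if modules is None:
        raise ValueError("modules not detected yet")
    rows = {}
    for label in modules.unique():
        members = modules.index[modules == label]
        missing = [g for g in members if g not in network.abundances.index]
        if missing:
            raise ValueError(f"module {label} members missing from tables: {missing}")
        acc = network.abundances.loc[members].sum(axis=0)
        sd = acc.std(ddof=1)
        if sd == 0:
            raise ValueError(f"module {label} has constant accumulated abundance")
        rows[label] = (acc - acc.mean()) / sd
    out = pd.DataFrame(rows).T
    out.index.name = "module"
    return out
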