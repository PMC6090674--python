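"""Hub identification, stage-network comparison and gene-set enrichment.

Hubs are the top 10% of RNA nodes by degree over competing edges (miRNA
nodes and regulatory edges are excluded from degree by default, matching
the "hub ceRNA" notion; an all-edges mode is available). Enrichment of a
node set for an annotated gene list is tested both by randomization
(uniform resampling of same-size sets from the background, add-one p-value
estimator) and by the upper-tail hypergeometric test with Benjamini-
Hochberg FDR across tested sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cerna import CeRNANetwork


@dataclass
class HubReport:
    stage_label: str
    degree: pd.Series
    hub_set: set[str]
    hub_fraction: float
    tie_policy: str = "expand-at-cutoff-degree"


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    expected: float
    p_perm: float | None
    p_hyper: float
    fdr: float | None
    n_perm: int | None
    seed: int | None


def find_hubs(net: CeRNANetwork, fraction: float = 0.10, degree_mode: str = "competing") -> HubReport:
    """Top ``ceil(fraction * n)`` RNA nodes by degree, ties at the cutoff expanded.

    ``degree_mode="competing"`` counts competing edges among RNA nodes only;
    ``"all-edges"`` counts regulatory edges too (still ranking RNA nodes).
    """
    rna = sorted(net.rna_nodes)
    if not rna:
        raise ValueError("empty network")
    if degree_mode == "competing":
        deg = {
            n: sum(1 for e in net.competing_edges if n in e)
            for n in rna
        }
    elif degree_mode == "all-edges":
        deg = {n: net.graph.degree(n) for n in rna}
    else:
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    degree = pd.Series(deg).sort_index()
    n_select = math.ceil(fraction * len(rna))
    ranked = sorted(rna, key=lambda n: (-degree[n], n))
    cutoff_degree = degree[ranked[n_select - 1]]
    hubs = {n for n in rna if degree[n] > cutoff_degree}
    hubs |= {n for n in rna if degree[n] == cutoff_degree}
    return HubReport(stage_label=net.stage_label, degree=degree, hub_set=hubs, hub_fraction=fraction)


def compare_hubs(growth: HubReport, senescence: HubReport) -> tuple[set, set, set]:
    """(common, growth-specific, senescence-specific) hub sets."""
    common = growth.hub_set & senescence.hub_set
    return common, growth.hub_set - common, senescence.hub_set - common


def extract_subnetwork(net: CeRNANetwork, node_set) -> CeRNANetwork:
    """Induced subgraph on ``node_set`` over competing edges, plus regulatory
    edges from miRNAs that stay shared by at least one retained pair."""
    node_set = set(node_set)
    if not node_set:
        raise ValueError("empty node set")
    import networkx as nx

    g = nx.Graph(stage=net.stage_label)
    for u, v, d in net.graph.edges(data=True):
        if d.get("edge_type") == "competing" and u in node_set and v in node_set:
            for n in (u, v):
                g.add_node(n, **net.graph.nodes[n])
            g.add_edge(u, v, **d)
    retained_rna = {n for n, d in g.nodes(data=True) if d.get("kind") == "rna"}
    for u, v, d in net.graph.edges(data=True):
        if d.get("edge_type") != "regulatory":
            continue
        mirna, rna = (u, v) if net.graph.nodes[u].get("kind") == "mirna" else (v, u)
        if rna not in retained_rna:
            continue
        # keep the miRNA only if it is shared by some retained competing pair
        partners = {
            (set(e) - {rna}).pop()
            for e in net.competing_edges
            if rna in e and (set(e) - {rna}).pop() in retained_rna
        }
        shared = any(
            net.graph.has_edge(mirna, p) for p in partners
        )
        if shared:
            g.add_node(mirna, **net.graph.nodes[mirna])
            g.add_edge(mirna, rna, **d)
    return CeRNANetwork(graph=g, stage_label=net.stage_label)


def randomization_enrichment(
    query: set, annotated: set, background: set,
    n_perm: int = 10_000, seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment of ``query`` for ``annotated`` within ``background``.

    Draws ``n_perm`` uniform subsets of size ``|query|`` from the background
    and reports p = (1 + #{overlap >= observed}) / (1 + n_perm), the add-one
    estimator, so p is never exactly zero. Deterministic given ``seed``.
    """
    query, annotated, background = set(query), set(annotated), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not annotated <= background:
        raise ValueError("annotated set must be a subset of the background")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = len(query & annotated)
    bg = sorted(background)
    is_annot = np.array([b in annotated for b in bg])
    q = len(query)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7) // max(1, len(bg))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, len(bg)))
        picks = np.argpartition(keys, q - 1, axis=1)[:, :q]
        overlaps = is_annot[picks].sum(axis=1)
        exceed += int((overlaps >= observed).sum())
        done += m
    p_perm = (1 + exceed) / (1 + n_perm)
    expected = q * len(annotated) / len(bg)
    p_hyper = float(stats.hypergeom.sf(observed - 1, len(bg), len(annotated), q))
    return EnrichmentResult(
        set_name="randomization", overlap=observed, expected=expected,
        p_perm=p_perm, p_hyper=p_hyper, fdr=None, n_perm=n_perm, seed=seed,
    )


def hypergeom_set_enrichment(
    queries: list[tuple[str, set]],
    annotated_sets: dict[str, set],
    background: set,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH FDR across tested sets.

    Each (query, annotated set) combination yields one test; the BH
    adjustment runs over all of them. Returns a tidy table with
    ``significant`` = fdr < fdr_max.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    rows = []
    for qname, query in queries:
        query = set(query) & background
        for aname, annotated in annotated_sets.items():
            annotated = set(annotated) & background
            overlap = len(query & annotated)
            expected = len(query) * len(annotated) / len(background)
            p = float(stats.hypergeom.sf(overlap - 1, len(background), len(annotated), len(query)))
            rows.append((qname, aname, len(query), len(annotated), overlap, expected, p))
    df = pd.DataFrame(rows, columns=[
        "query", "set_name", "query_size", "set_size", "overlap", "expected", "p_hyper",
    ])
    if len(df):
        df["fdr"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
        df["significant"] = df["fdr"] < fdr_max
    return df


def compare_stage_edges(
    growth: CeRNANetwork, senescence: CeRNANetwork, focus: set
) -> tuple[set, set, set]:
    """Partition stage competing edges touching ``focus`` nodes into
    (common, growth-only, senescence-only)."""
    focus = set(focus)
    ge = {e for e in growth.competing_edges if e & focus}
    se = {e for e in senescence.competing_edges if e & focus}
    common = ge & se
    return common, ge - common, se - common
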