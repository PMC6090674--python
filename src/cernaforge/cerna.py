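"""Competing-endogenous-RNA pair calling and network assembly.

A candidate ceRNA pair is two expressed transcripts whose miRNA target sets
overlap. Acceptance requires both published criteria:

1. shared-miRNA significance: the upper-tail hypergeometric probability of
   drawing at least ``k`` shared miRNAs when the two target sets (sizes
   ``K_a``, ``K_b``) are drawn from a universe of ``N`` expressed miRNAs is
   below ``p_hyper_max`` (default 0.05);
2. co-expression: Pearson r of the two temporal profiles exceeds ``r_min``
   (default 0.5) with correlation p below ``p_corr_max`` (default 0.05).

The universe ``N`` defaults to the miRNAs present in the restricted target
table. No multiple-testing correction is applied by default (fixed raw
thresholds); a Benjamini-Hochberg option exists behind a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .interactions import TargetTable

PAIR_COLUMNS = [
    "id_a", "id_b", "class_a", "class_b", "k_shared", "K_a", "K_b",
    "N_universe", "p_hyper", "r", "p_corr", "parent_pair", "accepted",
]


def hypergeom_shared_test(k: int, K_a: int, K_b: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K_a, K_b): overlap at least as
    extreme as observed. Symmetric in (K_a, K_b); equals 1 at k = 0."""
    if N < 1:
        raise ValueError("universe size N must be >= 1")
    if not (0 <= K_a <= N and 0 <= K_b <= N):
        raise ValueError("target-set sizes must lie in [0, N]")
    if not (0 <= k <= min(K_a, K_b)):
        raise ValueError("shared count k must lie in [0, min(K_a, K_b)]")
    return float(stats.hypergeom.sf(k - 1, N, K_a, K_b))


@dataclass
class CeRNAPair:
    id_a: str
    id_b: str
    class_a: str
    class_b: str
    k_shared: int
    K_a: int
    K_b: int
    N_universe: int
    p_hyper: float
    r: float
    p_corr: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("a ceRNA pair needs two distinct transcripts")
        if self.k_shared > min(self.K_a, self.K_b):
            raise ValueError("shared count exceeds a target-set size")


@dataclass
class CeRNACalls:
    """All tested candidate pairs plus the acceptance decisions."""

    candidates: pd.DataFrame
    n_universe: int

    @property
    def accepted(self) -> pd.DataFrame:
        return self.candidates[self.candidates["accepted"]].reset_index(drop=True)

    def accepted_pairs(self) -> list[CeRNAPair]:
        return [
            CeRNAPair(
                id_a=row.id_a, id_b=row.id_b, class_a=row.class_a, class_b=row.class_b,
                k_shared=int(row.k_shared), K_a=int(row.K_a), K_b=int(row.K_b),
                N_universe=int(row.N_universe), p_hyper=float(row.p_hyper),
                r=float(row.r), p_corr=float(row.p_corr),
            )
            for row in self.accepted.itertuples()
        ]

    def accepted_id_pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in zip(self.accepted["id_a"], self.accepted["id_b"])}


def call_cerna_pairs(
    table: TargetTable,
    expr: ExpressionMatrix,
    p_hyper_max: float = 0.05,
    r_min: float = 0.5,
    p_corr_max: float = 0.05,
    min_shared: int = 1,
    universe_size: int | None = None,
    parent_map: dict[str, str] | None = None,
    bh_correct: bool = False,
) -> CeRNACalls:
    """Enumerate and test candidate ceRNA pairs.

    Candidates are unordered transcript pairs sharing at least ``min_shared``
    miRNAs, found through an inverted miRNA -> targets index (identical to
    all-pairs enumeration, cheaper). ``expr`` must be log2(x+1) scale over a
    consistent sample set. Output rows are ordered lexicographically by ids.

    ``parent_map`` (circRNA id -> parent gene id) flags pairs between a
    circRNA and its own parent gene; they remain eligible. ``bh_correct``
    applies Benjamini-Hochberg to both p-value families before thresholding.
    """
    if expr.scale != "log2p1":
        raise ValueError("pair calling expects log2p1-scale expression")
    target_mirnas = table.mirnas_of()
    missing = sorted(set(target_mirnas) - set(expr.transcripts))
    if missing:
        raise ValueError(f"targets absent from expression matrix: {missing}")
    N = int(universe_size) if universe_size is not None else len(table.mirna_universe)
    if N < 1:
        raise ValueError("empty miRNA universe")
    parent_map = parent_map or {}

    # inverted index: candidate pairs co-occur in >= 1 miRNA's target list
    by_mirna: dict[str, list[str]] = {}
    for tid, mirnas in target_mirnas.items():
        for m in mirnas:
            by_mirna.setdefault(m, []).append(tid)
    candidate_keys: set[tuple[str, str]] = set()
    for targets in by_mirna.values():
        for a, b in itertools.combinations(sorted(targets), 2):
            candidate_keys.add((a, b))

    # standardized rows: r(a, b) = z_a . z_b
    vals = expr.values.to_numpy(float)
    n_samp = vals.shape[1]
    if n_samp < 3:
        raise ValueError("need >= 3 samples for the co-expression criterion")
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    row_of = {t: i for i, t in enumerate(expr.transcripts)}

    rows = []
    for a, b in sorted(candidate_keys):
        k = len(target_mirnas[a] & target_mirnas[b])
        if k < min_shared:
            continue
        ia, ib = row_of[a], row_of[b]
        if norms[ia] == 0 or norms[ib] == 0:
            continue  # constant profile: correlation undefined, cannot qualify
        r = float(np.clip(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]), -1, 1))
        rows.append((a, b, k, len(target_mirnas[a]), len(target_mirnas[b]), r))

    if rows:
        df = pd.DataFrame(rows, columns=["id_a", "id_b", "k_shared", "K_a", "K_b", "r"])
        df["N_universe"] = N
        df["p_hyper"] = stats.hypergeom.sf(df["k_shared"] - 1, N, df["K_a"], df["K_b"])
        with np.errstate(divide="ignore"):
            t = df["r"] * np.sqrt((n_samp - 2) / (1.0 - df["r"] ** 2))
        df["p_corr"] = np.where(np.isclose(np.abs(df["r"]), 1.0), 0.0,
                                2.0 * stats.t.sf(np.abs(t), df=n_samp - 2))
        df["class_a"] = expr.rna_class.reindex(df["id_a"]).to_numpy()
        df["class_b"] = expr.rna_class.reindex(df["id_b"]).to_numpy()
        df["parent_pair"] = [
            parent_map.get(a) == b or parent_map.get(b) == a
            for a, b in zip(df["id_a"], df["id_b"])
        ]
        p_hyper_eff = df["p_hyper"].to_numpy()
        p_corr_eff = df["p_corr"].to_numpy()
        if bh_correct and len(df):
            p_hyper_eff = multipletests(p_hyper_eff, method="fdr_bh")[1]
            p_corr_eff = multipletests(p_corr_eff, method="fdr_bh")[1]
        df["accepted"] = (
            (p_hyper_eff < p_hyper_max) & (df["r"] > r_min) & (p_corr_eff < p_corr_max)
        )
        df = df[PAIR_COLUMNS].sort_values(["id_a", "id_b"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=PAIR_COLUMNS)
    return CeRNACalls(candidates=df, n_universe=N)


# ---------------------------------------------------------------------------
# networks


@dataclass
class CeRNANetwork:
    """Graph of competing (RNA-RNA) and regulatory (miRNA-RNA) edges."""

    graph: nx.Graph
    stage_label: str = "global"

    @property
    def rna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "rna"}

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"}

    @property
    def competing_edges(self) -> set[frozenset]:
        return {
            frozenset((u, v))
            for u, v, d in self.graph.edges(data=True)
            if d.get("edge_type") == "competing"
        }

    @property
    def regulatory_edges(self) -> set[frozenset]:
        return {
            frozenset((u, v))
            for u, v, d in self.graph.edges(data=True)
            if d.get("edge_type") == "regulatory"
        }


def assemble_network(
    calls_or_pairs, table: TargetTable, stage_label: str = "global"
) -> CeRNANetwork:
    """Assemble accepted pairs into a ceRNA network.

    Nodes are the pair endpoints plus every miRNA shared by at least one
    accepted pair; regulatory edges are the target-table edges from those
    miRNAs to network RNA nodes.
    """
    if isinstance(calls_or_pairs, CeRNACalls):
        accepted = calls_or_pairs.accepted
    else:
        accepted = calls_or_pairs
    g = nx.Graph(stage=stage_label)
    target_mirnas = table.mirnas_of()
    shared_mirnas: set[str] = set()
    for row in accepted.itertuples():
        for node, cls in ((row.id_a, row.class_a), (row.id_b, row.class_b)):
            g.add_node(node, kind="rna", rna_class=cls)
        g.add_edge(row.id_a, row.id_b, edge_type="competing",
                   k_shared=int(row.k_shared), p_hyper=float(row.p_hyper),
                   r=float(row.r), p_corr=float(row.p_corr))
        shared_mirnas |= target_mirnas.get(row.id_a, frozenset()) & target_mirnas.get(row.id_b, frozenset())
    for m in sorted(shared_mirnas):
        g.add_node(m, kind="mirna", rna_class="miRNA")
    rna_nodes = {n for n, d in g.nodes(data=True) if d["kind"] == "rna"}
    for row in table.edges.itertuples():
        if row.mirna_id in shared_mirnas and row.target_id in rna_nodes:
            g.add_edge(row.mirna_id, row.target_id, edge_type="regulatory")
    return CeRNANetwork(graph=g, stage_label=stage_label)


def stage_networks(
    table: TargetTable,
    expr: ExpressionMatrix,
    stage_partition: dict[str, list[str]],
    **call_kwargs,
) -> dict[str, CeRNANetwork]:
    """Re-call pairs per developmental stage on that stage's samples only.

    The shared-miRNA test is unchanged (target sets are stage-independent);
    only the co-expression criterion sees fewer samples. Each stage needs at
    least 3 samples.
    """
    nets: dict[str, CeRNANetwork] = {}
    for stage, samples in stage_partition.items():
        if len(samples) < 3:
            raise ValueError(f"stage {stage!r} has {len(samples)} samples; need >= 3")
        calls = call_cerna_pairs(table, expr.select_samples(samples), **call_kwargs)
        nets[stage] = assemble_network(calls, table, stage_label=stage)
    return nets
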