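"""End-to-end orchestration: bundle loading, the normalization/filter funnel,
pair calling, networks, clustering, hubs and enrichment, with provenance.

The stages compose pure library calls; :func:`run_pipeline` works on
in-memory inputs (e.g. straight from :func:`cernaforge.synthetic_data.
generate_dataset`), while :func:`run_all` reads a bundle directory and
writes every intermediate artifact plus a checksum manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    CircJunction,
    TranscriptCandidate,
    classify_all,
    filter_lncrna_candidates,
    junctions_to_frame,
    merge_junction_calls,
    read_gene_models,
    read_junctions,
)
from .cerna import CeRNACalls, CeRNANetwork, assemble_network, call_cerna_pairs, stage_networks
from .clustering import (
    ClusterResult,
    SampleClustering,
    StagePartition,
    cluster_cernas,
    cluster_samples,
    default_stage_partition,
)
from .expression import (
    ExpressionMatrix,
    abundance_filter,
    day_of,
    fpkm,
    log2p1,
    parent_coexpression,
    reproducibility_filter,
    rpm,
    stage_de_ttest,
)
from .interactions import TargetTable, read_predictions, restrict_to_expressed, union_merge
from .network_analysis import (
    HubReport,
    compare_hubs,
    compare_stage_edges,
    extract_subnetwork,
    find_hubs,
    hypergeom_set_enrichment,
    randomization_enrichment,
)
from .synthetic_data import GroundTruth, SimConfig, generate_dataset, write_fixture_bundle

logger = logging.getLogger(__name__)

_REP_RE = re.compile(r"^(Day\d+)_r(\d+)$")


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the published defaults."""

    input_dir: str | None = None
    simulate: dict | None = None  # SimConfig overrides; triggers simulation
    outdir: str = "cernaforge_run"
    min_reads: int = 2
    support_mode: str = "per_sample"
    p_hyper_max: float = 0.05
    r_min: float = 0.5
    p_corr_max: float = 0.05
    min_shared: int = 1
    repro_r_min: float = 0.5
    repro_p_max: float = 0.05
    de_alpha: float = 0.05
    de_welch: bool = False
    hub_fraction: float = 0.10
    k: int = 6
    n_init: int = 50
    n_perm: int = 10_000
    stage_mode: str = "fixed-days"  # or "from-sample-clustering"
    bh_correct: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hyper_max", "p_corr_max", "repro_p_max", "de_alpha", "hub_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must be in [-1, 1]")
        if self.stage_mode not in ("fixed-days", "from-sample-clustering"):
            raise ValueError(f"unknown stage_mode {self.stage_mode!r}")
        if self.input_dir is None and self.simulate is None:
            raise ValueError("config needs input_dir or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class InputBundle:
    counts: dict[str, pd.DataFrame]
    lengths: pd.Series
    totals: pd.DataFrame
    predictor_edges: list[pd.DataFrame]
    junction_calls: dict[str, pd.DataFrame]
    genes: list
    lnc_candidates: list[TranscriptCandidate]
    gene_lists: dict[str, list[str]]
    truth: GroundTruth | None = None


def load_bundle(indir: str | Path) -> InputBundle:
    indir = Path(indir)
    counts = {
        cls: pd.read_csv(indir / f"counts_{cls.lower()}.tsv", sep="\t", index_col=0)
        for cls in ("mRNA", "lncRNA", "circRNA", "miRNA")
    }
    lengths = pd.read_csv(indir / "lengths.tsv", sep="\t", index_col=0)["length"]
    totals = pd.read_csv(indir / "totals.tsv", sep="\t", index_col=0)
    predictors = sorted(indir.glob("targets_*.tsv"))
    predictor_edges = [
        read_predictions(p, predictor_name=p.stem.replace("targets_", "")) for p in predictors
    ]
    callers = sorted(indir.glob("junctions_*.tsv"))
    junction_calls = {c.stem.replace("junctions_", ""): read_junctions(c) for c in callers}
    genes = read_gene_models(indir / "genes.gff3")

    lnc_candidates: list[TranscriptCandidate] = []
    cand_path = indir / "lncrna_candidates.tsv"
    if cand_path.exists():
        from Bio import SeqIO

        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(indir / "transcripts.fa"), "fasta")}
        meta = pd.read_csv(cand_path, sep="\t", dtype=str).fillna("")
        for row in meta.itertuples():
            coding = None if row.coding == "" else row.coding == "true"
            lnc_candidates.append(
                TranscriptCandidate(row.transcript_id, row.class_code, seqs[row.transcript_id], coding=coding)
            )
    gene_lists = {}
    for p in sorted((indir / "gene_lists").glob("*.txt")) if (indir / "gene_lists").exists() else []:
        gene_lists[p.stem] = [l for l in p.read_text().splitlines() if l]
    truth = None
    if (indir / "ground_truth.json").exists():
        truth = GroundTruth.read_json(indir / "ground_truth.json")
    return InputBundle(counts, lengths, totals, predictor_edges, junction_calls,
                       genes, lnc_candidates, gene_lists, truth)


def bundle_from_dataset(ds) -> InputBundle:
    """Adapt a :class:`SimulatedDataset` to the pipeline input interface."""
    predictor_edges = []
    for name, df in ds.predictor_edges.items():
        d = df.copy()
        d["predictors"] = [frozenset({name}) for _ in range(len(d))]
        predictor_edges.append(d[["mirna_id", "target_id", "target_class", "predictors"]])
    return InputBundle(
        counts={k: v.round(0) for k, v in ds.counts.items()},
        lengths=ds.lengths, totals=ds.totals,
        predictor_edges=predictor_edges, junction_calls=ds.junction_calls,
        genes=ds.genes, lnc_candidates=ds.lnc_candidates,
        gene_lists={k: list(v) for k, v in ds.truth.annotated_gene_sets.items()},
        truth=ds.truth,
    )


# ---------------------------------------------------------------------------
# expression funnel


@dataclass
class ExpressionResult:
    expr: ExpressionMatrix           # mRNA+lncRNA log2 FPKM, circRNA log2 RPM; replicate-averaged
    mirna_expr: ExpressionMatrix     # miRNA log2 RPM, replicate-averaged
    expressed: dict[str, list[str]]
    funnel: dict[str, dict[str, int]]


def _replicate_split(columns: list[str]) -> dict[int, list[str]]:
    reps: dict[int, list[str]] = {}
    for c in columns:
        m = _REP_RE.match(str(c))
        r = int(m.group(2)) if m else 1
        reps.setdefault(r, []).append(c)
    return reps


def _average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    tp = [f"Day{day_of(c)}" for c in df.columns]
    out = df.T.groupby(pd.Index(tp, name="timepoint"), sort=False).mean().T
    order = sorted(out.columns, key=lambda c: day_of(c))
    return out[order]


def normalized_log_expression(bundle: InputBundle) -> ExpressionMatrix:
    """Replicate-averaged log2(x+1) expression for every transcript, no
    filters: mRNA/lncRNA on FPKM, circRNA on RPM. Useful for experiments on
    planted profiles independent of the funnel."""
    counts_em = {
        cls: ExpressionMatrix(df.astype(float), pd.Series(cls, index=df.index), "raw_count")
        for cls, df in bundle.counts.items()
    }
    parts, classes = [], []
    for cls in ("mRNA", "lncRNA", "circRNA"):
        if cls == "circRNA":
            m = rpm(counts_em[cls], bundle.totals["rnaseq_total"])
        else:
            m = fpkm(counts_em[cls], bundle.lengths, bundle.totals["rnaseq_total"])
        part = np.log2(_average_replicates(m.values) + 1.0)
        parts.append(part)
        classes.append(pd.Series(cls, index=part.index))
    return ExpressionMatrix(pd.concat(parts), pd.concat(classes), "log2p1")


def normalize_and_filter(
    bundle: InputBundle,
    repro_r_min: float = 0.5,
    repro_p_max: float = 0.05,
) -> ExpressionResult:
    """The quantification funnel: FPKM/RPM, replicate-reproducibility filter,
    low-abundance filter, replicate averaging and log2(x+1)."""
    counts_em = {
        cls: ExpressionMatrix(df.astype(float), pd.Series(cls, index=df.index), "raw_count")
        for cls, df in bundle.counts.items()
    }
    normalized = {
        "mRNA": fpkm(counts_em["mRNA"], bundle.lengths, bundle.totals["rnaseq_total"]),
        "lncRNA": fpkm(counts_em["lncRNA"], bundle.lengths, bundle.totals["rnaseq_total"]),
        "circRNA": counts_em["circRNA"],  # abundance rule applies to raw junction counts
        "miRNA": rpm(counts_em["miRNA"], bundle.totals["smallrna_total"]),
    }
    circ_rpm = rpm(counts_em["circRNA"], bundle.totals["rnaseq_total"])

    reps = _replicate_split(list(bundle.counts["mRNA"].columns))
    funnel: dict[str, dict[str, int]] = {}
    expressed: dict[str, list[str]] = {}
    abundant = abundance_filter(normalized)
    for cls in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        m = normalized[cls] if cls != "circRNA" else circ_rpm
        total = len(m.transcripts)
        if len(reps) >= 2:
            r1, r2 = (reps[k] for k in sorted(reps)[:2])
            a = log2p1(m.select_samples(r1))
            b = log2p1(m.select_samples(r2))
            b.values.columns = a.values.columns  # align time-point labels
            reproducible = set(reproducibility_filter(a, b, repro_r_min, repro_p_max))
        else:
            reproducible = set(m.transcripts)
        keep = [t for t in m.transcripts if t in reproducible and t in set(abundant[cls])]
        expressed[cls] = keep
        funnel[cls] = {
            "input": total,
            "reproducible": len(reproducible),
            "abundant": len(abundant[cls]),
            "expressed": len(keep),
        }

    def avg_log(m: ExpressionMatrix, ids: list[str]) -> pd.DataFrame:
        return np.log2(_average_replicates(m.values.loc[ids]) + 1.0)

    parts, classes = [], []
    for cls, m in (("mRNA", normalized["mRNA"]), ("lncRNA", normalized["lncRNA"]), ("circRNA", circ_rpm)):
        part = avg_log(m, expressed[cls])
        parts.append(part)
        classes.append(pd.Series(cls, index=part.index))
    combined = ExpressionMatrix(pd.concat(parts), pd.concat(classes), "log2p1")
    mirna_part = avg_log(normalized["miRNA"], expressed["miRNA"])
    mirna_expr = ExpressionMatrix(mirna_part, pd.Series("miRNA", index=mirna_part.index), "log2p1")
    return ExpressionResult(expr=combined, mirna_expr=mirna_expr, expressed=expressed, funnel=funnel)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    config: RunConfig
    junctions: list[CircJunction]
    lnc_retained: list[str]
    expression: ExpressionResult
    target_table: TargetTable
    calls: CeRNACalls
    network: CeRNANetwork
    stage_nets: dict[str, CeRNANetwork]
    stage_partition: StagePartition
    hubs: dict[str, HubReport]
    hub_comparison: dict[str, list[str]]
    common_hub_subnet: CeRNANetwork | None
    stage_edge_partition: dict[str, int]
    clusters: ClusterResult | None
    sample_clustering: SampleClustering
    de_table: pd.DataFrame
    parent_coexpr: object
    enrichment: pd.DataFrame
    randomization: list
    recovery: dict | None = None


def evaluate_recovery(calls: CeRNACalls, truth: GroundTruth) -> dict:
    """Sensitivity/precision of accepted pairs against the planted truth."""
    accepted = calls.accepted_id_pairs()
    planted = truth.planted_pair_set()
    tp = len(accepted & planted)
    return {
        "n_accepted": len(accepted),
        "n_planted": len(planted),
        "true_positives": tp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(accepted) if accepted else float("nan"),
    }


def run_pipeline(bundle: InputBundle, config: RunConfig) -> PipelineResult:
    # -- annotation -------------------------------------------------------
    junctions = merge_junction_calls(bundle.junction_calls, min_reads=config.min_reads,
                                     support_mode=config.support_mode)
    classify_all(junctions, bundle.genes)
    lnc_retained = [c.transcript_id for c in filter_lncrna_candidates(bundle.lnc_candidates)]

    # -- expression -------------------------------------------------------
    exres = normalize_and_filter(bundle, config.repro_r_min, config.repro_p_max)
    # novel-lncRNA filter intersects the lncRNA expression set when candidate
    # metadata is available
    if bundle.lnc_candidates:
        keep_lnc = set(lnc_retained)
        exres.expressed["lncRNA"] = [t for t in exres.expressed["lncRNA"] if t in keep_lnc]
        drop = [t for t in exres.expr.transcripts
                if exres.expr.rna_class[t] == "lncRNA" and t not in keep_lnc]
        if drop:
            keep_ids = [t for t in exres.expr.transcripts if t not in set(drop)]
            exres = dataclasses.replace(
                exres,
                expr=ExpressionMatrix(exres.expr.values.loc[keep_ids],
                                      exres.expr.rna_class.loc[keep_ids], "log2p1"),
            )
    # circRNAs must additionally survive the junction merge filter
    merged_names = {j.name for j in junctions}
    exres.expressed["circRNA"] = [t for t in exres.expressed["circRNA"] if t in merged_names]

    # -- interactions -----------------------------------------------------
    table = union_merge(bundle.predictor_edges)
    expressed_targets = set(exres.expressed["mRNA"]) | set(exres.expressed["lncRNA"]) | set(exres.expressed["circRNA"])
    table = restrict_to_expressed(table, set(exres.expressed["miRNA"]), expressed_targets)

    # -- ceRNA calling ----------------------------------------------------
    parent_map = {j.name: sorted(j.parent_genes)[0] for j in junctions
                  if j.circ_class == "exonic" and len(j.parent_genes) == 1}
    expr_targets = exres.expr.subset(expressed_targets)
    calls = call_cerna_pairs(
        table, expr_targets, p_hyper_max=config.p_hyper_max, r_min=config.r_min,
        p_corr_max=config.p_corr_max, min_shared=config.min_shared,
        parent_map=parent_map, bh_correct=config.bh_correct,
    )
    network = assemble_network(calls, table, stage_label="global")

    # -- stages -----------------------------------------------------------
    sample_clust = cluster_samples(exres.expr)
    if config.stage_mode == "fixed-days":
        partition = default_stage_partition(exres.expr.samples)
    else:
        g1, g2 = sample_clust.groups
        mean_day = lambda g: np.mean([day_of(s) for s in g])
        growth, senescence = (g1, g2) if mean_day(g1) < mean_day(g2) else (g2, g1)
        key = lambda s: day_of(s)
        partition = StagePartition(sorted(growth, key=key), sorted(senescence, key=key))
    stage_nets = stage_networks(
        table, expr_targets, partition.as_dict(),
        p_hyper_max=config.p_hyper_max, r_min=config.r_min,
        p_corr_max=config.p_corr_max, min_shared=config.min_shared,
        parent_map=parent_map, bh_correct=config.bh_correct,
    )

    # -- hubs and comparison ---------------------------------------------
    hubs = {}
    for label, net in [("global", network)] + list(stage_nets.items()):
        try:
            hubs[label] = find_hubs(net, fraction=config.hub_fraction)
        except ValueError:
            logger.warning("no RNA nodes in %s network; hubs skipped", label)
    hub_comparison: dict[str, list[str]] = {}
    common_subnet = None
    stage_edge_partition: dict[str, int] = {}
    if "growth" in hubs and "senescence" in hubs:
        common, g_spec, s_spec = compare_hubs(hubs["growth"], hubs["senescence"])
        hub_comparison = {
            "common": sorted(common),
            "growth_specific": sorted(g_spec),
            "senescence_specific": sorted(s_spec),
        }
        if common:
            common_subnet = extract_subnetwork(network, common)
        ce, ge, se = compare_stage_edges(stage_nets["growth"], stage_nets["senescence"], common)
        stage_edge_partition = {"common": len(ce), "growth_only": len(ge), "senescence_only": len(se)}

    # -- clustering of ceRNA profiles -------------------------------------
    cerna_nodes = [t for t in exres.expr.transcripts if t in network.rna_nodes]
    clusters = None
    if len(cerna_nodes) >= config.k:
        clusters = cluster_cernas(exres.expr.subset(cerna_nodes), k=config.k,
                                  seed=config.seed, n_init=config.n_init)

    # -- stage DE ---------------------------------------------------------
    full_expr = ExpressionMatrix(
        pd.concat([exres.expr.values, exres.mirna_expr.values]),
        pd.concat([exres.expr.rna_class, exres.mirna_expr.rna_class]),
        "log2p1",
    )
    de = stage_de_ttest(full_expr, partition.growth, partition.senescence,
                        alpha=config.de_alpha, equal_var=not config.de_welch)

    # -- parent co-expression ---------------------------------------------
    ecirc = [j for j in junctions if j.circ_class == "exonic" and len(j.parent_genes) == 1
             and j.name in set(exres.expressed["circRNA"])]
    circ_ids = [t for t in exres.expr.transcripts if exres.expr.rna_class[t] == "circRNA"]
    gene_ids = [t for t in exres.expr.transcripts if exres.expr.rna_class[t] == "mRNA"]
    pc = parent_coexpression(ecirc, exres.expr.subset(circ_ids), exres.expr.subset(gene_ids))

    # -- enrichment --------------------------------------------------------
    background = set(exres.expressed["mRNA"])
    net_genes = {n for n in network.rna_nodes if exres.expr.rna_class.get(n) == "mRNA"}
    randomization = []
    annotated_sets = {k: set(v) & background for k, v in bundle.gene_lists.items()}
    for name, ann in sorted(annotated_sets.items()):
        if net_genes and ann:
            res = randomization_enrichment(net_genes, ann, background,
                                           n_perm=config.n_perm, seed=config.seed)
            res.set_name = name
            randomization.append(res)
    enrichment = hypergeom_set_enrichment(
        [("network_genes", net_genes)], annotated_sets, background
    ) if net_genes else pd.DataFrame()

    truth = bundle.truth
    recovery = evaluate_recovery(calls, truth) if truth is not None else None

    return PipelineResult(
        config=config, junctions=junctions, lnc_retained=lnc_retained, expression=exres,
        target_table=table, calls=calls, network=network, stage_nets=stage_nets,
        stage_partition=partition, hubs=hubs, hub_comparison=hub_comparison,
        common_hub_subnet=common_subnet, stage_edge_partition=stage_edge_partition,
        clusters=clusters, sample_clustering=sample_clust, de_table=de,
        parent_coexpr=pc, enrichment=enrichment, randomization=randomization,
        recovery=recovery,
    )


# ---------------------------------------------------------------------------
# file-level entry point


def _write_graphml(net: CeRNANetwork, path: Path) -> None:
    g = net.graph.copy()
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            d[k] = str(v)
    nx.write_graphml(g, str(path))


def run_all(config: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir``, return
    the run manifest (also written as ``manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_cfg = SimConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        indir = outdir / "sim"
        write_fixture_bundle(indir, sim_cfg)
        logger.info("simulated bundle written to %s", indir)
    else:
        indir = Path(config.input_dir)
    bundle = load_bundle(indir)
    result = run_pipeline(bundle, config)

    files: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        p = outdir / name
        writer(p)
        files[name] = p

    save("merged_junctions.tsv", lambda p: junctions_to_frame(result.junctions).to_csv(p, sep="\t", index=False))
    save("expression_log2p1.tsv", lambda p: result.expression.expr.values.to_csv(p, sep="\t"))
    save("mirna_expression_log2p1.tsv", lambda p: result.expression.mirna_expr.values.to_csv(p, sep="\t"))
    save("expressed_ids.json", lambda p: p.write_text(json.dumps(result.expression.expressed, indent=1, sort_keys=True)))
    save("target_table.tsv", lambda p: result.target_table.to_tsv(p))
    save("cerna_pairs.tsv", lambda p: result.calls.candidates.to_csv(p, sep="\t", index=False))
    save("network_global.graphml", lambda p: _write_graphml(result.network, p))
    for stage, net in result.stage_nets.items():
        save(f"network_{stage}.graphml", lambda p, net=net: _write_graphml(net, p))
    nodes = pd.DataFrame(
        [(n, d.get("kind"), d.get("rna_class")) for n, d in result.network.graph.nodes(data=True)],
        columns=["node", "kind", "rna_class"],
    ).sort_values("node")
    save("nodes.tsv", lambda p: nodes.to_csv(p, sep="\t", index=False))
    edges = pd.DataFrame(
        [(u, v, d.get("edge_type")) for u, v, d in result.network.graph.edges(data=True)],
        columns=["source", "target", "edge_type"],
    ).sort_values(["source", "target"])
    save("edges.tsv", lambda p: edges.to_csv(p, sep="\t", index=False))
    for label, rep in result.hubs.items():
        df = rep.degree.to_frame("degree")
        df["hub"] = [n in rep.hub_set for n in df.index]
        save(f"hubs_{label}.tsv", lambda p, df=df: df.to_csv(p, sep="\t"))
    save("hub_comparison.json", lambda p: p.write_text(json.dumps(result.hub_comparison, indent=1, sort_keys=True)))
    if result.clusters is not None:
        save("clusters.tsv", lambda p: result.clusters.assignment.to_frame().to_csv(p, sep="\t"))
        save("cluster_centroids.tsv", lambda p: result.clusters.centroids.to_csv(p, sep="\t"))
    save("samples_dendrogram.newick", lambda p: p.write_text(result.sample_clustering.to_newick() + "\n"))
    save("de_stage.tsv", lambda p: result.de_table.to_csv(p, sep="\t"))
    save("parent_coexpression.tsv", lambda p: result.parent_coexpr.table.to_csv(p, sep="\t", index=False))
    if len(result.enrichment):
        save("enrichment.tsv", lambda p: result.enrichment.to_csv(p, sep="\t", index=False))
    if result.randomization:
        save("randomization.json", lambda p: p.write_text(json.dumps(
            [dataclasses.asdict(r) for r in result.randomization], indent=1, sort_keys=True)))

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "cernaforge_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "funnel": result.expression.funnel,
        "counts": {
            "junctions_retained": len(result.junctions),
            "lncrna_candidates_retained": len(result.lnc_retained),
            "target_edges": len(result.target_table),
            "mirna_universe": len(result.target_table.mirna_universe),
            "candidate_pairs": int(len(result.calls.candidates)),
            "cerna_pairs": int(len(result.calls.accepted)),
            "regulatory_edges": len(result.network.regulatory_edges),
            "stage_pairs": {s: len(n.competing_edges) for s, n in result.stage_nets.items()},
            "hubs": {s: len(r.hub_set) for s, r in result.hubs.items()},
            "de_significant": int(result.de_table["significant"].sum()),
        },
        "parent_coexpression_fraction": result.parent_coexpr.fraction,
        "stage_partition": result.stage_partition.as_dict(),
        "recovery": result.recovery,
        "files": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in sorted(files.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
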