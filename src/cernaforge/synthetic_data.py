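"""Synthetic leaf-lifespan multi-omics generator with planted ground truth.

Emulates the study design the pipeline targets: 14 time points (Day 4 to
Day 30 in 2-day steps) over four RNA classes (mRNA, lncRNA, circRNA,
miRNA), replicate series, planted ceRNA pairs (significantly overlapping
miRNA target sets plus a shared temporal archetype), six archetypal
temporal shapes, a toy two-chromosome genome carrying all four circRNA
genomic classes, two-predictor target tables and two-caller junction
tables with partial overlap, and annotation gene lists.

Counts are drawn negative-binomially (gamma-Poisson, dispersion
configurable) around profile-scaled means. Identical seeds yield
byte-identical bundles.

Design notes that matter for interpreting ground truth:

* Planted pairs use the five *dynamic* archetypes; the flat archetype is
  represented by dedicated background "carrier" transcripts, because a flat
  profile cannot support a detectable co-expression signal.
* Predicted miRNA target sites cover only a fraction
  (``target_coverage``) of background transcripts, mirroring the sparsity
  of plant miRNA target prediction.
* Shared miRNA sets of distinct planted pairs overlap by at most one
  miRNA, and background-target draws for planted members avoid pushing any
  cross-pair shared count to 3 (which would be significant at the default
  universe size), so the planted-pair labels stay unambiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptCandidate, longest_orf

ARCHETYPE_NAMES = {
    1: "early-high-decaying",
    2: "rise-then-fall",
    3: "flat",
    4: "late-rising",
    5: "mid-peak",
    6: "monotone-increasing",
}
DYNAMIC_ARCHETYPES = (1, 2, 4, 5, 6)


def archetype_profiles(n_timepoints: int) -> dict[int, np.ndarray]:
    """The six temporal shapes on the day grid, z-scored across time
    (the flat shape is identically zero)."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = {
        1: np.exp(-2.5 * t),
        2: (t / 0.3) * np.exp(1.0 - t / 0.3),
        3: np.zeros_like(t),
        4: 1.0 / (1.0 + np.exp(-30.0 * (t - 0.82))),
        5: np.exp(-(((t - 0.45) / 0.16) ** 2)),
        6: t.copy(),
    }
    out = {}
    for k, s in shapes.items():
        if s.std() > 0:
            out[k] = (s - s.mean()) / s.std()
        else:
            out[k] = s
    return out


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings. Defaults are the standard study conditions."""

    n_timepoints: int = 14
    n_mrna: int = 200
    n_lncrna: int = 20
    n_circrna: int = 30
    n_mirna: int = 50
    n_planted_pairs: int = 30
    shared_mirnas_per_pair: int = 5
    background_targets_per_rna: int = 2
    target_coverage: float = 0.10
    profile_noise_sd: float = 0.3
    n_replicates: int = 2
    library_size: int = 5_000_000
    smallrna_library_size: int = 2_000_000
    cluster_archetypes: int = 6
    dispersion: float = 0.1
    profile_dynamic_sd: float = 1.2
    background_dynamic_fraction: float = 0.5
    background_dynamic_sd: float = 1.0
    background_stage_sd: float = 0.7
    unstable_sd: float = 0.15
    carriers_per_archetype: int = 6
    parent_coexpressed_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_timepoints=self.n_timepoints, n_mrna=self.n_mrna, n_lncrna=self.n_lncrna,
            n_circrna=self.n_circrna, n_mirna=self.n_mirna,
            n_planted_pairs=self.n_planted_pairs,
            shared_mirnas_per_pair=self.shared_mirnas_per_pair,
            background_targets_per_rna=self.background_targets_per_rna,
            n_replicates=self.n_replicates, library_size=self.library_size,
            cluster_archetypes=self.cluster_archetypes,
        )
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.profile_noise_sd < 0 or self.dispersion < 0:
            raise ConfigurationError("noise sd and dispersion must be >= 0")
        if self.cluster_archetypes != 6:
            raise ConfigurationError("the archetype catalogue has exactly 6 shapes")
        if self.shared_mirnas_per_pair + self.background_targets_per_rna > self.n_mirna:
            raise ConfigurationError(
                "target-set size exceeds the miRNA universe: "
                f"{self.shared_mirnas_per_pair}+{self.background_targets_per_rna} > {self.n_mirna}"
            )
        if self.n_circrna < 4:
            raise ConfigurationError("need >= 4 circRNAs to represent all genomic classes")
        comp = [_pair_composition(i) for i in range(self.n_planted_pairs)]
        need_mrna = sum(c.count("mRNA") for c in comp)
        need_lnc = sum(c.count("lncRNA") for c in comp)
        need_circ = sum(c.count("circRNA") for c in comp)
        n_carriers = 6 * self.carriers_per_archetype
        if need_mrna + n_carriers + 8 > self.n_mrna:
            raise ConfigurationError("n_mrna too small for planted members, carriers and genome genes")
        if need_lnc > self.n_lncrna or need_circ > self.n_circrna - 3:
            raise ConfigurationError("n_lncrna / n_circrna too small for the planted pairs")

    @property
    def days(self) -> list[int]:
        return [4 + 2 * i for i in range(self.n_timepoints)]

    @property
    def timepoint_labels(self) -> list[str]:
        return [f"Day{d}" for d in self.days]

    @property
    def sample_labels(self) -> list[str]:
        if self.n_replicates == 1:
            return self.timepoint_labels
        return [f"Day{d}_r{r}" for d in self.days for r in range(1, self.n_replicates + 1)]


def _pair_composition(i: int) -> tuple[str, str]:
    m = i % 5
    if m == 3:
        return ("mRNA", "lncRNA")
    if m == 4:
        return ("mRNA", "circRNA")
    return ("mRNA", "mRNA")


@dataclass
class GroundTruth:
    planted_pairs: list[tuple[str, str]]
    cluster_assignment: dict[str, int]
    stage_labels: dict[str, str]
    circ_classes: dict[str, str]
    annotated_gene_sets: dict[str, list[str]]
    parent_of: dict[str, str] = field(default_factory=dict)
    coexpressed_ecirc: list[str] = field(default_factory=list)
    low_support_junctions: list[str] = field(default_factory=list)

    def planted_pair_set(self) -> set[frozenset]:
        return {frozenset(p) for p in self.planted_pairs}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    config: SimConfig
    counts: dict[str, pd.DataFrame]
    latent_profiles: pd.DataFrame
    lengths: pd.Series
    totals: pd.DataFrame
    predictor_edges: dict[str, pd.DataFrame]
    all_edges: pd.DataFrame
    junction_calls: dict[str, pd.DataFrame]
    genes: list[GeneModel]
    chrom_sequences: dict[str, str]
    sequences: dict[str, str]
    lnc_candidates: list[TranscriptCandidate]
    truth: GroundTruth

    @property
    def rna_class(self) -> pd.Series:
        parts = []
        for cls, df in self.counts.items():
            parts.append(pd.Series(cls, index=df.index))
        return pd.concat(parts)


# ---------------------------------------------------------------------------
# target-set construction


def _draw_shared_sets(rng: np.random.Generator, cfg: SimConfig) -> list[set[int]]:
    sets: list[set[int]] = []
    for _ in range(cfg.n_planted_pairs):
        for _try in range(5000):
            cand = set(rng.choice(cfg.n_mirna, size=cfg.shared_mirnas_per_pair, replace=False).tolist())
            if all(len(cand & s) <= 1 for s in sets):
                sets.append(cand)
                break
        else:
            raise ConfigurationError(
                "cannot draw near-disjoint shared miRNA sets; "
                "n_planted_pairs x shared_mirnas_per_pair is infeasible for n_mirna"
            )
    return sets


def _draw_member_backgrounds(
    rng: np.random.Generator, cfg: SimConfig,
    shared_sets: list[set[int]], pair_of_member: list[int],
) -> list[set[int]]:
    """Background targets per planted member; avoids inflating within-pair or
    cross-pair shared counts."""
    full: list[set[int]] = []
    for idx, pair_idx in enumerate(pair_of_member):
        shared = shared_sets[pair_idx]
        pool = np.array(sorted(set(range(cfg.n_mirna)) - shared))
        for _try in range(20000):
            bg = set(rng.choice(pool, size=cfg.background_targets_per_rna, replace=False).tolist())
            cand = shared | bg
            ok = True
            # cap overlap with every other pair's shared set at 2, so later
            # members of those pairs stay drawable without significant overlap
            for j, other_shared in enumerate(shared_sets):
                if j != pair_idx and len(cand & other_shared) > 2:
                    ok = False
                    break
            if ok:
                for j, other in enumerate(full):
                    other_pair = pair_of_member[j]
                    overlap = len(cand & other)
                    if other_pair == pair_idx:
                        if overlap != cfg.shared_mirnas_per_pair:
                            ok = False
                            break
                    elif overlap >= 3:
                        ok = False
                        break
            if ok:
                full.append(cand)
                break
        else:
            raise ConfigurationError("cannot draw member background targets without cross-pair collisions")
    return full


# ---------------------------------------------------------------------------
# toy genome


def _build_genome(rng: np.random.Generator, gene_ids: list[str]) -> tuple[list[GeneModel], dict[str, list[GeneModel]], dict[str, str]]:
    genes: list[GeneModel] = []
    per_chrom: dict[str, list[GeneModel]] = {"chr1": [], "chr2": []}
    positions = {"chr1": 1500, "chr2": 1500}
    for i, gid in enumerate(gene_ids):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        pos = positions[chrom]
        n_exons = int(rng.integers(2, 6))
        # same strand for the first two genes of each chromosome so that a
        # two-gene ("other") junction can always be placed
        strand = "+" if len(per_chrom[chrom]) < 2 else ("+" if rng.random() < 0.5 else "-")
        exons = []
        cur = pos
        for e in range(n_exons):
            elen = int(rng.integers(150, 401))
            exons.append((cur, cur + elen))
            cur += elen
            if e < n_exons - 1:
                cur += int(rng.integers(200, 701))
        g = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                      start=exons[0][0], end=exons[-1][1], exons=exons)
        genes.append(g)
        per_chrom[chrom].append(g)
        positions[chrom] = cur + int(rng.integers(1500, 2600))
    chrom_seqs = {
        c: "".join(rng.choice(list("ACGT"), size=positions[c] + 2000).tolist())
        for c in ("chr1", "chr2")
    }
    return genes, per_chrom, chrom_seqs


_COMP = str.maketrans("ACGTN", "TGCAN")


def _spliced_sequence(g: GeneModel, chrom_seq: str) -> str:
    seq = "".join(chrom_seq[s:e] for s, e in g.exons)
    if g.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def _circ_class_counts(n: int) -> dict[str, int]:
    intronic = max(1, n // 10)
    intergenic = max(1, round(n * 0.13))
    other = max(1, n // 15)
    exonic = n - intronic - intergenic - other
    if exonic < 1:
        intronic = intergenic = other = 1
        exonic = n - 3
    return {"exonic": exonic, "intronic": intronic, "intergenic": intergenic, "other": other}


# ---------------------------------------------------------------------------
# main generator


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    days = cfg.days
    tp_labels = cfg.timepoint_labels
    n_tp = cfg.n_timepoints
    shapes = archetype_profiles(n_tp)

    # ---- id pools -------------------------------------------------------
    mrna_ids = [f"m{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    lnc_ids = [f"lnc{i:03d}" for i in range(1, cfg.n_lncrna + 1)]
    circ_ids = [f"circ{i:03d}" for i in range(1, cfg.n_circrna + 1)]
    mirna_ids = [f"miR{i:03d}" for i in range(1, cfg.n_mirna + 1)]

    # ---- planted pairs --------------------------------------------------
    compositions = [_pair_composition(i) for i in range(cfg.n_planted_pairs)]
    pair_archetype = [DYNAMIC_ARCHETYPES[i % len(DYNAMIC_ARCHETYPES)] for i in range(cfg.n_planted_pairs)]
    m_iter = iter(mrna_ids)
    lnc_iter = iter(lnc_ids)
    circ_iter = iter(circ_ids)
    take = {"mRNA": m_iter, "lncRNA": lnc_iter, "circRNA": circ_iter}
    planted_pairs: list[tuple[str, str]] = []
    member_ids: list[str] = []
    pair_of_member: list[int] = []
    member_class: dict[str, str] = {}
    for i, comp in enumerate(compositions):
        a, b = (next(take[comp[0]]), next(take[comp[1]]))
        planted_pairs.append((a, b))
        for mid, cls in zip((a, b), comp):
            member_ids.append(mid)
            pair_of_member.append(i)
            member_class[mid] = cls

    planted_circ = [m for m in member_ids if member_class[m] == "circRNA"]
    carriers = [next(m_iter) for _ in range(6 * cfg.carriers_per_archetype)]
    carrier_archetype = {c: 1 + (j // cfg.carriers_per_archetype) for j, c in enumerate(carriers)}
    bg_mrna = list(m_iter)
    bg_lnc = list(lnc_iter)
    bg_circ = list(circ_iter)

    # ---- background dynamics split -------------------------------------
    def split_dynamic(ids: list[str]) -> tuple[list[str], list[str]]:
        mask = rng.random(len(ids)) < cfg.background_dynamic_fraction
        return ([t for t, m in zip(ids, mask) if m], [t for t, m in zip(ids, mask) if not m])

    dyn_mrna, unstable_mrna = split_dynamic(bg_mrna)
    dyn_lnc, unstable_lnc = split_dynamic(bg_lnc)
    dyn_circ, unstable_circ = split_dynamic(bg_circ)

    # ---- toy genome -----------------------------------------------------
    n_genes = min(24, len(dyn_mrna))
    if n_genes < 4:
        raise ConfigurationError("too few dynamic background mRNAs to build the toy genome")
    genome_gene_ids = dyn_mrna[:n_genes]
    genes, per_chrom, chrom_seqs = _build_genome(rng, genome_gene_ids)
    gene_by_id = {g.gene_id: g for g in genes}

    # ---- circRNA placement ---------------------------------------------
    class_counts = _circ_class_counts(cfg.n_circrna)
    circ_classes: dict[str, str] = {}
    parent_of: dict[str, str] = {}
    junction_rows: list[dict] = []  # chrom,start,end,name,strand

    exonic_ids = planted_circ + [c for c in circ_ids if c not in planted_circ]
    exonic_ids = exonic_ids[: class_counts["exonic"]]
    remaining = [c for c in circ_ids if c not in exonic_ids]
    intronic_ids = remaining[: class_counts["intronic"]]
    remaining = remaining[len(intronic_ids):]
    intergenic_ids = remaining[: class_counts["intergenic"]]
    other_ids = remaining[len(intergenic_ids): len(intergenic_ids) + class_counts["other"]]

    multi_exon = [g for g in genes if len(g.exons) >= 2]
    for j, cid in enumerate(exonic_ids):
        g = genes[j % len(genes)]
        e1, e2 = g.exons[0], g.exons[-1]
        start = int(rng.integers(e1[0], e1[1] - 20))
        end = int(rng.integers(e2[0] + 20, e2[1]))
        junction_rows.append(dict(chrom=g.chrom, start=start, end=end, name=cid, strand=g.strand))
        circ_classes[cid] = "exonic"
        parent_of[cid] = g.gene_id
    for j, cid in enumerate(intronic_ids):
        g = multi_exon[j % len(multi_exon)]
        s, e = g.introns[0]
        junction_rows.append(dict(chrom=g.chrom, start=s + 10, end=e - 10, name=cid, strand=g.strand))
        circ_classes[cid] = "intronic"
        parent_of[cid] = g.gene_id
    for j, cid in enumerate(intergenic_ids):
        chrom = "chr1" if j % 2 == 0 else "chr2"
        last = per_chrom[chrom][-1]
        start = last.end + 600 + 500 * j
        junction_rows.append(dict(chrom=chrom, start=start, end=start + 300, name=cid, strand="+"))
        circ_classes[cid] = "intergenic"
    for j, cid in enumerate(other_ids):
        chrom = "chr1" if j % 2 == 0 else "chr2"
        g1, g2 = per_chrom[chrom][0], per_chrom[chrom][1]
        junction_rows.append(dict(chrom=chrom, start=g1.start + 50, end=g2.end - 50, name=cid, strand=g1.strand))
        circ_classes[cid] = "other"

    # a deliberately under-supported junction, to exercise the >= 2 filter
    low_id = "circLOW01"
    g = genes[0]
    junction_rows.append(dict(chrom=g.chrom, start=g.exons[0][0] + 5, end=g.exons[-1][1] - 5,
                              name=low_id, strand=g.strand))
    circ_classes[low_id] = "exonic"
    parent_of[low_id] = g.gene_id

    # ---- co-expressed ecircRNAs ----------------------------------------
    nonplanted_exonic = [c for c in exonic_ids if c not in planted_circ]
    n_coex = round(cfg.parent_coexpressed_fraction * len(exonic_ids))
    coexpressed = nonplanted_exonic[:n_coex]

    # ---- latent profiles ------------------------------------------------
    latent = {}

    def baseline(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    for mid in member_ids:
        arch = pair_archetype[pair_of_member[member_ids.index(mid)]]
        lo, hi = (2.5, 3.5) if member_class[mid] == "circRNA" else (3.5, 5.5)
        latent[mid] = baseline(lo, hi) + cfg.profile_dynamic_sd * shapes[arch] \
            + rng.normal(0.0, cfg.profile_noise_sd, n_tp)
    for c in carriers:
        latent[c] = baseline(3.5, 5.5) + cfg.profile_dynamic_sd * shapes[carrier_archetype[c]] \
            + rng.normal(0.0, cfg.profile_noise_sd, n_tp)
    # growth/senescence contrast carried by dynamic background transcripts
    # (mirrors the large stage-differential fraction seen in real leaves)
    stage_step = np.array([0.0 if d <= 18 else 1.0 for d in days])
    if stage_step.std() > 0:
        stage_step = (stage_step - stage_step.mean()) / stage_step.std()
    for ids, lo, hi in ((dyn_mrna, 3.5, 5.5), (dyn_lnc, 3.0, 5.0), (dyn_circ, 2.5, 3.5)):
        for t in ids:
            delta = rng.normal(0.0, cfg.background_stage_sd)
            latent[t] = baseline(lo, hi) + delta * stage_step \
                + rng.normal(0.0, cfg.background_dynamic_sd, n_tp)
    for ids, lo, hi in ((unstable_mrna, 3.5, 5.5), (unstable_lnc, 3.0, 5.0), (unstable_circ, 2.5, 3.5)):
        for t in ids:
            latent[t] = baseline(lo, hi) + rng.normal(0.0, cfg.unstable_sd, n_tp)
    for m in mirna_ids:
        latent[m] = baseline(3.0, 5.0) + rng.normal(0.0, 0.8, n_tp)
    # co-expressed ecircRNAs copy their parent's shape at circRNA magnitude
    for cid in coexpressed:
        parent_profile = latent[parent_of[cid]]
        shifted = parent_profile - parent_profile.mean() + baseline(2.5, 3.5)
        latent[cid] = shifted + rng.normal(0.0, 0.2, n_tp)

    order = mrna_ids + lnc_ids + circ_ids + mirna_ids
    latent_df = pd.DataFrame({t: latent[t] for t in order}, index=tp_labels).T
    latent_df = np.maximum(latent_df, 0.0)

    # ---- counts ---------------------------------------------------------
    sample_labels = cfg.sample_labels
    totals = pd.DataFrame(
        {
            "rnaseq_total": cfg.library_size * rng.uniform(0.85, 1.15, len(sample_labels)),
            "smallrna_total": cfg.smallrna_library_size * rng.uniform(0.85, 1.15, len(sample_labels)),
        },
        index=pd.Index(sample_labels, name="sample"),
    ).round(0)

    lengths = pd.Series(dtype=float)
    sequences: dict[str, str] = {}
    for gid in genome_gene_ids:
        sequences[gid] = _spliced_sequence(gene_by_id[gid], chrom_seqs[gene_by_id[gid].chrom])
    for mid in mrna_ids:
        if mid not in sequences:
            sequences[mid] = "".join(rng.choice(list("ACGT"), size=int(rng.integers(800, 2501))).tolist())
    for lid in lnc_ids:
        for _try in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(300, 1501))).tolist())
            if longest_orf(seq) <= 120:
                break
        sequences[lid] = seq
    lengths = pd.Series({t: len(sequences[t]) for t in mrna_ids + lnc_ids}, name="length")

    def nb(mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        if cfg.dispersion == 0:
            return rng.poisson(mean).astype(float)
        n_nb = 1.0 / cfg.dispersion
        p = n_nb / (n_nb + mean)
        return rng.negative_binomial(n_nb, p).astype(float)

    def rep_noise(v: np.ndarray) -> np.ndarray:
        return v + rng.normal(0.0, cfg.profile_noise_sd, v.shape)

    counts: dict[str, pd.DataFrame] = {}
    class_ids = {"mRNA": mrna_ids, "lncRNA": lnc_ids, "circRNA": circ_ids, "miRNA": mirna_ids}
    for cls, ids in class_ids.items():
        mat = np.zeros((len(ids), len(sample_labels)))
        for r, tid in enumerate(ids):
            base = latent_df.loc[tid].to_numpy()
            for c, sample in enumerate(sample_labels):
                ti = tp_labels.index(f"Day{base_day(sample)}")
                v = rep_noise(np.array([base[ti]]))[0]
                norm = max(2.0**v - 1.0, 0.0)
                if cls in ("mRNA", "lncRNA"):
                    mu = norm * (lengths[tid] / 1e3) * (totals.loc[sample, "rnaseq_total"] / 1e6)
                elif cls == "miRNA":
                    mu = norm * (totals.loc[sample, "smallrna_total"] / 1e6)
                else:  # circRNA junction reads
                    mu = norm
                mat[r, c] = nb(np.array([mu]))[0]
        counts[cls] = pd.DataFrame(mat, index=pd.Index(ids, name="transcript"), columns=sample_labels)

    # ---- junction caller tables -----------------------------------------
    circ_counts = counts["circRNA"]
    caller_a_rows, caller_b_rows = [], []
    b_reported = rng.random(len(junction_rows)) < 0.75
    for k, row in enumerate(junction_rows):
        if row["name"] == low_id:
            support = pd.Series(0.0, index=sample_labels)
            support.iloc[0] = 1.0
        else:
            support = circ_counts.loc[row["name"]]
        rec = dict(chrom=row["chrom"], start=row["start"], end=row["end"], name=row["name"],
                   score=int(support.max()), strand=row["strand"])
        rec.update({s: int(v) for s, v in support.items()})
        caller_a_rows.append(rec)
        if b_reported[k] and row["name"] != low_id:
            thin = {s: int(rng.binomial(int(v), 0.8)) for s, v in support.items()}
            rec_b = dict(chrom=row["chrom"], start=row["start"], end=row["end"], name=row["name"],
                         score=max(thin.values()), strand=row["strand"])
            rec_b.update(thin)
            caller_b_rows.append(rec_b)
    junction_calls = {
        "callerA": pd.DataFrame(caller_a_rows),
        "callerB": pd.DataFrame(caller_b_rows) if caller_b_rows else pd.DataFrame(
            columns=list(caller_a_rows[0].keys())),
    }

    # ---- targets --------------------------------------------------------
    shared_sets = _draw_shared_sets(rng, cfg)
    member_sets = _draw_member_backgrounds(rng, cfg, shared_sets, pair_of_member)
    target_sets: dict[str, set[int]] = {
        mid: member_sets[i] for i, mid in enumerate(member_ids)
    }
    background_pool = carriers + [t for t in bg_mrna] + bg_lnc + bg_circ
    covered = rng.random(len(background_pool)) < cfg.target_coverage
    for t, c in zip(background_pool, covered):
        if c:
            target_sets[t] = set(rng.choice(cfg.n_mirna, size=cfg.background_targets_per_rna,
                                            replace=False).tolist())

    cls_of = {t: "mRNA" for t in mrna_ids}
    cls_of.update({t: "lncRNA" for t in lnc_ids})
    cls_of.update({t: "circRNA" for t in circ_ids})
    edge_rows = []
    for t in sorted(target_sets):
        for m in sorted(target_sets[t]):
            edge_rows.append((mirna_ids[m], t, cls_of[t], round(float(rng.uniform(0.5, 5.0)), 1)))
    all_edges = pd.DataFrame(edge_rows, columns=["mirna_id", "target_id", "target_class", "score"])
    split = rng.random(len(all_edges))
    in_a = split < 0.75
    in_b = split >= 0.40
    predictor_edges = {
        "predictorA": all_edges[in_a].reset_index(drop=True),
        "predictorB": all_edges[in_b].reset_index(drop=True),
    }

    # ---- lncRNA candidates ---------------------------------------------
    codes = ["u", "i", "x"]
    lnc_candidates = [
        TranscriptCandidate(transcript_id=lid, class_code=codes[i % 3], sequence=sequences[lid])
        for i, lid in enumerate(lnc_ids)
    ]
    rej_short = "".join(rng.choice(list("ACGT"), size=150).tolist())
    orf_codons = ["ATG"] + ["".join(rng.choice(list("ACG"), size=3).tolist()) for _ in range(150)] + ["TAA"]
    rej_orf = "".join(orf_codons)
    rej_code = "".join(rng.choice(list("ACGT"), size=400).tolist())
    rej_cnci = "".join(rng.choice(list("ACGT"), size=500).tolist())
    lnc_candidates += [
        TranscriptCandidate("lncrej_short", "u", rej_short),
        TranscriptCandidate("lncrej_orf", "u", rej_orf),
        TranscriptCandidate("lncrej_code", "j", rej_code),
        TranscriptCandidate("lncrej_cnci", "u", rej_cnci, coding=True),
    ]
    for c in lnc_candidates:
        sequences[c.transcript_id] = c.sequence

    # ---- annotation gene lists ------------------------------------------
    planted_mrna = [m for m in member_ids if member_class[m] == "mRNA"]
    tf = [m for i, m in enumerate(planted_mrna) if i % 3 == 0]
    tf += [m for i, m in enumerate(bg_mrna) if i % 12 == 0]
    leaf = [m for i, m in enumerate(planted_mrna) if i % 2 == 0]
    leaf += [m for i, m in enumerate(bg_mrna) if i % 10 == 5]
    annotated = {"TF": sorted(tf), "leaf_associated": sorted(leaf)}

    # ---- ground truth ----------------------------------------------------
    cluster_assignment = {
        mid: pair_archetype[pair_of_member[i]] for i, mid in enumerate(member_ids)
    }
    cluster_assignment.update(carrier_archetype)
    stage_labels = {f"Day{d}": ("growth" if d <= 18 else "senescence") for d in days}
    truth = GroundTruth(
        planted_pairs=planted_pairs,
        cluster_assignment=cluster_assignment,
        stage_labels=stage_labels,
        circ_classes=circ_classes,
        annotated_gene_sets={k: list(v) for k, v in annotated.items()},
        parent_of=parent_of,
        coexpressed_ecirc=list(coexpressed),
        low_support_junctions=[low_id],
    )

    return SimulatedDataset(
        config=cfg, counts=counts, latent_profiles=latent_df, lengths=lengths,
        totals=totals, predictor_edges=predictor_edges, all_edges=all_edges,
        junction_calls=junction_calls, genes=genes, chrom_sequences=chrom_seqs,
        sequences=sequences, lnc_candidates=lnc_candidates, truth=truth,
    )


def base_day(sample_label: str) -> int:
    from .expression import day_of

    return day_of(sample_label)


# ---------------------------------------------------------------------------
# bundle writing


def _gff3_text(genes: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        lines.append("\t".join([g.chrom, "cernaforge", "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", attrs]))
        tid = f"{g.gene_id}.t1"
        lines.append("\t".join([g.chrom, "cernaforge", "mRNA", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", f"ID={tid};Parent={g.gene_id}"]))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append("\t".join([g.chrom, "cernaforge", "exon", str(s + 1), str(e),
                                    ".", g.strand, ".", f"ID={tid}.exon{i};Parent={tid}"]))
    return "\n".join(lines) + "\n"


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fixture_bundle(
    outdir: str | Path,
    config: SimConfig | None = None,
    dataset: SimulatedDataset | None = None,
) -> dict:
    """Write a complete input bundle plus ground truth and a checksum manifest."""
    if dataset is None:
        if config is None:
            config = SimConfig()
        dataset = generate_dataset(config)
    cfg = dataset.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    files: dict[str, Path] = {}

    def tsv(name: str, df: pd.DataFrame, index: bool) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=index)
        files[name] = p

    for cls, df in dataset.counts.items():
        tsv(f"counts_{cls.lower()}.tsv", df.round(0).astype(int), index=True)
    tsv("lengths.tsv", dataset.lengths.to_frame(), index=True)
    tsv("totals.tsv", dataset.totals.astype(int), index=True)
    for name, df in dataset.predictor_edges.items():
        tsv(f"targets_{name}.tsv", df, index=False)
    for name, df in dataset.junction_calls.items():
        tsv(f"junctions_{name}.tsv", df, index=False)

    gff = outdir / "genes.gff3"
    gff.write_text(_gff3_text(dataset.genes))
    files["genes.gff3"] = gff
    _write_fasta(outdir / "genome.fa", dataset.chrom_sequences)
    files["genome.fa"] = outdir / "genome.fa"
    _write_fasta(outdir / "transcripts.fa", dataset.sequences)
    files["transcripts.fa"] = outdir / "transcripts.fa"

    cand = pd.DataFrame(
        [(c.transcript_id, c.class_code, "" if c.coding is None else str(c.coding).lower())
         for c in dataset.lnc_candidates],
        columns=["transcript_id", "class_code", "coding"],
    )
    tsv("lncrna_candidates.tsv", cand, index=False)

    lists_dir = outdir / "gene_lists"
    lists_dir.mkdir(exist_ok=True)
    for name, ids in dataset.truth.annotated_gene_sets.items():
        p = lists_dir / f"{name}.txt"
        p.write_text("\n".join(ids) + "\n")
        files[f"gene_lists/{name}.txt"] = p

    dataset.truth.write_json(outdir / "ground_truth.json")
    files["ground_truth.json"] = outdir / "ground_truth.json"

    manifest = {
        "config": dataclasses.asdict(cfg),
        "files": {
            name: {
                "bytes": p.stat().st_size,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for name, p in sorted(files.items())
        },
        "n_planted_pairs": len(dataset.truth.planted_pairs),
        "n_edges_union": int(len(dataset.all_edges)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
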