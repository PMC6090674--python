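"""Gene models, back-splice junction merging/classification, lncRNA filters.

Coordinates are 0-based half-open internally and in junction tables; GFF3 is
read as 1-based closed and converted on ingest. circRNA classes follow the
usual plant convention: *exonic* (both back-splice ends inside exons of a
single protein-coding gene), *intronic* (span inside one intron),
*intergenic* (no gene overlap), *other* (spanning two or more protein-coding
genes, or any remaining single-gene geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

CIRC_CLASSES = ("exonic", "intronic", "intergenic", "other")

JUNCTION_BASE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        exons = sorted(self.exons)
        merged: list[list[int]] = []
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.exons = [(s, e) for s, e in merged]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def contains_in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass
class CircJunction:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    junction_reads: pd.Series  # per-sample support (max across callers)
    callers: set[str] = field(default_factory=set)
    circ_class: str | None = None
    parent_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"junction {self.name}: start must be < end")
        if (self.junction_reads < 0).any():
            raise ValueError(f"junction {self.name}: negative read support")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TranscriptCandidate:
    """An assembled transcript considered as a novel lncRNA."""

    transcript_id: str
    class_code: str
    sequence: str
    coding: bool | None = None  # optional precomputed coding-potential call
    length: int = field(init=False)
    longest_orf_aa: int = field(init=False)

    def __post_init__(self) -> None:
        self.length = len(self.sequence)
        self.longest_orf_aa = longest_orf(self.sequence)


# ---------------------------------------------------------------------------
# GFF3 ingest


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from GFF3 into :class:`GeneModel` records.

    GFF3 intervals (1-based, closed) are converted to 0-based half-open.
    The gene biotype is taken from a ``biotype`` attribute when present,
    else ``protein_coding``.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                biotype=biotype,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


# ---------------------------------------------------------------------------
# junction merging


def read_junctions(path: str | Path, caller: str | None = None) -> pd.DataFrame:
    """Read one caller's BED6-like junction table (extra columns = per-sample counts)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in JUNCTION_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing junction columns {missing}")
    for i, row in df.iterrows():
        if not (int(row["start"]) < int(row["end"])):
            raise ValueError(f"{path}: line {i + 2}: start >= end")
    if caller is not None:
        df = df.copy()
        df["caller"] = caller
    return df


def _sample_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in JUNCTION_BASE_COLUMNS + ["caller", "callers", "circ_class", "parent_genes"]]


def merge_junction_calls(
    call_sets: dict[str, pd.DataFrame],
    min_reads: int = 2,
    support_mode: str = "per_sample",
) -> list[CircJunction]:
    """Unify multi-caller back-splice calls and apply the junction-read filter.

    Junctions with identical ``(chrom, start, end, strand)`` are unified
    across callers; per-sample support is the max across callers. A junction
    is retained iff its support reaches ``min_reads`` in at least one sample
    (``support_mode="per_sample"``, the default) or summed over samples
    (``support_mode="summed"``).
    """
    if support_mode not in ("per_sample", "summed"):
        raise ValueError(f"unknown support_mode {support_mode!r}")
    chrom_sets = {name: set(df["chrom"].unique()) for name, df in call_sets.items() if len(df)}
    nonempty = list(chrom_sets)
    if len(nonempty) > 1:
        universe = set.union(*chrom_sets.values())
        for name, chroms in chrom_sets.items():
            others = set.union(*(chrom_sets[o] for o in nonempty if o != name)) if len(nonempty) > 1 else set()
            if others and not (chroms & others):
                raise ValueError(
                    "inconsistent chromosome names across junction files: "
                    + "; ".join(f"{n}: {sorted(c)}" for n, c in chrom_sets.items())
                )
        del universe

    merged: dict[tuple, CircJunction] = {}
    for caller, df in call_sets.items():
        sample_cols = _sample_columns(df)
        for i, row in df.iterrows():
            try:
                start, end = int(row["start"]), int(row["end"])
                reads = pd.Series({c: float(row[c]) for c in sample_cols}, dtype=float)
                j = CircJunction(
                    chrom=str(row["chrom"]), start=start, end=end,
                    strand=str(row["strand"]), name=str(row["name"]),
                    junction_reads=reads, callers={caller},
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"caller {caller!r}, line {i + 2}: {exc}") from exc
            if j.key in merged:
                prev = merged[j.key]
                prev.junction_reads = pd.concat([prev.junction_reads, j.junction_reads], axis=1).max(axis=1)
                prev.callers |= j.callers
            else:
                merged[j.key] = j

    kept = []
    for j in merged.values():
        support = j.junction_reads.sum() if support_mode == "summed" else j.junction_reads.max()
        if support >= min_reads:
            kept.append(j)
    kept.sort(key=lambda j: (j.chrom, j.start, j.end, j.strand))
    return kept


def junctions_to_frame(junctions: Sequence[CircJunction]) -> pd.DataFrame:
    """Serialize merged junctions back to the BED6+counts table layout."""
    rows = []
    for j in junctions:
        row = {
            "chrom": j.chrom, "start": j.start, "end": j.end, "name": j.name,
            "score": int(j.junction_reads.max()), "strand": j.strand,
        }
        row.update(j.junction_reads.to_dict())
        if j.circ_class is not None:
            row["circ_class"] = j.circ_class
            row["parent_genes"] = ",".join(sorted(j.parent_genes))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification


class GenomeIndex:
    """Interval index over gene models for junction classification."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.models:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, start: int, end: int, strand: str = ".") -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand in ("+", "-"):
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))


def classify_circ(junction: CircJunction, index: GenomeIndex | Iterable[GeneModel]) -> str:
    """Assign one of exonic/intronic/intergenic/other; populates parent_genes.

    Junctions with strand '.' are classified against genes on both strands.
    Every junction receives exactly one class.
    """
    if not isinstance(index, GenomeIndex):
        index = GenomeIndex(index)
    hits = index.overlapping(junction.chrom, junction.start, junction.end, junction.strand)
    coding = [g for g in hits if g.biotype == "protein_coding"]
    if not hits:
        junction.circ_class = "intergenic"
        junction.parent_genes = set()
        return junction.circ_class

    junction.parent_genes = {g.gene_id for g in (coding or hits)}
    if len(coding) >= 2:
        junction.circ_class = "other"
    elif len(coding) == 1:
        g = coding[0]
        # endpoints of the half-open span: first base and last base
        if g.contains_in_exon(junction.start) and g.contains_in_exon(junction.end - 1):
            junction.circ_class = "exonic"
        elif any(s <= junction.start and junction.end <= e for s, e in g.introns):
            junction.circ_class = "intronic"
        else:
            junction.circ_class = "other"
    else:
        # overlaps only non-coding annotation: not from exons of a coding gene
        junction.circ_class = "other"
    return junction.circ_class


def classify_all(junctions: Sequence[CircJunction], models: Iterable[GeneModel]) -> list[CircJunction]:
    index = GenomeIndex(models)
    for j in junctions:
        classify_circ(j, index)
    return list(junctions)


# ---------------------------------------------------------------------------
# ORF scan and lncRNA candidate filter

_STOPS = {"TAA", "TAG", "TGA"}
_VALID_NT = set("ACGTN")


def longest_orf(sequence: str) -> int:
    """Length (aa) of the longest ATG-initiated, stop-terminated ORF.

    Scans the three forward frames of the given stranded sequence; the stop
    codon is not counted. Returns 0 when no complete ORF exists.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def filter_lncrna_candidates(
    candidates: Sequence[TranscriptCandidate],
    min_len: int = 200,
    max_orf: int = 120,
    allowed_codes: tuple[str, ...] = ("i", "x", "u"),
) -> list[TranscriptCandidate]:
    """Retain novel-lncRNA candidates: class code i/x/u, length >= min_len nt,
    longest ORF <= max_orf aa (inclusive bounds). Candidates flagged coding by
    an upstream coding-potential score are rejected first."""
    kept = []
    for c in candidates:
        if c.coding is True:
            continue
        if c.class_code not in allowed_codes:
            continue
        if c.length < min_len or c.longest_orf_aa > max_orf:
            continue
        kept.append(c)
    return kept
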