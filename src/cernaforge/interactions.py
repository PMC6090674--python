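"""miRNA-target interaction tables: multi-predictor ingest, union merge,
restriction to expressed transcripts."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

EDGE_COLUMNS = ["mirna_id", "target_id", "target_class", "predictors"]
TARGET_CLASSES = ("mRNA", "circRNA", "lncRNA")


@dataclass
class TargetTable:
    """Deduplicated (miRNA, target) edges with predictor provenance.

    ``edges`` columns: mirna_id, target_id, target_class, predictors
    (frozenset of predictor names). ``mirna_universe`` is the set of
    expressed miRNAs backing at least one edge (populated by
    :func:`restrict_to_expressed`; before restriction it is every miRNA
    seen in an edge).
    """

    edges: pd.DataFrame
    mirna_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"target table missing columns {missing}")
        bad = set(self.edges["target_class"].unique()) - set(TARGET_CLASSES)
        if bad:
            raise ValueError(f"unknown target classes {sorted(bad)}")
        if self.edges.duplicated(["mirna_id", "target_id"]).any():
            raise ValueError("duplicate (mirna, target) edges")
        if not self.mirna_universe:
            self.mirna_universe = set(self.edges["mirna_id"].unique())

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, mirna: str) -> set[str]:
        return set(self.edges.loc[self.edges["mirna_id"] == mirna, "target_id"])

    def mirnas_of(self) -> dict[str, frozenset[str]]:
        """target id -> frozenset of regulating miRNAs."""
        grouped = self.edges.groupby("target_id")["mirna_id"].agg(frozenset)
        return grouped.to_dict()

    def to_tsv(self, path: str | Path) -> None:
        out = self.edges.copy()
        out["predictors"] = out["predictors"].map(lambda s: ",".join(sorted(s)))
        out.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path, predictor_name: str, dialect: str = "tsv") -> pd.DataFrame:
    """Read one predictor's output into a tagged, deduplicated edge list.

    The generic dialect is a TSV with at least ``mirna_id``, ``target_id``
    and ``target_class`` columns; extra columns (scores, positions) are
    carried opaquely.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna_id", "target_id", "target_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if row[required].isna().any():
            raise ValueError(f"{path}: line {i + 2}: empty field in {required}")
    df = df.drop_duplicates(["mirna_id", "target_id"]).reset_index(drop=True)
    df["predictors"] = [frozenset({predictor_name}) for _ in range(len(df))]
    return df[EDGE_COLUMNS]


def union_merge(tables: list[pd.DataFrame]) -> TargetTable:
    """Set union of predictor edge lists, accumulating predictor provenance."""
    if not tables:
        raise ValueError("union_merge needs at least one edge list")
    cat = pd.concat([t[EDGE_COLUMNS] for t in tables], ignore_index=True)
    merged = (
        cat.groupby(["mirna_id", "target_id", "target_class"], as_index=False)["predictors"]
        .agg(lambda sets: frozenset().union(*sets))
    )
    merged = merged.sort_values(["mirna_id", "target_id"]).reset_index(drop=True)
    if merged.duplicated(["mirna_id", "target_id"]).any():
        dup = merged[merged.duplicated(["mirna_id", "target_id"], keep=False)]
        raise ValueError(f"conflicting target_class for edges: {dup.to_dict('records')}")
    return TargetTable(edges=merged[EDGE_COLUMNS])


def intersect_merge(tables: list[pd.DataFrame]) -> TargetTable:
    """Intersection variant: keep only edges reported by every predictor."""
    union = union_merge(tables)
    n = len(tables)
    keep = union.edges["predictors"].map(len) >= n
    return TargetTable(edges=union.edges[keep].reset_index(drop=True))


def restrict_to_expressed(
    table: TargetTable, expressed_mirnas: set[str], expressed_targets: set[str]
) -> TargetTable:
    """Drop edges whose miRNA or target failed the expression filters."""
    e = table.edges
    keep = e["mirna_id"].isin(expressed_mirnas) & e["target_id"].isin(expressed_targets)
    kept = e[keep].reset_index(drop=True)
    return TargetTable(edges=kept, mirna_universe=set(kept["mirna_id"].unique()))
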