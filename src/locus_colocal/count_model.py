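"""Pfam occurrence tables and category joins.

Two counting units coexist because the downstream statistics need both:

* **gene-level occurrences** ``n_l`` — the number of genes in the group
  carrying Pfam *l* (one occurrence per gene even if the domain repeats on
  the protein).  These feed the permutation null and the Z-score.
* **region-level presence** ``r_l`` — the number of windows containing at
  least one gene with Pfam *l*.  These feed Fisher's exact test, whose unit
  of evidence is the region, not the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from locus_colocal.annotation_io import AnchorWindow
from locus_colocal.errors import ValidationError

COUNT_TSV_COLUMNS = ("Nucleotide_acc", "pfam", "group", "id")


@dataclass
class PfamCountTable:
    """Long-format Pfam occurrence records with derived count summaries.

    ``records`` has one row per (gene, Pfam) pair with columns
    ``region_id, pfam, group, gene_id``.
    """

    records: pd.DataFrame
    region_ids: list[str]

    def __post_init__(self) -> None:
        expected = {"region_id", "pfam", "group", "gene_id"}
        if not expected.issubset(self.records.columns):
            raise ValidationError(f"count table missing columns {expected - set(self.records.columns)}")

    @property
    def N(self) -> int:
        """Total number of Pfam occurrence rows."""
        return len(self.records)

    @property
    def n_l(self) -> pd.Series:
        """Gene-level occurrence count per Pfam."""
        return self.records.groupby("pfam").size().sort_index()

    @property
    def r_l(self) -> pd.Series:
        """Number of distinct regions containing each Pfam."""
        return self.records.groupby("pfam")["region_id"].nunique().sort_index()

    @property
    def k_r(self) -> pd.Series:
        """Occurrence total per region (zero-occurrence regions included)."""
        counts = self.records.groupby("region_id").size()
        return counts.reindex(self.region_ids, fill_value=0)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def pfams(self) -> list[str]:
        return sorted(self.records["pfam"].unique())


def build_count_table(windows: Sequence[AnchorWindow], filter_prefix: str = "PF") -> PfamCountTable:
    """Build the per-region Pfam occurrence table from anchored windows.

    One record per (gene, Pfam) pair; accessions not starting with
    ``filter_prefix`` (e.g. COG or TIGRFAM identifiers mixed into the
    annotation) are dropped.
    """
    if not windows:
        raise ValidationError("build_count_table requires at least one window")
    rows = []
    region_ids = []
    for w in windows:
        region_ids.append(w.region_id)
        for g in w.genes:
            for acc in g.pfams:
                if acc.startswith(filter_prefix):
                    rows.append((w.region_id, acc, w.group, g.gene_id))
    records = pd.DataFrame(rows, columns=["region_id", "pfam", "group", "gene_id"])
    return PfamCountTable(records=records, region_ids=region_ids)


def category_join(table: PfamCountTable, mapping: Mapping[str, Iterable[str] | str]) -> pd.DataFrame:
    """Summarise table Pfams per functional category.

    ``mapping`` maps a Pfam accession to one or more category labels
    (defence, mobilome, metabolism, ...).  Returns a frame indexed by
    category with the set of matching Pfams, their count, and the number of
    regions containing at least one mapped Pfam.  Unmapped Pfams are ignored.
    """
    by_category: dict[str, set[str]] = {}
    for pfam, labels in mapping.items():
        if isinstance(labels, str):
            labels = [labels]
        for label in labels:
            if not label:
                raise ValidationError(f"empty category label for {pfam}")
            by_category.setdefault(label, set()).add(pfam)

    table_pfams = set(table.records["pfam"].unique())
    region_pfams = table.records.groupby("region_id")["pfam"].agg(set)
    rows = []
    for label in sorted(by_category):
        hits = by_category[label] & table_pfams
        n_regions = int(sum(bool(pf & hits) for pf in region_pfams)) if hits else 0
        rows.append({
            "category": label,
            "pfams": sorted(hits),
            "n_pfams": len(hits),
            "n_regions": n_regions,
        })
    return pd.DataFrame(rows, columns=["category", "pfams", "n_pfams", "n_regions"]).set_index("category")


def write_count_table(table: PfamCountTable, path: str | Path) -> None:
    """Write occurrence records as TSV (columns Nucleotide_acc/pfam/group/id)."""
    out = table.records.rename(columns={"region_id": "Nucleotide_acc", "gene_id": "id"})
    out = out[list(COUNT_TSV_COLUMNS)]
    # Region universe is carried in a header comment so zero-occurrence
    # regions survive the round trip.
    with open(path, "w") as fh:
        fh.write("# regions: " + ",".join(table.region_ids) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_count_table(path: str | Path) -> PfamCountTable:
    path = Path(path)
    if not path.exists():
        raise OSError(f"count table not found: {path}")
    region_ids: list[str] | None = None
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("# regions:"):
            raw = first.split(":", 1)[1].strip()
            region_ids = [r for r in raw.split(",") if r]
            records = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            fh.seek(0)
            records = pd.read_csv(fh, sep="\t", dtype=str)
    if tuple(records.columns) != COUNT_TSV_COLUMNS:
        raise ValidationError(f"{path}: unexpected count-table header {list(records.columns)}")
    records = records.rename(columns={"Nucleotide_acc": "region_id", "id": "gene_id"})
    if region_ids is None:
        region_ids = list(dict.fromkeys(records["region_id"]))
    return PfamCountTable(records=records, region_ids=region_ids)
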