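"""Proximity of anchor genes to defence and anti-defence systems.

Distances are signed midpoint-to-midpoint offsets in bp (negative means the
feature lies upstream of the anchor in contig coordinates).  Multi-gene
systems are represented by the midpoint of their full span, mirroring the
midpoint convention used for genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

from locus_colocal.annotation_io import AnchorWindow, ContigAnnotation
from locus_colocal.enrichment import odds_ratio_ci
from locus_colocal.count_model import PfamCountTable
from locus_colocal.errors import ValidationError

logger = logging.getLogger(__name__)

ACTIVITIES = ("defence", "anti-defence")

# Pfams whose promiscuity inflates defence-region counts (AAA-like ATPase
# domains); excluded from the defence-Pfam region filter by default.
DEFAULT_AAA_EXCLUSION = frozenset({"PF13304"})


@dataclass
class DefenceAnnotation:
    """One defence or anti-defence system hit on a contig."""

    contig_id: str
    system_name: str
    activity: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"system {self.system_name} on {self.contig_id}: start >= end")
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"activity must be one of {ACTIVITIES}, got {self.activity!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class IntervalSet:
    """Labelled half-open intervals per contig (genomic islands etc.)."""

    label: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, ivals in self.intervals.items():
            for s, e in ivals:
                if s >= e:
                    raise ValidationError(
                        f"{self.label} interval [{s}, {e}) on {contig} is malformed")

    def contains(self, contig_id: str, position: int) -> bool:
        return any(s <= position < e for s, e in self.intervals.get(contig_id, []))


def distance_to_anchor(window: AnchorWindow, feature_start: int, feature_end: int) -> int:
    """Signed midpoint distance from the window's anchor to a feature."""
    return (feature_start + feature_end) // 2 - window.anchor_midpoint


def systems_within(window: AnchorWindow, systems: Sequence[DefenceAnnotation],
                   max_abs_distance: int) -> list[tuple[DefenceAnnotation, int]]:
    """Systems on the window's contig within ``max_abs_distance`` of the anchor."""
    if max_abs_distance <= 0:
        raise ValidationError("max_abs_distance must be positive")
    hits = []
    for sys_ in systems:
        if sys_.contig_id != window.contig_id:
            continue
        d = distance_to_anchor(window, sys_.start, sys_.end)
        if abs(d) <= max_abs_distance:
            hits.append((sys_, d))
    return hits


def defence_pfam_region_filter(table: PfamCountTable, defence_pfams: set[str],
                               exclusion: set[str] = DEFAULT_AAA_EXCLUSION,
                               min_hits: int = 5) -> list[str]:
    """Regions with at least ``min_hits`` defence-associated Pfam occurrences.

    Occurrence rows whose Pfam lies in ``defence_pfams`` minus ``exclusion``
    are counted per region; regions reaching ``min_hits`` pass.  The default
    exclusion removes AAA-like domains, which occur so broadly that they
    would otherwise dominate the count.
    """
    if min_hits < 1:
        raise ValidationError("min_hits must be >= 1")
    effective = set(defence_pfams) - set(exclusion)
    if not effective:
        return []
    rec = table.records
    hits = rec[rec["pfam"].isin(effective)].groupby("region_id").size()
    passing = set(hits[hits >= min_hits].index)
    return [r for r in table.region_ids if r in passing]


def locate_in_intervals(window: AnchorWindow, islands: IntervalSet,
                        plasmid_contigs: set[str]) -> tuple[bool, bool]:
    """(on_plasmid, in_island) flags for one window.

    A window is plasmid-borne iff its contig appears in the plasmid contig
    list; it is island-borne iff the anchor midpoint falls inside any
    genomic-island interval on its contig.
    """
    on_plasmid = window.contig_id in plasmid_contigs
    in_island = islands.contains(window.contig_id, window.anchor_midpoint)
    return on_plasmid, in_island


@dataclass
class BackgroundOddsResult:
    """2×2 comparison of defence presence near anchors vs random backbone."""

    table: np.ndarray  # [[test_with, test_without], [bg_with, bg_without]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    bg_positive: int
    n_samples: int
    seed: int

    @property
    def bg_rate(self) -> float:
        return self.bg_positive / self.n_samples


def background_defence_odds(control_contigs: Sequence[ContigAnnotation],
                            systems: Sequence[DefenceAnnotation],
                            test_presence: tuple[int, int],
                            k: int = 30, n_samples: int = 200,
                            seed: int = 0) -> BackgroundOddsResult:
    """Odds of defence-system presence near anchors vs random gene runs.

    Draws ``n_samples`` contigs (without replacement when enough are
    eligible), takes ``k`` consecutive CDS starting at a uniform random
    index from each, and calls the sample positive iff any system's midpoint
    falls within the sampled CDS span.  The background presence count is
    compared with the test group's presence (``test_presence`` =
    (regions_with_system, total_regions)) in a 2×2 table with sample odds
    ratio, Wald CI and two-sided Fisher p.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    eligible = []
    for contig in control_contigs:
        if len(contig.features) < k:
            logger.warning("skipping contig %s: fewer than %d CDS", contig.contig_id, k)
            continue
        eligible.append(contig)
    if len(eligible) < n_samples:
        raise ValidationError(
            f"only {len(eligible)} contigs with >= {k} CDS; need {n_samples}")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_samples, replace=False)
    by_contig: dict[str, list[DefenceAnnotation]] = {}
    for s in systems:
        by_contig.setdefault(s.contig_id, []).append(s)

    positives = 0
    for idx in chosen:
        contig = eligible[int(idx)]
        start_idx = int(rng.integers(0, len(contig.features) - k + 1))
        run = contig.features[start_idx:start_idx + k]
        span = (run[0].start, run[-1].end)
        hit = any(span[0] <= s.midpoint < span[1]
                  for s in by_contig.get(contig.contig_id, []))
        positives += int(hit)

    test_with, test_total = test_presence
    table = np.array([[test_with, test_total - test_with],
                      [positives, n_samples - positives]])
    or_, lo, hi = odds_ratio_ci(*table.ravel())
    p = float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    return BackgroundOddsResult(table=table, odds_ratio=or_, ci_low=lo, ci_high=hi,
                                fisher_p=p, bg_positive=positives,
                                n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# Tabular I/O

DEFENCE_TSV_COLUMNS = ("contig_id", "system_name", "activity", "start", "end", "genes")


def write_defence_table(systems: Iterable[DefenceAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DEFENCE_TSV_COLUMNS) + "\n")
        for s in systems:
            fh.write(f"{s.contig_id}\t{s.system_name}\t{s.activity}\t"
                     f"{s.start}\t{s.end}\t{','.join(s.gene_ids)}\n")


def read_defence_table(path: str | Path) -> list[DefenceAnnotation]:
    path = Path(path)
    if not path.exists():
        raise OSError(f"defence table not found: {path}")
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != DEFENCE_TSV_COLUMNS:
            raise ValidationError(f"{path}: unexpected defence-table header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            contig_id, name, activity, start, end, genes = line.split("\t")
            out.append(DefenceAnnotation(
                contig_id=contig_id, system_name=name, activity=activity,
                start=int(start), end=int(end),
                gene_ids=[g for g in genes.split(",") if g]))
    return out


def read_interval_table(path: str | Path, label: str = "genomic_island") -> IntervalSet:
    """Read a BED-like TSV (contig_id, start, end, label) into an IntervalSet."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"interval table not found: {path}")
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id"):
                continue
            parts = line.split("\t")
            contig_id, start, end = parts[0], int(parts[1]), int(parts[2])
            row_label = parts[3] if len(parts) > 3 else label
            if row_label == label:
                intervals.setdefault(contig_id, []).append((start, end))
    return IntervalSet(label=label, intervals=intervals)


def write_interval_table(islands: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstart\tend\tlabel\n")
        for contig_id in sorted(islands.intervals):
            for s, e in islands.intervals[contig_id]:
                fh.write(f"{contig_id}\t{s}\t{e}\t{islands.label}\n")
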