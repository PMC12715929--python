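"""Gene annotation I/O and anchored window extraction.

Coordinates are held internally as 0-based half-open intervals (the BED
convention); GFF3 and the tabular feature format are 1-based inclusive on
disk and are converted at the I/O boundary.  Strand is carried through but no
downstream statistic uses it.

An *anchor window* is the neighbourhood analysed around a marker gene: a
region of at most ``2 × half_width`` (40 kb by default) centred on the anchor
gene's midpoint and clipped to the contig.  A gene belongs to the window iff
its own midpoint falls inside the half-open window interval, so genes
straddling a boundary are assigned unambiguously.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils.iterators

from locus_colocal.errors import LookupFailure, ValidationError

PFAM_RE = re.compile(r"^PF\d{5}$")

FEATURE_TSV_COLUMNS = ("contig_id", "gene_id", "start", "end", "strand", "product", "pfams")

DEFAULT_HALF_WIDTH = 20_000


@dataclass
class GeneFeature:
    """One CDS with its coordinates and Pfam domain annotations.

    ``pfams`` is de-duplicated per gene: a domain occurring twice on one
    protein counts once for that gene, but every gene carrying it contributes
    an occurrence.
    """

    contig_id: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""
    product: str = ""
    pfams: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValidationError("GeneFeature requires a non-empty contig_id")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid coordinates for gene {self.gene_id!r}: "
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )
        seen: list[str] = []
        for acc in self.pfams:
            if acc not in seen:
                seen.append(acc)
        self.pfams = seen

    @property
    def midpoint(self) -> int:
        """Gene midpoint, (start + end) // 2 — integral by convention."""
        return (self.start + self.end) // 2


@dataclass
class ContigAnnotation:
    """All gene features of one contig, sorted by start coordinate."""

    contig_id: str
    features: list[GeneFeature] = field(default_factory=list)
    length: int | None = None

    def __post_init__(self) -> None:
        for f in self.features:
            if f.contig_id != self.contig_id:
                raise ValidationError(
                    f"feature {f.gene_id!r} belongs to contig {f.contig_id!r}, "
                    f"not {self.contig_id!r}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.gene_id))
        if self.features:
            max_end = max(f.end for f in self.features)
            if self.length is None:
                self.length = max_end
            elif self.length < max_end:
                raise ValidationError(
                    f"contig {self.contig_id}: declared length {self.length} "
                    f"< max feature end {max_end}"
                )

    def get_gene(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise LookupFailure(f"gene {gene_id!r} not found on contig {self.contig_id}")


@dataclass
class AnchorWindow:
    """A ≤ 40 kb neighbourhood centred on an anchor gene.

    ``group`` tags the window as belonging to the test set (anchored on the
    marker of interest, e.g. a LanM gene) or the control set (anchored on a
    neutral ubiquitous marker such as phosphofructokinase).
    """

    contig_id: str
    anchor_gene_id: str
    window_start: int
    window_end: int
    genes: list[GeneFeature]
    group: str = "test"
    anchor_midpoint: int = 0

    @property
    def span(self) -> int:
        return self.window_end - self.window_start

    @property
    def region_id(self) -> str:
        """Windows are identified by their contig accession."""
        return self.contig_id


def _parse_pfams(raw: str, where: str) -> list[str]:
    pfams: list[str] = []
    for acc in re.split(r"[;,]", raw):
        acc = acc.strip()
        if not acc:
            continue
        if not re.match(r"^[A-Za-z]+[0-9.]*$", acc):
            raise ValidationError(f"{where}: malformed domain accession {acc!r}")
        pfams.append(acc)
    return pfams


def _read_feature_tsv(path: Path) -> list[ContigAnnotation]:
    contigs: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != FEATURE_TSV_COLUMNS:
            raise ValidationError(
                f"{path}: unexpected feature-table header {header!r}; "
                f"expected {list(FEATURE_TSV_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(FEATURE_TSV_COLUMNS):
                raise ValidationError(f"{path} line {lineno}: expected "
                                      f"{len(FEATURE_TSV_COLUMNS)} columns, got {len(parts)}")
            contig_id, gene_id, start_s, end_s, strand, product, pfams_s = parts
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise ValidationError(f"{path} line {lineno}: non-integer coordinate") from exc
            if end_1 < start_1:
                raise ValidationError(
                    f"{path} line {lineno}: end {end_1} < start {start_1}"
                )
            try:
                feature = GeneFeature(
                    contig_id=contig_id,
                    start=start_1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_1,
                    strand=strand,
                    gene_id=gene_id,
                    product=product,
                    pfams=_parse_pfams(pfams_s, f"{path} line {lineno}"),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            contigs.setdefault(contig_id, []).append(feature)
    return [ContigAnnotation(contig_id=cid, features=feats) for cid, feats in contigs.items()]


def _read_gff3(path: Path) -> list[ContigAnnotation]:
    contigs: dict[str, list[GeneFeature]] = {}
    # gffutils' DataIterator parses GFF3 lines lazily without building a db.
    for rec in gffutils.iterators.DataIterator(str(path)):
        if rec.featuretype not in ("CDS", "gene"):
            continue
        attrs = rec.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [""])[0]
        product = (attrs.get("product") or [""])[0]
        pfam_raw = ",".join(attrs.get("pfam") or [])
        if rec.end < rec.start:
            raise ValidationError(f"{path}: feature {gene_id!r} has end < start")
        feature = GeneFeature(
            contig_id=rec.seqid,
            start=rec.start - 1,
            end=rec.end,
            strand=rec.strand if rec.strand in "+-" else ".",
            gene_id=gene_id,
            product=product,
            pfams=_parse_pfams(pfam_raw, f"{path} feature {gene_id!r}"),
        )
        contigs.setdefault(rec.seqid, []).append(feature)
    return [ContigAnnotation(contig_id=cid, features=feats) for cid, feats in contigs.items()]


def read_feature_table(path: str | Path, dialect: str = "feature_tsv") -> list[ContigAnnotation]:
    """Read gene annotations from GFF3 or the tabular feature format.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"gff3"`` (1-based inclusive; Pfam accessions in a comma-separated
        ``pfam`` attribute) or ``"feature_tsv"`` (columns
        ``contig_id gene_id start end strand product pfams``, coordinates
        1-based inclusive, pfams semicolon-separated).

    Returns
    -------
    list of :class:`ContigAnnotation`
        One entry per contig, features sorted by start, coordinates converted
        to the internal 0-based half-open convention.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"feature file not found: {path}")
    if dialect == "feature_tsv":
        return _read_feature_tsv(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValidationError(f"unsupported dialect {dialect!r}; use 'gff3' or 'feature_tsv'")


def write_feature_table(contigs: Iterable[ContigAnnotation], path: str | Path,
                        dialect: str = "feature_tsv") -> None:
    """Write annotations in a format :func:`read_feature_table` round-trips."""
    path = Path(path)
    contigs = list(contigs)
    if dialect == "feature_tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(FEATURE_TSV_COLUMNS) + "\n")
            for contig in contigs:
                for f in contig.features:
                    fh.write(
                        f"{f.contig_id}\t{f.gene_id}\t{f.start + 1}\t{f.end}\t"
                        f"{f.strand}\t{f.product}\t{';'.join(f.pfams)}\n"
                    )
    elif dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig in contigs:
                if contig.length is not None:
                    fh.write(f"##sequence-region {contig.contig_id} 1 {contig.length}\n")
                for f in contig.features:
                    attrs = [f"ID={f.gene_id}"]
                    if f.product:
                        attrs.append(f"product={f.product}")
                    if f.pfams:
                        attrs.append("pfam=" + ",".join(f.pfams))
                    fh.write(
                        f"{f.contig_id}\tlocus_colocal\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                        f"{f.strand}\t.\t{';'.join(attrs)}\n"
                    )
    else:
        raise ValidationError(f"unsupported dialect {dialect!r}")


def extract_window(contig: ContigAnnotation, anchor_gene_id: str,
                   half_width: int = DEFAULT_HALF_WIDTH, group: str = "test") -> AnchorWindow:
    """Extract the anchored neighbourhood window around one gene.

    The window is ``[anchor_midpoint - half_width, anchor_midpoint +
    half_width)`` intersected with the contig, so truncated contigs yield
    legal windows shorter than ``2 × half_width``.  A gene is a member iff its
    midpoint lies inside the half-open window.
    """
    if half_width <= 0:
        raise ValidationError(f"half_width must be positive, got {half_width}")
    anchor = contig.get_gene(anchor_gene_id)
    mid = anchor.midpoint
    contig_len = contig.length if contig.length is not None else max(
        (f.end for f in contig.features), default=0)
    window_start = max(0, mid - half_width)
    window_end = min(contig_len, mid + half_width)
    genes = [f for f in contig.features if window_start <= f.midpoint < window_end]
    return AnchorWindow(
        contig_id=contig.contig_id,
        anchor_gene_id=anchor_gene_id,
        window_start=window_start,
        window_end=window_end,
        genes=genes,
        group=group,
        anchor_midpoint=mid,
    )


def coding_density(window: AnchorWindow) -> float:
    """CDS count normalised to a 40 kb span (CDS per 40 kb)."""
    if window.span <= 0:
        raise ValidationError(f"window {window.region_id} has zero span")
    return len(window.genes) * 40_000 / window.span


# ---------------------------------------------------------------------------
# Window table I/O: one row per gene occurrence inside a window, so windows
# round-trip exactly (the window geometry is repeated on each row).

WINDOW_TSV_COLUMNS = (
    "contig_id", "group", "anchor_gene_id", "anchor_midpoint", "window_start",
    "window_end", "gene_id", "start", "end", "strand", "product", "pfams",
)


def write_windows(windows: Iterable[AnchorWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_TSV_COLUMNS) + "\n")
        for w in windows:
            for g in w.genes:
                fh.write(
                    f"{w.contig_id}\t{w.group}\t{w.anchor_gene_id}\t{w.anchor_midpoint}\t"
                    f"{w.window_start}\t{w.window_end}\t{g.gene_id}\t{g.start + 1}\t{g.end}\t"
                    f"{g.strand}\t{g.product}\t{';'.join(g.pfams)}\n"
                )


def read_windows(path: str | Path) -> list[AnchorWindow]:
    path = Path(path)
    if not path.exists():
        raise OSError(f"window file not found: {path}")
    windows: dict[tuple[str, str], AnchorWindow] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != WINDOW_TSV_COLUMNS:
            raise ValidationError(f"{path}: unexpected window-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            (contig_id, group, anchor_gene_id, anchor_mid, w_start, w_end,
             gene_id, start_s, end_s, strand, product, pfams_s) = parts
            key = (contig_id, anchor_gene_id)
            if key not in windows:
                windows[key] = AnchorWindow(
                    contig_id=contig_id,
                    anchor_gene_id=anchor_gene_id,
                    window_start=int(w_start),
                    window_end=int(w_end),
                    genes=[],
                    group=group,
                    anchor_midpoint=int(anchor_mid),
                )
            windows[key].genes.append(GeneFeature(
                contig_id=contig_id,
                start=int(start_s) - 1,
                end=int(end_s),
                strand=strand,
                gene_id=gene_id,
                product=product,
                pfams=_parse_pfams(pfams_s, f"{path} line {lineno}"),
            ))
    return list(windows.values())
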