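"""Synthetic annotated-genome corpora with planted colocalisation structure.

The generator emulates the statistical shape of a real anchored-window
study without any sequence content: contigs are tiled with CDS at a target
coding density (default 37 CDS per 40 kb), each gene carries 0–3 background
Pfam accessions drawn from a Zipf-distributed vocabulary (domain family
frequencies are heavy-tailed in real annotation), test contigs carry a
single anchor gene with its companion cluster Pfams nearby, and *planted*
Pfams are included per region with group-specific probabilities — giving a
known ground-truth odds ratio that recovery tests can check.  Defence
systems are emitted for planted defence Pfams and, at a background rate,
for control regions.

Everything is driven by one integer seed through a single
``numpy.random.Generator``, so identical seeds give bit-identical corpora
and output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from locus_colocal.annotation_io import (
    AnchorWindow,
    ContigAnnotation,
    GeneFeature,
    extract_window,
    write_feature_table,
)
from locus_colocal.errors import ValidationError
from locus_colocal.proximity import (
    DefenceAnnotation,
    IntervalSet,
    write_defence_table,
    write_interval_table,
)

_MIN_GENE_LEN = 60  # floor for truncated-normal gene lengths, bp


@dataclass
class ClusterPfam:
    """A companion Pfam present in every test region near the anchor."""

    pfam: str
    max_distance: int = 5_000


@dataclass
class PlantedPfam:
    """A Pfam planted with group-specific per-region inclusion probability.

    ``max_distance`` parameterises the placement law: the carrying gene is
    the one nearest a uniform random offset in (0, max_distance] on a random
    side of the anchor.  When ``system_name`` is set, each planted occurrence
    also emits a defence/anti-defence system annotation over the gene.
    """

    pfam: str
    p_test: float
    p_control: float
    max_distance: int = 10_000
    system_name: str | None = None
    activity: str = "defence"

    @property
    def nominal_odds_ratio(self) -> float:
        pt, pc = self.p_test, self.p_control
        return (pt * (1 - pc)) / (pc * (1 - pt))


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic corpus."""

    n_test: int = 200
    n_control: int = 400
    vocab_size: int = 2_000
    background_law: float = 1.0  # Zipf exponent of background Pfam frequencies
    genes_per_40kb: float = 37.0
    gene_length_mean: float = 900.0
    gene_length_sd: float = 250.0
    anchor_pfam: str = "PF05147"
    control_anchor_pfam: str = "PF00365"
    cluster_pfams: list[ClusterPfam] = field(default_factory=list)
    planted: list[PlantedPfam] = field(default_factory=list)
    defence_rate_control: float = 0.03
    plasmid_rate: float = 0.0
    island_rate: float = 0.0
    # ("fixed", L) | ("uniform", lo, hi) | ("mixture", full_len, p_full, lo, hi)
    contig_length_law: tuple = ("mixture", 46_000, 0.9, 8_000, 44_000)
    pfams_per_gene_probs: tuple = (0.35, 0.40, 0.18, 0.07)

    def __post_init__(self) -> None:
        if self.n_test < 1 or self.n_control < 1:
            raise ValidationError("n_test and n_control must be >= 1")
        if self.gene_length_mean <= 0:
            raise ValidationError("gene_length_mean must be positive")
        period = 40_000 / self.genes_per_40kb
        if self.gene_length_mean >= period:
            raise ValidationError(
                f"density {self.genes_per_40kb}/40kb unachievable: mean gene "
                f"length {self.gene_length_mean} exceeds the mean period {period:.0f}")
        for p in self.planted:
            if not (0 <= p.p_test <= 1 and 0 <= p.p_control <= 1):
                raise ValidationError(f"planted {p.pfam}: probabilities outside [0, 1]")
        if abs(sum(self.pfams_per_gene_probs) - 1) > 1e-9:
            raise ValidationError("pfams_per_gene_probs must sum to 1")

    @property
    def defence_pfams(self) -> set[str]:
        return {p.pfam for p in self.planted
                if p.system_name and p.activity == "defence"}


def default_spec(n_test: int = 1_412, n_control: int = 3_148,
                 vocab_size: int = 4_000) -> SyntheticSpec:
    """The study-scale corpus: 1,412 anchored test regions vs 3,148 control
    regions, a 4,000-Pfam background vocabulary, and planted companion and
    defence Pfams at region-presence rates mirroring an empirical
    lanthipeptide-neighbourhood survey."""
    cluster = [
        ClusterPfam("PF03412", 5_000),   # peptidase C39 leader protease
        ClusterPfam("PF00005", 5_000),   # ABC transporter NBD
        ClusterPfam("PF13575", 5_000),   # DUF4135 dehydratase body
        ClusterPfam("PF16934", 5_000),   # mersacidin-like precursor
    ]
    planted = [
        PlantedPfam("PF01420", 0.0552, 0.0035, 10_000, "RM_Type_I", "defence"),
        PlantedPfam("PF04313", 0.0340, 0.0029, 10_000, "RM_Type_I", "defence"),
        PlantedPfam("PF07669", 0.0361, 0.0076, 10_000, "RM_Type_IIG", "defence"),
        PlantedPfam("PF05016", 0.0524, 0.0010, 10_000, "ParDE_TA", "defence"),
        PlantedPfam("PF06414", 0.0467, 0.0010, 10_000, "Zeta_TA", "defence"),
        PlantedPfam("PF18766", 0.0489, 0.0048, 10_000, "Anti-phage_helicase", "defence"),
        PlantedPfam("PF07275", 0.0120, 0.0010, 10_000, "ArdA", "anti-defence"),
        PlantedPfam("PF00589", 0.0913, 0.0349, 15_000),  # phage integrase
        PlantedPfam("PF00239", 0.0821, 0.0044, 15_000),  # resolvase
        PlantedPfam("PF00583", 0.1402, 0.0537, 15_000),  # GNAT acetyltransferase
    ]
    return SyntheticSpec(
        n_test=n_test,
        n_control=n_control,
        vocab_size=vocab_size,
        cluster_pfams=cluster,
        planted=planted,
        plasmid_rate=0.148,
        island_rate=0.108,
    )


@dataclass
class PlantedTruth:
    """Ground truth for planted Pfams: nominal rates and realised counts."""

    n_test: int
    n_control: int
    # pfam -> dict(p_test, p_control, nominal_or, test_hits, control_hits)
    per_pfam: dict[str, dict] = field(default_factory=dict)


@dataclass
class Corpus:
    """One generated corpus with its windows, annotations and ground truth."""

    spec: SyntheticSpec
    seed: int
    contigs_test: list[ContigAnnotation]
    contigs_control: list[ContigAnnotation]
    windows_test: list[AnchorWindow]
    windows_control: list[AnchorWindow]
    systems: list[DefenceAnnotation]
    islands: IntervalSet
    plasmid_contigs: set[str]
    truth: PlantedTruth


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    w = ranks ** -exponent
    return w / w.sum()


def _draw_contig_length(rng: np.random.Generator, law: tuple) -> int:
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    if kind == "mixture":
        full_len, p_full, lo, hi = law[1:]
        if rng.random() < p_full:
            return int(full_len)
        return int(rng.integers(lo, hi + 1))
    raise ValidationError(f"unknown contig_length_law {law!r}")


def _tile_genes(rng: np.random.Generator, spec: SyntheticSpec,
                contig_id: str, length: int) -> list[GeneFeature]:
    period = 40_000 / spec.genes_per_40kb
    gap_mean = period - spec.gene_length_mean
    n_est = int(length / period * 1.6) + 12
    lens = np.maximum(
        _MIN_GENE_LEN,
        np.rint(rng.normal(spec.gene_length_mean, spec.gene_length_sd, n_est)),
    ).astype(int)
    gaps = np.rint(rng.exponential(gap_mean, n_est)).astype(int)
    gaps[0] = gaps[0] % max(1, int(period))  # start offset inside one period
    starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lens[:-1])))
    ends = starts + lens
    keep = ends <= length
    genes = []
    for i in np.flatnonzero(keep):
        genes.append(GeneFeature(
            contig_id=contig_id,
            start=int(starts[i]),
            end=int(ends[i]),
            strand="+" if rng.random() < 0.5 else "-",
            gene_id=f"{contig_id}_g{i + 1:04d}",
        ))
    return genes


def _assign_background_pfams(rng: np.random.Generator, spec: SyntheticSpec,
                             genes: list[GeneFeature], vocab: np.ndarray,
                             probs: np.ndarray) -> None:
    n_per_gene = rng.choice(len(spec.pfams_per_gene_probs),
                            size=len(genes), p=spec.pfams_per_gene_probs)
    total = int(n_per_gene.sum())
    draws = rng.choice(len(vocab), size=total, p=probs)
    pos = 0
    for gene, n in zip(genes, n_per_gene):
        accs = vocab[draws[pos:pos + n]]
        pos += n
        merged = list(dict.fromkeys(list(gene.pfams) + [str(a) for a in accs]))
        gene.pfams = merged


def _nearest_gene(genes: list[GeneFeature], position: float,
                  exclude: set[str]) -> GeneFeature | None:
    best, best_d = None, None
    for g in genes:
        if g.gene_id in exclude:
            continue
        d = abs(g.midpoint - position)
        if best_d is None or d < best_d:
            best, best_d = g, d
    return best


def generate_corpus(spec: SyntheticSpec, seed: int) -> Corpus:
    """Generate one deterministic corpus from a :class:`SyntheticSpec`."""
    rng = np.random.default_rng(seed)
    probs = _zipf_probs(spec.vocab_size, spec.background_law)
    vocab = np.array([f"PF9{i:04d}" for i in range(spec.vocab_size)])

    truth = PlantedTruth(n_test=spec.n_test, n_control=spec.n_control)
    for p in spec.planted:
        truth.per_pfam[p.pfam] = {
            "p_test": p.p_test,
            "p_control": p.p_control,
            "nominal_or": p.nominal_odds_ratio,
            "test_hits": 0,
            "control_hits": 0,
        }

    systems: list[DefenceAnnotation] = []
    islands: dict[str, list[tuple[int, int]]] = {}
    plasmids: set[str] = set()

    def make_region(group: str, index: int) -> tuple[ContigAnnotation, AnchorWindow]:
        prefix = "SYNT" if group == "test" else "SYNC"
        contig_id = f"{prefix}{index + 1:06d}.1"
        genes: list[GeneFeature] = []
        length = 0
        while len(genes) < 5:  # degenerate tilings are redrawn
            length = _draw_contig_length(rng, spec.contig_length_law)
            genes = _tile_genes(rng, spec, contig_id, length)
        _assign_background_pfams(rng, spec, genes, vocab, probs)

        anchor_acc = spec.anchor_pfam if group == "test" else spec.control_anchor_pfam
        anchor = _nearest_gene(genes, length / 2, set())
        anchor.pfams = [anchor_acc]
        anchor_mid = anchor.midpoint

        if group == "test":
            for cp in spec.cluster_pfams:
                host = _nearest_gene(
                    [g for g in genes if abs(g.midpoint - anchor_mid) <= cp.max_distance],
                    anchor_mid + rng.uniform(-cp.max_distance, cp.max_distance),
                    {anchor.gene_id},
                )
                if host is not None and cp.pfam not in host.pfams:
                    host.pfams = host.pfams + [cp.pfam]

        for p in spec.planted:
            prob = p.p_test if group == "test" else p.p_control
            if rng.random() >= prob:
                continue
            side = 1 if rng.random() < 0.5 else -1
            target = anchor_mid + side * rng.uniform(0, p.max_distance)
            host = _nearest_gene(genes, float(np.clip(target, 0, length)),
                                 {anchor.gene_id})
            if host is None:
                continue
            if p.pfam not in host.pfams:
                host.pfams = host.pfams + [p.pfam]
            key = "test_hits" if group == "test" else "control_hits"
            truth.per_pfam[p.pfam][key] += 1
            if p.system_name:
                systems.append(DefenceAnnotation(
                    contig_id=contig_id, system_name=p.system_name,
                    activity=p.activity, start=host.start, end=host.end,
                    gene_ids=[host.gene_id]))

        if group == "control" and rng.random() < spec.defence_rate_control:
            host = genes[int(rng.integers(0, len(genes)))]
            systems.append(DefenceAnnotation(
                contig_id=contig_id, system_name="Generic_defence",
                activity="defence", start=host.start, end=host.end,
                gene_ids=[host.gene_id]))

        if group == "test":
            if rng.random() < spec.island_rate:
                lo = max(0, anchor_mid - int(rng.integers(2_000, 15_000)))
                hi = min(length, anchor_mid + int(rng.integers(2_000, 15_000)))
                islands.setdefault(contig_id, []).append((lo, hi))
            if rng.random() < spec.plasmid_rate:
                plasmids.add(contig_id)

        contig = ContigAnnotation(contig_id=contig_id, features=genes, length=length)
        window = extract_window(contig, anchor.gene_id, group=group)
        return contig, window

    contigs_test, windows_test = [], []
    for i in range(spec.n_test):
        c, w = make_region("test", i)
        contigs_test.append(c)
        windows_test.append(w)
    contigs_control, windows_control = [], []
    for i in range(spec.n_control):
        c, w = make_region("control", i)
        contigs_control.append(c)
        windows_control.append(w)

    return Corpus(
        spec=spec, seed=seed,
        contigs_test=contigs_test, contigs_control=contigs_control,
        windows_test=windows_test, windows_control=windows_control,
        systems=systems,
        islands=IntervalSet(label="genomic_island", intervals=islands),
        plasmid_contigs=plasmids,
        truth=truth,
    )


def empirical_planted_or(truth: PlantedTruth) -> dict[str, float]:
    """Realised cross-product odds ratio per planted Pfam.

    Computed from the realised presence counts with the Haldane–Anscombe
    +0.5 correction when any cell is zero.
    """
    if not truth.per_pfam:
        raise ValidationError("empty planted truth")
    out = {}
    for pfam, info in truth.per_pfam.items():
        a = info["test_hits"]
        b = truth.n_test - a
        c = info["control_hits"]
        d = truth.n_control - c
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        out[pfam] = (a * d) / (b * c)
    return out


def write_corpus(corpus: Corpus, outdir: str | Path) -> dict[str, Path]:
    """Write the corpus as plain-text tables; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features_test": outdir / "features_test.tsv",
        "features_control": outdir / "features_control.tsv",
        "gff_test": outdir / "features_test.gff3",
        "gff_control": outdir / "features_control.gff3",
        "systems": outdir / "systems.tsv",
        "islands": outdir / "islands.tsv",
        "plasmids": outdir / "plasmid_contigs.txt",
        "truth": outdir / "truth.tsv",
    }
    write_feature_table(corpus.contigs_test, paths["features_test"], "feature_tsv")
    write_feature_table(corpus.contigs_control, paths["features_control"], "feature_tsv")
    write_feature_table(corpus.contigs_test, paths["gff_test"], "gff3")
    write_feature_table(corpus.contigs_control, paths["gff_control"], "gff3")
    write_defence_table(corpus.systems, paths["systems"])
    write_interval_table(corpus.islands, paths["islands"])
    with open(paths["plasmids"], "w") as fh:
        for cid in sorted(corpus.plasmid_contigs):
            fh.write(cid + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("pfam\tp_test\tp_control\tnominal_or\ttest_hits\tcontrol_hits\t"
                 "n_test\tn_control\n")
        for pfam in sorted(corpus.truth.per_pfam):
            info = corpus.truth.per_pfam[pfam]
            fh.write(f"{pfam}\t{info['p_test']:.6g}\t{info['p_control']:.6g}\t"
                     f"{info['nominal_or']:.6g}\t{info['test_hits']}\t"
                     f"{info['control_hits']}\t{corpus.truth.n_test}\t"
                     f"{corpus.truth.n_control}\n")
    return paths
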