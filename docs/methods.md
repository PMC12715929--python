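# Methods

## Window construction

Windows are anchored at the *midpoint* of the anchor gene and extend
`half_width` (default 20,000 bp) to each side, clipped to the contig:
`[max(0, mid − h), min(L, mid + h))`. The midpoint convention makes the
window symmetric around the anchor and gives multi-kilobase anchor genes no
directional bias. A gene is a window member iff its own midpoint
`⌊(start + end)/2⌋` lies inside the half-open interval — an unambiguous rule
for boundary-straddling genes. Truncated contigs are kept (windows of
2–40 kb are legal); a `min_span` filter is available but defaults to 0.
Coordinates are 0-based half-open internally; GFF3 and the tabular formats
are 1-based inclusive on disk and converted at the I/O boundary. Strand is
carried through but unused: all statistics are strand-free.

## Counting units

The occurrence table has one row per (gene, Pfam) pair. A domain repeated
on one protein counts once for that gene (per-gene de-duplication), but
every gene carrying it contributes an occurrence. Two summaries coexist
deliberately: gene-level occurrence counts `n_l` drive the permutation null
and the Z-score, while region-level presence counts `r_l` drive Fisher's
test, whose unit of evidence is the region. Accessions not matching the
`PF` prefix are dropped at table construction.

## Permutation null

Null hypothesis: Pfam identity is exchangeable across occurrence slots.
Each iteration redraws, for every region `r`, its `k_r` occurrences with
replacement from the pool with probabilities `f_l = n_l / N`. Since draws
are i.i.d. across regions, the per-Pfam total over all regions is
multinomial `(Σ k_r, f)`, which is how the null is simulated (chunked
multinomial draws; B = 10,000 by default). The empirical p-value is
`(b_l + 1)/(B + 1)` — never exactly zero, the standard permutation-test
pseudo-count — with BH adjustment across Pfams.

Pool choice matters. The default pool for a two-group analysis is the
combined test + control table (configurable to `test` or `control`). For
*calibration* runs the pool must be independent of the scored group: if the
pool is the scored table itself, `E[null count] = n_l = obs` by
construction and every p-value concentrates near 0.5. Calibration checks
therefore score the test group against the control pool.

A second caveat is intrinsic to discrete counts: with the `≥`-tie
exceedance rule the per-Pfam p-value is a step function, so the pooled
p-value distribution under a true null is *super-uniform* (conservative),
never exactly uniform. At realistic corpus sizes (≈ 35,000 occurrences over
a 1,000-Pfam Zipf(1) vocabulary) the rarest Pfams have expected counts
near 7 and point masses near 0.15, which places a Kolmogorov–Smirnov
distance of roughly 0.08–0.12 between the p-value distribution and the
uniform — entirely on the conservative side. The tests therefore assert the
two properties that matter for inference: the anticonservative excess
`sup_t (F̂(t) − t)` stays below 0.05, and the BH-significant fraction stays
at the nominal level. Exact two-sided uniformity is not attainable with
this estimator and is not claimed.

## Fisher test, odds ratios, multiplicity

Per Pfam the 2×2 region-presence table is tested with the two-sided exact
test (tables whose point probability does not exceed the observed one are
summed — verified in the tests against an exhaustive rational-arithmetic
hypergeometric enumeration to 1e-12). Bonferroni uses `m` = number of
Pfams tested by default; an external `m` can be supplied when the test
family is defined elsewhere. The *enriched* flag requires adjusted
p < α (0.05), positive proportion difference and odds ratio > 2.

The reported odds ratio is the sample cross-product `(ad)/(bc)` with the
Haldane–Anscombe +0.5 correction applied to all cells when any cell is
zero; its 95% CI is the Wald interval on `ln OR`. The exact-test
conditional MLE is available behind `or_estimator="conditional"` for users
who want the estimate matched to the test.

Pfams absent from every region of both groups are excluded with a warning
(their 2×2 is degenerate). BH tie-breaking follows the standard step-up
with monotone enforcement; input order is preserved.

## Z-score

With pool frequency `f_l` and group total `total_i`:
`m′ = total_i f_l`, `s′ = √(total_i f_l (1 − f_l))`, `Z = (obs − m′)/s′`.
`log1p(Z)` is reported for `Z ≥ 0` only; negative scores are left
untransformed (absent), since the transform exists to compress the upper
tail. Pfams with pool frequency 0 or 1 have zero variance and are skipped
with a warning. Expected counts conserve the group total
(`Σ_l m′ = total_i`) whenever no Pfam is skipped.

## Proximity and background odds

Distances are signed midpoint-to-midpoint offsets; a multi-gene system is
represented by the midpoint of its full span. "Within 10 kb" is a sharp
threshold on the absolute distance (configurable; 20 kb is the natural
alternative for whole-window membership). The defence-Pfam region filter
counts occurrence rows whose Pfam is in the defence set minus an exclusion
list (default: the promiscuous AAA-like domain PF13304, user-extendable)
and passes regions with ≥ 5 hits. Plasmid membership is contig-level;
island membership tests the anchor midpoint against half-open intervals.

The background comparison draws `n_samples` (default 200) control contigs
without replacement, takes 30 consecutive CDS from a uniform random start
index in each, and calls a sample positive iff any system midpoint falls in
the sampled span; the resulting presence count is compared against the test
group's in a 2×2 with sample OR, Wald CI and exact p. Contigs with fewer
than `k` CDS are skipped with a warning; too few eligible contigs is an
error, not a silent shrink.

## Subsampling trends

One seeded permutation of the regions is drawn and cumulative occurrence
counts are recorded at sizes 1..n_max (default 100); Spearman ρ (average
ranks, t-approximation p) relates size to count. Cumulative counting along
a single permutation — rather than independent redraws per size — is what
makes a ubiquitously present Pfam give ρ ≈ 1. Constant trajectories
(absent Pfams) yield an absent ρ with a "constant input" flag.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes, not
sequence content:

* **Coding density.** Genes are tiled with truncated-normal lengths
  (mean 900 bp, sd 250) and exponential gaps whose mean is chosen so the
  mean period is `40,000 / genes_per_40kb` (default 37 CDS per 40 kb, the
  empirical density of both study groups).
* **Background annotation.** Each gene carries 0–3 background Pfams
  (probabilities 0.35/0.40/0.18/0.07) drawn from a `PF9xxxx` vocabulary
  with Zipf(1) frequencies — the canonical heavy-tailed law for domain
  family abundance.
* **Structure.** Every test contig has exactly one anchor gene
  (PF05147) at its centre-most position plus companion cluster Pfams
  within 5 kb; control contigs are anchored on a neutral marker (PF00365).
  Planted Pfams are included per region with probabilities
  `p_test`/`p_control` and placed on the gene nearest a uniform random
  offset within `max_distance` of the anchor (default 10 kb, matching the
  observed concentration of defence systems near anchors). Planted defence
  Pfams emit DefenseFinder-style system annotations; control regions
  additionally carry a generic defence system at rate 0.03 (the 6/200
  background rate). Plasmid and island labels are assigned to test regions
  at rates 0.148 and 0.108.
* **Contig lengths.** A 90/10 mixture of full-length (46 kb) and truncated
  (8–44 kb uniform) contigs, so truncated windows are exercised routinely.
* **Determinism.** One `numpy.random.Generator` seeded from the single
  corpus seed drives everything; identical seeds give byte-identical
  output files.

What the generator does *not* emulate: phylogenetic correlation between
regions (real windows from related strains are not independent),
intra-genome Pfam co-occurrence structure beyond the planted effects,
operonic orientation, and annotation noise (missed or spurious domain
calls). Passing recovery tests therefore demonstrate statistical
correctness of the pipeline under independence, not robustness to
population structure — on real data the effective sample size is smaller
than the region count and p-values are optimistic in proportion.

## Pipeline determinism and problem sizes

Each stage derives its sub-seed as `seed XOR crc32(stage_name)` (kept below
2³¹), so stages are independently reproducible and a full re-run is
byte-identical. Test suites run on corpora of 50–1,000 regions with
B = 200–2,000 permutations; the acceptance script uses the full
1,412/3,148-region design with B = 10,000 and a 1,000-region null corpus
with B = 2,000 — sizes at which every stage completes in seconds on one
core while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The permutation null treats regions as independent and occurrence slots
  as exchangeable; clustered duplications within a region inflate
  significance.
* The Wald CI on the odds ratio is a large-sample approximation; with very
  sparse cells the Haldane correction biases the point estimate toward the
  null but keeps it finite.
* The `≥ 5 defence Pfams` filter counts occurrences, not distinct systems;
  a single large system can satisfy it.
* Empirical p-values are bounded below by `1/(B + 1)`; ranking below that
  resolution requires the Z-score or Fisher columns.
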