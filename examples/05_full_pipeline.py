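"""Run the whole pipeline from files, the way a shell user would.

Writes a corpus to disk, builds a RunConfig and calls run_full_analysis —
equivalent to `locus-colocal run --config run.yaml`.  All outputs are TSV
tables plus a JSON manifest; re-running with the same seed reproduces them
byte for byte.
"""

import tempfile
from pathlib import Path

from locus_colocal import RunConfig, default_spec, generate_corpus, run_full_analysis, write_corpus

workdir = Path(tempfile.mkdtemp(prefix="locus_colocal_demo_"))
corpus_dir = workdir / "corpus"
spec = default_spec(n_test=80, n_control=160, vocab_size=600)
write_corpus(generate_corpus(spec, seed=8), corpus_dir)

config = RunConfig(
    features_test=str(corpus_dir / "features_test.tsv"),
    features_control=str(corpus_dir / "features_control.tsv"),
    systems=str(corpus_dir / "systems.tsv"),
    islands=str(corpus_dir / "islands.tsv"),
    plasmids=str(corpus_dir / "plasmid_contigs.txt"),
    outdir=str(workdir / "results"),
    permutations=1_000,
    background_n=60,
    subsample_n=80,
    defence_pfams=sorted(spec.defence_pfams),
    seed=9,
)
manifest = run_full_analysis(config)

print(f"windows: {manifest['n_windows_test']} test / "
      f"{manifest['n_windows_control']} control")
print(f"enriched Pfams: {manifest['n_enriched']}")
print(f"regions passing the defence-Pfam filter: "
      f"{manifest['n_defence_filter_regions']}")
print("outputs:")
for name, path in sorted(manifest["outputs"].items()):
    print(f"  {name:<16} {Path(path).name}")
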