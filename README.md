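# temob

A toolkit for quantifying transposable-element (TE) mobilization from
sequencing alignments, with a fully synthetic test bed. It covers four
analyses that together trace a TE derepression event from small-RNA loss to
germline genome invasion:

* **smallrna** — classify small-RNA alignments into piRNA candidates
  (23–30 nt) and siRNA candidates (21 nt), annotate them against
  cluster/TE/3'UTR intervals (excluding rRNA/miRNA), re-assign candidates to
  canonical TE families, count fractionally (1/k over ex-aequo assignments)
  and normalize to the unique mappers of a designated germline piRNA cluster
  ("cluster1"). Also: per-size sense/antisense distributions, 5'-nucleotide
  bias, log2 fold changes and Spearman correlations.
* **mobilome** — quantify eccDNA reads: best-score TE assignment, re-mapping
  against canonical TE sequences, a score floor (alignments scoring strictly
  below −10 under a 0-is-perfect convention are discarded), 1/k down-weighting
  of ex-aequo hits and normalization per thousand mitochondrial reads.
* **insertion** — call de novo TE insertions from paired-end genomic
  alignments using soft-clipped reads and one-end-anchored (OEA) pairs:
  single-linkage positional clustering, local alignment of cluster queries
  against a library of 600-nt TE terminal segments (truncated to an
  insert-size cap of ~500 nt), and a second clustering step that defines the
  breakpoint.
* **compare** — family-aware windowed (±20 nt) intersection of call sets,
  per-family de novo insertion ratios between conditions (the false-positive
  control: artefactual TE–genome chimeras are equally abundant in
  coverage-matched libraries, so their ratio is ~1 while real insertions push
  it up), and coverage-matched random subsampling (44× by default) with
  per-family means.
* **rates** — transposition-rate arithmetic (new insertions per pre-existing
  copy per generation), Poisson probabilities of observing insertions across
  generations and individuals, compound copy-number growth, and TE-load fold
  changes with Shapiro/t-test statistics.
* **synthetic** — a deterministic toy-genome and read-library simulator
  (small-RNA, WGS with planted insertions and chimeric artefacts, mobilome
  circles + mtDNA background) that emits alignment records directly, with
  ground-truth tags, so the full pipeline is testable offline.

Coordinates are 0-based half-open internally (BED-style); SAM I/O is 1-based
via pysam.

## CLI

Everything is reachable through the `temob` entry point:

```bash
# simulate a toy genome plus libraries (config is a JSON file; see tests/test_cli.py)
temob simulate genome   --config cfg.json --seed 1 --out toy/
temob simulate smallrna --config cfg.json --seed 1 --out toy/
temob simulate wgs      --config cfg.json --seed 1 --out toy/ --coverage 30
temob simulate mobilome --config cfg.json --seed 1 --out toy/ --n-reads 2000

# analyses
temob smallrna count --sam toy/smallrna.sam --genome-dir toy/ --out counts.tsv
temob smallrna foldchange --table-a a.tsv --table-b b.tsv --out fc.tsv
temob mobilome count --sam toy/mobilome.sam --genome-dir toy/ --out mob.tsv
temob callins --sam toy/wgs.sam --te-fasta toy/te_library.fa --out calls.tsv \
    --min-support 2 --min-clip 20 --identity 0.9
temob compare unique --calls-a a.tsv --calls-b b.tsv --out-prefix cmp
temob compare ratio  --calls-a a.tsv --calls-b b.tsv --out ratio.tsv

# rate arithmetic
temob rates transposition --denovo 1 --preexisting 4
temob rates patleastone --rate 4e-6 --generations 2 --individuals 12
temob rates load --table load.tsv --baseline noKD --out out.tsv
```

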