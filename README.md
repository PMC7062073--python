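# mitoskew

Mitogenome architecture statistics, AT/GC strand-asymmetry (skew)
profiling, circular gene-order comparison, NCR scanning for residual tRNA
anticodon hairpins, and a synthetic-data wing for demonstrating
compositional long-branch attraction (LBA) under different outgroup
strategies.

## What it does

- **annotation** — read/write annotated circular mitogenomes (GenBank flat
  files, a compact tab-separated organisation-table dialect, FASTA);
  extract oriented feature sequences with origin-wrap handling; gene-name
  canonicalisation across GenBank dialects. A worked example annotation
  (the *Asotana magnifica* mitogenome organisation table) ships with the
  package (`mitoskew.annotation.load_example_annotation()`).
- **architecture** — signed spacer/overlap records on the circular
  coordinate system, non-coding-region catalogs, circular signed gene
  orders with rotation-invariant equality, breakpoint distances and
  gene-order uniqueness reports.
- **skew** — AT skew `(A−T)/(A+T)` and GC skew `(G−C)/(G+C)` at
  whole-genome / strand-class / gene / codon-position resolution, plus a
  pattern classifier (crustacean-type: positive AT, negative GC on the
  majority strand; inverted-type: the mirror; with a configurable
  dead-zone).
- **ncrscan** — scan non-coding regions (with flanks into neighbouring
  genes) on both strands for minimal anticodon arms: a 7-nt loop with a
  known anticodon at loop positions 3–5 closed by a Watson–Crick/GU stem.
- **synthetic** — simulate annotated mitogenomes with exact template
  architecture and controllable skew targets, and multi-taxon alignments
  under a composition-biased replacement model in which designated
  lineages converge on homoplastic base compositions.
- **lba** — p-distance and LogDet (paralinear) matrices, deterministic
  neighbor joining, clade and Robinson–Foulds tests, and a seeded
  replicate experiment measuring how often homoplastic-composition taxa
  unite as a clade under three outgroup strategies (none / single
  composition-matched outgroup / many outgroups).

## Command line

```sh
mitoskew arch stats annotation.tsv              # spacers, NCRs, summary counts
mitoskew arch order a.tsv b.tsv                 # orders + breakpoint matrix
mitoskew skew profile annotation.tsv --fasta genome.fasta
mitoskew ncr scan annotation.tsv --fasta genome.fasta
mitoskew simulate genome --seed 3 --out simdir  # TSV + FASTA
mitoskew simulate alignment --config cfg.json --out alndir
mitoskew lba run --replicates 200 --length 2000 --seed 0 --out lba.json
mitoskew report annotation.tsv --out reports/   # TSV + JSON bundle
```

Annotation inputs are either GenBank flat files (`.gb`/`.gbk`) or the
tab-separated organisation-table dialect with columns
`gene from to size IGR start stop anticodon strand` (1-based inclusive
coordinates; negative IGR = overlap). Printed `size`/`IGR` columns are
cross-validated but recomputed values are authoritative; discrepancies are
reported as warnings.

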