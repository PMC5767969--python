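# cdpsmine

Genome mining for cyclodipeptide synthases (CDPSs). Given prokaryotic
nucleotide genomes (FASTA/GenBank) or pre-called proteins, the pipeline:

1. detects CDPSs with a profile HMM (local Viterbi scoring in bits, seed
   self-score calibrated cutoffs),
2. classifies each hit into the NYH / XYP / SYQ subfamilies by competing
   subfamily models,
3. extracts the P1/P2 substrate-binding pocket residues by profile
   alignment to a reference alignment anchored on an AlbC-style row,
4. predicts the two aminoacyl-tRNA substrates with a categorical naive
   Bayes classifier (strict and physicochemically relaxed evaluation,
   fold enrichment over random expectation),
5. assembles the surrounding gene cluster (±2.5 kb windows, merged when
   overlapping) and annotates tailoring/resistance domains with a
   packaged HMM library,
6. emits predicted cyclodipeptide structures: the 2,5-diketopiperazine
   scaffold plus combinatorial tailoring libraries (RDKit reaction
   transforms for the six cyclodipeptide-specific tailoring enzymes),
   scored against known compounds by ECFP6/Tanimoto,
7. maps unique CDPSs into a sequence similarity network (internal
   Smith–Waterman + Karlin–Altschul E-values, edges at 1e-100) with
   named connected-component families.

A first-class `fixtures` module generates synthetic inputs with
machine-readable truth (planted-motif families, labeled training tables,
synthetic genomes embedding clusters), so everything is buildable and
testable offline. No curated CDPS sequence data is bundled: packaged
pocket/physicochemical data files are clearly labeled placeholders, and
the demo/validation assets are synthetic.

## CLI

```sh
# generate a synthetic survey (seed alignments, genomes, truth tables)
cdpsmine simulate --out sim/ --seed 0 --n-genomes 20

# build the model bundle from seed alignments
cdpsmine build-models --seeds sim/seeds --out bundle.json --margin-bits 150

# scan genomes; writes per-genome JSON (exit 3 when no CDPS is found)
cdpsmine scan sim/genomes/*.fasta --bundle bundle.json --out scan/

# similarity network from scan results (edge list, GraphML, node table)
cdpsmine network scan/ --out net/

# leave-one-out validation of every stage on synthetic fixtures
cdpsmine validate --seed 0 --out report.json
```

Every results directory contains a `resolved_config.json` with the
tool version, model hashes and parameters, so runs are reproducible.

## Conventions

- Internal coordinates are 0-based half-open; all emitted GFF3 is
  1-based inclusive.
- HMM scores are log2-odds bits against a uniform background; detection
  cutoffs are `min(seed self-scores) - margin` (default margin 10 bits;
  use a larger margin for divergent seed sets).
- E-values are carried in log10 space (BLOSUM62, gap open 11 / extend 1,
  pinned Karlin–Altschul parameters recorded in output metadata).
- Tailoring transforms are curator-editable defaults; site-ambiguous
  reactions enumerate all placements up to a library cap of 64.
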