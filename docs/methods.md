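# Methods

This note documents the models implemented in `nx1seq`, the assumptions
behind them, the defaults of the synthetic-data generator, and the numerical
and design choices a maintainer would want to know about.

## The assay being modelled

A microwell slide (default 160,000 wells of ~20 pL) is loaded first with
barcoded oligo-dT capture beads (one bead per well, enforced mechanically and
treated as deterministic here), then with a dilute cell suspension that
settles by gravity. Cells lyse in place; each cell's mRNA hybridizes to the
co-resident bead, whose oligos all carry the same random 12-nt barcode.
After reverse transcription, amplification and sequencing, read 1 of each
pair begins with the 12-nt cell barcode followed by fixed primer sequence,
and read 2 is cDNA fragment sequence. There are no UMIs in this chemistry:
the package counts reads ("tags") per (barcode, gene), which is why
`normalize_tags` exists and why counts are not collapsed by position.

## Bead barcode library

Barcodes are modelled as i.i.d. uniform draws from the 4^12 = 16.8M
12-mer space. For a library of n beads the per-bead collision probability is

    E[collision fraction] = 1 - (1 - 1/4^12)^(n-1)   (~6.0e-4 at n = 10,000)

`collision_fraction` measures the realized fraction in a sampled library;
the library-QC acceptance bound is 2%. The mechanistic source of real
barcode overlap (multiple template molecules in one emulsion-PCR droplet) is
not modelled; the uniform model is the stated acceptance surface. The
`build_capture_sequence` helper documents the 123-nt oligo layout (36-nt 5'
anchor, 25-nt poly-A, barcode, 50-nt 3' anchor) without simulating the
post-digestion single-stranding chemistry.

## Poisson loading

With n cells over w wells, per-well occupancy is binomial(n, 1/w), which at
w = 160,000 is Poisson with mean λ = n/w to excellent accuracy. The quantity
of interest is cell-centric: the probability that a *deposited cell* has its
well to itself. Size-biasing gives exactly e^-λ (the tagged cell's well holds
Poisson(λ) additional cells); the finite-population form is
(1 - 1/w)^(n-1). At the working ratio of 1:20 (λ = 0.05) the singlet
fraction is e^-0.05 = 0.9512, i.e. 95% to the nearest percent. The
alternative well-centric reading (fraction of occupied wells that are
singlets, ~97.5% at this λ) does not reproduce the stated 95% and is not
used. `simulate_loading` also applies Bernoulli thinning for the measured
90% seeding efficiency; bead occupancy is assumed complete.

## Demultiplexing and counting

* **Barcode extraction** takes the 12-nt prefix of read 1. Against a
  whitelist, `max_mismatch=1` rescues a read iff exactly one whitelist entry
  lies within Hamming distance 1; ambiguous rescues and reads containing N
  are rejected with distinct reasons, and the run report keeps a read
  conservation ledger (assigned + unassigned + rejected = total).
* **Gene assignment** is either (a) SAM mode: primary mapped records from an
  external aligner, with reads whose mapped records span more than one
  reference treated as ambiguous and discarded (multi-mapped reads are not
  fractionally assigned), or (b) toy mode: exact-substring search against a
  small transcriptome, unique hit required. The toy aligner exists so the
  whole pipeline is testable hermetically; it is seeded by a 25-mer index
  and is exact, not heuristic, on the generator's references.
* **Cell QC** keeps barcodes with *more than* 20,000 reads and *more than*
  400 detected genes (strict inequalities; boundary barcodes are dropped).
  Without a whitelist, top-N selection by read count (ties broken
  lexicographically) and a log-scale knee heuristic are provided, since the
  original cell-selection rule is not published.
* **Normalization** rescales each retained cell to 300,000 total tags,
  keeping fractional values so row sums are exact to 1e-6 relative. The
  processing order is QC → normalize → classify and is recorded in the run
  report.

## Species mixing (barnyard)

Per-barcode totals are split by a gene→species map (species-prefixed gene
ids by default). A barcode is called single-species when that species holds
at least the purity threshold of its reads; the default threshold is 0.9, a
conventional choice exposed in config because no threshold is published for
the original scatter. Zero-read barcodes have undefined purity and are
reported separately as mixed.

## Marker-rule classification and the EMT trichotomy

"Positive" means normalized tags ≥ a single global threshold, default 1 tag
(inclusive boundary). Cell classes are small any-of/all-of marker rules
applied in a configured priority order; multi-matches are logged and
resolved by priority. Among cancer cells, positivity for the epithelial set
with none of the mesenchymal set gives EA; the reverse gives EA_EMT; both
give EA_intEMT; neither gives "none" — an exhaustive, mutually exclusive
partition. The default partition of the eight screen markers is epithelial =
{EPCAM, CDH1}, mesenchymal = {ACTA2, VIM, FN1, ZEB1, THY1, CD44}. The
source material lists the eight markers without assigning them; CD44 and
THY1 are also stem-cell markers and their placement on the mesenchymal side
is a package decision, kept in config rather than code.

## Side-comparison tables

`side_table` counts positive cells per gene on each of two sides and reports
integer percentages (half rounded up) and fold ratios at one decimal. The
fold direction is an explicit parameter: the bundled published table uses
E-over-M for its spheroid-signature half and M-over-E for its serum-culture
half, a direction split verified arithmetically row by row (all 54 rows with
a nonzero denominator reproduce at one decimal). Zero-denominator folds are
reported as NaN; the published table itself is inconsistent in those cells
(one such row prints 1.0, another 0.0), so neither convention is mimicked.
The comparison population (e.g. 305 vs 180 estimated cancer cells) is an
input, not something the module guesses.

## Statistics

* Mann-Whitney U from midranks; exact mode enumerates all C(n1+n2, n1)
  labelings (auto-selected at n1+n2 ≤ 16, ≤ 12,870 labelings), with the
  two-sided p defined symmetrically around the null mean. The asymptotic
  mode uses the tie-corrected variance and a 0.5 continuity correction.
  The approximation tracks the exact p to ~0.01 for balanced untied samples
  at the switchover size; for heavily tied or very small samples the two
  can differ substantially at mid-range p, which is why exact mode is the
  default there.
* Benjamini-Hochberg q-values delegate to statsmodels' step-up
  implementation behind the module surface.
* `pearson_log` is Pearson correlation of log(x + 1); the +1 pseudocount is
  a package default (the transform's offset is not published).

## Synthetic-data generator

The generator is the test bed for every downstream claim, and its defaults
encode the study conditions:

* **Transcriptomes** — random A/C/G/T sequences, default 400–600 nt, with a
  guarantee that no 25-mer is shared between genes (offending sequences are
  re-drawn), making exact-substring assignment collision-free for ≥25-nt
  reads. Species namespaces are gene-id prefixes.
* **Cell populations** — each cell draws a class, side and species; marker
  genes are positive with the class's specified probability (positive cells
  get 1 + Poisson(19) fragments by default, negatives exactly 0, so
  positive fractions are exact by construction); all other same-species
  genes get Poisson(2) background. The bundled two-side tumor spec uses
  1,000 cells per side (the analyzed population size), a cancer/T/macrophage
  mix with higher T-cell infiltration on the M-side, and a
  spheroid-signature gene positive in 48% of E-side vs 31% of M-side cancer
  cells (the published template row). The barnyard spec is a ~1:1
  human/mouse mixture with a 5% doublet rate.
* **Reads** — read 2 starts uniformly in the final 300 nt of the transcript
  (3' bias of oligo-dT capture) with default length 75 nt; read 1 is
  barcode + 31-nt primer anchor. Errors are i.i.d. substitutions; indels,
  PCR duplication and quality-score structure are not modelled. Read
  lengths and the exact read-1 composition after the barcode are config
  defaults, not published values.

What passing tests on this generator show: the pipeline's bookkeeping is
exact (error-free data round-trips to the truth matrix bit-for-bit), its
error handling matches the stated rules, and its statistics agree with
independent oracles. What they do not show: robustness to real-data
artifacts absent from the generator — ambient RNA, barcode synthesis bias,
alignment ambiguity on real transcriptomes, PCR duplicates.

## Problem sizes

The bundled test suite and the reproduction script run at desk scale chosen
to exercise the mathematics, not the throughput: 60–800 synthetic cells,
200-gene two-species references, 200 loading replicates of 8,000 cells into
160,000 wells, and 100 replicate barcode libraries of 10,000 beads. The
loading and collision results are scale-exact (closed forms are evaluated at
the protocol's true operating point); only the FASTQ volumes are reduced.

## Known limitations

* The emulsion-PCR droplet mechanism behind real barcode overlap is not
  modelled; the <2% figure is checked against the uniform-sampling surrogate.
* The toy aligner requires exact substrings; it is not a general aligner and
  is not intended to replace one on real reads.
* Hierarchical clustering (`cluster_cells`) is a thin, deterministic
  convenience (log2(1+x), configurable metric/linkage); embedding methods
  such as t-SNE are deliberately out of scope.
* `knee_threshold` is a simple steepest-log-drop heuristic, provided because
  the original cell-selection rule is unpublished; prefer a whitelist or
  explicit top-N when ground truth is available.
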