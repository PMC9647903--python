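# Methods

This note documents the models and conventions implemented in `krabzfp`,
the choices made where a convention had to be fixed, and what the synthetic
families do and do not establish about real data.

## Cluster model

A cluster is a maximal run of same-chromosome genes in which every pair of
neighbours (sorted by start) lies within `max_gap` base pairs, with at
least `min_size` members. Defaults are `max_gap = 200000` and
`min_size = 2`, the standard operational definition for KRAB-ZFP families.
Strand is ignored. The gap is measured end-of-previous → start-of-next by
default — the strictest interval reading, under which overlapping or
book-ended genes always co-cluster; `start_to_start` and `midpoint`
metrics are provided because published censuses rarely state the metric,
and the choice should be probed when reproducing one. Cluster ids are
assigned 1..N in (chromosome lexicographic, span start) order; with more
than nine chromosomes, zero-padded names (`chr01`) keep lexicographic and
numeric order aligned. Input coordinates are 1-based inclusive
(genome-browser convention); BED exports are 0-based half-open.

## Tile model and fingerprints

Each protein is decomposed by a greedy leftmost non-overlapping scan for
the C2H2 pattern `C-X{a}-C-X{b}-H-X{c}-H`. The default is the exact
21-residue form (a,b,c) = (2,12,3); ranges such as (2–4, 10–14, 3–5) are
supported for real proteins, where spacer lengths vary. Within a range the
shortest spacer is preferred (lazy matching), a deterministic tie-break.
Two overlapping tile sets result: ZnF tiles are the matches themselves
(CXXC→HXXXH); linker tile *i* runs from the first zinc-coordinating His of
ZnF *i* through the inter-finger linker to the second Cys of ZnF *i+1*
(HXXXH→CXXC), so `n_linkers = n_znfs − 1`. Tiles map to the CDS as
`cds[3(a−1) .. 3b]` for protein span `[a, b]`; no intron handling is
needed because inputs are CDS, not genomic sequence.

The fingerprint is the residue triplet at α-helix positions −1, +3 and +6,
the primary determinant of a finger's DNA-triplet preference. With the
first His at helix position +7, these sit at offsets H1−8, H1−4, H1−1
within the tile. Anchoring on the His rather than on fixed tile offsets
keeps the definition valid for any C→H spacer length. This is one of
several conventions in circulation; the synthetic generator uses the same
one, so all recovery tests are self-consistent, but fingerprint strings
from other pipelines may be shifted by one position and should not be
compared letter-for-letter without checking the anchor.

Genes whose proteins contain no pattern match are retained with empty
annotations (they still count in cluster censuses) and flagged.

## Conservation profiles and PAM discovery

For a stack of same-type tiles, per-position letter frequencies are
computed and the information content is `ic[p] = log2(|Σ|) − H(freqs[p])`
(base-2 Shannon entropy, zero-frequency letters contributing zero), giving
at most 2 bits for nucleotides and log2 20 ≈ 4.32 bits for amino acids.
No small-sample correction is applied — profiles here are compared across
selections of similar depth, not used as absolute logo heights.
Variable-length tiles are reduced to the modal length (ties to the
shorter), with the discarded count reported; no alignment is attempted,
because ungapped stacking is the only reproducible choice absent a stated
alignment procedure.

A conserved PAM is any offset `o` in a nucleotide linker profile where the
G frequency at both `o+1` and `o+2` reaches `min_g_freq` (default 0.8; the
threshold is a package choice, exposed as a flag, since "conserved" dots
on a logo are inherently qualitative). The N position is unconstrained and
overlapping sites are all reported.

## sgRNA design

Candidates are enumerated on the coding strand only: linker tiles are
defined on the coding frame, and the conserved PAMs are read from
coding-strand profiles. For every NGG whose triplet starts inside a linker
tile, the 20 nt immediately 5′ of the N — taken from the gene's full CDS,
so the window may cross into the preceding ZnF tile — form the
protospacer. PAMs with fewer than 20 nt of upstream CDS are skipped and
logged. Identical protospacers merge; `design_frequency` counts their
source windows, and ranking is by frequency descending with lexicographic
tie-break, so `select_top(k)` is deterministic.

Cut-site prediction searches each CDS on **both** strands (cleavage is
strand-agnostic) for protospacer followed immediately by NGG. The default
is exact matching — "predicted cleavage site" means a perfect protospacer
match with canonical PAM; a mismatch tolerance (protospacer only, PAM
always exact) exists for exploration. NAG and other non-canonical PAMs
are out of scope. The search space is the provided gene set, not a whole
genome: the specificity question answered is "of the sites within this
gene family, how many lie in the target cluster(s)?" — genome-wide
off-target search is a different problem with dedicated tools.
The specificity matrix aggregates sites by the harbouring gene's cluster
(plus an `unclustered` column); a candidate with zero total sites reports
its on-target fraction as NaN, not 0.

## Expression selection

Thresholding is inclusive (`TPM >= t`), with 25 the conventional cutoff
for strong expression in cultured cells and 4 a workable cutoff in tissue
panels. TPM values are consumed as given; quantification from reads is
out of scope. A cluster is called "highly expressed" when its
expressed/total ratio strictly exceeds a cutoff (default 0.5).

## The synthetic family generator

The generator emits gene tables, protein/CDS FASTA, a TPM table and a
ground-truth record that are cross-consistent by construction and audited
by `truth_check` (translation is re-verified through Biopython, an
independent route from the generation code).

What it emulates, and how:

* **Layout.** Clusters are placed round-robin across chromosomes with
  member gaps drawn uniformly from 5–150 kb (safely under the 200 kb
  rule); successive clusters and isolated genes are separated by ≥ 2 Mb.
* **Arrays.** Each gene is N-flank + alternating ZnF/linker + C-flank,
  4–8 fingers by default. Flanks and ZnF interiors avoid Cys/His so the
  planted tiling is provably the unique leftmost scan result.
* **Fingerprints.** Each cluster draws a private pool (default 6 triplets,
  weights 0.35/0.25/0.15/0.12/0.08/0.05), reused across members — high
  within-cluster frequency, exact exclusivity answers. Isolated genes get
  their own small pools.
* **Linkers.** A fixed 14-aa consensus (HXXXH + spacer + CXXC, 42 nt) with
  codons chosen so exactly two GG dinucleotides exist, yielding NGG PAMs
  at offsets 24 and 33 — both with their full 20-nt windows inside the
  linker. Five spacer/HXXXH positions vary per cluster; uniqueness is
  enforced at the amino-acid level on the two positions covered by both
  guide windows, so no synonymous change can turn one cluster's guide
  into another's.
* **Noise.** `synonymous_wobble_rate` (default 0.10) varies codons outside
  linker tiles, keeping the protein fixed and linker nucleotides intact —
  this mirrors the empirical pattern of diverse ZnF nucleotide sequence
  against near-identical linker DNA. `linker_mutation_rate` (default
  0.01, i.e. "almost identical" within a gene and "fairly conserved"
  within a cluster) substitutes linker codons synonymously, under
  constraints that preserve the planted GG set; the per-codon probability
  is `1 − (1 − rate)^3`. Restricting linker noise to synonymous changes is
  a deliberate simplification: it keeps every planted tile detectable at
  all rates, so noise-response tests measure conservation decay rather
  than annotation dropout.
* **Reproducibility.** One `numpy` Generator seeded once; every stochastic
  decision draws from it unconditionally (draw-then-decide), so runs at
  different noise rates from one seed have nested mutation sets — mean
  linker information content and planted-guide frequency are monotone in
  the rate by construction, and same-seed runs are byte-identical.
* **Expression.** Background TPM is uniform 0–3; each cluster is planted
  "high" in one sample with per-member penetrance 0.6 and TPM uniform in
  40–60, so inclusive thresholding at 25 recovers the planted set exactly.

What passing on synthetic data does **not** show: real KRAB-ZFP proteins
have degenerate C2H2 spacing, Cys/His residues outside fingers, pseudogenes
and truncated arrays; real linkers diverge non-synonymously and real
paralogs share fingerprints across clusters; real expression is not
bimodal. Synthetic recovery validates the algorithms' correctness against
their definitions, not their robustness to annotation noise in any
particular genome release.

## Problem sizes

The default family (14 genes, ~90 fingers) keeps every stage well under a
second; oracle-equivalence tests use 200 randomized cases per operation at
up to ~5 kb of CDS, and the whole suite runs in a few seconds on one core.
These sizes were chosen because every statistic tested is already fully
determined at this scale; the pipeline itself is linear in total CDS
length and handles family sizes in the hundreds (the realistic range)
without any special handling.

## Known limitations

* Exact-match cut-site prediction understates activity of guides
  tolerating mismatches; the mismatch flag exists but no activity model
  (e.g. CFD/MIT scores) is included.
* Off-modal-length tiles are excluded from profiles rather than aligned.
* Gene coordinates are treated as opaque intervals; whether they denote
  gene bodies or CDS spans does not affect any computation here beyond the
  gap metric.
* The pipeline does not construct phylogenies or render heatmaps/logos;
  exports are formatted for standard external tools.
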