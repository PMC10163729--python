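# Methods

## Scope and model

`umicollide` studies one question: when does adding exogenous UMIs to a
duplex-consensus variant-calling workflow improve performance over
grouping reads by fragment mapping position alone? The answer hinges on
two quantities — the molecular count per locus (how many input
molecules were sequenced) and the collision rate (how often distinct
molecules share fragment coordinates). Both are modeled explicitly.

### Detection model

`N_alt ~ Binomial(N, VAF)` for `N` sequenced molecules overlapping a
locus. Detection with support threshold `k` has probability
`P(N_alt ≥ k)`, evaluated exactly through the binomial survival
function (scipy; log-space internally, safe for `N ≥ 1e5`; no Poisson
approximation). The model assumes every library molecule is sequenced
at least once — the regime a UMI workflow targets, enforced in the
simulator by ~5 reads/molecule. `required_molecules` inverts the model
by bracket-and-bisect on the monotone `N → P` map, returning the exact
smallest `N`. Percentages shown to users are rounded to the nearest
integer percent; raw fractions are kept internally.

### Molecular count

`N = 300 × Input(ng) × LCR`, linear in both factors, with 300 genome
equivalents per ng of human dsDNA. In the simulator this expectation
feeds a Poisson draw for the **total** molecule count over the panel;
per-locus coverage is this total divided by the number of panel loci
(each fragment is anchored on one uniformly chosen locus). Analyses
that compare against the detection model therefore always use the
*empirically measured* per-locus consensus-molecule counts rather than
the configured expectation, keeping the two bookkeeping conventions
from ever meeting in a number.

## Synthetic libraries

The generator emulates a hybridization-capture duplex experiment:

- **Panel.** Deterministic, evenly spaced loci with interleaved variant
  classes; the default mirrors a clinical-style design of 110 loci
  (70 SNVs, 20 deletions, 20 insertions) across a 46 kbp interrogated
  span. Indels are atomic alleles at their anchor position (the panel
  is locus-targeted; no realignment).
- **Fragmentation.** `random_shear` (FF, FFPE): length ~
  Normal(mean, sd) truncated at 50 bp, locus uniform within the
  fragment. `nucleosomal` (cfDNA): both endpoints near the linker cuts
  of a fixed, single-phase nucleosome grid with period
  147 (core) + 38 (linker) bp, Gaussian jitter (sd 5 bp) and rare
  intra-core cuts (1%). Fragments are single mono-nucleosome units
  (mean 185 bp vs ~170 bp in real cfDNA); only the restricted
  fragment-edge support matters for collisions, not the exact length.
  Linker length and jitter are not published quantities; the defaults
  are tunable and were chosen once to give a restricted endpoint
  support, which is what produces the cfDNA ≫ FF/FFPE collision
  ordering.
- **Genotypes.** Each molecule carries the alternative allele
  independently with probability `VAF` at every covered locus
  (two-sample mixture semantics; `VAF ≤ 0.5` enforced).
- **Duplex UMIs.** Independent random 4–5 bp tags per strand end; top
  reads observe `(u_top, u_bottom)`, bottom reads the swap. Strand of a
  read is taken from its alignment orientation (observable without
  UMIs, as in real paired-end data).
- **Duplicates and errors.** Per-strand duplicate counts
  ~ Poisson(reads_per_molecule/2); zero is allowed and produces simplex
  molecules, which is intended. Single-strand pre-amplification lesions
  at `lesion_rate` per strand per locus (never both strands of one
  locus; symmetric damage out of scope), then per-read substitution
  errors at `seq_error_rate` (1e-3 default) and per-base UMI errors at
  `umi_error_rate` (1e-3). No base qualities, GC bias, adapter
  artifacts or indel sequencing errors.
- **Presets.** FF: 100 ng, random shear (250±60 bp), lesions 1e-4,
  LCR 0.033. FFPE: 25 ng, shear (180±50 bp), lesions 2e-3, LCR 0.127.
  cfDNA: 12.5 ng, nucleosomal, lesions 1e-4, LCR 0.5 (the conversion
  rate reported for cfDNA workflows). The LCRs are set so
  `300 × Input × LCR` reproduces the mean molecular counts
  characteristic of each material (~1000, ~950, ~1900); FF converts
  poorly in practice, hence its low value.

What the simulator does **not** capture: real fragment-end
distributions (multi-phase nucleosome maps, tissue-specific cut
biases), AT/GC conversion bias, hairpin/end-repair artifacts,
sequencing-quality structure, and cross-locus linkage. Tests passing on
synthetic data therefore demonstrate the *mechanisms* (collision-driven
signal loss, duplex error suppression, binomial coverage limits), not
the numeric performance of any real assay.

## Grouping, consensus, calling

- Grouping keys on both fragment endpoints plus contig. UMI mode
  clusters canonicalized duplex pairs (lexicographic min of the two
  concatenation orders) within a fragment key by single linkage at
  Hamming ≤ 1 on the concatenated pair; cluster ids are the smallest
  member string, making the partition order-independent. The tolerance
  is applied to the concatenated pair, the minimal reading of
  "one mismatch"; per-UMI tolerance would merge slightly more.
- Duplex collapse: simplex groups discarded; ≥3 reads total required
  (attached to the group, not per strand — per-strand 3× would
  contradict observed duplex recovery at 5 reads/molecule); per-strand
  consensus needs ≥70% consistency among reads covering the locus;
  strand disagreement yields NO_CALL rather than reference (no
  reference bias); NO_CALL positions join neither pileup numerator nor
  denominator.
- Calling: support threshold on the molecule count per locus/allele.
  Specificity counts 5 theoretical false calls per interrogated
  position without an expected variant (3 base changes + insertion +
  deletion); FP/kb is the same count per kilobase. ROC sweeps the
  threshold from 1 to max observed count + 1, x-axis the false-call
  rate (complement of specificity, consistent with its definition),
  endpoints (0,0) and (1,1) appended, trapezoidal AUC. A Fisher's-exact
  utility compares sensitivities between configurations.

## Collisions and dilution

A position group collides if it contains ≥2 UMI-resolved molecules
(counted as one colliding group regardless of multiplicity, matching
the fraction-of-groups definition); with simulator truth available,
molecule ids replace UMI clustering as the oracle, separating collision
measurement from UMI-assignment error. Dilution series merge a
variant-bearing library with subsets of variant-free backgrounds
(multiset union with sample-tagged read ids, no cross-sample
deduplication — the analogue of concatenating FASTQ files); subsets are
enumerated deterministically (backgrounds by descending input, binary
counter), one combination kept per total input, successive totals at
least `min_step_ng` apart (20/10/5 ng for FF/FFPE/cfDNA in the study
conditions). Signal loss per dilution point is
`1 − ΣN_alt(position-only)/ΣN_alt(with-UMIs)` over truth variants.

## Numerical and design choices

- Coordinates: 0-based half-open internally, 1-based in all exported
  text (SAM/BED duality, stated to avoid drift).
- All randomness flows from a single integer seed through
  `numpy.random.Generator`; reruns are bit-identical, different seeds
  decorrelate.
- Ties in strand consensus cannot pass a >50% consistency threshold;
  the deterministic (count, allele) tie-break only matters at exactly
  50% and below.
- Degenerate inputs: empty read sets group to zero molecules; zero
  input DNA simulates zero molecules; UMI-less reads are rejected by
  UMI-mode grouping and by UMI-based collision measurement.
- Reads are exchanged as a SAM-like TSV (not BAM/SAM records): the read
  model is locus→allele calls, and fabricating SEQ/CIGAR would add
  bulk without information.

## Problem sizes in the test suite

Property checks run at sizes where the asserted effect exceeds
sampling noise by a comfortable factor, chosen once from the binomial
standard errors involved: lesion suppression over 1e4 molecules;
collision ordering over 10 seeds at ~1500 molecules per regime;
binomial-sensitivity agreement over 5 replicates of ~12000 molecules on
a 20-locus panel (≈470 duplexes/locus, 3-SE band); signal-loss trend
over 3 seeds on a 120-locus panel at ~25 molecules/locus undiluted
(so the undiluted point is collision-sparse) growing to ~100/locus;
VAF-independence over 3 seeds with ≥90 pooled ALT molecules per VAF
arm. Real-data headline values (observed sensitivities, FP/kb, AUC
tables, absolute collision percentages) depend on the deposited
sequencing data's fragment-end distributions and are covered by these
ordering/consistency properties, not numerically.

## Known limitations

- Single-phase nucleosome grid: real cfDNA shows position-dependent
  phasing; absolute collision rates are therefore not comparable to
  clinical data, only their ordering and scaling.
- UMI space at 4–5 bp per arm admits birthday collisions at high
  per-locus depth (~1% molecule undercount at ~600 molecules/locus);
  the truth-id oracle quantifies this in the tests.
- No quality-weighted consensus (majority vote only; no published
  weighting to implement), no simplex-only calling mode, no
  network/"directional" UMI correction with count asymmetry.
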