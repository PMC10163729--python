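# umicollide

Duplex consensus variant calling with and without exogenous UMIs, and
the mapping-position collisions that separate the two.

## The problem

Detecting somatic variants at allele fractions of 0.05–2% from targeted
sequencing (fresh-frozen tissue, FFPE blocks, cell-free DNA) requires
suppressing PCR and sequencing noise by collapsing duplicate reads into
per-molecule consensus sequences. Reads can be grouped into molecules
two ways: by their fragment mapping coordinates alone, or by mapping
coordinates plus an exogenous unique molecular identifier (UMI). The
position-only strategy fails when two distinct input molecules share
the same fragment coordinates — a *collision* — which is rare for
randomly sheared DNA but common for cfDNA, whose fragment ends are
constrained by nucleosome positioning (~147 bp cores, nuclease-exposed
linkers). `umicollide` implements both strategies end-to-end on
synthetic duplex libraries and quantifies when UMIs actually matter.

## The models at its core

With `N` sequenced molecules overlapping a locus at variant allele
fraction `VAF`, the variant-supporting molecule count is
`N_alt ~ Binomial(N, VAF)`, so the detection probability with a support
threshold `k` is `P(N_alt ≥ k)`; for `k = 1` this is
`1 − (1 − VAF)^N`. The molecular count itself follows
`N = 300 × Input(ng) × LCR`, with ~300 genome equivalents per ng of
dsDNA and `LCR` the library conversion rate. A `b`-bp UMI in an
`r`-bp read consumes `b/r` of sequencing output.

The pipeline around these models: simulate strand-tracked, UMI-tagged,
PCR-duplicated reads from a mixture of two genotypes over a capture
panel (default 110 variant loci across 46 kbp); group reads
(`position_only` / `with_umis`, single-linkage UMI clustering with a
1-mismatch tolerance on the canonicalized duplex pair); collapse duplex
groups (≥3 reads, both strands, ≥70% per-strand base consistency,
alternative alleles kept only when seen on both strands); pile up and
call by molecule-support threshold; score sensitivity, FP/kb
(false calls over 5 theoretical false calls per interrogated position),
ROC and AUC; and measure collision rates, molecule-count discrepancy,
in-silico dilution series and ALT-signal loss.

## Worked example

Detection-limit arithmetic:

```sh
$ umicollide models --n 1900 --vaf 0.002 --min-alt 2 --input-ng 20 --lcr 0.5
{
  "molecular_count": 3000.0,
  "probability": 0.8928583948873539,
  "probability_percent": 89
}
```

1900 duplex molecules at VAF 0.2% give an 89% chance of seeing ≥2
variant molecules; 20 ng at 50% conversion yields 3000 molecules — the
scale needed for 95% detection at VAF 0.1%.

A full synthetic cfDNA comparison (50 ng, VAF 2%, nucleosomal
fragmentation, ~5 reads/molecule):

```sh
$ umicollide run --condition cfDNA --seed 7 --vaf 0.02 --input-ng 50 --lcr 0.5
simulated 7406 molecules, 36919 reads
position_only: 6598 groups, 5424 duplex consensus molecules, 22 calls
with_umis: 7411 groups, 5893 duplex consensus molecules, 25 calls
{
  "collision": {
    "collision_rate": 0.10942709912094574,
    "count_discrepancy": 0.12321915732040012,
    ...
  },
  "comparison": {
    "auc_position_only": 0.7363636363636363,
    "auc_with_umis": 0.7863636363636364,
    "sensitivity_position_only": 0.2,
    "sensitivity_with_umis": 0.22727272727272727,
    ...
  },
  ...
}
```

Reading the numbers: 11% of position-only read groups contain at least
two distinct molecules (collisions), so position-only grouping
undercounts molecules by 12% and loses the variant evidence trapped in
those groups — UMIs recover it (AUC 0.79 vs 0.74, sensitivity 22.7% vs
20.0%). The per-locus molecular coverage here is only ~67, so the gap
is modest; it widens with molecular depth as collisions accumulate,
and vanishes for randomly sheared (FF/FFPE-like) libraries at ordinary
inputs.

Other subcommands: `simulate`, `group`, `collapse`, `call` (no-grouping
baseline), `collide`, `dilute`. The same functionality is available as
a library (`import umicollide`); see `docs/methods.md` for the model
details.

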