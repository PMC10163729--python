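"""Pileup, threshold variant calling, and performance metrics.

Consensus molecules are piled up per panel locus; a variant call is
emitted wherever the number of molecules supporting a non-reference
allele reaches a threshold.  Performance is summarized the way targeted
duplex panels are benchmarked:

* **sensitivity** — fraction of expected (truth) variants called;
* **specificity** — 1 minus the ratio of false calls to all
  theoretically possible false calls, where every interrogated position
  without an expected variant admits 5 potential false calls (three
  alternative bases, an insertion and a deletion);
* **FP/kb** — false calls per kilobase of interrogated positions, the
  more interpretable expression of the same quantity;
* **ROC / AUC** — sweep of the molecule-support threshold, x-axis the
  false-call rate (complement of specificity), numerically integrated
  by the trapezoidal rule with the (0,0) and (1,1) endpoints included.

A *no grouping* baseline (:func:`raw_pileup_call`) computes per-locus
allele fractions directly over reads, skipping deduplication entirely.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .consensus import NO_CALL, ConsensusMolecule
from .simulate import PanelDefinition, ReadRecord

#: Potential false calls per interrogated position without an expected
#: variant: three alternative bases, one insertion, one deletion.
FALSE_CALL_CLASSES_PER_POSITION = 5

CallKey = tuple[str, int, str]  # (contig, pos, allele)


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 0-based anchor
    ref: str
    alt: str
    n_support: int
    total: int

    @property
    def key(self) -> CallKey:
        return (self.contig, self.pos, self.alt)

    @property
    def fraction(self) -> float:
        return self.n_support / self.total if self.total else 0.0


@dataclass
class PileupCounts:
    """Per-locus allele support among consensus molecules."""

    contig: str
    counts: dict[int, Counter] = field(default_factory=dict)

    def total(self, pos: int) -> int:
        return sum(self.counts.get(pos, Counter()).values())

    def allele_count(self, pos: int, allele: str) -> int:
        return self.counts.get(pos, Counter()).get(allele, 0)

    def max_count(self) -> int:
        return max(
            (c for ctr in self.counts.values() for c in ctr.values()), default=0
        )


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: float
    specificity: float
    fp_per_kb: float
    roc_points: tuple[tuple[float, float], ...]
    auc: float


def pileup(
    consensus_molecules: Iterable[ConsensusMolecule], panel: PanelDefinition
) -> PileupCounts:
    """Count molecules supporting each allele at each panel locus.

    ``NO_CALL`` positions contribute to neither numerator nor
    denominator — a molecule with no confident call at a locus carries
    no molecular evidence there.
    """
    panel_positions = set(int(p) for p in panel.positions)
    contig = panel.loci[0].contig if panel.loci else "panel1"
    counts: dict[int, Counter] = defaultdict(Counter)
    for cm in consensus_molecules:
        for pos, allele in cm.per_locus.items():
            if allele is NO_CALL or pos not in panel_positions:
                continue
            counts[pos][allele] += 1
    return PileupCounts(contig=contig, counts=dict(counts))


def call_variants(
    pile: PileupCounts, panel: PanelDefinition, min_molecules: int
) -> list[VariantCall]:
    """Emit a call for every locus/allele with support >= ``min_molecules``.

    Only non-reference alleles are calls; the reference allele of each
    locus comes from the panel.
    """
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    by_pos = panel.by_position()
    calls: list[VariantCall] = []
    for pos in sorted(pile.counts):
        locus = by_pos.get(pos)
        if locus is None:
            continue
        total = pile.total(pos)
        for allele, n in sorted(pile.counts[pos].items()):
            if allele == locus.ref or n < min_molecules:
                continue
            calls.append(
                VariantCall(pile.contig, pos, locus.ref, allele, n, total)
            )
    return calls


def raw_pileup_call(
    reads: Iterable[ReadRecord], panel: PanelDefinition, vaf_threshold: float
) -> list[VariantCall]:
    """Variant calling without any read grouping (per-read fractions)."""
    if not 0.0 < vaf_threshold <= 1.0:
        raise ValueError("vaf_threshold must be in (0, 1]")
    by_pos = panel.by_position()
    counts: dict[int, Counter] = defaultdict(Counter)
    for read in reads:
        for pos, allele in read.calls.items():
            if pos in by_pos:
                counts[pos][allele] += 1
    calls: list[VariantCall] = []
    for pos in sorted(counts):
        locus = by_pos[pos]
        total = sum(counts[pos].values())
        for allele, n in sorted(counts[pos].items()):
            if allele == locus.ref:
                continue
            if n / total >= vaf_threshold:
                calls.append(
                    VariantCall(locus.contig, pos, locus.ref, allele, n, total)
                )
    return calls


def sensitivity(
    calls: Iterable[VariantCall], truth: Iterable[CallKey]
) -> float:
    """Fraction of expected variants that were called."""
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("truth set must be non-empty")
    called = {c.key for c in calls}
    return len(called & truth_set) / len(truth_set)


def theoretical_false_calls(interrogated_positions: int, n_truth: int) -> int:
    """All possible false calls over positions without an expected variant."""
    if interrogated_positions <= 0:
        raise ValueError("interrogated_positions must be positive")
    return (interrogated_positions - n_truth) * FALSE_CALL_CLASSES_PER_POSITION


def specificity_fp_per_kb(
    calls: Iterable[VariantCall],
    interrogated_positions: int,
    truth: Iterable[CallKey],
) -> tuple[float, float]:
    """Specificity and false positives per kilobase.

    Specificity is 1 minus the ratio of false calls to all theoretically
    possible false calls; since several false calls are possible per
    position this stays within [0, 1].
    """
    truth_set = set(truth)
    false_calls = sum(1 for c in calls if c.key not in truth_set)
    theoretical = theoretical_false_calls(interrogated_positions, len(truth_set))
    specificity = 1.0 - false_calls / theoretical if theoretical else 1.0
    fp_per_kb = false_calls / (interrogated_positions / 1000.0)
    return specificity, fp_per_kb


def roc_auc(
    pile: PileupCounts,
    panel: PanelDefinition,
    truth: Iterable[CallKey],
    interrogated_positions: int | None = None,
    report_threshold: int = 2,
) -> PerformanceReport:
    """Threshold sweep over the molecule-support count, with AUC.

    Thresholds run from 1 to the maximum observed molecule count plus
    one (guaranteeing the all-negative endpoint); per threshold the
    false-call rate (false calls over theoretical false calls) and
    sensitivity form one ROC point.  Points are sorted by false-call
    rate, the (0, 0) and (1, 1) endpoints appended, and the AUC obtained
    by trapezoidal integration.
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("truth set must be non-empty")
    if interrogated_positions is None:
        interrogated_positions = panel.interrogated_span_bp
    theoretical = theoretical_false_calls(interrogated_positions, len(truth_set))
    points: list[tuple[float, float]] = []
    report_sens = 0.0
    report_spec = 1.0
    report_fpkb = 0.0
    for threshold in range(1, pile.max_count() + 2):
        calls = call_variants(pile, panel, threshold)
        sens = sensitivity(calls, truth_set)
        spec, fpkb = specificity_fp_per_kb(
            calls, interrogated_positions, truth_set
        )
        points.append((1.0 - spec, sens))
        if threshold == report_threshold:
            report_sens, report_spec, report_fpkb = sens, spec, fpkb
    points.sort()
    curve = [(0.0, 0.0), *points, (1.0, 1.0)]
    xs, ys = zip(*curve)
    auc = float(np.trapezoid(ys, xs))
    return PerformanceReport(
        sensitivity=report_sens,
        specificity=report_spec,
        fp_per_kb=report_fpkb,
        roc_points=tuple(curve),
        auc=auc,
    )


def compare_sensitivities(
    calls_a: Iterable[VariantCall],
    calls_b: Iterable[VariantCall],
    truth: Iterable[CallKey],
) -> float:
    """Fisher's exact p-value for a difference in sensitivity.

    2x2 contingency of truth variants called vs missed under two calling
    configurations (two-sided).
    """
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("truth set must be non-empty")
    hit_a = len({c.key for c in calls_a} & truth_set)
    hit_b = len({c.key for c in calls_b} & truth_set)
    n = len(truth_set)
    table = [[hit_a, n - hit_a], [hit_b, n - hit_b]]
    return float(fisher_exact(table)[1])
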