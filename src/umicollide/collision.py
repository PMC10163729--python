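"""Mapping-position collisions, in-silico dilution, and ALT signal loss.

A *collision* occurs when two or more distinct input molecules share the
same fragment mapping coordinates and are therefore indistinguishable by
position-only grouping.  The collision rate is the fraction of
position-only read groups containing at least one collision (i.e. at
least two UMI-resolved — or truth-annotated — molecules).  Collisions
make the position-only molecule count an undercount; the relative
difference between the UMI-based and position-based counts is the count
discrepancy.

The dilution machinery mirrors in-silico merging of sequencing runs:
reads of a variant-bearing sample are merged (multiset union, with
sample-tagged read ids) with subsets of variant-free background
libraries, producing a series of growing total input amounts at
decreasing effective VAF.  Per dilution point, the number of
variant-supporting molecules (N_ALT) is measured under both grouping
modes; the fraction of ALT molecules lost by position-only grouping
quantifies the collision-induced signal loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .calling import CallKey, pileup
from .consensus import collapse_groups
from .grouping import GroupingMode, group_reads
from .simulate import PanelDefinition, ReadRecord, tag_sample


@dataclass(frozen=True)
class CollisionReport:
    n_position_groups: int
    n_umi_molecules: int
    n_colliding_groups: int

    @property
    def collision_rate(self) -> float:
        if self.n_position_groups == 0:
            return 0.0
        return self.n_colliding_groups / self.n_position_groups

    @property
    def count_discrepancy(self) -> float:
        """Relative excess of UMI molecules over position groups."""
        if self.n_position_groups == 0:
            return 0.0
        return (
            self.n_umi_molecules - self.n_position_groups
        ) / self.n_position_groups


def collision_rate(
    reads: Sequence[ReadRecord],
    max_umi_mismatch: int = 1,
    use_truth: bool = False,
) -> CollisionReport:
    """Measure the collision rate of a read set.

    Molecule identity inside each position group comes from UMI
    clustering (default) or, with ``use_truth``, from simulator truth
    molecule ids — the oracle that separates collision measurement from
    UMI-assignment error.  A group with k >= 2 molecules counts as one
    colliding group.
    """
    position_groups = group_reads(reads, "position_only")
    if use_truth:
        if any(r.molecule_id < 0 for r in reads):
            raise ValueError("use_truth requires simulator molecule ids")
        n_umi = 0
        colliding = 0
        for group in position_groups:
            k = len({r.molecule_id for r in group.members})
            n_umi += k
            colliding += k >= 2
    else:
        if any(not r.has_umi for r in reads):
            raise ValueError(
                "collision measurement needs UMIs or simulator truth ids"
            )
        n_umi = 0
        colliding = 0
        for group in position_groups:
            sub = group_reads(group.members, "with_umis", max_umi_mismatch)
            n_umi += len(sub)
            colliding += len(sub) >= 2
    return CollisionReport(
        n_position_groups=len(position_groups),
        n_umi_molecules=n_umi,
        n_colliding_groups=colliding,
    )


# ---------------------------------------------------------------------------
# dilution series


@dataclass(frozen=True)
class Sample:
    """A named read set with its DNA input amount."""

    name: str
    input_ng: float
    reads: tuple[ReadRecord, ...]


@dataclass(frozen=True)
class DilutionPoint:
    members: tuple[str, ...]  # sample names merged in
    total_input_ng: float
    reads: tuple[ReadRecord, ...]


@dataclass(frozen=True)
class DilutionSeries:
    points: tuple[DilutionPoint, ...]
    min_step_ng: float


def merge_reads(samples: Iterable[Sample]) -> list[ReadRecord]:
    """Multiset union of sample read sets with sample-tagged ids.

    No re-deduplication happens across samples before grouping — the
    in-silico analogue of concatenating FASTQ files.
    """
    merged: list[ReadRecord] = []
    for sample in samples:
        merged.extend(tag_sample(sample.reads, sample.name))
    return merged


def enumerate_dilutions(
    variant_sample: Sample,
    background_samples: Sequence[Sample],
    min_step_ng: float,
) -> DilutionSeries:
    """Enumerate merged combinations with a minimum input-amount step.

    Background subsets are enumerated deterministically (backgrounds
    sorted by input amount descending, subsets in binary-counter order);
    only one combination is kept per total input amount (the first in
    enumeration order), and successive kept totals must differ by at
    least ``min_step_ng``.  The undiluted sample is always the first
    point.
    """
    if min_step_ng < 0:
        raise ValueError("min_step_ng must be >= 0")
    backgrounds = sorted(
        background_samples, key=lambda s: (-s.input_ng, s.name)
    )
    combos: dict[float, tuple[str, ...]] = {}
    for mask in range(1 << len(backgrounds)):
        subset = [
            backgrounds[j] for j in range(len(backgrounds)) if mask >> j & 1
        ]
        total = variant_sample.input_ng + sum(s.input_ng for s in subset)
        if total not in combos:  # keep first per total
            combos[total] = tuple(s.name for s in subset)
    by_name = {s.name: s for s in backgrounds}
    points: list[DilutionPoint] = []
    last_total: float | None = None
    for total in sorted(combos):
        if last_total is not None and total - last_total < min_step_ng:
            continue
        names = combos[total]
        merged = merge_reads(
            [variant_sample, *(by_name[n] for n in names)]
        )
        points.append(
            DilutionPoint(
                members=(variant_sample.name, *names),
                total_input_ng=total,
                reads=tuple(merged),
            )
        )
        last_total = total
    return DilutionSeries(points=tuple(points), min_step_ng=min_step_ng)


@dataclass(frozen=True)
class SignalLossReport:
    """ALT molecule counts per truth variant, both grouping modes."""

    total_input_ng: float
    n_alt_with_umi: dict[CallKey, int] = field(default_factory=dict)
    n_alt_position_only: dict[CallKey, int] = field(default_factory=dict)

    @property
    def fraction_lost(self) -> float:
        """Fraction of UMI-resolved ALT molecules lost by position grouping."""
        denom = sum(self.n_alt_with_umi.values())
        if denom == 0:
            return 0.0
        num = sum(self.n_alt_position_only.values())
        return max(1.0 - num / denom, 0.0)


def _n_alt(
    reads: Sequence[ReadRecord],
    panel: PanelDefinition,
    truth: Iterable[CallKey],
    mode: GroupingMode,
    min_reads: int,
    min_consistency: float,
    max_umi_mismatch: int,
) -> dict[CallKey, int]:
    groups = group_reads(reads, mode, max_umi_mismatch)
    consensus = collapse_groups(groups, min_reads, min_consistency)
    pile = pileup(consensus, panel)
    return {
        (contig, pos, alt): pile.allele_count(pos, alt)
        for (contig, pos, alt) in truth
    }


def alt_signal_loss(
    series: DilutionSeries,
    panel: PanelDefinition,
    truth: Iterable[CallKey] | None = None,
    min_reads: int = 3,
    min_consistency: float = 0.70,
    max_umi_mismatch: int = 1,
) -> list[SignalLossReport]:
    """N_ALT under both grouping modes for every dilution point.

    Each merged read set runs through grouping, duplex collapse and
    pileup twice (with UMIs / position only); the report carries the
    per-variant ALT molecule counts and the pooled fraction lost.
    """
    truth_keys = set(truth) if truth is not None else set(panel.truth())
    reports: list[SignalLossReport] = []
    for point in series.points:
        with_umi = _n_alt(
            point.reads, panel, truth_keys, "with_umis",
            min_reads, min_consistency, max_umi_mismatch,
        )
        pos_only = _n_alt(
            point.reads, panel, truth_keys, "position_only",
            min_reads, min_consistency, max_umi_mismatch,
        )
        reports.append(
            SignalLossReport(
                total_input_ng=point.total_input_ng,
                n_alt_with_umi=with_umi,
                n_alt_position_only=pos_only,
            )
        )
    return reports
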