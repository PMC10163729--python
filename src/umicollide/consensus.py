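"""Duplex consensus collapsing of read groups.

A read group is collapsed to a single high-confidence molecule sequence
in two stages.  Per strand and per locus, the majority allele becomes
the strand consensus only if it reaches 70% consistency among the reads
of that strand covering the locus.  The duplex consensus then requires
the two strand consensuses to agree; any disagreement, or a missing
strand consensus, yields ``NO_CALL`` at that locus.  Groups with only
one strand sequenced (simplex) are discarded, as are groups with fewer
than 3 reads in total.  An alternative allele therefore survives only
when observed consistently on both original strands — the property that
suppresses single-strand lesions (e.g. FFPE damage) while retaining
true double-stranded variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .grouping import GroupingKey, ReadGroup, classify
from .simulate import ReadRecord

#: Sentinel for a position where no confident consensus exists.
NO_CALL = None

DEFAULT_MIN_CONSISTENCY = 0.70
DEFAULT_MIN_READS = 3


@dataclass(frozen=True)
class ConsensusMolecule:
    """Per-locus double-strand consensus for one inferred molecule."""

    key: GroupingKey
    per_locus: dict[int, str | None]  # pos -> allele, or NO_CALL (None)
    n_reads_top: int
    n_reads_bottom: int


def strand_consensus(
    reads: Sequence[ReadRecord],
    locus_pos: int,
    min_consistency: float = DEFAULT_MIN_CONSISTENCY,
) -> str | None:
    """Majority allele of one strand at one locus, or ``NO_CALL``.

    Only reads covering the locus vote; the majority allele must reach
    ``min_consistency`` of those votes.  Ties cannot reach a threshold
    above 0.5 and thus yield ``NO_CALL``.
    """
    votes = Counter(
        r.calls[locus_pos] for r in reads if locus_pos in r.calls
    )
    if not votes:
        return NO_CALL
    # deterministic tie-break (irrelevant above 50% consistency)
    allele, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
    if count / sum(votes.values()) >= min_consistency:
        return allele
    return NO_CALL


def duplex_collapse(
    group: ReadGroup,
    min_reads: int = DEFAULT_MIN_READS,
    min_consistency: float = DEFAULT_MIN_CONSISTENCY,
) -> ConsensusMolecule | None:
    """Collapse one read group to a duplex consensus, or reject it.

    Returns ``None`` (rejected) for simplex groups and for groups with
    fewer than ``min_reads`` reads in total.
    """
    if classify(group) != "duplex" or len(group.members) < min_reads:
        return None
    top = [r for r in group.members if r.strand == "top"]
    bottom = [r for r in group.members if r.strand == "bottom"]
    loci = sorted({pos for r in group.members for pos in r.calls})
    per_locus: dict[int, str | None] = {}
    for pos in loci:
        ct = strand_consensus(top, pos, min_consistency)
        cb = strand_consensus(bottom, pos, min_consistency)
        per_locus[pos] = ct if (ct is not NO_CALL and ct == cb) else NO_CALL
    return ConsensusMolecule(
        key=group.key,
        per_locus=per_locus,
        n_reads_top=len(top),
        n_reads_bottom=len(bottom),
    )


def collapse_groups(
    groups: Iterable[ReadGroup],
    min_reads: int = DEFAULT_MIN_READS,
    min_consistency: float = DEFAULT_MIN_CONSISTENCY,
) -> list[ConsensusMolecule]:
    """Collapse all groups, dropping rejected ones."""
    out: list[ConsensusMolecule] = []
    for group in groups:
        cm = duplex_collapse(group, min_reads, min_consistency)
        if cm is not None:
            out.append(cm)
    return out
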