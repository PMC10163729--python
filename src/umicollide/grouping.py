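"""Read grouping: mapping position alone, or position plus duplex UMIs.

Reads sharing a fragment mapping key ``(contig, start, end)`` form one
group in *position_only* mode.  In *with_umis* mode, reads within a
fragment key are further split by their duplex UMI pair: pairs are
canonicalized (lexicographic minimum of the two concatenation orders,
so that top- and bottom-strand reads of one molecule co-cluster) and
single-linkage clustered with a Hamming-distance tolerance on the
concatenated pair (default 1 mismatch, absorbing UMI sequencing
errors).  Each resulting group is one inferred input molecule, and is
classified *duplex* if reads from both original strands are present,
*simplex* otherwise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .simulate import ReadRecord

GroupingMode = Literal["position_only", "with_umis"]

FragmentKey = tuple[str, int, int]


@dataclass(frozen=True)
class GroupingKey:
    fragment_key: FragmentKey
    umi_cluster_id: str | None = None  # present iff grouped with UMIs


@dataclass(frozen=True)
class ReadGroup:
    key: GroupingKey
    members: tuple[ReadRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ReadGroup must have at least one member")

    @property
    def n_top(self) -> int:
        return sum(1 for r in self.members if r.strand == "top")

    @property
    def n_bottom(self) -> int:
        return sum(1 for r in self.members if r.strand == "bottom")

    @property
    def duplexity(self) -> str:
        return classify(self)


def canonical_umi_pair(u1: str, u2: str) -> str:
    """Strand-invariant representation of a duplex UMI pair.

    The lexicographic minimum of the two concatenation orders, so a
    molecule's top-strand reads (observing ``(u1, u2)``) and
    bottom-strand reads (observing ``(u2, u1)``) map to the same string.
    """
    return min(u1 + u2, u2 + u1)


def group_reads(
    reads: Iterable[ReadRecord],
    mode: GroupingMode = "position_only",
    max_umi_mismatch: int = 1,
) -> list[ReadGroup]:
    """Partition reads into molecule groups.

    The result is independent of input read order (members and groups
    are canonically sorted) and is a partition: every read belongs to
    exactly one group.
    """
    if mode not in ("position_only", "with_umis"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    by_key: dict[FragmentKey, list[ReadRecord]] = defaultdict(list)
    for read in reads:
        by_key[read.fragment_key].append(read)

    groups: list[ReadGroup] = []
    for fkey in sorted(by_key):
        members = sorted(by_key[fkey], key=lambda r: (r.read_id, r.strand))
        if mode == "position_only":
            groups.append(ReadGroup(GroupingKey(fkey), tuple(members)))
            continue
        for cluster_id, cluster in _cluster_by_umi(members, max_umi_mismatch):
            groups.append(
                ReadGroup(GroupingKey(fkey, cluster_id), tuple(cluster))
            )
    return groups


def _cluster_by_umi(
    members: Sequence[ReadRecord], max_mismatch: int
) -> list[tuple[str, list[ReadRecord]]]:
    """Single-linkage clustering of canonical UMI pairs within one key.

    Cluster id is the lexicographically smallest member UMI string;
    clusters are returned sorted by id.  Pairs of different lengths
    never merge.
    """
    for read in members:
        if not read.has_umi:
            raise ValueError(
                f"read {read.read_id} has no UMI; cannot group with_umis"
            )
    canon = [canonical_umi_pair(*r.umi_observed) for r in members]
    distinct = sorted(set(canon))
    parent = list(range(len(distinct)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_len: dict[int, list[int]] = defaultdict(list)
    for idx, u in enumerate(distinct):
        by_len[len(u)].append(idx)
    for length, idxs in by_len.items():
        if len(idxs) < 2 or length == 0:
            if length == 0 and len(idxs) > 1:  # pragma: no cover - guarded above
                raise ValueError("empty UMIs cannot be clustered")
            continue
        arr = np.frombuffer(
            "".join(distinct[i] for i in idxs).encode("ascii"), dtype=np.uint8
        ).reshape(len(idxs), length)
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        ii, jj = np.nonzero(np.triu(dist <= max_umi_mismatch_safe(max_mismatch), 1))
        for a, b in zip(ii.tolist(), jj.tolist()):
            union(idxs[a], idxs[b])

    cluster_of = {u: distinct[find(i)] for i, u in enumerate(distinct)}
    clusters: dict[str, list[ReadRecord]] = defaultdict(list)
    for read, u in zip(members, canon):
        clusters[cluster_of[u]].append(read)
    return sorted(clusters.items())


def max_umi_mismatch_safe(max_mismatch: int) -> int:
    if max_mismatch < 0:
        raise ValueError("max_umi_mismatch must be >= 0")
    return max_mismatch


def classify(group: ReadGroup) -> str:
    """``"duplex"`` if both strands are represented, else ``"simplex"``."""
    strands = {r.strand for r in group.members}
    return "duplex" if strands == {"top", "bottom"} else "simplex"


def count_molecules(groups: Iterable[ReadGroup]) -> int:
    """Molecule count: number of groups, simplex and duplex included."""
    return sum(1 for _ in groups)
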