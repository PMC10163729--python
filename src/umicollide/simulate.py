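"""Synthetic duplex-sequencing read generator.

Emulates a targeted hybridization-capture experiment on a panel of
variant loci, producing already-aligned, strand-tracked, UMI-tagged PCR
duplicate reads from a two-genotype mixture.  The generator models:

* a locus panel (default: 110 variant loci — 70 SNVs, 20 deletions,
  20 insertions — over a 46 kbp interrogated span);
* two fragmentation regimes: *random shear* (sonication/enzymatic, for
  fresh-frozen and FFPE DNA) and *nucleosomal* cutting (cell-free DNA),
  in which fragment ends concentrate near the linkers of a phased
  nucleosome grid (~147 bp core + linker), yielding the restricted set
  of highly frequent fragment edges responsible for mapping-position
  collisions;
* double-stranded UMIs of 4-5 bp per adapter arm, read in opposite
  order from the two strands;
* Poisson PCR duplication per strand (>= 5 reads per molecule on
  average in the study conditions);
* strand-asymmetric pre-amplification lesions (FFPE-like damage) and
  symmetric per-read sequencing errors, plus per-base UMI errors.

Reads are emitted as aligned records carrying the fragment interval and
locus-level allele calls; base-level sequence assembly and re-alignment
are out of scope.  Coordinates are 0-based half-open internally and
1-based in exported tabular text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .models import molecular_count

BASES = "ACGT"

VariantClass = Literal["snv", "deletion", "insertion"]
Strand = Literal["top", "bottom"]


# ---------------------------------------------------------------------------
# panel


@dataclass(frozen=True)
class Locus:
    """One targeted variant locus (0-based anchor position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered target panel plus the size of the interrogated span."""

    loci: tuple[Locus, ...]
    interrogated_span_bp: int

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for locus in self.loci:
            key = (locus.contig, locus.pos)
            if key in seen:
                raise ValueError(f"duplicate locus position {key}")
            seen.add(key)
            _check_alleles(locus)
        if self.interrogated_span_bp <= 0:
            raise ValueError("interrogated_span_bp must be positive")

    @property
    def positions(self) -> np.ndarray:
        """Sorted anchor positions (single-contig panels)."""
        return np.asarray(sorted(l.pos for l in self.loci), dtype=np.int64)

    def by_position(self) -> dict[int, Locus]:
        return {l.pos: l for l in self.loci}

    def truth(self) -> frozenset[tuple[str, int, str]]:
        """The expected variant calls as ``(contig, pos, alt)`` triples."""
        return frozenset((l.contig, l.pos, l.alt) for l in self.loci)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"snv": 0, "deletion": 0, "insertion": 0}
        for locus in self.loci:
            counts[locus.variant_class] += 1
        return counts


def _check_alleles(locus: Locus) -> None:
    ref, alt, vc = locus.ref, locus.alt, locus.variant_class
    if vc == "snv" and not (len(ref) == len(alt) == 1 and ref != alt):
        raise ValueError(f"inconsistent SNV alleles {ref}>{alt} at {locus.pos}")
    if vc == "deletion" and not (len(ref) > len(alt) >= 1):
        raise ValueError(f"inconsistent deletion alleles {ref}>{alt} at {locus.pos}")
    if vc == "insertion" and not (1 <= len(ref) < len(alt)):
        raise ValueError(f"inconsistent insertion alleles {ref}>{alt} at {locus.pos}")


def make_panel(
    n_snv: int,
    n_deletion: int,
    n_insertion: int,
    span_bp: int,
    contig: str = "panel1",
    first_pos: int = 150,
) -> PanelDefinition:
    """Build a deterministic evenly spaced panel with interleaved classes.

    Variant classes are interleaved along the panel (Bresenham-style
    proportional scheduling) so that any genomic sub-window mixes SNVs
    and indels, as a capture design would.
    """
    n = n_snv + n_deletion + n_insertion
    if n <= 0:
        raise ValueError("panel needs at least one locus")
    spacing = max((span_bp - 2 * first_pos) // max(n - 1, 1), 1)
    remaining = {"snv": n_snv, "deletion": n_deletion, "insertion": n_insertion}
    scheduled = {"snv": 0, "deletion": 0, "insertion": 0}
    loci: list[Locus] = []
    for i in range(n):
        # pick the class furthest behind its target proportion
        vc = max(
            (c for c in remaining if remaining[c] > 0),
            key=lambda c: remaining[c] / (scheduled[c] + 1),
        )
        scheduled[vc] += 1
        remaining[vc] -= 1
        pos = first_pos + i * spacing
        ref_base = BASES[i % 4]
        other = BASES[(i + 1) % 4]
        if vc == "snv":
            ref, alt = ref_base, other
        elif vc == "deletion":
            ref, alt = ref_base + other, ref_base
        else:
            ref, alt = ref_base, ref_base + other
        loci.append(Locus(contig, pos, ref, alt, vc))
    return PanelDefinition(tuple(loci), span_bp)


def default_panel() -> PanelDefinition:
    """The study panel: 110 loci (70 SNV, 20 del, 20 ins) over 46 kbp."""
    return make_panel(70, 20, 20, span_bp=46_000)


# ---------------------------------------------------------------------------
# fragmentation


@dataclass(frozen=True)
class FragmentationModel:
    """Fragment-endpoint model.

    ``random_shear`` draws lengths from a truncated normal (>= 50 bp)
    and a uniform offset of the target locus inside the fragment.
    ``nucleosomal`` places both endpoints near the linker cuts of a
    fixed phased nucleosome grid with period ``core_len +
    linker_len_mean``, jittered by ``cut_jitter_sd``; with probability
    ``core_cut_rate`` an endpoint is instead a rare intra-core cut.
    """

    regime: Literal["random_shear", "nucleosomal"] = "random_shear"
    mean_fragment_len: float = 250.0
    fragment_len_sd: float = 60.0
    core_len: int = 147
    linker_len_mean: int = 38
    cut_jitter_sd: float = 5.0
    core_cut_rate: float = 0.01
    grid_phase: int = 0

    MIN_FRAGMENT_LEN = 50

    def __post_init__(self) -> None:
        if self.mean_fragment_len <= 0:
            raise ValueError("mean_fragment_len must be positive")
        if self.regime not in ("random_shear", "nucleosomal"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.core_cut_rate <= 1.0:
            raise ValueError("core_cut_rate must be in [0, 1]")

    @property
    def grid_period(self) -> int:
        return self.core_len + self.linker_len_mean


def fragment_endpoints(
    model: FragmentationModel, locus_pos: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one fragment interval covering ``locus_pos`` (0-based half-open)."""
    starts, ends = _endpoints_vector(model, np.asarray([locus_pos]), rng)
    return int(starts[0]), int(ends[0])


def _endpoints_vector(
    model: FragmentationModel, loci: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if model.regime == "random_shear":
        return _shear_endpoints(model, loci, rng)
    return _nucleosomal_endpoints(model, loci, rng)


def _shear_endpoints(
    model: FragmentationModel, loci: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = loci.size
    lengths = rng.normal(model.mean_fragment_len, model.fragment_len_sd, n)
    lengths = np.maximum(np.rint(lengths), model.MIN_FRAGMENT_LEN).astype(np.int64)
    offsets = (rng.random(n) * lengths).astype(np.int64)  # uniform in [0, len)
    starts = np.maximum(loci - offsets, 0)
    return starts, starts + lengths


def _nucleosomal_endpoints(
    model: FragmentationModel, loci: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    period = model.grid_period
    unit = np.maximum((loci - model.grid_phase) // period, 0)
    s0 = model.grid_phase + unit * period
    e0 = s0 + period
    n = loci.size
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(20):  # redraw endpoints that fail to cover the locus
        m = todo.size
        s = np.rint(s0[todo] + rng.normal(0.0, model.cut_jitter_sd, m)).astype(np.int64)
        e = np.rint(e0[todo] + rng.normal(0.0, model.cut_jitter_sd, m)).astype(np.int64)
        if model.core_cut_rate > 0.0:
            core_s = rng.random(m) < model.core_cut_rate
            core_e = rng.random(m) < model.core_cut_rate
            if core_s.any():
                s[core_s] = s0[todo][core_s] + 1 + (
                    rng.random(core_s.sum()) * (period - 2)
                ).astype(np.int64)
            if core_e.any():
                e[core_e] = s0[todo][core_e] + 1 + (
                    rng.random(core_e.sum()) * (period - 2)
                ).astype(np.int64)
        starts[todo] = np.maximum(s, 0)
        ends[todo] = e
        ok = (starts[todo] <= loci[todo]) & (ends[todo] > loci[todo])
        todo = todo[~ok]
        if todo.size == 0:
            break
    if todo.size:  # degenerate jitter/locus geometry: clamp to cover
        starts[todo] = np.minimum(starts[todo], loci[todo])
        ends[todo] = np.maximum(ends[todo], loci[todo] + 1)
    return starts, ends


# ---------------------------------------------------------------------------
# configuration and records


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated library."""

    panel: PanelDefinition
    input_ng: float
    lcr: float
    vaf: float
    fragmentation: FragmentationModel = field(default_factory=FragmentationModel)
    umi_len: int = 5
    reads_per_molecule_mean: float = 5.0
    seq_error_rate: float = 1e-3
    lesion_rate: float = 1e-4
    umi_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vaf", "seq_error_rate", "lesion_rate", "umi_error_rate", "lcr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.vaf > 0.5:
            raise ValueError(
                f"vaf must be <= 0.5 (two-sample mixture semantics), got {self.vaf}"
            )
        if self.umi_len not in (0,) and self.umi_len < 4:
            raise ValueError("umi_len must be 0 (no UMI) or >= 4")
        if self.input_ng < 0:
            raise ValueError("input_ng must be >= 0")
        if self.reads_per_molecule_mean < 1:
            raise ValueError("reads_per_molecule_mean must be >= 1")

    def expected_molecules(self) -> float:
        return molecular_count(self.input_ng, self.lcr)


@dataclass(slots=True)
class Molecule:
    """A double-stranded input fragment with its true genotype and UMIs."""

    id: int
    contig: str
    start: int
    end: int
    genotype: dict[int, str]  # covered locus pos -> true allele
    umi_top: str
    umi_bottom: str
    lesions: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty molecule interval [{self.start}, {self.end})")


@dataclass(slots=True, frozen=True)
class ReadRecord:
    """One sequenced PCR duplicate of one strand of a molecule.

    ``umi_observed`` is the pair in read orientation: top-strand reads
    report ``(umi_top, umi_bottom)``, bottom-strand reads the swap.
    ``molecule_id`` is simulator ground truth (absent, -1, for records
    read back from external files without truth annotation).
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: Strand
    umi_observed: tuple[str, str]
    calls: Mapping[int, str]
    molecule_id: int = -1

    @property
    def fragment_key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def has_umi(self) -> bool:
        return bool(self.umi_observed[0] or self.umi_observed[1])


# ---------------------------------------------------------------------------
# generation


def _random_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if length == 0:
        return [""] * n
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes = lut[rng.integers(0, 4, size=(n, length))]
    return [row.tobytes().decode("ascii") for row in codes]


def _mutate_base_allele(allele: str, rng: np.random.Generator) -> str:
    """Substitute the anchor base for a different one (no indel errors)."""
    current = allele[0]
    choices = [b for b in BASES if b != current]
    return choices[int(rng.integers(0, 3))]


def simulate_molecules(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Molecule]:
    """Draw the input molecule population for one library.

    The total count is Poisson with mean ``300 * input_ng * lcr``; each
    molecule is anchored on a uniformly chosen panel locus, its endpoints
    drawn from the fragmentation model so the anchor is covered, and it
    carries the alternative allele independently with probability
    ``vaf`` at every covered locus.  Single-strand lesions are placed at
    ``lesion_rate`` per strand per covered locus (never on both strands
    of one locus: symmetric damage is out of scope).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.panel
    positions = panel.positions
    by_pos = panel.by_position()
    contig = panel.loci[0].contig if panel.loci else "panel1"

    n_total = int(rng.poisson(config.expected_molecules()))
    anchor_idx = rng.integers(0, positions.size, n_total)
    anchors = positions[anchor_idx]
    starts, ends = _endpoints_vector(config.fragmentation, anchors, rng)
    umis = _random_umis(2 * n_total, config.umi_len, rng)

    molecules: list[Molecule] = []
    for i in range(n_total):
        start, end = int(starts[i]), int(ends[i])
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        genotype: dict[int, str] = {}
        lesions: dict[tuple[str, int], str] = {}
        for pos in positions[lo:hi]:
            pos = int(pos)
            locus = by_pos[pos]
            is_alt = rng.random() < config.vaf
            genotype[pos] = locus.alt if is_alt else locus.ref
            if config.lesion_rate > 0.0:
                if rng.random() < config.lesion_rate:
                    lesions[("top", pos)] = _mutate_base_allele(genotype[pos], rng)
                elif rng.random() < config.lesion_rate:
                    lesions[("bottom", pos)] = _mutate_base_allele(genotype[pos], rng)
        molecules.append(
            Molecule(
                id=i,
                contig=contig,
                start=start,
                end=end,
                genotype=genotype,
                umi_top=umis[2 * i],
                umi_bottom=umis[2 * i + 1],
                lesions=lesions,
            )
        )
    return molecules


def generate_reads(
    molecules: Iterable[Molecule],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Sequence PCR duplicates of each strand of each molecule.

    Per-strand duplicate counts are ``Poisson(reads_per_molecule_mean / 2)``
    (zero is allowed and produces simplex or dropped molecules).  Each
    read inherits the molecule's alleles, then that strand's lesions,
    then independent per-locus sequencing errors; the observed UMI pair
    gets independent per-base errors and is reported in strand order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    molecules = list(molecules)
    n = len(molecules)
    dup_counts = rng.poisson(config.reads_per_molecule_mean / 2.0, size=(n, 2))
    reads: list[ReadRecord] = []
    for i, mol in enumerate(molecules):
        for strand_idx, strand in enumerate(("top", "bottom")):
            for j in range(int(dup_counts[i, strand_idx])):
                calls = dict(mol.genotype)
                for (les_strand, pos), allele in mol.lesions.items():
                    if les_strand == strand:
                        calls[pos] = allele
                if config.seq_error_rate > 0.0:
                    for pos in calls:
                        if rng.random() < config.seq_error_rate:
                            calls[pos] = _mutate_base_allele(calls[pos], rng)
                u1, u2 = mol.umi_top, mol.umi_bottom
                if config.umi_error_rate > 0.0 and config.umi_len > 0:
                    u1 = _umi_with_errors(u1, config.umi_error_rate, rng)
                    u2 = _umi_with_errors(u2, config.umi_error_rate, rng)
                observed = (u1, u2) if strand == "top" else (u2, u1)
                reads.append(
                    ReadRecord(
                        read_id=f"m{mol.id}.{strand[0]}{j}",
                        contig=mol.contig,
                        start=mol.start,
                        end=mol.end,
                        strand=strand,  # type: ignore[arg-type]
                        umi_observed=observed,
                        calls=calls,
                        molecule_id=mol.id,
                    )
                )
    return reads


def _umi_with_errors(umi: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(umi)) < rate
    if not mask.any():
        return umi
    chars = list(umi)
    for k in np.flatnonzero(mask):
        chars[k] = _mutate_base_allele(chars[k], rng)
    return "".join(chars)


def simulate_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Molecule], list[ReadRecord]]:
    """Convenience: molecules plus their reads from one seeded stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, rng)
    reads = generate_reads(molecules, config, rng)
    return molecules, reads


def tag_sample(
    reads: Iterable[ReadRecord], sample: str, keep_truth: bool = False
) -> list[ReadRecord]:
    """Prefix read ids with a sample tag (used when merging libraries).

    Truth molecule ids are dropped by default because they are only
    unique within one simulated library.
    """
    return [
        dataclasses.replace(
            r,
            read_id=f"{sample}:{r.read_id}",
            molecule_id=r.molecule_id if keep_truth else -1,
        )
        for r in reads
    ]
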