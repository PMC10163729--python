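"""Closed-form models for molecular detection limits.

Three small analytic models tie sequencing sensitivity to molecular input:

* **Detection probability.** If ``N`` molecules overlapping a locus are
  sequenced and each independently carries the alternative allele with
  probability ``VAF``, the number of variant-supporting molecules is
  ``N_alt ~ Binomial(N, VAF)``.  The probability of observing at least
  ``k`` variant molecules is the binomial survival function
  ``P(N_alt >= k)``; for ``k = 1`` this reduces to ``1 - (1 - VAF)^N``.
* **Molecular count.** Human dsDNA contains roughly 300 genome
  equivalents per nanogram, so an input of ``Input`` ng converted to
  library with efficiency ``LCR`` (library conversion rate) yields on
  average ``N = 300 * Input * LCR`` sequenced molecules per position.
* **UMI read overhead.** An exogenous barcode of ``b`` bases embedded in
  a read of ``r`` bases consumes the fraction ``b / r`` of sequencing
  output.

All probabilities are evaluated through :mod:`scipy.stats` in a
numerically safe way (no explicit factorials), so ``N`` of 1e6 or more
is fine.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

#: Genome equivalents per nanogram of human double-stranded DNA.
GENOME_EQUIVALENTS_PER_NG = 300.0


@dataclass(frozen=True)
class DetectionQuery:
    """Inputs of the binomial detection model.

    Parameters
    ----------
    n_molecules:
        Number of sequenced molecules overlapping the locus (``N``).
    vaf:
        Variant allele fraction, in ``[0, 1]``.
    min_alt:
        Minimum number of variant-supporting molecules required for a
        detection (``>= 1``).
    """

    n_molecules: int
    vaf: float
    min_alt: int = 1

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError(f"n_molecules must be >= 0, got {self.n_molecules}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.min_alt < 1:
            raise ValueError(f"min_alt must be >= 1, got {self.min_alt}")

    def probability(self) -> float:
        return detection_probability(self.n_molecules, self.vaf, self.min_alt)


@dataclass(frozen=True)
class CountModelParams:
    """Inputs of the linear molecular-count model."""

    input_ng: float
    lcr: float
    genome_equivalents_per_ng: float = GENOME_EQUIVALENTS_PER_NG

    def __post_init__(self) -> None:
        if self.input_ng < 0:
            raise ValueError(f"input_ng must be >= 0, got {self.input_ng}")
        if not 0.0 <= self.lcr <= 1.0:
            raise ValueError(f"lcr must be in [0, 1], got {self.lcr}")
        if self.genome_equivalents_per_ng <= 0:
            raise ValueError("genome_equivalents_per_ng must be positive")

    def count(self) -> float:
        return molecular_count(self.input_ng, self.lcr, self.genome_equivalents_per_ng)


def detection_probability(n_molecules: int, vaf: float, min_alt: int = 1) -> float:
    """Probability of sequencing at least ``min_alt`` variant molecules.

    ``P(N_alt >= min_alt)`` for ``N_alt ~ Binomial(n_molecules, vaf)``,
    evaluated exactly via the binomial survival function.
    """
    query = DetectionQuery(n_molecules, vaf, min_alt)  # validates
    if query.n_molecules == 0:
        return 0.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(binom.sf(query.min_alt - 1, query.n_molecules, query.vaf))


def required_molecules(vaf: float, target_prob: float, min_alt: int = 1) -> int:
    """Smallest molecule count reaching a target detection probability.

    Returns the smallest ``N`` with
    ``detection_probability(N, vaf, min_alt) >= target_prob``; the
    probability is monotone non-decreasing in ``N`` so a bracket-and-bisect
    search is exact.
    """
    if not 0.0 < vaf < 1.0:
        raise ValueError(f"vaf must be in (0, 1), got {vaf}")
    if not 0.0 < target_prob < 1.0:
        raise ValueError(f"target_prob must be in (0, 1), got {target_prob}")
    if min_alt < 1:
        raise ValueError(f"min_alt must be >= 1, got {min_alt}")

    hi = max(min_alt, 1)
    while detection_probability(hi, vaf, min_alt) < target_prob:
        hi *= 2
        if hi > 10**12:  # pragma: no cover - defensive
            raise RuntimeError("required_molecules search exceeded 1e12")
    lo = hi // 2  # probability at lo is below target (or lo < min_alt)
    while lo < hi:
        mid = (lo + hi) // 2
        if detection_probability(mid, vaf, min_alt) >= target_prob:
            hi = mid
        else:
            lo = mid + 1
    return hi


def molecular_count(
    input_ng: float,
    lcr: float,
    genome_equivalents_per_ng: float = GENOME_EQUIVALENTS_PER_NG,
) -> float:
    """Expected sequenced molecule count, ``300 * Input * LCR``."""
    params = CountModelParams(input_ng, lcr, genome_equivalents_per_ng)
    return params.genome_equivalents_per_ng * params.input_ng * params.lcr


def umi_read_overhead(umi_len: int, read_len: int) -> float:
    """Fraction of a sequencing read consumed by the UMI bases."""
    if umi_len < 0:
        raise ValueError(f"umi_len must be >= 0, got {umi_len}")
    if umi_len >= read_len:
        raise ValueError(f"umi_len ({umi_len}) must be < read_len ({read_len})")
    return umi_len / read_len


def as_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent (reporting granularity)."""
    return round(fraction * 100.0)
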