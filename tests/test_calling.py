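"""Pileup, threshold calling, sensitivity/specificity, ROC/AUC."""

import numpy as np
import pytest

from umicollide import (
    ConsensusMolecule,
    PileupCounts,
    SimulationConfig,
    VariantCall,
    call_variants,
    collapse_groups,
    compare_sensitivities,
    group_reads,
    make_panel,
    pileup,
    raw_pileup_call,
    roc_auc,
    sensitivity,
    simulate_library,
    specificity_fp_per_kb,
)
from umicollide.calling import theoretical_false_calls
from umicollide.grouping import GroupingKey
from .conftest import make_read


def consensus_fixture(panel, allele_lists):
    """One ConsensusMolecule per entry; entry maps pos -> allele/None."""
    out = []
    for i, per_locus in enumerate(allele_lists):
        out.append(
            ConsensusMolecule(
                key=GroupingKey(("panel1", i, i + 100), f"u{i}"),
                per_locus=per_locus,
                n_reads_top=3,
                n_reads_bottom=3,
            )
        )
    return out


@pytest.fixture
def tiny_panel():
    return make_panel(2, 0, 0, span_bp=1000)


class TestPileup:
    def test_counts_and_total(self, tiny_panel):
        pos = int(tiny_panel.positions[0])
        locus = tiny_panel.by_position()[pos]
        mols = consensus_fixture(
            tiny_panel,
            [{pos: locus.alt}] * 2 + [{pos: locus.ref}] * 8,
        )
        pile = pileup(mols, tiny_panel)
        assert pile.allele_count(pos, locus.alt) == 2
        assert pile.total(pos) == 10

    def test_no_call_excluded_from_both_sides(self, tiny_panel):
        pos = int(tiny_panel.positions[0])
        locus = tiny_panel.by_position()[pos]
        mols = consensus_fixture(
            tiny_panel, [{pos: locus.ref}, {pos: None}]
        )
        pile = pileup(mols, tiny_panel)
        assert pile.total(pos) == 1

    def test_alt_fraction_recovers_simulated_vaf(self):
        panel = make_panel(4, 1, 1, span_bp=1500)
        cfg = SimulationConfig(
            panel=panel, input_ng=7.0, lcr=0.5, vaf=0.2,
            seq_error_rate=0.0, lesion_rate=0.0, umi_error_rate=0.0, seed=23,
        )
        _, reads = simulate_library(cfg)
        cons = collapse_groups(group_reads(reads, "with_umis"))
        pile = pileup(cons, panel)
        alts = {l.pos: l.alt for l in panel.loci}
        n_alt = sum(pile.allele_count(p, alts[p]) for p in alts)
        n_tot = sum(pile.total(p) for p in alts)
        se = np.sqrt(0.2 * 0.8 / n_tot)
        assert n_alt / n_tot == pytest.approx(0.2, abs=3 * se)


class TestCallVariants:
    @pytest.mark.parametrize(
        "alt_count,threshold,called", [(2, 2, True), (1, 2, False), (1, 1, True)]
    )
    def test_threshold(self, tiny_panel, alt_count, threshold, called):
        pos = int(tiny_panel.positions[0])
        locus = tiny_panel.by_position()[pos]
        mols = consensus_fixture(
            tiny_panel,
            [{pos: locus.alt}] * alt_count + [{pos: locus.ref}] * 5,
        )
        calls = call_variants(pileup(mols, tiny_panel), tiny_panel, threshold)
        assert ((tiny_panel.loci[0].contig, pos, locus.alt) in
                {c.key for c in calls}) is called


class TestRawPileupCall:
    def test_fraction_at_high_vaf(self, tiny_panel):
        pos = int(tiny_panel.positions[0])
        locus = tiny_panel.by_position()[pos]
        reads = [
            make_read(f"r{i}", "top", calls={pos: locus.alt}) for i in range(5)
        ] + [
            make_read(f"s{i}", "top", calls={pos: locus.ref}) for i in range(5)
        ]
        calls = raw_pileup_call(reads, tiny_panel, 0.3)
        assert len(calls) == 1 and calls[0].fraction == pytest.approx(0.5)

    def test_duplicated_lesion_visible_without_grouping(self, tiny_panel):
        # a single-strand lesion amplified 5x among 100 reads shows up at
        # ~5% raw fraction -- noise that duplex calling suppresses
        pos = int(tiny_panel.positions[0])
        locus = tiny_panel.by_position()[pos]
        lesion_allele = "T" if locus.ref != "T" else "G"
        reads = [
            make_read(f"r{i}", "top", calls={pos: locus.ref}) for i in range(95)
        ] + [
            make_read(f"l{i}", "top", calls={pos: lesion_allele})
            for i in range(5)
        ]
        calls = raw_pileup_call(reads, tiny_panel, 0.04)
        keys = {c.key for c in calls}
        assert (locus.contig, pos, lesion_allele) in keys

    def test_empty_reads_no_calls(self, tiny_panel):
        assert raw_pileup_call([], tiny_panel, 0.1) == []


class TestSensitivitySpecificity:
    def test_sensitivity_fractions(self, tiny_panel):
        truth = [("c", i, "T") for i in range(110)]
        calls = [VariantCall("c", i, "A", "T", 3, 10) for i in range(55)]
        assert sensitivity(calls, truth) == 0.5
        assert sensitivity([], truth) == 0.0
        assert sensitivity(
            [VariantCall("c", i, "A", "T", 3, 10) for i in range(110)], truth
        ) == 1.0

    def test_rejects_empty_truth(self):
        with pytest.raises(ValueError):
            sensitivity([], [])

    def test_theoretical_false_calls_times_five(self):
        assert theoretical_false_calls(1000 + 110, 110) == 5000

    def test_perfect_specificity(self):
        truth = [("c", i, "T") for i in range(110)]
        spec, fpkb = specificity_fp_per_kb([], 46_000, truth)
        assert spec == 1.0 and fpkb == 0.0

    def test_fp_per_kb_arithmetic(self):
        truth = [("c", 999_999, "T")]
        calls = [VariantCall("c", i, "A", "G", 2, 10) for i in range(46)]
        spec, fpkb = specificity_fp_per_kb(calls, 46_000, truth)
        assert fpkb == pytest.approx(1.0)
        assert spec == pytest.approx(1.0 - 46 / ((46_000 - 1) * 5))


class TestRocAuc:
    def pile_from_counts(self, panel, truth_counts, noise_counts):
        """Pileup where each truth locus gets truth_counts[i] ALT molecules
        and each locus also carries a spurious allele with noise_counts[i]."""
        counts = {}
        from collections import Counter

        for locus, t_n, f_n in zip(panel.loci, truth_counts, noise_counts):
            ctr = Counter({locus.ref: 50})
            if t_n:
                ctr[locus.alt] = t_n
            if f_n:
                noise_allele = next(
                    b for b in "ACGT" if b not in (locus.ref, locus.alt)
                )
                ctr[noise_allele] = f_n
            counts[locus.pos] = ctr
        return PileupCounts(contig=panel.loci[0].contig, counts=counts)

    def test_perfect_separation_auc_one(self):
        panel = make_panel(10, 0, 0, span_bp=200)
        pile = self.pile_from_counts(panel, [3] * 10, [0] * 10)
        report = roc_auc(pile, panel, panel.truth())
        assert report.auc == pytest.approx(1.0)
        assert report.sensitivity == 1.0

    def test_exchangeable_counts_auc_half(self, rng):
        # truth and noise counts drawn from one distribution; the
        # interrogated span is sized so the theoretical false-call count
        # equals the truth count, making the axes symmetric
        n = 200
        panel = make_panel(n, 0, 0, span_bp=10 * n)
        counts = rng.poisson(3.0, size=2 * n)
        pile = self.pile_from_counts(panel, counts[:n], counts[n:])
        span = n + n // 5  # (span - n) * 5 == n theoretical false calls
        report = roc_auc(pile, panel, panel.truth(), interrogated_positions=span)
        # permutation oracle: AUC of exchangeable scores concentrates at 1/2
        assert report.auc == pytest.approx(0.5, abs=0.1)

    def test_auc_in_unit_interval_and_sensitivity_monotone(self, rng):
        panel = make_panel(20, 0, 0, span_bp=400)
        pile = self.pile_from_counts(
            panel, rng.poisson(2.0, 20), rng.poisson(1.0, 20)
        )
        report = roc_auc(pile, panel, panel.truth())
        assert 0.0 <= report.auc <= 1.0
        sens = [
            sensitivity(call_variants(pile, panel, t), panel.truth())
            for t in range(1, pile.max_count() + 2)
        ]
        assert sens == sorted(sens, reverse=True)


class TestCompareSensitivities:
    def test_identical_calls_p_one(self):
        truth = [("c", i, "T") for i in range(20)]
        calls = [VariantCall("c", i, "A", "T", 3, 10) for i in range(10)]
        assert compare_sensitivities(calls, calls, truth) == pytest.approx(1.0)

    def test_extreme_difference_small_p(self):
        truth = [("c", i, "T") for i in range(100)]
        all_calls = [VariantCall("c", i, "A", "T", 3, 10) for i in range(100)]
        assert compare_sensitivities(all_calls, [], truth) < 1e-7
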