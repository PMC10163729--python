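"""Synthetic library generator: panel, fragmentation, molecules, reads."""

import dataclasses

import numpy as np
import pytest

from umicollide import (
    FragmentationModel,
    Locus,
    PanelDefinition,
    SimulationConfig,
    default_panel,
    fragment_endpoints,
    generate_reads,
    make_panel,
    simulate_library,
    simulate_molecules,
)
from umicollide.simulate import _endpoints_vector


class TestPanel:
    def test_default_panel_composition(self):
        panel = default_panel()
        assert len(panel.loci) == 110
        assert panel.class_counts() == {"snv": 70, "deletion": 20, "insertion": 20}
        assert panel.interrogated_span_bp == 46_000
        positions = panel.positions
        assert len(set(positions.tolist())) == 110
        assert positions.max() < 46_000

    def test_rejects_duplicate_positions(self):
        locus = Locus("c", 10, "A", "T", "snv")
        with pytest.raises(ValueError, match="duplicate"):
            PanelDefinition((locus, locus), 100)

    def test_rejects_inconsistent_alleles(self):
        with pytest.raises(ValueError, match="deletion"):
            PanelDefinition((Locus("c", 10, "A", "AT", "deletion"),), 100)

    def test_truth_keys(self, small_panel):
        truth = small_panel.truth()
        assert len(truth) == 11
        assert all(len(k) == 3 for k in truth)


class TestFragmentEndpoints:
    def test_degenerate_nucleosomal_grid(self, rng):
        model = FragmentationModel(
            "nucleosomal", cut_jitter_sd=0.0, core_cut_rate=0.0
        )
        period = model.grid_period
        pairs = {
            fragment_endpoints(model, locus, rng)
            for locus in [10, 250, 999, 5000]
            for _ in range(50)
        }
        for start, end in pairs:
            assert (end - start) % period == 0
            assert start % period == 0
        assert len(pairs) <= 4  # finite endpoint support

    def test_nucleosomal_fewer_distinct_endpoints_than_shear(self, rng):
        n = 10_000
        loci = np.full(n, 5_000)
        nucl = FragmentationModel("nucleosomal")
        shear = FragmentationModel(
            "random_shear",
            mean_fragment_len=nucl.grid_period,
            fragment_len_sd=30.0,
        )
        distinct = {}
        for name, model in [("nucl", nucl), ("shear", shear)]:
            s, e = _endpoints_vector(model, loci, rng)
            distinct[name] = len(set(zip(s.tolist(), e.tolist())))
        assert distinct["nucl"] < distinct["shear"]

    def test_shear_mean_length(self, rng):
        n, mean, sd = 10_000, 170.0, 30.0
        model = FragmentationModel("random_shear", mean, sd)
        s, e = _endpoints_vector(model, np.full(n, 2000), rng)
        lengths = e - s
        se = sd / np.sqrt(n)
        assert lengths.mean() == pytest.approx(mean, abs=3 * se + 0.5)

    def test_always_covers_locus(self, rng):
        for model in (
            FragmentationModel("random_shear", 170, 30),
            FragmentationModel("nucleosomal"),
        ):
            for locus in [0, 3, 200, 12_345]:
                start, end = fragment_endpoints(model, locus, rng)
                assert start <= locus < end


def config(panel, **kw):
    base = dict(panel=panel, input_ng=2.0, lcr=0.5, vaf=0.1, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateMolecules:
    def test_vaf_zero_means_no_alt(self, small_panel):
        mols = simulate_molecules(config(small_panel, vaf=0.0))
        alts = {l.pos: l.alt for l in small_panel.loci}
        for mol in mols:
            for pos, allele in mol.genotype.items():
                assert allele != alts[pos]

    def test_count_concentrates_on_model_mean(self, small_panel):
        cfg = config(small_panel, input_ng=20.0, lcr=0.5, seed=11)
        n = len(simulate_molecules(cfg))
        assert abs(n - 3000) < 4 * np.sqrt(3000)

    def test_alt_fraction_binomial(self, small_panel, rng):
        cfg = config(small_panel, input_ng=70.0, lcr=1.0, vaf=0.01, seed=3)
        mols = simulate_molecules(cfg, rng)
        assert len(mols) > 10_000
        alts = {l.pos: l.alt for l in small_panel.loci}
        n_alt = sum(
            allele == alts[pos]
            for mol in mols
            for pos, allele in mol.genotype.items()
        )
        n_calls = sum(len(m.genotype) for m in mols)
        se = np.sqrt(0.01 * 0.99 / n_calls)
        assert n_alt / n_calls == pytest.approx(0.01, abs=3 * se)

    def test_rejects_mixture_breaking_vaf(self, small_panel):
        with pytest.raises(ValueError, match="vaf"):
            config(small_panel, vaf=0.6)

    def test_lesions_never_on_both_strands(self, small_panel):
        cfg = config(small_panel, lesion_rate=0.4, seed=5)
        for mol in simulate_molecules(cfg):
            loci_top = {p for (s, p) in mol.lesions if s == "top"}
            loci_bottom = {p for (s, p) in mol.lesions if s == "bottom"}
            assert not (loci_top & loci_bottom)


class TestGenerateReads:
    def test_clean_reads_equal_genotype(self, small_panel):
        cfg = config(
            small_panel, seq_error_rate=0.0, lesion_rate=0.0, umi_error_rate=0.0
        )
        mols, reads = simulate_library(cfg)
        by_id = {m.id: m for m in mols}
        assert reads
        for r in reads:
            assert dict(r.calls) == by_id[r.molecule_id].genotype

    def test_mean_reads_per_molecule(self, small_panel, rng):
        cfg = config(small_panel, input_ng=70.0, lcr=1.0, seed=9)
        mols = simulate_molecules(cfg, rng)
        reads = generate_reads(mols, cfg, rng)
        mean = len(reads) / len(mols)
        se = np.sqrt(5.0 / len(mols))
        assert mean == pytest.approx(5.0, abs=3 * se)

    def test_duplicates_share_key_and_complementary_umi_order(self, small_panel):
        cfg = config(small_panel, umi_error_rate=0.0)
        mols, reads = simulate_library(cfg)
        mol = next(m for m in mols if any(r.molecule_id == m.id for r in reads))
        mine = [r for r in reads if r.molecule_id == mol.id]
        assert len({r.fragment_key for r in mine}) == 1
        for r in mine:
            expected = (
                (mol.umi_top, mol.umi_bottom)
                if r.strand == "top"
                else (mol.umi_bottom, mol.umi_top)
            )
            assert r.umi_observed == expected

    def test_lesion_restricted_to_one_strand(self, small_panel):
        cfg = config(
            small_panel,
            lesion_rate=0.3,
            seq_error_rate=0.0,
            umi_error_rate=0.0,
            seed=21,
        )
        mols, reads = simulate_library(cfg)
        by_mol = {}
        for r in reads:
            by_mol.setdefault(r.molecule_id, []).append(r)
        checked = 0
        for mol in mols:
            for (strand, pos), allele in mol.lesions.items():
                other = "bottom" if strand == "top" else "top"
                for r in by_mol.get(mol.id, []):
                    if r.strand == strand:
                        assert r.calls[pos] == allele
                    elif r.strand == other:
                        assert r.calls[pos] == mol.genotype[pos]
                        checked += 1
        assert checked > 0

    def test_seed_reproducibility(self, small_panel):
        cfg = config(small_panel)
        a = simulate_library(cfg)
        b = simulate_library(cfg)
        assert a == b
        c = simulate_library(dataclasses.replace(cfg, seed=cfg.seed + 1))
        assert c != a
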