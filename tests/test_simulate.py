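"""Breeding-population simulator: meiosis, breeding, phenotypes, selection."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ilqtl import simulate
from ilqtl.core import MarkerMap, expected_genotype_freqs
from ilqtl.simulate import (
    QtlEffect,
    SelectionSpec,
    SimConfig,
    apply_selection,
    breed_population,
    build_marker_map,
    generate_dataset,
    simulate_gamete,
    simulate_phenotypes,
)


def _map_two_markers(cm_dist: float) -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["a", "b"],
                "chrom": [1, 1],
                "pos_bp": [1, 2],
                "cM": [0.0, cm_dist],
            }
        )
    )


class TestGamete:
    def test_zero_length_chromosome_copies_one_haplotype(self, rng):
        markers = _map_two_markers(0.0)
        h0 = np.array([0, 0])
        h1 = np.array([1, 1])
        for _ in range(50):
            g = simulate_gamete(h0, h1, markers, rng)
            assert g.tolist() in ([0, 0], [1, 1])

    def test_recombinant_fraction_matches_haldane(self, rng):
        markers = _map_two_markers(100.0)
        n = 20_000
        h0 = np.zeros((n, 2), dtype=np.uint8)
        h1 = np.ones((n, 2), dtype=np.uint8)
        g = simulate._gametes(h0, h1, markers.recomb_fractions(), rng)
        frac = (g[:, 0] != g[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-2.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_selfing_homozygote_is_identity(self, rng, tiny_map):
        h = np.array([0, 1, 1, 0, 0, 1, 0, 0, 1, 1], dtype=np.uint8)
        g = simulate_gamete(h, h.copy(), tiny_map, rng)
        assert np.array_equal(g, h)

    def test_empty_map_rejected(self, rng):
        empty = MarkerMap(
            pd.DataFrame(columns=["marker_id", "chrom", "pos_bp", "cM"])
        )
        with pytest.raises(ValueError):
            simulate_gamete(np.array([]), np.array([]), empty, rng)


class TestBreedPopulation:
    def test_bc1f4_class_frequencies(self):
        cfg = SimConfig(
            n_chromosomes=12,
            n_markers_per_chrom=1,
            n_lines=(10_000,),
            donors=("Teqing",),
            selection=None,
            n_selected=None,
        )
        rng = np.random.default_rng(5)
        pop, _ = breed_population(cfg, "Teqing", rng)
        e = expected_genotype_freqs(1, 3)
        # markers on different chromosomes are independent
        for code, pi in ((0, e.pi_A), (1, e.pi_H), (2, e.pi_B)):
            freq = (pop.genotypes == code).mean()
            se = np.sqrt(float(pi) * (1 - float(pi)) / (10_000 * 12))
            assert abs(freq - float(pi)) < 3 * se

    def test_allele_frequency_conserved_by_selfing(self):
        rng = np.random.default_rng(6)
        for s in (0, 3):
            cfg = SimConfig(
                n_chromosomes=12,
                n_markers_per_chrom=1,
                n_lines=(10_000,),
                donors=("Teqing",),
                scheme=(1, s),
                selection=None,
                n_selected=None,
            )
            pop, _ = breed_population(cfg, "Teqing", rng)
            freq = pop.genotypes.mean() / 2.0
            se = np.sqrt(0.25 * 0.75 / (10_000 * 12))
            assert abs(freq - 0.25) < 4 * se

    def test_f1_is_fully_heterozygous(self, rng):
        cfg = SimConfig(
            n_chromosomes=2,
            n_markers_per_chrom=5,
            n_lines=(20,),
            donors=("Teqing",),
            scheme=(0, 0),
            selection=None,
            n_selected=None,
        )
        pop, _ = breed_population(cfg, "Teqing", rng)
        assert (pop.genotypes == 1).all()

    def test_seeded_reproducibility(self, small_config):
        a, _ = breed_population(small_config, "Teqing", np.random.default_rng(42))
        b, _ = breed_population(small_config, "Teqing", np.random.default_rng(42))
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_mosaics_tile_chromosomes(self, small_config, rng):
        pop, truth = breed_population(small_config, "Teqing", rng)
        mosaics = truth.mosaics(0)
        for chrom, haps in mosaics.items():
            for segs in haps:
                assert segs[0][0] == 1
                for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                    assert s2 == e1 + 1


class TestPhenotypes:
    def test_no_effects_gives_baseline_scale(self, small_config, rng):
        pop, truth = breed_population(small_config, "Teqing", rng)
        ph = simulate_phenotypes(pop, truth, small_config, rng)
        gy = ph[ph["environment"] == "normal"]["GY"]
        base = simulate.BASELINES["normal"]["GY"]
        assert abs(gy.mean() - base) < 0.2 * base

    def test_planted_additive_effect_separates_dosage_groups(self):
        qtl = QtlEffect(
            chrom=1,
            pos_bp=15_000_001,
            trait="GY",
            effects={"normal": {"Teqing": 2.0}},
        )
        cfg = SimConfig(
            n_chromosomes=2,
            n_markers_per_chrom=10,
            n_lines=(4000,),
            donors=("Teqing",),
            qtl=(qtl,),
            heritability={"normal": 0.9},
            selection=None,
            n_selected=None,
            yield_component_coupling=False,
        )
        rng = np.random.default_rng(8)
        pop, truth = breed_population(cfg, "Teqing", rng)
        ph = simulate_phenotypes(pop, truth, cfg, rng, environments=("normal",))
        j = simulate._qtl_marker_index(pop.markers, 1, 15_000_001)
        gy = ph.set_index("line_id").loc[pop.line_ids, "GY"].to_numpy()
        d = pop.genotypes[:, j]
        diff = gy[d == 2].mean() - gy[d == 0].mean()
        assert abs(diff - 4.0) < 0.5

    def test_opposite_sign_effects_reduce_cross_environment_correlation(self):
        base = dict(
            n_chromosomes=2,
            n_markers_per_chrom=10,
            n_lines=(1000,),
            donors=("Teqing",),
            heritability={"low_nitrogen": 0.8, "normal": 0.8},
            selection=None,
            n_selected=None,
            yield_component_coupling=False,
            polygenic_cv=0.02,
        )
        gxe = QtlEffect(
            chrom=1, pos_bp=15_000_001, trait="GY",
            effects={"low_nitrogen": {"Teqing": -2.0}, "normal": {"Teqing": 2.0}},
        )
        no_gxe = QtlEffect(
            chrom=1, pos_bp=15_000_001, trait="GY",
            effects={"low_nitrogen": {"Teqing": 2.0}, "normal": {"Teqing": 2.0}},
        )
        corr = {}
        for name, q in (("gxe", gxe), ("no_gxe", no_gxe)):
            cfg = SimConfig(qtl=(q,), **base)
            rng = np.random.default_rng(9)
            pop, truth = breed_population(cfg, "Teqing", rng)
            ph = simulate_phenotypes(
                pop, truth, cfg, rng, environments=("low_nitrogen", "normal")
            )
            wide = ph.pivot_table(index="line_id", columns="environment", values="GY")
            corr[name] = wide["low_nitrogen"].corr(wide["normal"])
        assert corr["gxe"] < corr["no_gxe"] - 0.2

    def test_heritability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(heritability={"normal": 1.5})


class TestSelection:
    def test_keep_all_is_identity(self, small_config, rng):
        pop, truth = breed_population(small_config, "Teqing", rng)
        ph = simulate_phenotypes(pop, truth, small_config, rng)
        sel, idx = apply_selection(pop, ph, "GY", "drought", proportion=1.0)
        assert sel.line_ids == pop.line_ids
        assert np.array_equal(idx, np.arange(pop.n_lines))

    def test_selection_shifts_donor_allele_frequency_at_qtl(self):
        a = 0.6
        qtl = QtlEffect(
            chrom=1, pos_bp=15_000_001, trait="GY",
            effects={"drought": {"Teqing": a}},
        )
        cfg = SimConfig(
            n_chromosomes=12,
            n_markers_per_chrom=10,
            n_lines=(1250,),
            donors=("Teqing",),
            qtl=(qtl,),
            selection=SelectionSpec("GY", "drought", proportion=0.2, rounds=2),
            n_selected=None,
            yield_component_coupling=False,
            seed=10,
        )
        rng = np.random.default_rng(10)
        pop, truth = breed_population(cfg, "Teqing", rng)
        sel, _ = simulate.select_lines(pop, truth, cfg, rng, n_final=200)
        j = simulate._qtl_marker_index(sel.markers, 1, 15_000_001)
        dosage_sum = int(sel.genotypes[:, j].sum())
        # one-sided binomial test of donor-allele excess over the neutral 1/4
        p = stats.binomtest(
            dosage_sum, 2 * sel.n_lines, 0.25, alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_selection_on_pure_noise_leaves_frequencies_near_null(self):
        cfg = SimConfig(
            n_chromosomes=12,
            n_markers_per_chrom=2,
            n_lines=(200,),
            donors=("Teqing",),
            polygenic_cv=0.0,
            selection=SelectionSpec("GY", "drought", proportion=0.2, rounds=1),
            n_selected=None,
            yield_component_coupling=False,
        )
        rng = np.random.default_rng(11)
        hits = 0
        total = 0
        from ilqtl import msd

        for _ in range(30):
            pop, truth = breed_population(cfg, "Teqing", rng)
            sel, _ = simulate.select_lines(pop, truth, cfg, rng)
            scan = msd.msd_joint_scan([sel])
            pv = scan["p_value"].to_numpy()
            hits += int((pv < 0.001).sum())
            total += pv.size
        assert hits / total < 0.01

    def test_emptying_selection_rejected(self, small_config, rng):
        pop, truth = breed_population(small_config, "Teqing", rng)
        ph = simulate_phenotypes(pop, truth, small_config, rng)
        with pytest.raises(ValueError):
            apply_selection(pop, ph, "GY", "drought", n_keep=0)


class TestGenerateDataset:
    @pytest.fixture
    def small_dataset_config(self):
        return SimConfig(
            n_chromosomes=3,
            n_markers_per_chrom=20,
            seed=123,
        )

    def test_line_counts_before_and_after_selection(self, tmp_path, small_dataset_config):
        bundle = generate_dataset(small_dataset_config, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        initial = [v["n_initial"] for v in truth["populations"].values()]
        selected = [v["n_selected"] for v in truth["populations"].values()]
        assert sorted(initial) == [63, 68, 75]
        assert sorted(selected) == [18, 18, 21]
        assert [p.n_lines for p in bundle["populations"]] == [18, 18, 21]

    def test_same_seed_gives_identical_files(self, tmp_path, small_dataset_config):
        import hashlib

        def checksums(d):
            return {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(d.glob("*.tsv"))
            }

        generate_dataset(small_dataset_config, tmp_path / "a")
        generate_dataset(small_dataset_config, tmp_path / "b")
        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")

    def test_zero_donors_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(donors=(), n_lines=())
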