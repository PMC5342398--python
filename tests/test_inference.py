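import numpy as np
import pytest
from oracles import bh_oracle

from mirsea import simulate
from mirsea.inference import (
    MirseaConfig,
    bh_fdr,
    empirical_pvalue,
    normalize_es,
    permute_labels,
    run_mirsea,
)
from mirsea.io import ExpressionDataset, write_results


def small_run_inputs(seed=0, **design_overrides):
    defaults = dict(
        n_mirnas=60,
        n_genes=800,
        n_pathways=8,
        pathway_size_range=(20, 30),
        targets_per_mirna_range=(10, 15),
        n_planted=6,
        planted_overlap=8,
        n_samples_per_class=5,
    )
    defaults.update(design_overrides)
    design = simulate.SyntheticDesign(seed=seed, **defaults)
    return (
        simulate.make_expression(design),
        simulate.make_target_map(design),
        simulate.make_pathways(design),
        design,
    )


class TestPermuteLabels:
    def test_class_sizes_preserved(self):
        design = simulate.SyntheticDesign(seed=1, n_samples_per_class=4)
        ds = simulate.make_expression(design)
        masks = permute_labels(ds, n_perm=50, seed=3)
        assert masks.shape == (50, 8)
        assert np.all(masks.sum(axis=1) == 4)

    def test_stream_is_deterministic(self):
        design = simulate.SyntheticDesign(seed=1, n_samples_per_class=4)
        ds = simulate.make_expression(design)
        a = permute_labels(ds, 20, seed=9)
        b = permute_labels(ds, 20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_small_design_warns_and_duplicates(self):
        ds = ExpressionDataset(
            mirna_ids=["m1", "m2"],
            values=np.arange(8.0).reshape(2, 4),
            sample_ids=["s1", "s2", "s3", "s4"],
            phenotype=["A", "A", "B", "B"],
            classes=("A", "B"),
        )
        with pytest.warns(UserWarning, match="only 6 distinct"):
            masks = permute_labels(ds, n_perm=50, seed=0)
        # C(4,2)=6 distinct labelings: duplicates must occur among 50 draws
        assert len({tuple(row) for row in masks}) <= 6

    def test_swapped_dataset_gets_complementary_masks(self):
        design = simulate.SyntheticDesign(seed=2, n_samples_per_class=5)
        ds = simulate.make_expression(design)
        a = permute_labels(ds, 10, seed=4)
        b = permute_labels(ds.swap_classes(), 10, seed=4)
        np.testing.assert_array_equal(a, ~b)


class TestEmpiricalPvalue:
    def test_positive_branch_full_denominator(self):
        assert empirical_pvalue(2.0, np.array([1, 1, 3, 1]), denominator="all") == 0.25

    def test_negative_branch_full_denominator(self):
        null = np.array([-1.0, 0.0, 0.5, -0.95])
        assert empirical_pvalue(-0.9, null, denominator="all") == 0.5

    def test_observed_beyond_all_nulls(self):
        assert empirical_pvalue(0.99, np.array([0.1, -0.5, 0.2]), denominator="all") == 0.0
        assert empirical_pvalue(0.99, np.array([0.1, -0.5, 0.2])) == 0.0

    def test_same_sign_denominator(self):
        null = np.array([0.5, 0.3, -0.4, -0.2, 0.1])
        # 1 of 3 positive nulls exceeds 0.4
        assert empirical_pvalue(0.4, null) == pytest.approx(1 / 3)
        # 1 of 2 negative nulls is below -0.3
        assert empirical_pvalue(-0.3, null) == pytest.approx(1 / 2)

    def test_zero_observed_is_one(self):
        assert empirical_pvalue(0.0, np.array([1.0, -1.0])) == 1.0

    def test_smoothing_bounds_away_from_zero(self):
        null = np.array([0.1, 0.2, -0.3])
        assert empirical_pvalue(0.9, null, smooth=True) == pytest.approx(1 / 3)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty null"):
            empirical_pvalue(0.5, np.array([]))


class TestBhFdr:
    def test_evenly_spaced_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_values_follow_their_pvalues_under_reordering(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestNormalizeEs:
    def test_positive_rescaling(self):
        assert normalize_es(0.6, np.array([0.3, 0.3, -0.1])) == pytest.approx(2.0)

    def test_negative_rescaling_preserves_sign(self):
        assert normalize_es(-0.4, np.array([-0.2, -0.2, 0.5])) == pytest.approx(-2.0)

    def test_missing_same_sign_null_warns_nan(self):
        with pytest.warns(UserWarning, match="NmiRES undefined"):
            assert np.isnan(normalize_es(0.5, np.array([-0.1, -0.2])))

    def test_zero_observed_maps_to_zero(self):
        assert normalize_es(0.0, np.array([0.5, -0.5])) == 0.0


class TestRunMirsea:
    def test_constant_expression_aborts(self):
        ds, tm, pw, _ = small_run_inputs(seed=3)
        flat = ExpressionDataset(
            mirna_ids=ds.mirna_ids,
            values=np.ones_like(ds.values),
            sample_ids=ds.sample_ids,
            phenotype=ds.phenotype,
            classes=ds.classes,
        )
        with pytest.raises(ValueError, match="degenerate data|zero variance"):
            run_mirsea(flat, tm, pw, MirseaConfig(n_perm=5, seed=0, min_size=2))

    def test_result_invariants(self):
        ds, tm, pw, design = small_run_inputs(seed=4)
        res = run_mirsea(ds, tm, pw, MirseaConfig(n_perm=50, seed=5, min_size=2))
        assert res
        for r in res:
            assert 0.0 <= r.p_value <= 1.0
            assert 0.0 <= r.fdr <= 1.0
            assert -1.0 <= r.mires <= 1.0
            assert np.sign(r.nmires) == np.sign(r.mires)
            assert (r.direction == "down-regulated") == (r.mires > 0)
            assert set(r.core.mirna_ids) <= set(ds.mirna_ids)

    def test_planted_pathway_recovered_in_quick_run(self):
        ds, tm, pw, design = small_run_inputs(seed=6)
        res = run_mirsea(ds, tm, pw, MirseaConfig(n_perm=100, seed=7, min_size=2))
        order = sorted(res, key=lambda r: (r.fdr, -abs(r.nmires), r.pathway_id))
        assert order[0].pathway_id == design.planted_pathway

    def test_same_seed_gives_byte_identical_results(self, tmp_path):
        ds, tm, pw, _ = small_run_inputs(seed=8)
        cfg = MirseaConfig(n_perm=40, seed=9, min_size=2)
        out1, out2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_results(run_mirsea(ds, tm, pw, cfg), out1)
        write_results(run_mirsea(ds, tm, pw, cfg), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_class_swap_exchanges_groups_exactly(self):
        ds, tm, pw, _ = small_run_inputs(seed=10)
        cfg = MirseaConfig(n_perm=60, seed=11, min_size=2)
        a = {r.pathway_id: r for r in run_mirsea(ds, tm, pw, cfg)}
        b = {r.pathway_id: r for r in run_mirsea(ds.swap_classes(), tm, pw, cfg)}
        assert set(a) == set(b)
        for k in a:
            assert b[k].mires == -a[k].mires
            assert b[k].nmires == -a[k].nmires
            assert b[k].p_value == a[k].p_value
            assert {a[k].direction, b[k].direction} == {
                "down-regulated",
                "up-regulated",
            }

    def test_pooled_fdr_mode(self):
        ds, tm, pw, _ = small_run_inputs(seed=12)
        cfg = MirseaConfig(n_perm=30, seed=13, min_size=2, fdr_mode="pooled")
        res = run_mirsea(ds, tm, pw, cfg)
        np.testing.assert_allclose(
            sorted(r.fdr for r in res),
            sorted(bh_oracle(np.array([r.p_value for r in res]))),
            atol=1e-12,
        )


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text("n_perm: 77\nseed: 5\nq: 2\nfdr_mode: pooled\n")
        cfg = MirseaConfig.from_file(f)
        assert (cfg.n_perm, cfg.seed, cfg.q, cfg.fdr_mode) == (77, 5, 2, "pooled")

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text("nperm: 77\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            MirseaConfig.from_file(f)
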