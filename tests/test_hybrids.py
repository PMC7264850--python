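"""Hybrid index, heterozygosity, in-silico crossing, class assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hzclines.hybrids import (
    AncestryPoint,
    ancestry_point,
    build_class_clouds,
    classify,
    simulate_cross,
)


def _diagnostic_pools(n_loci=101, n_each=50):
    west = np.zeros((n_each, n_loci))
    east = np.full((n_each, n_loci), 2.0)
    return west, east


class TestAncestryPoint:
    def test_all_heterozygous_is_f1_corner(self):
        ap = ancestry_point(np.ones(101))
        assert ap.hi == 0.5
        assert ap.h == 1.0

    def test_pure_east_corner(self):
        ap = ancestry_point(np.full(50, 2.0))
        assert ap.hi == 1.0
        assert ap.h == 0.0

    def test_hand_counted_example(self):
        ap = ancestry_point(np.array([2.0, 1.0, 0.0, 1.0]))
        assert ap.hi == pytest.approx(0.5)
        assert ap.h == pytest.approx(0.5)

    def test_missing_loci_dropped(self):
        ap = ancestry_point(np.array([2.0, np.nan, 1.0]))
        assert ap.n_loci_used == 2
        assert ap.hi == pytest.approx(3.0 / 4.0)

    def test_all_missing_names_tree(self):
        with pytest.raises(ValueError, match="treeX"):
            ancestry_point(np.array([np.nan, np.nan]), "treeX")

    def test_invariance_to_locus_order(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 60).astype(float)
        a = ancestry_point(g)
        b = ancestry_point(g[::-1].copy())
        assert (a.hi, a.h) == (b.hi, b.h)


class TestSimulateCross:
    def test_fixed_pools_give_all_heterozygotes(self):
        west, east = _diagnostic_pools()
        off = simulate_cross(west, east, 200, seed=1)
        assert np.all(off == 1.0)

    def test_offspring_frequency_matches_parental_mean(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, (40, 30)).astype(float)
        b = rng.integers(0, 3, (40, 30)).astype(float)
        off = simulate_cross(a, b, 5000, seed=3)
        expected = (a.mean(axis=0) + b.mean(axis=0)) / 4.0  # allele frequency
        got = off.mean(axis=0) / 2.0
        se = np.sqrt(expected * (1 - expected) / (2 * 5000)) + 1e-9
        # parent resampling adds variance; 3 SE with a generous floor
        assert np.all(np.abs(got - expected) < 3 * se + 0.05)

    def test_missing_parent_locus_propagates(self):
        a = np.array([[1.0, np.nan]])
        b = np.array([[1.0, 2.0]])
        off = simulate_cross(a, b, 50, seed=4)
        assert np.all(np.isnan(off[:, 1]))
        assert np.all(np.isfinite(off[:, 0]))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            simulate_cross(np.zeros((0, 5)), np.zeros((3, 5)), 10, seed=0)

    def test_determinism(self):
        west, east = _diagnostic_pools(20, 10)
        o1 = simulate_cross(west, east, 50, seed=7)
        o2 = simulate_cross(west, east, 50, seed=7)
        np.testing.assert_array_equal(o1, o2)


class TestClassClouds:
    def test_diagnostic_f1_collapses_to_point(self):
        west, east = _diagnostic_pools()
        clouds = build_class_clouds(west, east, 500, seed=0)
        assert np.allclose(clouds["F1"].mean, [0.5, 1.0])
        assert np.allclose(clouds["F1"].points.std(axis=0), 0.0)

    def test_mendelian_means_within_3se(self):
        west, east = _diagnostic_pools()
        clouds = build_class_clouds(west, east, 500, seed=1)
        n_loci, n = 101, 500
        expectations = {
            "F2": (0.5, 0.5),
            "BC_east": (0.75, 0.5),
            "BC_west": (0.25, 0.5),
        }
        for cls, (e_hi, e_h) in expectations.items():
            m = clouds[cls].mean
            se_hi = np.sqrt(0.5 * 0.5 / (2 * n_loci)) / np.sqrt(n) * 2
            se_h = np.sqrt(0.5 * 0.5 / n_loci) / np.sqrt(n) * 2
            assert abs(m[0] - e_hi) < 3 * max(se_hi, 0.01)
            assert abs(m[1] - e_h) < 3 * max(se_h, 0.01)

    def test_semi_diagnostic_pools_dilute_f1_heterozygosity(self):
        rng = np.random.default_rng(9)
        # parental frequency differential 0.8: west p=0.1, east p=0.9
        west = rng.binomial(2, 0.1, (50, 101)).astype(float)
        east = rng.binomial(2, 0.9, (50, 101)).astype(float)
        clouds = build_class_clouds(west, east, 500, seed=2)
        # analytic: P(het) = p_w (1-p_e) + (1-p_w) p_e at each locus
        expected_h = 0.1 * 0.1 + 0.9 * 0.9
        assert clouds["F1"].mean[1] < 1.0
        assert clouds["F1"].mean[1] == pytest.approx(expected_h, abs=0.05)

    def test_default_cloud_size_is_500(self):
        west, east = _diagnostic_pools(20, 10)
        clouds = build_class_clouds(west, east, seed=0)
        for cls in ("F1", "F2", "BC_west", "BC_east"):
            assert len(clouds[cls].points) == 500


class TestClassify:
    def test_point_at_cloud_mean(self):
        rng = np.random.default_rng(3)
        west = rng.binomial(2, 0.05, (50, 101)).astype(float)
        east = rng.binomial(2, 0.95, (50, 101)).astype(float)
        clouds = build_class_clouds(west, east, 500, seed=3)
        m = clouds["F2"].mean
        label, d2 = classify(AncestryPoint("x", m[0], m[1], 101), clouds)
        assert label == "F2"
        assert d2["F2"] == pytest.approx(0.0, abs=1e-9)

    def test_far_point_unassigned(self):
        west, east = _diagnostic_pools()
        clouds = build_class_clouds(west, east, 500, seed=4)
        label, _ = classify(AncestryPoint("x", 0.5, 0.0, 101), clouds)
        assert label == "advanced/unassigned"

    def test_advanced_backcross_swarm_never_f1(self):
        rng = np.random.default_rng(5)
        west = rng.binomial(2, 0.05, (60, 101)).astype(float)
        east = rng.binomial(2, 0.95, (60, 101)).astype(float)
        clouds = build_class_clouds(west, east, 500, seed=5)
        # third-generation hybrids: F1 (gen 1) -> BC1 (gen 2) -> BC2 (gen 3)
        f1 = simulate_cross(west, east, 200, seed=6)
        bc1w = simulate_cross(f1, west, 100, seed=7)
        bc1e = simulate_cross(f1, east, 100, seed=8)
        swarm = np.vstack([
            simulate_cross(bc1w, west, 100, seed=9),
            simulate_cross(bc1e, east, 100, seed=10),
        ])
        labels = [
            classify(ancestry_point(g, f"s{i}"), clouds)[0]
            for i, g in enumerate(swarm)
        ]
        assert labels.count("F1") == 0
        frac_bc_or_advanced = np.mean([
            l in ("BC_west", "BC_east", "advanced/unassigned") for l in labels
        ])
        assert frac_bc_or_advanced > 0.5

    def test_no_clouds_errors(self):
        with pytest.raises(ValueError):
            classify(AncestryPoint("x", 0.5, 0.5, 10), {})


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 2), min_size=1, max_size=60))
def test_triangle_constraint(genotype):
    """H <= 2 min(HI, 1-HI): an exact combinatorial bound for any genotype."""
    ap = ancestry_point(np.array(genotype, dtype=float))
    assert ap.h <= 2.0 * min(ap.hi, 1.0 - ap.hi) + 1e-12
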