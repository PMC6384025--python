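"""Scene-generator tests: allocation law, determinism, planted structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compsyn.synthgen import (
    CompetitionParams,
    PlacementError,
    RnascopeClassParams,
    SceneSpec,
    allocate_synapses,
    generate_doublet_scene,
    generate_field_scene,
    generate_rnascope_scene,
)


class TestAllocation:
    def test_symmetric_weights_split_evenly(self):
        counts = allocate_synapses(CompetitionParams((1.0, 1.0), 1000, seed=3))
        se = np.sqrt(1000 * 0.25)
        assert abs(counts[0] - 500) <= 3 * se

    def test_degenerate_weight_gets_everything(self):
        counts = allocate_synapses(CompetitionParams((1.0, 0.0), 40, seed=0))
        assert tuple(counts) == (40, 0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            CompetitionParams((0.0, 0.0), 10)

    def test_matches_seeded_binomial_redraw(self):
        """e=(3,1): the two-cell draw IS Binomial(S, 0.75) under one stream."""
        params = CompetitionParams((3.0, 1.0), 40, seed=123)
        counts = allocate_synapses(params)
        redraw = np.random.default_rng(123).multinomial(40, [0.75, 0.25])
        assert np.array_equal(counts, redraw)

    def test_long_run_mean_matches_binomial(self):
        """Monte-Carlo mean over many seeds within 3 SE of S * p."""
        means = [
            allocate_synapses(CompetitionParams((3.0, 1.0), 40, seed=s))[0]
            for s in range(10_000)
        ]
        se = np.sqrt(40 * 0.75 * 0.25 / 10_000)
        assert abs(np.mean(means) - 30.0) <= 3 * se

    @given(
        w=st.tuples(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5)),
        pool=st.integers(0, 500),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_pool_conservation(self, w, pool, seed):
        counts = allocate_synapses(CompetitionParams(w, pool, seed))
        assert counts.sum() == pool

    def test_gamma_exponent_shifts_shares(self):
        p1 = CompetitionParams((2.0, 1.0), 0, gamma=1.0).probabilities()
        p2 = CompetitionParams((2.0, 1.0), 0, gamma=2.0).probabilities()
        assert p2[0] > p1[0]  # sharper competition under gamma > 1


class TestDoubletScene:
    def test_ground_truth_counts_conserve_pool(self, noiseless_doublet):
        _, params, _, gt = noiseless_doublet
        assert sum(gt.per_cell_counts.values()) == params.pool_size

    def test_determinism_bit_identical(self):
        spec = SceneSpec(n_cells=2)
        params = CompetitionParams((1.0, 0.6), 24, seed=7)
        im1, gt1 = generate_doublet_scene(spec, params)
        im2, gt2 = generate_doublet_scene(spec, params)
        for name in im1:
            assert np.array_equal(im1[name].pixels, im2[name].pixels)
        assert gt1.per_cell_counts == gt2.per_cell_counts

    def test_scene_seed_changes_placement_not_counts(self):
        spec = SceneSpec(n_cells=2)
        params = CompetitionParams((1.0, 0.6), 24, seed=7)
        im1, gt1 = generate_doublet_scene(spec, params, scene_seed=1)
        im2, gt2 = generate_doublet_scene(spec, params, scene_seed=2)
        assert gt1.per_cell_counts == gt2.per_cell_counts
        assert not np.array_equal(im1["vglut1"].pixels, im2["vglut1"].pixels)

    def test_zero_coloc_fraction_has_no_pairs(self):
        spec = SceneSpec(n_cells=2, coloc_fraction=0.0)
        params = CompetitionParams((1.0, 1.0), 20, seed=5)
        _, gt = generate_doublet_scene(spec, params)
        assert gt.colocalized_pairs() == []

    def test_short_dendrite_warns_in_ground_truth(self):
        spec = SceneSpec(n_cells=1, n_branches=1, branch_length_um=30.0)
        params = CompetitionParams((1.0,), 5, seed=2)
        _, gt = generate_doublet_scene(spec, params)
        assert any("50" in w for w in gt.warnings)

    def test_transfected_puncta_in_both_postsynaptic_channels(self, noiseless_doublet):
        _, _, images, gt = noiseless_doublet
        gfp = images["psd95gfp"].pixels > 100
        all_post = images["psd95"].pixels > 100
        assert (gfp & ~all_post).sum() == 0  # GFP puncta are a subset


class TestFieldScene:
    def test_cell_masks_disjoint(self):
        spec = SceneSpec(n_cells=4)
        params = CompetitionParams((1.0,) * 4, 60, seed=9)
        _, gt = generate_field_scene(spec, params)
        union = np.zeros(spec.shape, bool)
        for m in gt.cell_masks.values():
            assert not (union & m).any()
            union |= m

    def test_each_punctum_on_its_owner(self):
        spec = SceneSpec(n_cells=4)
        params = CompetitionParams((1.3, 1.0, 1.3, 1.0), 60, seed=4)
        _, gt = generate_field_scene(spec, params)
        for p in gt.puncta:
            owner = gt.cell_masks[p.cell]
            others = [m for c, m in gt.cell_masks.items() if c != p.cell]
            on_owner = owner[p.coords[:, 0], p.coords[:, 1]].sum()
            on_others = max(m[p.coords[:, 0], p.coords[:, 1]].sum() for m in others)
            assert on_owner > on_others

    def test_axon_fragments_below_removal_threshold(self):
        spec = SceneSpec(n_cells=2, n_axon_fragments=4)
        params = CompetitionParams((1.0, 1.0), 20, seed=6)
        images, gt = generate_field_scene(spec, params)
        assert gt.extra["n_axon_fragments"] == 4
        # fragments exist in the raw channels beyond the true cell masks
        raw = (images["tdtomato"].pixels > 100) | (images["egfp"].pixels > 100)
        truth = np.zeros(spec.shape, bool)
        for m in gt.cell_masks.values():
            truth |= m
        extra_px = (raw & ~truth).sum()
        assert 0 < extra_px * spec.pixel_size_um**2 < 50.0 * 4

    def test_one_to_one_plating_is_balanced(self, rng):
        """Red vs green cell counts across fields: no significant difference."""
        from compsyn.field import cell_count_balance

        red, green = [], []
        for _ in range(26):
            n = 4
            colors = rng.integers(0, 2, n)
            red.append(int((colors == 0).sum()))
            green.append(int((colors == 1).sum()))
        res = cell_count_balance(red, green)
        assert res.pvalue > 0.05


class TestRnascopeScene:
    def test_all_zero_counts_no_dots(self):
        spec = SceneSpec(field_size_um=(40.0, 40.0))
        classes = [RnascopeClassParams("null", 2, 0, 0, 0, "fixed")]
        images, gt = generate_rnascope_scene(spec, classes, seed=1)
        assert len(gt.puncta) == 0
        for probe in ("probe_ctip2", "probe_satb2", "probe_efnb3"):
            assert np.ptp(images[probe].pixels) == 0

    def test_fixed_counts_planted_exactly(self):
        spec = SceneSpec(field_size_um=(60.0, 60.0))
        classes = [RnascopeClassParams("CTIP2+", 3, 12, 2, 7, "fixed")]
        _, gt = generate_rnascope_scene(spec, classes, seed=2)
        for nuc in gt.extra["nuclei"]:
            assert nuc["counts"] == {
                "probe_ctip2": 12, "probe_satb2": 2, "probe_efnb3": 7
            }

    def test_overcrowded_request_raises(self):
        spec = SceneSpec(field_size_um=(20.0, 20.0), max_placement_tries=20)
        classes = [RnascopeClassParams("x", 40, 1, 1, 1, "fixed")]
        with pytest.raises(PlacementError):
            generate_rnascope_scene(spec, classes, seed=3)

    def test_poisson_counts_have_planted_mean(self):
        lam = 9.0
        spec = SceneSpec(field_size_um=(150.0, 150.0))
        classes = [RnascopeClassParams("c", 30, 2, 2, lam, "poisson")]
        _, gt = generate_rnascope_scene(spec, classes, seed=4)
        counts = [n["counts"]["probe_efnb3"] for n in gt.extra["nuclei"]]
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) <= 3 * se
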