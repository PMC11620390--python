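import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilagree.io_annotations import MaskStack
from tilagree.kappa_agreement import (
    AgreementCountTable,
    WeightMap,
    agreement_maps,
    boundary_weight_map,
    build_count_table,
    bwfk,
    extract_boundary,
    fleiss_kappa,
)
from conftest import random_stack


def brute_force_fleiss(ratings: np.ndarray) -> float:
    """Independent oracle: Fleiss' kappa from a raw observer × subject
    rating matrix via the per-subject agreement proportions."""
    n_obs, m = ratings.shape
    p_i = []
    for i in range(m):
        counts = np.bincount(ratings[:, i], minlength=2)
        p_i.append((counts * (counts - 1)).sum() / (n_obs * (n_obs - 1)))
    p_bar = np.mean(p_i)
    p_j = np.bincount(ratings.ravel(), minlength=2) / ratings.size
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


def uniform_weight_map(m: int) -> WeightMap:
    ones = np.ones(m)
    return WeightMap(raw=ones, flattened=ones, dt=100.0, normalized=ones)


class TestCountTable:
    def test_identical_masks_vote_unanimously(self, rng):
        mask = (rng.random((10, 10)) < 0.5).astype(np.uint8)
        stack = MaskStack(masks=np.stack([mask, mask]), observer_ids=["a", "b"])
        table = build_count_table(stack)
        assert set(map(tuple, table.n)) <= {(2, 0), (0, 2)}

    def test_vote_counts_match_definition(self):
        masks = np.zeros((4, 1, 1), dtype=np.uint8)
        masks[:3] = 1  # 3 of 4 observers vote stroma
        stack = MaskStack(masks=masks, observer_ids=list("abcd"))
        table = build_count_table(stack)
        assert table.n.tolist() == [[1, 3]]

    def test_exclusion_shrinks_universe(self, small_stack):
        excl = np.zeros(small_stack.shape, dtype=bool)
        excl[:10] = True
        table = build_count_table(small_stack, exclusion=excl)
        assert table.n_pixels == small_stack.shape[0] * small_stack.shape[1] - excl.sum()

    def test_all_excluded_fatal(self, small_stack):
        with pytest.raises(ValueError, match="excluded"):
            build_count_table(small_stack, exclusion=np.ones(small_stack.shape, bool))


class TestFleissKappa:
    def test_three_pixel_toy(self):
        # rows (2,0),(0,2),(1,1): Po=2/3, Pe=1/2, kappa=1/3
        table = AgreementCountTable(n=np.array([[2, 0], [0, 2], [1, 1]]),
                                    n_observers=2)
        res = fleiss_kappa(table)
        assert res.p_observed == pytest.approx(2 / 3, abs=1e-15)
        assert res.p_expected == pytest.approx(1 / 2, abs=1e-15)
        assert res.kappa == pytest.approx(1 / 3, abs=1e-12)

    def test_perfect_agreement_on_mixed_masks(self, rng):
        mask = (rng.random((12, 12)) < 0.5).astype(np.uint8)
        stack = MaskStack(masks=np.stack([mask] * 3), observer_ids=list("abc"))
        res = fleiss_kappa(build_count_table(stack))
        assert res.kappa == 1.0 and not res.degenerate

    def test_complete_disagreement(self):
        table = AgreementCountTable(n=np.tile([1, 1], (20, 1)), n_observers=2)
        res = fleiss_kappa(table)
        assert res.p_observed == 0.0
        assert res.kappa == pytest.approx(-res.p_expected / (1 - res.p_expected))

    def test_degenerate_single_category(self):
        stack = MaskStack(masks=np.ones((3, 5, 5), dtype=np.uint8),
                          observer_ids=list("abc"))
        res = fleiss_kappa(build_count_table(stack))
        assert res.kappa == 1.0 and res.degenerate

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_and_statsmodels(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_obs = int(rng.integers(2, 6))
        m = int(rng.integers(10, 400))
        ratings = (rng.random((n_obs, m)) < rng.random()).astype(int)
        table = AgreementCountTable(
            n=np.column_stack([(ratings == 0).sum(0), (ratings == 1).sum(0)]),
            n_observers=n_obs,
        )
        ours = fleiss_kappa(table).kappa
        assert ours == pytest.approx(brute_force_fleiss(ratings), abs=1e-12)
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fk

        assert ours == pytest.approx(sm_fk(table.n), abs=1e-10)

    def test_invariant_to_observer_order_and_relabeling(self, small_stack):
        base = fleiss_kappa(build_count_table(small_stack)).kappa
        perm = MaskStack(masks=small_stack.masks[::-1],
                         observer_ids=small_stack.observer_ids[::-1])
        assert fleiss_kappa(build_count_table(perm)).kappa == pytest.approx(base, abs=1e-14)
        flipped = MaskStack(masks=1 - small_stack.masks,
                            observer_ids=small_stack.observer_ids)
        assert fleiss_kappa(build_count_table(flipped)).kappa == pytest.approx(base, abs=1e-14)

    def test_decreases_with_noise_rate(self, rng):
        mask = (rng.random((64, 64)) < 0.5).astype(np.uint8)
        kappas = []
        for rate in (0.05, 0.15, 0.3):
            noise = rng.random(mask.shape) < rate
            noisy = np.where(noise, 1 - mask, mask)
            stack = MaskStack(masks=np.stack([mask, mask, noisy]),
                              observer_ids=list("abc"))
            kappas.append(fleiss_kappa(build_count_table(stack)).kappa)
        assert kappas[0] > kappas[1] > kappas[2]


class TestBoundaryWeights:
    def test_straight_boundary_gives_clipped_ramp(self):
        # identical masks, single vertical stroma/background edge at col 8
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[:, 8:] = 1
        stack = MaskStack(masks=np.stack([mask, mask]), observer_ids=["a", "b"])
        wm = boundary_weight_map(stack, dt=5)
        cols = np.arange(20)
        expected = np.minimum(np.abs(cols - 8), 5).astype(float)
        np.testing.assert_allclose(wm.flattened[10], expected)

    def test_uniform_distances_normalize_to_one(self):
        wm = WeightMap(raw=np.full(50, 7.0), flattened=np.full(50, 7.0),
                       dt=100.0, normalized=np.ones(50))
        assert wm.normalized.sum() == 50

    def test_mean_of_offset_boundaries_matches_brute_force(self):
        # two observers with vertical boundaries 10 px apart on 64x64
        masks = []
        for edge in (20, 30):
            m = np.zeros((64, 64), dtype=np.uint8)
            m[:, edge:] = 1
            masks.append(m)
        stack = MaskStack(masks=np.stack(masks), observer_ids=["a", "b"])
        wm = boundary_weight_map(stack, dt=1000)
        # brute force: per observer, per pixel, min distance to boundary set
        dists = np.zeros((2, 64, 64))
        for k, mask in enumerate(stack.masks):
            bnd = np.argwhere(extract_boundary(mask))
            for r in range(64):
                for c in range(64):
                    dists[k, r, c] = np.sqrt(((bnd - [r, c]) ** 2).sum(1)).min()
        np.testing.assert_allclose(wm.raw, dists.mean(axis=0), atol=1e-9)

    def test_no_boundary_mask_warns_constant_dt(self):
        stack = MaskStack(masks=np.stack([np.ones((8, 8), dtype=np.uint8)] * 2),
                          observer_ids=["a", "b"])
        with pytest.warns(UserWarning, match="no stroma boundary"):
            wm = boundary_weight_map(stack, dt=10)
        np.testing.assert_allclose(wm.raw, 10.0)

    def test_normalization_sums_to_m(self, small_stack):
        wm = boundary_weight_map(small_stack, dt=100)
        m = wm.normalized.size
        assert wm.normalized.sum() == pytest.approx(m, rel=1e-9)
        assert (wm.normalized >= 0).all()
        assert (wm.flattened <= 100).all()

    def test_boundary_excludes_image_border(self):
        mask = np.ones((6, 6), dtype=np.uint8)
        mask[2:4, 2:4] = 0
        bnd = extract_boundary(mask)
        assert not bnd[0].any() and not bnd[-1].any()
        # stroma pixels adjacent to the interior hole are boundary
        assert bnd[1, 2] and bnd[2, 1]


class TestBwfk:
    def test_uniform_weights_reduce_to_fk(self, small_stack):
        fk = fleiss_kappa(build_count_table(small_stack))
        m = small_stack.shape[0] * small_stack.shape[1]
        bw = bwfk(small_stack, weight_map=uniform_weight_map(m))
        assert bw.kappa == pytest.approx(fk.kappa, abs=1e-12)
        assert bw.p_observed == pytest.approx(fk.p_observed, abs=1e-12)
        assert bw.p_expected == pytest.approx(fk.p_expected, abs=1e-12)

    @pytest.mark.parametrize("dt", [10, 100])
    def test_identical_masks_score_one(self, rng, dt):
        mask = (rng.random((32, 32)) < 0.4).astype(np.uint8)
        stack = MaskStack(masks=np.stack([mask] * 4), observer_ids=list("abcd"))
        assert bwfk(stack, dt=dt).kappa == 1.0

    def test_boundary_localized_disagreement_rewarded(self, blob_stack):
        """Disagreement confined to a narrow band around a shared boundary
        is down-weighted: the weighted kappa strictly exceeds the plain one."""
        fk = fleiss_kappa(build_count_table(blob_stack)).kappa
        bw = bwfk(blob_stack, dt=100).kappa
        assert bw > fk

    def test_observer_order_invariance(self, blob_stack):
        base = bwfk(blob_stack, dt=50).kappa
        perm = MaskStack(masks=blob_stack.masks[[2, 0, 3, 1]],
                         observer_ids=list("cadb"))
        assert bwfk(perm, dt=50).kappa == pytest.approx(base, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_kappa_bounded_and_reduction_property(seed):
    """On arbitrary random stacks kappa lies in [-1, 1] and BWFK with forced
    uniform weights coincides with FK to double precision."""
    rng = np.random.default_rng(seed)
    stack = random_stack(rng, n=int(rng.integers(2, 5)), h=16, w=16,
                         p=float(rng.uniform(0.2, 0.8)))
    fk = fleiss_kappa(build_count_table(stack))
    assert -1.0 - 1e-12 <= fk.kappa <= 1.0 + 1e-12
    bw = bwfk(stack, weight_map=uniform_weight_map(16 * 16))
    assert bw.kappa == pytest.approx(fk.kappa, abs=1e-12)


class TestAgreementMaps:
    def test_counts_partition_observers(self, small_stack):
        maps = agreement_maps(small_stack)
        np.testing.assert_array_equal(
            maps.stroma_counts + maps.nonstroma_counts,
            np.full(small_stack.shape, small_stack.n_observers),
        )
        n = small_stack.n_observers
        assert maps.max_map.min() >= int(np.ceil(n / 2))
        assert maps.max_map.max() <= n

    def test_identical_masks_max_is_n(self, rng):
        mask = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        stack = MaskStack(masks=np.stack([mask] * 4), observer_ids=list("abcd"))
        assert (agreement_maps(stack).max_map == 4).all()

    def test_checkerboard_disagreement(self):
        a = np.indices((8, 8)).sum(axis=0) % 2
        stack = MaskStack(masks=np.stack([a, 1 - a]).astype(np.uint8),
                          observer_ids=["a", "b"])
        assert (agreement_maps(stack).max_map == 1).all()

    def test_render_shapes(self, small_stack):
        img = agreement_maps(small_stack).render("max")
        assert img.shape == (*small_stack.shape, 3) and img.dtype == np.uint8
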