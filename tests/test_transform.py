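"""CDF-matching transfer maps: oracle equivalence, monotonicity, rank
preservation, alignment bound, idempotence, and the augmentation protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spineharm import profile, transform
from spineharm.errors import (
    DegenerateInputError,
    IncompatibilityError,
    PlanValidationError,
)
from spineharm.imgio import GrayImage
from spineharm.profile import compute_profile
from spineharm.transform import (
    AugmentationPlan,
    TransferMap,
    apply_transfer_map,
    build_augmented_set,
    fit_transfer_map,
    harmonize,
)

from conftest import (
    brute_force_transfer_map,
    gray,
    random_image,
    random_small_profile,
)


def cdf_of(img: GrayImage, n_levels: int) -> np.ndarray:
    return compute_profile(img, n_levels=n_levels).cdf


class TestFitTransferMap:
    def test_self_matching_is_identity_on_occupied_levels(self, rng):
        img = random_image(rng)
        p = compute_profile(img)
        tm = fit_transfer_map(p, p)
        occ = np.flatnonzero(p.hist > 0)
        np.testing.assert_array_equal(tm.map[occ], occ)

    def test_four_pixel_example(self):
        src = compute_profile(gray([[10, 20], [30, 40]]))
        ref = compute_profile(gray([[0, 0], [255, 255]]))
        tm = fit_transfer_map(src, ref)
        assert tm.map[10] == 0
        assert tm.map[20] == 0
        assert tm.map[30] == 0  # tie |.75-.5| vs |.75-1| broken to smallest level
        assert tm.map[40] == 255

    def test_constant_source_example(self):
        src = compute_profile(gray(np.full((2, 2), 100)))
        ref = compute_profile(gray([[50, 200], [200, 200]]))
        tm = fit_transfer_map(src, ref)
        assert tm.map[100] == 200

    def test_oracle_equivalence_small_instances(self, rng):
        for _ in range(120):
            n_levels = int(rng.choice([4, 8, 16]))
            src = random_small_profile(rng, n_levels)
            ref = random_small_profile(rng, n_levels)
            tm = fit_transfer_map(src, ref)
            oracle = brute_force_transfer_map(src, ref)
            for s, t in oracle.items():
                assert tm.map[s] == t, (s, t, tm.map[s])

    def test_mismatched_levels_rejected(self, rng):
        a = random_small_profile(rng, 8)
        b = random_small_profile(rng, 16)
        with pytest.raises(IncompatibilityError):
            fit_transfer_map(a, b)

    def test_monotone_map_required(self):
        with pytest.raises(Exception):
            TransferMap(n_levels=4, map=np.array([1, 0, 2, 3]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fitted_maps_always_monotone(seed):
    """Every fitted map is non-decreasing, for arbitrary source/reference pairs."""
    rng = np.random.default_rng(seed)
    src = random_small_profile(rng, 16)
    ref = random_small_profile(rng, 16)
    tm = fit_transfer_map(src, ref)
    assert (np.diff(tm.map) >= 0).all()


class TestApplyTransferMap:
    def test_identity_map_is_noop(self, rng):
        img = random_image(rng, shape=(16, 16))
        tm = TransferMap(n_levels=256, map=np.arange(256))
        np.testing.assert_array_equal(apply_transfer_map(img, tm).pixels, img.pixels)

    def test_derived_map_application(self):
        img = gray([[10, 20], [30, 40]])
        tm = fit_transfer_map(compute_profile(img),
                              compute_profile(gray([[0, 0], [255, 255]])))
        np.testing.assert_array_equal(apply_transfer_map(img, tm).pixels.ravel(),
                                      [0, 0, 0, 255])

    def test_output_support_subset_of_map_range(self, rng):
        img = random_image(rng, shape=(32, 32))
        tm = fit_transfer_map(compute_profile(img),
                              compute_profile(random_image(rng, (32, 32))))
        out = apply_transfer_map(img, tm)
        assert set(np.unique(out.pixels)) <= set(tm.map.tolist())

    def test_rank_preservation(self, rng):
        for _ in range(10):
            img = random_image(rng, shape=(24, 24))
            ref = random_image(rng, shape=(24, 24))
            tm = fit_transfer_map(compute_profile(img), compute_profile(ref))
            a = img.pixels.ravel().astype(int)
            b = apply_transfer_map(img, tm).pixels.ravel().astype(int)
            order = np.argsort(a, kind="stable")
            assert (np.diff(b[order]) >= 0).all()

    def test_too_many_levels_for_bit_depth_rejected(self, rng):
        img = random_image(rng, shape=(8, 8))
        tm = TransferMap(n_levels=512, map=np.arange(512))
        with pytest.raises(IncompatibilityError):
            apply_transfer_map(img, tm)


class TestHarmonize:
    def test_self_reference_near_identity(self, rng):
        img = random_image(rng)
        out = harmonize(img, compute_profile(img))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_cdf_alignment_bound(self, rng):
        """Sup-norm gap between output and reference CDFs is at most the
        largest single-bin mass of the source histogram."""
        for _ in range(20):
            img = random_image(rng)
            ref = random_image(rng)
            ref_p = compute_profile(ref)
            src_p = compute_profile(img)
            out = harmonize(img, ref_p)
            gap = np.abs(cdf_of(out, 256) - ref_p.cdf).max()
            assert gap <= src_p.hist.max() + 1e-12

    def test_idempotent_up_to_one_level(self, rng):
        for _ in range(10):
            img = random_image(rng)
            ref_p = compute_profile(random_image(rng))
            once = harmonize(img, ref_p)
            twice = harmonize(once, ref_p)
            max_change = np.abs(twice.pixels.astype(int) - once.pixels.astype(int)).max()
            assert max_change <= 1

    def test_empty_reference_rejected(self, rng):
        img = random_image(rng, (8, 8))
        p = compute_profile(img)
        hollow = profile.IntensityProfile(n_levels=256, hist=np.zeros(256),
                                          brightness=0.0, spread=0.0, n_pixels=0)
        with pytest.raises(DegenerateInputError):
            fit_transfer_map(p, hollow)

    def test_gamma_distortion_recovery(self, rng):
        """Harmonizing a gamma-distorted copy against the original's profile
        moves it closer to the original (synthetic-recovery experiment)."""
        from spineharm.synth import (
            CenterProfile,
            SpinePhantomSpec,
            CurveSpec,
            apply_center_profile,
            generate_phantom,
        )

        img, _ = generate_phantom(
            SpinePhantomSpec(curves=[CurveSpec("T8", 25.0, "right")], seed=11))
        distorted = apply_center_profile(
            img, CenterProfile("G", gamma=1.5, contrast_scale=1.1, seed=5))
        recovered = harmonize(distorted, compute_profile(img))
        mad_before = np.abs(distorted.pixels.astype(float) - img.pixels).mean()
        mad_after = np.abs(recovered.pixels.astype(float) - img.pixels).mean()
        assert mad_after < mad_before

    def test_runtime_scales_subquadratically(self, rng):
        """O(n log n) smoke check: 4x the pixels should cost well under 16x."""
        import time

        small = random_image(rng, shape=(128, 128))
        large = random_image(rng, shape=(256, 256))
        ref = compute_profile(random_image(rng, shape=(64, 64)))

        def timed(img):
            t0 = time.perf_counter()
            for _ in range(5):
                harmonize(img, ref)
            return time.perf_counter() - t0

        timed(small)  # warm-up
        ratio = timed(large) / max(timed(small), 1e-9)
        assert ratio <= 12.0


class TestAugmentation:
    def _images(self, rng, n=10):
        return [random_image(rng, shape=(16, 16)) for _ in range(n)]

    def _plan(self, rng, m=2, seed=17):
        pools = [("A", [random_image(rng, (16, 16)), random_image(rng, (16, 16))]),
                 ("B", [random_image(rng, (16, 16))])]
        return AugmentationPlan(references=pools, transforms_per_image=m,
                                include_originals=True, seed=seed)

    def test_output_counts_and_provenance(self, rng):
        images = self._images(rng, 10)
        out = build_augmented_set(images, self._plan(rng, m=2))
        assert len(out) == 30
        transformed = [p for _, p in out if p.is_transformed]
        assert len(transformed) == 20
        assert all(p.center_id in ("A", "B") for p in transformed)

    def test_same_seed_bit_identical(self, rng):
        images = self._images(rng, 5)
        plan = self._plan(rng, m=2, seed=99)
        out1 = build_augmented_set(images, plan)
        out2 = build_augmented_set(images, plan)
        assert len(out1) == len(out2)
        for (img1, p1), (img2, p2) in zip(out1, out2):
            np.testing.assert_array_equal(img1.pixels, img2.pixels)
            assert p1 == p2

    def test_single_reference_alignment(self, rng):
        ref = random_image(rng, shape=(32, 32))
        ref_p = compute_profile(ref)
        images = [GrayImage(random_image(rng, (16, 16)).pixels, 8, f"img{i}")
                  for i in range(6)]
        by_id = {img.source_id: img for img in images}
        plan = AugmentationPlan(references=[("only", [ref])],
                                transforms_per_image=1,
                                include_originals=False, seed=3)
        for out, prov in build_augmented_set(images, plan):
            src_p = compute_profile(by_id[prov.source_id])
            gap = np.abs(cdf_of(out, 256) - ref_p.cdf).max()
            assert gap <= src_p.hist.max() + 1e-12

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(PlanValidationError):
            AugmentationPlan(references=[("empty", [])])

    def test_default_reference_profile_loads(self):
        p = transform.default_reference_profile()
        assert p.n_levels == 256
        assert p.hist.sum() == pytest.approx(1.0)
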