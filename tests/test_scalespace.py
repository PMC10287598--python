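import itertools
import math

import numpy as np
import pytest

from mcseg.scalespace import (
    Blob,
    build_scale_sequence,
    detect_blobs,
    disc_overlap_fraction,
    gaussian_scale_space,
    normalized_dog_stack,
    prune_overlapping_blobs,
)


def brute_force_maxima(values, t_dog):
    """Exhaustive 26-neighborhood scan with the plateau tie-break rule."""
    n_s, n_r, n_c = values.shape
    qualifying = set()
    for n, r, c in itertools.product(range(n_s), range(n_r), range(n_c)):
        v = values[n, r, c]
        if v <= t_dog:
            continue
        ge_all, gt_some = True, False
        for dn, dr, dc in itertools.product((-1, 0, 1), repeat=3):
            if (dn, dr, dc) == (0, 0, 0):
                continue
            nn, rr, cc = n + dn, r + dr, c + dc
            if 0 <= nn < n_s and 0 <= rr < n_r and 0 <= cc < n_c:
                if v < values[nn, rr, cc]:
                    ge_all = False
                    break
                if v > values[nn, rr, cc]:
                    gt_some = True
        if ge_all and gt_some:
            qualifying.add((n, r, c))
    # keep only the lexicographically smallest voxel per connected plateau
    keep = set()
    for vox in sorted(qualifying):
        component, stack, seen = [vox], [vox], {vox}
        while stack:
            cur = stack.pop()
            for dn, dr, dc in itertools.product((-1, 0, 1), repeat=3):
                nxt = (cur[0] + dn, cur[1] + dr, cur[2] + dc)
                if nxt in qualifying and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
                    component.append(nxt)
        if vox == min(component):
            keep.add(vox)
    return keep


class TestScaleSequence:
    def test_reference_ladder_from_study_endpoints(self):
        seq = build_scale_sequence(1.18, 3.1, k=2 ** (1 / 3))
        expected = [1.18 * 2 ** (n / 3) for n in range(6)]
        assert np.allclose(seq.sigmas, expected)
        assert seq.sigmas[-2] < 3.1 <= seq.sigmas[-1]

    def test_power_of_two_ladder(self):
        assert build_scale_sequence(1.0, 4.0, k=2.0).sigmas == (1.0, 2.0, 4.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            build_scale_sequence(3.1, 1.18)


class TestGaussianScaleSpace:
    def test_constant_image_is_preserved(self):
        seq = build_scale_sequence(1.0, 4.0)
        stack = gaussian_scale_space(np.full((32, 32), 0.7), seq)
        assert np.allclose(stack, 0.7)

    def test_impulse_response_matches_gaussian_peak(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        seq = build_scale_sequence(2.0, 2.5, k=1.26)
        stack = gaussian_scale_space(img, seq)
        # dense-kernel oracle: G(0, 0; 2) = 1 / (2 pi sigma^2)
        assert stack[0, 32, 32] == pytest.approx(1 / (2 * math.pi * 4), rel=0.05)

    def test_variance_decreases_with_scale(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        seq = build_scale_sequence(1.0, 8.0, k=2.0)
        stack = gaussian_scale_space(img, seq)
        variances = stack.var(axis=(1, 2))
        assert np.all(np.diff(variances) < 0)


class TestNormalizedDoG:
    def test_constant_image_gives_zero_stack(self):
        seq = build_scale_sequence(1.0, 4.0)
        dog = normalized_dog_stack(gaussian_scale_space(np.full((32, 32), 0.4), seq), seq)
        assert np.allclose(dog.values, 0.0, atol=1e-12)

    def test_linear_ramp_gives_zero_interior(self):
        img = np.tile(np.linspace(0, 1, 64), (64, 1))
        seq = build_scale_sequence(1.18, 3.1)
        dog = normalized_dog_stack(gaussian_scale_space(img, seq), seq)
        interior = dog.values[:, 16:-16, 16:-16]
        assert np.abs(interior).max() < 1e-9

    def test_peak_scale_tracks_bump_width(self):
        # brute-force sweep: central response is maximal at sigma_n nearest s
        seq = build_scale_sequence(1.18, 3.1)
        for s in (1.5, 2.0, 2.5):
            rr, cc = np.ogrid[:65, :65]
            img = 0.4 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * s * s))
            dog = normalized_dog_stack(gaussian_scale_space(img, seq), seq)
            central = dog.values[:, 32, 32]
            nearest = int(np.argmin(np.abs(np.array(seq.sigmas[:-1]) - s)))
            assert int(np.argmax(central)) == nearest


class TestDetectBlobs:
    def test_zero_stack_yields_no_blobs(self):
        from mcseg.scalespace import DoGStack

        seq = build_scale_sequence(1.0, 4.0, k=2.0)
        dog = DoGStack(values=np.zeros((2, 16, 16)), scales=seq)
        assert detect_blobs(dog, 0.006) == []

    def test_single_planted_spot_gives_one_central_blob(self):
        rr, cc = np.ogrid[:64, :64]
        img = 0.3 + 0.5 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 4.0))
        seq = build_scale_sequence(1.18, 3.1)
        dog = normalized_dog_stack(gaussian_scale_space(img, seq), seq)
        blobs = detect_blobs(dog, 0.006)
        assert len(blobs) == 1
        assert math.hypot(blobs[0].row - 32, blobs[0].col - 32) <= 1.0

    def test_threshold_above_global_max_empties_output(self):
        rr, cc = np.ogrid[:64, :64]
        img = 0.3 + 0.5 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 4.0))
        seq = build_scale_sequence(1.18, 3.1)
        dog = normalized_dog_stack(gaussian_scale_space(img, seq), seq)
        assert detect_blobs(dog, float(dog.values.max()) + 1e-9) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_scan(self, seed):
        from mcseg.scalespace import DoGStack

        rng = np.random.default_rng(seed)
        seq = build_scale_sequence(1.18, 3.1)
        values = rng.normal(0, 0.01, size=(5, 24, 24)).round(3)  # rounding makes plateaus
        dog = DoGStack(values=values, scales=seq)
        got = {(seq.sigmas.index(b.sigma), b.row, b.col) for b in detect_blobs(dog, 0.006)}
        assert got == brute_force_maxima(values, 0.006)

    def test_blob_count_nonincreasing_in_threshold(self):
        img, *_ = _phantom_image()
        seq = build_scale_sequence(1.18, 3.1)
        dog = normalized_dog_stack(gaussian_scale_space(img, seq), seq)
        counts = [len(detect_blobs(dog, t)) for t in (0.002, 0.006, 0.02, 0.06)]
        assert counts == sorted(counts, reverse=True)

    def test_response_is_linear_in_amplitude(self):
        seq = build_scale_sequence(1.18, 3.1)
        rr, cc = np.ogrid[:64, :64]
        base = np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 4.0))
        responses = []
        for a in (0.25, 0.5):
            dog = normalized_dog_stack(gaussian_scale_space(a * base, seq), seq)
            responses.append(max(b.response for b in detect_blobs(dog, 1e-6)))
        assert responses[1] == pytest.approx(2 * responses[0], abs=1e-9)


def _phantom_image():
    from mcseg.phantom import PhantomSpec, generate_phantom

    img, ann, truth, objs = generate_phantom(PhantomSpec(seed=3))
    return img.pixels, ann, truth, objs


class TestPruneOverlapping:
    def test_disjoint_blobs_both_kept(self):
        blobs = [Blob(10, 10, 2.0, 0.5), Blob(40, 40, 1.0, 0.4)]
        assert len(prune_overlapping_blobs(blobs, 0.0)) == 2

    def test_concentric_smaller_blob_removed(self):
        blobs = [Blob(20, 20, 2.0, 0.5), Blob(20, 20, 1.0, 0.4)]
        assert disc_overlap_fraction(*blobs) == pytest.approx(1.0)
        kept = prune_overlapping_blobs(blobs, 0.5)
        assert kept == [Blob(20, 20, 2.0, 0.5)]

    def test_unit_overlap_threshold_disables_pruning(self):
        blobs = [Blob(20, 20, 2.0, 0.5), Blob(20, 20, 1.0, 0.4)]
        assert len(prune_overlapping_blobs(blobs, 1.0)) == 2

    def test_overlap_fraction_matches_montecarlo_oracle(self):
        a, b = Blob(20, 20, 2.0, 0.5), Blob(22, 21, 1.5, 0.4)
        rng = np.random.default_rng(0)
        r_small = min(a.radius, b.radius)
        # sample within the smaller disc (b's)
        pts = rng.uniform(-r_small, r_small, size=(200000, 2))
        inside_b = (pts**2).sum(axis=1) <= r_small**2
        pts = pts + [b.row, b.col]
        inside_a = ((pts[:, 0] - a.row) ** 2 + (pts[:, 1] - a.col) ** 2) <= a.radius**2
        mc = (inside_a & inside_b).sum() / inside_b.sum()
        assert disc_overlap_fraction(a, b) == pytest.approx(mc, abs=0.01)
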