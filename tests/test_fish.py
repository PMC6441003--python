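"""Erosion-shell analysis: segmentation, equal-area partition, quantification."""

import numpy as np
import pytest
from scipy import ndimage

from fibroquant import fish
from fibroquant.synthetic import FieldSpec, generate_nucleus_field
from conftest import (
    boundary_distance,
    brute_force_shell_assignment,
    random_blob_mask,
    record_from_mask,
)


def disc_mask(radius: int, pad: int = 3) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:size, :size] - (radius + pad)
    return yy**2 + xx**2 <= radius**2


class TestSegmentation:
    def test_all_zero_image_yields_nothing(self):
        with pytest.warns(UserWarning, match="constant"):
            assert fish.segment_nuclei(np.zeros((64, 64))) == []

    def test_bright_disc_area_within_two_percent(self):
        img = np.full((128, 128), 100.0)
        mask = disc_mask(40)[:128, :128]
        img[: mask.shape[0], : mask.shape[1]][mask] = 10000.0
        records = fish.segment_nuclei(img, min_area=100)
        assert len(records) == 1
        assert records[0].area == pytest.approx(np.pi * 40**2, rel=0.02)

    def test_synthetic_field_recovers_truth_masks(self, small_field):
        records = fish.segment_nuclei(small_field.dna_channel, min_area=100)
        assert len(records) == small_field.spec.n_nuclei
        truth = small_field.truth_masks
        for rec in records:
            seg = np.zeros(truth.shape, dtype=bool)
            rr, cc = rec.field_coords()
            seg[rr, cc] = True
            lab = np.bincount(truth[seg]).argmax()
            assert lab > 0
            tmask = truth == lab
            jaccard = (seg & tmask).sum() / (seg | tmask).sum()
            assert jaccard >= 0.95

    def test_border_and_area_filters(self):
        img = np.full((96, 96), 10.0)
        img[0:20, 40:60] = 5000.0  # touches border
        img[40:60, 40:60] = 5000.0  # interior, area 400
        img[70:73, 10:13] = 5000.0  # too small
        records = fish.segment_nuclei(img, min_area=50, max_area=1000)
        assert len(records) == 1
        assert records[0].area == 400


class TestEqualAreaShells:
    def test_exact_division_for_100_pixel_mask(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 100 pixels
        part = fish.erode_equal_area_shells(record_from_mask(mask), 5)
        assert part.shell_areas.tolist() == [20, 20, 20, 20, 20]

    def test_disc_shell_boundaries_match_analytic_annuli(self):
        """Equal-area annuli of a continuous disc have outer radii r·sqrt(k/5)."""
        radius = 50
        mask = disc_mask(radius)
        rec = record_from_mask(mask)
        part = fish.erode_equal_area_shells(rec, 5)
        dist = boundary_distance(rec.mask)
        for k in range(1, 5):
            # innermost distance of shell k ~ boundary to shell k+1
            d_outer = dist[part.shell_map == k].max()
            r_inner_analytic = radius * np.sqrt(1 - k / 5)
            assert abs((radius - d_outer) - r_inner_analytic) <= 1.5

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng)
            part = fish.erode_equal_area_shells(record_from_mask(mask), 5)
            r0, c0, r1, c1 = part.nucleus.bbox
            assert np.array_equal(part.shell_map > 0, mask[r0:r1, c0:c1])
            assert part.shell_areas.sum() == mask.sum()
            assert part.shell_areas.max() - part.shell_areas.min() <= 1

    def test_matches_sort_free_brute_force_oracle(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng)
            rec = record_from_mask(mask)
            part = fish.erode_equal_area_shells(rec, 5)
            oracle = brute_force_shell_assignment(mask, 5)
            local_oracle = oracle[
                rec.bbox[0]:rec.bbox[2], rec.bbox[1]:rec.bbox[3]
            ]
            assert np.array_equal(part.shell_map, local_oracle)

    def test_shell_index_monotone_along_inward_distance(self):
        mask = disc_mask(30)
        rec = record_from_mask(mask)
        part = fish.erode_equal_area_shells(rec, 5)
        dist = boundary_distance(rec.mask)
        for k in range(1, 5):
            assert dist[part.shell_map == k].max() <= dist[part.shell_map == k + 1].min() + 1e-9

    def test_tiny_mask_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        with pytest.raises(ValueError, match="area"):
            fish.erode_equal_area_shells(record_from_mask(mask), 5)


class TestQuantification:
    def test_self_normalization_identity(self, small_field):
        dna = small_field.dna_channel
        for nuc in fish.segment_nuclei(dna, min_area=100):
            part = fish.erode_equal_area_shells(nuc, 5)
            prof = fish.quantify_shells(part, dna, dna)
            assert np.array_equal(prof.ratio, np.ones(5))

    def test_probe_confined_to_inner_shell(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        rec = record_from_mask(mask)
        part = fish.erode_equal_area_shells(rec, 5)
        dna = np.zeros((14, 14))
        dna[mask] = 7.0
        probe_field = np.zeros((14, 14))
        rr, cc = np.nonzero(part.shell_map == 5)
        probe_field[rr + rec.bbox[0], cc + rec.bbox[1]] = 3.0
        prof = fish.quantify_shells(part, dna, probe_field)
        assert np.allclose(prof.ratio, [0, 0, 0, 0, 5])
        assert prof.probe_pct.sum() == pytest.approx(100.0)
        assert prof.dna_pct.sum() == pytest.approx(100.0)

    def test_matches_brute_force_summation_oracle(self):
        field = generate_nucleus_field(
            FieldSpec(width=256, height=256, n_nuclei=5, radial_bias=3.0, seed=31)
        )
        dna = field.dna_channel.astype(float)
        probe = field.probe_channel.astype(float)
        for nuc in fish.segment_nuclei(dna, min_area=100):
            part = fish.erode_equal_area_shells(nuc, 5)
            prof = fish.quantify_shells(part, dna, probe)
            # independent per-pixel accumulation
            psum = np.zeros(5)
            dsum = np.zeros(5)
            r0, c0 = nuc.bbox[:2]
            for (r, c), k in np.ndenumerate(part.shell_map):
                if k > 0:
                    psum[k - 1] += probe[r + r0, c + c0]
                    dsum[k - 1] += dna[r + r0, c + c0]
            expected_ratio = (psum / psum.sum() * 100) / (dsum / dsum.sum() * 100)
            assert np.allclose(prof.ratio, expected_ratio)

    def test_zero_dna_nucleus_is_an_error(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        part = fish.erode_equal_area_shells(record_from_mask(mask), 5)
        with pytest.raises(ValueError, match="zero DNA"):
            fish.quantify_shells(part, np.zeros((10, 10)), np.ones((10, 10)))

    def test_rigid_translation_leaves_profiles_unchanged(self):
        spec = FieldSpec(width=256, height=256, n_nuclei=5, radial_bias=2.0, seed=33)
        field = generate_nucleus_field(spec)

        def profiles(dna, probe):
            out = {}
            for nuc in fish.segment_nuclei(dna, min_area=100):
                part = fish.erode_equal_area_shells(nuc, 5)
                p = fish.quantify_shells(part, dna, probe)
                out[round(nuc.centroid[0] + nuc.centroid[1], 4)] = p.ratio
            return out

        base = profiles(field.dna_channel.astype(float), field.probe_channel.astype(float))
        shifted_dna = np.roll(field.dna_channel.astype(float), (7, -5), axis=(0, 1))
        shifted_probe = np.roll(field.probe_channel.astype(float), (7, -5), axis=(0, 1))
        shifted = profiles(shifted_dna, shifted_probe)
        key_shift = 7 - 5
        for key, ratio in base.items():
            match = shifted[round(key + key_shift, 4)]
            assert np.allclose(ratio, match)

    def test_ninety_degree_rotation_preserves_shell_areas(self, rng):
        mask = random_blob_mask(rng)
        a = fish.erode_equal_area_shells(record_from_mask(mask), 5).shell_areas
        b = fish.erode_equal_area_shells(record_from_mask(np.rot90(mask).copy()), 5).shell_areas
        assert np.array_equal(a, b)


class TestAggregationAndComparison:
    def test_single_profile_mean_is_profile_with_warning(self):
        prof = fish.ShellProfile(1, np.full(5, 20.0), np.full(5, 20.0), np.ones(5))
        with pytest.warns(UserWarning, match="only 1"):
            s = fish.aggregate_condition([prof], "c", n_min=50)
        assert np.allclose(s.mean_ratio, 1.0)
        assert np.allclose(s.sem_ratio, 0.0)

    def test_identical_profiles_have_zero_sem(self):
        profs = [
            fish.ShellProfile(i, np.full(5, 20.0), np.full(5, 20.0), np.ones(5))
            for i in range(50)
        ]
        s = fish.aggregate_condition(profs, "c", n_min=50)
        assert np.allclose(s.mean_ratio, 1.0)
        assert np.allclose(s.sem_ratio, 0.0)

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            fish.aggregate_condition([], "c")

    def test_point_probe_uniform_field_is_calibrated(self):
        """In the small-PSF limit uniform probe gives shell ratios near 1."""
        ratios = []
        for seed in (41, 42, 43, 44):
            field = generate_nucleus_field(
                FieldSpec(n_nuclei=50, radial_bias=0.0, psf_sigma=0.2,
                          n_probe_spots=400, seed=seed)
            )
            dna = field.dna_channel
            probe = field.probe_channel
            for nuc in fish.segment_nuclei(dna, min_area=100):
                part = fish.erode_equal_area_shells(nuc, 5)
                ratios.append(fish.quantify_shells(part, dna, probe).ratio)
        mean = np.mean(ratios, axis=0)
        assert np.all(mean > 0.95) and np.all(mean < 1.05)

    def test_identical_samples_not_significant(self):
        x = np.tile(np.linspace(0.8, 1.2, 10)[:, None], (1, 5))
        cmp = fish.compare_conditions(x, x)
        assert np.allclose(cmp.t, 0.0)
        assert np.allclose(cmp.p, 1.0)
        assert not cmp.significant.any()

    def test_separated_conditions_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.2, 0.1, size=(50, 1))
        b = rng.normal(0.8, 0.1, size=(50, 1))
        cmp = fish.compare_conditions(a, b)
        assert cmp.p[0] < 1e-6
        assert cmp.significant[0]

    def test_welch_p_close_to_permutation_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 0.15, size=10)
        b = rng.normal(1.12, 0.15, size=10)
        cmp = fish.compare_conditions(a[:, None], b[:, None])
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:10].mean() - perm[10:].mean()) >= obs:
                count += 1
        perm_p = count / n_perm
        assert abs(cmp.p[0] - perm_p) < 0.01


class TestPositiveScoring:
    def test_zero_marker_scores_zero(self, small_field):
        nucs = fish.segment_nuclei(small_field.dna_channel, min_area=100)
        frac, calls = fish.score_positive_nuclei(
            nucs, np.zeros_like(small_field.dna_channel, dtype=float), 10.0
        )
        assert frac == 0.0 and not any(calls)

    def test_saturated_marker_scores_one(self, small_field):
        nucs = fish.segment_nuclei(small_field.dna_channel, min_area=100)
        marker = np.full(small_field.dna_channel.shape, 100.0)
        frac, calls = fish.score_positive_nuclei(nucs, marker, 10.0)
        assert frac == 1.0 and all(calls)

    def test_planted_positive_fraction_recovered(self):
        from scipy.stats import binom

        field = generate_nucleus_field(FieldSpec(n_nuclei=100, seed=55))
        rng = np.random.default_rng(56)
        marker = np.zeros(field.dna_channel.shape)
        positive_truth = rng.random(100) < 0.6
        for lab in np.nonzero(positive_truth)[0] + 1:
            rr, cc = np.nonzero(field.truth_masks == lab)
            marker[rr[0], cc[0]] = 500.0
        nucs = fish.segment_nuclei(field.dna_channel, min_area=100)
        frac, _ = fish.score_positive_nuclei(nucs, marker, 100.0)
        lo = binom.ppf(0.025, 100, 0.6) / 100
        hi = binom.ppf(0.975, 100, 0.6) / 100
        assert lo <= frac <= hi

    def test_empty_nucleus_list_rejected(self):
        with pytest.raises(ValueError):
            fish.score_positive_nuclei([], np.zeros((4, 4)), 1.0)
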