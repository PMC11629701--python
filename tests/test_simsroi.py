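"""Tests for ion-image alignment, correction, segmentation and ROI stats."""

import numpy as np
import pytest

from virovory.isotope import IsotopeConstants, atom_fraction_to_nitrogen_ion_ratio
from virovory.simsroi import (
    MASS_ORDER,
    IonImageStack,
    ROI,
    align_cycles,
    deadtime_correct,
    find_hotspots,
    roi_isotope_stats,
    segment_particles,
)
from virovory.synthetic_data import Particle, SceneSpec, generate_ion_stack


def _blob_stack(n_cycles=3, shape=(96, 96), shifts=None):
    """A bright square blob, optionally drifted per cycle."""
    base = np.zeros(shape)
    base[40:52, 30:42] = 200.0
    counts = np.zeros((4, n_cycles, *shape))
    for c in range(n_cycles):
        img = base
        if shifts and shifts[c] != (0, 0):
            img = np.roll(base, shifts[c], axis=(0, 1))
        counts[:, c] = img
    return IonImageStack(counts=counts)


class TestAlignment:
    def test_recovers_planted_drift(self):
        planted = [(0, 0), (3, -2), (-5, 4)]
        stack = _blob_stack(shifts=planted)
        aligned, shifts = align_cycles(stack)
        assert shifts == planted
        # after alignment all cycles agree on valid pixels
        cn = aligned.mass("12C14N")
        valid = aligned.valid_mask()
        for c in range(1, 3):
            both = valid[0] & valid[c]
            np.testing.assert_array_equal(cn[c][both], cn[0][both])

    def test_already_aligned_stack_gets_zero_shifts(self):
        stack = _blob_stack()
        _, shifts = align_cycles(stack)
        assert shifts == [(0, 0)] * 3

    def test_all_zero_cycle_flagged_with_zero_shift(self):
        stack = _blob_stack()
        counts = stack.counts.copy()
        counts[:, 1] = 0
        _, shifts = align_cycles(IonImageStack(counts=counts))
        assert shifts[1] == (0, 0)

    def test_noise_shifts_bounded_by_max_shift(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(2.0, size=(4, 5, 64, 64))
        _, shifts = align_cycles(IonImageStack(counts=counts), max_shift=10)
        assert all(abs(dy) <= 10 and abs(dx) <= 10 for dy, dx in shifts)

    def test_out_of_frame_pixels_marked_invalid(self):
        stack = _blob_stack(shifts=[(0, 0), (4, 0), (0, 0)])
        aligned, _ = align_cycles(stack)
        # correction rolls cycle 1 up by 4, so its bottom rows are invalid
        assert not aligned.valid_mask()[1, -1, :].any()
        assert aligned.valid_mask()[0].all()


class TestDeadtime:
    def test_zero_tau_is_identity(self):
        stack = _blob_stack()
        assert deadtime_correct(stack, tau_ns=0.0) is stack

    def test_formula_at_reference_point(self):
        counts = np.full((4, 1, 4, 4), 1000.0)
        corrected = deadtime_correct(IonImageStack(counts=counts), tau_ns=44.0)
        assert corrected.counts[0, 0, 0, 0] == pytest.approx(1000 / (1 - 0.044), rel=1e-9)

    def test_zero_counts_stay_zero(self):
        counts = np.zeros((4, 1, 4, 4))
        corrected = deadtime_correct(IonImageStack(counts=counts), tau_ns=44.0)
        assert np.all(corrected.counts == 0)

    def test_saturated_pixels_invalidated(self):
        counts = np.zeros((4, 1, 4, 4))
        counts[0, 0, 1, 1] = 1e6 / 44.0 * 1.1  # n*tau/dwell > 1
        corrected = deadtime_correct(IonImageStack(counts=counts), tau_ns=44.0)
        assert not corrected.valid_mask()[0, 1, 1]
        assert corrected.valid_mask()[0, 0, 0]


def _particle_scene(particles, **kw):
    defaults = dict(
        shape=(256, 256),
        particles=tuple(particles),
        background_density=0.02,
        yield_cn=200.0,
        n_cycles=10,
        beam_fwhm_nm=0.0,
        seed=11,
    )
    defaults.update(kw)
    return SceneSpec(**defaults)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_planted_disks_recovered_with_size_filter(self):
        # six disks above the minimum diameter plus one below it
        centers = [(40, 40), (40, 120), (40, 200), (120, 40), (120, 120), (200, 40)]
        particles = [Particle(center=c, diameter_um=1.2) for c in centers]
        particles.append(Particle(center=(200.0, 200.0), diameter_um=0.2))
        stack, masks, _ = generate_ion_stack(_particle_scene(particles))
        rois = segment_particles(stack, min_diameter_um=0.3)
        assert len(rois) == 6
        planted = [masks[f"particle_{i}"] for i in range(6)]
        for roi in rois:
            roi_mask = roi.mask(stack.shape)
            assert max(_jaccard(roi_mask, m) for m in planted) > 0.8

    def test_blank_image_yields_no_rois(self):
        counts = np.zeros((4, 3, 64, 64))
        assert segment_particles(IonImageStack(counts=counts)) == []

    def test_highly_labelled_particle_needs_cn_total_channel(self):
        """A ~97 at% 15N particle is dim in 12C14N and missed there, but
        its total CN signal stands out."""
        hot = Particle(
            center=(128.0, 128.0), diameter_um=1.5, f15N=0.97,
            c_density=0.15, n_density=0.15,
        )
        scene = _particle_scene([hot], background_density=0.05)
        stack, masks, _ = generate_ion_stack(scene)
        missed = segment_particles(stack, channel_spec="CN14")
        found = segment_particles(stack, channel_spec="CN_total")
        target = masks["particle_0"]
        assert not any(_jaccard(r.mask(stack.shape), target) > 0.3 for r in missed)
        assert any(_jaccard(r.mask(stack.shape), target) > 0.5 for r in found)

    def test_roi_count_monotone_in_threshold(self):
        particles = [
            Particle(center=(60, 60), diameter_um=1.0, n_density=0.5),
            Particle(center=(150, 150), diameter_um=1.0, n_density=2.0),
            Particle(center=(60, 180), diameter_um=1.0, n_density=6.0),
        ]
        stack, _, _ = generate_ion_stack(_particle_scene(particles))
        counts = [
            len(segment_particles(stack, threshold=t))
            for t in (50, 500, 2000, 6000, 1e9)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_translation_equivariance(self):
        particles = [Particle(center=(100, 100), diameter_um=1.5)]
        stack, _, _ = generate_ion_stack(_particle_scene(particles))
        shifted = IonImageStack(
            counts=np.roll(stack.counts, (9, -13), axis=(2, 3)),
            pixel_size_nm=stack.pixel_size_nm,
        )
        rois = segment_particles(stack)
        rois_shifted = segment_particles(shifted)
        assert len(rois) == len(rois_shifted) == 1
        moved = {(r + 9, c - 13) for r, c in rois[0].pixels}
        assert moved == set(rois_shifted[0].pixels)


class TestHotspots:
    # shallow large-area scan: 625 nm pixels -> 160 um field of view
    PX = 625.0

    def _scene(self, diameter_um):
        p = Particle(center=(128.0, 128.0), diameter_um=diameter_um, n_density=3.0)
        return _particle_scene([p], pixel_size_nm=self.PX)

    def test_protist_scale_hotspot_found(self):
        stack, _, _ = generate_ion_stack(self._scene(5.0))
        hotspots = find_hotspots(stack)
        assert len(hotspots) == 1
        assert hotspots[0].source == "hotspot"

    def test_bacteria_scale_particle_below_band(self):
        stack, _, _ = generate_ion_stack(self._scene(1.0))
        assert find_hotspots(stack) == []

    def test_oversized_blob_above_band(self):
        stack, _, _ = generate_ion_stack(self._scene(60.0))
        assert find_hotspots(stack) == []


class TestRoiIsotopeStats:
    def test_constant_counts_give_zero_sem(self):
        counts = np.zeros((4, 5, 32, 32))
        counts[0] = 100.0  # 12C2
        counts[1] = 10.0  # 13C12C
        counts[2] = 400.0  # 12C14N
        counts[3] = 20.0  # 12C15N
        stack = IonImageStack(counts=counts)
        roi = ROI.from_mask(np.ones((32, 32), bool), "all", "manual")
        rec = roi_isotope_stats(stack, roi)
        assert rec.carbon_ratio_mean == pytest.approx(0.1)
        assert rec.nitrogen_ratio_mean == pytest.approx(0.05)
        assert rec.carbon_ratio_sem == 0.0
        assert rec.nitrogen_ratio_sem == 0.0
        assert rec.n_cycles_used_carbon == 5

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30.0, size=(4, 8, 32, 32))
        stack = IonImageStack(counts=counts)
        mask = np.zeros((32, 32), bool)
        mask[5:15, 5:15] = True
        roi = ROI.from_mask(mask, "box", "manual")
        rec = roi_isotope_stats(stack, roi)
        ratios = []
        for cycle in range(8):
            num = counts[3, cycle][mask].sum()
            den = counts[2, cycle][mask].sum()
            ratios.append(num / den)
        import statistics

        assert rec.nitrogen_ratio_mean == pytest.approx(statistics.mean(ratios))
        assert rec.nitrogen_ratio_sem == pytest.approx(
            statistics.stdev(ratios) / np.sqrt(len(ratios))
        )

    def test_poisson_planted_enrichment_recovered(self):
        particle = Particle(center=(128.0, 128.0), diameter_um=2.0, f15N=0.30)
        scene = _particle_scene([particle], n_cycles=25, seed=5)
        stack, masks, _ = generate_ion_stack(scene)
        roi = ROI.from_mask(masks["particle_0"], "p0", "manual")
        rec = roi_isotope_stats(stack, roi)
        truth_ratio = atom_fraction_to_nitrogen_ion_ratio(0.30)
        assert abs(rec.nitrogen_ratio_mean - truth_ratio) < 3 * rec.nitrogen_ratio_sem

    def test_union_mean_lies_between_component_means(self):
        counts = np.zeros((4, 6, 32, 32))
        rng = np.random.default_rng(9)
        counts[2] = rng.poisson(500.0, size=(6, 32, 32))
        counts[3, :, :, :16] = rng.poisson(50.0, size=(6, 32, 16))
        counts[3, :, :, 16:] = rng.poisson(300.0, size=(6, 32, 16))
        stack = IonImageStack(counts=counts)
        left = np.zeros((32, 32), bool)
        left[:, :16] = True
        right = ~left
        rec_l = roi_isotope_stats(stack, ROI.from_mask(left, "l", "manual"))
        rec_r = roi_isotope_stats(stack, ROI.from_mask(right, "r", "manual"))
        rec_u = roi_isotope_stats(
            stack, ROI.from_mask(np.ones((32, 32), bool), "u", "manual")
        )
        lo, hi = sorted([rec_l.nitrogen_ratio_mean, rec_r.nitrogen_ratio_mean])
        assert lo <= rec_u.nitrogen_ratio_mean <= hi

    def test_all_zero_denominator_flagged_unusable(self):
        counts = np.zeros((4, 3, 16, 16))
        stack = IonImageStack(counts=counts)
        roi = ROI.from_mask(np.ones((16, 16), bool), "z", "manual")
        rec = roi_isotope_stats(stack, roi)
        assert not rec.usable
        assert rec.measurement is None

    def test_roi_outside_image_rejected(self):
        counts = np.zeros((4, 3, 16, 16))
        roi = ROI(id="bad", pixels=frozenset({(20, 2)}), source="manual", area_um2=0.1)
        with pytest.raises(ValueError, match="outside"):
            roi_isotope_stats(IonImageStack(counts=counts), roi)


class TestStackIO:
    def test_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(4, 3, 32, 32))
        stack = IonImageStack(counts=counts)
        path = tmp_path / "stack.tif"
        stack.save_tiff(path)
        loaded = IonImageStack.load_tiff(path)
        np.testing.assert_array_equal(loaded.counts, counts)
        assert loaded.pixel_size_nm == stack.pixel_size_nm

    def test_rle_roundtrip(self):
        mask = np.zeros((16, 16), bool)
        mask[3:7, 4:9] = True
        mask[10, 0] = True
        roi = ROI.from_mask(mask, "r1", "manual")
        rle = roi.to_rle(mask.shape)
        back = ROI.from_rle(rle)
        assert back.pixels == roi.pixels
        assert back.id == "r1"
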