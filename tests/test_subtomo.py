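import numpy as np
import pytest
from scipy import ndimage
from scipy.signal import argrelmin

import cristoscope.phantom as ph
import cristoscope.subtomo as st


class TestTemplateBank:
    def test_default_bank_spans_printed_range(self, bank):
        assert bank.n_templates == 40
        assert bank.separations_nm[0] == pytest.approx(2.2)
        assert bank.separations_nm[-1] == pytest.approx(88.0)
        assert np.all(np.diff(bank.separations_px) == 1)

    def test_templates_have_zero_mean_under_mask(self, bank):
        w = bank.mask
        for k in (0, 19, 39):
            mean = float((bank.templates[k] * w).sum() / w.sum())
            assert mean == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [5, 8, 12, 20, 30, 40])
    def test_axial_profile_troughs_at_separation(self, bank, k):
        """The continuous axial profile of template k has its two density
        troughs exactly k pixels apart (for separations wide enough that the
        two membranes are resolved)."""
        z = np.linspace(0, bank.box - 1, (bank.box - 1) * 50 + 1)
        prof = bank.axial_profile(k, z)
        minima = argrelmin(prof)[0]
        assert len(minima) == 2
        assert abs(z[minima[-1]] - z[minima[0]] - k) <= 0.05

    def test_overlapping_separations_merge_to_single_trough(self, bank):
        z = np.linspace(0, bank.box - 1, (bank.box - 1) * 50 + 1)
        prof = bank.axial_profile(1, z)
        assert len(argrelmin(prof)[0]) == 1

    def test_separation_must_fit_in_box(self):
        with pytest.raises(ValueError):
            st.make_template_bank(n=50, box=48)


class TestExtractSubtomograms:
    def test_constant_volume_gives_constant_subvolume(self):
        from cristoscope.volio import Tomogram

        tomo = Tomogram(np.full((40, 40, 40), 2.5), 1.0)
        parts = st.extract_subtomograms(tomo, [(20, 20, 20)], box=16)
        assert parts.n == 1
        np.testing.assert_allclose(parts.subvolumes[0], 2.5)

    def test_delta_lands_at_subvolume_center(self):
        from cristoscope.volio import Tomogram

        vol = np.zeros((40, 40, 40))
        vol[22, 25, 19] = 1.0
        tomo = Tomogram(vol, 1.0)
        parts = st.extract_subtomograms(tomo, [(22, 25, 19)], box=16)
        assert parts.subvolumes[0][8, 8, 8] == 1.0
        assert parts.subvolumes[0].sum() == 1.0

    def test_boundary_violations_dropped_and_counted(self):
        from cristoscope.volio import Tomogram

        tomo = Tomogram(np.zeros((30, 30, 30)), 1.0)
        parts = st.extract_subtomograms(tomo, [(2, 15, 15), (15, 15, 15)], box=16)
        assert parts.n == 1
        assert parts.n_dropped == 1


class TestAlignAndAverage:
    def _blob_reference(self, box=32, seed=7):
        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.normal(size=(box, box, box)), 3.0)

    def test_identical_particles_are_a_fixed_point(self):
        ref = self._blob_reference()
        subs = np.stack([ref] * 5)
        parts = st.ParticleSet(subs, np.zeros((5, 3), int), 1.0)
        avg, out = st.align_and_average(parts, n_iter=12, shift_bound_px=3, seed=0)
        assert avg.converged
        np.testing.assert_allclose(avg.density, ref, atol=1e-12)
        assert np.all(out.shifts == 0)
        assert avg.cc_trace[-1] == pytest.approx(1.0, abs=1e-9)

    def test_planted_integer_shifts_recovered_exactly(self):
        """Noiseless copies with planted integer shifts <= 4 px are recovered
        exactly (negated), and the alignment objective never decreases."""
        ref = self._blob_reference()
        rng = np.random.default_rng(11)
        shifts = rng.integers(-3, 4, size=(20, 3))
        shifts -= np.rint(shifts.mean(axis=0)).astype(int)  # still within +/-4
        subs = np.stack([np.roll(ref, s, axis=(0, 1, 2)) for s in shifts])
        parts = st.ParticleSet(subs, np.zeros((20, 3), int), 1.0)
        avg, out = st.align_and_average(parts, n_iter=12, shift_bound_px=4, seed=1)
        np.testing.assert_array_equal(out.shifts, -shifts)
        assert np.all(np.diff(avg.cc_trace) >= -1e-6)
        mask = st._soft_spherical_mask(32)
        assert st._masked_pearson(avg.density, ref, mask) > 0.99

    def test_deterministic_under_fixed_seed(self):
        ref = self._blob_reference(seed=3)
        rng = np.random.default_rng(4)
        subs = np.stack(
            [np.roll(ref, s, axis=(0, 1, 2)) for s in rng.integers(-3, 4, (8, 3))]
        )
        parts = st.ParticleSet(subs, np.zeros((8, 3), int), 1.0)
        avg1, out1 = st.align_and_average(parts, seed=5)
        avg2, out2 = st.align_and_average(parts, seed=5)
        np.testing.assert_array_equal(out1.shifts, out2.shifts)
        assert avg1.cc_trace == avg2.cc_trace

    def test_too_few_particles_raise(self):
        parts = st.ParticleSet(np.zeros((1, 8, 8, 8)), np.zeros((1, 3), int), 1.0)
        with pytest.raises(ValueError):
            st.align_and_average(parts)

    def test_all_zero_particles_excluded(self):
        ref = self._blob_reference()
        subs = np.stack([ref, ref, np.zeros_like(ref)])
        parts = st.ParticleSet(subs, np.zeros((3, 3), int), 1.0)
        avg, out = st.align_and_average(parts, seed=0)
        assert avg.n_particles == 2
        assert out.cc_scores[2] == 0.0


class TestEstimateWidth:
    def test_self_match_identity_for_every_template(self, bank):
        """estimate_width(template_k) returns k * pixel_size with cc 1."""
        for k in range(1, bank.n_templates + 1):
            w, cc, ki = st.estimate_width(bank.templates[k - 1], bank)
            assert ki == k - 1
            assert w == pytest.approx(k * bank.pixel_size_nm)
            assert cc == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_planted_separation(self, bank):
        """Noiseless membrane pairs at 3, 6, 9 px separations yield strictly
        increasing width calls."""
        z = np.arange(bank.box, dtype=float)
        widths = []
        for k in (3, 6, 9):
            prof = st._membrane_pair_profile(
                z, float(k), (bank.box - 1) / 2.0,
                bank.thickness_nm / bank.pixel_size_nm, bank.sigma_px,
            )
            vol = np.broadcast_to(prof[:, None, None], (bank.box,) * 3).copy()
            w, _, _ = st.estimate_width(vol, bank)
            widths.append(w)
        assert widths == sorted(widths)
        assert len(set(widths)) == 3

    def test_shifted_particle_still_called_correctly(self, bank):
        vol = np.roll(bank.templates[9], 4, axis=0)
        w, cc, _ = st.estimate_width(vol, bank)
        assert w == pytest.approx(22.0)
        assert cc > 0.98

    def test_box_mismatch_raises(self, bank):
        with pytest.raises(ValueError):
            st.estimate_width(np.zeros((32, 32, 32)), bank)

    def test_phantom_particles_recover_width_at_moderate_noise(self, bank):
        """30 particles from a 15 nm crista at SNR 1: the median width call
        lands within one template step of truth."""
        crista = ph.CristaSpec(
            "lamellar", width_nm=15.0, length_nm=110.0, height_nm=90.0,
            orientation=(0, 0, 1), junctions=[ph.JunctionSpec()],
        )
        spec = ph.PhantomSpec(
            box_shape=(96, 104, 112), semi_axes_nm=(100, 110, 120),
            cristae=[crista], wedge_half_angle_deg=0.0, seed=21,
        )
        _, labels, ground = ph.generate_phantom(spec)
        spec.noise_sigma = ph.noise_sigma_for_snr(ph.render_density(labels, spec), 1.0)
        tomo, labels, ground = ph.generate_phantom(spec)
        pos, normals = ph.sample_particles(labels, ground, 30, seed=22, min_margin_px=24)
        parts = st.extract_subtomograms(tomo, pos, bank.box)
        calls = []
        for i in range(parts.n):
            vol = st.orient_to_z(parts.subvolumes[i], normals[i])
            calls.append(st.estimate_width(vol, bank)[0])
        assert np.median(calls) == pytest.approx(15.0, abs=bank.pixel_size_nm)

    def test_orientation_refinement_rescues_tilted_particle(self, bank):
        """A membrane pair tilted 15 deg off the template normal correlates
        better after the orientation search."""
        rot = st._orientation_grid(15.0, 15.0)[1]
        vol = st._rotate_volume(bank.templates[11], rot)
        w_plain, cc_plain, _ = st.estimate_width(vol, bank)
        w_ref, cc_ref, _ = st.estimate_width(
            vol, bank, refine_orientation=True, max_tilt_deg=20.0
        )
        assert cc_ref >= cc_plain
        assert w_ref == pytest.approx(12 * 2.2, abs=bank.pixel_size_nm)


class TestWidthTables:
    def test_single_width_single_bin(self):
        hist = st.width_histogram([22.0], bin_nm=2.2)
        assert hist["count"].sum() == 1
        assert hist.loc[hist["count"] == 1, "bin_left_nm"].iloc[0] == pytest.approx(22.0)

    @pytest.mark.parametrize("bin_nm", [1.0, 2.2, 5.0])
    def test_counts_conserve_n(self, bin_nm):
        rng = np.random.default_rng(8)
        widths = rng.uniform(2, 80, 137)
        hist = st.width_histogram(widths, bin_nm=bin_nm)
        assert hist["count"].sum() == 137
        ratio = hist["bin_left_nm"].to_numpy() / bin_nm
        assert np.allclose(ratio, np.round(ratio))

    def test_bimodal_mixture_shows_two_modes(self, bank):
        """Width calls from a 5 px / 12 px planted mixture histogram into two
        modes at the planted bins."""
        calls = []
        for k, n in ((5, 30), (12, 30)):
            for i in range(n):
                rng = np.random.default_rng(100 * k + i)
                vol = bank.templates[k - 1] + rng.normal(
                    0, 0.3 * bank.templates[k - 1].std(), size=(bank.box,) * 3
                )
                calls.append(st.estimate_width(vol, bank)[0])
        hist = st.width_histogram(calls, bin_nm=2.2)
        counts = hist.set_index("bin_left_nm")["count"]
        top_two = counts.sort_values(ascending=False).index[:2]
        assert set(np.round(top_two, 1)) == {round(5 * 2.2, 1), round(12 * 2.2, 1)}

    def test_empty_widths_raise(self):
        with pytest.raises(ValueError):
            st.width_histogram([])

    def test_width_table_requires_estimates(self):
        parts = st.ParticleSet(np.zeros((2, 8, 8, 8)), np.zeros((2, 3), int), 1.0)
        with pytest.raises(ValueError):
            st.width_table(parts, "WT")


class TestMeasureAverageWidth:
    def test_average_of_template_copies(self, bank):
        avg = st.AverageMap(
            density=bank.templates[9].copy(), n_particles=10, cc_trace=[1.0],
            converged=True, pixel_size_nm=bank.pixel_size_nm,
        )
        assert st.measure_average_width(avg, bank) == pytest.approx(22.0)

    def test_agrees_with_per_particle_mode_on_noiseless_set(self, bank):
        subs = np.stack([bank.templates[14]] * 6)
        parts = st.ParticleSet(subs, np.zeros((6, 3), int), bank.pixel_size_nm)
        avg, _ = st.align_and_average(parts, seed=2)
        per_particle = [st.estimate_width(s, bank)[0] for s in subs]
        mode = max(set(per_particle), key=per_particle.count)
        assert st.measure_average_width(avg, bank) == pytest.approx(mode)
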