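"""FLD profiles, peak detection, contacts, stacking and sedimentation."""

import numpy as np
import pytest

from fibertopo.fixtures import canonical_fiber
from fibertopo.geometry import (BasePairFrame, FiberSpec, StepParams,
                                build_chain, regular_fiber)
from fibertopo.observables import (FLDProfile, classify_contacts,
                                   detect_peaks, fld_profile, sedimentation)


def _straight_dna(n=500):
    frames = build_chain(BasePairFrame.identity(),
                         [StepParams.relaxed()] * (n - 1))
    return np.array([f.origin for f in frames])


class TestFLDProfile:
    def test_break_correlation_weight_values(self):
        """Two points at distance 0 weigh 1; at d = lambda they weigh
        1/e."""
        pts = np.zeros((300, 3))
        pts[:, 2] = np.arange(300) * 0.34
        prof = fld_profile(pts, lambda_nm=4.0, n_range=(250, 260))
        # pair separated by n bp sits at 0.34*n nm on straight DNA
        for n in (250, 255):
            expected = np.exp(-0.34 * n / 4.0)
            assert prof.value_at(n) == pytest.approx(expected, rel=1e-9)

    def test_straight_dna_profile_is_strictly_decreasing(self):
        prof = fld_profile(_straight_dna(), lambda_nm=4.0, n_range=(250, 400))
        assert np.all(np.diff(prof.values) < 0)
        assert detect_peaks(prof) == []

    def test_linearity_over_conformations(self, t2_fiber, template):
        other = regular_fiber(t2_fiber.spec, StepParams(0, 0, 34.0, 0, 0, 0.34),
                              template=template)
        p2 = fld_profile(t2_fiber, n_range=(260, 300))
        p1 = fld_profile(other, n_range=(260, 300))
        both = fld_profile([t2_fiber, other], n_range=(260, 300))
        np.testing.assert_allclose(both.values,
                                   0.5 * (p1.values + p2.values), rtol=1e-12)

    def test_mismatched_bp_counts_rejected(self, t2_fiber, t1_fiber):
        with pytest.raises(ValueError, match="same bp count"):
            fld_profile([t2_fiber, t1_fiber], n_range=(260, 300))

    def test_rigid_motion_invariance_and_lambda_scaling(self, t2_fiber, rng):
        from scipy.spatial.transform import Rotation
        pts = t2_fiber.bp_origins()
        p0 = fld_profile(pts, lambda_nm=4.0, n_range=(250, 300))
        R = Rotation.random(random_state=3).as_matrix()
        p1 = fld_profile(pts @ R.T + rng.normal(0, 30, 3), lambda_nm=4.0,
                         n_range=(250, 300))
        np.testing.assert_allclose(p1.values, p0.values, rtol=1e-9)
        # scaling coordinates by c is the same as lambda -> lambda / c
        c = 1.7
        p2 = fld_profile(pts * c, lambda_nm=4.0 * c, n_range=(250, 300))
        np.testing.assert_allclose(p2.values, p0.values, rtol=1e-9)

    def test_overlong_fragments_are_absent_not_zero(self):
        pts = _straight_dna(300)
        prof = fld_profile(pts, n_range=(250, 400))
        assert prof.range == (250, 299)
        with pytest.raises(KeyError):
            prof.value_at(350)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            fld_profile(_straight_dna(300), lambda_nm=-1.0)


class TestDetectPeaks:
    def test_single_gaussian_bump_gives_one_peak_at_center(self):
        n = np.arange(250, 401)
        y = np.exp(-0.5 * ((n - 320) / 12.0) ** 2)
        prof = FLDProfile(lambda_nm=4.0, n_values=n, values=y)
        peaks = detect_peaks(prof, 0.05)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 320) <= 2

    def test_monotone_profile_has_no_peaks(self):
        n = np.arange(250, 401)
        prof = FLDProfile(lambda_nm=4.0, n_values=n,
                          values=np.exp(-n / 50.0))
        assert detect_peaks(prof, 0.05) == []

    def test_t2_fiber_has_the_two_zigzag_peaks(self, nrl187_t2_12mer):
        """Optimal T2 fiber at NRL 187: two FLD maxima in 250-400 nt, the
        first in the 280-290 nt region (one-gyre-short of two repeats),
        the second near two repeats."""
        prof = fld_profile(nrl187_t2_12mer, lambda_nm=4.0, n_range=(250, 400))
        peaks = detect_peaks(prof, 0.05)
        assert len(peaks) >= 2
        positions = [p for p, _, _ in peaks]
        assert 270 <= positions[0] <= 295
        assert 350 <= positions[-1] <= 380


class TestContacts:
    def test_mononucleosome_has_no_contacts(self, template):
        from fibertopo.geometry import assemble_fiber
        fiber = assemble_fiber(FiberSpec(L=20, n_nucleosomes=1), [],
                               template=template)
        stats = classify_contacts(fiber)
        assert sum(stats.counts_by_offset.values()) == 0
        assert stats.stacking_fraction == 0.0

    def test_canonical_t2_is_fully_stacked_via_offset_two(self, t2_fiber):
        stats = classify_contacts(t2_fiber)
        assert stats.counts_by_offset[2] > 0
        assert stats.counts_by_offset[3] == 0
        assert stats.stacking_fraction > 0.9
        assert stats.flipout_rate == 0.0

    def test_nrl187_t2_contacts_are_all_offset_two(self, nrl187_t2_12mer):
        """At NRL 187 the two stacks are far enough apart that every
        close contact is of the (i, i+-2) type."""
        stats = classify_contacts(nrl187_t2_12mer)
        assert stats.counts_by_offset[2] > 0
        assert stats.contact_fraction(2) == pytest.approx(1.0)


class TestSedimentation:
    def test_single_nucleosome_sediments_at_s_mono(self, template):
        from fibertopo.geometry import assemble_fiber
        fiber = assemble_fiber(FiberSpec(L=20, n_nucleosomes=1), [],
                               template=template)
        res = sedimentation(fiber, s_mono=11.1)
        assert res.s20w == pytest.approx(11.1)

    def test_uniform_compression_increases_s(self, t2_fiber):
        centers = t2_fiber.core_centers_axes()[0]
        s_full = sedimentation(centers).s20w
        s_compressed = sedimentation(centers * 0.5).s20w
        assert s_compressed > s_full

    def test_t2_is_more_compact_than_t1(self, t2_fiber, t1_fiber):
        c2 = t2_fiber.core_centers_axes()[0]
        c1 = t1_fiber.core_centers_axes()[0]
        assert sedimentation(c2).s20w > sedimentation(c1).s20w

    def test_coincident_centers_are_degenerate(self):
        centers = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            sedimentation(centers)


class TestFLDFamilyAsymmetry:
    def test_t1_fold_suppresses_the_lower_peak_region(self):
        """In the stacked T1 fold the cross-stack gyres are spatially
        distant, so the ~285-nt FLD signal relative to the ~365-nt
        signal is weaker than in the T2 fold."""
        from fibertopo.fixtures import STACKED_T1_LINKER
        t2_12 = canonical_fiber("T2", n_nucleosomes=12)
        t1_12 = regular_fiber(FiberSpec(L=25, n_nucleosomes=12),
                              STACKED_T1_LINKER)
        p2 = fld_profile(t2_12, n_range=(250, 400))
        p1 = fld_profile(t1_12, n_range=(250, 400))

        def ratio(prof, lo_center, hi_center):
            lo = np.mean([prof.value_at(n) for n in range(lo_center - 5,
                                                          lo_center + 6)])
            hi = np.mean([prof.value_at(n) for n in range(hi_center - 5,
                                                          hi_center + 6)])
            return lo / hi

        # compare each family's low region to its own high region
        assert ratio(p1, 285, 365) < ratio(p2, 285, 365)
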