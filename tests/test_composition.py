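"""Dyad-frame reorientation, composition matrices, logos, symmetry, motifs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cleavemap as cm
from cleavemap.composition import reverse_complement_pattern
from cleavemap.errors import DataError
from cleavemap.io import Region
from cleavemap.peaks import Peak
from cleavemap.synth import reverse_complement


class TestExtractDyadWindow:
    def test_hand_indexed_top_window(self):
        ref = cm.ReferenceSequence("x", "AAGCATTA", topology="circular")
        window = cm.extract_dyad_window(ref, Peak(3, "top", 0.0), halfwidth=2)
        assert window == "GCAT"  # relative (-2,-1,+1,+2) = G,C,A,T

    def test_bottom_window_is_reverse_complement_of_paired_top(self):
        ref = cm.ReferenceSequence("x", "AAGCATTA", topology="circular")
        # same DSB: top read at dyad_left, bottom read at dyad_left + 1
        top_w = cm.extract_dyad_window(ref, Peak(3, "top", 0.0), 3)
        bottom_w = cm.extract_dyad_window(ref, Peak(4, "bottom", 0.0), 3)
        assert bottom_w == reverse_complement(top_w)

    def test_halfwidth_one_gives_dyad_flanking_bases(self):
        ref = cm.ReferenceSequence("x", "AAGCATTA", topology="circular")
        assert cm.extract_dyad_window(ref, Peak(3, "top", 0.0), 1) == "CA"

    def test_linear_out_of_range_rejected(self):
        ref = cm.ReferenceSequence("x", "ACGTACGT", topology="linear")
        with pytest.raises(DataError):
            cm.extract_dyad_window(ref, Peak(0, "top", 0.0), 3)

    @given(st.integers(min_value=0, max_value=59))
    def test_reorientation_consistency_everywhere(self, dyad_left):
        ref = cm.generate_reference(60, gc=0.5, topology="circular", seed=17)
        top_w = cm.extract_dyad_window(ref, Peak(dyad_left, "top", 0.0), 4)
        bottom_w = cm.extract_dyad_window(ref, Peak((dyad_left + 1) % 60, "bottom", 0.0), 4)
        assert bottom_w == reverse_complement(top_w)


class TestCompositionMatrix:
    def test_identical_windows_give_one_hot_columns(self):
        comp = cm.composition_matrix(["GATC"] * 5)
        expected = np.zeros((4, 4))
        for i, b in enumerate("GATC"):
            expected[i, "ACGT".index(b)] = 1.0
        assert np.array_equal(comp.fractions, expected)

    def test_uniform_windows_approach_quarter_fractions(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(4000)]
        comp = cm.composition_matrix(windows)
        assert np.allclose(comp.fractions, 0.25, atol=0.05)

    def test_width_mismatch_rejected(self):
        with pytest.raises(DataError):
            cm.composition_matrix(["ACGT", "ACG"])

    def test_biased_library_recovers_g_minus3_c_plus3(self, ref10k, biased_library):
        rpm = cm.normalize_rpm(biased_library["map"])
        peaks = cm.top_n_peaks(cm.filter_fillin_artifacts(cm.call_peaks(rpm, 3000), rpm), 50)
        comp = cm.composition_matrix(
            [cm.extract_dyad_window(ref10k, p, 3) for p in peaks]
        )
        frame = comp.to_frame()
        assert frame.loc[-3].idxmax() == "G"
        assert frame.loc[3].idxmax() == "C"


class TestGcCorrectedLogo:
    def test_background_equal_observed_gives_zero_heights(self):
        f = np.tile([0.3, 0.2, 0.2, 0.3], (4, 1))
        comp = cm.CompositionMatrix(halfwidth=2, fractions=f, n_sites=10)
        logo = cm.gc_corrected_logo(comp, background_gc=0.4)
        assert np.allclose(logo.heights, 0.0, atol=1e-12)
        assert np.allclose(logo.information, 0.0, atol=1e-12)

    def test_one_hot_column_on_uniform_background_is_two_bits(self):
        f = np.zeros((2, 4))
        f[:, 2] = 1.0  # all G
        comp = cm.CompositionMatrix(halfwidth=1, fractions=f, n_sites=10)
        logo = cm.gc_corrected_logo(comp, background_gc=0.5)
        assert np.allclose(logo.information, 2.0)
        assert logo.heights[0, 2] == pytest.approx(2.0)

    def test_local_gc_override_changes_information(self):
        f = np.zeros((2, 4))
        f[:, 2] = 1.0
        comp = cm.CompositionMatrix(halfwidth=1, fractions=f, n_sites=10)
        genome_avg = cm.gc_corrected_logo(comp, background_gc=0.385)
        local = cm.gc_corrected_logo(comp, background_gc=0.478)
        # all-G column is less surprising on a more GC-rich background
        assert local.information[0] < genome_avg.information[0]

    def test_degenerate_background_rejected(self):
        comp = cm.CompositionMatrix(halfwidth=1, fractions=np.full((2, 4), 0.25), n_sites=1)
        for gc in (0.0, 1.0):
            with pytest.raises(DataError):
                cm.gc_corrected_logo(comp, gc)


class TestSymmetryScore:
    def test_exactly_symmetric_matrix_scores_zero(self):
        # f(p, b) = f(-p, complement(b)) by construction
        left = np.array([[0.5, 0.1, 0.2, 0.2], [0.4, 0.3, 0.2, 0.1]])
        right = left[::-1][:, [3, 2, 1, 0]]
        comp = cm.CompositionMatrix(halfwidth=2, fractions=np.vstack([left, right]), n_sites=5)
        assert cm.symmetry_score(comp) == 0.0

    def test_uniform_matrix_scores_zero(self):
        comp = cm.CompositionMatrix(halfwidth=3, fractions=np.full((6, 4), 0.25), n_sites=5)
        assert cm.symmetry_score(comp) == 0.0

    def test_asymmetric_matrix_scores_positive(self):
        f = np.full((4, 4), 0.25)
        f[0] = [1.0, 0.0, 0.0, 0.0]
        comp = cm.CompositionMatrix(halfwidth=2, fractions=f, n_sites=5)
        assert cm.symmetry_score(comp) > 0.1


class TestMotifScan:
    def test_gnatnc_matches_ggatac(self):
        ref = cm.ReferenceSequence("x", "GGATAC", topology="linear")
        assert cm.motif_scan(ref, "GNATNC") == [0]

    def test_cntang_does_not_match_ggatac(self):
        ref = cm.ReferenceSequence("x", "GGATAC", topology="linear")
        assert cm.motif_scan(ref, "CNTANG") == []

    def test_gnatnc_is_its_own_reverse_complement(self):
        assert reverse_complement_pattern("GNATNC") == "GNATNC"
        assert reverse_complement_pattern("CNTANG") == "CNTANG"

    def test_scanning_both_strands_is_moot_for_palindromic_pattern(self, ref10k):
        single = cm.motif_scan(ref10k, "GNATNC")
        both = cm.motif_scan(ref10k, "GNATNC", scan_bottom=True)
        assert single == both

    def test_overlapping_matches_all_reported(self):
        ref = cm.ReferenceSequence("x", "GGATACGAATTC", topology="linear")
        hits = cm.motif_scan(ref, "GNATNC")
        assert hits == [0, 6]

    def test_region_restriction(self):
        ref = cm.ReferenceSequence("x", "GGATACGAATTC", topology="linear")
        hits = cm.motif_scan(ref, "GNATNC", regions=[Region("x", 6, 12)])
        assert hits == [6]

    def test_circular_wraparound_match(self):
        # match spans the origin: TNC|GNA at positions 9..11 + 0..2
        ref = cm.ReferenceSequence("x", "ATACAAAAAGG", topology="circular")
        assert 9 in cm.motif_scan(ref, "GNATNC")

    def test_invalid_iupac_letter_rejected(self, ref10k):
        with pytest.raises(DataError):
            cm.motif_scan(ref10k, "GNAXNC")


class TestAverageProfile:
    def test_single_anchor_returns_window_slice(self, uniform_library):
        smap = uniform_library["map"]
        prof = cm.average_profile_around(smap, [100], halfwidth=5)
        assert np.array_equal(prof.top, smap.top[95:106])
        assert prof.matrix_top.shape == (1, 11)

    def test_motif_anchored_profile_peaks_at_dyad_read_positions(self, ref10k, biased_library):
        smap = biased_library["map"]
        anchors = cm.motif_scan(ref10k, "GNATNC")
        prof = cm.average_profile_around(smap, anchors, halfwidth=6)
        center = 6
        # cleavage at motif placements puts the top read 2 nt and the bottom
        # read 3 nt right of the motif start (the A/T flanking the dyad)
        assert prof.top.argmax() == center + 2
        assert prof.bottom.argmax() == center + 3

    def test_random_anchors_give_flat_background_profile(self, ref10k, biased_library):
        smap = biased_library["map"]
        motif_sites = set(cm.motif_scan(ref10k, "GNATNC"))
        rng = np.random.default_rng(8)
        anchors = [int(a) for a in rng.integers(0, len(ref10k), 300)
                   if a not in motif_sites][:200]
        prof = cm.average_profile_around(smap, anchors, halfwidth=6)
        signal = cm.average_profile_around(smap, sorted(motif_sites), halfwidth=6)
        assert prof.top.max() < 0.1 * signal.top.max()

    def test_empty_anchor_list_rejected(self, uniform_library):
        with pytest.raises(DataError):
            cm.average_profile_around(uniform_library["map"], [], 5)
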