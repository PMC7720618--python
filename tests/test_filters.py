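"""Filter cascade: depth masking, missingness, MAF, parentage assignment,
and the chi-square segregation-distortion test with its df-2 closed form."""

import numpy as np
import pytest
from scipy.stats import chi2

from f2radmap import filters, synth
from f2radmap.filters import FilterConfig, segregation_test
from f2radmap.io import A, B, H, MISSING
from tests.conftest import make_matrix


class TestMaskLowDepth:
    def test_only_shallow_calls_masked(self):
        mat = make_matrix([[A, H, B]], depths=[[5, 4, 9]])
        out = filters.mask_low_depth(mat, 5)
        assert out.calls.tolist() == [[A, MISSING, B]]

    def test_threshold_zero_is_identity(self):
        mat = make_matrix([[A, H]], depths=[[0, 0]])
        out = filters.mask_low_depth(mat, 0)
        assert np.array_equal(out.calls, mat.calls)

    def test_missing_depths_rejected(self):
        mat = make_matrix([[A, H]])
        with pytest.raises(ValueError, match="depth"):
            filters.mask_low_depth(mat, 5)


class TestDropIndividuals:
    def test_high_missingness_individual_removed(self):
        calls = np.full((2, 20), A, dtype=np.int8)
        calls[1, :19] = MISSING  # 95% missing
        mat = make_matrix(calls)
        out, removed = filters.drop_individuals(mat, 0.9)
        assert removed == ["s1"] and out.n_samples == 1

    def test_complete_data_untouched_and_threshold_one_keeps_all(self):
        calls = np.full((3, 5), H, dtype=np.int8)
        mat = make_matrix(calls)
        assert filters.drop_individuals(mat, 0.9)[0].n_samples == 3
        calls[0] = MISSING
        assert filters.drop_individuals(make_matrix(calls), 1.0)[0].n_samples == 3


class TestMAF:
    def test_allele_counting(self):
        # 60 A, 100 H, 40 B -> MAF (80+100)/400 = 0.45 kept;
        # 99 A, 0 H, 1 B -> MAF 2/200 = 0.01 dropped; monomorphic dropped
        col1 = [A] * 60 + [H] * 100 + [B] * 40
        col2 = [A] * 99 + [B] * 1 + [A] * 100
        col3 = [A] * 200
        mat = make_matrix(np.array([col1, col2, col3]).T)
        out = filters.filter_maf(mat, 0.05)
        assert list(out.markers["id"]) == ["M0"]


class TestSiteMissing:
    @pytest.mark.parametrize("n_called,kept", [(79, False), (80, False), (81, True), (100, True)])
    def test_called_fraction_threshold(self, n_called, kept):
        col = [A] * n_called + [MISSING] * (100 - n_called)
        mat = make_matrix(np.array([col]).T)
        out = filters.filter_site_missing(mat, 0.20)
        assert (out.n_markers == 1) == kept

    def test_all_missing_dropped(self):
        mat = make_matrix(np.full((10, 1), MISSING, dtype=np.int8))
        assert filters.filter_site_missing(mat, 0.2).n_markers == 0


class TestParentage:
    def _mat(self, p1_calls, p2_calls, progeny=((A, H), (H, B))):
        rows = list(p1_calls) + list(p2_calls) + [list(p) for p in progeny]
        roles = (["parent1"] * len(p1_calls) + ["parent2"] * len(p2_calls)
                 + ["progeny"] * len(progeny))
        return make_matrix(np.array(rows, dtype=np.int8), roles=roles, coding="ref")

    def test_clean_polymorphic_site_recode(self):
        # parent1 hom-ref x4, parent2 hom-alt x3 at both sites
        mat = self._mat([[A, A]] * 4, [[B, B]] * 3)
        out, report = filters.assign_parentage(mat)
        assert out.n_markers == 2 and len(report) == 0
        assert out.coding == "ab"

    def test_parent1_alt_site_flips_to_A(self):
        # at marker 0 parent1 is hom-alt -> alt allele becomes "A"
        mat = self._mat([[B, A]] * 2, [[A, B]] * 2, progeny=[[B, A], [A, B]])
        out, _ = filters.assign_parentage(mat)
        # progeny hom matching parent1 must be coded A at both markers
        prog = out.progeny_index
        assert out.calls[prog[0]].tolist() == [A, A]
        assert out.calls[prog[1]].tolist() == [B, B]

    def test_any_het_parent_replicate_excludes_site(self):
        mat = self._mat([[H, A]] * 1 + [[A, A]] * 3, [[B, B]] * 3)
        out, report = filters.assign_parentage(mat)
        assert list(out.markers["id"]) == ["M1"]
        assert report.iloc[0]["reason"] == "parental_het"

    def test_monomorphic_between_parents_excluded(self):
        mat = self._mat([[A, A]] * 2, [[A, B]] * 2)
        out, report = filters.assign_parentage(mat)
        assert list(out.markers["id"]) == ["M1"]
        assert report.iloc[0]["reason"] == "monomorphic"

    def test_tied_replicates_excluded_as_undetermined(self):
        mat = self._mat([[A, A], [B, A]], [[B, B], [B, B]])  # marker0 p1 tie A/B
        out, report = filters.assign_parentage(mat)
        assert list(out.markers["id"]) == ["M1"]
        assert report.iloc[0]["reason"] == "undetermined_consensus"

    def test_no_parents_rejected(self):
        mat = make_matrix([[A, H]], coding="ref")
        with pytest.raises(ValueError, match="parent"):
            filters.assign_parentage(mat)


class TestSegregationTest:
    def test_perfect_ratio(self):
        res = segregation_test((48, 96, 48))
        assert res.statistic == 0 and res.p_value == 1 and not res.excluded

    def test_distorted_counts_closed_form(self):
        # (70,100,30) vs E=(50,100,50): X2 = 16, p = e^-8
        res = segregation_test((70, 100, 30))
        assert res.statistic == pytest.approx(16.0)
        assert res.p_value == pytest.approx(np.exp(-8), rel=1e-12)
        assert res.excluded

    def test_mild_deviation_kept(self):
        res = segregation_test((55, 95, 50))
        assert res.statistic == pytest.approx(0.75)
        assert res.p_value == pytest.approx(np.exp(-0.375), rel=1e-12)
        assert not res.excluded

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            segregation_test((0, 0, 0))

    def test_closed_form_matches_chi2_distribution(self):
        # p = exp(-X2/2) is exactly the df-2 survival function
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.multinomial(200, [0.3, 0.4, 0.3])
            res = segregation_test(tuple(counts))
            assert res.p_value == pytest.approx(
                chi2.sf(res.statistic, df=2), abs=1e-10
            )

    def test_null_exclusion_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(200, [0.25, 0.5, 0.25], size=4000)
        excl = sum(segregation_test(tuple(c)).excluded for c in counts)
        assert abs(excl / 4000 - 0.01) < 0.005

    def test_distorted_transmission_is_detected(self):
        # transmission ratio 0.8 -> genotype probs (0.64, 0.32, 0.04)
        rng = np.random.default_rng(2)
        counts = rng.multinomial(200, [0.64, 0.32, 0.04], size=40)
        assert all(segregation_test(tuple(c)).excluded for c in counts)


class TestCascade:
    @pytest.fixture(scope="class")
    def clean_bundle(self):
        m = synth.SimMap.uniform(2, 60, length_cM=80.0, length_bp=500_000)
        return synth.simulate_bundle(m, 120, synth.ErrorModel(), seed=31)

    def test_clean_bundle_survives_lenient_config(self, clean_bundle):
        cfg = FilterConfig(min_depth_call=0, seg_distortion_alpha=1e-12)
        out, report = filters.run_cascade(clean_bundle.observed, None, cfg)
        assert out.n_markers == clean_bundle.truth.n_markers
        frame = report.to_frame()
        assert (frame["snps_out"] <= frame["snps_in"]).all()
        assert list(frame["stage"]) == [
            "biallelic_parse", "drop_individuals", "mask_low_depth",
            "maf", "site_missing", "parentage_ab", "segregation",
        ]

    def test_cascade_idempotent_on_own_output(self, clean_bundle):
        cfg = FilterConfig(min_depth_call=0, seg_distortion_alpha=1e-12)
        out1, _ = filters.run_cascade(clean_bundle.observed, None, cfg)
        out2, _ = filters.run_cascade(out1, None, cfg)
        assert np.array_equal(out1.calls, out2.calls)
        assert list(out1.markers["id"]) == list(out2.markers["id"])
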