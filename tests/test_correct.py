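"""Sliding-window corrector: consensus rules, crossover guard, hetero-run
binning, imputation, and recovery of the true genotypes on simulated data."""

import numpy as np
import pytest

from f2radmap import correct, synth
from f2radmap.correct import CorrectionConfig
from f2radmap.io import A, B, H, MISSING
from tests.conftest import make_matrix


def one_row(calls, **kw):
    return make_matrix(np.array([calls], dtype=np.int8), **kw)


class TestConsensusCorrection:
    def test_lone_homozygote_in_run_corrected(self):
        mat = one_row([A, A, A, B, A, A, A])
        with pytest.warns(UserWarning, match="truncated"):
            out, rep = correct.correct_genotypes(mat)
        assert out.calls[0].tolist() == [A] * 7
        assert rep.n_corrected == 1
        assert rep.type_matrix[2, 0] == 1  # B -> A

    def test_undercalled_het_in_het_region_corrected(self):
        mat = one_row([H, H, H, A, H, H, H])
        with pytest.warns(UserWarning):
            out, rep = correct.correct_genotypes(mat)
        assert out.calls[0].tolist() == [H] * 7
        assert rep.type_matrix[0, 1] == 1  # A -> AB

    def test_crossover_zone_left_alone(self):
        mat = one_row([A, A, A, H, H, H])
        with pytest.warns(UserWarning):
            out, rep = correct.correct_genotypes(mat)
        assert rep.n_corrected == 0
        assert np.array_equal(out.calls, mat.calls)

    def test_guard_off_allows_edits_at_transition(self):
        cfg = CorrectionConfig(window_size=5, crossover_guard=False,
                               consensus_min_fraction=0.6)
        mat = one_row([A, A, A, A, A, H, H])
        out, rep = correct.correct_genotypes(mat, cfg)
        assert rep.n_corrected >= 1  # the boundary het gets flattened

    def test_windows_do_not_cross_chromosomes(self):
        calls = [A, A, A, B, B, B]
        mat = one_row(calls, chrom=["c1"] * 3 + ["c2"] * 3)
        with pytest.warns(UserWarning):
            out, rep = correct.correct_genotypes(mat)
        assert rep.n_corrected == 0


class TestImputation:
    def test_missing_in_uniform_region_imputed(self):
        mat = one_row([A, A, A, MISSING, A, A, A])
        with pytest.warns(UserWarning):
            out, rep = correct.impute_missing(mat)
        assert out.calls[0, 3] == A
        assert rep.n_imputed == 1
        assert rep.type_matrix[3, 0] == 1  # missing -> A

    def test_missing_at_crossover_boundary_left_missing(self):
        mat = one_row([A, A, A, MISSING, H, H, H])
        with pytest.warns(UserWarning):
            out, rep = correct.impute_missing(mat)
        assert out.calls[0, 3] == MISSING

    def test_fully_missing_individual_warned(self):
        mat = one_row([MISSING] * 5)
        with pytest.warns(UserWarning, match="nothing to impute"):
            _, rep = correct.impute_missing(mat)
        assert rep.n_imputed == 0


class TestBinning:
    def _population(self, majority_cols, bp):
        """20 progeny whose per-marker majority call follows majority_cols."""
        rows = []
        for i in range(20):
            row = []
            for c in majority_cols:
                row.append(c if i < 15 else (H if c != H else A))
            rows.append(row)
        return make_matrix(np.array(rows, dtype=np.int8), bp=bp)

    def test_short_hom_run_in_het_context_collapsed(self):
        # 3 A-majority markers spanning 120 bp flanked by H-majority markers
        mat = self._population([H, A, A, A, H], bp=[100, 200, 260, 320, 500])
        out, rep = correct.bin_hetero_runs(mat)
        assert out.n_markers == 3
        assert rep.markers_removed == ["M2", "M3"]
        assert list(out.markers["id"]) == ["M0", "M1", "M4"]

    def test_wide_span_not_collapsed(self):
        mat = self._population([H, A, A, A, H], bp=[100, 200, 300, 401, 500])
        out, _ = correct.bin_hetero_runs(mat)  # span 201 bp > 150
        assert out.n_markers == 5

    def test_long_run_not_collapsed(self):
        cols = [H] + [A] * 9 + [H]
        mat = self._population(cols, bp=list(range(100, 100 + 11 * 10, 10)))
        out, _ = correct.bin_hetero_runs(mat)  # 9 > max_hom_run
        assert out.n_markers == 11

    def test_no_hom_runs_no_change(self):
        mat = self._population([H, H, H, H], bp=[10, 20, 30, 40])
        out, rep = correct.bin_hetero_runs(mat)
        assert out.n_markers == 4 and rep.markers_removed == []

    def test_representative_takes_individual_majority(self):
        mat = self._population([H, A, A, A, H], bp=[100, 200, 260, 320, 500])
        # individual 0 has A,A,A over the run -> representative call A
        out, _ = correct.bin_hetero_runs(mat)
        assert out.calls[0, 1] == A


class TestRecovery:
    @pytest.fixture(scope="class")
    def scenario(self):
        m = synth.SimMap.uniform(2, 600, length_cM=150.0, length_bp=24_000_000)
        return synth.simulate_bundle(
            m, 96, synth.ErrorModel(u_het_to_hom=0.10, p_missing=0.20), seed=51
        )

    def test_accuracy_improves_and_types_match_undercall(self, scenario):
        b = scenario
        prog = b.truth.progeny_index
        fixed, rep = correct.correct_and_impute(b.observed)
        pre = (b.observed.calls[prog] == b.truth.calls[prog]).mean()
        post = (fixed.calls[prog] == b.truth.calls[prog]).mean()
        assert post > pre
        assert post >= 0.95
        # undercall errors produce mostly hom -> AB corrections
        tm = rep.type_matrix
        corr_total = tm[:3].sum()
        assert (tm[0, 1] + tm[2, 1]) / corr_total > 0.5

    def test_second_pass_nearly_idempotent(self):
        # at the ~6% undercall rate the replicate-discordance estimate
        # implies, a repeated pass changes almost nothing
        m = synth.SimMap.uniform(2, 600, length_cM=150.0, length_bp=24_000_000)
        b = synth.simulate_bundle(
            m, 96, synth.ErrorModel(u_het_to_hom=0.06, p_missing=0.20), seed=54
        )
        fixed, _ = correct.correct_and_impute(b.observed)
        again, _ = correct.correct_genotypes(fixed)
        changed = (again.calls != fixed.calls).mean()
        assert changed <= 0.001

    def test_error_free_zero_recombination_data_never_touched(self):
        # chromosomes of 0 cM: no crossovers, so nothing resembles an error
        m = synth.SimMap.uniform(2, 100, length_cM=0.0, length_bp=1_000_000)
        b = synth.simulate_bundle(m, 50, None, seed=52)
        out, rep = correct.correct_genotypes(b.truth)
        assert rep.n_corrected == 0
        assert np.array_equal(out.calls, b.truth.calls)

    def test_error_free_edits_limited_to_short_double_recombinant_islands(self):
        # with real crossovers, the only calls the corrector may touch lie
        # in very short true double-recombinant islands, which are locally
        # indistinguishable from genotyping errors; they are rare
        m = synth.SimMap.uniform(2, 400, length_cM=150.0, length_bp=10_000_000)
        b = synth.simulate_bundle(m, 100, None, seed=53)
        out, rep = correct.correct_genotypes(b.truth)
        n_calls = b.truth.calls[b.truth.progeny_index].size
        assert rep.n_corrected / n_calls < 1e-3
        diff = out.calls != b.truth.calls
        for i, j in zip(*np.nonzero(diff)):
            g = b.truth.calls[i]
            # true run containing the edited call spans <= 3 markers
            lo = j
            while lo > 0 and g[lo - 1] == g[j]:
                lo -= 1
            hi = j
            while hi < len(g) - 1 and g[hi + 1] == g[j]:
                hi += 1
            assert hi - lo + 1 <= 3
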