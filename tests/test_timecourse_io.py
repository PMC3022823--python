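import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsclust import (
    ColumnSchema,
    compute_log_ratios,
    flag_filter,
    median_profile,
    read_assignments,
    read_ratio_table,
    write_assignments,
    write_ratio_table,
)
from tsclust.timecourse_io import FormatError, ValidationError

from .conftest import make_experiment


class TestRatioTableIO:
    def test_round_trip_preserves_values_and_grid(self, tmp_path, rng):
        exp = make_experiment(rng.normal(size=(2, 6, 4)))
        path = tmp_path / "ratios.tsv"
        exp.condition_label = "IR"
        write_ratio_table(exp, path)
        back = read_ratio_table(path)
        assert back.gene_ids == exp.gene_ids
        assert back.condition_label == "IR"
        np.testing.assert_allclose(back.times, exp.times)
        np.testing.assert_allclose(back.ratios, exp.ratios)

    def test_gene_with_empty_time_point_is_dropped_with_warning(self, tmp_path, rng, caplog):
        vals = rng.normal(size=(2, 6, 4))
        vals[1, 2, :] = np.nan  # all four replicates missing at t=2
        header = ["gene_id"] + [
            f"IR_{t:g}_{r+1}" for t in [0.5, 1, 2, 4, 6, 24] for r in range(4)
        ]
        lines = ["\t".join(header)]
        for g in range(2):
            cells = [f"g{g}"] + [
                "" if np.isnan(vals[g, t, r]) else f"{vals[g, t, r]:.6f}"
                for t in range(6)
                for r in range(4)
            ]
            lines.append("\t".join(cells))
        path = tmp_path / "ratios.tsv"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level(logging.WARNING):
            exp = read_ratio_table(path)
        assert exp.gene_ids == ["g0"]
        assert "dropping" in caplog.text

    def test_malformed_header_names_offending_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tIR_halfhour_1\ng0\t1.0\n")
        with pytest.raises(FormatError, match="IR_halfhour_1"):
            read_ratio_table(path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tIR_1_1\tIR_2_1\ng0\t1\t2\ng0\t3\t4\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_ratio_table(path)

    def test_assignment_round_trip_is_identity(self, tmp_path):
        genes = [f"g{i}" for i in range(10)]
        clusters = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
        dist = np.linspace(0, 1, 10)
        path = tmp_path / "assign.tsv"
        write_assignments(path, genes, clusters, dist)
        back = read_assignments(path)
        assert back["gene_id"].tolist() == genes
        assert back["cluster"].tolist() == clusters
        np.testing.assert_allclose(back["distance_to_medoid"], dist)


class TestComputeLogRatios:
    times = [1.0, 2.0]
    genes = ["a", "b", "c"]

    def test_equal_intensities_give_zero(self, rng):
        raw = rng.uniform(1, 10, size=(3, 2, 2))
        exp = compute_log_ratios(raw, raw, self.genes, self.times)
        np.testing.assert_allclose(exp.ratios, 0.0)

    def test_doubling_gives_unit_log_ratio(self, rng):
        control = rng.uniform(1, 10, size=(3, 2, 2))
        treated = control.copy()
        treated[1, 0, 1] *= 2
        exp = compute_log_ratios(treated, control, self.genes, self.times)
        assert exp.ratios[1, 0, 1] == pytest.approx(1.0)

    def test_matches_elementwise_scalar_oracle(self, rng):
        treated = rng.uniform(0.5, 20, size=(3, 2, 2))
        control = rng.uniform(0.5, 20, size=(3, 2, 2))
        exp = compute_log_ratios(treated, control, self.genes, self.times)
        for g in range(3):
            for t in range(2):
                for r in range(2):
                    expected = np.log2(treated[g, t, r] / control[g, t, r])
                    assert exp.ratios[g, t, r] == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_condition_swap(self, rng):
        treated = rng.uniform(0.5, 20, size=(3, 2, 2))
        control = rng.uniform(0.5, 20, size=(3, 2, 2))
        ab = compute_log_ratios(treated, control, self.genes, self.times)
        ba = compute_log_ratios(control, treated, self.genes, self.times)
        np.testing.assert_allclose(ab.ratios, -ba.ratios, atol=1e-12)

    def test_nonpositive_intensity_identifies_cell(self, rng):
        treated = rng.uniform(1, 2, size=(3, 2, 2))
        control = treated.copy()
        treated[2, 1, 0] = -0.5
        with pytest.raises(ValueError, match=r"gene='c'.*time=2"):
            compute_log_ratios(treated, control, self.genes, self.times)


class TestMedianProfile:
    def test_even_count_median_is_midpoint(self):
        exp = make_experiment(np.array([[[1.0, 3.0]]]), times=[1.0])
        assert median_profile(exp, "g0").u[0] == pytest.approx(2.0)

    def test_median_robust_to_outlier_replicate(self):
        exp = make_experiment(np.array([[[1.0, 2.0, 100.0]]]), times=[1.0])
        assert median_profile(exp, "g0").u[0] == pytest.approx(2.0)

    def test_matches_sort_and_pick_oracle(self, rng):
        vals = rng.normal(size=(4, 3, 5))
        exp = make_experiment(vals, times=[1, 2, 4])
        for g, gene in enumerate(exp.gene_ids):
            u = median_profile(exp, gene).u
            for t in range(3):
                srt = np.sort(vals[g, t])
                assert u[t] == pytest.approx(srt[2])  # middle of 5

    @given(perm=st.permutations(range(4)))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_replicate_ordering(self, perm):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(2, 3, 4))
        a = make_experiment(vals, times=[1, 2, 4])
        b = make_experiment(vals[:, :, list(perm)], times=[1, 2, 4])
        np.testing.assert_allclose(
            median_profile(a, "g0").u, median_profile(b, "g0").u
        )


class TestFlagFilter:
    def test_clean_gene_retained(self):
        detect = np.ones((1, 6, 4), dtype=bool)
        outlier = np.zeros((1, 6, 4), dtype=bool)
        assert flag_filter(detect, outlier).tolist() == [True]

    def test_gene_just_over_threshold_dropped(self):
        detect = np.ones((1, 6, 4), dtype=bool)
        detect[0, 0, :3] = False  # 3 bad of 24 = 12.5% > 10%
        outlier = np.zeros((1, 6, 4), dtype=bool)
        assert flag_filter(detect, outlier, max_bad_fraction=0.10).tolist() == [False]

    def test_matches_counting_oracle(self, rng):
        detect = rng.random(size=(20, 6, 4)) > 0.1
        outlier = rng.random(size=(20, 6, 4)) < 0.05
        kept = flag_filter(detect, outlier, max_bad_fraction=0.10)
        for g in range(20):
            n_bad = sum(
                (not detect[g, t, r]) or outlier[g, t, r]
                for t in range(6)
                for r in range(4)
            )
            assert kept[g] == (n_bad / 24 <= 0.10)

    def test_retained_set_monotone_in_threshold(self, rng):
        detect = rng.random(size=(30, 6, 4)) > 0.15
        outlier = rng.random(size=(30, 6, 4)) < 0.05
        sizes = [
            flag_filter(detect, outlier, max_bad_fraction=f).sum()
            for f in np.linspace(0, 1, 11)
        ]
        assert sizes == sorted(sizes)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            flag_filter(np.ones((2, 3, 4), bool), np.zeros((2, 3, 3), bool))


class TestExperimentInvariants:
    def test_duplicate_gene_ids_rejected(self, rng):
        with pytest.raises(ValidationError, match="duplicate"):
            make_experiment(rng.normal(size=(2, 3, 2)), times=[1, 2, 4],
                            gene_ids=["a", "a"])

    def test_nonincreasing_times_rejected(self, rng):
        with pytest.raises(ValidationError, match="increasing"):
            make_experiment(rng.normal(size=(2, 3, 2)), times=[1, 4, 2])

    def test_unknown_gene_raises_keyerror(self, six_point_experiment):
        with pytest.raises(KeyError):
            six_point_experiment.gene_index("nope")
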