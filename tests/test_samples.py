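"""Data model, CSV parsing, collagen QC and group statistics."""

import io
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isomix.samples import (
    IsotopeSample,
    QCConfig,
    apply_qc,
    assess_collagen_quality,
    load_samples,
    mann_whitney_u,
    summarize_groups,
)


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestLoadSamples:
    def test_unicode_minus_parsed(self):
        samples = load_samples(_csv("sample_id,d13C_coll\nTC1,−19.0"))
        assert samples[0].d13C_coll == -19.0

    def test_blank_cells_become_missing(self):
        s = load_samples(_csv("sample_id,d13C_coll,d15N\nTC1,,9.5"))[0]
        assert s.d13C_coll is None and s.d15N == 9.5

    def test_duplicate_id_rejected_with_names(self):
        with pytest.raises(ValueError, match="TC8"):
            load_samples(_csv("sample_id,d15N\nTC8,9.0\nTC8,9.1"))

    def test_unparseable_cell_reports_row_and_column(self):
        with pytest.raises(ValueError, match="row 3.*d15N"):
            load_samples(_csv("sample_id,d15N\nTC1,9.0\nTC2,oops"))

    def test_unknown_columns_preserved_as_metadata(self):
        s = load_samples(_csv("sample_id,d15N,lab_code\nTC1,9.0,MPI-1"))[0]
        assert s.extra["lab_code"] == "MPI-1"

    def test_row_count_preserved(self):
        rows = "\n".join(f"H{i},{-19 - 0.01 * i}" for i in range(134))
        assert len(load_samples(_csv("sample_id,d13C_coll\n" + rows))) == 134


class TestCollagenQC:
    def test_midrange_cn_passes(self):
        s = IsotopeSample("a", cn_atomic=3.2, d13C_carb=-12.0)
        flag = assess_collagen_quality(s)
        assert flag.collagen_ok and flag.carbonate_ok and flag.reasons == []

    def test_bad_cn_excludes_carbonate_too(self):
        s = IsotopeSample("a", cn_atomic=3.8, d13C_carb=-12.0)
        flag = assess_collagen_quality(s)
        assert not flag.collagen_ok
        assert not flag.carbonate_ok
        assert "collagen_failed_so_carbonate_excluded" in flag.reasons

    def test_low_yield_flagged_insufficient(self):
        s = IsotopeSample("a", cn_atomic=3.2, collagen_yield=0.2)
        flag = assess_collagen_quality(s, QCConfig(min_yield=1.0))
        assert not flag.collagen_ok
        assert "insufficient_collagen" in flag.reasons

    def test_missing_cn_is_flag_not_error(self):
        flag = assess_collagen_quality(IsotopeSample("a", d13C_coll=-19.0))
        assert not flag.collagen_ok and "missing_measurement" in flag.reasons

    @pytest.mark.parametrize(
        "n_total,n_bad_cn,n_low_yield,expected_pct",
        [(134, 15, 1, 11.9), (10, 1, 0, 10.0), (20, 0, 0, 0.0)],
    )
    def test_exclusion_percentage(self, n_total, n_bad_cn, n_low_yield, expected_pct):
        samples = []
        for i in range(n_total):
            if i < n_bad_cn:
                cn = 3.9
                y = 5.0
            elif i < n_bad_cn + n_low_yield:
                cn = 3.2
                y = 0.3
            else:
                cn = 3.2
                y = 5.0
            samples.append(IsotopeSample(f"H{i}", cn_atomic=cn, collagen_yield=y, d15N=9.0))
        accepted, report = apply_qc(samples)
        assert report.groups["human"]["percent_excluded"] == expected_pct
        # conservation: excluded + accepted = total
        assert len(accepted) + report.groups["human"]["n_excluded"] == n_total

    def test_failed_collagen_never_reaches_carbonate_summary(self, rng):
        samples = [
            IsotopeSample(f"S{i}", cn_atomic=3.9 if i % 3 == 0 else 3.2, d13C_carb=float(v))
            for i, v in enumerate(rng.normal(-12, 1, 30))
        ]
        accepted, report = apply_qc(samples)
        carb_ok_ids = {sid for sid, f in report.per_sample.items() if f.carbonate_ok}
        failed_ids = {sid for sid, f in report.per_sample.items() if not f.collagen_ok}
        assert carb_ok_ids.isdisjoint(failed_ids)


class TestGroupSummaries:
    def test_two_value_mean_and_sd(self):
        samples = [
            IsotopeSample("a", site="X", d13C_coll=-19.0),
            IsotopeSample("b", site="X", d13C_coll=-21.0),
        ]
        (summary,) = summarize_groups(samples, ["site"], ["d13C_coll"])
        assert summary.stats["d13C_coll"]["mean"] == -20.0
        assert summary.stats["d13C_coll"]["sd"] == pytest.approx(np.sqrt(2))

    def test_matches_independent_oracle_on_hand_table(self):
        vals = [-19.0, -18.5, -20.1, -19.7, -18.9]
        samples = [IsotopeSample(f"s{i}", site="X", d15N=v) for i, v in enumerate(vals)]
        (summary,) = summarize_groups(samples, ["site"], ["d15N"])
        assert summary.stats["d15N"]["mean"] == pytest.approx(statistics.fmean(vals))
        assert summary.stats["d15N"]["sd"] == pytest.approx(statistics.stdev(vals))
        assert summary.stats["d15N"]["min"] == min(vals)
        assert summary.stats["d15N"]["max"] == max(vals)

    def test_permutation_invariance(self, rng):
        samples = [
            IsotopeSample(f"s{i}", site=str(i % 3), d15N=float(v))
            for i, v in enumerate(rng.normal(9, 1, 30))
        ]
        a = summarize_groups(samples, ["site"], ["d15N"])
        perm = [samples[i] for i in rng.permutation(len(samples))]
        b = summarize_groups(perm, ["site"], ["d15N"])
        assert [s.group_key for s in a] == [s.group_key for s in b]
        for x, y in zip(a, b):
            assert x.stats["d15N"]["mean"] == pytest.approx(y.stats["d15N"]["mean"])

    def test_missing_values_skipped_per_proxy(self):
        samples = [
            IsotopeSample("a", site="X", d15N=9.0, d13C_coll=-19.0),
            IsotopeSample("b", site="X", d15N=11.0),
        ]
        (summary,) = summarize_groups(samples, ["site"], ["d15N", "d13C_coll"])
        assert summary.stats["d15N"]["n"] == 2
        assert summary.stats["d13C_coll"]["n"] == 1
        assert "sd" not in summary.stats["d13C_coll"]


def _brute_force_u(a, b):
    """Independent oracle: count pairs directly, ties as half."""
    u_ab = sum(1.0 if x < y else 0.5 if x == y else 0.0 for x in a for y in b)
    return min(u_ab, len(a) * len(b) - u_ab)


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).U == 0

    def test_interleaved_pairs(self):
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.U == _brute_force_u([1, 3], [2, 4]) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    def test_u_equals_brute_force_enumeration(self, a, b):
        res = mann_whitney_u(a, b)
        assert res.U == pytest.approx(_brute_force_u(a, b))
        assert 0 <= res.U <= res.n1 * res.n2
        assert 0 <= res.p_two_sided <= 1

    def test_exact_method_used_for_small_tie_free_samples(self):
        res = mann_whitney_u([1.0, 2.5], [3.5, 4.0])
        assert res.method == "exact_enumeration"
        res2 = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res2.method == "normal_approx_tie_corrected"
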