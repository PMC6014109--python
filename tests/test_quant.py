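"""Quantitation identities: integration, classing, ratios, roll-up, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedmrm import quant
from seedmrm.quant import (
    classify_signal,
    compare_groups,
    integrate_peak,
    match_channels,
    peptide_ratio,
    peptide_ratios,
    protein_rollup,
)


def _record(peptide, fraction, transition, channel, area, sample=("WT", "24", 1),
            clean=True):
    g, t, r = sample
    return {
        "genotype": g, "timepoint": t, "replicate": r, "fraction": fraction,
        "peptide": peptide, "transition": transition, "channel": channel,
        "area": area, "interference_free": clean,
    }


class TestIntegratePeak:
    def test_all_zero_trace(self):
        t = np.linspace(0, 10, 101)
        area, _ = integrate_peak(t, np.zeros_like(t), (2, 8))
        assert area == 0.0

    def test_gaussian_recovers_closed_form_area(self):
        amp, sd, mu = 5000.0, 0.2, 5.0
        t = np.linspace(0, 10, 4001)
        y = amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
        area, apex = integrate_peak(t, y, (3, 7))
        assert area == pytest.approx(amp * sd * np.sqrt(2 * np.pi), rel=0.01)
        assert apex == pytest.approx(mu, abs=0.01)

    def test_constant_baseline_is_subtracted(self):
        t = np.linspace(0, 10, 2001)
        y = 300.0 * np.exp(-0.5 * ((t - 5) / 0.3) ** 2)
        a0, _ = integrate_peak(t, y, (3, 7))
        a1, _ = integrate_peak(t, y + 40.0, (3, 7))
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_window_outside_grid_raises(self):
        t = np.linspace(0, 10, 101)
        with pytest.raises(ValueError, match="outside"):
            integrate_peak(t, np.zeros_like(t), (8, 12))


def test_match_channels_closed_boundary():
    assert match_channels(10.0, 10.0)
    assert match_channels(10.0, 10.2, tolerance=0.2)
    assert not match_channels(10.0, 10.41, tolerance=0.2)


class TestClassifySignal:
    def test_threshold_is_strictly_above(self):
        assert classify_signal([10_001.0]) == ("good", 10_001.0)
        assert classify_signal([9_999.0]) == ("low", 9_999.0)
        assert classify_signal([10_000.0])[0] == "low"
        assert classify_signal([4000.0, 6001.0])[0] == "good"

    def test_none_when_all_missing(self):
        assert classify_signal([])[0] == "none"
        assert classify_signal([np.nan, np.nan])[0] == "none"


class TestPeptideRatio:
    def _hand_example(self):
        # natural all in fraction 1; heavy split across fractions 1 and 2
        rows = [
            _record("PEP", 1, "T1", "natural", 500.0),
            _record("PEP", 1, "T2", "natural", 250.0),
            _record("PEP", 1, "T3", "natural", 250.0),
            _record("PEP", 1, "T1", "heavy", 60.0),
            _record("PEP", 1, "T2", "heavy", 60.0),
            _record("PEP", 1, "T3", "heavy", 30.0),
            _record("PEP", 2, "T1", "heavy", 40.0),
            _record("PEP", 2, "T2", "heavy", 40.0),
            _record("PEP", 2, "T3", "heavy", 20.0),
        ]
        return pd.DataFrame(rows)

    def test_hand_computed_sum_then_ratio(self):
        out = peptide_ratios(self._hand_example())
        assert len(out) == 1
        assert out["ratio"].iloc[0] == pytest.approx(4.0)
        assert out["n_transitions_used"].iloc[0] == 3

    def test_identity_ratio(self):
        rows = [
            _record("PEP", 1, t, ch, a)
            for t, a in [("T1", 100.0), ("T2", 200.0), ("T3", 300.0)]
            for ch in ("natural", "heavy")
        ]
        out = peptide_ratios(pd.DataFrame(rows))
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_two_clean_transitions_is_missing(self):
        df = self._hand_example()
        df.loc[df["transition"] == "T3", "interference_free"] = False
        out = peptide_ratios(df)
        assert np.isnan(out["ratio"].iloc[0])
        assert "interference-free" in out["reason"].iloc[0]

    def test_no_standard_signal(self):
        df = self._hand_example()
        df = df[df["channel"] == "natural"]
        out = peptide_ratios(df)
        assert np.isnan(out["ratio"].iloc[0])
        assert out["reason"].iloc[0] == "no standard signal"

    def test_atomic_operation_matches_table_level(self):
        df = self._hand_example()
        nat = df[df["channel"] == "natural"]
        hvy = df[df["channel"] == "heavy"]
        ratio, reason = peptide_ratio(nat, hvy, ["T1", "T2", "T3"], [1, 2])
        assert reason is None and ratio == pytest.approx(4.0)
        ratio, reason = peptide_ratio(nat, hvy, ["T1", "T2"], [1, 2])
        assert reason is not None and np.isnan(ratio)

    @given(
        st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=3, max_size=5),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_fraction_splitting_invariance(self, areas, split):
        """Moving part of every peak into an adjacent fraction leaves the
        sum-then-ratio unchanged."""
        one = pd.DataFrame(
            [
                _record("PEP", 1, f"T{i}", ch, a)
                for i, a in enumerate(areas, 1)
                for ch in ("natural", "heavy")
            ]
        )
        two = pd.DataFrame(
            [
                _record("PEP", f, f"T{i}", ch, a * w)
                for i, a in enumerate(areas, 1)
                for ch in ("natural", "heavy")
                for f, w in [(1, split), (2, 1 - split)]
            ]
        )
        r1 = peptide_ratios(one)["ratio"].iloc[0]
        r2 = peptide_ratios(two)["ratio"].iloc[0]
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_scale_equivariance(self):
        df = self._hand_example()
        scaled = df.copy()
        scaled.loc[scaled["channel"] == "natural", "area"] *= 7.5
        r = peptide_ratios(df)["ratio"].iloc[0]
        rs = peptide_ratios(scaled)["ratio"].iloc[0]
        assert rs == pytest.approx(7.5 * r)

    def test_censored_cells_imputed_at_half_the_declared_floor(self):
        # heavy present in a cell where natural was censored: with a declared
        # floor the natural sum gains lod/2 for that cell
        df = self._hand_example()
        out0 = peptide_ratios(df)["ratio"].iloc[0]
        out = peptide_ratios(df, lod_counts=100.0)["ratio"].iloc[0]
        # natural missing in 3 heavy-only cells of fraction 2
        assert out == pytest.approx((1000 + 3 * 50.0) / 250.0)
        assert out0 == pytest.approx(4.0)


class TestProteinRollup:
    def _ratios(self, values, peptide_names=None):
        peptide_names = peptide_names or [f"PEP{i}" for i in range(len(values))]
        return pd.DataFrame(
            {
                "peptide": peptide_names,
                "genotype": "WT",
                "timepoint": "24",
                "replicate": 1,
                "ratio": values,
                "n_transitions_used": 3,
                "n_fractions_used": 1,
                "reason": None,
            }
        )

    @pytest.mark.parametrize(
        "values,expected",
        [([2.0, 0.5], 1.0), ([1.0, 2.0, 4.0], 2.0), ([3.7], 3.7)],
    )
    def test_geometric_mean_over_peptides(self, values, expected):
        ratios = self._ratios(values)
        mapping = {p: "PROT" for p in ratios["peptide"]}
        rep, summary = protein_rollup(ratios, mapping)
        assert rep["abundance"].iloc[0] == pytest.approx(expected)
        assert summary["mean"].iloc[0] == pytest.approx(expected)

    def test_missing_peptides_are_omitted_not_imputed(self):
        ratios = self._ratios([2.0, np.nan, 8.0])
        mapping = {p: "PROT" for p in ratios["peptide"]}
        rep, _ = protein_rollup(ratios, mapping)
        assert rep["abundance"].iloc[0] == pytest.approx(4.0)
        assert rep["n_peptides"].iloc[0] == 2

    def test_replicates_summarized_arithmetically(self):
        frames = []
        for r, val in [(1, 1.0), (2, 2.0), (3, 4.0)]:
            f = self._ratios([val], ["PEP0"])
            f["replicate"] = r
            frames.append(f)
        ratios = pd.concat(frames)
        rep, summary = protein_rollup(ratios, {"PEP0": "PROT"})
        assert summary["mean"].iloc[0] == pytest.approx(7.0 / 3.0)
        assert summary["sd"].iloc[0] == pytest.approx(np.std([1, 2, 4], ddof=1))
        assert summary["n_replicates"].iloc[0] == 3


class TestCompareGroups:
    def test_identical_zero_variance_groups(self):
        c = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert c.fold_change == pytest.approx(1.0)
        assert c.p_value == 1.0

    def test_clear_separation(self):
        eps = 1e-9
        c = compare_groups([2 + eps, 2.0, 2 - eps], [1 + eps, 1.0, 1 - eps])
        assert c.fold_change == pytest.approx(2.0)
        assert c.p_value < 1e-6

    def test_symmetric_groups_give_p_one(self):
        c = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.p_value == pytest.approx(1.0)

    def test_single_replicate_reports_fold_only(self):
        c = compare_groups([3.0], [1.0, 1.0, 1.0])
        assert c.fold_change == pytest.approx(3.0)
        assert c.p_value is None

    def test_matches_scipy_equal_variance(self):
        from scipy import stats

        a, b = [1.2, 1.9, 1.4], [0.8, 1.1, 0.7]
        c = compare_groups(a, b)
        assert c.p_value == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue
        )


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8])
    adj = quant.benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    assert adj[0] == pytest.approx(0.004)
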