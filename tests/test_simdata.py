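"""Generative-model properties: determinism, noiseless identities, censoring,
heavy-channel invariance, and sampling-variance calibration."""

import numpy as np
import pandas as pd
import pytest

from seedmrm import quant, simdata
from seedmrm.simdata import (
    SimConfig,
    band_centers,
    fraction_weights,
    load_sim_config,
    noiseless,
    render_chromatograms,
    simulate,
    simulate_blot,
    simulate_o2_traces,
    simulate_qpcr,
)


def test_default_config_loads_study_design():
    cfg = load_sim_config()
    assert cfg.genotypes == ("WT", "ftsh4-1", "ftsh4-2")
    assert cfg.timepoints == ("DS", "0", "6", "12", "24", "42")
    assert cfg.n_replicates == 3 and cfg.n_fractions == 12
    assert len(cfg.peptides) == 18
    assert sum(len(v) for v in cfg.peptides.values()) == 71
    # programmed fold changes behind the headline contrasts
    assert cfg.abundance("SDH2-2", "WT", "24") / cfg.abundance(
        "SDH2-2", "ftsh4-1", "24"
    ) == pytest.approx(2.6)
    assert cfg.abundance("RIESKE", "WT", "24") / cfg.abundance(
        "RIESKE", "WT", "42"
    ) == pytest.approx(7.0)


def test_simulation_is_reproducible_from_seed(small_config):
    a, _ = simulate(small_config, 42)
    b, _ = simulate(small_config, 42)
    c, _ = simulate(small_config, 43)
    pd.testing.assert_frame_equal(a, b)
    assert not a["area"].equals(c["area"])


def test_missing_anchor_raises(small_config):
    cfg = small_config
    cfg.peptides["P3"] = ["LLEVDNR"]
    with pytest.raises(KeyError, match="P3"):
        simulate(cfg, 0)


def test_anchor_interpolation_is_log_linear():
    cfg = SimConfig(anchors={"P": {"WT": {"6": 1.0, "24": 4.0}}})
    # 12 h lies at (12-6)/(24-6) of the log interval between the anchors
    assert cfg.abundance("P", "WT", "12") == pytest.approx(4.0 ** (6 / 18))


def test_noiseless_recovery_is_exact(small_config, pep2prot):
    cfg = noiseless(small_config)
    peaks, truth = simulate(cfg, 7)
    ratios = quant.peptide_ratios(peaks)
    mapping = {s: p for p, seqs in cfg.peptides.items() for s in seqs}
    _, summary = quant.protein_rollup(ratios, mapping)
    merged = summary.merge(
        truth.abundance, on=["protein", "genotype", "timepoint"]
    )
    assert len(merged) == len(truth.abundance)
    assert np.allclose(merged["mean"], merged["true_ratio"], rtol=1e-12)


def test_heavy_channel_is_invariant_across_timepoints(small_config):
    """The SIS spike is constant by construction: the slope of log heavy
    area against timepoint is indistinguishable from zero."""
    peaks, _ = simulate(small_config, 11)
    heavy = peaks[peaks["channel"] == "heavy"]
    sums = (
        heavy.groupby(["peptide", "timepoint"])["area"].sum().reset_index()
    )
    for _, sub in sums.groupby("peptide"):
        logs = np.log(sub.sort_values("timepoint")["area"].to_numpy())
        assert abs(logs[1] - logs[0]) < 0.1


def test_censoring_monotonicity(small_config):
    from dataclasses import replace

    detected = []
    for lod in (0.0, 2000.0, 20000.0):
        peaks, _ = simulate(replace(small_config, lod_counts=lod), 5)
        det = quant.detection_summary(peaks)
        detected.append(det[det["signal_class"] != "none"]["peptide"].nunique())
    assert detected[0] >= detected[1] >= detected[2]


def test_interference_flags_and_background(small_config):
    from dataclasses import replace

    cfg = replace(small_config, interference_rate=0.5)
    peaks, _ = simulate(cfg, 3)
    flagged = peaks[~peaks["interference_free"]]
    assert len(flagged) > 0
    # background hits the natural channel; heavy areas stay label-clean
    nat = flagged[flagged["channel"] == "natural"]
    assert len(nat) > 0


def test_fraction_weights_normalized_and_centered():
    w = fraction_weights(6.0, 0.8, 12)
    assert w.sum() == pytest.approx(1.0)
    assert np.argmax(w) == 5  # fraction 6
    centers = band_centers(["heavy_p", "light_p"], {"heavy_p": 80, "light_p": 10}, 12)
    assert centers["heavy_p"] == 1.0 and centers["light_p"] == 12.0


def test_truth_table_fold_changes(small_config):
    _, truth = simulate(noiseless(small_config), 0)
    assert truth.fold_change(
        "P1", ("WT", "24"), ("ftsh4-1", "24")
    ) == pytest.approx(1.0 / 0.4)


class TestChromatograms:
    def test_rendered_area_matches_record(self, small_config):
        peaks, _ = simulate(noiseless(small_config), 1)
        sub = peaks.head(4)
        traces = render_chromatograms(sub)
        for trace, (_, row) in zip(traces, sub.iterrows()):
            area, apex = quant.integrate_peak(
                trace.times,
                trace.intensities,
                (trace.times[0], trace.times[-1]),
            )
            assert area == pytest.approx(row["area"], rel=0.005)
            assert apex == pytest.approx(trace.apex_rt, abs=0.01)

    def test_zero_area_record_is_flat(self):
        df = pd.DataFrame(
            [
                {
                    "peptide": "AVDSLVPIGR",
                    "transition": "T1",
                    "channel": "natural",
                    "area": 0.0,
                }
            ]
        )
        trace = render_chromatograms(df)[0]
        assert np.all(trace.intensities == 0.0)

    def test_channels_coelute_without_jitter(self):
        df = pd.DataFrame(
            [
                {"peptide": "AVDSLVPIGR", "transition": "T1",
                 "channel": ch, "area": 100.0}
                for ch in ("natural", "heavy")
            ]
        )
        nat, heavy = render_chromatograms(df, coelution_jitter=0.0)
        assert nat.apex_rt == heavy.apex_rt
        assert quant.match_channels(nat.apex_rt, heavy.apex_rt)


def test_fold_change_sampling_sd_matches_delta_method():
    """Across-seed spread of a log fold-change estimate agrees with the
    delta-method prediction from the programmed noise structure."""
    cfg = SimConfig(
        genotypes=("WT", "ftsh4-1"),
        timepoints=("24",),
        n_replicates=3,
        n_fractions=4,
        anchors={"P1": {"WT": {"24": 1.0}, "ftsh4": {"24": 0.5}}},
        mw_kda={"P1": 50.0},
        peptides={"P1": ["AVDSLVPIGR", "TTIAIDTILNQK"]},
        transition_profile="equal",
        lod_counts=0.0,
        interference_rate=0.0,
    )
    mapping = {s: "P1" for s in cfg.peptides["P1"]}
    log_fcs = []
    for seed in range(200):
        peaks, _ = simulate(cfg, seed)
        ratios = quant.peptide_ratios(peaks)
        rep, _ = quant.protein_rollup(ratios, mapping)
        means = rep.groupby("genotype")["abundance"].mean()
        log_fcs.append(np.log(means["WT"] / means["ftsh4-1"]))
    observed_sd = np.std(log_fcs, ddof=1)

    sb2 = np.log1p(cfg.biol_cv**2)
    sn2 = np.log1p(cfg.noise_cv**2)
    fw = fraction_weights(2.5, cfg.fraction_sd, cfg.n_fractions)
    sum_w2 = (fw**2).sum() / cfg.n_transitions
    var_rep = sb2 + 2 * sn2 * sum_w2 / len(mapping)
    predicted_sd = np.sqrt(2 * (np.expm1(var_rep)) / cfg.n_replicates)
    assert observed_sd == pytest.approx(predicted_sd, rel=0.25)


class TestAssayGenerators:
    def test_blot_generator_reproducible_and_positive(self):
        a = simulate_blot(seed=9)
        b = simulate_blot(seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a["band_intensity"] > 0).all()
        assert (a["loading_intensity"] > 0).all()
        assert set(a["protein"]) == {"Tim17-2", "RIESKE", "AOX"}

    def test_qpcr_generator_encodes_levels(self):
        df = simulate_qpcr(ct_sd=0.0)
        from seedmrm import assays

        levels = assays.relative_expression(df, ("WT", "DS"))
        mut = levels[
            (levels["gene"] == "AOX1A")
            & (levels["genotype"] == "ftsh4-1")
            & (levels["timepoint"] == "0")
        ]["level"]
        assert mut.mean() == pytest.approx(12.0, rel=1e-6)

    def test_o2_traces_have_programmed_slopes(self):
        traces = simulate_o2_traces(total_rate=0.5, dry_weight_mg=10.0)
        t = traces["none"]
        slope = np.polyfit(t["time_min"], t["o2_nmol"], 1)[0]
        assert -slope / 10.0 == pytest.approx(0.5, rel=1e-9)
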