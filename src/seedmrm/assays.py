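"""Orthogonal-assay arithmetic: qPCR relative expression, western-blot
densitometry normalization, and seed-respiration pathway partitioning.

These are the classical cross-checks run alongside the MRM assay: transcript
levels by the 2^-ddCt convention against a reference gene and a calibrator
condition, band densitometry normalized to a loading control and a calibrator
lane, and Clark-electrode O2 drawdown slopes partitioned into cytochrome
(COX) and alternative-oxidase (AOX) pathway activity with the inhibitors SHAM
and KCN.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quant import compare_groups

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# qRT-PCR
# ---------------------------------------------------------------------------


def relative_expression(
    records: pd.DataFrame,
    calibrator: tuple[str, str],
) -> pd.DataFrame:
    """Per-record relative transcript level by 2^-ddCt.

    dCt = ct_target - ct_reference per record; ddCt subtracts the per-gene
    mean dCt of the calibrator (genotype, timepoint) condition, so the
    calibrator's geometric-mean level is 1 by construction.  Records with a
    missing reference Ct are dropped with a warning.  Perfect amplification
    efficiency is assumed; ``efficiency`` columns are not consulted.
    """
    df = records.copy()
    bad = df["ct_reference"].isna() | df["ct_target"].isna()
    if bad.any():
        logger.warning("dropping %d qPCR records with missing Ct", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no usable qPCR records")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]

    cal_geno, cal_tp = calibrator
    cal = df[(df["genotype"] == cal_geno) & (df["timepoint"] == cal_tp)]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator} absent")
    cal_mean = cal.groupby("gene")["delta_ct"].mean()

    df["ddct"] = df["delta_ct"] - df["gene"].map(cal_mean)
    if df["ddct"].isna().any():
        missing = sorted(df.loc[df["ddct"].isna(), "gene"].unique())
        raise ValueError(f"calibrator lacks genes {missing}")
    df["level"] = np.exp2(-df["ddct"])
    return df[
        ["gene", "genotype", "timepoint", "replicate", "delta_ct", "ddct", "level"]
    ].reset_index(drop=True)


def expression_summary(levels: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of relative levels per (gene, genotype, timepoint)."""
    return (
        levels.groupby(["gene", "genotype", "timepoint"], observed=True)["level"]
        .agg(mean="mean", sd=lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"), n="size")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Western-blot densitometry
# ---------------------------------------------------------------------------


def blot_relative(
    records: pd.DataFrame,
    calibrator: tuple[str, str] = ("WT", "0"),
    wild_type: str = "WT",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loading-normalized band intensities relative to a calibrator lane.

    value = (band / loading) / mean(band / loading of the calibrator
    condition), per protein.  Returns ``(per_record, summary)`` where the
    summary holds mean +/- SD per condition plus a two-tailed t-test of each
    mutant genotype against wild type at the same timepoint.
    """
    df = records.copy()
    if (df["loading_intensity"] <= 0).any():
        raise ValueError("loading-control intensity must be > 0")
    if (df["band_intensity"] < 0).any():
        raise ValueError("band intensity must be >= 0")
    df["normalized"] = df["band_intensity"] / df["loading_intensity"]

    cal_geno, cal_tp = calibrator
    cal = df[(df["genotype"] == cal_geno) & (df["timepoint"] == cal_tp)]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator} absent")
    cal_mean = cal.groupby("protein")["normalized"].mean()
    df["value"] = df["normalized"] / df["protein"].map(cal_mean)

    summary = (
        df.groupby(["protein", "genotype", "timepoint"], observed=True)["value"]
        .agg(mean="mean", sd=lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"), n="size")
        .reset_index()
    )

    pvals = []
    for _, row in summary.iterrows():
        if row["genotype"] == wild_type:
            pvals.append(float("nan"))
            continue
        a = df[
            (df["protein"] == row["protein"])
            & (df["genotype"] == row["genotype"])
            & (df["timepoint"] == row["timepoint"])
        ]["value"]
        b = df[
            (df["protein"] == row["protein"])
            & (df["genotype"] == wild_type)
            & (df["timepoint"] == row["timepoint"])
        ]["value"]
        cmp_ = compare_groups(a, b, row["protein"], equal_var=equal_var)
        pvals.append(cmp_.p_value if cmp_.p_value is not None else float("nan"))
    summary["p_vs_wt"] = pvals
    keep = ["protein", "genotype", "timepoint", "replicate", "value"]
    return df[keep].reset_index(drop=True), summary


# ---------------------------------------------------------------------------
# Seed respiration
# ---------------------------------------------------------------------------


def respiration_rate(
    time_min: np.ndarray,
    o2_nmol: np.ndarray,
    dry_weight_mg: float,
    window: tuple[float, float] | None = None,
) -> float:
    """O2 consumption rate (nmol O2 / min / mg dry weight) from a drawdown
    trace: minus the least-squares slope of O2 against time, per mg.

    Negative fitted rates (O2 apparently increasing) are truncated to zero
    with a warning.  Requires at least 4 points in the fit window.
    """
    t = np.asarray(time_min, dtype=float)
    o2 = np.asarray(o2_nmol, dtype=float)
    if t.shape != o2.shape:
        raise ValueError("time and O2 series differ in length")
    if dry_weight_mg <= 0:
        raise ValueError("dry weight must be > 0")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, o2 = t[mask], o2[mask]
    if t.size < 4:
        raise ValueError(f"only {t.size} points in fit window; need >= 4")
    slope = stats.linregress(t, o2).slope
    rate = -slope / dry_weight_mg
    if rate < 0:
        warnings.warn(
            f"fitted O2 slope implies negative consumption ({rate:.4g}); "
            "truncated to 0",
            stacklevel=2,
        )
        rate = 0.0
    return float(rate)


def respiration_partition(
    traces: dict[str, pd.DataFrame],
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Partition respiration into pathway activities from inhibitor traces.

    ``traces`` maps inhibitor in {none, SHAM, KCN} to a drawdown table with
    columns time_min, o2_nmol, dry_weight_mg.  SHAM-insensitive respiration
    is the COX-mediated rate; KCN-insensitive respiration is the AOX-mediated
    rate.
    """
    out = {}
    names = {"none": "total", "SHAM": "COX_mediated", "KCN": "AOX_mediated"}
    for inhibitor, label in names.items():
        if inhibitor not in traces:
            continue
        tr = traces[inhibitor]
        out[label] = respiration_rate(
            tr["time_min"].to_numpy(),
            tr["o2_nmol"].to_numpy(),
            float(tr["dry_weight_mg"].iloc[0]),
            window=window,
        )
    return out
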