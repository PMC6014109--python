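"""Quantitation core: peak integration, signal classing, Natural/Heavy
ratios with gel-fraction summation, geometric-mean protein roll-up, and
group comparisons.

The quantitation atom is a transition-level peak area in one of two channels:
``natural`` (endogenous peptide) and ``heavy`` (spiked stable-isotope
standard).  A peptide's abundance readout is the Natural-to-Heavy ratio,

    ratio = sum over fractions and transitions of natural areas
          / sum over the same fractions and transitions of heavy areas,

computed sum-then-ratio with the identical fraction and transition sets in
both channels, fixed across all samples of an analysis.  Protein abundance is
the geometric mean of its peptides' ratios within each biological replicate,
then mean +/- SD over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SAMPLE_KEYS = ["genotype", "timepoint", "replicate"]

GOOD_SIGNAL_COUNTS = 10_000.0


# ---------------------------------------------------------------------------
# Chromatogram integration
# ---------------------------------------------------------------------------


def integrate_peak(
    times: np.ndarray,
    intensities: np.ndarray,
    rt_window: tuple[float, float],
    edge_points: int = 3,
) -> tuple[float, float]:
    """Integrate one chromatographic peak inside ``rt_window``.

    The baseline is the median of the samples at the window edges; the peak
    apex is the in-window maximum after baseline subtraction; integration
    boundaries walk outward from the apex until the smoothed signal falls back
    to the baseline.  The area is the trapezoidal sum above baseline and is
    never negative.  Returns ``(area, apex_rt)``.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    lo, hi = rt_window
    if lo >= hi:
        raise ValueError("empty retention-time window")
    if lo < times[0] or hi > times[-1]:
        raise ValueError(
            f"window ({lo:g}, {hi:g}) outside the trace grid "
            f"({times[0]:g}, {times[-1]:g})"
        )
    mask = (times >= lo) & (times <= hi)
    t, y = times[mask], intensities[mask]
    if t.size < 2:
        raise ValueError("window contains fewer than two samples")

    k = min(edge_points, t.size // 2)
    baseline = float(np.median(np.concatenate([y[:k], y[-k:]])))
    corrected = y - baseline

    apex_idx = int(np.argmax(corrected))
    apex_rt = float(t[apex_idx])
    if corrected[apex_idx] <= 0:
        return 0.0, apex_rt

    # 3-point moving average for boundary detection only.
    smooth = np.convolve(corrected, np.ones(3) / 3.0, mode="same")
    left = apex_idx
    while left > 0 and smooth[left - 1] > 0:
        left -= 1
    right = apex_idx
    while right < t.size - 1 and smooth[right + 1] > 0:
        right += 1
    seg = np.clip(corrected[left : right + 1], 0.0, None)
    area = float(np.trapezoid(seg, t[left : right + 1]))
    return max(area, 0.0), apex_rt


def match_channels(
    natural_apex_rt: float, heavy_apex_rt: float, tolerance: float = 0.2
) -> bool:
    """Co-elution check: the endogenous peak must sit on the standard's
    retention time.  Closed boundary: a difference equal to the tolerance
    still matches."""
    return abs(natural_apex_rt - heavy_apex_rt) <= tolerance


# ---------------------------------------------------------------------------
# Signal classing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalClass:
    peptide: str
    sample: tuple
    signal_class: str  # good | low | none
    summed_intensity: float


def classify_signal(
    natural_areas, good_threshold: float = GOOD_SIGNAL_COUNTS
) -> tuple[str, float]:
    """Class a peptide-in-sample by its summed natural intensity.

    good: strictly above the threshold; low: positive but at or below it;
    none: no detected signal at all.
    """
    areas = np.asarray(
        [a for a in np.atleast_1d(natural_areas) if not np.isnan(a)],
        dtype=float,
    )
    if areas.size == 0:
        return "none", 0.0
    total = float(areas.sum())
    if total > good_threshold:
        return "good", total
    if total > 0:
        return "low", total
    return "none", total


def detection_summary(
    peaks: pd.DataFrame, good_threshold: float = GOOD_SIGNAL_COUNTS
) -> pd.DataFrame:
    """Per (peptide, sample) signal class from the natural channel.

    Interference-flagged transitions are excluded: co-eluting background is
    not evidence of the analyte.
    """
    nat = peaks[peaks["channel"] == "natural"]
    if "interference_free" in nat.columns:
        nat = nat[nat["interference_free"]]
    grouped = (
        nat.groupby(["peptide", *SAMPLE_KEYS], observed=True)["area"]
        .sum()
        .reset_index(name="summed_intensity")
    )
    grouped["signal_class"] = np.where(
        grouped["summed_intensity"] > good_threshold,
        "good",
        np.where(grouped["summed_intensity"] > 0, "low", "none"),
    )
    return grouped


# ---------------------------------------------------------------------------
# Natural/Heavy peptide ratios
# ---------------------------------------------------------------------------


def peptide_ratio(
    natural: pd.DataFrame,
    heavy: pd.DataFrame,
    transitions: list[str],
    fractions: list[int],
    min_transitions: int = 3,
    max_transitions: int = 5,
) -> tuple[float, str | None]:
    """Sum-then-ratio for a single peptide in a single sample, given the
    analysis-wide transition and fraction sets.  Returns (ratio, reason);
    the ratio is NaN when a reason is given."""
    if not (min_transitions <= len(transitions) <= max_transitions):
        return float("nan"), "transition count outside 3..5"
    nat = natural[
        natural["transition"].isin(transitions)
        & natural["fraction"].isin(fractions)
    ]["area"].sum()
    hvy = heavy[
        heavy["transition"].isin(transitions)
        & heavy["fraction"].isin(fractions)
    ]["area"].sum()
    if hvy <= 0:
        return float("nan"), "no standard signal"
    return float(nat / hvy), None


def peptide_ratios(
    peaks: pd.DataFrame,
    min_transitions: int = 3,
    max_transitions: int = 5,
    lod_counts: float = 0.0,
) -> pd.DataFrame:
    """Natural/Heavy ratios for every (peptide, sample) in a peak table.

    Per peptide, the analysis first fixes the usable transition set (those
    interference-free everywhere, capped at ``max_transitions``) and the
    fraction set (every fraction where either channel shows detectable signal
    in any sample), then applies both sets identically to all samples —
    mirroring how fractions "containing detectable peptide signals" are summed
    equally across an analysis.  Peptides with fewer than ``min_transitions``
    clean transitions get missing ratios with a reason.

    ``lod_counts`` declares the reporting floor of the upstream peak export,
    if any.  When it is nonzero, a (transition, fraction) cell that is present
    in one channel but censored in the other is imputed at half the floor —
    the usual left-censoring substitution — instead of being summed as zero,
    which would systematically deflate low-abundance samples.  With the
    default of 0 the sums use exactly the reported areas.
    """
    required = {"peptide", "transition", "fraction", "channel", "area"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table lacks columns {sorted(missing)}")

    out_rows = []
    samples = (
        peaks[SAMPLE_KEYS].drop_duplicates().itertuples(index=False)
        if set(SAMPLE_KEYS) <= set(peaks.columns)
        else None
    )
    if samples is None:
        raise ValueError("peak table lacks sample key columns")
    sample_list = list(samples)

    for peptide, sub in peaks.groupby("peptide", observed=True, sort=True):
        # Transition set: interference-free in every record where it appears.
        clean = (
            sub.groupby("transition", observed=True)["interference_free"]
            .all()
            .pipe(lambda s: sorted(s[s].index))
            if "interference_free" in sub.columns
            else sorted(sub["transition"].unique())
        )
        transitions = clean[:max_transitions]
        n_used = len(transitions)
        usable = sub[sub["transition"].isin(transitions)]
        fractions = sorted(
            usable.loc[usable["area"].notna(), "fraction"].unique()
        )
        in_sets = usable[usable["fraction"].isin(fractions)]
        nat = in_sets[in_sets["channel"] == "natural"]
        hvy = in_sets[in_sets["channel"] == "heavy"]
        nat_sums = nat.groupby(SAMPLE_KEYS, observed=True)["area"].sum().to_dict()
        hvy_sums = hvy.groupby(SAMPLE_KEYS, observed=True)["area"].sum().to_dict()
        nat_cells = (
            nat.groupby(SAMPLE_KEYS, observed=True)
            .apply(
                lambda g: set(zip(g["transition"], g["fraction"])),
                include_groups=False,
            )
            .to_dict()
        )
        hvy_cells = (
            hvy.groupby(SAMPLE_KEYS, observed=True)
            .apply(
                lambda g: set(zip(g["transition"], g["fraction"])),
                include_groups=False,
            )
            .to_dict()
        )
        for s in sample_list:
            key = tuple(s)
            ratio, reason = float("nan"), None
            if not (min_transitions <= n_used <= max_transitions):
                reason = (
                    f"{n_used} interference-free transitions "
                    f"(need {min_transitions}..{max_transitions})"
                )
            else:
                h = float(hvy_sums.get(key, 0.0))
                n_ = float(nat_sums.get(key, 0.0))
                nc = nat_cells.get(key, set())
                hc = hvy_cells.get(key, set())
                if h <= 0:
                    reason = "no standard signal"
                elif lod_counts > 0 and not nc:
                    # imputation covers partial censoring, not absent analyte
                    reason = "no analyte signal"
                else:
                    if lod_counts > 0:
                        n_ += 0.5 * lod_counts * len(hc - nc)
                        h += 0.5 * lod_counts * len(nc - hc)
                    ratio = n_ / h
            out_rows.append(
                {
                    "peptide": peptide,
                    **dict(zip(SAMPLE_KEYS, key)),
                    "ratio": ratio,
                    "n_transitions_used": n_used,
                    "n_fractions_used": len(fractions),
                    "reason": reason,
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Protein roll-up
# ---------------------------------------------------------------------------


def protein_rollup(
    ratios: pd.DataFrame,
    peptide_to_protein: dict[str, str],
    warn_missing_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll peptide ratios up to protein abundances.

    Within each replicate the protein abundance is the geometric mean of the
    available (non-missing) peptide ratios; replicates are then summarized as
    arithmetic mean +/- SD.  Returns ``(replicate_table, summary_table)``.
    Peptides missing in more than ``warn_missing_frac`` of samples are logged.
    """
    df = ratios.copy()
    df["protein"] = df["peptide"].map(peptide_to_protein)
    df = df[df["protein"].notna()]

    miss = df.assign(missing=df["ratio"].isna()).groupby("peptide")["missing"].mean()
    for pep, frac in miss[miss > warn_missing_frac].items():
        logger.warning(
            "peptide %s missing in %.0f%% of samples", pep, 100 * frac
        )

    ok = df[df["ratio"].notna() & (df["ratio"] > 0)]
    rep = (
        ok.groupby(["protein", *SAMPLE_KEYS], observed=True)
        .agg(
            abundance=("ratio", lambda r: float(np.exp(np.mean(np.log(r))))),
            n_peptides=("ratio", "size"),
            peptides_used=("peptide", lambda p: ",".join(sorted(p))),
        )
        .reset_index()
    )
    summary = (
        rep.groupby(["protein", "genotype", "timepoint"], observed=True)
        .agg(
            mean=("abundance", "mean"),
            sd=("abundance", lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else float("nan")),
            n_replicates=("abundance", "size"),
        )
        .reset_index()
    )
    return rep, summary


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    protein: str
    contrast: str
    fold_change: float
    p_value: float | None
    n_a: int = 0
    n_b: int = 0
    notes: str | None = None


def compare_groups(
    a,
    b,
    protein: str = "",
    contrast: str = "",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample comparison: fold change = mean(a)/mean(b), two-tailed
    Student's t-test (equal variance by default, Welch optional).

    With fewer than 2 replicates on either side only the fold change is
    reported.  Two identical zero-variance groups get p = 1.0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return GroupComparison(protein, contrast, float("nan"), None,
                               a.size, b.size, "empty group")
    fold = float(a.mean() / b.mean()) if b.mean() != 0 else float("inf")
    if a.size < 2 or b.size < 2:
        return GroupComparison(protein, contrast, fold, None, a.size, b.size,
                               "fewer than 2 replicates; no test")
    notes = None
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            p = 1.0
            notes = "identical zero-variance groups; p set to 1 by convention"
        else:
            p = 0.0
            notes = "distinct zero-variance groups"
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return GroupComparison(protein, contrast, fold, p, a.size, b.size, notes)


def compare_table(
    replicate_abundances: pd.DataFrame,
    wild_type: str = "WT",
    germinated_wt: str = "24",
    germinated_mutant: str = "42",
    equal_var: bool = True,
) -> pd.DataFrame:
    """All study contrasts from a replicate-level protein abundance table.

    Chronological contrasts compare wild type against each mutant allele at
    every shared timepoint (fold = WT/mutant); the developmental contrast
    compares each mutant at its germination end point against wild type at
    its own (fold = mutant@42h / WT@24h), matching seeds of similar
    developmental stage rather than age.
    """
    df = replicate_abundances
    mutants = sorted(set(df["genotype"]) - {wild_type})
    rows = []

    def values(protein, genotype, timepoint):
        sel = df[
            (df["protein"] == protein)
            & (df["genotype"] == genotype)
            & (df["timepoint"] == timepoint)
        ]
        return sel["abundance"].to_numpy()

    for protein in sorted(df["protein"].unique()):
        for mut in mutants:
            for tp in sorted(df["timepoint"].unique()):
                cmp_ = compare_groups(
                    values(protein, wild_type, tp),
                    values(protein, mut, tp),
                    protein,
                    f"chron:{wild_type}@{tp}_vs_{mut}@{tp}",
                    equal_var=equal_var,
                )
                rows.append(cmp_)
            cmp_ = compare_groups(
                values(protein, mut, germinated_mutant),
                values(protein, wild_type, germinated_wt),
                protein,
                f"dev:{mut}@{germinated_mutant}h_vs_{wild_type}@{germinated_wt}h",
                equal_var=equal_var,
            )
            rows.append(cmp_)
    return pd.DataFrame(
        {
            "protein": [r.protein for r in rows],
            "contrast": [r.contrast for r in rows],
            "fold_change": [r.fold_change for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_a": [r.n_a for r in rows],
            "n_b": [r.n_b for r in rows],
            "notes": [r.notes for r in rows],
        }
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; offered as an
    option for users who want multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out
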