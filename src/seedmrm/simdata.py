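"""Seeded generative model of the germinating-seed MRM experiment.

The simulator emulates the full study design: three genotypes (wild type and
two protease-knockout alleles) sampled at six stages (dry seed, post
stratification, and 6/12/24/42 h of germination), three biological replicates,
SDS-PAGE fractionation into 12 gel slices, five monitored transitions per
peptide in a natural (endogenous) and a heavy (stable-isotope standard, SIS)
channel.  Protein time courses are programmed through per-genotype anchor
tables; everything downstream of the anchors — peptide response, gel-band
distribution, transition intensity split, biological and measurement noise,
detection floor, interference — is multiplicative structure the quantitation
pipeline must see through.

Expected areas:

    natural = abundance_scale * anchor(p,g,t) * biol(replicate)
              * response(peptide) * band_weight(fraction) * split(transition)
    heavy   = spike_counts * response(peptide)
              * band_weight(fraction) * split(transition)

both multiplied by mean-one lognormal measurement noise.  The heavy channel is
independent of genotype and timepoint by construction (the spike is constant),
so the Natural/Heavy ratio recovers ``anchor * abundance_scale /
spike_counts``.  Records below the detection floor are censored (dropped).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import panel as panel_mod

TIMEPOINT_HOURS = {"DS": -60.0, "0": 0.0, "6": 6.0, "12": 12.0, "24": 24.0, "42": 42.0}


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    s = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


@dataclass
class SimConfig:
    """Generative parameters; defaults reproduce the study design."""

    genotypes: tuple[str, ...] = ("WT", "ftsh4-1", "ftsh4-2")
    timepoints: tuple[str, ...] = ("DS", "0", "6", "12", "24", "42")
    n_replicates: int = 3
    n_fractions: int = 12
    abundance_scale: float = 200_000.0
    spike_counts: float = 200_000.0
    noise_cv: float = 0.15
    biol_cv: float = 0.20
    lod_counts: float = 1_000.0
    good_signal_counts: float = 10_000.0
    peptide_response_sigma: float = 0.8
    transition_profile: str = "dirichlet"
    n_transitions: int = 5
    fraction_sd: float = 0.8
    interference_rate: float = 0.1
    anchors: dict = field(default_factory=dict)
    mw_kda: dict = field(default_factory=dict)
    peptides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cv in (self.noise_cv, self.biol_cv):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if self.transition_profile not in ("dirichlet", "equal"):
            raise ValueError(f"unknown transition_profile {self.transition_profile!r}")
        for protein, table in self.anchors.items():
            for geno, tps in table.items():
                for tp, value in tps.items():
                    if not value > 0:
                        raise ValueError(
                            f"anchor for {protein}/{geno}/{tp} must be > 0"
                        )

    def anchor_table(self, protein: str, genotype: str) -> Mapping[str, float]:
        try:
            table = self.anchors[protein]
        except KeyError:
            raise KeyError(f"no anchors for protein {protein!r}") from None
        if genotype in table:
            return table[genotype]
        if genotype.startswith("ftsh4") and "ftsh4" in table:
            return table["ftsh4"]
        raise KeyError(f"no anchors for {protein!r} in genotype {genotype!r}")

    def abundance(self, protein: str, genotype: str, timepoint: str) -> float:
        """Programmed relative abundance, log-linearly interpolated in time
        when the exact timepoint has no anchor."""
        table = self.anchor_table(protein, genotype)
        if timepoint in table:
            return float(table[timepoint])
        if timepoint not in TIMEPOINT_HOURS:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        xs = sorted(
            (TIMEPOINT_HOURS[tp], float(v))
            for tp, v in table.items()
            if tp in TIMEPOINT_HOURS
        )
        if len(xs) < 2:
            raise KeyError(f"cannot interpolate {protein!r} at {timepoint!r}")
        x = TIMEPOINT_HOURS[timepoint]
        hours = np.array([p[0] for p in xs])
        logv = np.log([p[1] for p in xs])
        return float(np.exp(np.interp(x, hours, logv)))


class TruthTable:
    """Programmed ground truth implied by a :class:`SimConfig`."""

    def __init__(self, config: SimConfig, proteins: Sequence[str]):
        self._config = config
        rows = []
        for protein in proteins:
            for geno in config.genotypes:
                for tp in config.timepoints:
                    a = config.abundance(protein, geno, tp)
                    rows.append(
                        {
                            "protein": protein,
                            "genotype": geno,
                            "timepoint": tp,
                            "true_abundance": a,
                            "true_ratio": a
                            * config.abundance_scale
                            / config.spike_counts,
                        }
                    )
        self.abundance = pd.DataFrame(rows)

    def fold_change(
        self,
        protein: str,
        numerator: tuple[str, str],
        denominator: tuple[str, str],
    ) -> float:
        """True fold change between two (genotype, timepoint) conditions."""
        c = self._config
        return c.abundance(protein, *numerator) / c.abundance(
            protein, *denominator
        )


def fraction_weights(center: float, sd: float, n_fractions: int) -> np.ndarray:
    """Discrete Gaussian gel-band profile over fractions 1..n, summing to 1."""
    f = np.arange(1, n_fractions + 1, dtype=float)
    w = np.exp(-0.5 * ((f - center) / sd) ** 2)
    return w / w.sum()


def band_centers(
    proteins: Sequence[str], mw_kda: Mapping[str, float], n_fractions: int
) -> dict[str, float]:
    """Assign gel-band centers by molecular-weight rank (heaviest on top)."""
    ranked = sorted(proteins, key=lambda p: (-mw_kda.get(p, 30.0), p))
    n = len(ranked)
    if n == 1:
        return {ranked[0]: (1 + n_fractions) / 2.0}
    return {
        p: 1 + (n_fractions - 1) * i / (n - 1) for i, p in enumerate(ranked)
    }


def load_sim_config(path=None) -> SimConfig:
    """Load a simulation TOML; with no path, the bundled default
    configuration with the germination-study anchors and the bundled panel."""
    if path is None:
        src = resources.files("seedmrm.data") / "paper_anchors.toml"
        raw = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    design = raw.get("design", {})
    signal = raw.get("signal", {})
    _, peptides = panel_mod.load_panel()
    by_protein = panel_mod.peptides_by_protein(peptides)
    anchors = raw.get("anchors", {})
    if anchors:
        # simulate exactly the proteins the config programs
        by_protein = {p: by_protein[p] for p in anchors if p in by_protein}
    cfg = SimConfig(
        genotypes=tuple(design.get("genotypes", SimConfig.genotypes)),
        timepoints=tuple(str(t) for t in design.get("timepoints", SimConfig.timepoints)),
        n_replicates=int(design.get("n_replicates", 3)),
        n_fractions=int(design.get("n_fractions", 12)),
        anchors={
            p: {g: {str(t): float(v) for t, v in tps.items()} for g, tps in table.items()}
            for p, table in anchors.items()
        },
        mw_kda={p: float(v) for p, v in raw.get("mw_kda", {}).items()},
        peptides=by_protein,
        **{
            k: type(getattr(SimConfig, k))(v)
            if not isinstance(getattr(SimConfig, k), str)
            else str(v)
            for k, v in signal.items()
        },
    )
    return cfg


def noiseless(config: SimConfig) -> SimConfig:
    """The idealized-instrument limit: no noise, no interference, and no
    detection floor (censoring would otherwise break exact identities)."""
    return replace(
        config, noise_cv=0.0, biol_cv=0.0, interference_rate=0.0, lod_counts=0.0
    )


def simulate(
    config: SimConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, TruthTable]:
    """Generate the transition-level peak-area table and its ground truth.

    Returns a long-form table with one row per (genotype, timepoint,
    replicate, fraction, peptide, transition, channel); censored (sub-LOD)
    records are absent.  Fully reproducible from the seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    proteins = sorted(p for p in config.peptides if config.peptides[p])
    for p in proteins:
        config.anchor_table(p, config.genotypes[0])  # raises if missing

    truth = TruthTable(config, proteins)

    # Per-peptide structure: response multiplier and transition split.
    pep_rows = [
        (p, pep) for p in proteins for pep in sorted(config.peptides[p])
    ]
    n_pep = len(pep_rows)
    response = (
        rng.lognormal(0.0, config.peptide_response_sigma, size=n_pep)
        if config.peptide_response_sigma > 0
        else np.ones(n_pep)
    )
    nt = config.n_transitions
    if config.transition_profile == "dirichlet":
        splits = rng.dirichlet(np.full(nt, 2.0), size=n_pep)
    else:
        splits = np.full((n_pep, nt), 1.0 / nt)
    interfered = rng.random((n_pep, nt)) < config.interference_rate

    pep_df = pd.DataFrame(
        {
            "protein": np.repeat([r[0] for r in pep_rows], nt),
            "peptide": np.repeat([r[1] for r in pep_rows], nt),
            "transition": np.tile([f"T{i + 1}" for i in range(nt)], n_pep),
            "tsplit": splits.ravel(),
            "interference_free": ~interfered.ravel(),
        }
    )

    # Per-protein gel-band fraction weights.
    centers = band_centers(proteins, config.mw_kda, config.n_fractions)
    frac_df = pd.DataFrame(
        {
            "protein": np.repeat(proteins, config.n_fractions),
            "fraction": np.tile(
                np.arange(1, config.n_fractions + 1), len(proteins)
            ),
            "fweight": np.concatenate(
                [
                    fraction_weights(
                        centers[p], config.fraction_sd, config.n_fractions
                    )
                    for p in proteins
                ]
            ),
        }
    )

    # Samples and their programmed abundances / replicate factors.
    samples = pd.DataFrame(
        [
            (g, t, r)
            for g in config.genotypes
            for t in config.timepoints
            for r in range(1, config.n_replicates + 1)
        ],
        columns=["genotype", "timepoint", "replicate"],
    )
    cond = pd.DataFrame(
        [
            {
                "protein": p,
                "genotype": g,
                "timepoint": t,
                "replicate": r,
                "anchor": config.abundance(p, g, t),
            }
            for p in proteins
            for g in config.genotypes
            for t in config.timepoints
            for r in range(1, config.n_replicates + 1)
        ]
    )
    cond["biol"] = _noise(rng, config.biol_cv, len(cond))

    grid = pep_df.merge(frac_df, on="protein").merge(cond, on="protein")
    base = grid["tsplit"] * grid["fweight"]
    nat_expected = (
        config.abundance_scale * grid["anchor"] * grid["biol"] * base
    )
    heavy_expected = config.spike_counts * base
    resp = dict(zip([f"{p}|{s}" for p, s in pep_rows], response))
    pep_resp = (grid["protein"] + "|" + grid["peptide"]).map(resp).to_numpy()

    n = len(grid)
    nat_area = nat_expected.to_numpy() * pep_resp * _noise(rng, config.noise_cv, n)
    heavy_area = (
        heavy_expected.to_numpy() * pep_resp * _noise(rng, config.noise_cv, n)
    )
    # Additive co-eluting background on interference-flagged natural records.
    flagged = ~grid["interference_free"].to_numpy()
    if flagged.any():
        background = (
            rng.uniform(0.5, 2.0, size=int(flagged.sum()))
            * config.spike_counts
            * base.to_numpy()[flagged]
        )
        nat_area[flagged] = nat_area[flagged] + background

    key_cols = [
        "genotype",
        "timepoint",
        "replicate",
        "fraction",
        "protein",
        "peptide",
        "transition",
        "interference_free",
    ]
    nat = grid[key_cols].copy()
    nat["channel"] = "natural"
    nat["area"] = nat_area
    heavy = grid[key_cols].copy()
    heavy["channel"] = "heavy"
    heavy["area"] = heavy_area
    peaks = pd.concat([nat, heavy], ignore_index=True)
    peaks = peaks[peaks["area"] >= config.lod_counts].reset_index(drop=True)
    peaks = peaks[
        [
            "genotype",
            "timepoint",
            "replicate",
            "fraction",
            "protein",
            "peptide",
            "transition",
            "channel",
            "area",
            "interference_free",
        ]
    ]
    peaks = peaks.sort_values(
        ["genotype", "timepoint", "replicate", "protein", "peptide",
         "transition", "fraction", "channel"],
        kind="mergesort",
    ).reset_index(drop=True)
    return peaks, truth


@dataclass
class ChromTrace:
    """A rendered SRM chromatogram for one transition record."""

    peptide: str
    transition: str
    channel: str
    times: np.ndarray  # minutes
    intensities: np.ndarray  # counts
    apex_rt: float
    width_sd: float


def _peptide_base_rt(peptide: str, lo: float = 12.0, hi: float = 48.0) -> float:
    # Deterministic pseudo-retention time from the sequence alone.
    h = 0
    for ch in peptide:
        h = (h * 131 + ord(ch)) % 100_003
    return lo + (hi - lo) * h / 100_002


def render_chromatograms(
    peaks: pd.DataFrame,
    rt_sd_min: float = 0.05,
    coelution_jitter: float = 0.0,
    baseline_noise: float = 0.0,
    grid_halfwidth_sd: float = 6.0,
    points_per_trace: int = 121,
    seed: int | np.random.Generator = 0,
) -> list[ChromTrace]:
    """Render Gaussian elution peaks whose integrals equal the record areas.

    Natural and heavy channels of a peptide share an apex (co-elution);
    ``coelution_jitter`` adds a small Gaussian offset to the heavy apex.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    traces = []
    for _, row in peaks.iterrows():
        apex = _peptide_base_rt(row["peptide"])
        if row["channel"] == "heavy" and coelution_jitter > 0:
            apex += rng.normal(0.0, coelution_jitter)
        t = np.linspace(
            apex - grid_halfwidth_sd * rt_sd_min,
            apex + grid_halfwidth_sd * rt_sd_min,
            points_per_trace,
        )
        area = float(row["area"])
        y = (
            area
            / (rt_sd_min * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((t - apex) / rt_sd_min) ** 2)
        )
        if baseline_noise > 0:
            y = np.clip(y + rng.normal(0.0, baseline_noise, size=y.size), 0, None)
        traces.append(
            ChromTrace(
                peptide=row["peptide"],
                transition=row["transition"],
                channel=row["channel"],
                times=t,
                intensities=y,
                apex_rt=apex,
                width_sd=rt_sd_min,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Orthogonal-assay generators
# ---------------------------------------------------------------------------


@dataclass
class BlotConfig:
    """Western-blot densitometry generator parameters."""

    genotypes: tuple[str, ...] = ("WT", "ftsh4-1", "ftsh4-2")
    timepoints: tuple[str, ...] = ("0", "24", "42")
    n_replicates: int = 3
    band_scale: float = 1000.0
    loading_scale: float = 1000.0
    noise_cv: float = 0.15
    loading_cv: float = 0.10
    anchors: dict = field(default_factory=dict)

    def anchor(self, protein: str, genotype: str, timepoint: str) -> float:
        table = self.anchors[protein]
        if genotype in table:
            return float(table[genotype][timepoint])
        if genotype.startswith("ftsh4") and "ftsh4" in table:
            return float(table["ftsh4"][timepoint])
        raise KeyError(f"no blot anchors for {protein!r}/{genotype!r}")


def load_blot_config(path=None) -> BlotConfig:
    if path is None:
        src = resources.files("seedmrm.data") / "blot_anchors.toml"
        raw = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    design = raw.get("design", {})
    signal = raw.get("signal", {})
    return BlotConfig(
        genotypes=tuple(design.get("genotypes", BlotConfig.genotypes)),
        timepoints=tuple(str(t) for t in design.get("timepoints", BlotConfig.timepoints)),
        n_replicates=int(design.get("n_replicates", 3)),
        band_scale=float(signal.get("band_scale", 1000.0)),
        loading_scale=float(signal.get("loading_scale", 1000.0)),
        noise_cv=float(signal.get("noise_cv", 0.15)),
        loading_cv=float(signal.get("loading_cv", 0.10)),
        anchors={
            p: {g: {str(t): float(v) for t, v in tps.items()} for g, tps in table.items()}
            for p, table in raw.get("anchors", {}).items()
        },
    )


def simulate_blot(
    config: BlotConfig | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Generate densitometry records (band and loading-control intensities).

    The per-lane loading factor multiplies both the band and the loading
    control, so the band/loading ratio is loading-invariant up to measurement
    noise — exactly the property the normalization arithmetic exploits.
    """
    config = config or load_blot_config()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    lanes = [
        (g, t, r)
        for g in config.genotypes
        for t in config.timepoints
        for r in range(1, config.n_replicates + 1)
    ]
    lane_load = dict(
        zip(lanes, _noise(rng, config.loading_cv, len(lanes)))
    )
    for protein in sorted(config.anchors):
        for g, t, r in lanes:
            load = lane_load[(g, t, r)]
            band = (
                config.band_scale
                * config.anchor(protein, g, t)
                * load
                * _noise(rng, config.noise_cv, 1)[0]
            )
            loading = (
                config.loading_scale * load * _noise(rng, config.noise_cv, 1)[0]
            )
            rows.append(
                {
                    "protein": protein,
                    "genotype": g,
                    "timepoint": t,
                    "replicate": r,
                    "band_intensity": band,
                    "loading_intensity": loading,
                }
            )
    return pd.DataFrame(rows)


DEFAULT_QPCR_ANCHORS: dict = {
    # Relative transcript levels (calibrator: WT dry seed = 1).  The mutant
    # AOX1A transcript over-accumulates after stratification and again late
    # in germination; the reference-housekeeping channel is flat.
    "AOX1A": {
        "WT": {"DS": 1.0, "0": 1.5, "6": 2.0, "12": 2.5, "24": 3.0},
        "ftsh4": {"DS": 1.0, "0": 12.0, "6": 10.0, "12": 8.0, "24": 15.0},
    },
}


def simulate_qpcr(
    anchors: Mapping | None = None,
    genotypes: Sequence[str] = ("WT", "ftsh4-1", "ftsh4-2"),
    n_replicates: int = 3,
    ct_reference: float = 22.0,
    base_delta_ct: float = 5.0,
    ct_sd: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate qPCR Ct records consistent with programmed relative levels."""
    anchors = anchors or DEFAULT_QPCR_ANCHORS
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    for gene, table in sorted(anchors.items()):
        for g in genotypes:
            levels = table.get(g) or (
                table.get("ftsh4") if g.startswith("ftsh4") else None
            )
            if levels is None:
                raise KeyError(f"no qPCR anchors for {gene!r}/{g!r}")
            for tp, level in levels.items():
                for r in range(1, n_replicates + 1):
                    ref = ct_reference + rng.normal(0.0, ct_sd)
                    tgt = (
                        ct_reference
                        + base_delta_ct
                        - np.log2(level)
                        + rng.normal(0.0, ct_sd)
                    )
                    rows.append(
                        {
                            "gene": gene,
                            "genotype": g,
                            "timepoint": str(tp),
                            "replicate": r,
                            "ct_target": tgt,
                            "ct_reference": ref,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_o2_traces(
    total_rate: float = 0.5,
    cox_fraction: float = 0.6,
    aox_fraction: float = 0.3,
    dry_weight_mg: float = 10.0,
    duration_min: float = 10.0,
    n_points: int = 41,
    o2_start_nmol: float = 250.0,
    noise_sd_nmol: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Linear O2-drawdown traces under no inhibitor, SHAM, and KCN.

    SHAM blocks the alternative oxidase, leaving the cytochrome (COX) pathway;
    KCN blocks COX, leaving the alternative (AOX) pathway.  Rates are in
    nmol O2 / min / mg dry weight.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = np.linspace(0.0, duration_min, n_points)
    rates = {
        "none": total_rate,
        "SHAM": cox_fraction * total_rate,
        "KCN": aox_fraction * total_rate,
    }
    out = {}
    for inhibitor, rate in rates.items():
        o2 = o2_start_nmol - rate * dry_weight_mg * t
        if noise_sd_nmol > 0:
            o2 = o2 + rng.normal(0.0, noise_sd_nmol, size=o2.size)
        out[inhibitor] = pd.DataFrame(
            {"time_min": t, "o2_nmol": o2, "dry_weight_mg": dry_weight_mg}
        )
    return out
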