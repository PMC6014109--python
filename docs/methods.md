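# Methods

## The assay being modeled

`seedmrm` implements the analysis side of a targeted proteomics (MRM/SRM)
experiment that tracks mitochondrial protein biogenesis during Arabidopsis
seed germination. The biological design contrasts wild type against two
alleles of a knockout of the inner-membrane ATP-dependent protease FTSH4
across six stages — dry seed (DS), post-stratification (0 h), and 6, 12, 24
and 42 h of germination at 30 °C — with three biological replicates. Because
mitochondria cannot be enriched from such small seeds, total seed protein is
fractionated into 12 SDS-PAGE slices; each slice is digested and measured by
a triple quadrupole monitoring five transitions per peptide in two channels:
the endogenous ("natural") peptide and a spiked stable-isotope-labeled
standard ("heavy", SIS) carrying a C-terminal Lys(+8.01420 Da) or
Arg(+10.00827 Da).

The quantitation chain is:

1. **Peptide ratio.** For each peptide and sample, the Natural-to-Heavy
   ratio is the sum of natural transition peak areas over fractions and
   transitions, divided by the sum of heavy areas over the same fraction and
   transition sets (sum-then-ratio, never a mean of per-fraction ratios).
   Only interference-free transitions are used, and a ratio requires 3–5 of
   them; the fraction and transition sets are fixed per peptide across all
   samples of an analysis.
2. **Protein roll-up.** Within a biological replicate, protein abundance is
   the geometric mean of its available peptide ratios; replicates are then
   summarized as arithmetic mean ± SD.
3. **Comparisons.** Two-tailed Student's t (equal variance; Welch optional)
   between genotypes at the same chronological age, and a developmental-stage
   contrast matching mutant seeds at 42 h (germination complete) against wild
   type at 24 h.

## Pinned interpretations and conventions

Several choices were genuinely open; they are pinned as follows.

- **Fraction set.** "Fractions containing detectable peptide signals, summed
  equally across samples" is implemented as: per peptide, the union over all
  samples and *both channels* of fractions with detectable signal, applied
  identically to every sample. The channel union is forced by the arithmetic
  of the sum-then-ratio (the heavy standard can be detectable in a fraction
  where the endogenous peptide is not, and its signal there belongs in the
  denominator).
- **Censored cells.** Peak exports carry a reporting floor (default 1,000
  counts): a transition × fraction cell below it is absent from the table.
  Summing absent natural cells as zero while their heavy partners survive
  systematically deflates low-abundance samples, so when the caller declares
  the floor (`peptide_ratios(..., lod_counts=...)`) a cell present in one
  channel and censored in the other is imputed at half the floor — the
  standard left-censoring substitution. A peptide whose natural channel is
  never detected in a sample is reported missing ("no analyte signal"), not
  imputed: imputation covers partial censoring, never an absent analyte.
- **Replicate aggregation order.** Geometric mean over peptides *within* a
  replicate, then arithmetic mean ± SD *over* replicates. The alternative
  order (mean over replicates per peptide first) is available by composing
  the primitives but is not the default.
- **Zero-variance groups.** Two identical constant groups get p = 1.0 by
  convention (the t statistic is 0/0); distinct constant groups get p = 0.
- **Signal classes.** A peptide-in-sample is "good" when its summed natural
  intensity strictly exceeds 10,000 counts, "low" when positive but at or
  below it, "none" when nothing was detected. Interference-flagged
  transitions do not count as evidence of the analyte.
- **Selection rules.** Peptide length 6–20 residues is a hard filter (the
  lower bound is our addition: shorter peptides are rarely proteotypic; it
  is configurable). The N-terminal C/M/W/Q rule and the DP/DG/NG/QG motif
  rule are *soft* — recorded as ranking penalties, never excluding — because
  curated panels legitimately retain such peptides when no cleaner candidate
  exists. Uniqueness is exact substring counting over a supplied proteome
  (I/L collapsible via a flag); homology-aware matching is out of scope.
- **Mass arithmetic.** Monoisotopic throughout; proton 1.007276 Da; fragment
  charge defaults to 1+; precursor charge defaults to 2+ with 3+ for
  peptides carrying an internal His/Lys/Arg. Collision energy and cone
  voltage are configuration inputs, not predicted.

## The synthetic-data generator

Real LC-MS measurements cannot be regenerated, so the package ships a seeded
generative model whose defaults encode the study design and the published
protein fold changes (`data/paper_anchors.toml`). Expected areas:

    natural(s, f, τ) = A · anchor(p, g, t) · biol(s) · resp(pep) · w_f · d_τ
    heavy(s, f, τ)   = S · resp(pep) · w_f · d_τ

with `A` the abundance scale (200,000 counts per unit relative abundance),
`S` the spike scale (200,000 counts, the 2.5 pmol SIS equivalent),
`biol` a mean-one lognormal replicate factor (CV 0.20), `resp` a per-peptide
lognormal response (σ = 0.8 log-units; cancels in the ratio), `w_f` a
Gaussian gel-band profile over the 12 fractions (SD 0.8 fractions, center
assigned by molecular-weight rank, heaviest protein on top), and `d_τ` a
per-peptide Dirichlet(2) split over the five transitions. Every record is
multiplied by mean-one lognormal measurement noise (CV 0.15); records below
the 1,000-count floor are dropped; with probability 0.1 a transition carries
additive co-eluting background and is flagged not interference-free. Anchor
tables are per (protein, genotype, timepoint); missing timepoints interpolate
log-linearly in germination hours. The three proteins the real assay could
not quantify (COB, AOX2, CLS) are programmed two orders of magnitude below
the quantified panel so they fall under the floor.

The heavy channel is genotype- and timepoint-invariant by construction, so
the pipeline's ratio estimates recover `anchor · A / S`. In the
idealized-instrument limit — all CVs zero, no interference, *and no
detection floor* — the recovery is exact to machine precision; a nonzero
floor is excluded from that limit because censoring asymmetries break exact
identities by construction.

Companion generators emit western-blot densitometry records (shared per-lane
loading factor multiplying band and loading control; anchors in
`data/blot_anchors.toml`, including the 1.85-fold germinated-mutant Tim17-2
excess), qPCR Ct tables consistent with programmed relative levels, and
linear O2-drawdown traces with programmed cytochrome/alternative pathway
fractions.

**What the generator does not model:** digestion variability and
missed-cleavage leakage, matrix effects and ionization suppression,
retention-time drift, isotope-envelope overlap, saturation, or
between-fraction carryover. Passing recovery tests therefore demonstrates
that the quantitation arithmetic is correct and unbiased under multiplicative
noise and censoring — not that any real instrument behaves this well.

## Numerical choices

- Lognormal noise is parameterized by CV with mean exactly one
  (σ² = ln(1+CV²), μ = −σ²/2), so programmed anchors are also expectations;
  CV = 0 yields exactly 1, keeping noiseless runs bit-exact.
- Peak integration: baseline = median of the window-edge samples; apex = the
  baseline-subtracted in-window maximum; boundaries walk outward from the
  apex until a 3-point moving average returns to baseline; area =
  trapezoidal sum, clipped at zero. Co-elution uses a closed-boundary
  retention-time tolerance (default 0.2 min).
- Transition selection breaks intensity ties deterministically by
  (series, index); candidate sorting in panel design breaks ties by sequence.
- Respiration rates are least-squares slopes over ≥4 points, truncated at
  zero with a warning when a trace drifts upward.
- Fold-change sampling variance under the generator follows the delta
  method: per-replicate log-abundance variance σ_b² + 2σ_n²·Σŵ²/m (m
  peptides, ŵ the normalized cell weights, both channels contributing), and
  Var(log FC) ≈ 2(e^V−1)/n for n replicates; the test suite verifies the
  simulator against this prediction over 200 seeds.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the full study design
(3 × 6 × 3 samples, 12 fractions, 71 peptides, 5 transitions, 2 channels ≈
230,000 expected records per dataset). Parameter-recovery medians use 20–24
independent seeds; the null-calibration check draws 1,000 replicate-level
null group pairs from the generator's biological-noise model and pushes them
through the comparison operation directly, which exercises the identical
statistic at a fraction of the cost of full-experiment simulation. The
delta-method calibration uses a reduced one-protein design over 200 seeds.

## Known limitations

- Uniqueness screening is exact-match only; peptides shared with unsequenced
  or homologous proteins are not caught.
- The half-floor imputation slightly inflates ratios of peptides sitting
  almost entirely below the floor; such peptides are usually excluded
  upstream by the no-analyte rule, but a single detected cell admits them.
- Single-replicate conditions report abundances without SD and comparisons
  without p-values rather than borrowing variance.
- The blot and qPCR generators share the MRM generator's multiplicative-noise
  idealization; antibody nonlinearity and primer-efficiency deviations from 2
  are not modeled (an efficiency-corrected ddCt is a straightforward caller-
  side extension since the arithmetic exposes ΔCt).
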