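"""Peptide/fragment m/z arithmetic and SRM transition-list construction.

Monoisotopic masses only.  Heavy (SIS) peptides carry a C-terminal
isotope-labeled residue: Lys(13C6,15N2) at +8.01420 Da or Arg(13C6,15N4) at
+10.00827 Da.  Because the label sits on the C-terminus, y-series fragments of
a heavy peptide shift by the full label mass (divided by fragment charge)
while b-series fragments are identical to the light form — the property that
lets a triple-quadrupole verify co-elution of endogenous and standard peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

# Monoisotopic residue masses (Da), standard amino-acid building blocks.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.007276

#: C-terminal label mass shifts (Da): 6x(13C-12C) + n x (15N-14N).
LABEL_SHIFTS: dict[str, float] = {"K": 8.01420, "R": 10.00827}

LABELS = ("light", "heavy")


@dataclass(frozen=True)
class LabeledPeptide:
    sequence: str
    label: str = "light"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        for aa in self.sequence:
            if aa not in MONOISOTOPIC:
                raise ValueError(f"invalid residue {aa!r}")
        if self.label == "heavy" and self.sequence[-1] not in LABEL_SHIFTS:
            raise ValueError(
                "heavy labeling requires a C-terminal K or R, got "
                f"{self.sequence[-1]!r}"
            )

    @property
    def label_mass_shift(self) -> float:
        if self.label == "light":
            return 0.0
        return LABEL_SHIFTS[self.sequence[-1]]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float

    @property
    def name(self) -> str:
        return f"{self.series}{self.index}"


@dataclass(frozen=True)
class Transition:
    """One Q1/Q3 ion pair with its instrument parameters."""

    peptide: LabeledPeptide
    precursor_charge: int
    precursor_mz: float
    fragment: FragmentIon
    cone_voltage: float = 35.0
    collision_energy: float = 25.0
    dwell_ms: float = 10.0
    interference_free: bool = True


def _residue_sum(sequence: str) -> float:
    try:
        return sum(MONOISOTOPIC[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r}") from None


def peptide_mass(sequence: str, label: str = "light") -> float:
    """Neutral monoisotopic peptide mass (Da)."""
    pep = LabeledPeptide(sequence, label)
    return _residue_sum(sequence) + WATER + pep.label_mass_shift


def peptide_mz(sequence: str, charge: int, label: str = "light") -> float:
    """Precursor m/z: (neutral mass + z protons) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(sequence, label) + charge * PROTON) / charge


def fragment_mzs(
    peptide: LabeledPeptide | str, charge: int = 1
) -> list[FragmentIon]:
    """Full b- and y-series at the given fragment charge.

    For a peptide of n residues, the series run b1..b(n-1) and y1..y(n-1).
    The C-terminal label shifts only y ions, by label_mass_shift / charge.
    """
    if isinstance(peptide, str):
        peptide = LabeledPeptide(peptide)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    seq = peptide.sequence
    shift = peptide.label_mass_shift
    ions = []
    prefix = 0.0
    for i in range(1, len(seq)):
        prefix += MONOISOTOPIC[seq[i - 1]]
        ions.append(
            FragmentIon("b", i, charge, (prefix + charge * PROTON) / charge)
        )
    suffix = 0.0
    for i in range(1, len(seq)):
        suffix += MONOISOTOPIC[seq[len(seq) - i]]
        ions.append(
            FragmentIon(
                "y",
                i,
                charge,
                (suffix + WATER + shift + charge * PROTON) / charge,
            )
        )
    return ions


def select_transitions(
    ranked_intensities: Mapping[FragmentIon, float] | Mapping[tuple, float],
    k: int = 5,
    cone_voltage: float = 35.0,
    collision_energy: float = 25.0,
) -> list:
    """Pick the top-k fragments by intensity.

    Ties at the cutoff break deterministically by (series, index).  Fewer than
    3 candidates triggers a warning since quantitation downstream requires 3-5
    interference-free ion pairs.
    """
    items = list(ranked_intensities.items())
    for frag, inten in items:
        if inten < 0:
            raise ValueError(f"negative intensity for {frag}")

    def sort_key(item):
        frag = item[0]
        series = frag.series if isinstance(frag, FragmentIon) else frag[0]
        index = frag.index if isinstance(frag, FragmentIon) else frag[1]
        return (-item[1], series, index)

    items.sort(key=sort_key)
    selected = [frag for frag, _ in items[:k]]
    if len(selected) < 3:
        warnings.warn(
            f"only {len(selected)} transition candidates; quantitation "
            "requires at least 3 interference-free ion pairs",
            stacklevel=2,
        )
    return selected


def default_precursor_charge(sequence: str) -> int:
    """2+ by default; 3+ for peptides with an internal H, K, or R."""
    internal = sequence[:-1]
    return 3 if any(aa in "HKR" for aa in internal) else 2


def build_transition_table(
    peptides: Sequence[str] | Iterable[str],
    fragment_charge: int = 1,
    k: int = 5,
    cone_voltage: float = 35.0,
    collision_energy: float = 25.0,
    dwell_ms: float = 10.0,
):
    """Light+heavy transition list for a peptide panel, as a DataFrame.

    With no empirical intensities available, fragments are ranked by a simple
    y-over-b, longer-over-shorter preference (high-index y ions dominate
    tryptic peptide spectra); CE/CV are constant config inputs.
    """
    import pandas as pd

    rows = []
    for seq in peptides:
        n = len(seq)
        prior = {}
        for frag in fragment_mzs(seq, fragment_charge):
            rank = frag.index + (n if frag.series == "y" else 0)
            prior[frag] = float(rank)
        chosen = {(f.series, f.index) for f in select_transitions(prior, k=k)}
        for label in LABELS:
            if label == "heavy" and seq[-1] not in LABEL_SHIFTS:
                continue
            pep = LabeledPeptide(seq, label)
            z = default_precursor_charge(seq)
            pre = peptide_mz(seq, z, label)
            for frag in fragment_mzs(pep, fragment_charge):
                if (frag.series, frag.index) not in chosen:
                    continue
                rows.append(
                    {
                        "peptide": seq,
                        "label": label,
                        "precursor_charge": z,
                        "precursor_mz": round(pre, 4),
                        "fragment": frag.name,
                        "fragment_mz": round(frag.mz, 4),
                        "CE": collision_energy,
                        "CV": cone_voltage,
                        "dwell_ms": dwell_ms,
                    }
                )
    return pd.DataFrame(rows)
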