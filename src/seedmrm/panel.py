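"""Proteotypic peptide panel design and the bundled target panel.

In targeted MRM assays a protein is measured through a small set of
*proteotypic* peptides: fully tryptic, unique to the parent protein, of a
length the instrument handles well, and free of chemistry-prone residues.
This module performs the in-silico part of that design — tryptic digestion,
rule-based candidate scoring, exact-substring uniqueness screening — and loads
the bundled panel of 18 mitochondrial proteins and their 71 peptides used in
the germinating-seed assay.

Coordinates are 1-based and inclusive on both ends throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
_VALID_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

GENOMES = ("nuclear", "mitochondrial")
CATEGORIES = (
    "complex I",
    "complex II",
    "complex III",
    "complex IV",
    "ATP synthase",
    "energy dissipation",
    "membrane biogenesis",
    "scaffold",
    "transport",
)
DETECTION_CLASSES = ("good", "low", "none")


@dataclass(frozen=True)
class TargetProtein:
    """A protein targeted by the MRM panel."""

    accession: str
    name: str
    short_name: str
    genome: str
    category: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.genome not in GENOMES:
            raise ValueError(f"unknown genome {self.genome!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class PanelPeptide:
    """A proteotypic peptide with its position in the parent protein.

    ``variant_group`` ties alternative sequences occupying identical
    coordinates (RNA-edited versus genomic forms of mitochondrial peptides);
    ``detected`` optionally records the empirical signal class.
    """

    protein: TargetProtein
    sequence: str
    start: int
    end: int
    variant_group: str | None = None
    detected: str | None = None

    def __post_init__(self) -> None:
        if not _VALID_RE.match(self.sequence):
            raise ValueError(f"invalid residues in {self.sequence!r}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}..{self.end} does not match length of "
                f"{self.sequence!r}"
            )
        if self.detected is not None and self.detected not in DETECTION_CLASSES:
            raise ValueError(f"unknown detection class {self.detected!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SelectionRules:
    """Peptide selection rules.

    Length limits are hard filters; the N-terminal residue and internal-motif
    rules are soft (recorded as penalties, never excluding) because real
    panels retain such peptides when nothing better exists.
    """

    max_length: int = 20
    min_length: int = 6
    forbidden_nterm: frozenset[str] = frozenset("CMWQ")
    penalized_motifs: tuple[str, ...] = ("DP", "DG", "NG", "QG")
    require_unique: bool = True
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not (self.max_length >= self.min_length >= 1):
            raise ValueError("require max_length >= min_length >= 1")


@dataclass
class CandidateScore:
    """Outcome of applying :class:`SelectionRules` to one candidate."""

    peptide: PanelPeptide
    hard_pass: bool
    penalties: list[str] = field(default_factory=list)
    observability: float = 0.0
    unique_in_proteome: bool | None = None


def _cleavage_sites(sequence: str) -> list[int]:
    # Positions i such that cleavage occurs between sequence[i-1] and
    # sequence[i]; trypsin cuts C-terminal to K/R unless followed by P.
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            sites.append(i)
    return sites


def digest_trypsin(
    sequence: str, missed_cleavages: int = 0
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest with KP/RP cleavage suppression.

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive
    coordinates.  At zero missed cleavages the products tile the input; with
    ``k`` missed cleavages every concatenation of up to ``k + 1`` adjacent
    fully tryptic fragments is also emitted, in order of position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {aa!r} at position {pos + 1}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    bounds = [0, *_cleavage_sites(sequence), len(sequence)]
    fragments = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    out: list[tuple[str, int, int]] = []
    for i, (lo, _) in enumerate(fragments):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            hi = fragments[j][1]
            out.append((sequence[lo:hi], lo + 1, hi))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def is_fully_tryptic(peptide: str) -> bool:
    """True when the peptide contains no internal cleavable K/R."""
    return not _cleavage_sites(peptide)


def apply_rules(
    candidates: Sequence[PanelPeptide],
    rules: SelectionRules | None = None,
    priors: Mapping[str, float] | None = None,
) -> list[CandidateScore]:
    """Score candidates against the selection rules.

    Never drops a candidate: hard length failures are flagged via
    ``hard_pass`` and soft rules accumulate in ``penalties``.  The result is
    sorted best-first by (hard_pass, fewest penalties, observability prior),
    with the sequence as a deterministic final tie-break.
    """
    rules = rules or SelectionRules()
    priors = priors or {}
    scored = []
    for pep in candidates:
        hard = rules.min_length <= len(pep) <= rules.max_length
        penalties = []
        if pep.sequence[0] in rules.forbidden_nterm:
            penalties.append("forbidden_nterm")
        for motif in rules.penalized_motifs:
            if motif in pep.sequence:
                penalties.append(f"motif:{motif}")
        scored.append(
            CandidateScore(
                peptide=pep,
                hard_pass=hard,
                penalties=penalties,
                observability=float(priors.get(pep.sequence, 0.0)),
            )
        )
    scored.sort(
        key=lambda s: (
            not s.hard_pass,
            len(s.penalties),
            -s.observability,
            s.peptide.sequence,
        )
    )
    return scored


def check_uniqueness(
    peptide: str,
    proteome: Mapping[str, str],
    il_equivalent: bool = False,
) -> int:
    """Count occurrences of ``peptide`` across a proteome, overlaps included.

    A proteotypic peptide occurs exactly once.  ``il_equivalent`` treats the
    isobaric leucine and isoleucine as interchangeable.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if not _VALID_RE.match(peptide):
        raise ValueError(f"invalid peptide {peptide!r}")
    needle = peptide.replace("I", "L") if il_equivalent else peptide
    count = 0
    for seq in proteome.values():
        hay = seq.replace("I", "L") if il_equivalent else seq
        start = 0
        while (idx := hay.find(needle, start)) != -1:
            count += 1
            start = idx + 1
    return count


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into {id: sequence}, stripping ``*`` stops."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).rstrip("*").upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _bundled_panel_path():
    return resources.files("seedmrm.data") / "table1_panel.tsv"


def load_panel(path=None) -> tuple[list[TargetProtein], list[PanelPeptide]]:
    """Load a panel TSV; with no path, the bundled 18-protein panel.

    Validates every row (residues, span arithmetic, controlled vocabularies)
    and that variant-group members share protein and coordinates.  Errors name
    the offending row.
    """
    src = path if path is not None else _bundled_panel_path()
    with resources.as_file(src) if path is None else _open_ctx(src) as fh:
        rows = list(csv.DictReader(_readlines(fh), delimiter="\t"))
    if not rows:
        raise ValueError("panel file contains no rows")

    proteins: dict[str, TargetProtein] = {}
    peptides: list[PanelPeptide] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            acc = row["accession"]
            if acc not in proteins:
                proteins[acc] = TargetProtein(
                    accession=acc,
                    name=row["protein_name"],
                    short_name=row["short_name"],
                    genome=row["genome"],
                    category=row["category"],
                )
            peptides.append(
                PanelPeptide(
                    protein=proteins[acc],
                    sequence=row["sequence"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    variant_group=row.get("variant_group") or None,
                    detected=row.get("detected") or None,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"panel row {i}: {exc}") from exc

    groups: dict[str, set[tuple[str, int, int]]] = {}
    for pep in peptides:
        if pep.variant_group:
            groups.setdefault(pep.variant_group, set()).add(
                (pep.protein.accession, pep.start, pep.end)
            )
    for name, spans in groups.items():
        if len(spans) != 1:
            raise ValueError(
                f"variant group {name!r} spans inconsistent coordinates {spans}"
            )
    return list(proteins.values()), peptides


def _open_ctx(path):
    return open(path, newline="")


def _readlines(fh) -> Iterable[str]:
    if hasattr(fh, "read_text"):  # importlib.resources Traversable
        return fh.read_text().splitlines()
    return fh


def peptides_by_protein(
    peptides: Sequence[PanelPeptide],
) -> dict[str, list[str]]:
    """Map protein short names to their panel peptide sequences."""
    out: dict[str, list[str]] = {}
    for pep in peptides:
        out.setdefault(pep.protein.short_name, []).append(pep.sequence)
    return out
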