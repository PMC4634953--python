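"""In-silico tryptic digestion and peptide mass arithmetic.

Implements the enzymatic and modification conventions used when searching
ancient bone collagen by mass spectrometry: trypsin/P cleavage (cut after
every K or R, including before proline), a configurable number of missed
cleavages, and the monoisotopic mass shifts of the modifications routinely
observed in degraded collagen — carbamidomethylation of cysteine (fixed,
from iodoacetamide alkylation), hydroxylation/oxidation of lysine, proline
and optionally methionine, and deamidation of asparagine/glutamine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from pyteomics import mass as _pymass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses (Da), from the standard amino-acid table.
RESIDUE_MASS = {aa: _pymass.std_aa_mass[aa] for aa in STANDARD_AA}

WATER_MONO = 18.0105646
PROTON_MASS = 1.007276

#: Monoisotopic modification deltas (Da). Full precision is used internally;
#: reports conventionally round these to +57.02, +15.99 and +0.98.
CARBAMIDOMETHYL_DELTA = 57.021464
OXIDATION_DELTA = 15.994915
DEAMIDATION_DELTA = 0.984016


class DigestError(ValueError):
    """Raised for sequences or modification sets that violate preconditions."""


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with coordinates in its parent sequence.

    ``start``/``end`` are 0-based half-open indices into the parent protein,
    so ``parent[start:end] == sequence``.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise DigestError("empty peptide sequence")
        if self.end - self.start != len(self.sequence):
            raise DigestError("peptide coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModificationSet:
    """Counts of post-translational modifications applied to one peptide.

    ``n_oxidation`` counts +15.994915 Da events on K/P (hydroxylation) and,
    when ``oxidize_met`` is enabled at validation time, on M as well — the
    two are isobaric and indistinguishable by mass. ``n_deamidation`` counts
    +0.984016 Da events on N/Q, and ``n_carbamidomethyl`` the fixed
    +57.021464 Da alkylation of C.
    """

    n_carbamidomethyl: int = 0
    n_oxidation: int = 0
    n_deamidation: int = 0

    def __post_init__(self):
        for n in (self.n_carbamidomethyl, self.n_oxidation, self.n_deamidation):
            if n < 0:
                raise DigestError("modification counts must be non-negative")

    @property
    def mass_delta(self) -> float:
        return (
            self.n_carbamidomethyl * CARBAMIDOMETHYL_DELTA
            + self.n_oxidation * OXIDATION_DELTA
            + self.n_deamidation * DEAMIDATION_DELTA
        )

    def validate_for(self, peptide: str, oxidize_met: bool = False) -> None:
        """Check each count against the number of eligible residues."""
        ox_targets = "KPM" if oxidize_met else "KP"
        eligible_ox = sum(peptide.count(a) for a in ox_targets)
        eligible_deam = peptide.count("N") + peptide.count("Q")
        eligible_cam = peptide.count("C")
        if self.n_carbamidomethyl > eligible_cam:
            raise DigestError(
                f"{self.n_carbamidomethyl} carbamidomethyl for {eligible_cam} cysteine(s)"
            )
        if self.n_oxidation > eligible_ox:
            raise DigestError(
                f"{self.n_oxidation} oxidation(s) for {eligible_ox} eligible residue(s) ({ox_targets})"
            )
        if self.n_deamidation > eligible_deam:
            raise DigestError(
                f"{self.n_deamidation} deamidation(s) for {eligible_deam} N/Q residue(s)"
            )

    def to_string(self) -> str:
        """Compact text form used in PSM tables, e.g. ``cam:1;ox:2;deam:1``."""
        parts = []
        if self.n_carbamidomethyl:
            parts.append(f"cam:{self.n_carbamidomethyl}")
        if self.n_oxidation:
            parts.append(f"ox:{self.n_oxidation}")
        if self.n_deamidation:
            parts.append(f"deam:{self.n_deamidation}")
        return ";".join(parts) if parts else "-"

    @classmethod
    def from_string(cls, text: str) -> "ModificationSet":
        text = (text or "").strip()
        if text in ("", "-"):
            return cls()
        kw = {"cam": 0, "ox": 0, "deam": 0}
        for part in text.split(";"):
            key, _, num = part.partition(":")
            key = key.strip().lower()
            if key not in kw:
                raise DigestError(f"unknown modification tag {key!r}")
            kw[key] = int(num)
        return cls(n_carbamidomethyl=kw["cam"], n_oxidation=kw["ox"], n_deamidation=kw["deam"])


NO_MODS = ModificationSet()


def _validate_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in STANDARD_AA:
            raise DigestError(
                f"non-standard residue {ch!r} at position {pos} (0-based); "
                "only the 20 standard amino acids are accepted"
            )


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin/P cuts: after every K or R.

    Unlike strict trypsin, the /P rule cleaves even when the next residue is
    proline. The C terminus is not a cleavage site.
    """
    return [i + 1 for i, ch in enumerate(sequence[:-1]) if ch in "KR"]


def tryptic_digest(sequence: str, max_missed: int = 0) -> list[Peptide]:
    """Digest ``sequence`` with trypsin/P allowing up to ``max_missed`` missed cleavages.

    Returns peptides ordered by start position then length; the 0-missed
    peptides tile the parent exactly. The C-terminal fragment is always
    emitted even without a trailing K/R.
    """
    if max_missed < 0:
        raise DigestError("max_missed must be >= 0")
    _validate_sequence(sequence)
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(sequence[start:end], start, end, missed_cleavages=j - i - 1)
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(peptide: str, mods: ModificationSet | None = None,
                 oxidize_met: bool = False) -> float:
    """Monoisotopic mass (Da) of a peptide with optional modifications.

    mass = sum of residue monoisotopic masses + one water + modification deltas.
    """
    _validate_sequence(peptide)
    mods = mods or NO_MODS
    mods.validate_for(peptide, oxidize_met=oxidize_met)
    return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER_MONO + mods.mass_delta


def mz_from_mass(mass: float, charge: int = 1) -> float:
    """m/z of a positively charged ion: (M + z*proton) / z."""
    if mass <= 0:
        raise DigestError("mass must be positive")
    if charge < 1:
        raise DigestError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def write_digest_tsv(peptides: list[Peptide], path, mods: ModificationSet | None = None) -> None:
    """Write a digest as TSV: peptide, start, end, missed cleavages, mass."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "start", "end", "missed_cleavages", "mass"])
        for p in peptides:
            w.writerow([p.sequence, p.start, p.end, p.missed_cleavages,
                        f"{peptide_mass(p.sequence, mods):.6f}"])
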