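"""Partial consensus sequence assembly from filtered peptide matches.

Ancient-protein sequencing recovers a patchwork of peptides over a reference
alignment rather than a complete chain. The conventions used here follow
standard palaeoproteomic practice: uncovered alignment sites are written X
(unknown residue), sites falling in reference indel columns are written ?
(no homologous residue expected), leucine/isoleucine cannot be distinguished
by the mass-spectrometric workflow so I/L calls are harmonised to the most
abundant of the two in each alignment column, and the two collagen chains
are concatenated through a single linker residue R into one character matrix.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .psm import PSM

logger = logging.getLogger(__name__)

UNKNOWN = "X"
INDEL_UNKNOWN = "?"
GAP = "-"
MISSING_CHARS = {UNKNOWN, INDEL_UNKNOWN, GAP}


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusSequence:
    """An aligned partial consensus for one taxon.

    ``residues`` is a string over the 20 amino acids plus X/?/- of fixed
    alignment length; ``support`` counts contributing peptides per site.
    """

    taxon: str
    residues: str
    support: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.support is None:
            self.support = np.zeros(len(self.residues), dtype=int)
        self.support = np.asarray(self.support, dtype=int)
        if len(self.support) != len(self.residues):
            raise ConsensusError("support vector length must match residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def determined_fraction(self) -> float:
        """Fraction of sites carrying an actual residue call (not X/?/-)."""
        n = sum(c not in MISSING_CHARS for c in self.residues)
        return n / len(self.residues) if self.residues else 0.0


def assemble_consensus(
    matches: list[PSM],
    alignment_length: int,
    taxon: str = "consensus",
) -> ConsensusSequence:
    """Place peptide matches onto the reference coordinate system.

    Every site covered by at least one peptide carries the residue those
    peptides imply; uncovered sites are X. When peptides disagree at a site
    the residue with the greatest summed PSM score wins; an exact score tie
    is left as X and logged, since no principled automated choice exists.
    Decoy PSMs are rejected outright.
    """
    if any(m.is_decoy for m in matches):
        raise ConsensusError("decoy PSMs must not enter consensus assembly")
    weights: list[dict] = [defaultdict(float) for _ in range(alignment_length)]
    support = np.zeros(alignment_length, dtype=int)
    for m in matches:
        if m.ref_start < 0 or m.ref_end > alignment_length:
            raise ConsensusError(
                f"peptide {m.peptide!r}@{m.ref_start} outside alignment of "
                f"length {alignment_length}"
            )
        for offset, residue in enumerate(m.peptide):
            site = m.ref_start + offset
            weights[site][residue] += m.score
            support[site] += 1
    residues = []
    for site, site_weights in enumerate(weights):
        if not site_weights:
            residues.append(UNKNOWN)
            continue
        best = max(site_weights.values())
        winners = sorted(r for r, w in site_weights.items() if w == best)
        if len(winners) > 1:
            logger.warning(
                "site %d: score tie between %s (weight %.3g); calling X",
                site, "/".join(winners), best,
            )
            residues.append(UNKNOWN)
        else:
            if len(site_weights) > 1:
                logger.info(
                    "site %d: conflicting calls %s resolved to %s by score weight",
                    site, dict(site_weights), winners[0],
                )
            residues.append(winners[0])
    return ConsensusSequence(taxon=taxon, residues="".join(residues), support=support)


def apply_reference_gaps(consensus: ConsensusSequence,
                         reference_column_has_gap: np.ndarray) -> ConsensusSequence:
    """Rewrite uncovered sites that are gap columns in the reference to '?'.

    The ? convention marks sites where other taxa carry an indel, so absence
    of a peptide there is expected rather than informative.
    """
    if len(reference_column_has_gap) != len(consensus):
        raise ConsensusError("gap mask length must match consensus length")
    out = [
        INDEL_UNKNOWN if (c == UNKNOWN and gap) else c
        for c, gap in zip(consensus.residues, reference_column_has_gap)
    ]
    return ConsensusSequence(consensus.taxon, "".join(out), consensus.support)


def normalize_isobaric(
    proteomic: dict[str, str],
    references: dict[str, str],
) -> dict[str, str]:
    """Harmonise I/L in proteomics-derived sequences column by column.

    At every alignment column containing both I and L across all sequences,
    each proteomics-derived I/L residue is replaced by whichever of the two
    is most abundant in that column (references included in the count);
    database-derived reference sequences are never altered. Exact ties keep
    the observed letter and are logged.
    """
    if not proteomic:
        return {}
    lengths = {len(s) for s in list(proteomic.values()) + list(references.values())}
    if len(lengths) != 1:
        raise ConsensusError("all sequences must have equal aligned length")
    (length,) = lengths
    out = {taxon: list(seq) for taxon, seq in proteomic.items()}
    all_seqs = list(proteomic.values()) + list(references.values())
    for col in range(length):
        column = [s[col] for s in all_seqs]
        n_i = column.count("I")
        n_l = column.count("L")
        if n_i == 0 or n_l == 0:
            continue
        if n_i == n_l:
            logger.warning("column %d: I/L tie (%d each); keeping observed letters", col, n_i)
            continue
        winner = "I" if n_i > n_l else "L"
        for taxon in out:
            if out[taxon][col] in ("I", "L"):
                out[taxon][col] = winner
    return {taxon: "".join(chars) for taxon, chars in out.items()}


def concatenate_chains(
    a1: ConsensusSequence, a2: ConsensusSequence, linker: str = "R"
) -> ConsensusSequence:
    """Concatenate the two collagen chains through a single linker residue."""
    if a1.taxon != a2.taxon:
        raise ConsensusError(
            f"cannot concatenate chains of different taxa: {a1.taxon!r} vs {a2.taxon!r}"
        )
    residues = a1.residues + linker + a2.residues
    support = np.concatenate([a1.support, [0], a2.support])
    return ConsensusSequence(a1.taxon, residues, support)


def _determined(a: str, b: str):
    return a not in MISSING_CHARS and b not in MISSING_CHARS


def count_variations(seq_a: str | ConsensusSequence, seq_b: str | ConsensusSequence) -> int:
    """Count columns where both sequences carry a determined residue and differ."""
    a = seq_a.residues if isinstance(seq_a, ConsensusSequence) else seq_a
    b = seq_b.residues if isinstance(seq_b, ConsensusSequence) else seq_b
    if len(a) != len(b):
        raise ConsensusError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if _determined(x, y) and x != y)


def count_confirmed_variations(
    specimen1: str | ConsensusSequence,
    specimen2: str | ConsensusSequence,
    other: str | ConsensusSequence,
) -> int:
    """Count substitutions replicated in both specimens of a fossil taxon.

    A site counts only when both specimen-level sequences show the same
    determined residue and it differs from the other taxon's determined
    residue — the "confirmed in both fossil replicates" convention.
    """
    s1 = specimen1.residues if isinstance(specimen1, ConsensusSequence) else specimen1
    s2 = specimen2.residues if isinstance(specimen2, ConsensusSequence) else specimen2
    o = other.residues if isinstance(other, ConsensusSequence) else other
    if not (len(s1) == len(s2) == len(o)):
        raise ConsensusError("all three sequences must have equal length")
    count = 0
    for x, y, z in zip(s1, s2, o):
        if _determined(x, y) and x == y and z not in MISSING_CHARS and x != z:
            count += 1
    return count


def variation_matrix(sequences: dict[str, str]) -> "pd.DataFrame":
    """Pairwise determined-site difference counts as a symmetric DataFrame."""
    import pandas as pd

    taxa = list(sequences)
    mat = np.zeros((len(taxa), len(taxa)), dtype=int)
    for i, ta in enumerate(taxa):
        for j, tb in enumerate(taxa):
            if i < j:
                mat[i, j] = mat[j, i] = count_variations(sequences[ta], sequences[tb])
    return pd.DataFrame(mat, index=taxa, columns=taxa)
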