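"""Target-decoy quality control for peptide-spectrum matches (PSMs).

Ancient-protein searches produce match lists contaminated by false positives.
The filtering strategy implemented here scores quality per analysis with the
decoy-based false discovery rate, then applies the highest-false-positive-score
(HFPS) rule: only target matches scoring strictly above the best decoy match
of that same analysis are retained. For extinct taxa sequenced from duplicate
specimens, only peptide matches replicated in both specimens enter the
consensus sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .digestion import ModificationSet

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match from a database search.

    ``ref_start`` is the 0-based start of the peptide in the reference
    alignment of its collagen chain (``chain_id``, typically COL1A1 or
    COL1A2). ``score`` is a search-engine ion score (Mascot-like, higher is
    better); ``is_decoy`` marks matches against the reversed/decoy database.
    """

    peptide: str
    score: float
    specimen_id: str
    chain_id: str
    ref_start: int
    is_decoy: bool = False
    mods: ModificationSet = field(default_factory=ModificationSet)

    def __post_init__(self):
        if self.score < 0:
            raise FilterError("PSM score must be non-negative")
        if self.ref_start < 0:
            raise FilterError("ref_start must be non-negative")

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.peptide)

    def identity_key(self, include_position: bool = True):
        if include_position:
            return (self.peptide, self.chain_id, self.ref_start)
        return (self.peptide, self.chain_id)


@dataclass
class FilterReport:
    """Per-analysis quality summary (one row per specimen/search)."""

    specimen_id: str
    fdr_percent: float
    hfps: float
    total_score: float
    n_matches: int
    n_unique_sequences: int
    coverage_percent: dict  # chain_id -> percent, plus "combined"

    def to_row(self) -> dict:
        row = {
            "specimen": self.specimen_id,
            "fdr_percent": round(self.fdr_percent, 2),
            "hfps": self.hfps,
            "total_score": round(self.total_score, 1),
            "n_matches": self.n_matches,
            "n_unique_sequences": self.n_unique_sequences,
        }
        for chain, pct in sorted(self.coverage_percent.items()):
            row[f"coverage_percent_{chain}"] = round(pct, 1)
        return row


def hfps(psms: list[PSM]) -> float:
    """Highest false positive score: the maximum score among decoy PSMs."""
    decoy_scores = [p.score for p in psms if p.is_decoy]
    if not decoy_scores:
        raise FilterError(
            "no decoy PSMs present: supply a decoy search or an explicit threshold"
        )
    return max(decoy_scores)


def filter_by_hfps(psms: list[PSM], threshold: float) -> list[PSM]:
    """Keep target PSMs scoring strictly above ``threshold``; order preserved."""
    if not (threshold == threshold and abs(threshold) != float("inf")):
        raise FilterError("threshold must be finite")
    kept = [p for p in psms if not p.is_decoy and p.score > threshold]
    if psms and not kept:
        logger.warning("HFPS filter at %.3g removed every target PSM", threshold)
    return kept


def fdr_percent(psms: list[PSM]) -> float:
    """Decoy-based false discovery rate: 100 * n_decoy / n_target."""
    n_decoy = sum(p.is_decoy for p in psms)
    n_target = sum(not p.is_decoy for p in psms)
    if n_target == 0:
        raise FilterError("FDR undefined with zero target PSMs")
    return 100.0 * n_decoy / n_target


def replicate_intersection(
    filtered_a: list[PSM],
    filtered_b: list[PSM],
    include_position: bool = True,
) -> list[PSM]:
    """Peptide matches replicated in both specimens of the same taxon.

    The identity key is (peptide sequence, chain, reference start) by
    default; modification state is deliberately ignored because diagenetic
    modifications vary between specimens. Set ``include_position=False`` to
    key on sequence+chain alone. Returns the matches of both specimens whose
    key occurs in both, preserving order (A's first).
    """
    specimens_a = {p.specimen_id for p in filtered_a}
    specimens_b = {p.specimen_id for p in filtered_b}
    if specimens_a and specimens_a == specimens_b:
        raise FilterError(
            f"both PSM lists come from specimen(s) {sorted(specimens_a)}: "
            "replicate intersection requires distinct specimens"
        )
    keys_a = {p.identity_key(include_position) for p in filtered_a}
    keys_b = {p.identity_key(include_position) for p in filtered_b}
    shared = keys_a & keys_b
    return [p for p in filtered_a + filtered_b if p.identity_key(include_position) in shared]


def coverage_percent(psms: list[PSM], reference_length: int) -> float:
    """Percent of reference positions covered by at least one peptide."""
    if reference_length <= 0:
        raise FilterError("reference_length must be positive")
    covered: set[int] = set()
    for p in psms:
        if p.ref_end > reference_length:
            raise FilterError(
                f"peptide {p.peptide!r} at {p.ref_start} extends past reference "
                f"end ({reference_length})"
            )
        covered.update(range(p.ref_start, p.ref_end))
    return 100.0 * len(covered) / reference_length


def make_filter_report(
    psms: list[PSM],
    chain_lengths: dict[str, int],
    threshold: float | None = None,
) -> tuple[FilterReport, list[PSM]]:
    """Apply the HFPS rule to one analysis and summarise it.

    ``threshold`` defaults to the analysis' own HFPS. Returns the report and
    the filtered target PSMs. FDR is computed over all supplied PSMs (the
    search engine's reported set), the remaining statistics over the
    filtered set, mirroring how per-analysis quality tables are reported.
    """
    if not psms:
        raise FilterError("empty PSM list")
    specimen_ids = {p.specimen_id for p in psms}
    if len(specimen_ids) != 1:
        raise FilterError(f"expected a single specimen, got {sorted(specimen_ids)}")
    thr = hfps(psms) if threshold is None else threshold
    kept = filter_by_hfps(psms, thr)
    coverage = {}
    total_len = 0
    for chain, length in chain_lengths.items():
        chain_psms = [p for p in kept if p.chain_id == chain]
        coverage[chain] = coverage_percent(chain_psms, length)
        total_len += length
    if chain_lengths:
        combined_hits = sum(
            coverage[c] * l / 100.0 for c, l in chain_lengths.items()
        )
        coverage["combined"] = 100.0 * combined_hits / total_len
    report = FilterReport(
        specimen_id=next(iter(specimen_ids)),
        fdr_percent=fdr_percent(psms),
        hfps=thr,
        total_score=sum(p.score for p in kept),
        n_matches=len(kept),
        n_unique_sequences=len({p.peptide for p in kept}),
        coverage_percent=coverage,
    )
    return report, kept


PSM_COLUMNS = [
    "peptide", "modifications", "score", "specimen_id", "chain_id",
    "ref_start", "is_decoy",
]


def read_psm_table(path) -> list[PSM]:
    """Read a tab-separated PSM table with the standard column header."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "modifications": str})
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise FilterError(f"PSM table {path} missing columns: {sorted(missing)}")
    psms = []
    for rec in df.itertuples(index=False):
        psms.append(
            PSM(
                peptide=rec.peptide,
                mods=ModificationSet.from_string(
                    "" if pd.isna(rec.modifications) else rec.modifications
                ),
                score=float(rec.score),
                specimen_id=str(rec.specimen_id),
                chain_id=str(rec.chain_id),
                ref_start=int(rec.ref_start),
                is_decoy=bool(rec.is_decoy),
            )
        )
    return psms


def write_psm_table(psms: list[PSM], path) -> None:
    rows = [
        {
            "peptide": p.peptide,
            "modifications": p.mods.to_string(),
            "score": p.score,
            "specimen_id": p.specimen_id,
            "chain_id": p.chain_id,
            "ref_start": p.ref_start,
            "is_decoy": p.is_decoy,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)
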