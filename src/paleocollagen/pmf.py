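"""MALDI peptide-mass-fingerprint comparison.

Collagen fingerprints from different taxa are compared without any sequence
interpretation: the N most intense peaks of each centroided spectrum are
selected and the number of peaks shared within a mass tolerance is counted.
Shared-peak counts shrink as amino-acid substitutions shift tryptic peptide
masses, so the statistic tracks sequence divergence at zero sequencing cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_INSTRUMENT_RANGE = (700.0, 3700.0)


class PeakListError(ValueError):
    pass


@dataclass
class PeakList:
    """A centroided MALDI fingerprint: (m/z, intensity) pairs, sorted by m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    instrument_range: tuple[float, float] = DEFAULT_INSTRUMENT_RANGE

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise PeakListError("m/z and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise PeakListError("intensities must be non-negative")
        lo, hi = self.instrument_range
        inside = (self.mz >= lo) & (self.mz <= hi)
        if not np.all(inside):
            logger.info("dropping %d peak(s) outside instrument range [%g, %g]",
                        int((~inside).sum()), lo, hi)
            self.mz, self.intensity = self.mz[inside], self.intensity[inside]
        order = np.argsort(self.mz, kind="stable")
        self.mz, self.intensity = self.mz[order], self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


def read_peaklist(path, instrument_range=DEFAULT_INSTRUMENT_RANGE) -> PeakList:
    """Read a two-column (m/z, intensity) whitespace/TSV peak list."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise PeakListError(f"{path}: expected two columns (m/z, intensity)")
    return PeakList(data[:, 0], data[:, 1], instrument_range=instrument_range)


def write_peaklist(pl: PeakList, path) -> None:
    np.savetxt(path, np.column_stack([pl.mz, pl.intensity]), fmt="%.6f\t%.4f")


def top_n_peaks(pl: PeakList, n: int = 100) -> PeakList:
    """The n most intense peaks, re-sorted by m/z.

    Intensity ties at the cutoff rank are broken toward lower m/z. If fewer
    than n peaks exist all are returned with a warning.
    """
    if n < 1:
        raise PeakListError("n must be >= 1")
    if len(pl) == 0:
        raise PeakListError("empty peak list")
    if len(pl) <= n:
        if len(pl) < n:
            logger.warning("peak list has only %d peaks (requested %d)", len(pl), n)
        return PeakList(pl.mz.copy(), pl.intensity.copy(), pl.instrument_range)
    # sort by (-intensity, m/z); pl is already m/z-sorted so a stable sort on
    # descending intensity realises the lower-m/z tie-break.
    order = np.argsort(-pl.intensity, kind="stable")[:n]
    keep = np.sort(order)
    return PeakList(pl.mz[keep], pl.intensity[keep], pl.instrument_range)


def _tol_da(mz_a: float, mz_b: float, tol: float, ppm: bool) -> float:
    if ppm:
        return tol * 1e-6 * 0.5 * (mz_a + mz_b)
    return tol


def shared_peak_count(a: PeakList, b: PeakList, tol: float = 0.2, ppm: bool = False) -> int:
    """Size of a one-to-one matching of peaks within ``tol``.

    Candidate pairs with |mz_a - mz_b| <= tol are matched greedily by
    ascending m/z distance, each peak used at most once. Greedy-by-distance
    makes the count symmetric and prevents one peak absorbing several.
    """
    if tol <= 0:
        raise PeakListError("tolerance must be positive")
    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            d = abs(mza - mzb)
            if d <= _tol_da(mza, mzb, tol, ppm):
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    count = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        count += 1
    return count


def pairwise_shared_matrix(
    peaklists: dict[str, PeakList],
    n: int = 100,
    tol: float = 0.2,
    ppm: bool = False,
) -> pd.DataFrame:
    """Shared-peak counts over all taxon pairs after top-n selection.

    The diagonal holds min(n, peaks available) for each taxon — a
    fingerprint always shares all of its selected peaks with itself.
    """
    if not peaklists:
        raise PeakListError("no peak lists supplied")
    selected = {t: top_n_peaks(pl, n) for t, pl in peaklists.items()}
    taxa = list(selected)
    mat = np.zeros((len(taxa), len(taxa)), dtype=int)
    for i, ta in enumerate(taxa):
        mat[i, i] = len(selected[ta])
        for j in range(i + 1, len(taxa)):
            c = shared_peak_count(selected[ta], selected[taxa[j]], tol=tol, ppm=ppm)
            mat[i, j] = mat[j, i] = c
    return pd.DataFrame(mat, index=taxa, columns=taxa)
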