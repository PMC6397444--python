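"""PSSM scanning of region sets and reverse cumulative score tabulation.

Every overlapping L-mer of every sequence is assigned a PSSM score; for
both-strand sets each start position yields two windows, the forward read
and the reverse-complement read of the same interval, counted
independently.  Windows containing N are skipped and excluded from the
window total; windows never span sequence boundaries.

Two comparators are used deliberately: cumulative counts use "greater or
equal" at each cutoff, while the ΔN excess statistic (montecarlo module)
uses strictly greater.  Floating-point comparisons at a cutoff are snapped
toward inclusion with a 1e-9 tolerance so analytically-zero scores count
at cutoff 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .alphabet import N_CODE, encode
from .genome_io import SequenceSet
from .motif_model import Pssm

SNAP = 1e-9


@dataclass
class CutoffGrid:
    """Strictly increasing score cutoffs (bits)."""

    cutoffs: np.ndarray

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if self.cutoffs.size == 0 or np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be non-empty, strictly increasing")

    @classmethod
    def default_for(cls, pssm: Pssm, start: float = 0.0) -> "CutoffGrid":
        """Integer-bit steps from ``start`` up to ceil(max_score)."""
        top = max(int(math.ceil(pssm.max_score)), int(start) + 1)
        return cls(np.arange(start, top + 1.0))

    def __len__(self):
        return self.cutoffs.size


@dataclass
class ReverseCumulativeDistribution:
    """count(c) = number of scored windows with S >= c, per cutoff c."""

    cutoffs: np.ndarray
    counts: np.ndarray
    n_windows: int
    max_observed: float

    def to_tsv(self, path, header: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header or {}).items():
                fh.write(f"# {k}: {v}\n")
            fh.write("cutoff\tcount\n")
            for c, n in zip(self.cutoffs, self.counts):
                fh.write(f"{c:g}\t{int(n)}\n")


@dataclass(frozen=True)
class Hit:
    """One window at or above a score threshold."""

    seq_name: str
    position: int  # 0-based start within the named sequence
    strand: str
    score: float
    window: str  # as read on the reported strand


def _window_scores_array(matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all windows of ``codes`` under a 4xL score matrix.

    Windows containing N (code 4) are returned as NaN so callers can drop
    or locate them; N contributes 0 to the raw sum before masking.
    """
    L = matrix.shape[1]
    m = codes.size - L + 1
    if m <= 0:
        return np.empty(0)
    padded = np.vstack([matrix, np.zeros((1, L))])  # row 4: N placeholder
    scores = np.zeros(m)
    for i in range(L):
        scores += padded[codes[i:i + m], i]
    is_n = (codes == N_CODE)
    if is_n.any():
        c = np.cumsum(is_n)
        n_in_window = c[L - 1:] - np.concatenate(([0], c[:-L]))
        scores[n_in_window > 0] = np.nan
    return scores


def _concat_codes(seqs: SequenceSet, L: int) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Concatenate entries with L-1 Ns between them (windows cannot straddle).

    Returns the padded code array and per-entry (offset, name) bookkeeping.
    """
    pad = np.full(L - 1, N_CODE, dtype=np.int8) if L > 1 else np.empty(0, dtype=np.int8)
    pieces: list[np.ndarray] = []
    offsets: list[tuple[int, str]] = []
    pos = 0
    for entry in seqs:
        if pieces:
            pieces.append(pad)
            pos += pad.size
        offsets.append((pos, entry.name))
        codes = encode(entry.sequence)
        pieces.append(codes)
        pos += codes.size
    if not pieces:
        return np.empty(0, dtype=np.int8), []
    return np.concatenate(pieces), offsets


def window_scores(pssm: Pssm, seqs: SequenceSet) -> np.ndarray:
    """All valid window scores of a region set (both strands if applicable)."""
    codes, _ = _concat_codes(seqs, pssm.length)
    fwd = _window_scores_array(pssm.s, codes)
    parts = [fwd[~np.isnan(fwd)]]
    if seqs.scan_mode == "both_strands":
        rev = _window_scores_array(pssm.rc_matrix(), codes)
        parts.append(rev[~np.isnan(rev)])
    return np.concatenate(parts) if parts else np.empty(0)


def rcd_from_scores(scores: np.ndarray, grid: CutoffGrid
                    ) -> ReverseCumulativeDistribution:
    """Tabulate S >= cutoff counts (1e-9 snap toward inclusion)."""
    finite = scores[np.isfinite(scores)]
    srt = np.sort(finite)
    idx = np.searchsorted(srt, grid.cutoffs - SNAP, side="left")
    counts = srt.size - idx
    max_obs = float(scores.max()) if scores.size else float("-inf")
    return ReverseCumulativeDistribution(
        grid.cutoffs.copy(), counts.astype(np.int64), int(scores.size), max_obs)


def scan(pssm: Pssm, seqs: SequenceSet, grid: CutoffGrid
         ) -> ReverseCumulativeDistribution:
    """Score every overlapping window of a region set and tabulate counts."""
    return rcd_from_scores(window_scores(pssm, seqs), grid)


def top_hits(pssm: Pssm, seqs: SequenceSet, threshold: float) -> list[Hit]:
    """All windows with S >= threshold, ordered by score desc, then
    sequence name, position, strand ('+' before '-')."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    L = pssm.length
    hits: list[Hit] = []
    for entry in seqs:
        codes = encode(entry.sequence)
        strands = [("+", pssm.s)]
        if entry.scan_mode == "both_strands":
            strands.append(("-", pssm.rc_matrix()))
        for strand, matrix in strands:
            scores = _window_scores_array(matrix, codes)
            ok = np.where(~np.isnan(scores) & (scores >= threshold - SNAP))[0]
            for pos in ok:
                text = entry.sequence[pos:pos + L]
                if strand == "-":
                    from .alphabet import revcomp
                    text = revcomp(text)
                hits.append(Hit(entry.name, int(pos), strand,
                                float(scores[pos]), text))
    hits.sort(key=lambda h: (-h.score, h.seq_name, h.position, h.strand))
    return hits


def hits_to_tsv(hits: Iterable[Hit], path, header: Optional[dict] = None,
                L: int = 0) -> None:
    """BED-compatible hit table: seq, start, end, strand, score, window."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("seq\tstart\tend\tstrand\tscore\twindow\n")
        for h in hits:
            end = h.position + (L or len(h.window))
            fh.write(f"{h.seq_name}\t{h.position}\t{end}\t{h.strand}"
                     f"\t{h.score:.6f}\t{h.window}\n")
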