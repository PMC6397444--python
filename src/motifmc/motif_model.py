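"""The motif model chain: count matrix -> probability matrix -> PSSM.

A binding-site motif of length L is summarised by a 4xL frequency matrix
{N_{a,i}} of letter counts over an aligned training set.  Adding a
pseudocount and normalising gives the probability matrix {p_{a,i}}; the
position-specific score matrix is the per-position log-odds against a
strand-symmetric background derived from the scanned genome's GC content,

    s_{a,i} = log2(p_{a,i} / q_a),

and an L-mer scores S = sum_i s_{a_i,i} (bits).  S = 0 means the window is
equally likely under the motif model and under the background.

Zero probabilities (possible with pseudocount 0) map to a -inf score
sentinel: any window containing one can never pass a finite cutoff.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import LETTERS, encode

_COLSUM_TOL = 1e-6


@dataclass
class TrainingSet:
    """Aligned equal-length binding-site sequences."""

    sites: list[str]

    def __post_init__(self):
        if not self.sites:
            raise ValueError("training set needs at least one site")
        L = len(self.sites[0])
        if any(len(s) != L for s in self.sites):
            raise ValueError("training-set sites must have equal length")
        self.sites = [s.upper() for s in self.sites]

    @property
    def length(self) -> int:
        return len(self.sites[0])

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class FrequencyMatrix:
    """4xL letter counts; rows ordered A, C, G, T.

    Column sums may be fractional for matrices downloaded as normalised
    frequencies; they must agree across columns.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4xL matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        sums = self.counts.sum(axis=0)
        if np.ptp(sums) > _COLSUM_TOL * max(1.0, sums.max()):
            raise ValueError("column sums differ across positions")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> float:
        return float(self.counts[:, 0].sum())


@dataclass
class ProbabilityMatrix:
    """4xL per-position letter probabilities (columns sum to 1)."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != 4:
            raise ValueError("p must be a 4xL matrix")
        if np.any(self.p < 0) or np.any(np.abs(self.p.sum(axis=0) - 1) > 1e-9):
            raise ValueError("columns must be probability distributions")

    @property
    def length(self) -> int:
        return self.p.shape[1]


@dataclass
class Background:
    """Strand-symmetric single-letter background: q_A=q_T, q_C=q_G from GC."""

    gc: float

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        at = (1.0 - self.gc) / 2.0
        gc = self.gc / 2.0
        return np.array([at, gc, gc, at])


@dataclass
class Pssm:
    """Log-odds score matrix in bits, with its background and metadata."""

    s: np.ndarray  # 4xL, may contain -inf
    background: Background
    n_sites: float = 0.0
    name: str = ""
    log_base: float = 2.0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)

    @property
    def length(self) -> int:
        return self.s.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.s.max(axis=0).sum())

    def rc_matrix(self) -> np.ndarray:
        """Score matrix that reads the reverse-complement strand of a window."""
        return self.s[::-1, ::-1]

    def consensus(self) -> str:
        return "".join(LETTERS[a] for a in self.s.argmax(axis=0))

    def to_json(self, path) -> None:
        obj = {
            "name": self.name,
            "length": self.length,
            "n_sites": self.n_sites,
            "log_base": self.log_base,
            "gc": self.background.gc,
            "max_score": self.max_score,
            "s": [[None if not np.isfinite(v) else v for v in row]
                  for row in self.s],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Pssm":
        with open(path) as fh:
            obj = json.load(fh)
        s = np.array([[-np.inf if v is None else v for v in row]
                      for row in obj["s"]])
        return cls(s, Background(obj["gc"]), obj.get("n_sites", 0.0),
                   obj.get("name", ""), obj.get("log_base", 2.0))


def counts_from_alignment(sites: TrainingSet) -> FrequencyMatrix:
    """Tally letter counts per motif position from an aligned site set."""
    codes = np.stack([encode(s) for s in sites.sites])
    if np.any(codes > 3):
        raise ValueError("training sites must be over {A,C,G,T}")
    counts = np.zeros((4, sites.length))
    for a in range(4):
        counts[a] = (codes == a).sum(axis=0)
    return FrequencyMatrix(counts)


def probabilities(freq: FrequencyMatrix, pseudocount: float = 0.5
                  ) -> ProbabilityMatrix:
    """Convert counts to probabilities: p = (N + c) / (n_sites + 4c)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    total = freq.counts.sum(axis=0) + 4.0 * pseudocount
    if np.any(total == 0):
        raise ValueError("zero column total with pseudocount 0")
    return ProbabilityMatrix((freq.counts + pseudocount) / total)


def background_from_genome(genome) -> Background:
    """GC-content background of the scanned genome (N excluded)."""
    codes = genome.codes() if hasattr(genome, "codes") else encode(str(genome))
    counts = np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome has no A/C/G/T characters")
    return Background(gc=float(counts[1] + counts[2]) / total)


def build_pssm(prob: ProbabilityMatrix, bg: Background, *,
               n_sites: float = 0.0, name: str = "",
               log_base: float = 2.0) -> Pssm:
    """Per-position log-odds scores; zero probabilities become -inf."""
    q = bg.q
    if np.any(q == 0):
        raise ValueError("background probabilities must be positive")
    with np.errstate(divide="ignore"):
        s = np.log(prob.p / q[:, None]) / np.log(log_base)
    return Pssm(s, bg, n_sites=n_sites, name=name, log_base=log_base)


def pssm_from_sites(sites: TrainingSet, bg: Background, *,
                    pseudocount: float = 0.5, name: str = "") -> Pssm:
    """Convenience: alignment -> counts -> probabilities -> PSSM."""
    freq = counts_from_alignment(sites)
    return build_pssm(probabilities(freq, pseudocount), bg,
                      n_sites=sites.n_sites, name=name)


def pssm_from_matrix(freq: FrequencyMatrix, bg: Background, *,
                     pseudocount: float = 0.5, name: str = "") -> Pssm:
    return build_pssm(probabilities(freq, pseudocount), bg,
                      n_sites=freq.n_sites, name=name)


def information_content(prob: ProbabilityMatrix) -> float:
    """Total motif information content in bits: sum_i (2 - H_i).

    Equals the summed letter heights of the motif's sequence logo.  When
    reporting a motif's IC, build ``prob`` from raw frequencies
    (pseudocount 0), the logo convention.
    """
    p = prob.p
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + plogp.sum(axis=0)).sum())


def column_heights(prob: ProbabilityMatrix) -> np.ndarray:
    """Per-column, per-letter logo heights: p_{a,i} * (2 - H_i), 4xL."""
    p = prob.p
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return p * ic[None, :]


def score(pssm: Pssm, lmer: str) -> float:
    """PSSM score of one L-mer; -inf if it contains N or a zero-prob letter."""
    codes = encode(lmer)
    if codes.size != pssm.length:
        raise ValueError(
            f"L-mer length {codes.size} != motif length {pssm.length}")
    if np.any(codes > 3):
        return float("-inf")
    return float(pssm.s[codes, np.arange(pssm.length)].sum())


def reduce_training_set(sites: TrainingSet, n: int, *,
                        pseudocount: float = 0.5) -> TrainingSet:
    """Keep the n sites scoring highest under the full-set motif model.

    Sites are scored with the PSSM built from the complete set (uniform
    background, so the ranking is by motif-model likelihood); ties are
    broken by input order.
    """
    if not 1 <= n <= sites.n_sites:
        raise ValueError("n must be in [1, n_sites]")
    model = pssm_from_sites(sites, Background(0.5), pseudocount=pseudocount)
    scores = np.array([score(model, s) for s in sites.sites])
    keep = sorted(np.argsort(-scores, kind="stable")[:n])
    return TrainingSet([sites.sites[i] for i in keep])


_ROW_RE = re.compile(r"^\s*>?\s*([ACGTacgt])\s*[|:]?\s*([0-9.\seE+-]+?)\s*$")


def read_matrix(path, dialect: str = "plain4row",
                name: Optional[str] = None) -> FrequencyMatrix:
    """Read a frequency matrix from a text file.

    dialect 'plain4row': four whitespace-separated numeric rows in A,C,G,T
    order (row labels optional).  dialect 'regulondb': one or more named
    blocks, each with labeled A/C/G/T rows (RegulonDB PSSMSet style);
    ``name`` selects the block (substring match, case-insensitive), default
    first block.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "plain4row":
        rows = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _ROW_RE.match(line)
            fields = m.group(2).split() if m else line.split()
            rows.append([float(x) for x in fields])
        if len(rows) != 4:
            raise ValueError(f"expected 4 numeric rows, found {len(rows)}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("rows have unequal lengths")
        return FrequencyMatrix(np.array(rows))
    if dialect == "regulondb":
        return _read_regulondb(lines, name)
    raise ValueError(f"unknown matrix dialect {dialect!r}")


def _read_regulondb(lines: Sequence[str], name: Optional[str]
                    ) -> FrequencyMatrix:
    blocks: list[tuple[str, dict[str, list[float]]]] = []
    header = ""
    current: dict[str, list[float]] = {}
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        m = _ROW_RE.match(stripped)
        if m:
            letter = m.group(1).upper()
            current[letter] = [float(x) for x in m.group(2).split()]
            if len(current) == 4:
                blocks.append((header, current))
                current = {}
        else:
            if current:  # malformed partial block; reset
                current = {}
            header = stripped.lstrip(">#").strip().rstrip(":")
    if not blocks:
        raise ValueError("no A/C/G/T matrix block found")
    if name is None:
        chosen = blocks[0][1]
    else:
        matches = [b for h, b in blocks if name.lower() in h.lower()]
        if not matches:
            raise KeyError(f"no matrix block matching {name!r}")
        chosen = matches[0]
    rows = [chosen[a] for a in "ACGT"]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows have unequal lengths")
    counts = np.array(rows)
    # matrices distributed as normalised frequencies: keep as-is (column
    # sums ~1); probabilities() handles fractional totals
    return FrequencyMatrix(counts)
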