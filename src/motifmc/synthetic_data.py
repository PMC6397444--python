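"""Synthetic annotated bacterial chromosomes with optional planted sites.

The generator emulates the structure the null models assume: alternating
protein-coding genes and intergenic regions.  Genes start with ATG, end
with a stop codon, draw interior codons from a codon-usage table (biased
or GC-derived) and are assigned a strand; intergenic text follows a
first-order dinucleotide chain (biased or GC-derived).  Binding sites can
be planted at known positions by substitution, so every pipeline stage is
testable against exact ground truth without downloading real genomes.

The default spec is a miniature E. coli-like chromosome: 200 genes of
100-500 codons (mean 300), intergenic gaps of 20-220 nt (mean 120), GC
0.51 — small enough for minutes-scale simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import LETTERS, decode, encode, revcomp, revcomp_codes
from .genome_io import CdsFeature, GenomeRecord, Segment, SegmentPartition
from .motif_model import Background, ProbabilityMatrix, TrainingSet
from .randomizer import CODONS, _CODON_BASES

STOP_CODONS = ("TAA", "TAG", "TGA")
_STOP_IDX = np.array([CODONS.index(c) for c in STOP_CODONS])
_ATG_IDX = CODONS.index("ATG")


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic chromosome."""

    n_genes: int = 200
    gene_codons_min: int = 100
    gene_codons_max: int = 500
    ig_len_min: int = 20
    ig_len_max: int = 220
    gc: float = 0.51
    minus_strand_fraction: float = 0.5
    codon_usage: Optional[np.ndarray] = None  # (64,) weights; None -> from GC
    ig_transition: Optional[np.ndarray] = None  # (4,4); None -> i.i.d. from GC
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.gene_codons_min < 2:
            raise ValueError("need n_genes >= 0 and genes of >= 2 codons "
                             "(start + stop)")
        if self.gene_codons_max < self.gene_codons_min:
            raise ValueError("gene_codons_max < gene_codons_min")
        if self.ig_len_min < 1 or self.ig_len_max < self.ig_len_min:
            raise ValueError("bad intergenic length range")
        if not (0 <= self.gc <= 1 and 0 <= self.minus_strand_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            for key in ("n_genes", "gene_codons_min", "gene_codons_max",
                        "ig_len_min", "ig_len_max", "gc",
                        "minus_strand_fraction", "seed"):
                fh.write(f"{key} = {getattr(self, key)}\n")


def gc_base_probs(gc: float) -> np.ndarray:
    return Background(gc).q


def gc_codon_table(gc: float) -> np.ndarray:
    """Codon weights as independent products of GC-derived base probabilities."""
    p = gc_base_probs(gc)
    w = (p[_CODON_BASES[:, 0]] * p[_CODON_BASES[:, 1]] * p[_CODON_BASES[:, 2]])
    return w / w.sum()


def biased_codon_table(gc: float = 0.51, gc3_shift: float = 0.25,
                       sharpness: float = 2.0) -> np.ndarray:
    """A strongly biased codon table mimicking translational preference.

    Third-codon positions are pushed toward G/C by ``gc3_shift`` and the
    whole table is sharpened (weights raised to ``sharpness``), producing
    the kind of codon usage that the 'm1c1' null reproduces and the
    Bernoulli nulls miss.
    """
    p = gc_base_probs(gc)
    p3 = gc_base_probs(min(1.0, gc + gc3_shift))
    w = (p[_CODON_BASES[:, 0]] * p[_CODON_BASES[:, 1]] * p3[_CODON_BASES[:, 2]])
    w = w ** sharpness
    return w / w.sum()


def at_stacking_ig_transition(gc: float = 0.40, boost: float = 2.5
                              ) -> np.ndarray:
    """Intergenic dinucleotide bias: A/T runs (AA, TT, AT, TA) enriched."""
    p = gc_base_probs(gc)
    t = np.tile(p, (4, 1))
    for a in (0, 3):
        for b in (0, 3):
            t[a, b] *= boost
    return t / t.sum(axis=1, keepdims=True)


def _interior_codon_probs(table: np.ndarray) -> np.ndarray:
    w = table.copy().astype(float)
    w[_STOP_IDX] = 0.0  # gene interiors exclude stops so CDS are well-formed
    if w.sum() == 0:
        raise ValueError("codon table has mass only on stop codons")
    return w / w.sum()


def _stop_probs(table: np.ndarray) -> np.ndarray:
    w = table[_STOP_IDX].astype(float)
    if w.sum() == 0:
        w = np.ones(3)
    return w / w.sum()


def _sample_ig(length: int, base_p: np.ndarray, trans: Optional[np.ndarray],
               rng: np.random.Generator) -> np.ndarray:
    if trans is None:
        return rng.choice(4, size=length, p=base_p).astype(np.int8)
    out = np.empty(length, dtype=np.int8)
    state = rng.choice(4, p=base_p)
    out[0] = state
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        state = int(np.searchsorted(cum[state], u[t] * cum[state, -1],
                                    side="right"))
        state = min(state, 3)
        out[t] = state
    return out


def make_genome(spec: SyntheticGenomeSpec,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[GenomeRecord, SegmentPartition]:
    """Generate a chromosome and its ground-truth partition.

    Layout: ig_0 gene_1 ig_1 ... gene_n ig_n.  Each gene is
    ATG + interior codons + stop, reverse-complemented into genome
    coordinates when assigned to the minus strand.
    """
    rng = rng or np.random.default_rng(spec.seed)
    table = spec.codon_usage if spec.codon_usage is not None \
        else gc_codon_table(spec.gc)
    interior_p = _interior_codon_probs(np.asarray(table, dtype=float))
    stop_p = _stop_probs(np.asarray(table, dtype=float))
    base_p = gc_base_probs(spec.gc)

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    features: list[CdsFeature] = []
    pos = 0

    def add_ig():
        nonlocal pos
        length = int(rng.integers(spec.ig_len_min, spec.ig_len_max + 1))
        pieces.append(_sample_ig(length, base_p, spec.ig_transition, rng))
        segments.append(Segment(pos, pos + length, "intergenic"))
        pos += length

    add_ig()
    for g in range(spec.n_genes):
        n_codons = int(rng.integers(spec.gene_codons_min,
                                    spec.gene_codons_max + 1))
        interior = rng.choice(64, size=n_codons - 2, p=interior_p)
        stop = _STOP_IDX[rng.choice(3, p=stop_p)]
        cods = np.concatenate(([_ATG_IDX], interior, [stop]))
        sense = _CODON_BASES[cods].reshape(-1).astype(np.int8)
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        text = revcomp_codes(sense) if strand == "-" else sense
        pieces.append(text)
        start, end = pos, pos + sense.size
        segments.append(Segment(start, end, "gene", strand, g))
        features.append(CdsFeature(start, end, strand,
                                   label=f"sg_{g + 1:04d}"))
        pos = end
        add_ig()

    genome = GenomeRecord(id="synthetic_chromosome",
                          sequence=decode(np.concatenate(pieces)),
                          features=features)
    return genome, SegmentPartition(segments, pos)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted binding site (genome coordinates)."""

    start: int
    end: int
    strand: str  # strand on which the site text reads forward
    sequence: str  # the site as planted (reads on `strand`)
    region_class: str


@dataclass
class PlantSpec:
    """What to plant and where."""

    k: int
    motif: ProbabilityMatrix
    consensus_only: bool = True
    region_class: str = "intergenic"  # intergenic | gene_coding | gene_template
    seed: int = 0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.region_class not in ("intergenic", "gene_coding",
                                     "gene_template"):
            raise ValueError(f"bad region class {self.region_class!r}")


def _sample_site(plant: PlantSpec, rng: np.random.Generator) -> str:
    p = plant.motif.p
    if plant.consensus_only:
        codes = p.argmax(axis=0)
    else:
        codes = np.array([rng.choice(4, p=p[:, i] / p[:, i].sum())
                          for i in range(p.shape[1])])
    return "".join(LETTERS[c] for c in codes)


def plant_sites(genome: GenomeRecord, partition: SegmentPartition,
                plant: PlantSpec) -> tuple[GenomeRecord, list[PlantedSite]]:
    """Overwrite k non-overlapping stretches with motif sites.

    Substitution keeps every coordinate stable: segment boundaries and the
    feature table are untouched.  For intergenic plants the strand is
    random; for gene classes the site is oriented so that it reads
    forward on the gene's coding (gene_coding) or template
    (gene_template) strand.
    """
    rng = np.random.default_rng(plant.seed)
    L = plant.motif.length
    target_klass = ("intergenic" if plant.region_class == "intergenic"
                    else "gene")
    candidates: list[tuple[int, str]] = []  # (genome start, gene strand)
    for seg in partition.by_class(target_klass):
        for s in range(seg.start, seg.end - L + 1):
            candidates.append((s, seg.strand or "+"))
    rng.shuffle(candidates)
    chosen: list[tuple[int, str]] = []
    occupied: list[tuple[int, int]] = []
    for s, gstrand in candidates:
        if len(chosen) == plant.k:
            break
        if any(s < e0 and s + L > s0 for s0, e0 in occupied):
            continue
        chosen.append((s, gstrand))
        occupied.append((s, s + L))
    if len(chosen) < plant.k:
        raise ValueError(
            f"cannot place {plant.k} non-overlapping {L}-mers in "
            f"{plant.region_class} regions")

    seq = list(genome.sequence)
    planted: list[PlantedSite] = []
    for s, gstrand in sorted(chosen):
        site = _sample_site(plant, rng)
        if plant.region_class == "intergenic":
            strand = "+" if rng.random() < 0.5 else "-"
        elif plant.region_class == "gene_coding":
            strand = gstrand
        else:  # gene_template: opposite of the coding strand
            strand = "-" if gstrand == "+" else "+"
        text = site if strand == "+" else revcomp(site)
        seq[s:s + L] = text
        planted.append(PlantedSite(s, s + L, strand, site,
                                   plant.region_class))
    new_genome = GenomeRecord(genome.id, "".join(seq), genome.circular,
                              list(genome.features))
    return new_genome, planted


def planted_to_tsv(sites: list[PlantedSite], path) -> None:
    """BED-compatible ground-truth table of planted sites."""
    with open(path, "w") as fh:
        fh.write("#start\tend\tstrand\tregion_class\tsequence\n")
        for s in sites:
            fh.write(f"{s.start}\t{s.end}\t{s.strand}\t{s.region_class}"
                     f"\t{s.sequence}\n")


def synthetic_motif(length: int, total_ic: float,
                    consensus: Optional[str] = None) -> ProbabilityMatrix:
    """A motif with uniform per-column information content.

    Each column puts probability mass ``p`` on the consensus letter and
    (1-p)/3 on the rest, with p solved so the column IC is
    ``total_ic / length`` bits.  Useful for planting experiments where the
    motif's strength must be controlled exactly.
    """
    if not 0 < total_ic <= 2 * length:
        raise ValueError("total_ic must be in (0, 2L]")
    target = total_ic / length

    def col_ic(p: float) -> float:
        rest = (1.0 - p) / 3.0
        h = -(p * np.log2(p) + (3 * rest * np.log2(rest) if rest > 0 else 0.0))
        return 2.0 - h

    lo, hi = 0.25 + 1e-12, 1.0 - 1e-12
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if col_ic(mid) < target:
            lo = mid
        else:
            hi = mid
    p = (lo + hi) / 2.0
    letters = consensus or "".join(LETTERS[i % 4] for i in range(length))
    if len(letters) != length:
        raise ValueError("consensus length mismatch")
    mat = np.full((4, length), (1.0 - p) / 3.0)
    for i, ch in enumerate(letters.upper()):
        mat[LETTERS.index(ch), i] = p
    mat /= mat.sum(axis=0, keepdims=True)
    return ProbabilityMatrix(mat)


def training_set_from_motif(motif: ProbabilityMatrix, n_sites: int,
                            rng: np.random.Generator) -> TrainingSet:
    """Sample an aligned training set from a probability matrix."""
    sites = []
    for _ in range(n_sites):
        codes = [rng.choice(4, p=motif.p[:, i]) for i in range(motif.length)]
        sites.append("".join(LETTERS[c] for c in codes))
    return TrainingSet(sites)
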