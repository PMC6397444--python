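"""Genome randomization under three null models: 'b', 'bb', 'm1c1'.

'b'    — one genome-wide Bernoulli model: reproduces only overall GC
         content (the classic homogeneous null).
'bb'   — per-segment Bernoulli: each gene (on its sense strand) and each
         intergenic segment gets its own letter composition, so gene-scale
         compositional heterogeneity and coding/template strand asymmetry
         are preserved.
'm1c1' — each intergenic (and unmodeled) segment is a first-order Markov
         chain on the nucleotide alphabet; each gene is a first-order
         chain on the codon alphabet in which the next codon's probability
         is conditioned on the last base of the previous codon.  This
         additionally reproduces dinucleotide biases and codon usage,
         including dinucleotides spanning adjacent codons.

Models are generative (segments are re-sampled, not shuffled): original
composition is matched in expectation.  Sampled genomes keep the original
length, segment frame, strand assignment and feature table byte-for-byte;
only the residues change, and the output alphabet is {A,C,G,T} (positions
that were N in the input are regenerated from the fitted model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .alphabet import LETTERS, decode, encode, revcomp_codes
from .genome_io import GenomeRecord, Segment, SegmentPartition

MODEL_KINDS = ("b", "bb", "m1c1")

CODONS = tuple(a + b + c for a in LETTERS for b in LETTERS for c in LETTERS)
# codon index -> its three base codes / its last base code
_CODON_BASES = np.array([[LETTERS.index(ch) for ch in c] for c in CODONS],
                        dtype=np.int8)
_CODON_LAST = _CODON_BASES[:, 2].astype(np.int64)

DEFAULT_ALPHA_NUC = 0.1
DEFAULT_ALPHA_CODON = 0.01


@dataclass
class BernoulliModel:
    """I.i.d. letters with fixed probabilities."""

    p: np.ndarray  # (4,)


@dataclass
class NucMarkovModel:
    """First-order nucleotide chain: initial distribution + 4x4 transitions."""

    initial: np.ndarray  # (4,)
    transition: np.ndarray  # (4,4), rows sum to 1


@dataclass
class CodonChainModel:
    """First-order codon chain conditioned on the previous codon's last base."""

    marginal: np.ndarray  # (64,) codon frequencies of the gene
    transition: np.ndarray  # (4,64): P(next codon | last base of previous)
    n_codons: int


@dataclass
class VerbatimModel:
    """Single-letter (or otherwise unfittable) segment copied as-is."""

    codes: np.ndarray


SegmentModel = Union[BernoulliModel, NucMarkovModel, CodonChainModel,
                     VerbatimModel]


@dataclass
class GenomeNullModel:
    """A fitted null model bound to one genome's segment frame."""

    kind: str
    genome: GenomeRecord
    partition: SegmentPartition
    global_model: Optional[BernoulliModel] = None
    segment_models: list[SegmentModel] = field(default_factory=list)
    alpha_nuc: float = DEFAULT_ALPHA_NUC
    alpha_codon: float = DEFAULT_ALPHA_CODON

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        obj = {"kind": self.kind, "genome": self.genome.id,
               "alpha_nuc": self.alpha_nuc, "alpha_codon": self.alpha_codon}
        if self.global_model is not None:
            obj["global"] = arr(self.global_model.p)
        segs = []
        for seg, model in zip(self.partition, self.segment_models):
            d = {"start": seg.start, "end": seg.end, "klass": seg.klass,
                 "model": type(model).__name__}
            if isinstance(model, BernoulliModel):
                d["p"] = arr(model.p)
            elif isinstance(model, NucMarkovModel):
                d["initial"] = arr(model.initial)
                d["transition"] = arr(model.transition)
            elif isinstance(model, CodonChainModel):
                d["marginal"] = arr(model.marginal)
                d["transition"] = arr(model.transition)
                d["n_codons"] = model.n_codons
            segs.append(d)
        obj["segments"] = segs
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _letter_probs(codes: np.ndarray) -> np.ndarray:
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def _sense_codes(genome_codes: np.ndarray, seg: Segment) -> np.ndarray:
    codes = genome_codes[seg.start:seg.end]
    return revcomp_codes(codes) if seg.strand == "-" else codes


def _fit_nuc_markov(codes: np.ndarray, alpha: float) -> NucMarkovModel:
    counts = np.full((4, 4), alpha, dtype=float)
    valid = codes < 4
    a, b = codes[:-1], codes[1:]
    ok = valid[:-1] & valid[1:]
    np.add.at(counts, (a[ok].astype(np.int64), b[ok].astype(np.int64)), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return NucMarkovModel(_letter_probs(codes), counts / rows)


def _gene_codon_indices(sense: np.ndarray) -> np.ndarray:
    trip = sense.reshape(-1, 3).astype(np.int64)
    if np.any(trip > 3):
        # N inside a gene: substitute the gene's commonest letter so the
        # codon alphabet stays defined (N positions are regenerated anyway)
        fill = int(np.argmax(_letter_probs(sense)))
        trip = np.where(trip > 3, fill, trip)
    return trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]


def _fit_codon_chain(sense: np.ndarray, alpha: float) -> CodonChainModel:
    cods = _gene_codon_indices(sense)
    marginal = np.bincount(cods, minlength=64).astype(float)
    marginal /= marginal.sum()
    counts = np.full((4, 64), alpha, dtype=float)
    if cods.size > 1:
        prev_last = _CODON_LAST[cods[:-1]]
        np.add.at(counts, (prev_last, cods[1:]), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return CodonChainModel(marginal, counts / rows, int(cods.size))


def fit(genome: GenomeRecord, partition: SegmentPartition, kind: str, *,
        alpha_nuc: float = DEFAULT_ALPHA_NUC,
        alpha_codon: float = DEFAULT_ALPHA_CODON) -> GenomeNullModel:
    """Fit a null model of the requested kind to one genome."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    codes = genome.codes()
    model = GenomeNullModel(kind, genome, partition,
                            alpha_nuc=alpha_nuc, alpha_codon=alpha_codon)
    if kind == "b":
        model.global_model = BernoulliModel(_letter_probs(codes))
        return model
    for seg in partition:
        seg_codes = (_sense_codes(codes, seg) if seg.klass == "gene"
                     else codes[seg.start:seg.end])
        if seg.length == 1:
            model.segment_models.append(VerbatimModel(seg_codes.copy()))
        elif kind == "bb":
            model.segment_models.append(BernoulliModel(_letter_probs(seg_codes)))
        elif seg.klass == "gene":
            model.segment_models.append(_fit_codon_chain(seg_codes, alpha_codon))
        else:
            model.segment_models.append(_fit_nuc_markov(seg_codes, alpha_nuc))
    return model


# ---------------------------------------------------------------------------
# sampling


def _sample_iid(p_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row of a stack of 4-letter distributions."""
    cum = np.cumsum(p_rows, axis=1)
    u = rng.random(p_rows.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1).astype(np.int8)


def _sample_chains(initial: np.ndarray, cum_trans: np.ndarray,
                   lengths: np.ndarray, rng: np.random.Generator
                   ) -> list[np.ndarray]:
    """Sample many independent 4-state chains in parallel.

    initial: (n,4); cum_trans: (n,4,4) cumulative rows; lengths: (n,).
    Returns one int8 array per chain.
    """
    n = lengths.size
    max_len = int(lengths.max())
    out = np.empty((n, max_len), dtype=np.int8)
    state = _sample_iid(initial, rng).astype(np.int64)
    out[:, 0] = state
    idx = np.arange(n)
    for t in range(1, max_len):
        rows = cum_trans[idx, state]  # (n,4)
        u = rng.random(n) * rows[:, -1]
        state = (rows < u[:, None]).sum(axis=1)
        out[:, t] = state
    return [out[i, :lengths[i]] for i in range(n)]


def _sample_codon_chains(marginals: np.ndarray, cum_trans: np.ndarray,
                         n_codons: np.ndarray, rng: np.random.Generator
                         ) -> list[np.ndarray]:
    """Sample many codon chains in parallel; returns base-code arrays.

    marginals: (g,64); cum_trans: (g,4,64) cumulative over codons;
    n_codons: (g,).
    """
    g = n_codons.size
    max_c = int(n_codons.max())
    cods = np.empty((g, max_c), dtype=np.int16)
    cum_marg = np.cumsum(marginals, axis=1)
    u = rng.random(g) * cum_marg[:, -1]
    cur = (cum_marg < u[:, None]).sum(axis=1)
    cods[:, 0] = cur
    idx = np.arange(g)
    for t in range(1, max_c):
        rows = cum_trans[idx, _CODON_LAST[cur]]  # (g,64)
        u = rng.random(g) * rows[:, -1]
        cur = (rows < u[:, None]).sum(axis=1)
        cods[:, t] = cur
    return [_CODON_BASES[cods[i, :n_codons[i]]].reshape(-1)
            for i in range(g)]


def sample_codes(model: GenomeNullModel, rng: np.random.Generator
                 ) -> np.ndarray:
    """Sample one randomized genome as an int8 code array over {A,C,G,T}."""
    part = model.partition
    n = part.genome_length
    out = np.empty(n, dtype=np.int8)
    if model.kind == "b":
        if model.global_model is None:
            raise RuntimeError("model not fitted")
        cum = np.cumsum(model.global_model.p)
        u = rng.random(n) * cum[-1]
        out[:] = np.searchsorted(cum, u, side="right").astype(np.int8)
        return out
    if len(model.segment_models) != len(part.segments):
        raise RuntimeError("model not fitted")

    # group segments by model type for vectorized sampling
    bern_idx, markov_idx, codon_idx = [], [], []
    for i, m in enumerate(model.segment_models):
        if isinstance(m, VerbatimModel):
            seg = part.segments[i]
            text = m.codes
            if seg.klass == "gene" and seg.strand == "-":
                text = revcomp_codes(text)
            out[seg.start:seg.end] = np.where(text > 3, 0, text)
        elif isinstance(m, BernoulliModel):
            bern_idx.append(i)
        elif isinstance(m, NucMarkovModel):
            markov_idx.append(i)
        else:
            codon_idx.append(i)

    def _place(i: int, sense: np.ndarray) -> None:
        seg = part.segments[i]
        if seg.klass == "gene" and seg.strand == "-":
            sense = revcomp_codes(sense)
        out[seg.start:seg.end] = sense

    if bern_idx:
        lengths = np.array([part.segments[i].length for i in bern_idx])
        probs = np.stack([model.segment_models[i].p for i in bern_idx])
        per_pos = np.repeat(probs, lengths, axis=0)
        draws = _sample_iid(per_pos, rng)
        splits = np.cumsum(lengths)[:-1]
        for i, chunk in zip(bern_idx, np.split(draws, splits)):
            _place(i, chunk)
    if markov_idx:
        lengths = np.array([part.segments[i].length for i in markov_idx])
        init = np.stack([model.segment_models[i].initial for i in markov_idx])
        cum_t = np.cumsum(
            np.stack([model.segment_models[i].transition for i in markov_idx]),
            axis=2)
        for i, chunk in zip(markov_idx,
                            _sample_chains(init, cum_t, lengths, rng)):
            _place(i, chunk)
    if codon_idx:
        ncod = np.array([model.segment_models[i].n_codons for i in codon_idx])
        marg = np.stack([model.segment_models[i].marginal for i in codon_idx])
        cum_t = np.cumsum(
            np.stack([model.segment_models[i].transition for i in codon_idx]),
            axis=2)
        for i, bases in zip(codon_idx,
                            _sample_codon_chains(marg, cum_t, ncod, rng)):
            _place(i, bases)
    return out


def sample(model: GenomeNullModel, seed) -> GenomeRecord:
    """Sample one randomized genome, preserving the feature frame exactly.

    ``seed`` may be an int, a numpy SeedSequence, or a Generator.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    codes = sample_codes(model, rng)
    return GenomeRecord(
        id=model.genome.id,
        sequence=decode(codes),
        circular=model.genome.circular,
        features=list(model.genome.features),
    )


def expected_codon_distribution(model: CodonChainModel) -> np.ndarray:
    """Expected codon frequencies over one sampled gene under the chain.

    The first codon follows the marginal; each later position follows the
    transition conditioned on the previous position's last-base
    distribution.  Averaging over all positions gives the distribution a
    long-run codon tally of samples converges to.
    """
    d = model.marginal.copy()
    total = d.copy()
    for _ in range(1, model.n_codons):
        base_dist = np.zeros(4)
        np.add.at(base_dist, _CODON_LAST, d)
        d = base_dist @ model.transition
        total += d
    return total / total.sum()


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent generator for one replicate of a seeded run."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed),
                               spawn_key=(int(replicate),)))
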