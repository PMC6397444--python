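"""Monte Carlo simulation driver: observed vs randomized score distributions.

The observed genome and each of N randomized genomes are decomposed with
the same segment frame, the same four region sets are extracted, and each
is scanned with the same PSSM and cutoff grid.  Per cutoff, the replicate
counts yield percentile envelopes (1, 5, 25, 50, 75, 95, 99); per region
set, the replicate maximum scores yield the ΔN excess-site statistic:

    ΔN = #{observed windows with S strictly greater than the median of
           the replicate maximum scores}

ΔN_genome, ΔN_ig, ΔN_cod and ΔN_tem use the maxima of their own region
set.  Cumulative counts use >= at each cutoff ("greater or equal"); ΔN
uses strict > with a 1e-9 tie snap ("higher than").  Replicate sequences
are streamed — peak memory does not grow with the replicate count — while
per-replicate counts and maxima are retained for the envelopes and can be
persisted to TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import randomizer
from .genome_io import (GenomeRecord, SegmentPartition, extract_region_set,
                        partition_genome, REGION_MODES)
from .motif_model import Pssm
from .scanner import (CutoffGrid, ReverseCumulativeDistribution, SNAP,
                      rcd_from_scores, window_scores)

PERCENTILES = (1, 5, 25, 50, 75, 95, 99)

REGION_DELTA_NAMES = {"genome": "dn_genome", "intergenic": "dn_ig",
                      "coding": "dn_cod", "template": "dn_tem"}


def percentile(values: Sequence[float], p: float) -> float:
    """Percentile convention used throughout the package.

    p=50: the median — mean of the two central order statistics for even
    n, the middle value for odd n.  Other p: nearest rank, i.e. the
    ceil(p*n/100)-th order statistic.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("empty value list")
    if p == 50:
        mid = n // 2
        return float(arr[mid]) if n % 2 else float((arr[mid - 1] + arr[mid]) / 2)
    rank = max(1, math.ceil(p * n / 100.0))
    return float(arr[min(rank, n) - 1])


def delta_n(observed_scores: np.ndarray, replicate_maxima: Sequence[float]
            ) -> int:
    """Observed windows scoring strictly above the median replicate maximum."""
    med = percentile(replicate_maxima, 50)
    scores = np.asarray(observed_scores)
    return int(np.sum(scores > med + SNAP))


@dataclass
class SimulationConfig:
    """Knobs of one Monte Carlo run."""

    n_replicates: int = 1000
    model_kind: str = "m1c1"
    seed: int = 0
    regions: tuple[str, ...] = REGION_MODES
    grid: Optional[CutoffGrid] = None  # default: integer bits 0..ceil(max)
    pseudocount: float = 0.5  # provenance only; the PSSM is built upstream
    alpha_nuc: float = randomizer.DEFAULT_ALPHA_NUC
    alpha_codon: float = randomizer.DEFAULT_ALPHA_CODON

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for r in self.regions:
            if r not in REGION_MODES:
                raise ValueError(f"unknown region {r!r}")


@dataclass
class RegionResult:
    """Observed distribution, null envelope and ΔN for one region set."""

    region: str
    observed: ReverseCumulativeDistribution
    envelope: dict[int, np.ndarray]  # percentile -> counts per cutoff
    replicate_counts: np.ndarray  # (n_replicates, n_cutoffs)
    replicate_maxima: np.ndarray  # (n_replicates,)
    observed_max: float
    median_max: float
    delta_n: int

    def envelope_tsv(self, path, header: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header or {}).items():
                fh.write(f"# {k}: {v}\n")
            cols = "\t".join(f"p{p}" for p in PERCENTILES)
            fh.write(f"cutoff\tobserved\t{cols}\n")
            for j, c in enumerate(self.observed.cutoffs):
                row = "\t".join(f"{self.envelope[p][j]:g}"
                                for p in PERCENTILES)
                fh.write(f"{c:g}\t{self.observed.counts[j]}\t{row}\n")


@dataclass
class SimulationResult:
    """All region results of one run plus provenance."""

    regions: dict[str, RegionResult]
    config: SimulationConfig
    genome_id: str
    motif_name: str

    @property
    def delta_report(self) -> dict[str, int]:
        return {REGION_DELTA_NAMES[r]: res.delta_n
                for r, res in self.regions.items()}

    def maxima_tsv(self, path, header: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header or {}).items():
                fh.write(f"# {k}: {v}\n")
            names = list(self.regions)
            fh.write("replicate\t" + "\t".join(names) + "\n")
            n = self.config.n_replicates
            for r in range(n):
                row = "\t".join(f"{self.regions[m].replicate_maxima[r]:.6f}"
                                for m in names)
                fh.write(f"{r}\t{row}\n")


def _region_scores(genome: GenomeRecord, partition: SegmentPartition,
                   pssm: Pssm, regions: Sequence[str]) -> dict[str, np.ndarray]:
    return {mode: window_scores(pssm, extract_region_set(genome, partition, mode))
            for mode in regions}


def run(genome: GenomeRecord, pssm: Pssm, config: SimulationConfig, *,
        partition: Optional[SegmentPartition] = None) -> SimulationResult:
    """Scan the observed genome and ``n_replicates`` randomized genomes.

    The PSSM's background should derive from this genome unless a
    cross-species search is intended (pass the PSSM built against the
    source matrix with the target genome's background).
    """
    if partition is None:
        partition = partition_genome(genome)
    grid = config.grid or CutoffGrid.default_for(pssm)
    observed = _region_scores(genome, partition, pssm, config.regions)

    model = randomizer.fit(genome, partition, config.model_kind,
                           alpha_nuc=config.alpha_nuc,
                           alpha_codon=config.alpha_codon)
    n_rep, n_cut = config.n_replicates, len(grid)
    counts = {r: np.zeros((n_rep, n_cut), dtype=np.int64)
              for r in config.regions}
    maxima = {r: np.zeros(n_rep) for r in config.regions}
    for rep in range(n_rep):
        rng = randomizer.replicate_rng(config.seed, rep)
        codes = randomizer.sample_codes(model, rng)
        rand_genome = GenomeRecord(genome.id, randomizer.decode(codes),
                                   genome.circular, list(genome.features))
        for region, scores in _region_scores(
                rand_genome, partition, pssm, config.regions).items():
            rcd = rcd_from_scores(scores, grid)
            counts[region][rep] = rcd.counts
            maxima[region][rep] = rcd.max_observed

    results: dict[str, RegionResult] = {}
    for region in config.regions:
        obs_scores = observed[region]
        obs_rcd = rcd_from_scores(obs_scores, grid)
        env = {p: np.array([percentile(counts[region][:, j], p)
                            for j in range(n_cut)])
               for p in PERCENTILES}
        med = percentile(maxima[region], 50)
        results[region] = RegionResult(
            region=region,
            observed=obs_rcd,
            envelope=env,
            replicate_counts=counts[region],
            replicate_maxima=maxima[region],
            observed_max=obs_rcd.max_observed,
            median_max=med,
            delta_n=delta_n(obs_scores, maxima[region]),
        )
    return SimulationResult(results, config, genome.id, pssm.name)
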