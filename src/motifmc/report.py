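"""Per-motif report cards and multi-motif summary tables.

A report card bundles, for one (motif, genome) run: motif metadata (L,
training-set size, information content, maximum PSSM score, per-column
logo letter heights), the observed reverse cumulative distribution with
its null envelope for each region set, the four ΔN statistics, and full
run provenance.  A summary table has one row per card with the columns
protein, genome, motif length, # of sites, information content,
ΔN_genome, ΔN_ig, ΔN_cod, ΔN_tem.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .montecarlo import PERCENTILES, REGION_DELTA_NAMES, SimulationResult

SUMMARY_COLUMNS = ["protein", "genome", "motif_length", "n_sites",
                   "information_content", "dn_genome", "dn_ig", "dn_cod",
                   "dn_tem"]


@dataclass
class ReportCard:
    """JSON-serialisable bundle of one simulation run."""

    motif_name: str
    genome_id: str
    motif_length: int
    n_sites: float
    information_content: float
    max_score: float
    letter_heights: list[list[float]]  # 4 x L logo heights
    panels: dict  # region -> {cutoffs, observed, envelope{p->counts}, ...}
    delta: dict[str, int]
    provenance: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReportCard":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_report_card(result: SimulationResult, *,
                      motif_name: str = "", genome_id: str = "",
                      information_content: float = float("nan"),
                      n_sites: float = 0.0, max_score: float = float("nan"),
                      letter_heights: Optional[np.ndarray] = None,
                      extra_provenance: Optional[dict] = None) -> ReportCard:
    """Assemble the card; panels follow genome, intergenic, coding, template order."""
    panels = {}
    order = [r for r in ("genome", "intergenic", "coding", "template")
             if r in result.regions]
    missing = [r for r in result.config.regions if r not in result.regions]
    for r in missing:  # pragma: no cover - defensive
        warnings.warn(f"panel {r} missing from results; emitting placeholder")
        panels[r] = None
    for r in order:
        res = result.regions[r]
        panels[r] = {
            "cutoffs": res.observed.cutoffs.tolist(),
            "observed": res.observed.counts.tolist(),
            "n_windows": res.observed.n_windows,
            "observed_max": res.observed_max,
            "median_max": res.median_max,
            "envelope": {str(p): res.envelope[p].tolist()
                         for p in PERCENTILES},
        }
    cfg = result.config
    provenance = {
        "genome": genome_id or result.genome_id,
        "model": cfg.model_kind,
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
        "pseudocount": cfg.pseudocount,
        "alpha_nuc": cfg.alpha_nuc,
        "alpha_codon": cfg.alpha_codon,
        "regions": list(cfg.regions),
        "version": __version__,
    }
    provenance.update(extra_provenance or {})
    delta = {REGION_DELTA_NAMES[r]: result.regions[r].delta_n for r in order}
    heights = (np.asarray(letter_heights).tolist()
               if letter_heights is not None else [])
    return ReportCard(
        motif_name=motif_name or result.motif_name,
        genome_id=genome_id or result.genome_id,
        motif_length=0 if letter_heights is None else len(heights[0]),
        n_sites=n_sites,
        information_content=information_content,
        max_score=max_score,
        letter_heights=heights,
        panels=panels,
        delta=delta,
        provenance=provenance,
    )


def build_summary(cards: list[ReportCard]) -> pd.DataFrame:
    """One row per card, sorted by protein then genome; duplicates suffixed."""
    if not cards:
        raise ValueError("need at least one report card")
    rows = []
    seen: dict[tuple[str, str], int] = {}
    for card in cards:
        key = (card.motif_name, card.genome_id)
        protein = card.motif_name
        if key in seen:
            seen[key] += 1
            protein = f"{card.motif_name}_{seen[key]}"
            warnings.warn(f"duplicate (motif, genome) run {key}; suffixed")
        else:
            seen[key] = 0
        rows.append({
            "protein": protein,
            "genome": card.genome_id,
            "motif_length": card.motif_length,
            "n_sites": card.n_sites,
            "information_content": card.information_content,
            "dn_genome": card.delta.get("dn_genome"),
            "dn_ig": card.delta.get("dn_ig"),
            "dn_cod": card.delta.get("dn_cod"),
            "dn_tem": card.delta.get("dn_tem"),
        })
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df.sort_values(["protein", "genome"]).reset_index(drop=True)


def plot_report_card(card: ReportCard, path) -> None:
    """Four-panel observed-vs-envelope plot (log count axis, zeros as gaps)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [(r, p) for r, p in card.panels.items() if p]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), squeeze=False)
    for ax, (region, panel) in zip(axes.ravel(), panels):
        x = np.asarray(panel["cutoffs"])
        obs = np.asarray(panel["observed"], dtype=float)
        obs[obs == 0] = np.nan  # gap on the log axis
        for p in PERCENTILES:
            env = np.asarray(panel["envelope"][str(p)], dtype=float)
            env[env == 0] = np.nan
            lw = 2.0 if p == 50 else 0.7
            ax.plot(x, env, color="black", lw=lw)
        ax.plot(x, obs, color="tab:blue", lw=1.6)
        ax.set_yscale("log")
        ax.set_title(region)
        ax.set_xlabel("score cutoff (bits)")
        ax.set_ylabel("windows ≥ cutoff")
    for ax in axes.ravel()[len(panels):]:
        ax.axis("off")
    fig.suptitle(f"{card.motif_name} on {card.genome_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
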