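"""Shared fixtures: toy GenBank texts, small synthetic genomes, oracles."""

import numpy as np
import pytest

from motifmc import genome_io as gio
from motifmc import motif_model as mm
from motifmc import synthetic_data as sd
from motifmc.alphabet import revcomp

TOY_GB = """\
LOCUS       toy                       60 bp    DNA     linear   UNK 01-JAN-1980
DEFINITION  toy test record.
ACCESSION   toy
VERSION     toy.1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     CDS             {location}
                     /locus_tag="g1"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture
def toy_gb_factory(tmp_path):
    def make(location="7..36", origin=None):
        text = TOY_GB.format(location=location)
        if origin is not None:
            head, _, _ = text.partition("ORIGIN")
            text = head + origin
        path = tmp_path / "toy.gb"
        path.write_text(text)
        return path

    return make


@pytest.fixture(scope="session")
def small_genome():
    """A ~20 kb synthetic chromosome with ground-truth partition."""
    spec = sd.SyntheticGenomeSpec(n_genes=30, gene_codons_min=50,
                                  gene_codons_max=150, ig_len_min=20,
                                  ig_len_max=120, seed=11)
    return sd.make_genome(spec)


@pytest.fixture(scope="session")
def small_pssm(small_genome):
    genome, _ = small_genome
    bg = mm.background_from_genome(genome)
    return mm.build_pssm(sd.synthetic_motif(12, 13.0), bg, name="toy12")


def naive_window_scores(pssm, seqs):
    """Brute-force per-window scoring oracle (independent of the scanner)."""
    out = []
    L = pssm.length
    for entry in seqs:
        s = entry.sequence
        for i in range(len(s) - L + 1):
            w = s[i:i + L]
            if "N" in w:
                continue
            out.append(mm.score(pssm, w))
            if entry.scan_mode == "both_strands":
                out.append(mm.score(pssm, revcomp(w)))
    return np.array(out)


def naive_counts(scores, cutoffs):
    return np.array([(scores >= c - 1e-9).sum() for c in cutoffs])
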