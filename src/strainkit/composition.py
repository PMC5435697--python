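"""Genome and proteome composition statistics.

Amino-acid composition and codon usage are relative frequencies (rows sum
to one); the per-feature coefficient of variation across strains
(``100 * population sd / mean``) quantifies which residues or codons vary
most between genomes.  Hierarchical clustering of the strain rows yields
the merge table behind composition heat-map dendrograms.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io_formats import GenomeRecord, StrainkitError

__all__ = [
    "AA_ORDER",
    "CODON_ORDER",
    "CODON_TO_AA",
    "amino_acid_composition",
    "codon_usage",
    "variable_coefficient",
    "gc_content",
    "cluster_strains",
]

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
_EXCLUDED_RESIDUES = set("XBZJUO*")

CODON_ORDER = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")

_TABLE11_FWD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L", "CTA": "L",
    "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M", "GTT": "V", "GTC": "V",
    "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S", "CCT": "P",
    "CCC": "P", "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H",
    "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    "TAA": "*", "TAG": "*", "TGA": "*",
}
CODON_TO_AA = dict(_TABLE11_FWD)


def amino_acid_composition(proteomes: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Relative amino-acid frequencies per strain.

    ``proteomes`` maps strain id to its protein sequences.  Stops and
    ambiguous residues (X, B, Z, J, U, O) are excluded from the counts;
    each returned row sums to 1.
    """
    rows = {}
    for strain, proteins in proteomes.items():
        counts = dict.fromkeys(AA_ORDER, 0)
        total = 0
        for protein in proteins:
            for aa in protein:
                if aa in _EXCLUDED_RESIDUES:
                    continue
                if aa in counts:
                    counts[aa] += 1
                    total += 1
        if total == 0:
            raise StrainkitError(f"proteome of strain {strain!r} has no countable residues")
        rows[strain] = [counts[aa] / total for aa in AA_ORDER]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AA_ORDER))


def codon_usage(cds_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Relative codon frequencies (64 codons, stops included) per strain.

    A CDS whose length is not a multiple of three loses its trailing
    partial codon with a warning; codons containing ``N`` are excluded.
    """
    rows = {}
    for strain, cds_list in cds_sets.items():
        counts = dict.fromkeys(CODON_ORDER, 0)
        total = 0
        for cds in cds_list:
            if len(cds) % 3:
                warnings.warn(
                    f"CDS length {len(cds)} not a multiple of 3 in strain {strain!r}; "
                    "trailing partial codon dropped", UserWarning, stacklevel=2)
            for i in range(0, len(cds) - len(cds) % 3, 3):
                codon = cds[i : i + 3]
                if codon in counts:
                    counts[codon] += 1
                    total += 1
        if total == 0:
            raise StrainkitError(f"strain {strain!r} has no countable codons")
        rows[strain] = [counts[c] / total for c in CODON_ORDER]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CODON_ORDER))


def variable_coefficient(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature coefficient of variation across strains, in percent.

    Uses the population standard deviation (``ddof=0``).  A feature with
    zero mean (absent everywhere) is reported as CV 0.
    """
    if len(matrix) < 2:
        raise StrainkitError("variable_coefficient requires at least 2 strains")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean.to_numpy() > 0, 100.0 * sd.to_numpy() / mean.to_numpy(), 0.0)
    # a feature that is literally constant must come out as exactly 0,
    # immune to one-ulp rounding of the column mean
    constant = (matrix == matrix.iloc[0]).all(axis=0).to_numpy()
    cv[constant] = 0.0
    return pd.Series(cv, index=matrix.columns, name="cv_percent")


def gc_content(genome: GenomeRecord | str) -> float:
    """G+C percentage over unambiguous bases; N excluded from both sides."""
    if isinstance(genome, GenomeRecord):
        seq = "".join(s for _, s in genome.contigs)
    else:
        seq = genome
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise StrainkitError("genome contains no unambiguous bases")
    return 100.0 * gc / atgc


def cluster_strains(matrix: pd.DataFrame, method: str = "average",
                    metric: str = "euclidean") -> pd.DataFrame:
    """Hierarchical agglomerative clustering of strain rows.

    Returns the merge table: one row per internal node with its two
    children (ids < n are the input rows in order), merge height and
    leaf count — enough to redraw the dendrogram.  scipy's linkage
    resolves ties by lowest index, so the output is deterministic.
    """
    if len(matrix) < 2:
        raise StrainkitError("clustering requires at least 2 strains")
    z = linkage(pdist(matrix.to_numpy(), metric=metric), method=method)
    table = pd.DataFrame(z, columns=["child_1", "child_2", "height", "n_leaves"])
    table[["child_1", "child_2", "n_leaves"]] = table[
        ["child_1", "child_2", "n_leaves"]].astype(int)
    table.insert(0, "node", range(len(matrix), len(matrix) + len(table)))
    return table
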