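"""Average nucleotide identity, per-category divergence, 16S identity, NJ trees.

Whole-genome ANI follows the fragment-based (Goris-style) recipe: one
genome is cut into consecutive, non-overlapping fragments (default
1020 bp, trailing remainder discarded), each fragment is locally aligned
to the other genome on both strands, and a fragment contributes the
percent identity of its best alignment iff that alignment exceeds the
identity cutoff (default 30%) and covers at least the alignable fraction
(default 70%) of the fragment.  ANI is the mean over contributing
fragments; the reciprocal mean averages the two one-way values.  A
comparison with no contributing fragments is reported with the 0
sentinel, never as missing.

Per-category ANI applies the same cutoffs but the aligned units are whole
gene nucleotide sequences searched against the other genome's same-category
gene set, which makes the 0 sentinel an informative signal of category
loss or extreme divergence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .homology import SearchParams, hit_from_alignment, hit_sort_key
from .io_formats import GeneRecord, GenomeRecord, StrainkitError, reverse_complement

__all__ = [
    "AniParams",
    "AniResult",
    "CategoryAniProfile",
    "DistanceMatrix",
    "Tree",
    "compute_ani",
    "compute_category_ani",
    "classify_category_regions",
    "identity_16s",
    "nj_tree",
    "distance_matrix_from_identity",
]


@dataclass
class AniParams:
    """Cutoffs of the fragment-based ANI computation (all configurable)."""

    fragment_length: int = 1020
    min_identity: float = 30.0          # percent, strict inequality
    min_alignable_frac: float = 0.7     # of the fragment length, in columns
    search: SearchParams = field(default_factory=lambda: SearchParams(alphabet="nt"))
    band_width: int = 64                # diagonal binning for seeding
    max_bands: int = 5                  # candidate windows aligned per fragment
    min_band_seeds: int = 3             # absolute seed floor for a candidate band
    rel_band_seeds: float = 0.1         # ... and relative to the best band
    window_pad: int = 60


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: float                      # %, 0.0 sentinel when no fragment qualifies
    n_fragments_used: int
    direction: str                  # "a->b", "b->a" or "reciprocal-mean"
    one_way: tuple["AniResult", "AniResult"] | None = None


@dataclass
class CategoryAniProfile:
    genome_a: str
    genome_b: str
    categories: dict[str, tuple[float, int]]    # letter -> (ani %, qualifying gene hits)
    genome_ani: float | None = None


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise StrainkitError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise StrainkitError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise StrainkitError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise StrainkitError("negative distances")

    def triangle_violations(self) -> int:
        """Count of ordered triples violating the triangle inequality (flag only;
        neighbor joining does not require metricity)."""
        d = self.values
        n = len(self.labels)
        count = 0
        for i, j, k in itertools.permutations(range(n), 3):
            if d[i, j] > d[i, k] + d[k, j] + 1e-12:
                count += 1
        return count


@dataclass
class _Node:
    name: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    min_leaf: str = ""

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class Tree:
    """Unrooted tree as a trifurcating-root node structure, Newick-serializable."""

    root: _Node

    def to_newick(self) -> str:
        return self.root.newick() + ";"

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if not node.children:
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return sorted(out)


# ---------------------------------------------------------------------------
# fragment mapping machinery


class _TargetIndex:
    """k-mer index over target sequences (both strands) for fragment seeding."""

    def __init__(self, genome: GenomeRecord, params: AniParams):
        self.params = params
        k = params.search.word_size
        self.seqs: list[str] = []
        self.indexes: list[dict[str, list[int]]] = []
        for _, seq in genome.contigs:
            for s in (seq, reverse_complement(seq)):
                index: dict[str, list[int]] = {}
                for i in range(len(s) - k + 1):
                    index.setdefault(s[i : i + k], []).append(i)
                self.seqs.append(s)
                self.indexes.append(index)

    def candidate_windows(self, fragment: str) -> list[tuple[int, int, int]]:
        """Best-seeded (seq_idx, lo, hi) windows, most seeds first."""
        k = self.params.search.word_size
        w = self.params.band_width
        counts: dict[tuple[int, int], int] = {}
        for q in range(len(fragment) - k + 1):
            word = fragment[q : q + k]
            for si, index in enumerate(self.indexes):
                for t in index.get(word, ()):
                    band = (t - q) // w
                    key = (si, band)
                    counts[key] = counts.get(key, 0) + 1
        if not counts:
            return []
        top = max(counts.values())
        floor = max(self.params.min_band_seeds, self.params.rel_band_seeds * top)
        qualified = {k: v for k, v in counts.items() if v >= floor}
        best = sorted(qualified.items(), key=lambda kv: (-kv[1], kv[0]))[: self.params.max_bands]
        windows = []
        pad = self.params.window_pad
        for (si, band), _ in best:
            lo = max(0, band * w - pad)
            hi = min(len(self.seqs[si]), (band + 1) * w + len(fragment) + pad)
            windows.append((si, lo, hi))
        return windows


def _best_fragment_hit(fragment: str, index: _TargetIndex, aligner: Align.PairwiseAligner,
                       params: AniParams) -> tuple[float, int] | None:
    """(percent identity, alignment columns) of the best-scoring placement."""
    best_score = -1.0
    best = None
    for si, lo, hi in index.candidate_windows(fragment):
        window = index.seqs[si][lo:hi]
        alns = aligner.align(window, fragment)
        if not len(alns) or alns.score <= best_score:
            continue
        hit = hit_from_alignment(alns[0], "frag", "win", fragment, window,
                                 params.search, len(window))
        best_score = alns.score
        best = (hit.percent_identity, hit.aln_length)
    return best


def _fragments(genome: GenomeRecord, length: int) -> list[str]:
    frags = []
    for _, seq in genome.contigs:
        for i in range(0, len(seq) - length + 1, length):
            frags.append(seq[i : i + length])
    return frags


def _one_way_ani(genome_a: GenomeRecord, genome_b: GenomeRecord, params: AniParams,
                 direction: str) -> AniResult:
    frags = _fragments(genome_a, params.fragment_length)
    if not frags:
        raise StrainkitError(
            f"genome {genome_a.genome_id!r} has no contig of at least "
            f"{params.fragment_length} bp")
    index = _TargetIndex(genome_b, params)
    aligner = params.search.make_aligner()
    min_cols = params.min_alignable_frac * params.fragment_length
    identities = []
    for frag in frags:
        hit = _best_fragment_hit(frag, index, aligner, params)
        if hit is None:
            continue
        pid, cols = hit
        if pid > params.min_identity and cols >= min_cols:
            identities.append(pid)
    ani = float(np.mean(identities)) if identities else 0.0
    return AniResult(genome_a=genome_a.genome_id, genome_b=genome_b.genome_id, ani=ani,
                     n_fragments_used=len(identities), direction=direction)


def compute_ani(genome_a: GenomeRecord, genome_b: GenomeRecord,
                params: AniParams | None = None,
                direction: str = "reciprocal-mean") -> AniResult:
    """Fragment-based ANI between two genomes.

    ``direction`` is ``"a->b"``, ``"b->a"`` or ``"reciprocal-mean"`` (the
    default, averaging the two one-way values; one-way results are kept
    on the returned object).  A comparison where no fragment qualifies
    carries ``ani = 0.0`` and ``n_fragments_used = 0``.
    """
    if params is None:
        params = AniParams()
    if direction == "a->b":
        return _one_way_ani(genome_a, genome_b, params, direction)
    if direction == "b->a":
        return _one_way_ani(genome_b, genome_a, params, direction)
    if direction != "reciprocal-mean":
        raise StrainkitError(f"unknown direction {direction!r}")
    ab = _one_way_ani(genome_a, genome_b, params, "a->b")
    ba = _one_way_ani(genome_b, genome_a, params, "b->a")
    used = [r for r in (ab, ba) if r.n_fragments_used > 0]
    ani = float(np.mean([r.ani for r in used])) if used else 0.0
    return AniResult(genome_a=genome_a.genome_id, genome_b=genome_b.genome_id, ani=ani,
                     n_fragments_used=ab.n_fragments_used + ba.n_fragments_used,
                     direction="reciprocal-mean", one_way=(ab, ba))


# ---------------------------------------------------------------------------
# per-category gene-cluster ANI


def _one_way_category_mean(queries: list[GeneRecord], subjects: list[GeneRecord],
                           params: AniParams, aligner: Align.PairwiseAligner
                           ) -> tuple[float | None, int]:
    """Mean best-hit identity over query genes with a qualifying hit."""
    if not queries or not subjects:
        return None, 0
    k = params.search.word_size
    index: dict[str, set[int]] = {}
    for j, s in enumerate(subjects):
        for i in range(len(s.cds) - k + 1):
            index.setdefault(s.cds[i : i + k], set()).add(j)
    identities = []
    for q in queries:
        candidates: set[int] = set()
        for i in range(len(q.cds) - k + 1):
            candidates |= index.get(q.cds[i : i + k], set())
        best_score, best = -1.0, None
        for j in sorted(candidates):
            s = subjects[j]
            if s.gene_id == q.gene_id:
                continue
            alns = aligner.align(s.cds, q.cds)
            if len(alns) and alns.score > best_score:
                hit = hit_from_alignment(alns[0], q.gene_id, s.gene_id, q.cds, s.cds,
                                         params.search, len(s.cds))
                best_score = alns.score
                best = hit
        if best is None:
            continue
        if (best.percent_identity > params.min_identity
                and best.aln_length >= params.min_alignable_frac * len(q.cds)):
            identities.append(best.percent_identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def compute_category_ani(genes_a: Sequence[GeneRecord], genes_b: Sequence[GeneRecord],
                         category_map: Mapping[str, str],
                         params: AniParams | None = None,
                         genome_ani: float | None = None) -> CategoryAniProfile:
    """Per-functional-category gene-cluster ANI between two genomes.

    For each category, every gene of one genome is aligned against the
    other genome's genes *of the same category*; qualifying best hits
    (same identity/alignable cutoffs as whole-genome ANI, relative to the
    gene's own length) are averaged per direction, then the two one-way
    means are averaged.  A category with no qualifying hit in either
    direction carries the 0 sentinel; a category absent from both
    genomes is omitted entirely.
    """
    if params is None:
        params = AniParams()
    aligner = params.search.make_aligner()

    def by_cat(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in genes:
            if g.feature_type != "cds":
                continue
            cat = category_map.get(g.gene_id, g.category)
            if cat and cat != "UNASSIGNED":
                out.setdefault(cat, []).append(g)
        return out

    cats_a, cats_b = by_cat(genes_a), by_cat(genes_b)
    profile: dict[str, tuple[float, int]] = {}
    genome_a = next((g.genome_id for g in genes_a), "A")
    genome_b = next((g.genome_id for g in genes_b), "B")
    for cat in sorted(set(cats_a) | set(cats_b)):
        qa, qb = cats_a.get(cat, []), cats_b.get(cat, [])
        mean_ab, n_ab = _one_way_category_mean(qa, qb, params, aligner)
        mean_ba, n_ba = _one_way_category_mean(qb, qa, params, aligner)
        means = [m for m in (mean_ab, mean_ba) if m is not None]
        ani = float(np.mean(means)) if means else 0.0
        profile[cat] = (ani, n_ab + n_ba)
    return CategoryAniProfile(genome_a=genome_a, genome_b=genome_b, categories=profile,
                              genome_ani=genome_ani)


def classify_category_regions(profiles: Sequence[CategoryAniProfile],
                              identity_16s_map: Mapping[tuple[str, str], float],
                              theta_up: float = 0.9,
                              threshold_16s: float = 94.5):
    """Assign each category to the upper / middle / divergent region.

    Across all genome pairs: ``upper`` when the category ANI exceeds the
    genome ANI in at least ``theta_up`` of the pairs and no pair carries
    the 0 sentinel; ``divergent`` when 0-sentinel pairs occur among pairs
    whose 16S identity is below ``threshold_16s`` percent; ``middle``
    otherwise.  Returns a DataFrame indexed by category with the
    supporting fractions.
    """
    import pandas as pd

    if len(profiles) < 3:
        raise StrainkitError("region classification needs profiles for >= 3 genome pairs")

    def pair_16s(a: str, b: str) -> float:
        if (a, b) in identity_16s_map:
            return identity_16s_map[(a, b)]
        if (b, a) in identity_16s_map:
            return identity_16s_map[(b, a)]
        raise StrainkitError(f"no 16S identity for pair ({a!r}, {b!r})")

    cats = sorted({c for p in profiles for c in p.categories})
    rows = []
    for cat in cats:
        n_pairs = n_above = n_below = n_zero = n_zero_low16s = 0
        for p in profiles:
            if cat not in p.categories:
                continue
            ani, _ = p.categories[cat]
            if p.genome_ani is None:
                raise StrainkitError("profiles must carry genome_ani for classification")
            n_pairs += 1
            if ani == 0.0:
                n_zero += 1
                if pair_16s(p.genome_a, p.genome_b) < threshold_16s:
                    n_zero_low16s += 1
            elif ani > p.genome_ani:
                n_above += 1
            else:
                n_below += 1
        f_above = n_above / n_pairs if n_pairs else 0.0
        f_below = n_below / n_pairs if n_pairs else 0.0
        if n_zero_low16s > 0:
            label = "divergent"
        elif f_above >= theta_up and n_zero == 0:
            label = "upper"
        else:
            label = "middle"
        rows.append((cat, n_pairs, f_above, f_below, n_zero, label))
    return pd.DataFrame(rows, columns=["category", "n_pairs", "f_above", "f_below",
                                       "n_zero", "region"]).set_index("category")


# ---------------------------------------------------------------------------
# 16S identity


def identity_16s(seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0,
                 open_gap: float = -2.0, extend_gap: float = -0.5) -> float:
    """Percent identity of a global 16S alignment, terminal gaps excluded.

    End gaps are free in the alignment scoring, and columns where one
    sequence has run out (terminal gap columns) do not enter the identity
    denominator, so a perfect prefix scores 100.  The pair is ordered
    canonically before aligning, making the value symmetric even when
    several alignments tie for the optimal score; an alignment with no
    aligned columns at all (nothing in common) scores 0.
    """
    if not seq_a or not seq_b:
        raise StrainkitError("identity_16s requires two non-empty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.end_insertion_score = 0.0   # free terminal gaps, both sequences
    aligner.end_deletion_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return 0.0
    ident = aligned_len = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        a, b = seq_a[ts:te], seq_b[qs:qe]
        aligned_len += te - ts
        ident += sum(1 for x, y in zip(a, b) if x == y and x != "N")
    ts0, te1 = int(tblocks[0][0]), int(tblocks[-1][1])
    qs0, qe1 = int(qblocks[0][0]), int(qblocks[-1][1])
    core_columns = (te1 - ts0) + (qe1 - qs0) - aligned_len
    return 100.0 * ident / core_columns if core_columns else 0.0


# ---------------------------------------------------------------------------
# neighbor joining


def distance_matrix_from_identity(labels: Sequence[str],
                                  identity_map: Mapping[tuple[str, str], float]
                                  ) -> DistanceMatrix:
    """p-distance matrix ``d = 1 - identity/100`` from pairwise identities."""
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = labels[i], labels[j]
        pid = identity_map.get((a, b), identity_map.get((b, a)))
        if pid is None:
            raise StrainkitError(f"missing identity for pair ({a!r}, {b!r})")
        values[i, j] = values[j, i] = 1.0 - pid / 100.0
    return DistanceMatrix(labels=list(labels), values=values)


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Standard neighbor joining with deterministic tie-breaking.

    Q-matrix ties are broken by the lexicographically smallest pair of
    node labels (an internal node is labelled by its smallest descendant
    leaf).  Negative branch lengths are clamped to zero with the deficit
    moved to the sister branch, preserving the path length between the
    joined nodes.  The result is the usual unrooted tree with a
    trifurcating root.
    """
    n = len(dist.labels)
    if n < 3:
        raise StrainkitError("neighbor joining requires at least 3 taxa")
    nodes: list[_Node] = [_Node(name=lbl, min_leaf=lbl) for lbl in dist.labels]
    d = dist.values.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best_q, best_pair = math.inf, None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                la, lb = sorted((nodes[i].min_leaf, nodes[j].min_leaf))
                key = (q, la, lb)
                if best_pair is None or key < (best_q, *best_pair_labels):
                    best_q, best_pair, best_pair_labels = q, (i, j), (la, lb)
        i, j = best_pair
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = _Node(name=None, children=[(nodes[i], li), (nodes[j], lj)],
                    min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf))
        new_idx = len(nodes)
        nodes.append(new)
        grown = np.zeros((new_idx + 1, new_idx + 1))
        grown[:new_idx, :new_idx] = d
        d = grown
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = (d[i, k] + d[j, k] - d[i, j]) / 2
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    root = _Node(name=None,
                 children=[(nodes[a], max(la, 0.0)), (nodes[b], max(lb, 0.0)),
                           (nodes[c], max(lc, 0.0))],
                 min_leaf=min(nodes[a].min_leaf, nodes[b].min_leaf, nodes[c].min_leaf))
    return Tree(root=root)
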