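"""All-vs-all homology search, ortholog/specific-gene calling, HGT classification.

The search is k-mer seeded: only query/subject pairs sharing at least one
exact word of length ``word_size`` are aligned, then scored with a full
affine-gap local (Smith-Waterman) alignment, so every reported hit carries
the true optimal local score for the pair.  E-values follow the
Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)`` with ``m`` the
query length and ``n`` the total database length.

Ortholog calls are reciprocal best hits (RBH); a gene participating in no
significant hit in either direction is "specific".  A gene is horizontally
transferred when it has significant hits but none within the focal
taxonomic order; its donor order is the order of the best hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import StrainkitError, TaxonomyLabel

__all__ = [
    "SearchParams",
    "AlignmentHit",
    "OrthologCall",
    "HgtCall",
    "search",
    "best_hit_per_query",
    "call_orthologs",
    "classify_hgt",
    "summarize_hgt",
    "write_hit_table",
    "read_hit_table",
]

# Canonical amino-acid alphabet accepted by the protein scorer; anything
# else is mapped to X before alignment.
_AA_CANON = set("ARNDCQEGHILKMFPSTWYVBZX")


class WordSizeError(StrainkitError):
    """Word size exceeds the shortest input sequence."""


class MissingTaxonomyError(StrainkitError):
    """A hit subject has no taxonomy entry."""


@dataclass
class SearchParams:
    """Scoring and statistics for the seeded local-alignment search.

    Defaults mirror common nucleotide-search practice: word size 11,
    +1/-2 match/mismatch with Karlin-Altschul ``lambda = 1.33``,
    ``K = 0.621``; protein mode uses word size 3 and BLOSUM62 with the
    ungapped ``lambda = 0.3176``, ``K = 0.134``.  Any alignment column
    containing ``N`` scores as a mismatch and never counts as an
    identity.
    """

    alphabet: str = "nt"            # "nt" or "aa"
    word_size: int | None = None    # default 11 nt / 3 aa
    match: float = 1.0
    mismatch: float = -2.0
    open_gap: float | None = None   # cost of the first gapped column; -5 nt / -11 aa
    extend_gap: float | None = None  # each further gapped column; -2 nt / -1 aa
    lambda_: float | None = None
    karlin_k: float | None = None
    e_ceiling: float = 1e-5
    # Minimum seed words on one diagonal before a pair is aligned.  One
    # suffices for nucleotide words (length 11); short protein words use
    # the two-hit heuristic to avoid aligning every random pair.
    min_diagonal_seeds: int | None = None

    def __post_init__(self) -> None:
        if self.alphabet not in {"nt", "aa"}:
            raise StrainkitError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")
        if self.word_size is None:
            self.word_size = 11 if self.alphabet == "nt" else 3
        if self.lambda_ is None:
            self.lambda_ = 1.33 if self.alphabet == "nt" else 0.3176
        if self.karlin_k is None:
            self.karlin_k = 0.621 if self.alphabet == "nt" else 0.134
        if self.min_diagonal_seeds is None:
            self.min_diagonal_seeds = 1 if self.alphabet == "nt" else 2
        if self.open_gap is None:
            self.open_gap = -5.0 if self.alphabet == "nt" else -11.0
        if self.extend_gap is None:
            self.extend_gap = -2.0 if self.alphabet == "nt" else -1.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.alphabet == "nt":
            alpha = "ACGTN"
            matrix = substitution_matrices.Array(alphabet=alpha, dims=2)
            for x in alpha:
                for y in alpha:
                    matrix[x, y] = self.match if (x == y and x != "N") else self.mismatch
            aligner.substitution_matrix = matrix
        else:
            aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = self.open_gap
        aligner.extend_gap_score = self.extend_gap
        return aligner


@dataclass
class AlignmentHit:
    """One local-alignment hit between a query and a subject sequence."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gaps: int
    qstart: int
    qend: int
    sstart: int
    send: int
    raw_score: float
    bit_score: float
    e_value: float
    query_coverage: float

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


@dataclass(frozen=True)
class OrthologCall:
    gene_a: str
    gene_b: str
    bidirectional: bool = True


@dataclass
class HgtCall:
    gene_id: str
    is_hgt: bool
    donor_order: str | None = None
    best_outside_hit: AlignmentHit | None = None
    n_hits: int = 0


def _sanitize_protein(seq: str) -> str:
    return "".join(c if c in _AA_CANON else "X" for c in seq.upper())


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _evalue(params: SearchParams, score: float, m: int, n: int) -> float:
    # computed in log space; huge scores underflow cleanly to 0.0
    log_e = math.log(params.karlin_k * m * n) - params.lambda_ * score
    if log_e < -700:
        return 0.0
    return math.exp(log_e)


def _bit_score(params: SearchParams, score: float) -> float:
    return (params.lambda_ * score - math.log(params.karlin_k)) / math.log(2)


def _identity_counts(alignment, tseq: str, qseq: str) -> tuple[int, int, int]:
    """(identities, aligned columns, gap columns) — N never identical."""
    tblocks, qblocks = alignment.aligned
    ident = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        a, b = tseq[ts:te], qseq[qs:qe]
        aligned_len += te - ts
        ident += sum(1 for x, y in zip(a, b) if x == y and x != "N")
    gap_cols = alignment.length - aligned_len
    return ident, aligned_len, gap_cols


def hit_from_alignment(alignment, query_id: str, subject_id: str, qseq: str, sseq: str,
                       params: SearchParams, db_length: int) -> AlignmentHit:
    """Build an :class:`AlignmentHit` from a Biopython local alignment.

    The alignment must have been produced with the subject as target and
    the query as query.
    """
    ident, aligned_len, gap_cols = _identity_counts(alignment, sseq, qseq)
    cols = alignment.length
    tblocks, qblocks = alignment.aligned
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(tblocks[0][0]), int(tblocks[-1][1])
    score = float(alignment.score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * ident / cols if cols else 0.0,
        aln_length=cols,
        mismatches=aligned_len - ident,
        gaps=gap_cols,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        raw_score=score,
        bit_score=_bit_score(params, score),
        e_value=_evalue(params, score, len(qseq), db_length),
        query_coverage=(qend - qstart) / len(qseq) if qseq else 0.0,
    )


def hit_sort_key(hit: AlignmentHit):
    """Deterministic hit ordering: bit score desc, identity desc, subject id."""
    return (-hit.bit_score, -hit.percent_identity, hit.subject_id)


def search(query_genes: Sequence[tuple[str, str]], db_genes: Sequence[tuple[str, str]],
           params: SearchParams | None = None) -> list[AlignmentHit]:
    """Seeded all-vs-all local alignment of query sequences against a database.

    A query/subject pair is aligned when it shares
    ``params.min_diagonal_seeds`` exact words on one alignment diagonal
    (one word for nucleotides; two for proteins, the classic two-hit
    heuristic).  Returns hits with ``e_value <= params.e_ceiling``,
    grouped by query in input order and sorted by descending bit score
    within each query.  Self-hits (same id) are retained; callers may
    filter on :attr:`AlignmentHit.is_self`.
    """
    if params is None:
        params = SearchParams()
    if not query_genes or not db_genes:
        raise StrainkitError("search requires non-empty query and database sets")
    k = params.word_size
    shortest = min(len(s) for _, s in list(query_genes) + list(db_genes))
    if k > shortest:
        raise WordSizeError(f"word size {k} exceeds shortest sequence length {shortest}")

    if params.alphabet == "aa":
        query_genes = [(i, _sanitize_protein(s)) for i, s in query_genes]
        db_genes = [(i, _sanitize_protein(s)) for i, s in db_genes]

    aligner = params.make_aligner()
    db_length = sum(len(s) for _, s in db_genes)

    # word -> [(db index, position)] over all db sequences
    word_index: dict[str, list[tuple[int, int]]] = {}
    for j, (_, sseq) in enumerate(db_genes):
        for w, positions in _kmer_positions(sseq, k).items():
            word_index.setdefault(w, []).extend((j, p) for p in positions)

    hits: list[AlignmentHit] = []
    for qid, qseq in query_genes:
        diag_counts: dict[tuple[int, int], int] = {}
        for w, qpositions in _kmer_positions(qseq, k).items():
            targets = word_index.get(w)
            if not targets:
                continue
            for qp in qpositions:
                for j, sp in targets:
                    key = (j, qp - sp)
                    diag_counts[key] = diag_counts.get(key, 0) + 1
        candidates = {j for (j, _), c in diag_counts.items()
                      if c >= params.min_diagonal_seeds}
        per_query: list[AlignmentHit] = []
        for j in sorted(candidates):
            sid, sseq = db_genes[j]
            alns = aligner.align(sseq, qseq)
            if not len(alns) or alns.score <= 0:
                continue
            hit = hit_from_alignment(alns[0], qid, sid, qseq, sseq, params, db_length)
            if hit.e_value <= params.e_ceiling:
                per_query.append(hit)
        per_query.sort(key=hit_sort_key)
        hits.extend(per_query)
    return hits


def best_hit_per_query(hits: Iterable[AlignmentHit], exclude_self: bool = True
                       ) -> dict[str, AlignmentHit]:
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if exclude_self and hit.is_self:
            continue
        cur = best.get(hit.query_id)
        if cur is None or hit_sort_key(hit) < hit_sort_key(cur):
            best[hit.query_id] = hit
    return best


def call_orthologs(hits_ab: Sequence[AlignmentHit], hits_ba: Sequence[AlignmentHit],
                   e_cutoff: float = 1e-5,
                   genes_a: Sequence[str] | None = None,
                   genes_b: Sequence[str] | None = None,
                   ) -> tuple[list[OrthologCall], list[str], list[str]]:
    """Reciprocal-best-hit ortholog calls plus per-genome specific genes.

    A pair ``(a, b)`` is orthologous iff ``b`` is ``a``'s best hit and
    ``a`` is ``b``'s best hit, both at ``e_value <= e_cutoff``.  Ties are
    broken by bit score, then percent identity, then subject id.  A gene
    appearing in no significant hit in either direction (as query or as
    subject) is specific; gene id universes may be supplied explicitly so
    zero-hit genes are counted.
    """
    ab = [h for h in hits_ab if h.e_value <= e_cutoff]
    ba = [h for h in hits_ba if h.e_value <= e_cutoff]
    best_ab = best_hit_per_query(ab, exclude_self=False)
    best_ba = best_hit_per_query(ba, exclude_self=False)

    pairs: list[OrthologCall] = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(OrthologCall(gene_a=a, gene_b=b))

    seen_a = {h.query_id for h in ab} | {h.subject_id for h in ba}
    seen_b = {h.subject_id for h in ab} | {h.query_id for h in ba}
    universe_a = set(genes_a) if genes_a is not None else seen_a
    universe_b = set(genes_b) if genes_b is not None else seen_b
    specific_a = sorted(universe_a - seen_a)
    specific_b = sorted(universe_b - seen_b)
    return pairs, specific_a, specific_b


def classify_hgt(gene_id: str, hits: Sequence[AlignmentHit],
                 taxonomy: Mapping[str, TaxonomyLabel], focal_order: str,
                 exclude_subjects: Iterable[str] = ()) -> HgtCall:
    """Classify one gene as horizontally transferred or not.

    ``hits`` must already be filtered to significant E-values.  The gene
    is HGT iff it has at least one hit and none of its hits falls in
    ``focal_order``; the donor is the order of the best remaining hit.
    A gene with no hits at all is *not* HGT — it is a candidate specific
    gene.  Subjects in ``exclude_subjects`` (e.g. the gene's own genome)
    are ignored.
    """
    excluded = set(exclude_subjects)
    kept = [h for h in hits if h.query_id == gene_id and h.subject_id not in excluded]
    for h in kept:
        if h.subject_id not in taxonomy:
            raise MissingTaxonomyError(f"subject {h.subject_id!r} missing from taxonomy map")
    if not kept:
        return HgtCall(gene_id=gene_id, is_hgt=False, n_hits=0)
    orders = {taxonomy[h.subject_id].order for h in kept}
    if focal_order in orders:
        return HgtCall(gene_id=gene_id, is_hgt=False, n_hits=len(kept))
    best = min(kept, key=hit_sort_key)
    return HgtCall(
        gene_id=gene_id,
        is_hgt=True,
        donor_order=taxonomy[best.subject_id].order,
        best_outside_hit=best,
        n_hits=len(kept),
    )


def summarize_hgt(calls: Sequence[HgtCall], gene_categories: Mapping[str, str]
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor-order and per-functional-category HGT summaries.

    Returns ``(orders, categories)`` data frames sorted by descending
    count then name; category percentages are over the HGT genes only
    and sum to 100 up to rounding.  Both are empty when no gene is HGT.
    """
    hgt = [c for c in calls if c.is_hgt]
    if not hgt:
        return (pd.DataFrame(columns=["order", "count"]),
                pd.DataFrame(columns=["category", "count", "percent"]))
    order_counts: dict[str, int] = {}
    cat_counts: dict[str, int] = {}
    for c in hgt:
        order_counts[c.donor_order] = order_counts.get(c.donor_order, 0) + 1
        cat = gene_categories.get(c.gene_id, "UNASSIGNED")
        cat_counts[cat] = cat_counts.get(cat, 0) + 1
    orders = pd.DataFrame(
        sorted(order_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["order", "count"],
    )
    total = len(hgt)
    cats = pd.DataFrame(
        [(k, v, 100.0 * v / total)
         for k, v in sorted(cat_counts.items(), key=lambda kv: (-kv[1], kv[0]))],
        columns=["category", "count", "percent"],
    )
    return orders, cats


# ---------------------------------------------------------------------------
# 12-column tabular hit format (the de-facto tabular output of BLAST-like
# searches: query, subject, %identity, length, mismatches, gaps, qstart,
# qend, sstart, send, evalue, bitscore) — 1-based inclusive coordinates on
# disk, converted at the boundary.


def write_hit_table(path, hits: Iterable[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}", str(h.aln_length),
                str(h.mismatches), str(h.gaps), str(h.qstart + 1), str(h.qend),
                str(h.sstart + 1), str(h.send), f"{h.e_value:.2e}", f"{h.bit_score:.1f}",
            ]) + "\n")


def read_hit_table(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(AlignmentHit(
                query_id=f[0], subject_id=f[1], percent_identity=float(f[2]),
                aln_length=int(f[3]), mismatches=int(f[4]), gaps=int(f[5]),
                qstart=int(f[6]) - 1, qend=int(f[7]), sstart=int(f[8]) - 1, send=int(f[9]),
                raw_score=float("nan"), bit_score=float(f[11]), e_value=float(f[10]),
                query_coverage=float("nan"),
            ))
    return hits
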