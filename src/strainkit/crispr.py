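"""CRISPR array detection: direct repeats (DR) separated by unique spacers.

A simplified repeat-chain detector: exact seed words of the minimum DR
length recurring at spacer-compatible intervals are chained, each chain is
extended outwards while all copies agree, and extra copies whose repeat
differs from the consensus by at most the mismatch budget are rescued at
the expected periods.  Overlapping candidates are resolved by spacer
count, then DR length, then leftmost start.  An array is "confirmed" when
it has at least the minimum number of spacers and all spacers are
pairwise distinct, otherwise "questionable".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GenomeRecord

__all__ = ["CrisprParams", "CrisprArray", "detect_crispr_arrays", "write_crispr_table"]


@dataclass
class CrisprParams:
    dr_min: int = 23
    dr_max: int = 55
    spacer_min_frac: float = 0.6    # of the DR length
    spacer_max_frac: float = 2.5
    max_dr_mismatch: int = 1        # per rescued copy, against the consensus
    min_spacers_confirmed: int = 3
    max_seed_occurrences: int = 200  # skip hyper-repetitive words


@dataclass
class CrisprArray:
    contig_id: str
    start: int
    end: int                         # 0-based half-open
    dr_consensus: str
    dr_length: int
    n_spacers: int
    spacer_length_min: int
    spacer_length_max: int
    confidence: str                  # "confirmed" | "questionable"

    @property
    def length(self) -> int:
        return self.end - self.start


def _chain_seed_positions(positions: list[int], per_min: int, per_max: int
                          ) -> list[list[int]]:
    """Maximal runs of positions whose successive gaps are spacer-compatible."""
    chains: list[list[int]] = []
    current = [positions[0]]
    for p in positions[1:]:
        gap = p - current[-1]
        if per_min <= gap <= per_max:
            current.append(p)
        elif gap > per_max:
            if len(current) >= 2:
                chains.append(current)
            current = [p]
        # gap < per_min: overlapping occurrence, ignore
    if len(current) >= 2:
        chains.append(current)
    return chains


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _extend_chain(seq: str, starts: list[int], k: int, params: CrisprParams
                  ) -> tuple[list[int], int] | None:
    """Extend seed copies outwards while unanimous; returns (DR starts, dr_len)."""
    left = 0
    while (starts[0] - left - 1 >= 0
           and k + left + 1 + 0 <= params.dr_max
           and len({seq[p - left - 1] for p in starts}) == 1):
        left += 1
    right = 0
    while (starts[-1] + k + right < len(seq)
           and k + left + right + 1 <= params.dr_max
           and len({seq[p + k + right] for p in starts}) == 1):
        right += 1
    dr_len = k + left + right
    dr_starts = [p - left for p in starts]
    # validate spacer lengths; keep the longest valid run of copies
    lo = params.spacer_min_frac * dr_len
    hi = params.spacer_max_frac * dr_len
    best_run: list[int] = []
    run = [dr_starts[0]]
    for p in dr_starts[1:]:
        spacer = p - run[-1] - dr_len
        if lo <= spacer <= hi:
            run.append(p)
        else:
            if len(run) > len(best_run):
                best_run = run
            run = [p]
    if len(run) > len(best_run):
        best_run = run
    if len(best_run) < 2:
        return None
    return best_run, dr_len


def _refine_boundaries(seq: str, starts: list[int], dr_len: int, params: CrisprParams
                       ) -> tuple[list[int], int]:
    """Re-derive the DR window against the full copy set.

    Rescued copies can carry mismatches, so the DR found on a sub-chain
    may overhang the true repeat: trim boundary columns on which the
    copies disagree, then re-extend unanimously, keeping spacers legal.
    """
    while dr_len > params.dr_min and len({seq[p] for p in starts}) > 1:
        starts = [p + 1 for p in starts]
        dr_len -= 1
    while dr_len > params.dr_min and len({seq[p + dr_len - 1] for p in starts}) > 1:
        dr_len -= 1

    def min_spacer(st: list[int], dl: int) -> float:
        return min((b - a - dl) for a, b in zip(st, st[1:])) if len(st) > 1 else float("inf")

    while (dr_len < params.dr_max and starts[0] > 0
           and len({seq[p - 1] for p in starts}) == 1
           and min_spacer([p - 1 for p in starts], dr_len + 1)
           >= params.spacer_min_frac * (dr_len + 1)):
        starts = [p - 1 for p in starts]
        dr_len += 1
    while (dr_len < params.dr_max and starts[-1] + dr_len < len(seq)
           and len({seq[p + dr_len] for p in starts}) == 1
           and min_spacer(starts, dr_len + 1) >= params.spacer_min_frac * (dr_len + 1)):
        dr_len += 1
    return starts, dr_len


def _rescue_copies(seq: str, starts: list[int], dr_len: int, params: CrisprParams
                   ) -> list[int]:
    """Admit flanking copies matching the consensus within the mismatch budget."""
    consensus = seq[starts[0] : starts[0] + dr_len]
    lo = int(params.spacer_min_frac * dr_len)
    hi = int(params.spacer_max_frac * dr_len)
    starts = list(starts)
    changed = True
    while changed:
        changed = False
        # rightwards
        base = starts[-1] + dr_len
        best = None
        for spacer in range(lo, hi + 1):
            t = base + spacer
            if t + dr_len > len(seq):
                break
            mm = _hamming(seq[t : t + dr_len], consensus)
            if mm <= params.max_dr_mismatch and (best is None or mm < best[0]):
                best = (mm, t)
        if best is not None:
            starts.append(best[1])
            changed = True
        # leftwards
        best = None
        for spacer in range(lo, hi + 1):
            t = starts[0] - spacer - dr_len
            if t < 0:
                break
            mm = _hamming(seq[t : t + dr_len], consensus)
            if mm <= params.max_dr_mismatch and (best is None or mm < best[0]):
                best = (mm, t)
        if best is not None:
            starts.insert(0, best[1])
            changed = True
    return starts


def detect_crispr_arrays(genome: GenomeRecord, params: CrisprParams | None = None
                         ) -> list[CrisprArray]:
    """Detect CRISPR arrays in every contig of a genome.

    Returns non-overlapping arrays sorted by (contig, start); an empty
    genome or one without qualifying repeats yields an empty list.
    """
    if params is None:
        params = CrisprParams()
    k = params.dr_min
    per_min = int((1 + params.spacer_min_frac) * params.dr_min)
    per_max = int((1 + params.spacer_max_frac) * params.dr_max)

    candidates: list[tuple[str, list[int], int]] = []   # (contig, DR starts, dr_len)
    for contig_id, seq in genome.contigs:
        if len(seq) < 2 * k:
            continue
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        seen: set[tuple[int, ...]] = set()
        for positions in index.values():
            if not (2 <= len(positions) <= params.max_seed_occurrences):
                continue
            for chain in _chain_seed_positions(positions, per_min, per_max):
                extended = _extend_chain(seq, chain, k, params)
                if extended is None:
                    continue
                starts, dr_len = extended
                starts = _rescue_copies(seq, starts, dr_len, params)
                starts, dr_len = _refine_boundaries(seq, starts, dr_len, params)
                key = (hash(contig_id), dr_len, *starts)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append((contig_id, starts, dr_len))

    # overlap resolution: more spacers, then longer DR, then leftmost
    arrays: list[CrisprArray] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    contig_seq = dict(genome.contigs)
    candidates.sort(key=lambda c: (-(len(c[1]) - 1), -c[2], c[1][0], c[0]))
    for contig_id, starts, dr_len in candidates:
        start, end = starts[0], starts[-1] + dr_len
        spans = occupied.setdefault(contig_id, [])
        if any(s < end and start < e for s, e in spans):
            continue
        seq = contig_seq[contig_id]
        spacers = [seq[starts[i] + dr_len : starts[i + 1]] for i in range(len(starts) - 1)]
        consensus = seq[starts[0] : starts[0] + dr_len]
        # a "spacer" containing the repeat itself means the chain skipped
        # copies of a tandem repeat, not a CRISPR array
        if any(consensus in s for s in spacers):
            continue
        spans.append((start, end))
        distinct = len(set(spacers)) == len(spacers)
        confidence = ("confirmed"
                      if len(spacers) >= params.min_spacers_confirmed and distinct
                      else "questionable")
        arrays.append(CrisprArray(
            contig_id=contig_id, start=start, end=end,
            dr_consensus=seq[starts[0] : starts[0] + dr_len], dr_length=dr_len,
            n_spacers=len(spacers),
            spacer_length_min=min(len(s) for s in spacers),
            spacer_length_max=max(len(s) for s in spacers),
            confidence=confidence))
    arrays.sort(key=lambda a: (a.contig_id, a.start))
    return arrays


def write_crispr_table(path, arrays_by_genome: dict[str, list[CrisprArray]]) -> None:
    """TSV report: one row per array with length, DR length, spacer count and range."""
    with open(path, "w") as fh:
        fh.write("genome_id\tarray\tcontig_id\tstart\tlength\tdr_length\tn_spacers"
                 "\tspacer_length\tconfidence\n")
        for genome_id in sorted(arrays_by_genome):
            for i, a in enumerate(arrays_by_genome[genome_id], start=1):
                spacer_range = (str(a.spacer_length_min)
                                if a.spacer_length_min == a.spacer_length_max
                                else f"{a.spacer_length_min}-{a.spacer_length_max}")
                fh.write(f"{genome_id}\tCRISPR {i}\t{a.contig_id}\t{a.start}\t{a.length}"
                         f"\t{a.dr_length}\t{a.n_spacers}\t{spacer_range}"
                         f"\t{a.confidence}\n")
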