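"""Quadripartite plastome architecture detection and genome summaries.

A typical plastome is a circle partitioned into a large single-copy region
(LSC) and a small single-copy region (SSC) separated by two inverted
repeats (IRa/IRb) that are exact reverse complements of each other.  The
detector below finds the maximal pair of disjoint exact reverse-complement
repeats and derives the two single-copy regions from the gaps between them,
honoring circularity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from .io_formats import Plastome, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class QuadripartiteStructure:
    """The four regions, 1-based inclusive on the linearized genome.

    Intervals may wrap the origin, in which case start > end; lengths are
    always the circular arc lengths.  ``ira`` is the inverted-repeat copy
    that follows the LSC in coordinate direction.
    """

    found: bool
    genome_len: int
    lsc: Optional[tuple[int, int]] = None
    ira: Optional[tuple[int, int]] = None
    ssc: Optional[tuple[int, int]] = None
    irb: Optional[tuple[int, int]] = None

    def _arc_len(self, iv: Optional[tuple[int, int]]) -> int:
        if iv is None:
            return 0
        lo, hi = iv
        return hi - lo + 1 if lo <= hi else self.genome_len - lo + 1 + hi

    @property
    def lsc_len(self) -> int:
        return self._arc_len(self.lsc)

    @property
    def ssc_len(self) -> int:
        return self._arc_len(self.ssc)

    @property
    def ir_len(self) -> int:
        return self._arc_len(self.ira)


def gc_content(p: Plastome) -> float:
    """(G+C) / (A+C+G+T), with N excluded from the denominator.

    Returned as a fraction; report ``round(100 * gc, 2)`` for a percentage.
    """
    seq = p.sequence
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise ValueError(f"{p.id}: sequence contains no unambiguous bases")
    return gc / atgc


def _candidate_runs(seq: str, n: int, k: int):
    """Anti-diagonal runs of reverse-complement k-mer matches.

    Yields (a, b, length) for maximal seed runs where seq[a:a+length] is the
    reverse complement of seq[b:b+length]; ``seq`` may be the doubled
    sequence of a circular genome, in which case ``n`` is the original
    length and only i < n is scanned.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq) - k + 1):
        index[seq[j:j + k]].append(j)
    # group matches (i, j) by anti-diagonal d = i + j
    diags: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        w = revcomp(seq[i:i + k])
        for j in index.get(w, ()):
            if i < j < i + n:
                diags[i + j].append(i)
    for d, starts in diags.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:] + [None]:  # type: ignore[list-item]
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            yield run_start, d - prev, length
            if i is not None:
                run_start = prev = i

def detect_quadripartite(p: Plastome, min_ir_len: int = 10_000,
                         k: int = 63) -> QuadripartiteStructure:
    """Locate LSC/IRa/SSC/IRb by maximal exact reverse-complement repeats.

    Returns ``found=False`` when no disjoint reverse-complement repeat pair
    of at least ``min_ir_len`` exists.  Ties between maximal pairs are
    broken by minimizing the SSC length (plastome convention).  Detection
    is invariant under rotation of a circular genome.
    """
    n = len(p.sequence)
    if min_ir_len < k:
        raise ValueError("min_ir_len must be at least the seed size")
    seq = p.sequence + p.sequence if p.circular else p.sequence
    best: Optional[tuple[int, int, int]] = None  # (length, -ssc_len, key) + intervals
    best_iv: Optional[tuple[int, int, int]] = None
    for a, b, length in _candidate_runs(seq, n, k):
        if length < min_ir_len:
            continue
        # extend outward (a left / b right) and inward while exact and disjoint
        while a > 0 and b + length < len(seq) and \
                seq[a - 1] == _COMP[seq[b + length]] and (b + length) - a < n - 1:
            a -= 1
            length += 1
        while a + length < b and seq[a + length] == _COMP[seq[b - 1]]:
            b -= 1
            length += 1
        if a + length > b or (b + length) - a > n:  # overlapping arcs
            continue
        gap_inner = b - (a + length)           # arc between IR copies (one way)
        gap_outer = n - 2 * length - gap_inner  # the other way around the circle
        if gap_outer < 0:
            continue
        ssc = min(gap_inner, gap_outer)
        key = (length, -ssc, -(a % n))
        if best is None or key > best:
            best = key
            best_iv = (a % n, b % n, length)
    if best_iv is None:
        return QuadripartiteStructure(found=False, genome_len=n)
    a, b, length = best_iv

    def iv(start0: int, arc: int) -> tuple[int, int]:
        lo = start0 % n
        hi = (start0 + arc - 1) % n
        return lo + 1, hi + 1

    # arcs on the circle: [a, a+L) and [b, b+L); single-copy gaps between them
    gap_ab = (b - (a + length)) % n   # from end of copy A to start of copy B
    gap_ba = (a - (b + length)) % n   # from end of copy B to start of copy A
    if gap_ab >= gap_ba:
        lsc_start, lsc_len = a + length, gap_ab
        ira_start, ssc_start, ssc_len, irb_start = b, b + length, gap_ba, a
    else:
        lsc_start, lsc_len = b + length, gap_ba
        ira_start, ssc_start, ssc_len, irb_start = a, a + length, gap_ab, b
    return QuadripartiteStructure(
        found=True, genome_len=n,
        lsc=iv(lsc_start, lsc_len), ira=iv(ira_start, length),
        ssc=iv(ssc_start, ssc_len), irb=iv(irb_start, length),
    )
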