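"""Assembly-vs-assembly plastome comparison.

Two finished plastome sequences are aligned through *anchors*: k-mers that
occur exactly once in each genome.  Anchors shared in the same orientation
are chained into collinear forward blocks; anchors shared in opposite
orientation chain into inverted blocks (inversions).  Within forward
blocks, the short stretches between exact anchor matches are globally
aligned with affine gap scores and emitted as left-normalized SNP/INS/DEL
events.  Inverted blocks are reported as :class:`InversionCall`\\ s and are
excluded from variant calling.

Coordinate conventions for :class:`VariantRecord`:

* SNP  - ``pos`` is the substituted reference base (1-based).
* DEL  - ``pos`` is the first deleted reference base; ``alt_allele`` empty.
* INS  - the inserted sequence sits immediately *before* reference base
  ``pos``; ``ref_allele`` empty.

Indels are left-aligned against the reference within their homopolymer or
repeat context (SAMtools convention), which makes event counting
deterministic.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io_formats import GeneFeature, Plastome, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: affine-gap scores for inter-anchor gap alignment
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -4, -1
#: longest gap pair handed to the global aligner
MAX_ALIGN_LEN = 20_000
#: start codons accepted at codon 1 when a gene allows alternative initiation
_START_CODONS = {"ATG", "GTG", "ACG", "TTG"}


class AlignmentError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One normalized difference between two plastomes."""

    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | INS | DEL | MNP
    region: Optional[str] = None  # CDS | intron | intergenic
    gene: Optional[str] = None
    effect: Optional[str] = None  # 'synonymous' or e.g. 'P58S'

    def __post_init__(self) -> None:
        if self.vtype == "SNP" and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise ValueError("SNP must have single-base ref and alt alleles")
        if self.vtype == "INS" and self.ref_allele:
            raise ValueError("INS must have an empty ref allele")
        if self.vtype == "DEL" and self.alt_allele:
            raise ValueError("DEL must have an empty alt allele")

    def key(self) -> tuple:
        return (self.pos, self.vtype, self.ref_allele, self.alt_allele)


@dataclass
class AnchorBlock:
    """A run of orientation-consistent anchors; coordinates 0-based half-open."""

    orientation: str  # 'forward' | 'inverted'
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int
    anchors: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AnchorChain:
    ref: Plastome
    query: Plastome
    k: int
    blocks: list[AnchorBlock]

    def forward_blocks(self) -> list[AnchorBlock]:
        return [b for b in self.blocks if b.orientation == "forward"]

    def inverted_blocks(self) -> list[AnchorBlock]:
        return [b for b in self.blocks if b.orientation == "inverted"]

    def ref_coverage(self) -> float:
        ivs = [(b.ref_start, b.ref_end) for b in self.blocks]
        return _union_len(ivs) / len(self.ref.sequence)

    def query_coverage(self) -> float:
        ivs = [(b.q_start, b.q_end) for b in self.blocks]
        return _union_len(ivs) / len(self.query.sequence)


@dataclass
class InversionCall:
    """A reverse-complemented segment shared between two plastomes.

    Intervals are 1-based inclusive.  When a repeat pair flanks the
    inversion (a common mediator of plastome recombination), its intervals
    and percent identity are reported.
    """

    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    length: int
    flank_left: Optional[tuple[int, int]] = None
    flank_right: Optional[tuple[int, int]] = None
    flank_identity: Optional[float] = None  # matches / aligned columns
    flank_matches: Optional[int] = None
    flank_aligned: Optional[int] = None


@dataclass
class DiagnosticLocusSet:
    """SNP loci whose alleles distinguish two genomes (cytotypes)."""

    pair_ids: tuple[str, str]
    loci: list[tuple[int, str, str]]  # (pos, allele_A, allele_B)

    def __post_init__(self) -> None:
        prev = 0
        for pos, a, b in self.loci:
            if a == b:
                raise ValueError(f"locus {pos}: alleles must differ")
            if pos <= prev:
                raise ValueError("locus positions must be strictly increasing")
            prev = pos

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def positions(self) -> list[int]:
        return [pos for pos, _, _ in self.loci]


# ---------------------------------------------------------------------------
# anchoring and chaining
# ---------------------------------------------------------------------------

def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for lo, hi in sorted(intervals):
        lo = max(lo, last)
        if hi > lo:
            total += hi - lo
            last = hi
        last = max(last, hi)
    return total


def _unique_kmer_map(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        counts[w] = -1 if w in counts else i
    return {w: i for w, i in counts.items() if i >= 0}


def _lis_chain(anchors: list[tuple[int, int]], decreasing_q: bool) -> list[tuple[int, int]]:
    """Longest chain of anchors with r strictly increasing and q strictly
    monotone (increasing, or decreasing when ``decreasing_q``)."""
    if not anchors:
        return []
    anchors = sorted(anchors)
    qs = [(-q if decreasing_q else q) for _, q in anchors]
    tails: list[int] = []          # q-value of smallest tail per chain length
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for i, q in enumerate(qs):
        j = bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out: list[tuple[int, int]] = []
    i = tails_idx[-1]
    while i >= 0:
        out.append(anchors[i])
        i = prev[i]
    return out[::-1]


def _split_blocks(chain: list[tuple[int, int]], k: int, orientation: str,
                  max_join_gap: int) -> list[AnchorBlock]:
    blocks: list[AnchorBlock] = []
    group: list[tuple[int, int]] = []

    def flush() -> None:
        if not group:
            return
        rs, re = group[0][0], group[-1][0] + k
        if orientation == "forward":
            qs, qe = group[0][1], group[-1][1] + k
        else:
            qs, qe = group[-1][1], group[0][1] + k
        blocks.append(AnchorBlock(orientation, rs, re, qs, qe, list(group)))

    for r, q in chain:
        if group:
            pr, pq = group[-1]
            dr = r - pr
            dq = (pq - q) if orientation == "inverted" else (q - pq)
            if dr > max_join_gap or dq > max_join_gap or abs(dr - dq) > max_join_gap:
                flush()
                group = []
        group.append((r, q))
    flush()
    return blocks


def _extend_block(b: AnchorBlock, ref: str, query: str) -> None:
    """Grow a block by exact base matching beyond the outermost anchors."""
    if b.orientation == "forward":
        while b.ref_start > 0 and b.q_start > 0 and \
                ref[b.ref_start - 1] == query[b.q_start - 1]:
            b.ref_start -= 1
            b.q_start -= 1
        while b.ref_end < len(ref) and b.q_end < len(query) and \
                ref[b.ref_end] == query[b.q_end]:
            b.ref_end += 1
            b.q_end += 1
    else:
        # ref[rs:re] ~ revcomp(query[qs:qe])
        while b.ref_start > 0 and b.q_end < len(query) and \
                ref[b.ref_start - 1] == _COMP[query[b.q_end]]:
            b.ref_start -= 1
            b.q_end += 1
        while b.ref_end < len(ref) and b.q_start > 0 and \
                ref[b.ref_end] == _COMP[query[b.q_start - 1]]:
            b.ref_end += 1
            b.q_start -= 1


def anchor_align(ref: Plastome, query: Plastome, k: int = 31,
                 max_join_gap: int = 5_000) -> AnchorChain:
    """Chain unique k-mer anchors into forward and inverted blocks.

    Forward anchors are chained first (longest monotone subsequence); the
    inversion search then runs only over the stretches the forward chain
    leaves uncovered, which keeps the two identical IR copies paired
    copy-to-copy by position rather than cross-paired as a spurious
    inversion.
    """
    rseq, qseq = ref.sequence, query.sequence
    if len(rseq) < k or len(qseq) < k:
        raise AlignmentError(f"sequences must be at least k={k} long")
    rmap = _unique_kmer_map(rseq, k)
    qmap = _unique_kmer_map(qseq, k)
    forward = [(r, qmap[w]) for w, r in rmap.items() if w in qmap]
    inverted = []
    for w, r in rmap.items():
        q = qmap.get(revcomp(w))
        if q is not None:
            inverted.append((r, q))
    if not forward and not inverted:
        raise AlignmentError(
            f"no unique shared {k}-mer anchors between {ref.id} and {query.id}; "
            "try a smaller k"
        )
    fchain = _lis_chain(forward, decreasing_q=False)
    blocks = _split_blocks(fchain, k, "forward", max_join_gap)
    # inversions live in the stretches not touched by chained forward
    # anchors themselves (forward blocks absorb unanchored gaps, so block
    # extents would hide any inversion shorter than the join gap)
    anchors_r = sorted(r for r, _ in fchain)
    anchors_q = sorted(q for _, q in fchain)

    def _on_anchor(starts: list[int], x: int) -> bool:
        i = bisect_left(starts, x + 1) - 1
        return i >= 0 and starts[i] + k > x

    inv_free = [(r, q) for r, q in inverted
                if not _on_anchor(anchors_r, r) and not _on_anchor(anchors_q, q)]
    ichain = _lis_chain(inv_free, decreasing_q=True)
    blocks.extend(_split_blocks(ichain, k, "inverted", max_join_gap))
    for b in blocks:
        _extend_block(b, rseq, qseq)
    blocks.sort(key=lambda b: b.ref_start)
    return AnchorChain(ref=ref, query=query, k=k, blocks=blocks)


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _match_segments(block: AnchorBlock, k: int) -> list[tuple[int, int, int]]:
    """Merge overlapping same-diagonal anchors into exact match segments."""
    segs: list[tuple[int, int, int]] = []
    for r, q in block.anchors:
        if segs:
            r0, q0, ln = segs[-1]
            if q - r == q0 - r0 and r <= r0 + ln:
                segs[-1] = (r0, q0, r + k - r0)
                continue
        segs.append((r, q, k))
    return segs


def _left_normalize_del(ref: str, i: int, deleted: str) -> tuple[int, str]:
    L = len(deleted)
    while i > 0 and ref[i - 1] == ref[i + L - 1]:
        i -= 1
    return i, ref[i:i + L]


def _left_normalize_ins(ref: str, i: int, inserted: str) -> tuple[int, str]:
    while i > 0 and ref[i - 1] == inserted[-1]:
        inserted = ref[i - 1] + inserted[:-1]
        i -= 1
    return i, inserted


def _gap_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _events_from_gap(ref: str, r0: int, ref_gap: str, q_gap: str,
                     aligner: PairwiseAligner) -> list[VariantRecord]:
    """Align one inter-anchor gap pair and emit normalized events.

    ``r0`` is the 0-based reference offset of the gap start.
    """
    events: list[VariantRecord] = []

    def add_del(i: int, deleted: str) -> None:
        i, deleted = _left_normalize_del(ref, i, deleted)
        events.append(VariantRecord(i + 1, deleted, "", "DEL"))

    def add_ins(i: int, inserted: str) -> None:
        i, inserted = _left_normalize_ins(ref, i, inserted)
        events.append(VariantRecord(i + 1, "", inserted, "INS"))

    if not ref_gap and not q_gap:
        return events
    if not q_gap:
        add_del(r0, ref_gap)
        return events
    if not ref_gap:
        add_ins(r0, q_gap)
        return events

    aln = aligner.align(ref_gap, q_gap)[0]
    arow, brow = str(aln[0]), str(aln[1])
    ri = r0
    col = 0
    while col < len(arow):
        a, b = arow[col], brow[col]
        if a == "-":  # insertion relative to reference
            j = col
            while j < len(arow) and arow[j] == "-":
                j += 1
            add_ins(ri, brow[col:j])
            col = j
        elif b == "-":  # deletion
            j = col
            while j < len(arow) and brow[j] == "-":
                j += 1
            add_del(ri, arow[col:j])
            ri += j - col
            col = j
        else:
            if a != b:
                events.append(VariantRecord(ri + 1, a, b, "SNP"))
            ri += 1
            col += 1
    return events


def call_variants(ref: Plastome, query: Plastome, chain: AnchorChain,
                  max_align_len: int = MAX_ALIGN_LEN,
                  min_coverage: float = 0.95) -> list[VariantRecord]:
    """Call left-normalized SNP/INS/DEL events within forward blocks.

    Inverted blocks are excluded (see :func:`detect_inversions`); runs of
    adjacent substitutions are emitted as separate SNPs (use
    :func:`merge_adjacent_snps` to collapse them into MNPs for reporting).
    """
    if chain.ref_coverage() < min_coverage or chain.query_coverage() < min_coverage:
        raise AlignmentError(
            f"anchor chain covers only {chain.ref_coverage():.1%} of {ref.id} / "
            f"{chain.query_coverage():.1%} of {query.id}; need >= {min_coverage:.0%}"
        )
    rseq, qseq = ref.sequence, query.sequence
    aligner = _gap_aligner()
    inverted_r = [(b.ref_start, b.ref_end) for b in chain.inverted_blocks()]

    segments: list[tuple[int, int, int]] = []
    for b in chain.forward_blocks():
        segments.extend(_match_segments(b, chain.k))
    segments.sort()
    # adjacent segments may overlap on one genome through different
    # diagonals (e.g. both sides of an indel inside a homopolymer); trim
    # each segment's front so boundaries are consistent on both genomes
    bounds: list[tuple[int, int, int]] = [(0, 0, 0)]
    for r, q, ln in segments:
        pr, pq, pln = bounds[-1]
        t = max(0, (pr + pln) - r, (pq + pln) - q)
        if ln - t <= 0:
            continue
        bounds.append((r + t, q + t, ln - t))
    bounds.append((len(rseq), len(qseq), 0))

    events: list[VariantRecord] = []
    for (r0, q0, ln), (r1, q1, _) in zip(bounds, bounds[1:]):
        re, qe = r0 + ln, q0 + ln
        if re >= r1 and qe >= q1:
            continue
        if any(lo < r1 and re < hi for lo, hi in inverted_r):
            continue  # the gap is (or contains) an inversion
        ref_gap, q_gap = rseq[re:r1], qseq[qe:q1]
        if len(ref_gap) > max_align_len or len(q_gap) > max_align_len:
            raise AlignmentError(
                f"unalignable gap pair ref[{re + 1}:{r1}] "
                f"({len(ref_gap)} bp) vs query[{qe + 1}:{q1}] ({len(q_gap)} bp) "
                f"exceeds {max_align_len} bp"
            )
        events.extend(_events_from_gap(rseq, re, ref_gap, q_gap, aligner))
    events.sort(key=lambda v: (v.pos, v.vtype))
    return events


def merge_adjacent_snps(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Collapse runs of adjacent SNPs into MNP records (reporting option)."""
    out: list[VariantRecord] = []
    for v in variants:
        if (out and v.vtype == "SNP" and out[-1].vtype in {"SNP", "MNP"}
                and out[-1].pos + len(out[-1].ref_allele) == v.pos):
            prev = out.pop()
            out.append(VariantRecord(
                prev.pos, prev.ref_allele + v.ref_allele,
                prev.alt_allele + v.alt_allele, "MNP"))
        else:
            out.append(v)
    return out


def apply_variants(seq: str, variants: Sequence[VariantRecord]) -> str:
    """Apply SNP/INS/DEL records to a reference sequence (test utility)."""
    s = list(seq)
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - 1
        if v.vtype == "SNP":
            s[i] = v.alt_allele
        elif v.vtype == "DEL":
            del s[i:i + len(v.ref_allele)]
        elif v.vtype == "INS":
            s[i:i] = list(v.alt_allele)
        else:
            raise ValueError(f"cannot apply vtype {v.vtype}")
    return "".join(s)


# ---------------------------------------------------------------------------
# inversions
# ---------------------------------------------------------------------------

def _flank_repeat(ref: str, rs: int, re: int, window: int):
    """Best local alignment of the left flank vs the reverse complement of
    the right flank; returns (left_iv, right_iv, identity, matches, cols)."""
    left = ref[max(0, rs - window):rs]
    right = ref[re:re + window]
    if len(left) < 10 or len(right) < 10:
        return None
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    alns = aligner.align(left, revcomp(right))
    if len(alns) == 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if counts.identities < 15:
        return None
    (lspan, rspan) = aln.aligned[0], aln.aligned[1]
    l0, l1 = int(lspan[0][0]), int(lspan[-1][1])
    r0, r1 = int(rspan[0][0]), int(rspan[-1][1])
    off_l = max(0, rs - window)
    left_iv = (off_l + l0 + 1, off_l + l1)
    # right span was taken on the reverse complement; map back
    rlen = len(right)
    right_iv = (re + (rlen - r1) + 1, re + (rlen - r0))
    return left_iv, right_iv, counts.identities / cols, counts.identities, cols


def detect_inversions(chain: AnchorChain, flank_window: int = 500) -> list[InversionCall]:
    """One :class:`InversionCall` per maximal inverted block, with an
    inverted-repeat pair searched within ``flank_window`` bp of each side."""
    calls = []
    ref = chain.ref.sequence
    for b in chain.inverted_blocks():
        call = InversionCall(
            ref_interval=(b.ref_start + 1, b.ref_end),
            query_interval=(b.q_start + 1, b.q_end),
            length=b.ref_end - b.ref_start,
        )
        hit = _flank_repeat(ref, b.ref_start, b.ref_end, flank_window)
        if hit is not None:
            (call.flank_left, call.flank_right, call.flank_identity,
             call.flank_matches, call.flank_aligned) = hit
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# genomic context and coding effect
# ---------------------------------------------------------------------------

def classify_region(v: VariantRecord, p: Plastome) -> tuple[str, Optional[str]]:
    """Assign (region, gene) for a variant position.

    CDS if inside a protein-coding exon; intron if inside a gene span but
    not inside any of its exons; intergenic otherwise (positions inside
    tRNA/rRNA exons and pseudogene exons count as noncoding/intergenic).
    """
    pos = v.pos
    for f in p.features:
        if f.kind == "CDS" and not f.is_pseudo and f.contains(pos):
            return "CDS", f.name
    for f in p.features:
        if f.in_span(pos) and not f.contains(pos):
            return "intron", f.name
    return "intergenic", None


def _translate_codon(codon: str, first: bool, alt_start_ok: bool) -> str:
    if first and codon in _START_CODONS and (codon == "ATG" or alt_start_ok):
        return "M"
    return str(Seq(codon).translate(table=11))


def annotate_effect(v: VariantRecord, p: Plastome) -> str:
    """Coding effect of a CDS SNP: 'synonymous' or an aa change like 'P58S'.

    Rebuilds the affected codon in transcription direction (strand-aware,
    exon-joined, honoring codon_start and ACG/GTG alternative initiation)
    and translates with the plastid/bacterial code.
    """
    if v.vtype != "SNP":
        raise ValueError("effect annotation is defined for SNPs only")
    feat = next((f for f in p.features
                 if f.kind == "CDS" and not f.is_pseudo and f.contains(v.pos)), None)
    if feat is None:
        raise ValueError(f"position {v.pos} is not inside a protein-coding exon")
    cds = feat.cds_sequence(p.sequence)
    if (len(cds) - (feat.codon_start - 1)) % 3 != 0:
        raise ValueError(
            f"CDS {feat.name!r} length {len(cds)} is not a codon multiple"
        )
    off = 0
    for lo, hi in feat.exons:
        if lo <= v.pos <= hi:
            off += (v.pos - lo) if feat.strand == "+" else (hi - v.pos)
            break
        off += hi - lo + 1
    alt_base = v.alt_allele if feat.strand == "+" else _COMP[v.alt_allele]
    ref_base = v.ref_allele if feat.strand == "+" else _COMP[v.ref_allele]
    if cds[off] != ref_base:
        raise ValueError(
            f"reference allele {v.ref_allele!r} does not match CDS "
            f"{feat.name!r} at position {v.pos}"
        )
    off -= feat.codon_start - 1
    if off < 0:
        raise ValueError(f"position {v.pos} precedes codon_start of {feat.name!r}")
    ci = off // 3
    ref_codon = cds[feat.codon_start - 1 + 3 * ci: feat.codon_start - 1 + 3 * ci + 3]
    alt_codon = ref_codon[:off % 3] + alt_base + ref_codon[off % 3 + 1:]
    aa_ref = _translate_codon(ref_codon, ci == 0, feat.alt_start_ok)
    aa_alt = _translate_codon(alt_codon, ci == 0, feat.alt_start_ok)
    if aa_ref == aa_alt:
        return "synonymous"
    return f"{aa_ref}{ci + 1}{aa_alt}"


def annotate_variants(variants: Sequence[VariantRecord],
                      p: Plastome) -> list[VariantRecord]:
    """Fill region/gene for all records and effect for CDS SNPs, in place."""
    for v in variants:
        v.region, v.gene = classify_region(v, p)
        if v.region == "CDS" and v.vtype == "SNP":
            v.effect = annotate_effect(v, p)
    return list(variants)


def diagnostic_loci(genome_a: Plastome, genome_b: Plastome,
                    chain: Optional[AnchorChain] = None,
                    k: int = 31) -> DiagnosticLocusSet:
    """The SNP subset of a pairwise comparison, keyed by reference position.

    Indels are excluded: their read-level frequencies are unreliable, so
    cytotype classification and heteroplasmy quantification use SNPs only.
    """
    if chain is None:
        chain = anchor_align(genome_a, genome_b, k=k)
    variants = call_variants(genome_a, genome_b, chain)
    loci = [(v.pos, v.ref_allele, v.alt_allele)
            for v in variants if v.vtype == "SNP"]
    return DiagnosticLocusSet(pair_ids=(genome_a.id, genome_b.id), loci=loci)
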