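"""Population-level summaries: nucleotide diversity, haplotypes, trees.

Nucleotide diversity (pi) is the average per-site proportion of pairwise
differences among the sampled sequences, computed with pairwise deletion:
a site with a gap or N in either member of a pair is excluded from that
pair's numerator and denominator.  The sliding-window profile lays windows
from alignment position 1 and drops the trailing partial window (DnaSP
behavior); a configured interval (e.g. a known inversion) can be masked.

Trees are neighbor-joining over Jukes-Cantor distances, with taxa ordered
lexicographically before clustering so that ties break deterministically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


@dataclass
class AlignmentMatrix:
    """Equal-length aligned sequences (gaps '-' allowed) with optional
    excluded intervals (1-based inclusive) masked from all computations."""

    ids: list[str]
    matrix: np.ndarray  # (n_samples, L) dtype '<U1'
    excluded: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_sequences(cls, records: Sequence[tuple[str, str]],
                       excluded: Sequence[tuple[int, int]] = ()) -> "AlignmentMatrix":
        ids = [r[0] for r in records]
        lengths = {len(r[1]) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences must share one length, got {lengths}")
        mat = np.array([list(r[1].upper()) for r in records], dtype="<U1")
        return cls(ids=ids, matrix=mat, excluded=list(excluded))

    def __post_init__(self) -> None:
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("one id per row required")
        L = self.matrix.shape[1]
        for lo, hi in self.excluded:
            if not (1 <= lo <= hi <= L):
                raise ValueError(f"excluded interval ({lo}, {hi}) out of bounds")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def valid_mask(self) -> np.ndarray:
        """(n, L) bool: informative (non-gap, non-N, non-excluded) cells."""
        m = (self.matrix != "-") & (self.matrix != "N")
        for lo, hi in self.excluded:
            m[:, lo - 1:hi] = False
        return m


@dataclass
class DiversityProfile:
    midpoints: np.ndarray
    pi: np.ndarray
    window_len: int
    step: int
    mean_pi: float


@dataclass
class HaplotypeTable:
    """Variant loci x samples allele matrix with haplotype grouping."""

    loci: list[tuple[int, str]]  # (pos, ref_allele_or_event_key)
    sample_ids: list[str]
    alleles: np.ndarray  # (n_loci, n_samples) dtype object/str
    haplotype_of: dict[str, str]
    haplotype_counts: dict[str, int]
    exclusive: list[bool]  # per locus: non-ref allele private to one group

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_counts)


def pairwise_pi(a: str, b: str) -> float:
    """Mismatches / compared sites between two aligned sequences, sites with
    a gap or N in either excluded (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    ok = ~np.isin(x, [b"-", b"N"]) & ~np.isin(y, [b"-", b"N"])
    n = int(ok.sum())
    if n == 0:
        raise ValueError("zero comparable sites")
    return float(((x != y) & ok).sum() / n)


def _pair_arrays(m: AlignmentMatrix):
    """Per-pair boolean (diff, comparable) arrays over alignment columns."""
    valid = m.valid_mask()
    for i, j in combinations(range(len(m.ids)), 2):
        ok = valid[i] & valid[j]
        diff = (m.matrix[i] != m.matrix[j]) & ok
        yield diff, ok


def mean_pi(m: AlignmentMatrix) -> float:
    """Mean over all unordered sample pairs of (differences / compared sites)."""
    vals = []
    for diff, ok in _pair_arrays(m):
        n = ok.sum()
        if n == 0:
            raise ValueError("a sample pair shares zero comparable sites")
        vals.append(diff.sum() / n)
    if not vals:
        raise ValueError("need >= 2 samples")
    return float(np.mean(vals))


def sliding_window_pi(m: AlignmentMatrix, window: int = 1200,
                      step: int = 400) -> DiversityProfile:
    """Windowed pi: per window, the mean over sample pairs of pairwise pi
    restricted to the window; masked intervals contribute nothing."""
    if len(m.ids) < 2:
        raise ValueError("need >= 2 samples")
    L = m.length
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    n_windows = (L - window) // step + 1
    starts = np.arange(n_windows) * step
    diffs, oks = [], []
    for diff, ok in _pair_arrays(m):
        diffs.append(np.concatenate([[0], np.cumsum(diff)]))
        oks.append(np.concatenate([[0], np.cumsum(ok)]))
    pis = np.zeros(n_windows)
    for w, s in enumerate(starts):
        e = s + window
        vals = []
        for d, o in zip(diffs, oks):
            nsites = o[e] - o[s]
            vals.append((d[e] - d[s]) / nsites if nsites else 0.0)
        pis[w] = np.mean(vals)
    midpoints = starts + (window + 1) / 2.0
    return DiversityProfile(midpoints=midpoints, pi=pis, window_len=window,
                            step=step, mean_pi=mean_pi(m))


def alignment_from_variants(
    ref_seq: str,
    variants_per_sample: Mapping[str, Sequence],
    excluded: Sequence[tuple[int, int]] = (),
) -> AlignmentMatrix:
    """Reference-projected alignment from per-sample variant calls.

    Each sample row starts as the reference; SNPs substitute their allele,
    deleted reference positions become gaps, and insertions (which have no
    reference column) are dropped.  This is the standard projection for
    computing diversity over resequenced samples without a multiple
    alignment.
    """
    rows = []
    for sample in sorted(variants_per_sample):
        s = list(ref_seq)
        for v in variants_per_sample[sample]:
            i = v.pos - 1
            if v.vtype == "SNP":
                s[i] = v.alt_allele
            elif v.vtype == "DEL":
                for j in range(i, i + len(v.ref_allele)):
                    s[j] = "-"
        rows.append((sample, "".join(s)))
    return AlignmentMatrix.from_sequences(rows, excluded=excluded)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def build_haplotype_table(
    variants_per_sample: Mapping[str, Sequence],
    groups: Optional[Mapping[str, str]] = None,
) -> HaplotypeTable:
    """Collapse per-sample variant calls (one shared reference coordinate
    system) into a haplotype table.

    ``variants_per_sample`` maps sample id to VariantRecord-like objects;
    samples without a call at a locus carry the reference allele.  Two
    different calls at one position in one sample raise ``ValueError``.
    ``groups`` (sample -> cytotype label) enables the per-locus exclusivity
    flag: a locus is exclusive when every carrier of its non-reference
    allele belongs to one group.
    """
    sample_ids = sorted(variants_per_sample)
    locus_ref: dict[int, str] = {}
    alt_of: dict[str, dict[int, str]] = {s: {} for s in sample_ids}
    for s in sample_ids:
        for v in variants_per_sample[s]:
            key = f"{v.vtype}:{v.ref_allele}"
            alt = v.alt_allele
            if v.pos in alt_of[s] and alt_of[s][v.pos] != (key, alt):
                raise ValueError(f"conflicting calls at position {v.pos} in {s}")
            if v.pos in locus_ref and locus_ref[v.pos] != key:
                raise ValueError(f"conflicting reference context at position {v.pos}")
            locus_ref[v.pos] = key
            alt_of[s][v.pos] = (key, alt)
    positions = sorted(locus_ref)
    loci = [(pos, locus_ref[pos]) for pos in positions]
    alleles = np.empty((len(loci), len(sample_ids)), dtype=object)
    for j, s in enumerate(sample_ids):
        for i, pos in enumerate(positions):
            call = alt_of[s].get(pos)
            alleles[i, j] = call[1] if call else "."  # '.' = reference allele
    # identical allele columns <=> identical haplotype
    hap_ids: dict[tuple, str] = {}
    haplotype_of: dict[str, str] = {}
    for j, s in enumerate(sample_ids):
        colkey = tuple(alleles[:, j])
        if colkey not in hap_ids:
            hap_ids[colkey] = f"H{len(hap_ids) + 1}"
        haplotype_of[s] = hap_ids[colkey]
    counts: dict[str, int] = {}
    for h in haplotype_of.values():
        counts[h] = counts.get(h, 0) + 1
    exclusive = []
    for i, pos in enumerate(positions):
        carriers = [s for j, s in enumerate(sample_ids) if alleles[i, j] != "."]
        if groups and carriers:
            exclusive.append(len({groups[s] for s in carriers}) == 1)
        else:
            exclusive.append(False)
    return HaplotypeTable(loci=loci, sample_ids=sample_ids, alleles=alleles,
                          haplotype_of=haplotype_of, haplotype_counts=counts,
                          exclusive=exclusive)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def jc_distance_matrix(m: AlignmentMatrix) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) from pairwise pi."""
    n = len(m.ids)
    d = np.zeros((n, n))
    pairs = list(combinations(range(n), 2))
    valid = m.valid_mask()
    for i, j in pairs:
        ok = valid[i] & valid[j]
        nsites = ok.sum()
        if nsites == 0:
            raise ValueError(f"pair ({m.ids[i]}, {m.ids[j]}): zero comparable sites")
        p = ((m.matrix[i] != m.matrix[j]) & ok).sum() / nsites
        if p >= 0.75:
            raise ValueError(
                f"pair ({m.ids[i]}, {m.ids[j]}): p-distance {p:.3f} >= 0.75, "
                "Jukes-Cantor distance undefined"
            )
        d[i, j] = d[j, i] = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return DistanceMatrix(d, ids=m.ids)


def nj_tree(dm) -> str:
    """Neighbor-joining newick string with branch lengths; taxa are sorted
    lexicographically first so tie-breaking is deterministic.

    ``dm`` is a skbio DistanceMatrix (or any dissimilarity matrix with
    ``data`` and ``ids``); asymmetric input is rejected.
    """
    data = np.asarray(dm.data)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(data, ids=list(dm.ids))
    order = sorted(dm.ids)
    dm = dm.filter(order)
    tree = nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def has_bipartition(newick: str, group: Sequence[str]) -> bool:
    """Whether some edge of the (unrooted) tree splits ``group`` from the
    remaining taxa."""
    tree = TreeNode.read(io.StringIO(newick))
    all_tips = frozenset(t.name for t in tree.tips())
    want = frozenset(group)
    if not want <= all_tips:
        raise ValueError("group contains taxa absent from the tree")
    for node in tree.non_tips(include_self=True):
        clade = frozenset(t.name for t in node.tips())
        if clade == want or (all_tips - clade) == want:
            return True
    return False


def bootstrap_support(m: AlignmentMatrix, group: Sequence[str],
                      n_replicates: int = 100, seed: int = 0) -> float:
    """Fraction of column-resampled NJ replicates containing the bipartition
    that separates ``group`` from the rest."""
    rng = np.random.default_rng(seed)
    L = m.length
    base = m.matrix.copy()
    for lo, hi in m.excluded:
        base[:, lo - 1:hi] = "N"
    hits = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = AlignmentMatrix(ids=list(m.ids), matrix=base[:, cols])
        try:
            tree = nj_tree(jc_distance_matrix(rep))
        except ValueError:
            continue
        if has_bipartition(tree, group):
            hits += 1
    return hits / n_replicates
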