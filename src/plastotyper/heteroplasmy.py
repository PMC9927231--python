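"""Mixed-cytotype heteroplasmy quantification from filtered base counts.

Given a set of diagnostic SNP loci (positions whose alleles differ fixedly
between two plastome cytotypes) and a per-site base-count profile for one
deeply sequenced sample, the estimator

1. applies quality/strand filters (bases must pass the Phred threshold and
   an allele must be seen on both strands to count at all),
2. classifies the sample's major cytotype by per-locus allele majorities,
3. reports the minor cytotype's per-locus frequency vector and its median
   (robust to the few loci disturbed by organellar-insert homology) and
   mean,
4. guards against nuclear/mitochondrial plastid-insert artifacts: genuine
   plastid heteroplasmy rides at plastid depth (hundreds-fold), whereas a
   homologous insert in another compartment is sequenced at that
   compartment's depth (tens-fold), so the minor-allele read depth must
   exceed the nuclear depth by ``numt_ratio_threshold``-fold.

A sample is called heteroplasmic when the median minor frequency reaches
``het_cutoff`` (default 2%), the minor allele is seen at at least
``consistency_fraction`` of usable loci (genome-wide signal, not
locus-restricted heterogeneity), and the depth-ratio guard passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .compare import DiagnosticLocusSet
from .io_formats import ALLELES, BaseCountProfile

_BASE_INDEX = {b: i for i, b in enumerate(ALLELES)}


@dataclass
class HeteroplasmyConfig:
    min_phred: int = 20              # exclusive: quality must be > min_phred
    require_both_strands: bool = True
    het_cutoff: float = 0.02
    numt_ratio_threshold: float = 3.0
    consistency_fraction: float = 0.9
    min_loci: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.het_cutoff < 0.5):
            raise ValueError("het_cutoff must be in (0, 0.5)")
        if self.numt_ratio_threshold <= 0 or self.consistency_fraction <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class HeteroplasmyCall:
    sample_id: str
    major_type: str
    minor_type: str
    positions: np.ndarray            # usable diagnostic loci
    minor_freq: np.ndarray           # per-locus minor-type frequency
    minor_fraction: float            # median of minor_freq
    minor_fraction_mean: float
    fraction_of_loci_supporting: float   # loci with minor freq >= het_cutoff
    fraction_of_loci_with_minor: float   # loci where the minor allele survives filtering
    minor_mean_depth: float
    nuclear_depth: float
    verdict: str                     # heteroplasmy | ambiguous | below_cutoff
    n_usable_loci: int = 0
    depth_ratio: Optional[float] = None


def filter_basecounts(raw: BaseCountProfile,
                      cfg: HeteroplasmyConfig | None = None) -> BaseCountProfile:
    """Return a profile with the strand-bias rule applied.

    Counts in a :class:`BaseCountProfile` are already restricted to bases
    passing the Phred filter (the on-disk dialect stores quality-passing
    counts).  Here, any allele observed on only one strand has both its
    strand counts zeroed, and depth is recomputed as the sum of surviving
    counts.
    """
    cfg = cfg or HeteroplasmyConfig()
    counts = raw.counts.copy()
    if cfg.require_both_strands:
        seen_both = (counts[:, :, 0] > 0) & (counts[:, :, 1] > 0)
        counts *= seen_both[:, :, None]
    return BaseCountProfile(
        sample_id=raw.sample_id,
        positions=raw.positions.copy(),
        ref=raw.ref.copy(),
        counts=counts,
        nuclear_depth_estimate=raw.nuclear_depth_estimate,
    )


def _locus_counts(profile: BaseCountProfile, loci: DiagnosticLocusSet):
    """(positions, countA, countB, depth) at diagnostic loci present in the
    profile; counts are strand-summed for each cytotype's allele."""
    pos_index = {int(p): i for i, p in enumerate(profile.positions)}
    totals = profile.strand_total()
    depth_all = profile.depth
    rows, ca, cb, dp = [], [], [], []
    for pos, allele_a, allele_b in loci.loci:
        i = pos_index.get(pos)
        if i is None:
            continue
        rows.append(pos)
        ca.append(totals[i, _BASE_INDEX[allele_a]])
        cb.append(totals[i, _BASE_INDEX[allele_b]])
        dp.append(depth_all[i])
    return (np.array(rows, dtype=np.int64), np.array(ca, dtype=np.int64),
            np.array(cb, dtype=np.int64), np.array(dp, dtype=np.int64))


def classify_major_type(profile: BaseCountProfile, loci: DiagnosticLocusSet,
                        cfg: HeteroplasmyConfig | None = None) -> str:
    """The cytotype whose allele is the per-locus majority at > 50% of
    usable (depth > 0) diagnostic loci.  Ties raise ``ValueError``."""
    cfg = cfg or HeteroplasmyConfig()
    label_a, label_b = loci.pair_ids
    pos, ca, cb, dp = _locus_counts(profile, loci)
    usable = dp > 0
    if usable.sum() < cfg.min_loci:
        raise ValueError(
            f"only {int(usable.sum())} diagnostic loci with coverage; "
            f"need >= {cfg.min_loci}"
        )
    votes_a = int((ca[usable] > cb[usable]).sum())
    votes_b = int((cb[usable] > ca[usable]).sum())
    n = int(usable.sum())
    if votes_a * 2 > n and votes_a > votes_b:
        return label_a
    if votes_b * 2 > n and votes_b > votes_a:
        return label_b
    raise ValueError(
        f"cannot assign a major cytotype: {votes_a} loci favor {label_a}, "
        f"{votes_b} favor {label_b} of {n} usable"
    )


def estimate_minor_fraction(
    profile: BaseCountProfile,
    loci: DiagnosticLocusSet,
    cfg: HeteroplasmyConfig | None = None,
    mask: Sequence[tuple[int, int]] = (),
) -> HeteroplasmyCall:
    """Quantify the minor cytotype from filtered counts at diagnostic loci.

    ``mask`` excludes loci inside known organellar-insert homolog intervals
    (1-based inclusive).  The summary minor fraction is the median over
    usable loci of count(minor allele)/depth; the verdict is 'heteroplasmy'
    only when the median reaches ``het_cutoff``, at least
    ``consistency_fraction`` of loci carry the minor allele at or above the
    cutoff, and :func:`numt_guard` passes.
    """
    cfg = cfg or HeteroplasmyConfig()
    major = classify_major_type(profile, loci, cfg)
    label_a, label_b = loci.pair_ids
    minor = label_b if major == label_a else label_a
    pos, ca, cb, dp = _locus_counts(profile, loci)
    keep = dp > 0
    for lo, hi in mask:
        keep &= ~((pos >= lo) & (pos <= hi))
    if keep.sum() == 0:
        raise ValueError("zero usable diagnostic loci after masking")
    minor_counts = (cb if minor == label_b else ca)[keep]
    freq = minor_counts / dp[keep]
    call = HeteroplasmyCall(
        sample_id=profile.sample_id,
        major_type=major,
        minor_type=minor,
        positions=pos[keep],
        minor_freq=freq,
        minor_fraction=float(np.median(freq)),
        minor_fraction_mean=float(freq.mean()),
        fraction_of_loci_supporting=float((freq >= cfg.het_cutoff).mean()),
        fraction_of_loci_with_minor=float((minor_counts > 0).mean()),
        minor_mean_depth=float(minor_counts.mean()),
        nuclear_depth=float(profile.nuclear_depth_estimate),
        verdict="below_cutoff",
        n_usable_loci=int(keep.sum()),
    )
    # the genome-wide-signal criterion tests minor-allele *presence* across
    # loci: a mixture sitting exactly at the cutoff still shows its allele
    # at essentially every locus, whereas locus-restricted heterogeneity
    # (or an organellar-insert homolog spanning a few loci) does not
    if (call.minor_fraction >= cfg.het_cutoff
            and call.fraction_of_loci_with_minor >= cfg.consistency_fraction):
        call.verdict = "heteroplasmy"
        call.verdict = numt_guard(call, cfg)
    return call


def numt_guard(call: HeteroplasmyCall,
               cfg: HeteroplasmyConfig | None = None) -> str:
    """Depth-ratio disambiguation of heteroplasmy vs organellar-insert reads.

    Leaves a 'below_cutoff' call unchanged.  Otherwise: 'heteroplasmy' when
    minor_mean_depth / nuclear_depth >= the configured ratio (the minor
    signal is sequenced at plastid depth); 'ambiguous' when the minor depth
    is commensurate with nuclear depth, or when no nuclear-depth estimate
    is available.
    """
    cfg = cfg or HeteroplasmyConfig()
    if call.verdict == "below_cutoff":
        return call.verdict
    if call.nuclear_depth <= 0:
        call.depth_ratio = None
        return "ambiguous"
    call.depth_ratio = call.minor_mean_depth / call.nuclear_depth
    return ("heteroplasmy" if call.depth_ratio >= cfg.numt_ratio_threshold
            else "ambiguous")
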