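"""Filters, cytotype classification, and minor-fraction estimation."""

import numpy as np
import pytest

from plastotyper.compare import DiagnosticLocusSet
from plastotyper.heteroplasmy import (HeteroplasmyCall, HeteroplasmyConfig,
                                      classify_major_type,
                                      estimate_minor_fraction,
                                      filter_basecounts, numt_guard)
from plastotyper.io_formats import ALLELES, BaseCountProfile
from plastotyper.simulate import SimulationConfig, simulate_basecounts

BASE = {b: i for i, b in enumerate(ALLELES)}


def _profile(rows, nuclear=45.0, sample="s"):
    """rows: list of (pos, ref, {allele: (fwd, rev)})."""
    positions = [r[0] for r in rows]
    refs = [r[1] for r in rows]
    counts = np.zeros((len(rows), 6, 2), dtype=np.int64)
    for i, (_, _, alleles) in enumerate(rows):
        for allele, (f, r) in alleles.items():
            counts[i, BASE[allele]] = (f, r)
    return BaseCountProfile(sample_id=sample, positions=positions,
                            ref=refs, counts=counts,
                            nuclear_depth_estimate=nuclear)


def _loci(n=20, start=100, step=50):
    return DiagnosticLocusSet(
        pair_ids=("Type1", "Type2"),
        loci=[(start + i * step, "A", "C") for i in range(n)])


def test_filter_keeps_both_strand_alleles():
    prof = _profile([(10, "A", {"A": (50, 40), "C": (3, 2)})])
    out = filter_basecounts(prof)
    assert np.array_equal(out.counts, prof.counts)
    assert out.depth[0] == 95


def test_filter_removes_single_strand_alleles():
    prof = _profile([(10, "A", {"A": (50, 40), "C": (5, 0)})])
    out = filter_basecounts(prof)
    assert out.strand_total()[0, BASE["C"]] == 0
    assert out.depth[0] == 90  # depth recomputed after exclusion


def test_filter_matches_independent_recount(mini_pair):
    ga, gb, truth, cfg = mini_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    prof, _ = simulate_basecounts(loci, 0.05, cfg)
    out = filter_basecounts(prof)
    # recount oracle: per locus, per allele, keep only both-strand alleles
    for i in range(len(prof.positions)):
        for a in range(6):
            f, r = prof.counts[i, a]
            want = (f, r) if (f > 0 and r > 0) else (0, 0)
            assert tuple(out.counts[i, a]) == want


def _mixture_profile(loci, f, depth, seed, error=0.002):
    cfg = SimulationConfig(seed=0, depth=depth, error_rate=error)
    prof, _ = simulate_basecounts(loci, f, cfg, seed=seed)
    return filter_basecounts(prof)


def test_classify_major_type_mixtures(study_pair):
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    for f, expect in [(0.0, "Type1"), (0.02, "Type1")]:
        prof = _mixture_profile(loci, f, 8_000, seed=11)
        assert classify_major_type(prof, loci) == expect
    # 2:98 mixture (second cytotype predominant) classifies as Type2
    cfg = SimulationConfig(seed=0, depth=8_000, error_rate=0.002)
    prof, _ = simulate_basecounts(loci, 0.02, cfg, major="B", seed=12)
    assert classify_major_type(filter_basecounts(prof), loci) == "Type2"


def test_classify_requires_loci_and_rejects_ties():
    few = _loci(n=4)
    prof = _profile([(pos, "A", {"A": (40, 40)}) for pos, _, _ in few.loci])
    with pytest.raises(ValueError, match="diagnostic loci"):
        classify_major_type(prof, few)
    tied = _loci(n=10)
    rows = [(pos, "A", {"A": (40, 40)}) for pos, _, _ in tied.loci[:5]]
    rows += [(pos, "A", {"C": (40, 40)}) for pos, _, _ in tied.loci[5:]]
    with pytest.raises(ValueError, match="major cytotype"):
        classify_major_type(_profile(rows), tied)


def test_pure_profile_is_below_cutoff():
    loci = _loci(n=30)
    rows = [(pos, "A", {"A": (2_000, 2_000)}) for pos, _, _ in loci.loci]
    call = estimate_minor_fraction(_profile(rows), loci)
    assert call.minor_fraction == 0.0
    assert call.verdict == "below_cutoff"


def test_minor_fraction_recovery_low_mixture(study_pair):
    """A 2% mixture at ~8000x is recovered within +-0.005 and called."""
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    call = estimate_minor_fraction(_mixture_profile(loci, 0.02, 8_000, seed=21),
                                   loci)
    assert call.minor_fraction == pytest.approx(0.02, abs=0.005)
    assert call.major_type == "Type1" and call.minor_type == "Type2"
    assert call.verdict == "heteroplasmy"


def test_minor_fraction_recovery_high_mixture(study_pair):
    """An 11% mixture at 4000x is recovered within +-0.01."""
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    call = estimate_minor_fraction(_mixture_profile(loci, 0.11, 4_000, seed=22),
                                   loci)
    assert call.minor_fraction == pytest.approx(0.11, abs=0.01)
    assert call.verdict == "heteroplasmy"


def test_label_swap_leaves_call_invariant(study_pair):
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    prof = _mixture_profile(loci, 0.05, 4_000, seed=23)
    call = estimate_minor_fraction(prof, loci)
    swapped = DiagnosticLocusSet(pair_ids=(loci.pair_ids[1], loci.pair_ids[0]),
                                 loci=[(p, b, a) for p, a, b in loci.loci])
    call2 = estimate_minor_fraction(prof, swapped)
    assert call2.major_type == call.major_type
    assert call2.minor_fraction == call.minor_fraction
    assert call2.verdict == call.verdict


def test_masked_loci_are_excluded(study_pair):
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    prof = _mixture_profile(loci, 0.05, 4_000, seed=24)
    full = estimate_minor_fraction(prof, loci)
    lo = int(loci.positions[0])
    hi = int(loci.positions[9])
    masked = estimate_minor_fraction(prof, loci, mask=[(lo, hi)])
    assert masked.n_usable_loci == full.n_usable_loci - 10
    assert not np.isin(masked.positions,
                       np.array(loci.positions[:10])).any()


def test_numt_guard_depth_ratio_rule():
    cfg = HeteroplasmyConfig()

    def call_with(minor_depth, nuclear, verdict="heteroplasmy"):
        return HeteroplasmyCall(
            sample_id="s", major_type="Type1", minor_type="Type2",
            positions=np.array([1]), minor_freq=np.array([0.05]),
            minor_fraction=0.05, minor_fraction_mean=0.05,
            fraction_of_loci_supporting=1.0, fraction_of_loci_with_minor=1.0,
            minor_mean_depth=minor_depth, nuclear_depth=nuclear,
            verdict=verdict)

    assert numt_guard(call_with(450, 45), cfg) == "heteroplasmy"  # ratio 10
    assert numt_guard(call_with(40, 45), cfg) == "ambiguous"      # ratio 0.89
    below = call_with(0, 45, verdict="below_cutoff")
    assert numt_guard(below, cfg) == "below_cutoff"               # unchanged


def test_numt_background_flagged_ambiguous():
    """A plastid-insert homolog read in at nuclear depth mimics ~1-2%
    heteroplasmy but fails the depth-ratio guard."""
    loci = _loci(n=30)
    numt = [pos for pos, _, _ in loci.loci]
    cfg = SimulationConfig(seed=5, depth=2_000, error_rate=0.0,
                           nuclear_depth=60.0, phred_fail_fraction=0.0)
    prof, _ = simulate_basecounts(loci, 0.0, cfg, numt_loci=numt)
    call = estimate_minor_fraction(filter_basecounts(prof), loci)
    assert call.minor_fraction >= 0.02  # looks like heteroplasmy...
    assert call.verdict == "ambiguous"  # ...but rides at nuclear depth


def test_false_positive_rate_zero_under_pure_error(study_pair):
    """f=0 with 0.2% error never reaches the 2% cutoff (error floor is
    ~0.07%), across 200 seeded replicates."""
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    cfg = SimulationConfig(seed=0, depth=8_000, error_rate=0.002)
    calls = 0
    for seed in range(200):
        prof, _ = simulate_basecounts(loci, 0.0, cfg, seed=seed)
        call = estimate_minor_fraction(filter_basecounts(prof), loci)
        calls += call.verdict == "heteroplasmy"
        assert call.minor_fraction < 0.02
    assert calls == 0


def test_estimator_bias_shrinks_with_depth(study_pair):
    """Median minor fraction converges to truth as depth grows (error-free
    simulations isolate estimator bias from the error-inflation floor)."""
    ga, gb, truth, _ = study_pair
    loci = truth.diagnostic_loci((ga.id, gb.id))
    f = 0.02
    errors = []
    for depth in (500, 2_000, 8_000):
        cfg = SimulationConfig(seed=0, depth=depth, error_rate=0.0,
                               phred_fail_fraction=0.0)
        est = np.array([estimate_minor_fraction(
                            filter_basecounts(simulate_basecounts(loci, f, cfg,
                                                                  seed=s)[0]),
                            loci).minor_fraction
                        for s in range(50)])
        errors.append(float(np.mean(np.abs(est - f))))
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[2] < 1e-3
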