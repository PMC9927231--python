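"""Nucleotide diversity, haplotype tables, JC distances and NJ trees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix, TreeNode

from conftest import mini_config, random_dna
from plastotyper.compare import VariantRecord
from plastotyper.popgen import (AlignmentMatrix, alignment_from_variants,
                                build_haplotype_table, has_bipartition,
                                jc_distance_matrix, mean_pi, nj_tree,
                                pairwise_pi, sliding_window_pi)
from plastotyper.simulate import (PopulationSpec, default_population_spec,
                                  make_cytotype_pair, simulate_population)


def _pi_oracle(a, b):
    diffs = comp = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        comp += 1
        diffs += x != y
    return diffs / comp


def test_pairwise_pi_basics():
    assert pairwise_pi("ACGT", "ACGT") == 0.0
    assert pairwise_pi("AAAA", "AAAT") == 0.25
    # pairwise deletion: gap/N sites leave numerator and denominator
    assert pairwise_pi("AC-TN", "ACGTA") == 0.0
    with pytest.raises(ValueError, match="comparable"):
        pairwise_pi("---", "AAA")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_pairwise_pi_matches_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT-N"))
    a = "".join(chars[rng.integers(0, 6, 80)])
    b = "".join(chars[rng.integers(0, 6, 80)])
    try:
        expected = _pi_oracle(a, b)
    except ZeroDivisionError:
        with pytest.raises(ValueError):
            pairwise_pi(a, b)
        return
    assert pairwise_pi(a, b) == pytest.approx(expected, abs=1e-15)


def test_sliding_window_matches_hand_computation():
    seqs = [("s1", "AAAAAAAAAAAAAAAAAAAA"),
            ("s2", "AAAAACAAAAAAAAAAAAAT"),
            ("s3", "AAAAACAAAAA-AAAAAAAA"),
            ("s4", "GAAAAAAAAAANAAAAAAAA")]
    m = AlignmentMatrix.from_sequences(seqs)
    prof = sliding_window_pi(m, window=10, step=5)
    assert len(prof.pi) == (20 - 10) // 5 + 1 == 3
    # independent oracle: average pairwise pi restricted to each window
    for w, start in enumerate(range(0, 11, 5)):
        vals = []
        for i in range(4):
            for j in range(i + 1, 4):
                vals.append(_pi_oracle(seqs[i][1][start:start + 10],
                                       seqs[j][1][start:start + 10]))
        assert prof.pi[w] == pytest.approx(np.mean(vals), abs=1e-15)
    assert prof.midpoints[0] == pytest.approx(5.5)


def test_all_identical_alignment_gives_zero_everywhere(rng):
    s = random_dna(rng, 3_000)
    m = AlignmentMatrix.from_sequences([(f"s{i}", s) for i in range(4)])
    prof = sliding_window_pi(m, window=1_200, step=400)
    assert np.all(prof.pi == 0) and prof.mean_pi == 0
    assert len(prof.pi) == (3_000 - 1_200) // 400 + 1


def test_window_longer_than_alignment_raises(rng):
    m = AlignmentMatrix.from_sequences([("a", "ACGT"), ("b", "ACGT")])
    with pytest.raises(ValueError, match="window"):
        sliding_window_pi(m, window=10, step=5)


def test_masked_interval_excluded(rng):
    s = random_dna(rng, 2_000)
    other = s[:1_000] + random_dna(rng, 50) + s[1_050:]
    masked = AlignmentMatrix.from_sequences([("a", s), ("b", other)],
                                            excluded=[(1_001, 1_050)])
    assert mean_pi(masked) == 0.0
    peak = sliding_window_pi(AlignmentMatrix.from_sequences([("a", s), ("b", other)]),
                             window=200, step=100)
    assert peak.pi.max() > 0  # unmasked, the divergent window shows up


def test_mean_pi_equals_per_site_average_on_gapless_alignment(rng):
    mat = np.array([list(random_dna(rng, 500)) for _ in range(5)])
    m = AlignmentMatrix(ids=[f"s{i}" for i in range(5)], matrix=mat)
    n = 5
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    per_site = np.mean([
        np.mean([mat[i, c] != mat[j, c] for i, j in pairs])
        for c in range(mat.shape[1])
    ])
    assert mean_pi(m) == pytest.approx(per_site, abs=1e-12)


def test_pi_invariant_under_sample_and_column_permutation(rng):
    mat = np.array([list(random_dna(rng, 300)) for _ in range(4)])
    m = AlignmentMatrix(ids=list("abcd"), matrix=mat)
    perm_rows = AlignmentMatrix(ids=list("dcab"), matrix=mat[[3, 2, 0, 1]])
    perm_cols = AlignmentMatrix(ids=list("abcd"),
                                matrix=mat[:, rng.permutation(300)])
    assert mean_pi(m) == pytest.approx(mean_pi(perm_rows), abs=1e-15)
    assert mean_pi(m) == pytest.approx(mean_pi(perm_cols), abs=1e-15)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def test_haplotype_table_trivial_cases():
    table = build_haplotype_table({"a": [], "b": [], "c": []})
    assert table.n_haplotypes == 1 and table.loci == []
    nested = {
        "a": [],
        "b": [VariantRecord(10, "A", "C", "SNP")],
        "c": [VariantRecord(10, "A", "C", "SNP"), VariantRecord(20, "G", "T", "SNP")],
    }
    table = build_haplotype_table(nested)
    assert table.n_haplotypes == 3
    assert [pos for pos, _ in table.loci] == [10, 20]


def test_haplotype_table_conflicting_calls_raise():
    bad = {"a": [VariantRecord(10, "A", "C", "SNP"),
                 VariantRecord(10, "A", "G", "SNP")]}
    with pytest.raises(ValueError, match="conflicting"):
        build_haplotype_table(bad)


def test_haplotype_exclusivity_flags():
    calls = {
        "t1a": [VariantRecord(5, "A", "C", "SNP")],
        "t1b": [VariantRecord(5, "A", "C", "SNP")],
        "t2a": [VariantRecord(9, "G", "T", "SNP")],
        "t2b": [VariantRecord(9, "G", "T", "SNP"),
                VariantRecord(5, "A", "C", "SNP")],
    }
    groups = {"t1a": "1", "t1b": "1", "t2a": "2", "t2b": "2"}
    table = build_haplotype_table(calls, groups)
    flags = dict(zip([pos for pos, _ in table.loci], table.exclusive))
    assert flags[9] is True    # allele private to group 2
    assert flags[5] is False   # carriers span both groups


def test_programmed_population_recovers_haplotype_count():
    cfg = mini_config(seed=3, n_diag_indels=0, inversion_len=0)
    ga, gb, truth = make_cytotype_pair(cfg)
    spec = default_population_spec(ga, truth, cfg)
    assert len(spec.samples) == 43
    programmed = len({spec.samples[s] for s in spec.samples})
    assert programmed == 15
    _, pop_truth = simulate_population(ga, gb, truth, spec)
    table = build_haplotype_table(pop_truth.variants_per_sample,
                                  pop_truth.cytotype_of)
    assert table.n_haplotypes == 15


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def test_jc_distance_formula(rng):
    s = random_dna(rng, 4_000)
    seqs = [("a", s)]
    for name in ("b", "c"):
        t = list(s)
        for i in rng.choice(4_000, size=40, replace=False):
            t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
        seqs.append((name, "".join(t)))
    m = AlignmentMatrix.from_sequences(seqs)
    dm = jc_distance_matrix(m)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        p = pairwise_pi(seqs[i][1], seqs[j][1])
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert dm[i, j] == pytest.approx(expected, rel=1e-12)
    assert dm[0, 0] == 0.0
    # small-p limit: d ~ p
    p = pairwise_pi(seqs[0][1], seqs[1][1])
    assert dm[0, 1] == pytest.approx(p, rel=5e-2)


def test_jc_distance_saturated_pair_raises():
    m = AlignmentMatrix.from_sequences([("a", "AAAA" * 5), ("b", "CCCC" * 5)])
    with pytest.raises(ValueError, match="0.75"):
        jc_distance_matrix(m)


def test_nj_three_taxa_additive():
    dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float),
                        ids=list("abc"))
    tree = TreeNode.read([nj_tree(dm)])
    dists = tree.tip_tip_distances()
    for i, j in [("a", "b"), ("a", "c"), ("b", "c")]:
        assert dists[i, j] == pytest.approx(dm[i, j], abs=1e-12)


def test_nj_recovers_additive_four_taxon_tree():
    # ((a,b),(c,d)) with internal edge 3
    d = np.array([[0, 5, 10, 11],
                  [5, 0, 11, 12],
                  [10, 11, 0, 7],
                  [11, 12, 7, 0]], float)
    dm = DistanceMatrix(d, ids=list("abcd"))
    nwk = nj_tree(dm)
    tree = TreeNode.read([nwk])
    dists = tree.tip_tip_distances()
    for i in "abcd":
        for j in "abcd":
            if i < j:
                assert dists[i, j] == pytest.approx(dm[i, j], abs=1e-12)
    assert has_bipartition(nwk, ["a", "b"])


def test_nj_rejects_asymmetric_input():
    from skbio.stats.distance import DissimilarityMatrix

    d = np.array([[0, 5, 2], [1, 0, 3], [2, 3, 0]], float)
    dm = DissimilarityMatrix(d, ids=list("abc"))
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(dm)


def test_two_cytotype_population_splits_into_two_clades():
    cfg = mini_config(seed=3, n_diag_indels=0, inversion_len=0)
    ga, gb, truth = make_cytotype_pair(cfg)
    spec = default_population_spec(ga, truth, cfg)
    samples, pop_truth = simulate_population(ga, gb, truth, spec)
    m = AlignmentMatrix.from_sequences(samples)
    nwk = nj_tree(jc_distance_matrix(m))
    type2 = [s for s, c in pop_truth.cytotype_of.items() if c == "2"]
    assert has_bipartition(nwk, type2)


def test_alignment_from_variants_projection():
    ref = "ACGTACGTAC"
    calls = {
        "a": [],
        "b": [VariantRecord(3, "G", "T", "SNP"),
              VariantRecord(6, "CG", "", "DEL")],
    }
    m = alignment_from_variants(ref, calls)
    assert m.ids == ["a", "b"]
    assert "".join(m.matrix[1]) == "ACTTA--TAC"
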