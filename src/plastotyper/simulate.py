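"""Synthetic two-cytotype plastome data with known ground truth.

The generator emulates the statistical structure of a deeply sequenced,
two-cytotype plastome study: a circular ~161.5 kb genome with exact
LSC/IRa/SSC/IRb architecture and sparse gene annotation; a second cytotype
derived from it by a fixed set of diagnostic SNPs and small indels plus one
short inversion; geographic subgroups realized as private SNP sets on top
of one cytotype; and per-site base-count profiles for mixed-cytotype
samples at organellar depth, with sequencing error, per-base quality
thinning, strand splitting, and an optional nuclear plastid-insert (NUMT)
background at the nuclear depth.

Every generator returns its :class:`TruthSet`; implant-recover tests in the
analysis modules consume only these truths.  All outputs are bit-identical
for identical seeds and configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .compare import DiagnosticLocusSet, VariantRecord, apply_variants
from .io_formats import BaseCountProfile, GeneFeature, Plastome, revcomp

_BASES = np.array(list("ACGT"))
_BASE_TO_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the deeply sequenced two-cytotype study the package
    models: a 161,537 bp genome with 30,896 bp IRs and a 13,632 bp SSC,
    cytotypes separated by 105 SNPs + 36 indels and a 230 bp inversion,
    25 within-cytotype subgroup variants, ~8,175x organellar depth, 0.2%
    per-base error, and 45x nuclear depth.
    """

    seed: int = 0
    genome_len: int = 161_537
    ir_len: int = 30_896
    ssc_len: int = 13_632
    n_diag_snps: int = 105
    n_diag_indels: int = 36
    inversion_len: int = 230
    n_subgroup_variants: int = 25
    mixture_fraction: float = 0.0
    depth: int = 8_175
    error_rate: float = 0.002
    nuclear_depth: float = 45.0
    phred_fail_fraction: float = 0.05  # fraction of bases failing the >Q20 filter
    gc: float = 0.36
    gene_spacing: tuple[int, int] = (150, 600)  # intergenic gap range, bp
    min_event_spacing: int = 100

    def __post_init__(self) -> None:
        if self.lsc_len <= 0:
            raise ValueError("genome_len - ssc_len - 2*ir_len must be positive")
        if not (0.0 <= self.mixture_fraction <= 0.5):
            raise ValueError("mixture_fraction must be in [0, 0.5]")
        if min(self.n_diag_snps, self.n_diag_indels, self.inversion_len) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def lsc_len(self) -> int:
        return self.genome_len - self.ssc_len - 2 * self.ir_len


@dataclass
class TruthSet:
    """Ground truth of one simulation; positions are 1-based on genome A."""

    variants: list[VariantRecord] = field(default_factory=list)
    inversion_ref: Optional[tuple[int, int]] = None
    inversion_query: Optional[tuple[int, int]] = None
    haplotype_of: dict[str, str] = field(default_factory=dict)
    variants_per_sample: dict[str, list[VariantRecord]] = field(default_factory=dict)
    cytotype_of: dict[str, str] = field(default_factory=dict)
    mixture_fraction: dict[str, float] = field(default_factory=dict)

    def diagnostic_loci(self, pair_ids: tuple[str, str]) -> DiagnosticLocusSet:
        loci = [(v.pos, v.ref_allele, v.alt_allele)
                for v in sorted(self.variants, key=lambda v: v.pos)
                if v.vtype == "SNP"]
        return DiagnosticLocusSet(pair_ids=pair_ids, loci=loci)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _place_genes(rng: np.random.Generator, regions: list[tuple[int, int]],
                 spacing: tuple[int, int]) -> list[GeneFeature]:
    """Sparse non-overlapping gene models (some intron-bearing) within the
    given 0-based half-open single-copy regions."""
    features: list[GeneFeature] = []
    idx = 0
    for lo, hi in regions:
        pos = lo + int(rng.integers(*spacing))
        while True:
            kind = ["CDS", "CDS", "CDS", "tRNA", "rRNA"][int(rng.integers(5))]
            if kind == "CDS":
                glen = 3 * int(rng.integers(100, 400))
            elif kind == "tRNA":
                glen = 72
            else:
                glen = 1500
            intron = 0
            if kind != "rRNA" and rng.random() < 0.35:
                intron = int(rng.integers(100, 400))
            total = glen + intron
            if pos + total + spacing[1] >= hi:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos + 1  # to 1-based
            if intron:
                cut = int(rng.integers(1, glen))
                e1 = (start, start + cut - 1)
                e2 = (start + cut + intron, start + glen + intron - 1)
                exons = [e1, e2] if strand == "+" else [e2, e1]
            else:
                exons = [(start, start + glen - 1)]
            idx += 1
            features.append(GeneFeature(
                name=f"g{idx:03d}", kind=kind, strand=strand, exons=exons))
            pos += total + int(rng.integers(*spacing))
    return features


def _intergenic_intervals(features: Sequence[GeneFeature],
                          regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """0-based half-open intervals inside the regions not covered by genes."""
    spans = sorted((f.span[0] - 1, f.span[1]) for f in features)
    out = []
    for lo, hi in regions:
        cur = lo
        for s, e in spans:
            if e <= lo or s >= hi:
                continue
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < hi:
            out.append((cur, hi))
    return out


def make_cytotype_pair(cfg: SimulationConfig) -> tuple[Plastome, Plastome, TruthSet]:
    """A random quadripartite genome and a second cytotype derived from it.

    Genome A is LSC | IRa | SSC | IRb with IRb the exact reverse complement
    of IRa.  Genome B carries ``n_diag_snps`` SNPs, ``n_diag_indels``
    1-10 bp indels (intergenic, left-normalization-stable) and one
    ``inversion_len`` bp inversion, all outside the IRs.  Events are spaced
    at least ``min_event_spacing`` bp apart.
    """
    rng = np.random.default_rng(cfg.seed)
    lsc = cfg.lsc_len
    ira_start, ssc_start = lsc, lsc + cfg.ir_len
    irb_start = ssc_start + cfg.ssc_len
    single = _random_sequence(rng, lsc + cfg.ir_len + cfg.ssc_len, cfg.gc)
    ira = single[lsc:lsc + cfg.ir_len]
    seq_a = single + revcomp(ira)
    regions = [(0, lsc), (ssc_start, irb_start)]
    features = _place_genes(rng, regions, cfg.gene_spacing)
    genome_a = Plastome(id="Type1", sequence=seq_a, circular=True,
                        features=list(features))

    occupied: list[tuple[int, int]] = []  # 0-based half-open exclusion zones

    def free(lo: int, hi: int) -> bool:
        return all(hi + cfg.min_event_spacing <= s or
                   lo - cfg.min_event_spacing >= e for s, e in occupied)

    # --- inversion (intergenic, boundary not extendable) -------------------
    inv_iv = None
    if cfg.inversion_len > 0:
        spots = [iv for iv in _intergenic_intervals(features, [(0, lsc)])
                 if iv[1] - iv[0] >= cfg.inversion_len + 2]
        if not spots:
            raise ValueError("no intergenic interval can host the inversion")
        for _ in range(200):
            lo, hi = spots[int(rng.integers(len(spots)))]
            a = int(rng.integers(lo + 1, hi - cfg.inversion_len))
            L = cfg.inversion_len
            comp = str.maketrans("ACGT", "TGCA")
            if seq_a[a - 1].translate(comp) != seq_a[a + L]:
                inv_iv = (a, a + L)
                break
        else:
            raise ValueError("could not place a non-extendable inversion")
        occupied.append(inv_iv)

    # --- indels (intergenic, left-shift-stable) ----------------------------
    variants: list[VariantRecord] = []
    inter = _intergenic_intervals(features, regions)
    for j in range(cfg.n_diag_indels):
        for _ in range(500):
            lo, hi = inter[int(rng.integers(len(inter)))]
            if hi - lo < 30:
                continue
            L = int(rng.integers(1, 11))
            i = int(rng.integers(lo + 2, hi - L - 2))
            if not free(i, i + L):
                continue
            if j % 2 == 0:  # deletion of seq_a[i:i+L]
                if seq_a[i - 1] == seq_a[i + L - 1]:
                    continue
                variants.append(VariantRecord(i + 1, seq_a[i:i + L], "", "DEL"))
            else:           # insertion before 0-based i
                ins = _random_sequence(rng, L, cfg.gc)
                if seq_a[i - 1] == ins[-1]:
                    continue
                variants.append(VariantRecord(i + 1, "", ins, "INS"))
            occupied.append((i, i + L))
            break
        else:
            raise ValueError("could not place all indels; genome too crowded")

    # --- diagnostic SNPs (anywhere single-copy outside the IRs) ------------
    for _ in range(cfg.n_diag_snps):
        for _ in range(500):
            ri = int(rng.integers(2))
            lo, hi = regions[ri]
            i = int(rng.integers(lo + 2, hi - 2))
            if not free(i, i + 1):
                continue
            ref_base = seq_a[i]
            choices = [b for b in "ACGT" if b != ref_base]
            alt = choices[int(rng.integers(3))]
            variants.append(VariantRecord(i + 1, ref_base, alt, "SNP"))
            occupied.append((i, i + 1))
            break
        else:
            raise ValueError("could not place all SNPs; genome too crowded")

    variants.sort(key=lambda v: v.pos)

    # --- realize genome B --------------------------------------------------
    seq_b = seq_a
    inv_ref = inv_query = None
    if inv_iv is not None:
        a, e = inv_iv
        seq_b = seq_b[:a] + revcomp(seq_b[a:e]) + seq_b[e:]
        inv_ref = (a + 1, e)
    seq_b = apply_variants(seq_b, variants)
    if inv_ref is not None:
        delta = sum(len(v.alt_allele) - len(v.ref_allele)
                    for v in variants if v.vtype != "SNP" and v.pos <= inv_ref[0])
        inv_query = (inv_ref[0] + delta, inv_ref[1] + delta)

    def _shift(pos: int) -> int:
        return pos + sum(len(v.alt_allele) - len(v.ref_allele)
                         for v in variants if v.vtype != "SNP" and v.pos <= pos)

    features_b = [
        replace(f, exons=[(_shift(lo), _shift(hi)) for lo, hi in f.exons])
        for f in features
    ]
    genome_b = Plastome(id="Type2", sequence=seq_b, circular=True,
                        features=features_b)
    truth = TruthSet(variants=variants, inversion_ref=inv_ref,
                     inversion_query=inv_query)
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Assignment of each sample to a cytotype and a private variant set."""

    # haplotype id -> (cytotype '1'|'2', extra SNPs private to the haplotype)
    haplotypes: dict[str, tuple[str, list[VariantRecord]]]
    # sample id -> haplotype id
    samples: dict[str, str]


def default_population_spec(genome_a: Plastome, truth: TruthSet,
                            cfg: SimulationConfig,
                            n_samples: int = 43, n_type2: int = 7,
                            n_type1_haplotypes: int = 14) -> PopulationSpec:
    """A study-shaped population: ``n_type2`` identical second-cytotype
    samples plus first-cytotype samples spread over ``n_type1_haplotypes``
    haplotypes built from ``cfg.n_subgroup_variants`` private SNP loci."""
    rng = np.random.default_rng(cfg.seed + 1)
    seq = genome_a.sequence
    taken = {v.pos for v in truth.variants}
    lsc = cfg.lsc_len
    extra: list[VariantRecord] = []
    while len(extra) < cfg.n_subgroup_variants:
        i = int(rng.integers(2, lsc - 2))
        if any(abs(i + 1 - p) < cfg.min_event_spacing for p in taken):
            continue
        ref_base = seq[i]
        alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(3))]
        extra.append(VariantRecord(i + 1, ref_base, alt, "SNP"))
        taken.add(i + 1)
    perm = rng.permutation(len(extra))
    haplotypes: dict[str, tuple[str, list[VariantRecord]]] = {}
    for h in range(n_type1_haplotypes):
        chosen = sorted(perm[:h])  # nested prefixes => all sets distinct
        haplotypes[f"T1-{h + 1}"] = ("1", [extra[i] for i in chosen])
    haplotypes["T2-1"] = ("2", [])
    samples: dict[str, str] = {}
    n_type1 = n_samples - n_type2
    hap_ids = [f"T1-{h + 1}" for h in range(n_type1_haplotypes)]
    assignment = list(range(n_type1_haplotypes))  # every haplotype realized
    assignment += list(rng.integers(0, n_type1_haplotypes,
                                    size=n_type1 - n_type1_haplotypes))
    for s, h in enumerate(sorted(assignment)):
        samples[f"S{s + 1:02d}"] = hap_ids[h]
    for s in range(n_type2):
        samples[f"U{s + 1:02d}"] = "T2-1"
    return PopulationSpec(haplotypes=haplotypes, samples=samples)


def simulate_population(
    genome_a: Plastome, genome_b: Plastome, truth: TruthSet,
    spec: PopulationSpec,
) -> tuple[list[tuple[str, str]], TruthSet]:
    """Realize each sample's genome from its haplotype's variant set.

    First-cytotype samples are genome A plus their private variants;
    second-cytotype samples are genome B plus theirs.  The programmed
    haplotype count equals the number of distinct variant sets.
    """
    out: list[tuple[str, str]] = []
    pop_truth = TruthSet(variants=list(truth.variants),
                         inversion_ref=truth.inversion_ref,
                         inversion_query=truth.inversion_query)
    for sample_id in sorted(spec.samples):
        hap = spec.samples[sample_id]
        cytotype, private = spec.haplotypes[hap]
        positions = [v.pos for v in private]
        if len(set(positions)) != len(positions):
            raise ValueError(f"haplotype {hap}: colliding variant positions")
        if cytotype == "1":
            seq = apply_variants(genome_a.sequence, private)
            sample_variants = list(private)
        else:
            seq = apply_variants(genome_b.sequence, private)
            sample_variants = sorted(truth.variants + list(private),
                                     key=lambda v: v.pos)
        out.append((sample_id, seq))
        pop_truth.haplotype_of[sample_id] = hap
        pop_truth.cytotype_of[sample_id] = cytotype
        pop_truth.variants_per_sample[sample_id] = sample_variants
    return out, pop_truth


# ---------------------------------------------------------------------------
# base counts
# ---------------------------------------------------------------------------

def simulate_basecounts(
    loci: DiagnosticLocusSet,
    f: float,
    cfg: SimulationConfig,
    sample_id: str = "sim",
    major: str = "A",
    numt_loci: Sequence[int] = (),
    seed: Optional[int] = None,
) -> tuple[BaseCountProfile, TruthSet]:
    """Mixed-cytotype base counts at the diagnostic loci.

    At every locus, allele counts are multinomial over (major allele, minor
    allele, two off-target alleles) with the per-base error ``cfg.error_rate``
    spread equally over the three non-template bases; counts are thinned by
    the configured Phred-failure fraction (the profile stores
    quality-passing counts), then split binomially between strands.  Loci
    listed in ``numt_loci`` additionally receive a Poisson(nuclear_depth)
    dose of minor-allele reads emulating a nuclear/mitochondrial
    plastid-insert homolog.
    """
    if not (0.0 <= f <= 0.5):
        raise ValueError("mixture fraction must be in [0, 0.5]")
    if cfg.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    e = cfg.error_rate
    n = len(loci)
    positions = np.array(loci.positions, dtype=np.int64)
    counts = np.zeros((n, 6, 2), dtype=np.int64)
    ref_bases = []
    numt = set(numt_loci)
    for row, (pos, allele_a, allele_b) in enumerate(loci.loci):
        maj, mnr = (allele_a, allele_b) if major == "A" else (allele_b, allele_a)
        ref_bases.append(allele_a)
        probs = np.full(4, e / 3.0)
        probs[_BASE_TO_IDX[maj]] = (1 - f) * (1 - e) + f * e / 3.0
        probs[_BASE_TO_IDX[mnr]] = f * (1 - e) + (1 - f) * e / 3.0
        raw = rng.multinomial(cfg.depth, probs / probs.sum())
        passing = rng.binomial(raw, 1.0 - cfg.phred_fail_fraction)
        if pos in numt:
            passing[_BASE_TO_IDX[mnr]] += rng.poisson(cfg.nuclear_depth)
        fwd = rng.binomial(passing, 0.5)
        counts[row, :4, 0] = fwd
        counts[row, :4, 1] = passing - fwd
    profile = BaseCountProfile(
        sample_id=sample_id,
        positions=positions,
        ref=np.array(ref_bases, dtype="<U1"),
        counts=counts,
        nuclear_depth_estimate=cfg.nuclear_depth,
    )
    truth = TruthSet(mixture_fraction={sample_id: f},
                     cytotype_of={sample_id: major})
    return profile, truth
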