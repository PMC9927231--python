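# Methods

## Problem setting

A plastome (chloroplast genome) is a circular molecule of ~120–170 kb
with a conserved quadripartite layout: a large single-copy region (LSC)
and a small single-copy region (SSC) separated by two inverted repeats
(IRa/IRb) that are reverse-complement copies of each other. Within some
species, two distinct plastome *cytotypes* segregate, differing at a
fixed set of loci and occasionally by short inversions; deep sequencing
can further reveal *heteroplasmy* — both cytotypes present in one
individual, one at low frequency. This package implements the analyses
such a study needs, each testable against synthetic data with known
truth.

Coordinates are 1-based inclusive on disk and in user-facing records
(GenBank convention); internal arithmetic is 0-based half-open, with the
conversion confined to `io_formats`. Circular genomes are linearized at
the deposited origin; ambiguity codes other than N are rejected at parse
time so malformed inputs fail loudly.

## Quadripartite detection (`structure`)

The detector finds the maximal pair of disjoint, *exact*
reverse-complement repeats of at least `min_ir_len` (default 10 kb) and
derives LSC/SSC from the two gaps between the repeat arcs on the circle
(LSC is the longer gap, SSC the shorter; ties between maximal pairs are
broken toward the smaller SSC, the plastome convention). Candidate
repeats come from reverse-complement k-mer matches (seed k = 63) grouped
by anti-diagonal and extended base-wise; circularity is honored by
scanning the doubled sequence, which also makes detection invariant
under rotation. Exactness is a deliberate modeling choice: IR copies
are homogenized by the plastome's own copy-correction machinery and
observed length-identical across samples; requiring exact copies keeps
the search linear and the answer unambiguous. GC content is
(G+C)/(A+C+G+T) with N excluded from the denominator.

## Pairwise comparison (`compare`)

Anchors are k-mers (default k = 31) occurring exactly once in each
genome. Forward-orientation anchors are chained by longest monotone
subsequence; the chain is split into blocks wherever the anchor gap or
diagonal shift exceeds `max_join_gap` (5 kb). Because the two IR copies
are internally identical, their k-mers still occur once per genome in
forward orientation, so the chain pairs IRa with IRa and IRb with IRb —
copy-to-copy by position — rather than cross-pairing them as a spurious
30 kb inversion. The inversion search then runs only over stretches not
covered by chained forward anchors: opposite-orientation anchors are
chained with reference increasing and query decreasing, and each maximal
inverted block is extended base-wise to the exact inversion boundary.

Within forward blocks, overlapping same-diagonal anchors merge into
exact match segments; where adjacent segments overlap on one genome
through different diagonals (both sides of an indel inside a repeat),
the downstream segment is trimmed so boundaries are consistent. Each
inter-segment gap pair (bounded at 20 kb) is globally aligned with
affine gap scores +1/−2/−4/−1 — values chosen so that indel placement is
canonical after normalization — and parsed into events:

* SNPs: one event per substituted base; runs of adjacent substitutions
  stay separate SNPs (a `merge_adjacent_snps` reporting option collapses
  them to MNPs).
* Indels: left-aligned against the reference within their
  homopolymer/repeat context (the SAMtools convention), making event
  counts deterministic. An insertion's position is the reference base
  *before which* the inserted sequence sits; a deletion's position is
  its first deleted base.

Inverted blocks are excluded from variant calling and reported as
`InversionCall`s; an inverted repeat pair flanking the inversion (the
usual recombination mediator) is searched within 500 bp of each side by
local alignment and reported with percent identity when at least 15
bases match.

Region classification assigns CDS (inside a protein-coding exon), intron
(inside a gene span but outside its exons — this includes tRNA/rRNA gene
introns), or intergenic; positions inside tRNA/rRNA or pseudogene exons
are reported as intergenic since the three-way scheme has no separate
noncoding-exon class. Coding effects rebuild the affected codon in
transcription direction (strand-aware, exon-joined, `codon_start`
honored) and translate with the plastid/bacterial code; ACG/GTG
alternative initiation codons translate as Met at codon 1 when the gene
is flagged `alt_start_ok`, so a GTG→ATG change at codon 1 is
synonymous.

Diagnostic loci are the SNP subset of a pairwise comparison. Indels are
excluded by design: read-level indel frequencies are unreliable, so
classification and heteroplasmy quantification rest on SNPs only.

## SSR scanning (`ssr`)

Maximal perfect tandem repeats with motif length 1–6 and repeat counts
of at least 10/6/5/5/5/5 (mono→hexa). Motifs must have minimal period
(a poly-A run is never reported as "AA" repeats); the reported interval
keeps only complete repeats, dropping the partial tail; SSRs separated
by ≤ 100 bp merge into one compound SSR that counts once in totals.
Summaries group A with T mononucleotides, matching the field's usual
reporting. The scanner is run-based and linear; tests compare it
against an exhaustive O(n²) enumerator on random and low-complexity
strings.

## Diversity, haplotypes, trees (`popgen`)

π between two aligned sequences is mismatches over compared sites, with
any site carrying a gap or N in either sequence excluded from both
numerator and denominator (pairwise deletion). Window profiles lay
1200 bp windows every 400 bp from alignment position 1 and drop the
trailing partial window; window π is the mean over all unordered sample
pairs of pairwise π restricted to the window. A known interval (e.g. an
inversion, which alignment would misrepresent) can be masked rather
than realigned. For resequenced samples expressed as variant calls on
one reference, `alignment_from_variants` projects them into a
reference-length matrix (SNPs substituted, deletions as gaps,
insertions dropped).

Haplotype tables collapse identical allele vectors across the union of
variant loci; a locus is flagged *exclusive* when every carrier of its
non-reference allele belongs to one cytotype group. Distances are
Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, with an explicit error for
saturated pairs (p ≥ 0.75). Trees are neighbor-joining (scikit-bio)
over those distances, with taxa sorted lexicographically beforehand so
tie-breaking is deterministic; only topology-level statements (e.g. the
two-cytotype bipartition) are asserted, never branch support from a
single tree. Bootstrap support, when requested, multinomially resamples
alignment columns with a fixed seed (default 100 replicates).

## Heteroplasmy (`heteroplasmy`)

The on-disk base-count dialect is the post-quality pileup view: the
per-strand columns hold counts of bases passing the Phred filter
(threshold strictly greater than 20, a literal reading of "above 20"),
and depth is their sum. `filter_basecounts` applies the strand rule —
an allele observed on only one strand is zeroed on both — and recomputes
depth.

The major cytotype is the one whose allele is the per-locus majority at
more than half of covered diagnostic loci (at least 10 required; ties
are an error). The minor fraction at a locus is minor-allele count over
depth; the sample summary is the **median** across loci, robust to the
few loci disturbed by organellar-insert homology (the mean is reported
alongside, as the choice of summary is a convention). No error
correction is subtracted: with per-base error e, a pure sample shows a
floor of about e/3 (~0.07% at e = 0.2%), far below the 2% cutoff.

A sample is called heteroplasmic when three criteria hold:

1. median minor fraction ≥ `het_cutoff` (default 2%);
2. the minor allele survives filtering at ≥ `consistency_fraction`
   (default 90%) of loci — the genome-wide signature, as opposed to
   heterogeneity restricted to some loci. (The *fraction of loci at or
   above the cutoff* is also reported, but is not used as the gate: at a
   true mixture equal to the cutoff, sampling noise puts roughly half
   the loci below it, so gating on it would make the boundary case
   uncallable by construction.)
3. the depth-ratio guard: mean minor-allele read count divided by the
   nuclear depth estimate ≥ `numt_ratio_threshold` (default 3). A
   genuine plastid admixture is sequenced at plastid depth; a
   homologous insert in the nuclear or mitochondrial genome is
   sequenced at that compartment's depth, so a minor signal riding at
   ~1× nuclear depth is returned as `ambiguous`. Known insert intervals
   can additionally be masked from the locus set when their coordinates
   are available; absent a mask, the ratio guard alone applies.

## Synthetic data (`simulate`)

The generator reproduces the study design, not just convenient inputs.
Defaults are the study conditions: genome 161,537 bp with 30,896 bp IRs
and 13,632 bp SSC; 105 diagnostic SNPs + 36 indels (1–10 bp) and a
230 bp inversion between cytotypes; 25 within-cytotype subgroup
variants; depth 8,175×; error 0.002; nuclear depth 45×; 36% GC; 5% of
bases failing the >Q20 filter (a typical high-quality run). Base
composition is i.i.d. at 36% GC; gene models (CDS/tRNA/rRNA, ~35%
intron-bearing, both strands) are placed sparsely in the single-copy
regions.

Implant rules guarantee that truth equals the canonical call: diagnostic
events sit outside the IRs (an unmirrored IR edit would break the
exact-IR invariant, and real IRs carry almost no variation), at least
100 bp apart; indels are intergenic (no coding indels, matching
observation) and chosen left-shift-stable, so the left-normalized call
coincides with the implanted record; the inversion boundary is resampled
until not extendable by one base, so the detected interval is exact.
Base counts at diagnostic loci are multinomial over (major, minor, two
off-alleles) with the error spread equally over non-template bases,
thinned binomially by the quality-failure fraction, split binomially
between strands, with an optional Poisson(nuclear depth) minor-allele
dose at designated NUMT loci. Everything is driven by
`numpy.random.default_rng(seed)` and bit-reproducible.

What the simulator does *not* emulate — and hence what green tests do
not establish about real data: read-level artifacts (mapping bias,
alignment error around indels, quality-score miscalibration), locally
A/T-rich spacer composition (real plastomes yield many more SSRs than
an i.i.d. 36%-GC sequence), IR boundary shifts between samples,
recombination, and real multiple-alignment uncertainty (population π
uses reference projection, not a de novo alignment).

## Numerical and design notes

* Anchor k = 31 balances plastome-scale uniqueness against tolerance of
  the IRs; `detect_quadripartite` uses a longer seed (63) because its
  repeats are 10 kb+.
* Variant-calling coverage guard: the anchor chain must cover ≥ 95% of
  both genomes, else the comparison is refused rather than silently
  partial.
* The pairwise comparison reports the total event count; which loci are
  *exclusive* to a cytotype is a population-level property and lives in
  the haplotype table's exclusivity flags, not in the pairwise caller.
* Window midpoints are reported as (start + (window+1)/2) so profiles
  plot against the conventional window-midpoint x-axis.
* All pipeline outputs (including GenBank, which embeds a fixed date
  stamp) are byte-identical across reruns with the same seed and
  config.
* Error handling favors explicit failure: unalignable gap pairs name
  the interval, saturated JC pairs name the pair, classification ties
  and insufficient loci raise instead of guessing.

## Problem sizes used in the test suite

Implant–recover and round-trip tests run on a 40 kb genome with the full
architectural structure (8 kb IRs, 4 kb SSC, 40 SNPs + 10 indels +
230 bp inversion); study-sized checks (161.5 kb pair, 122-locus mixtures
at 4,000–8,000×, the 200-replicate false-positive control, and the
43-sample × 161.5 kb population π) run once each on shared fixtures.
These sizes were chosen so the whole suite exercises every path at full
scale at least once while staying fast enough to run on every commit.

## Known limitations

* The comparison targets closely related assemblies (two cytotypes of
  one species, or congeners); it is not a general whole-genome aligner
  and refuses inputs its anchor chain cannot cover.
* Inversion calls report whatever maximal interval the data supports;
  nested or overlapping rearrangements are out of scope.
* Heteroplasmy estimates are not error-corrected; at mixtures below
  ~0.5% the error floor begins to matter and the 2% cutoff is the
  intended operating point.
* The NJ tree is a distance method used for topology-level claims; for
  publication-grade phylogenies with support values, use a dedicated
  ML tool on a true multiple alignment.
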