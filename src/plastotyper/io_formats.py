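"""Readers and writers for the formats the pipeline consumes and produces.

All on-disk coordinates are 1-based inclusive (GenBank convention); internal
arithmetic elsewhere in the package is 0-based half-open, and the conversion
is confined to this module and to the dataclass accessors defined here.

Dialects
--------
* GenBank flat files are read/written through Biopython; only gene-level
  features (CDS, tRNA, rRNA) are retained.  Circular genomes are linearized
  at the deposited origin; a feature spanning the origin appears as a
  two-interval join.
* Base-count TSV: one row per (sample, position) with per-strand,
  quality-passing base counts.  Columns::

      sample pos ref A_f A_r C_f C_r G_f G_r T_f T_r ins_f ins_r del_f del_r depth

  ``*_f``/``*_r`` are forward/reverse-strand counts of bases passing the
  Phred filter applied upstream when the pileup was counted; ``depth`` is
  their sum.
* Variant TSV (VCF-like): ``chrom pos ref alt type region gene effect``,
  with ``type`` one of SNP/INS/DEL; INS rows have empty ``ref``, DEL rows
  empty ``alt``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: allele order used throughout base-count arrays
ALLELES = ("A", "C", "G", "T", "ins", "del")

_BASECOUNT_COLUMNS = [
    "sample", "pos", "ref",
    "A_f", "A_r", "C_f", "C_r", "G_f", "G_r", "T_f", "T_r",
    "ins_f", "ins_r", "del_f", "del_r", "depth",
]

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "type", "region", "gene", "effect"]


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates the dialect this module defines."""


@dataclass
class GeneFeature:
    """A gene-level annotation on a plastome.

    ``exons`` are 1-based inclusive intervals ordered in transcription
    direction (ascending coordinates on '+', descending on '-').
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]]
    is_pseudo: bool = False
    alt_start_ok: bool = False
    codon_start: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"CDS", "tRNA", "rRNA", "intron", "pseudogene"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name!r} has no exons")
        for lo, hi in self.exons:
            if lo < 1 or hi < lo:
                raise ValueError(f"bad exon interval ({lo}, {hi}) in {self.name!r}")

    @property
    def span(self) -> tuple[int, int]:
        """(min, max) genomic extent over all exons, 1-based inclusive."""
        los = [lo for lo, _ in self.exons]
        his = [hi for _, hi in self.exons]
        return min(los), max(his)

    def length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.exons)

    def contains(self, pos: int) -> bool:
        """Whether 1-based ``pos`` lies inside any exon."""
        return any(lo <= pos <= hi for lo, hi in self.exons)

    def in_span(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def cds_sequence(self, genome: str) -> str:
        """Spliced sequence in transcription direction (5'->3' of the mRNA)."""
        parts = []
        for lo, hi in self.exons:
            s = genome[lo - 1:hi]
            parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)


@dataclass
class Plastome:
    """A (typically circular) plastid genome with gene annotation."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    structure: Optional["object"] = None  # QuadripartiteStructure, set lazily

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"plastome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"plastome {self.id!r} contains ambiguity codes other than N: "
                f"{sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            _, hi = f.span
            if hi > n:
                raise ValueError(
                    f"feature {f.name!r} extends to {hi} beyond genome length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BaseCountProfile:
    """Per-site, per-strand, quality-passing base counts for one sample.

    ``counts`` has shape (n_positions, 6, 2): allele axis ordered as
    :data:`ALLELES`, strand axis (forward, reverse).  ``depth`` equals the
    sum of counts at each position.
    """

    sample_id: str
    positions: np.ndarray  # 1-based, strictly increasing
    ref: np.ndarray  # reference base per position (dtype '<U1')
    counts: np.ndarray  # (n, 6, 2) int64
    nuclear_depth_estimate: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="<U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.positions)
        if self.counts.shape != (n, 6, 2):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, 6, 2)")
        if n and np.any(np.diff(self.positions) <= 0):
            raise FormatError("positions must be strictly increasing and unique")
        if np.any(self.counts < 0):
            raise FormatError("negative base count")

    @property
    def depth(self) -> np.ndarray:
        """Total quality-passing depth per position."""
        return self.counts.sum(axis=(1, 2))

    def strand_total(self) -> np.ndarray:
        """(n, 6) counts summed over strands."""
        return self.counts.sum(axis=2)

    def __eq__(self, other: object) -> bool:  # value semantics, for round trips
        if not isinstance(other, BaseCountProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
            and self.nuclear_depth_estimate == other.nuclear_depth_estimate
        )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}


def _feature_from_seqfeature(sf: SeqFeature, genome: str) -> GeneFeature:
    kind = _GB_TO_KIND[sf.type]
    name = (sf.qualifiers.get("gene") or sf.qualifiers.get("locus_tag") or ["?"])[0]
    strand = "-" if sf.location.strand == -1 else "+"
    exons = [(int(p.start) + 1, int(p.end)) for p in sf.location.parts]
    exons.sort(key=lambda iv: iv[0], reverse=(strand == "-"))
    is_pseudo = "pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers
    codon_start = int(sf.qualifiers.get("codon_start", ["1"])[0])
    feat = GeneFeature(
        name=name, kind=kind, strand=strand, exons=exons,
        is_pseudo=is_pseudo, codon_start=codon_start,
    )
    if kind == "CDS" and not is_pseudo:
        cds = feat.cds_sequence(genome)
        feat.alt_start_ok = cds[:3] in {"GTG", "ACG", "TTG"}
    return feat


def read_genbank(path: str | Path) -> Plastome:
    """Read a GenBank flat file into a :class:`Plastome`.

    Retains gene-level features (CDS/tRNA/rRNA), joining multi-exon
    locations and flagging pseudogenes.  Raises :class:`FormatError` on a
    missing sequence or on ambiguity codes other than N.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GenBank record: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise FormatError(f"{path}: record {record.id} has no usable sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    features = [
        _feature_from_seqfeature(sf, seq)
        for sf in record.features
        if sf.type in _GB_TO_KIND
    ]
    return Plastome(id=record.id, sequence=seq, circular=circular, features=features)


def write_genbank(p: Plastome, path: str | Path) -> None:
    """Write a :class:`Plastome` as a GenBank flat file (round-trip safe)."""
    record = SeqRecord(Seq(p.sequence), id=p.id, name=p.id.split(".")[0][:16],
                       description="plastome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if p.circular else "linear"
    record.annotations["date"] = "01-JAN-2000"  # fixed: outputs are bit-stable
    for f in p.features:
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(lo - 1, hi, strand) for lo, hi in
                 sorted(f.exons, key=lambda iv: iv[0])]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.kind == "CDS":
            quals["codon_start"] = [str(f.codon_start)]
        if f.is_pseudo:
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind],
                                          qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of (id, upper-case sequence)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET - {"-"}
        if bad:
            raise FormatError(
                f"{path}: record {rec.id} contains ambiguity codes other than N: "
                f"{sorted(bad)}"
            )
        out.append((rec.id, seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Base-count TSV
# ---------------------------------------------------------------------------

def read_basecounts(path: str | Path,
                    nuclear_depth_estimate: float = 0.0) -> BaseCountProfile:
    """Read one sample's base-count TSV into a validated profile.

    Raises :class:`FormatError` on negative counts, duplicated positions, or
    a ``depth`` column inconsistent with the per-base counts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "ref": str})
    missing = [c for c in _BASECOUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing base-count columns {missing}")
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise FormatError(f"{path}: expected one sample per file, found {list(samples)}")
    count_cols = _BASECOUNT_COLUMNS[3:15]
    counts = df[count_cols].to_numpy(dtype=np.int64).reshape(len(df), 6, 2)
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative base count")
    depth = df["depth"].to_numpy(dtype=np.int64)
    if not np.array_equal(depth, counts.sum(axis=(1, 2))):
        raise FormatError(f"{path}: depth column inconsistent with per-base counts")
    try:
        return BaseCountProfile(
            sample_id=str(samples[0]),
            positions=df["pos"].to_numpy(np.int64),
            ref=df["ref"].to_numpy(dtype="<U1"),
            counts=counts,
            nuclear_depth_estimate=nuclear_depth_estimate,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_basecounts(profile: BaseCountProfile, path: str | Path) -> None:
    n = len(profile.positions)
    flat = profile.counts.reshape(n, 12)
    df = pd.DataFrame({"sample": profile.sample_id, "pos": profile.positions,
                       "ref": profile.ref})
    for i, col in enumerate(_BASECOUNT_COLUMNS[3:15]):
        df[col] = flat[:, i]
    df["depth"] = profile.depth
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant TSV
# ---------------------------------------------------------------------------

def write_variant_table(variants: Sequence, path: str | Path,
                        chrom: str = ".") -> None:
    """Write variants as a VCF-like TSV, bit-stable across runs.

    ``variants`` must be sorted by position; each item needs the
    :class:`~plastotyper.compare.VariantRecord` attributes.
    """
    positions = [v.pos for v in variants]
    if positions != sorted(positions):
        raise ValueError("variants must be sorted by position")
    buf = io.StringIO()
    buf.write("\t".join(_VARIANT_COLUMNS) + "\n")
    for v in variants:
        buf.write("\t".join([
            chrom, str(v.pos), v.ref_allele, v.alt_allele, v.vtype,
            v.region or "", v.gene or "", v.effect or "",
        ]) + "\n")
    Path(path).write_text(buf.getvalue())


def read_variant_table(path: str | Path) -> list:
    """Read a variant TSV back into :class:`~plastotyper.compare.VariantRecord`s."""
    from .compare import VariantRecord  # deferred: compare imports this module

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(VariantRecord(
            pos=int(row.pos), ref_allele=row.ref, alt_allele=row.alt,
            vtype=row.type, region=row.region or None, gene=row.gene or None,
            effect=row.effect or None,
        ))
    return out


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


# ---------------------------------------------------------------------------
# Diagnostic-locus TSV
# ---------------------------------------------------------------------------

def write_diagnostic_loci(loci, path: str | Path) -> None:
    """TSV of cytotype-diagnostic SNP loci: ``pos allele_A allele_B`` with
    the source genome pair recorded in a ``#pair=`` header line."""
    lines = [f"#pair={loci.pair_ids[0]},{loci.pair_ids[1]}",
             "pos\tallele_A\tallele_B"]
    lines += [f"{pos}\t{a}\t{b}" for pos, a, b in loci.loci]
    Path(path).write_text("\n".join(lines) + "\n")


def read_diagnostic_loci(path: str | Path):
    from .compare import DiagnosticLocusSet  # deferred: avoids import cycle

    text = Path(path).read_text().splitlines()
    pair = ("A", "B")
    loci = []
    for line in text:
        if line.startswith("#pair="):
            ids = line[len("#pair="):].split(",")
            if len(ids) == 2:
                pair = (ids[0], ids[1])
            continue
        if not line or line.startswith("pos\t"):
            continue
        pos, a, b = line.split("\t")
        loci.append((int(pos), a, b))
    return DiagnosticLocusSet(pair_ids=pair, loci=loci)
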