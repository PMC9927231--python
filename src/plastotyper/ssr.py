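"""MISA-semantics microsatellite (SSR) detection.

An SSR is a maximal perfect tandem repeat of a 1-6 bp motif whose repeat
count reaches a per-unit-length threshold.  Motifs must have minimal
period (poly-A is reported as a mononucleotide run, never as an "AA"
dinucleotide), trailing partial repeats are dropped from the reported
interval, and SSRs separated by at most ``compound_max_gap`` bp merge into
one compound SSR that counts once in totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_formats import Plastome
from .compare import VariantRecord, classify_region


@dataclass
class SSRConfig:
    """Detection thresholds: minimum repeat count per motif length 1..6."""

    min_repeats: tuple[int, int, int, int, int, int] = (10, 6, 5, 5, 5, 5)
    compound_max_gap: int = 100

    def __post_init__(self) -> None:
        if len(self.min_repeats) != 6 or any(t < 1 for t in self.min_repeats):
            raise ValueError("min_repeats must be six thresholds >= 1")


@dataclass
class SSRMotif:
    """One simple or compound SSR; coordinates 1-based inclusive."""

    start: int
    end: int
    motif: str
    unit_len: int  # 0 for compound
    n_repeats: int  # 0 for compound
    kind: str = "simple"  # simple | compound
    parts: list["SSRMotif"] = field(default_factory=list)
    location: Optional[str] = None
    gene: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _minimal_period(motif: str) -> bool:
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def find_simple_ssrs(sequence: str, cfg: SSRConfig | None = None) -> list[SSRMotif]:
    """All maximal perfect tandem repeats meeting the thresholds, sorted by
    start; no compound merging (see :func:`find_ssrs`)."""
    cfg = cfg or SSRConfig()
    s = sequence.upper()
    n = len(s)
    out: list[SSRMotif] = []
    for u in range(1, 7):
        threshold = cfg.min_repeats[u - 1]
        j = u
        while j < n:
            if s[j] != s[j - u]:
                j += 1
                continue
            j0 = j
            while j < n and s[j] == s[j - u]:
                j += 1
            start = j0 - u          # 0-based array start
            total = (j - j0) + u    # full array length incl. partial tail
            reps = total // u
            motif = s[start:start + u]
            if reps >= threshold and "N" not in motif and _minimal_period(motif):
                out.append(SSRMotif(
                    start=start + 1, end=start + reps * u,
                    motif=motif, unit_len=u, n_repeats=reps,
                ))
    out.sort(key=lambda m: (m.start, m.unit_len))
    return out


def find_ssrs(p: Plastome | str, cfg: SSRConfig | None = None) -> list[SSRMotif]:
    """Simple SSRs plus compound merging of SSRs <= ``compound_max_gap`` apart.

    A compound SSR replaces its parts and counts once in totals, matching
    the convention in which a 79-SSR total decomposes as, e.g., 63 mono +
    5 di + 1 tri + 10 compound.
    """
    cfg = cfg or SSRConfig()
    sequence = p.sequence if isinstance(p, Plastome) else p
    simple = find_simple_ssrs(sequence, cfg)
    out: list[SSRMotif] = []
    for m in simple:
        if out and m.start - out[-1].end - 1 <= cfg.compound_max_gap:
            prev = out[-1]
            if prev.kind == "compound":
                prev.parts.append(m)
                prev.end = max(prev.end, m.end)
                prev.motif = prev.motif + "+" + m.motif
                continue
            out[-1] = SSRMotif(
                start=prev.start, end=max(prev.end, m.end),
                motif=prev.motif + "+" + m.motif, unit_len=0, n_repeats=0,
                kind="compound", parts=[prev, m],
            )
            continue
        out.append(m)
    return out


def classify_ssr_locations(ssrs: Sequence[SSRMotif],
                           p: Plastome) -> dict[str, int]:
    """Assign each SSR a genomic context by its start coordinate and return
    counts by location (counts always sum to the SSR total)."""
    counts = {"CDS": 0, "intron": 0, "intergenic": 0}
    for m in ssrs:
        probe = VariantRecord(m.start, "N", "N", "SNP")
        m.location, m.gene = classify_region(probe, p)
        counts[m.location] += 1
    return counts


def summarize_ssrs(ssrs: Sequence[SSRMotif]) -> dict[str, int]:
    """Counts by repeat class, with A and T mononucleotides grouped."""
    out = {"total": len(ssrs), "mono": 0, "mono_AT": 0, "di": 0, "tri": 0,
           "tetra": 0, "penta": 0, "hexa": 0, "compound": 0}
    names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
    for m in ssrs:
        if m.kind == "compound":
            out["compound"] += 1
            continue
        out[names[m.unit_len]] += 1
        if m.unit_len == 1 and m.motif in {"A", "T"}:
            out["mono_AT"] += 1
    return out
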