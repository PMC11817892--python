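"""Telomere and centromere landmark detection.

Telomeres are tandem arrays of the plant 7-mer TTTAGGG at chromosome
termini: the forward unit at the 3' end and its reverse complement
(CCCTAAA) at the 5' end.  Centromeres are tandem arrays of a ~107-nt
monomer; array membership is decided by per-copy alignment identity
against the canonical monomer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .core_io import GenomeSequence

#: canonical plant telomere unit (3' strand)
TELOMERE_UNIT = "TTTAGGG"

#: the grape centromeric monomer (107 nt)
CENTROMERE_MONOMER = (
    "AGTACCGAAAAAGGGTCGAATCAGTGTGAGTACCGAAAAATGGTAGAATCCGGGCG"
    "AGTACCGGGAAAAGGTAGAATCCGTGCGAGTATCGAAAAACTGTCCGGGCG"
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TelomereCall:
    chrom_id: str
    terminus: str  # "5prime" | "3prime"
    start: int
    end: int
    copies: int
    motif_used: str


@dataclass
class CentromereCall:
    chrom_id: str
    start: int
    end: int
    copies: int
    mean_identity: float


def scan_telomeres(
    seq: GenomeSequence,
    motif: str = TELOMERE_UNIT,
    min_copies: int = 10,
    terminal_window: int = 50_000,
) -> list[TelomereCall]:
    """Find tandem telomere-unit runs within each terminal window.

    The forward motif is searched at the 3' terminus and its reverse
    complement at the 5' terminus; the longest qualifying run per
    terminus is reported.
    """
    motif = motif.upper()
    if len(motif) < 5:
        raise ValueError("telomere motif must be at least 5 bp")
    if set(motif) - set("ACGT"):
        raise ValueError(f"telomere motif contains non-ACGT characters: {motif!r}")
    if terminal_window > seq.length:
        terminal_window = seq.length
    calls: list[TelomereCall] = []
    for terminus, unit, lo, hi in (
        ("5prime", revcomp(motif), 0, terminal_window),
        ("3prime", motif, seq.length - terminal_window, seq.length),
    ):
        best = _longest_run(seq.seq, unit, lo, hi)
        if best is not None and best[2] >= min_copies:
            start, end, copies = best
            calls.append(TelomereCall(seq.chrom_id, terminus, start, end, copies, unit))
    return calls


def _longest_run(seq: str, unit: str, lo: int, hi: int) -> tuple[int, int, int] | None:
    """Longest maximal tandem run of ``unit`` inside seq[lo:hi]."""
    window = seq[lo:hi]
    best = None
    for m in re.finditer(f"(?:{re.escape(unit)})+", window):
        copies = (m.end() - m.start()) // len(unit)
        if best is None or copies > best[2]:
            best = (lo + m.start(), lo + m.start() + copies * len(unit), copies)
    return best


def scan_monomer_array(
    seq: GenomeSequence,
    monomer: str = CENTROMERE_MONOMER,
    min_identity: float = 80.0,
    min_copies: int = 10,
) -> list[CentromereCall]:
    """Find tandem arrays of a monomer by chained approximate matching.

    Each array is grown copy-by-copy: the monomer is aligned to a prefix
    of the remaining sequence (allowing up to ``1 - min_identity/100``
    errors per copy) and consecutive qualifying copies are merged.
    Arrays shorter than ``min_copies`` copies are discarded.
    """
    if not monomer:
        raise ValueError("monomer must be non-empty")
    if not (50.0 < min_identity <= 100.0):
        raise ValueError("min_identity must lie in (50, 100]")
    monomer = monomer.upper()
    m = len(monomer)
    kmax = int(m * (1.0 - min_identity / 100.0))
    s = seq.seq
    n = len(s)
    rmonomer = monomer[::-1]
    calls: list[CentromereCall] = []
    pos = 0
    while pos <= n - m:
        hit = edlib.align(monomer, s[pos:], mode="HW", task="locations", k=kmax)
        if hit["editDistance"] == -1:
            break
        anchor = pos + hit["locations"][0][0]
        # the anchor is the best copy, possibly mid-array: extend both ways
        identities: list[float] = []
        cur = anchor
        while cur <= n - int(m * 0.9):
            window = s[cur : cur + m + max(kmax, 1)]
            r = edlib.align(monomer, window, mode="SHW", task="locations", k=kmax)
            if r["editDistance"] == -1:
                break
            copy_end = cur + r["locations"][0][1] + 1
            cols = max(m, copy_end - cur)
            identities.append(100.0 * (cols - r["editDistance"]) / cols)
            cur = copy_end
        first = anchor
        while first >= int(m * 0.9):
            window = s[max(0, first - m - max(kmax, 1)) : first]
            # prefix alignment on the reversed strings walks one copy backwards
            r = edlib.align(rmonomer, window[::-1], mode="SHW", task="locations", k=kmax)
            if r["editDistance"] == -1:
                break
            copy_start = first - (r["locations"][0][1] + 1)
            cols = max(m, first - copy_start)
            identities.insert(0, 100.0 * (cols - r["editDistance"]) / cols)
            first = copy_start
        copies = len(identities)
        if copies >= min_copies:
            calls.append(
                CentromereCall(
                    chrom_id=seq.chrom_id,
                    start=first,
                    end=cur,
                    copies=copies,
                    mean_identity=sum(identities) / copies,
                )
            )
        pos = max(cur, anchor + m)
    return calls


def total_array_length(calls: list[CentromereCall]) -> dict[str, int]:
    """Total monomer-array span per chromosome."""
    out: dict[str, int] = {}
    for c in calls:
        out[c.chrom_id] = out.get(c.chrom_id, 0) + (c.end - c.start)
    return out


def landmark_bed(
    telomeres: list[TelomereCall], centromeres: list[CentromereCall], path
) -> None:
    """Write all landmark calls as BED (score column = copies)."""
    rows = [
        (t.chrom_id, t.start, t.end, f"telomere_{t.terminus}", t.copies)
        for t in telomeres
    ] + [(c.chrom_id, c.start, c.end, "centromere", c.copies) for c in centromeres]
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def telomere_summary(telomeres: list[TelomereCall], n_chroms: int) -> str:
    """Summary in the 'found / possible' style, e.g. '17/19'."""
    return f"{len(telomeres)}/{2 * n_chroms}"
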