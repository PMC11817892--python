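"""Structural-variant merging, zygosity, hemizygous genes and SV/ASE density.

Per-haplotype SV calls against one reference are merged by type,
position and length similarity (single-linkage over pairwise
compatibility, so merging the merged set is a no-op).  A variant seen on
exactly one haplotype of a diploid is heterozygous; on both, homozygous.
A gene is hemizygous when heterozygous SVs cover strictly more than 10%
of its coding-region union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import GeneModel, SVRecord, merge_intervals


@dataclass
class GenotypedSV:
    merged_id: str
    chrom_id: str
    pos: int
    sv_type: str
    length: int
    supporting_haplotypes: frozenset[str]
    zygosity: str  # "heterozygous" | "homozygous"

    @property
    def span(self) -> tuple[int, int]:
        if self.sv_type == "INS":
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + self.length)


@dataclass
class HemizygousCall:
    gene_id: str
    sv_ids: list[str]
    coding_overlap_bp: int
    coding_overlap_fraction: float


def _compatible(a: SVRecord, b: SVRecord, pos_tol: int, len_tol: float) -> bool:
    if a.chrom_id != b.chrom_id or a.sv_type != b.sv_type:
        return False
    if abs(a.pos - b.pos) > pos_tol:
        return False
    return abs(a.length - b.length) <= len_tol * max(a.length, b.length)


def merge_svs(
    per_haplotype_calls: dict[str, list[SVRecord]],
    pos_tolerance: int = 1000,
    len_tolerance: float = 0.25,
    haplotype_pair: Optional[tuple[str, str]] = None,
    min_support: int = 1,
) -> list[GenotypedSV]:
    """Merge per-haplotype SV calls and genotype zygosity.

    Calls of the same type within ``pos_tolerance`` bp whose lengths
    differ by at most ``len_tolerance`` (fraction of the larger) are
    merged transitively.  ``haplotype_pair`` names the diploid's two
    haplotypes (defaults to the dict keys, which must then number two).
    ``min_support`` drops merged SVs supported by fewer haplotypes
    (e.g. 2 to keep only multi-genome-supported SVs).
    """
    if haplotype_pair is None:
        if len(per_haplotype_calls) != 2:
            raise ValueError(
                "haplotype_pair must be given unless exactly two haplotypes supplied"
            )
        haplotype_pair = tuple(per_haplotype_calls)  # type: ignore[assignment]
    chroms_by_hap = {
        h: {c.chrom_id for c in calls} for h, calls in per_haplotype_calls.items()
    }
    all_chroms = set.union(*chroms_by_hap.values()) if chroms_by_hap else set()
    for h, chroms in chroms_by_hap.items():
        foreign = chroms - all_chroms
        if foreign:
            raise ValueError(f"haplotype {h}: unknown chromosomes {sorted(foreign)}")

    calls = [c for cs in per_haplotype_calls.values() for c in cs]
    calls.sort(key=lambda c: (c.chrom_id, c.sv_type, c.pos, c.length, c.sv_id))
    # single-linkage components over the compatibility relation
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if (a.chrom_id, a.sv_type) != (b.chrom_id, b.sv_type):
                break
            if b.pos - a.pos > pos_tolerance:
                break
            if _compatible(a, b, pos_tolerance, len_tolerance):
                parent[find(i)] = find(j)

    groups: dict[int, list[SVRecord]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])

    merged = []
    for k, members in enumerate(
        sorted(groups.values(), key=lambda ms: (ms[0].chrom_id, ms[0].pos))
    ):
        support = frozenset(m.source_haplotype for m in members)
        if len(support) < min_support:
            continue
        pos = int(np.median([m.pos for m in members]))
        length = int(np.median([m.length for m in members]))
        zyg = (
            "homozygous"
            if all(h in support for h in haplotype_pair)
            else "heterozygous"
        )
        merged.append(
            GenotypedSV(
                merged_id=f"msv{k + 1}",
                chrom_id=members[0].chrom_id,
                pos=pos,
                sv_type=members[0].sv_type,
                length=length,
                supporting_haplotypes=support,
                zygosity=zyg,
            )
        )
    return merged


def call_hemizygous(
    het_svs: Sequence[GenotypedSV],
    genes: Sequence[GeneModel],
    min_fraction: float = 0.10,
) -> list[HemizygousCall]:
    """Genes whose coding union is covered > ``min_fraction`` by het SVs.

    Only heterozygous SVs are admitted (homozygous input is a usage
    error); the threshold is strict, so exactly 10% does not call.
    """
    for sv in het_svs:
        if sv.zygosity != "heterozygous":
            raise ValueError(f"SV {sv.merged_id} is not heterozygous")
    by_chrom: dict[str, list[GenotypedSV]] = {}
    for sv in het_svs:
        by_chrom.setdefault(sv.chrom_id, []).append(sv)
    calls = []
    for g in genes:
        coding = g.coding_intervals
        total = g.coding_length
        if total == 0:
            import warnings

            warnings.warn(f"gene {g.gene_id} has zero coding length; skipped")
            continue
        ivs = []
        sv_ids = []
        for sv in by_chrom.get(g.chrom_id, []):
            s, e = sv.span
            pieces = [
                (max(s, cs), min(e, ce)) for cs, ce in coding if e > cs and s < ce
            ]
            pieces = [(a, b) for a, b in pieces if b > a]
            if pieces:
                ivs.extend(pieces)
                sv_ids.append(sv.merged_id)
        overlap = sum(e - s for s, e in merge_intervals(ivs))
        frac = overlap / total
        if frac > min_fraction:
            calls.append(HemizygousCall(g.gene_id, sv_ids, overlap, frac))
    return calls


def promoter_interval(gene: GeneModel, promoter_len: int = 2000) -> tuple[int, int]:
    """Strand-aware promoter: ``promoter_len`` bp upstream of the TSS, clipped at 0."""
    if gene.strand == "+":
        return (max(0, gene.start - promoter_len), gene.start)
    return (gene.end, gene.end + promoter_len)


def promoter_sv_genes(
    genes: Sequence[GeneModel],
    het_svs: Sequence[GenotypedSV],
    promoter_len: int = 2000,
) -> set[str]:
    """Genes with at least one heterozygous SV overlapping their promoter."""
    by_chrom: dict[str, list[GenotypedSV]] = {}
    for sv in het_svs:
        by_chrom.setdefault(sv.chrom_id, []).append(sv)
    out = set()
    for g in genes:
        lo, hi = promoter_interval(g, promoter_len)
        for sv in by_chrom.get(g.chrom_id, []):
            s, e = sv.span
            if e > lo and s < hi:
                out.add(g.gene_id)
                break
    return out


def sv_ase_density_correlation(
    het_svs: Sequence[GenotypedSV],
    ase_genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> tuple[float, float]:
    """Spearman correlation of per-bin het-SV and ASE-gene counts.

    Genomic bins of ``bin_size`` tile every chromosome; a bin's SV count
    uses SV start positions and its ASE count uses gene starts.
    Requires >= 10 bins that are non-empty for at least one series.
    """
    bins: dict[tuple[str, int], list[int]] = {}
    for chrom, length in chrom_lengths.items():
        for b in range(0, length, bin_size):
            bins[(chrom, b // bin_size)] = [0, 0]
    for sv in het_svs:
        key = (sv.chrom_id, sv.pos // bin_size)
        if key in bins:
            bins[key][0] += 1
    for g in ase_genes:
        key = (g.chrom_id, g.start // bin_size)
        if key in bins:
            bins[key][1] += 1
    sv_counts = np.array([v[0] for v in bins.values()])
    ase_counts = np.array([v[1] for v in bins.values()])
    nonempty = int(np.sum((sv_counts > 0) | (ase_counts > 0)))
    if nonempty < 10:
        raise ValueError(f"need >= 10 non-empty bins, got {nonempty}")
    if sv_counts.std() == 0 or ase_counts.std() == 0:
        raise ValueError("undefined correlation: a count vector is constant")
    rho, p = stats.spearmanr(sv_counts, ase_counts)
    return float(rho), float(p)
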