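"""Diploid toy-genome generator with planted, machine-readable ground truth.

Every pipeline stage is testable without external downloads: chromosomes
carry terminal telomere arrays and an interior centromeric monomer
array; genes are placed non-overlapping with the eight R-gene domain
architectures represented; TE intervals are planted dense near R genes
and sparse elsewhere; heterozygous SVs overlap coding regions of target
genes; and allele-count tables carry planted expression imbalance.  The
planted truth is serialised as one JSON sidecar next to the fixture.

The generator emulates the *statistical* structure the pipeline
measures (densities, effect sizes, category composition), not sequence
evolution: proteins are random strings, homologous families are seed
sequences with point substitutions, and reads are never simulated.
"""

from __future__ import annotations

import hashlib
import json
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import core_io
from .classify import AMINO_ACIDS, RCategory
from .core_io import DomainHit, GeneModel, GenomeSequence, IntactLTR, SVRecord, TEFeature
from .landmarks import CENTROMERE_MONOMER, TELOMERE_UNIT, revcomp

_CATEGORY_DOMAINS = {
    RCategory.NB: ("NB-ARC",),
    RCategory.NL: ("NB-ARC", "LRR"),
    RCategory.TN: ("TIR", "NB-ARC"),
    RCategory.TNL: ("TIR", "NB-ARC", "LRR"),
    RCategory.CN: ("CC", "NB-ARC"),
    RCategory.CNL: ("CC", "NB-ARC", "LRR"),
    RCategory.RN: ("RPW8", "NB-ARC"),
    RCategory.RNL: ("RPW8", "NB-ARC", "LRR"),
}

_TE_CLASS_WEIGHTS = {
    "LTR/Gypsy": 0.40,
    "LTR/Copia": 0.25,
    "TIR/Mutator": 0.15,
    "LINE": 0.10,
    "Helitron": 0.05,
    "other": 0.05,
}

GENE_LEN = 3000
_CDS_TEMPLATE = ((0, 1000), (1200, 2200), (2400, 3000))
PROTEIN_LEN = 200
LTR_LEN = 200


@dataclass
class SyntheticConfig:
    n_chroms: int = 4
    chrom_len: int = 2_000_000
    telomere_copies: int = 20
    centromere_copies: int = 30
    monomer_divergence: float = 0.05
    n_genes: int = 120
    n_rgenes_per_category: int = 4
    te_density_near_r: float = 0.6
    te_density_background: float = 0.2
    n_het_svs: int = 40
    sv_gene_overlap_fraction: float = 0.3
    n_hom_svs: int = 8
    ase_effect_genes: int = 20
    ase_fold: float = 4.0
    seed: int = 0
    flank: int = 50_000  # near-R window half-width used for TE planting

    def __post_init__(self) -> None:
        for name in (
            "monomer_divergence",
            "te_density_near_r",
            "te_density_background",
            "sv_gene_overlap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_len", "telomere_copies", "centromere_copies", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ase_effect_genes > self.n_genes:
            raise ValueError("ase_effect_genes cannot exceed n_genes")
        if self.ase_fold < 1.0:
            raise ValueError("ase_fold must be >= 1")


class CapacityError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


@dataclass
class TruthSet:
    telomeres: list[dict] = field(default_factory=list)
    centromeres: list[dict] = field(default_factory=list)
    rgene_categories: dict[str, str] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    het_svs: list[dict] = field(default_factory=list)
    hom_svs: list[dict] = field(default_factory=list)
    hemizygous_genes: list[str] = field(default_factory=list)
    hemizygous_negative_genes: list[str] = field(default_factory=list)
    promoter_sv_genes: list[str] = field(default_factory=list)
    ase_genes: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Fixture:
    """In-memory view of one generated fixture plus its on-disk paths."""

    out_dir: Path
    sequences: list[GenomeSequence]
    genes: list[GeneModel]
    proteins: dict[str, str]
    domain_hits: list[DomainHit]
    tes: list[TEFeature]
    intact_ltrs: list[IntactLTR]
    sv_calls: dict[str, list[SVRecord]]
    allele_counts: pd.DataFrame
    genes_b: list[GeneModel]
    proteins_b: dict[str, str]
    domain_hits_b: list[DomainHit]
    ortholog_map: dict[str, str]
    truth: TruthSet

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {s.chrom_id: s.length for s in self.sequences}

    def path(self, name: str) -> Path:
        return self.out_dir / name


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_protein(rng: np.random.Generator, n: int = PROTEIN_LEN) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float, alphabet: str) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = alphabet.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _layout(cfg: SyntheticConfig) -> dict:
    """Fixed per-chromosome coordinate plan; raises CapacityError early."""
    L = cfg.chrom_len
    tel_len = cfg.telomere_copies * len(TELOMERE_UNIT)
    cen_len = cfg.centromere_copies * len(CENTROMERE_MONOMER)
    cen_start = L // 2 - cen_len // 2
    cen_end = cen_start + cen_len
    margin = 60_000
    left_arm = (margin, cen_start - margin)
    right_arm = (cen_end + margin, L - margin)
    if tel_len + 500 > margin or cen_start <= tel_len + 500:
        raise CapacityError("telomere/centromere arrays exceed chromosome capacity")
    # per-chromosome gene budgets
    n_r = 8 * cfg.n_rgenes_per_category
    n_nonr = cfg.n_genes - n_r
    if n_nonr < 0:
        raise CapacityError("more R genes requested than n_genes")
    r_per_chrom = -(-n_r // cfg.n_chroms)  # ceil
    nonr_per_chrom = -(-n_nonr // cfg.n_chroms)
    r_spacing = 80_000  # keeps R windows dense but genes distinct
    if left_arm[1] - left_arm[0] < r_per_chrom * r_spacing + GENE_LEN:
        raise CapacityError(
            f"left arm cannot hold {r_per_chrom} R genes at {r_spacing} bp spacing"
        )
    nonr_spacing = (right_arm[1] - right_arm[0] - GENE_LEN) // max(nonr_per_chrom, 1)
    if nonr_spacing < GENE_LEN + 6_000:
        raise CapacityError(
            f"right arm cannot hold {nonr_per_chrom} genes without overlap"
        )
    return {
        "tel_len": tel_len,
        "cen": (cen_start, cen_end),
        "left_arm": left_arm,
        "right_arm": right_arm,
        "n_r": n_r,
        "n_nonr": n_nonr,
        "r_spacing": r_spacing,
        "nonr_spacing": nonr_spacing,
    }


def _place_genes(cfg: SyntheticConfig, lay: dict, rng: np.random.Generator):
    """R genes on left arms, non-R genes on right arms, never overlapping.

    The >= 2*flank separation between R and non-R genes (enforced by the
    arm layout) keeps background windows clear of near-R TE density.
    """
    genes: list[GeneModel] = []
    r_ids: list[str] = []
    nonr_ids: list[str] = []
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n_r_here = min(lay["n_r"] - len(r_ids), -(-lay["n_r"] // cfg.n_chroms))
        pos = lay["left_arm"][0] + 40_000
        for _ in range(n_r_here):
            gid += 1
            gene_id = f"g{gid:04d}"
            start = pos + int(rng.integers(0, 5_000))
            genes.append(_make_gene(gene_id, chrom, start, rng))
            r_ids.append(gene_id)
            pos += lay["r_spacing"]
        n_nonr_here = min(lay["n_nonr"] - len(nonr_ids), -(-lay["n_nonr"] // cfg.n_chroms))
        pos = lay["right_arm"][0] + 5_000
        for _ in range(n_nonr_here):
            gid += 1
            gene_id = f"g{gid:04d}"
            start = pos + int(rng.integers(0, 2_000))
            genes.append(_make_gene(gene_id, chrom, start, rng))
            nonr_ids.append(gene_id)
            pos += lay["nonr_spacing"]
    return genes, r_ids, nonr_ids


def _make_gene(gene_id: str, chrom: str, start: int, rng: np.random.Generator) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    cds = [(start + s, start + e) for s, e in _CDS_TEMPLATE]
    return GeneModel(gene_id, chrom, start, start + GENE_LEN, strand, cds)


def _assign_r_architecture(cfg: SyntheticConfig, r_ids: list[str], rng: np.random.Generator):
    """Categories, proteins and homology families for the R genes.

    The first four R genes on chr1 form a homologous family that will be
    assembly-A-specific; the first four on chr2 form a family shared
    with assembly B.  All other R proteins are unrelated singletons.
    """
    categories = [cat for cat in _CATEGORY_DOMAINS for _ in range(cfg.n_rgenes_per_category)]
    assert len(categories) == len(r_ids)
    proteins: dict[str, str] = {}
    per_chrom = -(-len(r_ids) // cfg.n_chroms)
    fam_a = r_ids[:4] if per_chrom >= 4 else []
    fam_b = r_ids[per_chrom : per_chrom + 4] if len(r_ids) >= per_chrom + 4 else []
    seed_a = _random_protein(rng)
    seed_b = _random_protein(rng)
    for gid in r_ids:
        if gid in fam_a:
            proteins[gid] = _mutate(rng, seed_a, 0.05, AMINO_ACIDS)
        elif gid in fam_b:
            proteins[gid] = _mutate(rng, seed_b, 0.05, AMINO_ACIDS)
        else:
            proteins[gid] = _random_protein(rng)
    cat_map = dict(zip(r_ids, (c.value for c in categories)))
    return cat_map, proteins, fam_a, fam_b


def _domain_hits_for(cat_map: dict[str, str], rng: np.random.Generator) -> list[DomainHit]:
    hits = []
    for gid, cat in cat_map.items():
        q = 1
        for dom in _CATEGORY_DOMAINS[RCategory(cat)]:
            hits.append(DomainHit(gid, dom, 10.0 ** -float(rng.integers(10, 40)), q, q + 50))
            q += 60
    return hits


class _NonOverlapSampler:
    """Rejection-sample non-overlapping intervals into target regions."""

    def __init__(self, regions: list[tuple[int, int]], rng: np.random.Generator):
        self.regions = [r for r in regions if r[1] > r[0]]
        self.rng = rng
        self.total = sum(e - s for s, e in self.regions)
        self.weights = np.array([e - s for s, e in self.regions], dtype=float)
        self.weights /= self.weights.sum()
        self.placed_starts: list[int] = []  # sorted; parallel ends
        self.placed: dict[int, int] = {}

    def _free(self, s: int, e: int) -> bool:
        i = bisect_left(self.placed_starts, e)
        if i > 0:
            prev = self.placed_starts[i - 1]
            if self.placed[prev] > s:
                return False
        return True

    def fill(self, target_fraction: float, length_range=(500, 3000), max_fail=2000):
        covered = 0
        fails = 0
        out = []
        while covered < target_fraction * self.total and fails < max_fail:
            ri = self.rng.choice(len(self.regions), p=self.weights)
            lo, hi = self.regions[ri]
            length = int(self.rng.integers(*length_range))
            if hi - lo <= length:
                fails += 1
                continue
            s = int(self.rng.integers(lo, hi - length))
            e = s + length
            if not self._free(s, e):
                fails += 1
                continue
            insort(self.placed_starts, s)
            self.placed[s] = e
            covered += length
            fails = 0
            out.append((s, e))
        return out


def _complement(regions: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    cur = lo
    for s, e in sorted(regions):
        if s > cur:
            out.append((cur, min(s, hi)))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return [r for r in out if r[1] > r[0]]


def _plant_tes(cfg, lay, genes, r_ids, rng):
    """TE intervals at te_density_near_r inside R windows, background elsewhere."""
    classes = list(_TE_CLASS_WEIGHTS)
    probs = np.array(list(_TE_CLASS_WEIGHTS.values()))
    tes: list[TEFeature] = []
    ltrs: list[IntactLTR] = []
    r_set = set(r_ids)
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        L = cfg.chrom_len
        near = core_io.merge_intervals(
            (max(0, g.start - cfg.flank), min(L, g.end + cfg.flank))
            for g in genes
            if g.chrom_id == chrom and g.gene_id in r_set
        )
        guard = 2_000  # keep TEs off the chromosome tips (telomere arrays)
        background = _complement(near, guard, L - guard)
        for regions, density, intact_p, ltr_div in (
            (near, cfg.te_density_near_r, 0.35, 0.01),
            (background, cfg.te_density_background, 0.08, 0.10),
        ):
            if not regions:
                continue
            sampler = _NonOverlapSampler(regions, rng)
            for s, e in sampler.fill(density):
                te_class = classes[int(rng.choice(len(classes), p=probs))]
                intact = te_class.startswith("LTR/") and rng.random() < intact_p
                te = TEFeature(chrom, s, e, te_class, intact)
                tes.append(te)
                if intact:
                    ltr5 = _random_dna(rng, LTR_LEN)
                    ltr3 = _mutate(rng, ltr5, ltr_div, "ACGT")
                    ltrs.append(IntactLTR(te, ltr5, ltr3))
    tes.sort(key=lambda t: (t.chrom_id, t.start))
    return tes, ltrs


def make_sv_overlay(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel],
    r_ids: Sequence[str],
    nonr_ids: Sequence[str],
    rng: np.random.Generator,
):
    """Plant heterozygous and homozygous SVs relative to the base genome.

    A stated subset of heterozygous DELs covers > 10% of a target gene's
    coding span (those genes become hemizygous truth); about six het
    DELs sit in promoters; the remainder is intergenic.  One homozygous
    DEL covers a gene's coding span to provide a guaranteed negative.
    """
    by_id = {g.gene_id: g for g in genes}
    n_target = round(cfg.n_het_svs * cfg.sv_gene_overlap_fraction)
    n_promoter = min(6, max(0, cfg.n_het_svs - n_target))
    n_intergenic = cfg.n_het_svs - n_target - n_promoter
    pool = list(nonr_ids)
    if len(pool) < n_target + n_promoter + 1:
        raise CapacityError("not enough non-R genes for the requested SV overlay")
    chosen = [pool[i] for i in rng.choice(len(pool), n_target + n_promoter + 1, replace=False)]
    target_genes = chosen[:n_target]
    promoter_genes = chosen[n_target : n_target + n_promoter]
    hom_target_gene = chosen[-1]

    calls: dict[str, list[SVRecord]] = {"hap1": [], "hap2": []}
    truth_het, truth_hom = [], []
    k = 0

    def het_record(chrom, pos, sv_type, length):
        nonlocal k
        k += 1
        hap = "hap1" if rng.random() < 0.5 else "hap2"
        rec = SVRecord(f"sv{k:03d}", chrom, pos, sv_type, length, hap)
        calls[hap].append(rec)
        truth_het.append(
            {"sv_id": rec.sv_id, "chrom": chrom, "pos": pos, "type": sv_type,
             "length": length, "haplotype": hap}
        )
        return rec

    for gid in target_genes:
        g = by_id[gid]
        # covers CDS1 partially: 600 of 2600 coding bp (~23%) > 10%
        het_record(g.chrom_id, g.start + 100, "DEL", 600)
    for gid in promoter_genes:
        g = by_id[gid]
        pos = g.start - 1600 if g.strand == "+" else g.end + 1300
        het_record(g.chrom_id, pos, "DEL", 300)

    # intergenic placements: midway between consecutive right-arm genes
    gaps = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom_id, []).append(g)
    for chrom, gs in sorted(by_chrom.items()):
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start - a.end > 14_000:
                gaps.append((chrom, a.end + 5_000, b.start - 5_000))
    if len(gaps) < n_intergenic + cfg.n_hom_svs - 1:
        raise CapacityError("not enough intergenic space for the requested SVs")
    order = rng.permutation(len(gaps))
    gi = 0
    for _ in range(n_intergenic):
        chrom, lo, hi = gaps[order[gi]]
        gi += 1
        sv_type = "DEL" if rng.random() < 0.5 else "INS"
        pos = int(rng.integers(lo, hi - 500))
        het_record(chrom, pos, sv_type, int(rng.integers(100, 2000)))

    def hom_record(chrom, pos, sv_type, length):
        nonlocal k
        k += 1
        for hap in ("hap1", "hap2"):
            calls[hap].append(SVRecord(f"sv{k:03d}", chrom, pos, sv_type, length, hap))
        truth_hom.append(
            {"sv_id": f"sv{k:03d}", "chrom": chrom, "pos": pos, "type": sv_type,
             "length": length}
        )

    g = by_id[hom_target_gene]
    hom_record(g.chrom_id, g.start + 100, "DEL", 600)  # hemizygosity negative
    for _ in range(cfg.n_hom_svs - 1):
        chrom, lo, hi = gaps[order[gi]]
        gi += 1
        pos = int(rng.integers(lo, hi - 500))
        hom_record(chrom, pos, "DEL", int(rng.integers(100, 2000)))

    return calls, truth_het, truth_hom, target_genes, promoter_genes, hom_target_gene


def make_allele_counts(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel],
    preferred_effect: Sequence[str],
    rng: np.random.Generator,
    n_snps: int = 5,
    mean_depth: float = 60.0,
    dispersion: float = 10.0,
):
    """Overdispersed allele counts with planted imbalance for effect genes.

    Per-SNP depth is negative binomial (mean ``mean_depth``, size
    ``dispersion``); hap1 counts are binomial with success probability
    fold/(1+fold) for effect genes (direction random) and 0.5 otherwise.
    Effect genes are drawn preferring ``preferred_effect`` (genes with
    promoter SVs / hemizygosity) so that ASE colocalises with SVs.
    """
    gene_ids = [g.gene_id for g in genes]
    preferred = [g for g in preferred_effect if g in set(gene_ids)]
    n_eff = min(cfg.ase_effect_genes, len(gene_ids))
    effect = list(preferred[:n_eff])
    others = [g for g in gene_ids if g not in set(effect)]
    extra = n_eff - len(effect)
    if extra > 0:
        effect += [others[i] for i in rng.choice(len(others), extra, replace=False)]
    effect_set = set(effect)
    p_nb = dispersion / (dispersion + mean_depth)
    rows = []
    truth: dict[str, float] = {}
    for gid in gene_ids:
        if gid in effect_set:
            p_hi = cfg.ase_fold / (1.0 + cfg.ase_fold)
            p1 = p_hi if rng.random() < 0.5 else 1.0 - p_hi
        else:
            p1 = 0.5
        depth_total = 0
        for s in range(n_snps):
            depth = int(rng.negative_binomial(dispersion, p_nb))
            h1 = int(rng.binomial(depth, p1)) if depth > 0 else 0
            rows.append(
                {"gene_id": gid, "snp_id": f"{gid}_snp{s + 1}", "hap1": h1,
                 "hap2": depth - h1}
            )
            depth_total += depth
        if gid in effect_set and depth_total > 0:
            truth[gid] = cfg.ase_fold
    return pd.DataFrame(rows), truth


def _build_sequences(cfg: SyntheticConfig, lay: dict, rng: np.random.Generator, truth: TruthSet):
    sequences = []
    tel_unit = TELOMERE_UNIT
    tel_len = lay["tel_len"]
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        L = cfg.chrom_len
        seq = list(_random_dna(rng, L))
        # 5' terminus carries the reverse-complement unit, 3' the forward unit
        five = revcomp(tel_unit) * cfg.telomere_copies
        three = tel_unit * cfg.telomere_copies
        seq[500 : 500 + tel_len] = five
        seq[L - 500 - tel_len : L - 500] = three
        truth.telomeres.append(
            {"chrom": chrom, "terminus": "5prime", "start": 500, "end": 500 + tel_len}
        )
        truth.telomeres.append(
            {"chrom": chrom, "terminus": "3prime", "start": L - 500 - tel_len, "end": L - 500}
        )
        cen_start, cen_end = lay["cen"]
        array = "".join(
            _mutate(rng, CENTROMERE_MONOMER, cfg.monomer_divergence, "ACGT")
            for _ in range(cfg.centromere_copies)
        )
        seq[cen_start : cen_start + len(array)] = array
        truth.centromeres.append(
            {"chrom": chrom, "start": cen_start, "end": cen_start + len(array),
             "copies": cfg.centromere_copies}
        )
        sequences.append(GenomeSequence(chrom, "".join(seq)))
    return sequences


def make_genome(cfg: SyntheticConfig, out_dir: str | Path) -> Fixture:
    """Generate the full fixture (files + truth sidecar) under ``out_dir``.

    A fixed seed yields byte-identical files.  Raises CapacityError
    before writing anything if the requested features cannot fit.
    """
    lay = _layout(cfg)
    out_dir = Path(out_dir)
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet(config=asdict(cfg))

    sequences = _build_sequences(cfg, lay, rng, truth)
    genes, r_ids, nonr_ids = _place_genes(cfg, lay, rng)
    cat_map, r_proteins, fam_a, fam_b = _assign_r_architecture(cfg, r_ids, rng)
    truth.rgene_categories = dict(sorted(cat_map.items()))
    proteins = {g.gene_id: r_proteins.get(g.gene_id) or _random_protein(rng) for g in genes}
    domain_hits = _domain_hits_for(cat_map, rng)
    # a couple of LRR-only decoys among non-R genes (classified as none)
    for gid in nonr_ids[:2]:
        domain_hits.append(DomainHit(gid, "LRR", 1e-12, 1, 60))

    tes, intact_ltrs = _plant_tes(cfg, lay, genes, r_ids, rng)

    (sv_calls, truth_het, truth_hom, hemi_genes, promoter_genes, hom_gene) = make_sv_overlay(
        cfg, genes, r_ids, nonr_ids, rng
    )
    truth.het_svs = truth_het
    truth.hom_svs = truth_hom
    truth.hemizygous_genes = sorted(hemi_genes)
    truth.hemizygous_negative_genes = [hom_gene]
    truth.promoter_sv_genes = sorted(promoter_genes)

    counts, ase_truth = make_allele_counts(
        cfg, genes, sorted(set(promoter_genes) | set(hemi_genes)), rng
    )
    truth.ase_genes = dict(sorted(ase_truth.items()))

    by_id = {g.gene_id: g for g in genes}
    for fam, name, spec in ((fam_a, "clusterA", "A-specific"), (fam_b, "clusterB", "shared")):
        if fam:
            members = sorted(fam, key=lambda gid: by_id[gid].start)
            truth.clusters.append(
                {
                    "name": name,
                    "chrom": by_id[members[0]].chrom_id,
                    "members": members,
                    "span": [by_id[members[0]].start, by_id[members[-1]].end],
                    "specificity": spec,
                }
            )

    # assembly B: same gene plan; the A-specific family's homology erased
    genes_b = [
        GeneModel(f"B_{g.gene_id}", g.chrom_id, g.start, g.end, g.strand,
                  list(g.coding_intervals))
        for g in genes
    ]
    proteins_b = {}
    for g in genes:
        if g.gene_id in set(fam_a):
            proteins_b[f"B_{g.gene_id}"] = _random_protein(rng)
        else:
            proteins_b[f"B_{g.gene_id}"] = proteins[g.gene_id]
    domain_hits_b = [
        DomainHit(f"B_{h.gene_id}", h.domain, h.evalue, h.qstart, h.qend)
        for h in domain_hits
    ]
    ortholog_map = {g.gene_id: f"B_{g.gene_id}" for g in genes}

    fixture = Fixture(
        out_dir=out_dir,
        sequences=sequences,
        genes=genes,
        proteins=proteins,
        domain_hits=domain_hits,
        tes=tes,
        intact_ltrs=intact_ltrs,
        sv_calls=sv_calls,
        allele_counts=counts,
        genes_b=genes_b,
        proteins_b=proteins_b,
        domain_hits_b=domain_hits_b,
        ortholog_map=ortholog_map,
        truth=truth,
    )
    _write_fixture(fixture)
    return fixture


def _write_fixture(fx: Fixture) -> None:
    fx.out_dir.mkdir(parents=True, exist_ok=True)
    core_io.write_fasta(fx.sequences, fx.path("genome.fa"))
    core_io.write_gff_genes(fx.genes, fx.path("genes.gff3"))
    core_io.write_protein_fasta(fx.proteins, fx.path("proteins.faa"))
    core_io.write_domain_hits(fx.domain_hits, fx.path("domains.tsv"))
    core_io.write_te_gff(fx.tes, fx.path("tes.gff3"))
    core_io.write_intact_ltrs(fx.intact_ltrs, fx.path("intact_ltrs.tsv"))
    contigs = fx.chrom_lengths
    for hap, calls in fx.sv_calls.items():
        core_io.write_sv_vcf(calls, fx.path(f"{hap}.vcf"), contigs)
    core_io.write_allele_counts(fx.allele_counts, fx.path("allele_counts.tsv"))
    core_io.write_gff_genes(fx.genes_b, fx.path("assemblyB_genes.gff3"))
    core_io.write_protein_fasta(fx.proteins_b, fx.path("assemblyB_proteins.faa"))
    core_io.write_domain_hits(fx.domain_hits_b, fx.path("assemblyB_domains.tsv"))
    with open(fx.path("ortholog_map.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(fx.ortholog_map.items()):
            fh.write(f"{a}\t{b}\n")
    fx.truth.to_json(fx.path("truth.json"))


def fixture_digest(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every emitted fixture file (determinism contract)."""
    out_dir = Path(out_dir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.iterdir())
        if p.is_file()
    }
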