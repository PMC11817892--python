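"""TE coverage around R genes versus a resampled non-R-gene background.

The window around each gene is [start - flank, end + flank), clipped to
the chromosome; "TE proportion" is the bp-coverage fraction of the
window by the union of overlapping TE intervals (any partial overlap
contributes its overlapping bp).  Enrichment is a two-sided Welch t-test
of per-gene R fractions against pooled per-gene background fractions,
with delete-one jackknife over R genes reported as a stability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from scipy import stats

from .core_io import GeneModel, TEFeature, TE_CLASSES, merge_intervals


@dataclass
class WindowProfile:
    gene_id: str
    window: tuple[int, int]
    te_fraction_total: float
    te_fraction_by_class: dict[str, float]
    intact_ltr_fraction: float


@dataclass
class EnrichmentResult:
    te_class: str  # a TE class or "total" / "intact"
    r_mean: float
    bg_mean: float
    background_means: list[float]  # per-replicate mean fractions
    p_value: float
    jackknife_stable: bool
    degenerate: bool = False
    jackknife_alpha: float = 0.05


def _clipped_window(gene: GeneModel, flank: int, chrom_len: Optional[int]) -> tuple[int, int]:
    lo = max(0, gene.start - flank)
    hi = gene.end + flank
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return lo, hi


def window_te_fraction(
    gene: GeneModel,
    tes: Sequence[TEFeature],
    flank: int = 50_000,
    chrom_len: Optional[int] = None,
) -> WindowProfile:
    """Coverage fraction of the gene's flanking window by TEs, per class and total."""
    lo, hi = _clipped_window(gene, flank, chrom_len)
    if hi <= lo:
        raise ValueError(f"gene {gene.gene_id}: empty window after clipping")
    span = hi - lo
    overlaps: dict[str, list[tuple[int, int]]] = {}
    all_ivs: list[tuple[int, int]] = []
    intact_ivs: list[tuple[int, int]] = []
    for te in tes:
        if te.chrom_id != gene.chrom_id or te.end <= lo or te.start >= hi:
            continue
        iv = (max(te.start, lo), min(te.end, hi))
        all_ivs.append(iv)
        overlaps.setdefault(te.te_class, []).append(iv)
        if te.intact:
            intact_ivs.append(iv)
    total = sum(e - s for s, e in merge_intervals(all_ivs)) / span
    by_class = {
        cls: sum(e - s for s, e in merge_intervals(ivs)) / span
        for cls, ivs in overlaps.items()
    }
    intact = sum(e - s for s, e in merge_intervals(intact_ivs)) / span
    return WindowProfile(gene.gene_id, (lo, hi), total, by_class, intact)


def profile_genes(
    genes: Sequence[GeneModel],
    tes: Sequence[TEFeature],
    flank: int = 50_000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[WindowProfile]:
    by_chrom: dict[str, list[TEFeature]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom_id, []).append(te)
    return [
        window_te_fraction(
            g,
            by_chrom.get(g.chrom_id, []),
            flank,
            chrom_lengths.get(g.chrom_id) if chrom_lengths else None,
        )
        for g in genes
    ]


@dataclass
class BackgroundResample:
    """Per-replicate background gene samples and their window profiles."""

    replicate_means: list[dict[str, float]]  # per replicate: class/total -> mean
    profiles: list[WindowProfile] = field(default_factory=list)  # pooled over replicates


def background_resample(
    all_genes: Sequence[GeneModel],
    r_gene_ids: set[str],
    tes: Sequence[TEFeature],
    n_reps: int = 100,
    seed: int = 0,
    flank: int = 50_000,
    chrom_lengths: Optional[dict[str, int]] = None,
    sample_size: Optional[int] = None,
) -> BackgroundResample:
    """Resample |R| non-R genes ``n_reps`` times and profile their windows.

    ``sample_size`` overrides the default equal-count sampling (e.g. a
    fixed fraction of all genes, as some genome-background conventions use).
    """
    non_r = [g for g in all_genes if g.gene_id not in r_gene_ids]
    n = sample_size if sample_size is not None else len(r_gene_ids)
    if len(non_r) < n:
        raise ValueError(
            f"too few non-R genes to resample: need {n}, have {len(non_r)}"
        )
    rng = np.random.default_rng(seed)
    # profile each distinct gene once; replicates index into the cache
    cache: dict[str, WindowProfile] = {
        p.gene_id: p
        for p in profile_genes(non_r, tes, flank, chrom_lengths)
    }
    replicate_means = []
    pooled: list[WindowProfile] = []
    for _ in range(n_reps):
        sample = rng.choice(len(non_r), size=n, replace=False)
        profs = [cache[non_r[i].gene_id] for i in sample]
        pooled.extend(profs)
        means = {"total": float(np.mean([p.te_fraction_total for p in profs])),
                 "intact": float(np.mean([p.intact_ltr_fraction for p in profs]))}
        for cls in TE_CLASSES:
            means[cls] = float(
                np.mean([p.te_fraction_by_class.get(cls, 0.0) for p in profs])
            )
        replicate_means.append(means)
    return BackgroundResample(replicate_means, pooled)


def _fraction(profile: WindowProfile, key: str) -> float:
    if key == "total":
        return profile.te_fraction_total
    if key == "intact":
        return profile.intact_ltr_fraction
    return profile.te_fraction_by_class.get(key, 0.0)


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Two-sided Welch t-test p-value; degenerate (both zero-variance) -> p=1."""
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0, True
    t = stats.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):
        return 1.0, True
    return p, False


def enrichment_test(
    r_profiles: Sequence[WindowProfile],
    background: BackgroundResample,
    alpha: float = 0.05,
    classes: Sequence[str] = ("total",) + TE_CLASSES,
) -> list[EnrichmentResult]:
    """Per-class Welch t-test of R-gene window fractions vs pooled background.

    ``jackknife_stable`` is True when the full test is significant at
    ``alpha`` and every delete-one (over R genes) re-test stays below it.
    """
    if len(r_profiles) < 3:
        raise ValueError("need at least 3 R genes for the enrichment test")
    results = []
    for cls in classes:
        r = np.array([_fraction(p, cls) for p in r_profiles])
        bg = np.array([_fraction(p, cls) for p in background.profiles])
        p_full, degenerate = _welch_p(r, bg)
        stable = False
        if not degenerate and p_full < alpha:
            stable = all(
                _welch_p(np.delete(r, i), bg)[0] < alpha for i in range(len(r))
            )
        results.append(
            EnrichmentResult(
                te_class=cls,
                r_mean=float(r.mean()),
                bg_mean=float(bg.mean()) if len(bg) else 0.0,
                background_means=[m.get(cls, 0.0) for m in background.replicate_means],
                p_value=p_full,
                jackknife_stable=stable,
                degenerate=degenerate,
                jackknife_alpha=alpha,
            )
        )
    return results


def intact_ltr_windows(
    r_profiles: Sequence[WindowProfile],
    background: BackgroundResample,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Enrichment of intact-LTR coverage near R genes (same test machinery)."""
    return enrichment_test(r_profiles, background, alpha, classes=("intact",))[0]


def ltr_pair_identity(ltr5_seq: str, ltr3_seq: str) -> float:
    """Global-alignment percent identity between the two LTRs of one element.

    Higher identity means a more recent insertion (the LTRs were
    identical at integration and diverge with time).
    """
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("both LTR sequences must be non-empty")
    a, b = ltr5_seq.upper(), ltr3_seq.upper()
    res = edlib.align(a, b, mode="NW", task="path")
    cols = sum(int(n) for n, _ in _cigar_ops(res["cigar"]))
    return 100.0 * (cols - res["editDistance"]) / cols


def _cigar_ops(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield num, c
            num = ""
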