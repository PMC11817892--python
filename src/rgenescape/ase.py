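"""Allele-specific expression calling from allele counts at heterozygous SNPs.

Per gene, the allelic imbalance level is the mean of per-SNP read counts
for each haplotype.  Significance comes from an exact two-sided binomial
test of summed haplotype-1 counts against a balanced null (p = 0.5),
corrected across genes by Benjamini-Hochberg.  A gene is called ASE when
fold change (larger over smaller mean) >= 2 and FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneAlleleSummary:
    gene_id: str
    n_snps: int
    mean_hap1: float
    mean_hap2: float
    sum_hap1: int
    sum_hap2: int


@dataclass
class ASEResult:
    gene_id: str
    mean_hap1: float
    mean_hap2: float
    fold_change: float  # larger mean over smaller mean; >= 1
    p_raw: float
    fdr: float
    called: bool


def summarize_alleles(
    table: pd.DataFrame,
    min_snps: int = 1,
    min_depth: int = 10,
) -> tuple[list[GeneAlleleSummary], dict[str, str]]:
    """Per-gene mean allele counts, with exclusion reasons.

    A gene is excluded when it has fewer than ``min_snps`` SNP rows or
    its total depth (hap1 + hap2 summed over SNPs) is below ``min_depth``.
    Returns (summaries, {gene_id: reason} for excluded genes).
    """
    summaries: list[GeneAlleleSummary] = []
    excluded: dict[str, str] = {}
    for gene_id, rows in table.groupby("gene_id", sort=True):
        n = len(rows)
        s1, s2 = int(rows["hap1"].sum()), int(rows["hap2"].sum())
        if n < min_snps:
            excluded[str(gene_id)] = "too_few_snps"
            continue
        if s1 + s2 < min_depth:
            excluded[str(gene_id)] = "low_depth"
            continue
        summaries.append(
            GeneAlleleSummary(
                str(gene_id), n, float(rows["hap1"].mean()), float(rows["hap2"].mean()), s1, s2
            )
        )
    return summaries, excluded


def call_ase(
    summaries: list[GeneAlleleSummary],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> list[ASEResult]:
    """Call ASE genes by the fold-change + FDR rule.

    Genes with zero total count are untestable and dropped.
    """
    testable = [s for s in summaries if s.sum_hap1 + s.sum_hap2 > 0]
    if not testable:
        raise ValueError("no testable genes (all zero total count)")
    p_raw = np.array(
        [
            stats.binomtest(s.sum_hap1, s.sum_hap1 + s.sum_hap2, 0.5).pvalue
            for s in testable
        ]
    )
    fdr = multipletests(p_raw, method="fdr_bh")[1]
    results = []
    for s, p, q in zip(testable, p_raw, fdr):
        lo, hi = sorted((s.mean_hap1, s.mean_hap2))
        fold = np.inf if lo == 0 else hi / lo
        called = bool(fold >= fc_threshold and q < fdr_threshold)
        results.append(
            ASEResult(s.gene_id, s.mean_hap1, s.mean_hap2, float(fold), float(p), float(q), called)
        )
    return results


def ase_table(results: list[ASEResult], excluded: Optional[dict[str, str]] = None) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "mean_hap1": r.mean_hap1,
            "mean_hap2": r.mean_hap2,
            "fold_change": r.fold_change,
            "p_raw": r.p_raw,
            "fdr": r.fdr,
            "called": r.called,
            "reason": "tested",
        }
        for r in results
    ]
    for gid, reason in (excluded or {}).items():
        rows.append(
            {
                "gene_id": gid,
                "mean_hap1": np.nan,
                "mean_hap2": np.nan,
                "fold_change": np.nan,
                "p_raw": np.nan,
                "fdr": np.nan,
                "called": False,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
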