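"""SV merging/zygosity, hemizygous-gene calling, promoter SVs, density correlation."""

import numpy as np
import pytest
from scipy import stats

from rgenescape.core_io import GeneModel, SVRecord
from rgenescape.sv import (
    GenotypedSV,
    call_hemizygous,
    merge_svs,
    promoter_interval,
    promoter_sv_genes,
    sv_ase_density_correlation,
)


def _sv(sv_id, pos, sv_type="DEL", length=500, hap="hap1", chrom="c1"):
    return SVRecord(sv_id, chrom, pos, sv_type, length, hap)


def _merge_oracle(calls, pos_tol, len_tol):
    """Exhaustive-pairing oracle: connected components of pairwise compatibility."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if (
                a.chrom_id == b.chrom_id
                and a.sv_type == b.sv_type
                and abs(a.pos - b.pos) <= pos_tol
                and abs(a.length - b.length) <= len_tol * max(a.length, b.length)
            ):
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def test_identical_sv_both_haplotypes_homozygous():
    merged = merge_svs({"hap1": [_sv("a", 1000)], "hap2": [_sv("b", 1000, hap="hap2")]})
    assert len(merged) == 1
    assert merged[0].zygosity == "homozygous"
    assert merged[0].supporting_haplotypes == {"hap1", "hap2"}


def test_single_haplotype_sv_heterozygous():
    merged = merge_svs({"hap1": [_sv("a", 1000)], "hap2": []})
    assert len(merged) == 1
    assert merged[0].zygosity == "heterozygous"


def test_nearby_similar_svs_merge():
    # 500 bp apart, lengths within 10%, tolerance 1 kb -> one SV
    merged = merge_svs(
        {"hap1": [_sv("a", 1000, length=1000)],
         "hap2": [_sv("b", 1500, length=950, hap="hap2")]},
        pos_tolerance=1000, len_tolerance=0.10,
    )
    assert len(merged) == 1
    assert merged[0].zygosity == "homozygous"


def test_different_types_never_merge():
    merged = merge_svs(
        {"hap1": [_sv("a", 1000, "DEL")], "hap2": [_sv("b", 1000, "INS", hap="hap2")]}
    )
    assert len(merged) == 2
    assert all(m.zygosity == "heterozygous" for m in merged)


def test_min_support_filter_drops_singletons():
    merged = merge_svs(
        {"hap1": [_sv("a", 1000), _sv("c", 50_000)],
         "hap2": [_sv("b", 1000, hap="hap2")]},
        min_support=2,
    )
    assert len(merged) == 1
    assert merged[0].zygosity == "homozygous"


def test_merge_agrees_with_exhaustive_pairing_oracle():
    rng = np.random.default_rng(0)
    for trial in range(15):
        calls = {"hap1": [], "hap2": []}
        flat = []
        for i in range(int(rng.integers(4, 25))):
            hap = "hap1" if rng.random() < 0.5 else "hap2"
            sv = _sv(
                f"s{i}",
                int(rng.integers(0, 30_000)),
                "DEL" if rng.random() < 0.7 else "INS",
                int(rng.integers(50, 2000)),
                hap,
            )
            calls[hap].append(sv)
            flat.append(sv)
        merged = merge_svs(calls, pos_tolerance=1000, len_tolerance=0.25)
        oracle = _merge_oracle(flat, 1000, 0.25)
        assert len(merged) == len(oracle)


def test_merge_idempotent():
    """Re-merging the merged output changes nothing."""
    rng = np.random.default_rng(3)
    calls = {"hap1": [], "hap2": []}
    for i in range(20):
        hap = "hap1" if rng.random() < 0.5 else "hap2"
        calls[hap].append(_sv(f"s{i}", int(rng.integers(0, 20_000)), hap=hap))
    merged = merge_svs(calls)
    again = merge_svs(
        {
            "hap1": [SVRecord(m.merged_id, m.chrom_id, m.pos, m.sv_type, m.length, "hap1")
                     for m in merged],
            "hap2": [],
        }
    )
    assert len(again) == len(merged)
    assert [(m.pos, m.sv_type, m.length) for m in again] == [
        (m.pos, m.sv_type, m.length) for m in merged
    ]


def _gene(gid, start=10_000, strand="+", cds=None, chrom="c1"):
    cds = cds if cds is not None else [(start, start + 1000)]
    return GeneModel(gid, chrom, start, start + 3000, strand, cds)


def _het(pos, length, sv_type="DEL", chrom="c1", sv_id="m1"):
    return GenotypedSV(sv_id, chrom, pos, sv_type, length, frozenset({"hap1"}), "heterozygous")


def test_hemizygous_called_above_threshold():
    g = _gene("g1")  # coding 1000 bp at [10000, 11000)
    calls = call_hemizygous([_het(10_000, 200)], [g])
    assert len(calls) == 1
    assert calls[0].coding_overlap_fraction == pytest.approx(0.20)


def test_exactly_ten_percent_not_called():
    g = _gene("g1")
    calls = call_hemizygous([_het(10_000, 100)], [g])  # exactly 0.10
    assert calls == []


def test_homozygous_sv_rejected_by_precondition():
    hom = GenotypedSV("m1", "c1", 10_000, "DEL", 500, frozenset({"hap1", "hap2"}),
                      "homozygous")
    with pytest.raises(ValueError, match="not heterozygous"):
        call_hemizygous([hom], [_gene("g1")])


def test_insertion_cannot_trigger_hemizygosity():
    # an insertion's reference footprint is 1 bp, below any >10% threshold
    g = _gene("g1")
    assert call_hemizygous([_het(10_500, 5000, "INS")], [g]) == []


def test_zero_coding_gene_skipped_with_warning():
    g = GeneModel("g1", "c1", 10_000, 13_000, "+", [])
    with pytest.warns(UserWarning, match="zero coding"):
        assert call_hemizygous([_het(10_000, 600)], [g]) == []


def test_hemizygosity_invariant_to_cds_fragmentation():
    """Splitting a CDS into abutting pieces changes nothing (bitmap oracle)."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        start = 10_000
        whole = _gene("g1", start, cds=[(start, start + 2000)])
        cut1, cut2 = sorted(rng.integers(start + 1, start + 1999, 2))
        frag = _gene(
            "g1", start,
            cds=[(start, int(cut1)), (int(cut1), int(cut2)), (int(cut2), start + 2000)],
        )
        svs = [
            _het(int(rng.integers(start - 500, start + 1900)), int(rng.integers(50, 800)),
                 sv_id=f"m{k}")
            for k in range(3)
        ]
        a = call_hemizygous(svs, [whole])
        b = call_hemizygous(svs, [frag])
        assert [(c.gene_id, c.coding_overlap_bp) for c in a] == [
            (c.gene_id, c.coding_overlap_bp) for c in b
        ]
        # bp-bitmap oracle for the overlap
        bitmap = np.zeros(5000, dtype=bool)
        for sv in svs:
            s, e = sv.span
            bitmap[max(0, s - start) : max(0, e - start)] = True
        coding_mask = np.zeros(5000, dtype=bool)
        coding_mask[0:2000] = True
        expected = int((bitmap & coding_mask).sum())
        if a:
            assert a[0].coding_overlap_bp == expected


def test_promoter_strand_aware():
    plus = _gene("gp", 10_000, "+")
    minus = _gene("gm", 10_000, "-")
    assert promoter_interval(plus) == (8_000, 10_000)
    assert promoter_interval(minus) == (13_000, 15_000)
    # + gene: DEL 1.5 kb upstream in; 3 kb upstream out
    assert promoter_sv_genes([plus], [_het(8_500, 300)]) == {"gp"}
    assert promoter_sv_genes([plus], [_het(6_800, 150)]) == set()
    # - gene: DEL 1.5 kb beyond the reference end is in its promoter
    assert promoter_sv_genes([minus], [_het(14_500, 200)]) == {"gm"}


def test_promoter_clipped_at_zero():
    g = GeneModel("g1", "c1", 500, 3500, "+", [(500, 1500)])
    assert promoter_interval(g) == (0, 500)


def _density_setup(sv_positions, ase_positions, chrom_len=20_000_000):
    het = [
        GenotypedSV(f"m{i}", "c1", p, "DEL", 100, frozenset({"hap1"}), "heterozygous")
        for i, p in enumerate(sv_positions)
    ]
    genes = [
        GeneModel(f"a{i}", "c1", p, p + 1000, "+", [(p, p + 1000)])
        for i, p in enumerate(ase_positions)
    ]
    return het, genes, {"c1": chrom_len}


def test_identical_density_vectors_rho_one():
    positions = [i * 1_000_000 + 500 for i in range(15)] * 3
    extra = [i * 1_000_000 + 600 for i in range(5)]  # gradient
    het, genes, lens = _density_setup(positions + extra, positions + extra)
    rho, p = sv_ase_density_correlation(het, genes, lens)
    assert rho == pytest.approx(1.0)


def test_null_poisson_densities_calibrated():
    """Independent Poisson count vectors: mean rho ~ 0, rejection ~ alpha."""
    rng = np.random.default_rng(9)
    n_sims, n_bins, alpha = 1000, 30, 0.05
    rhos, rejections = [], 0
    for _ in range(n_sims):
        a = rng.poisson(3, n_bins)
        b = rng.poisson(3, n_bins)
        if a.std() == 0 or b.std() == 0:
            continue
        rho, p = stats.spearmanr(a, b)
        rhos.append(rho)
        rejections += p < alpha
    assert abs(np.mean(rhos)) < 0.02
    se = np.sqrt(alpha * (1 - alpha) / n_sims)
    assert abs(rejections / n_sims - alpha) < 2.5 * se + 0.01


def test_planted_linear_coupling_detected():
    rng = np.random.default_rng(10)
    sv_pos, ase_pos = [], []
    for b in range(20):
        lam = 1 + b  # increasing density across bins couples the two series
        base = b * 1_000_000
        sv_pos += [base + int(x) for x in rng.integers(0, 900_000, rng.poisson(lam))]
        ase_pos += [base + int(x) for x in rng.integers(0, 900_000, rng.poisson(lam))]
    het, genes, lens = _density_setup(sv_pos, ase_pos)
    rho, p = sv_ase_density_correlation(het, genes, lens)
    assert rho > 0
    assert p < 0.01


def test_correlation_requires_enough_bins():
    het, genes, lens = _density_setup([100], [200], chrom_len=2_000_000)
    with pytest.raises(ValueError, match="non-empty bins"):
        sv_ase_density_correlation(het, genes, lens)


def test_default_fixture_hemizygous_recovery(default_fixture, pipeline_run):
    """All planted hemizygous genes called; no homozygous-SV false calls."""
    import pandas as pd

    cfg, _ = pipeline_run
    df = pd.read_csv(f"{cfg.out_dir}/hemizygous_genes.tsv", sep="\t")
    called = set(df["gene_id"])
    truth = default_fixture.truth
    assert called == set(truth.hemizygous_genes)
    assert not called & set(truth.hemizygous_negative_genes)


def test_default_fixture_every_hemizygous_sv_is_heterozygous(default_fixture):
    from rgenescape import core_io
    from rgenescape.sv import merge_svs as ms

    r1 = core_io.read_sv_vcf(default_fixture.path("hap1.vcf"), "hap1")
    r2 = core_io.read_sv_vcf(default_fixture.path("hap2.vcf"), "hap2")
    merged = ms({"hap1": r1.records, "hap2": r2.records})
    het = [m for m in merged if m.zygosity == "heterozygous"]
    calls = call_hemizygous(het, default_fixture.genes)
    het_ids = {m.merged_id for m in het}
    for c in calls:
        assert set(c.sv_ids) <= het_ids
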