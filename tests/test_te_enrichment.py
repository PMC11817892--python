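"""TE window coverage, resampled background, enrichment test, LTR identity."""

import numpy as np
import pytest
from scipy import stats

from rgenescape.core_io import GeneModel, TEFeature
from rgenescape.te_enrichment import (
    BackgroundResample,
    WindowProfile,
    background_resample,
    enrichment_test,
    intact_ltr_windows,
    ltr_pair_identity,
    profile_genes,
    window_te_fraction,
)


def _gene(gid, start, end, chrom="c1"):
    return GeneModel(gid, chrom, start, end, "+", [(start, end)])


def test_window_fully_covered():
    g = _gene("g1", 60_000, 62_000)
    tes = [TEFeature("c1", 0, 200_000, "LINE")]
    p = window_te_fraction(g, tes)
    assert p.te_fraction_total == pytest.approx(1.0)


def test_no_tes_zero_fraction():
    p = window_te_fraction(_gene("g1", 60_000, 62_000), [])
    assert p.te_fraction_total == 0.0
    assert p.intact_ltr_fraction == 0.0


def test_overlapping_tes_counted_once():
    # two 30-kb TEs overlapping by 10 kb inside a 100-kb window -> union 50 kb
    g = _gene("g1", 49_000, 51_000)
    lo, hi = 0, 102_000  # window [start-50k, end+50k) clipped at 0 is [0, 101000)
    tes = [
        TEFeature("c1", 10_000, 40_000, "LINE"),
        TEFeature("c1", 30_000, 60_000, "LINE"),
    ]
    p = window_te_fraction(g, tes, chrom_len=1_000_000)
    span = p.window[1] - p.window[0]
    assert p.te_fraction_total == pytest.approx(50_000 / span)


def test_partial_overlap_counts_overlapping_bp():
    g = _gene("g1", 60_000, 61_000)
    # TE hangs off the left window edge: only in-window bp count
    tes = [TEFeature("c1", 0, 20_000, "LINE")]
    p = window_te_fraction(g, tes)
    span = p.window[1] - p.window[0]
    assert p.te_fraction_total == pytest.approx(10_000 / span)


def test_window_clipped_at_chromosome_ends():
    g = _gene("g1", 1_000, 2_000)
    p = window_te_fraction(g, [], chrom_len=30_000)
    assert p.window == (0, 30_000)
    assert 0.0 <= p.te_fraction_total <= 1.0


def test_union_matches_bitmap_oracle():
    """Interval-union coverage equals a per-bp bitmap on small instances."""
    rng = np.random.default_rng(0)
    chrom_len = 200_000
    for trial in range(20):
        g = _gene("g1", 90_000, 95_000)
        tes = []
        for _ in range(rng.integers(1, 30)):
            s = int(rng.integers(0, chrom_len - 5000))
            e = s + int(rng.integers(100, 5000))
            tes.append(TEFeature("c1", s, min(e, chrom_len), "LINE", intact=bool(rng.random() < 0.3)))
        p = window_te_fraction(g, tes, flank=50_000, chrom_len=chrom_len)
        lo, hi = p.window
        bitmap = np.zeros(hi - lo, dtype=bool)
        intact_bitmap = np.zeros(hi - lo, dtype=bool)
        for te in tes:
            s, e = max(te.start, lo), min(te.end, hi)
            if e > s:
                bitmap[s - lo : e - lo] = True
                if te.intact:
                    intact_bitmap[s - lo : e - lo] = True
        assert p.te_fraction_total == pytest.approx(bitmap.mean())
        assert p.intact_ltr_fraction == pytest.approx(intact_bitmap.mean())
        # subset property: intact coverage never exceeds total
        assert p.intact_ltr_fraction <= p.te_fraction_total + 1e-12


def test_monotonicity_adding_te_never_decreases_fraction():
    rng = np.random.default_rng(1)
    g = _gene("g1", 60_000, 63_000)
    tes = []
    prev = 0.0
    for _ in range(15):
        s = int(rng.integers(0, 150_000))
        tes.append(TEFeature("c1", s, s + int(rng.integers(200, 3000)), "LINE"))
        frac = window_te_fraction(g, tes).te_fraction_total
        assert frac >= prev - 1e-12
        prev = frac


def _uniform_genes(n, chrom_len=2_000_000, spacing=15_000):
    return [_gene(f"g{i}", 100_000 + i * spacing, 100_000 + i * spacing + 2_000)
            for i in range(n)]


def test_background_identical_fractions_constant_means():
    genes = _uniform_genes(30)
    tes = [TEFeature("c1", 0, 2_000_000, "LINE")]  # everything fully covered
    bg = background_resample(genes, {"g0", "g1", "g2"}, tes, n_reps=10, seed=0)
    for rep in bg.replicate_means:
        assert rep["total"] == pytest.approx(1.0)


def test_background_seed_reproducible():
    genes = _uniform_genes(40)
    rng = np.random.default_rng(5)
    tes = []
    for _ in range(100):
        s = int(rng.integers(0, 1_900_000))
        tes.append(TEFeature("c1", s, s + 2_000, "LINE"))
    r_ids = {"g0", "g1", "g2", "g3", "g4"}
    a = background_resample(genes, r_ids, tes, n_reps=20, seed=42)
    b = background_resample(genes, r_ids, tes, n_reps=20, seed=42)
    assert a.replicate_means == b.replicate_means
    c = background_resample(genes, r_ids, tes, n_reps=20, seed=43)
    assert a.replicate_means != c.replicate_means


def test_background_too_few_nonr_genes():
    genes = _uniform_genes(4)
    with pytest.raises(ValueError, match="too few"):
        background_resample(genes, {"g0", "g1", "g2"}, [], n_reps=5, seed=0)


def test_replicate_mean_sd_matches_sampling_oracle():
    """SD of replicate means agrees with a direct Monte-Carlo resampling oracle."""
    rng = np.random.default_rng(7)
    genes = _uniform_genes(120)
    tes = []
    for g in genes:
        if rng.random() < 0.5:  # half the windows get one 20-kb TE
            tes.append(TEFeature("c1", g.start - 10_000, g.start + 10_000, "LINE"))
    r_ids = {f"g{i}" for i in range(20)}
    bg = background_resample(genes, r_ids, tes, n_reps=400, seed=1)
    measured_sd = np.std([m["total"] for m in bg.replicate_means])
    # oracle: resample the exact per-gene fraction population directly
    pool = np.array([
        p.te_fraction_total
        for p in profile_genes([g for g in genes if g.gene_id not in r_ids], tes)
    ])
    orng = np.random.default_rng(2)
    oracle = [
        orng.choice(pool, size=len(r_ids), replace=False).mean() for _ in range(2000)
    ]
    assert measured_sd == pytest.approx(np.std(oracle), rel=0.2)


def _profiles_from_fractions(fracs, intact=None):
    out = []
    for i, f in enumerate(fracs):
        out.append(WindowProfile(f"g{i}", (0, 100), float(f), {"LINE": float(f)},
                                 float(intact[i]) if intact is not None else 0.0))
    return out


def test_planted_enrichment_detected_and_stable():
    """Coverage 0.6 near R vs 0.2 background over 30 R genes: p<0.001, stable."""
    rng = np.random.default_rng(10)
    r = _profiles_from_fractions(rng.normal(0.6, 0.05, 30).clip(0, 1))
    bg = BackgroundResample(
        [{"total": 0.2, "LINE": 0.2, "intact": 0.0}],
        _profiles_from_fractions(rng.normal(0.2, 0.05, 300).clip(0, 1)),
    )
    res = {r_.te_class: r_ for r_ in enrichment_test(r, bg)}
    assert res["total"].p_value < 1e-3
    assert res["total"].jackknife_stable
    assert res["total"].r_mean > res["total"].bg_mean


def test_type_i_error_calibrated():
    """Null rejection rate of the Welch test ~ alpha over 1000 simulations."""
    rng = np.random.default_rng(123)
    alpha = 0.05
    n_sims = 1000
    rejections = 0
    for _ in range(n_sims):
        a = rng.beta(2, 5, size=25)
        b = rng.beta(2, 5, size=80)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rejections += p < alpha
    se = np.sqrt(alpha * (1 - alpha) / n_sims)
    assert abs(rejections / n_sims - alpha) <= 2.5 * se + 0.01


def test_degenerate_constant_fractions_p_one():
    r = _profiles_from_fractions([0.3] * 5)
    bg = BackgroundResample([{"total": 0.3}], _profiles_from_fractions([0.3] * 50))
    res = enrichment_test(r, bg, classes=("total",))[0]
    assert res.p_value == 1.0
    assert res.degenerate
    assert not res.jackknife_stable


def test_enrichment_needs_three_r_genes():
    with pytest.raises(ValueError, match="3 R genes"):
        enrichment_test(_profiles_from_fractions([0.5, 0.5]), BackgroundResample([], []))


def test_intact_ltr_enrichment_on_planted_contrast():
    rng = np.random.default_rng(20)
    r = _profiles_from_fractions(
        rng.normal(0.5, 0.05, 30).clip(0, 1), intact=rng.normal(0.2, 0.03, 30).clip(0, 1)
    )
    bg = BackgroundResample(
        [{"intact": 0.0}],
        _profiles_from_fractions(
            rng.normal(0.5, 0.05, 200).clip(0, 1), intact=np.zeros(200)
        ),
    )
    res = intact_ltr_windows(r, bg)
    assert res.te_class == "intact"
    assert res.p_value < 1e-3


def test_intact_none_anywhere_degenerate():
    r = _profiles_from_fractions([0.4] * 5, intact=[0.0] * 5)
    bg = BackgroundResample([{"intact": 0.0}], _profiles_from_fractions([0.4] * 30, intact=[0.0] * 30))
    res = intact_ltr_windows(r, bg)
    assert res.degenerate and res.p_value == 1.0


def test_ltr_identity_identical():
    assert ltr_pair_identity("ACGT" * 50, "ACGT" * 50) == pytest.approx(100.0)


def test_ltr_identity_single_substitution():
    a = "ACGT" * 25  # 100 bp
    b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
    assert ltr_pair_identity(a, b) == pytest.approx(99.0)


def test_ltr_identity_disjoint_alphabets_near_zero():
    assert ltr_pair_identity("A" * 120, "G" * 120) == pytest.approx(0.0)


def test_default_fixture_effect_recovered_within_ten_percent(default_fixture, pipeline_run):
    """Planted near-R minus background coverage difference estimated within 10%."""
    import pandas as pd

    cfg, report = pipeline_run
    df = pd.read_csv(f"{cfg.out_dir}/te_enrichment.tsv", sep="\t")
    total = df[df.te_class == "total"].iloc[0]
    syn = default_fixture.truth.config
    planted_effect = syn["te_density_near_r"] - syn["te_density_background"]
    measured_effect = total.r_mean - total.bg_mean
    assert measured_effect == pytest.approx(planted_effect, rel=0.10)
    assert total.p_value < 1e-3
    assert bool(total.jackknife_stable)
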