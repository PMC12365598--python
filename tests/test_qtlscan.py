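"""Interval mapping, permutation thresholds, gene action, segregation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binqtl import linkmap, qtlscan
from binqtl.linkmap import GeneticMap, IBDInterval
from binqtl.matrix import A, B, H, MISSING, GenotypeMatrix


# ------------------------------------------------------------- chi-square
@pytest.mark.parametrize(
    "counts,expected_chi2",
    [((85, 91), 0.20), ((80, 60), 2.86), ((88, 88), 0.0)],
)
def test_segregation_chi2_one_to_one(counts, expected_chi2):
    chi2, df, p = qtlscan.segregation_chi2(counts, (1, 1))
    assert round(chi2, 2) == expected_chi2
    assert df == 1


def test_segregation_chi2_1_2_1():
    chi2, df, p = qtlscan.segregation_chi2((25, 50, 25), (1, 2, 1))
    assert chi2 == 0.0 and df == 2


def test_segregation_chi2_rejects_bad_input():
    with pytest.raises(ValueError):
        qtlscan.segregation_chi2((0, 0), (1, 1))
    with pytest.raises(ValueError):
        qtlscan.segregation_chi2((10, 10), (1, 0))


# ------------------------------------------------------------- gene action
@pytest.mark.parametrize(
    "a,d,expected",
    [
        (-4.5, -1.2, "PD"),  # d/a = 0.27
        (1.0, 0.0, "A"),
        (1.0, 1.0, "D"),
        (1.0, 0.25, "A"),  # band edge -> lower dominance class
        (1.0, 0.75, "PD"),
        (1.0, 1.25, "D"),
        (1.0, 2.0, "OD"),
        (0.0, 1.0, "n/a"),
        (-2.5, 0.8, "PD"),  # |d/a| = 0.32
    ],
)
def test_classify_gene_action(a, d, expected):
    assert qtlscan.classify_gene_action(a, d) == expected


@settings(derandomize=True, max_examples=100)
@given(
    st.floats(min_value=-10, max_value=10).filter(lambda v: abs(v) > 1e-6),
    st.floats(min_value=-10, max_value=10),
    st.floats(min_value=0.01, max_value=100),
)
def test_gene_action_is_scale_invariant(a, d, k):
    assert qtlscan.classify_gene_action(a, d) == qtlscan.classify_gene_action(k * a, k * d)


# -------------------------------------------------- genotype probabilities
def test_probs_at_marker_are_indicators():
    left = np.array([0, 1, MISSING], dtype=np.int8)
    probs = qtlscan.qtl_genotype_probs(left, left, 0.0, 0.0, "BC")
    assert np.allclose(probs[0], [1, 0], atol=1e-8)
    assert np.allclose(probs[1], [0, 1], atol=1e-8)
    assert np.allclose(probs[2], [0.5, 0.5])  # both flanks missing -> prior


def test_probs_midpoint_with_zero_recombination_copies_flanks():
    left = np.array([0, 1], dtype=np.int8)
    probs = qtlscan.qtl_genotype_probs(left, left, 0.0, 0.0, "BC")
    assert np.allclose(probs, [[1, 0], [0, 1]], atol=1e-8)


def _brute_force_probs(gl, gr, r1, r2, design):
    """Enumerate the three-locus chain directly (independent oracle)."""
    if design == "BC":
        states = [0, 1]
        prior = {0: 0.5, 1: 0.5}
        t1 = {(i, j): (1 - r1 if i == j else r1) for i in states for j in states}
        t2 = {(i, j): (1 - r2 if i == j else r2) for i in states for j in states}
    else:
        states = [0, 1, 2]
        prior = {0: 0.25, 1: 0.5, 2: 0.25}

        def step(r):
            p = 1 - r
            m = {
                (0, 0): p * p, (0, 1): 2 * p * r, (0, 2): r * r,
                (1, 0): p * r, (1, 1): p * p + r * r, (1, 2): p * r,
                (2, 0): r * r, (2, 1): 2 * p * r, (2, 2): p * p,
            }
            return m

        t1, t2 = step(r1), step(r2)
    num = {q: prior[gl] * t1[(gl, q)] * t2[(q, gr)] for q in states}
    z = sum(num.values())
    return np.array([num[q] / z for q in states])


@pytest.mark.parametrize("design", ["BC", "F2"])
def test_probs_match_brute_force_enumeration(design):
    k = 2 if design == "BC" else 3
    r1, r2 = 0.07, 0.13
    for gl in range(k):
        for gr in range(k):
            got = qtlscan.qtl_genotype_probs(
                np.array([gl], dtype=np.int8), np.array([gr], dtype=np.int8), r1, r2, design
            )[0]
            want = _brute_force_probs(gl, gr, r1, r2, design)
            assert np.allclose(got, want, atol=1e-9), (design, gl, gr)


def test_probs_sum_to_one_under_missingness():
    rng = np.random.default_rng(2)
    left = rng.choice([0, 1, MISSING], size=50).astype(np.int8)
    right = rng.choice([0, 1, MISSING], size=50).astype(np.int8)
    probs = qtlscan.qtl_genotype_probs(left, right, 0.1, 0.2, "BC")
    assert np.allclose(probs.sum(axis=1), 1.0)


# --------------------------------------------------------------- the scan
def _toy_map(n_bins=6, n_ind=120, design="BC", seed=0, spacing_cm=10.0):
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_bins) + 1) * 1_000_000
    markers = pd.DataFrame({"name": [f"Pp01_{p}" for p in pos], "chrom": 1, "pos": pos})
    if design == "BC":
        calls = rng.integers(0, 2, size=(1, n_ind)).astype(np.int8)
        rows = [calls[0]]
        r = linkmap.kosambi_inv(spacing_cm)
        for _ in range(n_bins - 1):
            prev = rows[-1]
            flip = rng.random(n_ind) < r
            rows.append(np.where(flip, 1 - prev, prev).astype(np.int8))
        calls = np.vstack(rows)
    else:
        r = linkmap.kosambi_inv(spacing_cm)
        gam = rng.integers(0, 2, size=(2, n_ind))
        rows = []
        gams = [gam]
        for _ in range(n_bins - 1):
            prev = gams[-1]
            flip = rng.random((2, n_ind)) < r
            gams.append(np.where(flip, 1 - prev, prev))
        for g in gams:
            rows.append((g[0] + g[1]).astype(np.int8))
        calls = np.vstack(rows)
    onebin = GenotypeMatrix(markers, [f"i{k}" for k in range(n_ind)], calls)
    table = pd.DataFrame(
        {"group": 1, "name": markers["name"], "chrom": 1, "pos": pos, "cm": np.arange(n_bins) * spacing_cm}
    )
    return GeneticMap(table), onebin


def test_hk_at_marker_positions_equals_class_mean_regression():
    gmap, onebin = _toy_map(design="F2", seed=5)
    rng = np.random.default_rng(6)
    g = onebin.calls[2].astype(float)
    y = np.where(g == 1, 0.4, np.where(g == 0, 1.0, -1.0)) + rng.normal(0, 0.5, g.size)
    profile = qtlscan.scan_interval_mapping(
        gmap, onebin, y, "F2", qtlscan.ScanConfig(step_cm=10.0, seed=0)
    )
    at_marker = profile[profile["cm"] == 20.0].iloc[0]
    # explicit class-mean regression oracle
    X = np.column_stack([np.ones(g.size), (g == 0).astype(float) - (g == 2).astype(float), (g == 1).astype(float)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = resid @ resid
    rss0 = ((y - y.mean()) ** 2).sum()
    lod = (g.size / 2) * np.log10(rss0 / rss1)
    assert at_marker["lod"] == pytest.approx(lod, abs=1e-9)
    assert at_marker["a"] == pytest.approx(beta[1], abs=1e-6)
    assert at_marker["d"] == pytest.approx(beta[2], abs=1e-6)
    # and the fitted class means reproduce the footnote definitions
    mean_a = beta[0] + beta[1]
    mean_b = beta[0] - beta[1]
    mean_h = beta[0] + beta[2]
    assert (mean_a - mean_b) / 2 == pytest.approx(beta[1])
    assert mean_h - (mean_a + mean_b) / 2 == pytest.approx(beta[2])


def test_f2_additive_truth_classifies_as_additive():
    gmap, onebin = _toy_map(design="F2", n_ind=300, seed=7)
    rng = np.random.default_rng(8)
    g = onebin.calls[3].astype(float)
    y = np.where(g == 0, 1.0, np.where(g == 2, -1.0, 0.0)) + rng.normal(0, 0.7, g.size)
    profile = qtlscan.scan_interval_mapping(gmap, onebin, y, "F2", qtlscan.ScanConfig(seed=0))
    peak = profile.iloc[int(profile["lod"].idxmax())]
    assert abs(peak["d"] / peak["a"]) < 0.25
    assert qtlscan.classify_gene_action(peak["a"], peak["d"]) == "A"


def test_zero_variance_phenotype_gives_flat_profile():
    gmap, onebin = _toy_map(seed=9)
    with pytest.warns(UserWarning, match="zero-variance"):
        profile = qtlscan.scan_interval_mapping(gmap, onebin, np.ones(onebin.n_individuals), "BC")
    assert (profile["lod"] == 0).all()


def test_scan_requires_twenty_phenotyped_individuals():
    gmap, onebin = _toy_map(n_ind=30, seed=10)
    y = np.full(30, np.nan)
    y[:10] = 1.0
    with pytest.raises(ValueError, match="20"):
        qtlscan.scan_interval_mapping(gmap, onebin, y, "BC")


# ------------------------------------------------------------ permutations
def test_alpha_one_threshold_is_minimum_of_max_lods():
    gmap, onebin = _toy_map(seed=11)
    y = np.random.default_rng(12).normal(size=onebin.n_individuals)
    cfg = qtlscan.ScanConfig(n_permutations=200, alpha=1.0, seed=1)
    t_min = qtlscan.permutation_threshold(gmap, onebin, y, "BC", cfg)
    cfg2 = qtlscan.ScanConfig(n_permutations=200, alpha=0.05, seed=1)
    t_05 = qtlscan.permutation_threshold(gmap, onebin, y, "BC", cfg2)
    assert t_min <= t_05


def test_threshold_reproducible_and_stable_under_more_permutations():
    gmap, onebin = _toy_map(seed=13)
    y = np.random.default_rng(14).normal(size=onebin.n_individuals)
    cfg = qtlscan.ScanConfig(n_permutations=500, alpha=0.05, seed=7)
    t1 = qtlscan.permutation_threshold(gmap, onebin, y, "BC", cfg)
    t2 = qtlscan.permutation_threshold(gmap, onebin, y, "BC", cfg)
    assert t1 == t2
    t_double = qtlscan.permutation_threshold(
        gmap, onebin, y, "BC", qtlscan.ScanConfig(n_permutations=1000, alpha=0.05, seed=7)
    )
    assert abs(t_double - t1) < 0.5  # Monte-Carlo wobble only


def test_few_permutations_warn():
    with pytest.warns(UserWarning, match="permutations"):
        qtlscan.ScanConfig(n_permutations=50)


# ------------------------------------------------------- support intervals
def _triangle_profile():
    cm = np.arange(20.0, 41.0)
    lod = 5.0 - 0.5 * np.abs(cm - 30.0)
    return pd.DataFrame(
        {"group": 1, "cm": cm, "chrom": 1, "bp": (cm * 1e5).astype(int), "lod": lod}
    )


def test_triangular_profile_support_interval():
    prof = _triangle_profile()
    (cm_lo, cm_hi), _, flagged = qtlscan.lod_support_interval(prof)
    assert (cm_lo, cm_hi) == (28.0, 32.0)
    assert not flagged


def test_support_interval_truncated_at_ibd_boundary():
    prof = _triangle_profile()
    ibd = [IBDInterval(1, 3_050_000, 4_000_000)]  # starts just right of the peak (bp 3e6)
    _, (bp_lo, bp_hi), _ = qtlscan.lod_support_interval(prof, ibd_intervals=ibd)
    assert bp_hi == 3_050_000
    assert bp_lo == 2_800_000


def test_flat_profile_spans_group_with_flag():
    prof = _triangle_profile()
    prof["lod"] = 3.0
    (cm_lo, cm_hi), _, flagged = qtlscan.lod_support_interval(prof)
    assert flagged and cm_lo == 20.0 and cm_hi == 40.0


# ------------------------------------------------------------- major genes
def test_major_gene_maps_to_generating_bin():
    rng = np.random.default_rng(15)
    _, onebin = _toy_map(n_bins=8, n_ind=100, seed=16)
    trait = onebin.calls[4].copy()
    name, mismatch, linked = qtlscan.map_major_gene(trait, onebin)
    assert name == onebin.markers["name"].iloc[4]
    assert mismatch == 0.0 and linked


def test_major_gene_tolerates_label_noise():
    rng = np.random.default_rng(17)
    _, onebin = _toy_map(n_bins=8, n_ind=200, seed=18)
    trait = onebin.calls[4].astype(int).copy()
    flip = rng.random(trait.size) < 0.02
    trait[flip] = 1 - trait[flip]
    name, mismatch, linked = qtlscan.map_major_gene(trait, onebin)
    assert name == onebin.markers["name"].iloc[4]
    assert mismatch == pytest.approx(flip.mean(), abs=1e-9)  # exactly the injected flips


def test_random_trait_is_unlinked():
    rng = np.random.default_rng(19)
    _, onebin = _toy_map(n_bins=8, n_ind=300, seed=20)
    trait = rng.integers(0, 2, 300)
    _, mismatch, linked = qtlscan.map_major_gene(trait, onebin)
    assert mismatch > 0.3 and not linked


def test_major_gene_rejects_nonbinary_trait():
    _, onebin = _toy_map(seed=21)
    with pytest.raises(ValueError, match="two classes"):
        qtlscan.map_major_gene(np.arange(onebin.n_individuals), onebin)


# ---------------------------------------------------------------- reporting
def _qtl(map_name, lod, significant=True):
    return qtlscan.QTLResult(
        trait="MD", year=2021, map_name=map_name, group=6, position_cm=10.0,
        peak_bins=[], interval_cm=(8, 12), interval_bp=(1, 2), lod=lod,
        pct_ev=10.0, a=1.0, d=0.1, d_over_a=0.1, action="A", significant=significant,
    )


def test_report_prefers_highest_lod_among_significant_maps():
    results = {"SF": [_qtl("SF", 5.0)], "ZP": [], "SFxZP": [_qtl("SFxZP", 4.0)]}
    out = qtlscan.report_qtls(results)
    assert len(out) == 1 and out[0].map_name == "SF"
    results = {"SF": [_qtl("SF", 3.0)], "ZP": [], "SFxZP": [_qtl("SFxZP", 4.5)]}
    out = qtlscan.report_qtls(results)
    assert out[0].map_name == "SFxZP"  # combined map may carry the report when a parent is also significant


def test_combined_map_only_is_not_reported():
    results = {"SF": [], "ZP": [], "SFxZP": [_qtl("SFxZP", 6.0)]}
    assert qtlscan.report_qtls(results) == []


def test_nothing_significant_reports_nothing():
    results = {"SF": [_qtl("SF", 5.0, significant=False)], "ZP": [], "SFxZP": []}
    assert qtlscan.report_qtls(results) == []
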