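import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from intgen.config import QCThresholds
from intgen.prs import (
    PRSError,
    ancestry_adjust,
    hwe_exact_pvalue,
    ld_prune,
    project_samples,
    reference_pca,
    relatedness_prune,
    score_prs,
    variant_qc,
)

from conftest import make_gm


# --- HWE -------------------------------------------------------------------

def test_hwe_equilibrium_not_rejected():
    # 250 AA / 500 Aa / 250 aa is exactly HWE at p = 0.5
    assert hwe_exact_pvalue(500, 250, 250) > 0.5


def test_hwe_extreme_disequilibrium_rejected():
    # all heterozygotes: grossly out of equilibrium
    assert hwe_exact_pvalue(500, 0, 0) < 1e-6


def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(0, 100, 0) == 1.0


def test_hwe_exact_matches_chi2_at_large_n():
    # above the enumeration cut-off the implementation switches to chi-square
    n_het, n_hom1, n_hom2 = 4_000, 3_900, 2_100
    n = n_het + n_hom1 + n_hom2
    p = (2 * n_hom1 + n_het) / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_hom1, n_het, n_hom2])
    stat = ((observed - expected) ** 2 / expected).sum()
    assert hwe_exact_pvalue(n_het, n_hom1, n_hom2) == pytest.approx(
        float(chi2.sf(stat, 1)), rel=1e-6
    )


@settings(max_examples=50, deadline=None)
@given(
    st.integers(min_value=0, max_value=120),
    st.integers(min_value=0, max_value=120),
    st.integers(min_value=0, max_value=120),
)
def test_hwe_pvalue_is_probability(n_het, n_hom1, n_hom2):
    p = hwe_exact_pvalue(n_het, n_hom1, n_hom2)
    assert 0.0 <= p <= 1.0 + 1e-12


# --- variant QC ------------------------------------------------------------

def test_variant_qc_boundaries(rng):
    n = 400
    base = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
    gm = make_gm(base)
    gm.variants.loc[0, "info_score"] = 0.9    # boundary: kept (>=)
    gm.variants.loc[1, "info_score"] = 0.8999  # fails
    gm.dosages[: int(0.05 * n), 2] = np.nan    # missingness exactly 0.05: kept
    gm.dosages[: int(0.05 * n) + 1, 3] = np.nan  # just above: fails
    gm.dosages[:, 4] = 0.0
    gm.dosages[0, 4] = 1.0                    # MAF ~ 0.00125 < 0.01: fails
    keep, report = variant_qc(gm, QCThresholds())
    assert keep.tolist() == [True, False, True, False, False]
    assert report["fail_info"] == 1 and report["fail_maf"] == 1


def test_variant_qc_hwe_sample_mask(rng):
    # two diverged populations in HWE within themselves: pooled HWE rejects
    # (Wahlund effect), single-population HWE retains
    n = 600
    a = rng.binomial(2, 0.05, size=(n, 1)).astype(float)
    b = rng.binomial(2, 0.95, size=(n, 1)).astype(float)
    gm = make_gm(np.vstack([a, b]))
    keep_pooled, _ = variant_qc(gm, QCThresholds())
    mask = np.zeros(2 * n, dtype=bool)
    mask[:n] = True
    keep_within, _ = variant_qc(gm, QCThresholds(), hwe_sample_mask=mask)
    assert not keep_pooled[0]
    assert keep_within[0]


# --- relatedness ------------------------------------------------------------

def test_relatedness_prune_breaks_all_pairs():
    kin = pd.DataFrame(
        {"id1": ["A", "B", "C"], "id2": ["B", "C", "D"],
         "kinship": [0.25, 0.20, 0.05]}
    )
    removed = relatedness_prune(kin, threshold=0.0884, seed=1)
    for _, row in kin.iterrows():
        if row["kinship"] > 0.0884:
            assert row["id1"] in removed or row["id2"] in removed
    assert "D" not in removed or "C" in removed  # sub-threshold pair untouched


def test_relatedness_prune_threshold_strict():
    kin = pd.DataFrame({"id1": ["A"], "id2": ["B"], "kinship": [0.0884]})
    assert relatedness_prune(kin, threshold=0.0884, seed=0) == set()


# --- PRS scoring -------------------------------------------------------------

def _weights(gm, w):
    return pd.DataFrame(
        {"variant_id": gm.variant_ids, "effect_allele": gm.variants["effect_allele"],
         "weight": w}
    )


def test_score_prs_simple_sum(rng):
    gm = make_gm([[0, 1], [2, 0]])
    w = _weights(gm, [0.5, 1.0])
    prs, report = score_prs(gm, w)
    np.testing.assert_allclose(prs, [1.0, 1.0])
    assert report["n_scored"] == 2 and report["n_flipped"] == 0


def test_score_prs_allele_flip():
    gm = make_gm([[0.0, 0.0], [2.0, 2.0]])
    w = pd.DataFrame(
        {"variant_id": ["rs0", "rs1"], "effect_allele": ["G", "A"], "weight": [1.0, 1.0]}
    )
    # rs0's weight is on the other allele: dosage enters as 2 - d
    prs, report = score_prs(gm, w)
    np.testing.assert_allclose(prs, [2.0, 2.0])
    assert report["n_flipped"] == 1


def test_score_prs_strand_complement_flip():
    gm = make_gm([[1.0]])  # effect A / other G
    w = pd.DataFrame({"variant_id": ["rs0"], "effect_allele": ["C"], "weight": [2.0]})
    # C is the strand complement of other allele G: flip
    prs, report = score_prs(gm, w)
    assert report["n_flipped"] == 1
    np.testing.assert_allclose(prs, [2.0])


def test_score_prs_missing_mean_imputed():
    gm = make_gm([[0.0], [2.0], [np.nan]])
    prs, _ = score_prs(gm, _weights(gm, [1.0]))
    assert prs[2] == pytest.approx(1.0)  # mean of observed dosages


def test_score_prs_irreconcilable_dropped_and_empty_raises():
    gm = make_gm([[1.0, 1.0]])
    w = pd.DataFrame(
        {"variant_id": ["rs0", "rs1"], "effect_allele": ["A", "X"], "weight": [1.0, 1.0]}
    )
    _, report = score_prs(gm, w)
    assert report["n_dropped"] == 1
    bad = pd.DataFrame({"variant_id": ["zz"], "effect_allele": ["A"], "weight": [1.0]})
    with pytest.raises(PRSError):
        score_prs(gm, bad)


# --- LD pruning --------------------------------------------------------------

def test_ld_prune_removes_duplicate_variant(rng):
    x = rng.binomial(2, 0.4, size=300).astype(float)
    y = rng.binomial(2, 0.4, size=300).astype(float)
    gm = make_gm(np.column_stack([x, x, y]))
    keep = ld_prune(gm, window=10, step=5, r2_threshold=0.05)
    assert keep.sum() == 2
    assert not (keep[0] and keep[1])  # one of the identical pair pruned
    assert keep[2]


def test_ld_prune_keeps_independent_variants(rng):
    dos = rng.binomial(2, 0.4, size=(500, 8)).astype(float)
    keep = ld_prune(make_gm(dos), window=10, step=5, r2_threshold=0.5)
    assert keep.all()


# --- PCA / ancestry adjustment ----------------------------------------------

def _two_pop_gm(rng, n_per=300, m=60, delta=0.3):
    p = rng.uniform(0.2, 0.8, size=m)
    p2 = np.clip(p + delta, 0.01, 0.99)
    a = rng.binomial(2, p, size=(n_per, m)).astype(float)
    b = rng.binomial(2, p2, size=(n_per, m)).astype(float)
    return make_gm(np.vstack([a, b])), np.repeat([0, 1], n_per)


def test_reference_pca_separates_populations(rng):
    gm, pops = _two_pop_gm(rng)
    model = reference_pca(gm, k=2)
    pc1 = model.reference_scores[:, 0]
    assert abs(pc1[pops == 0].mean() - pc1[pops == 1].mean()) > 2 * pc1.std() / 2


def test_reference_pca_deterministic_sign(rng):
    gm, _ = _two_pop_gm(rng)
    m1 = reference_pca(gm, k=3)
    m2 = reference_pca(gm, k=3)
    np.testing.assert_allclose(m1.loadings, m2.loadings)
    for c in range(3):
        j = np.argmax(np.abs(m1.loadings[:, c]))
        assert m1.loadings[j, c] > 0


def test_reference_pca_k_beyond_rank_raises(rng):
    gm = make_gm(rng.binomial(2, 0.5, size=(5, 3)).astype(float))
    with pytest.raises(PRSError):
        reference_pca(gm, k=10)


def test_projection_matches_reference_scores(rng):
    gm, _ = _two_pop_gm(rng)
    model = reference_pca(gm, k=2)
    projected = project_samples(gm, model)
    np.testing.assert_allclose(projected, model.reference_scores, atol=1e-8)


def test_ancestry_adjust_removes_population_shift(rng):
    gm, pops = _two_pop_gm(rng, n_per=500)
    w = _weights(gm, rng.normal(size=gm.n_variants))
    raw, _ = score_prs(gm, w)
    model = reference_pca(gm, k=2)
    adjusted, adjuster = ancestry_adjust(raw, model.reference_scores, k=2)
    gap_raw = abs(raw[pops == 0].mean() - raw[pops == 1].mean()) / raw.std()
    gap_adj = abs(adjusted[pops == 0].mean() - adjusted[pops == 1].mean())
    assert gap_adj < 0.2 * gap_raw
    assert adjusted.std() == pytest.approx(1.0, abs=0.01)  # scale="sd" default


def test_ancestry_adjust_var_scaling(rng):
    raw = rng.normal(size=400)
    pcs = rng.normal(size=(400, 5))
    adj_sd, a1 = ancestry_adjust(raw, pcs, k=5, scale="sd")
    adj_var, a2 = ancestry_adjust(raw, pcs, k=5, scale="var")
    np.testing.assert_allclose(adj_var * a2.resid_var, adj_sd * a1.resid_sd)
    with pytest.raises(PRSError):
        ancestry_adjust(raw, pcs, k=5, scale="bogus")


def test_ancestry_adjust_apply_consistency(rng):
    raw = rng.normal(size=300)
    pcs = rng.normal(size=(300, 5))
    adjusted, adjuster = ancestry_adjust(raw, pcs, k=5)
    np.testing.assert_allclose(adjusted, adjuster.apply(raw, pcs))
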