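"""Variant/sample QC, polygenic scoring, and post-hoc ancestry adjustment.

The ancestry adjustment follows the reference-panel projection approach: fit
principal components in an external multi-ancestry panel, regress the panel's
raw scores on the leading components, then standardise any target sample's
raw score by subtracting the PC-predicted mean and dividing by the reference
residual spread.  The result is a score on one scale across ancestries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import QCThresholds
from .genotypes import GenotypeMatrix, complement


class PRSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (given the allele
    counts) no more probable than the observed one.  Falls back to a 1-df
    chi-square for samples above 1000 genotypes, where enumeration buys
    nothing.  Monomorphic variants return 1.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise PRSError("negative genotype counts")
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or rare == 0:
        return 1.0
    if n > 1000:
        p = (2 * n_hom1 + n_het) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
        obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        return float(chi2.sf(stat, df=1))
    # enumeration over heterozygote counts with the observed parity
    common = 2 * n - rare
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalised log-probabilities of each possible het count
    from scipy.special import gammaln

    def logprob(h):
        n1 = (rare - h) // 2          # rare homozygotes
        n2 = (common - h) // 2        # common homozygotes
        return (
            h * np.log(2)
            - gammaln(h + 1) - gammaln(n1 + 1) - gammaln(n2 + 1)
        )

    lp = np.array([logprob(h) for h in hets if (common - h) >= 0 and (common - h) % 2 == 0])
    valid_hets = np.array([h for h in hets if (common - h) >= 0 and (common - h) % 2 == 0])
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    p_obs = probs[valid_hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """HWE p per variant, computed on hard-called genotypes."""
    calls = gm.hard_calls()
    out = np.empty(gm.n_variants)
    for j in range(gm.n_variants):
        c = calls[:, j]
        c = c[~np.isnan(c)]
        n_hom1 = int((c == 2).sum())
        n_het = int((c == 1).sum())
        n_hom2 = int((c == 0).sum())
        out[j] = hwe_exact_pvalue(n_het, n_hom1, n_hom2)
    return out


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def variant_qc(
    gm: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_sample_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, dict]:
    """Retain variants passing INFO, missingness, MAF and HWE filters.

    Returns a boolean mask over variants and a report of per-filter removal
    counts.  ``hwe_sample_mask`` optionally restricts the HWE computation to a
    sample subset (e.g. one population in a structured cohort).
    """
    th = thresholds or QCThresholds()
    info_ok = gm.variants["info_score"].to_numpy() >= th.min_info
    miss_ok = gm.variant_missingness() <= th.max_missingness
    maf_ok = gm.maf() >= th.min_maf
    hwe_gm = gm if hwe_sample_mask is None else gm.subset_samples(hwe_sample_mask)
    hwe_ok = hwe_pvalues(hwe_gm) >= th.min_hwe_p
    keep = info_ok & miss_ok & maf_ok & hwe_ok
    report = {
        "n_variants": gm.n_variants,
        "fail_info": int((~info_ok).sum()),
        "fail_missingness": int((~miss_ok).sum()),
        "fail_maf": int((~maf_ok).sum()),
        "fail_hwe": int((~hwe_ok).sum()),
        "retained": int(keep.sum()),
    }
    return keep, report


# ---------------------------------------------------------------------------
# relatedness pruning
# ---------------------------------------------------------------------------

def relatedness_prune(
    kinship: pd.DataFrame,
    threshold: float = 0.0884,
    seed: int | np.random.Generator = 0,
) -> set:
    """Remove one random member of every related pair above ``threshold``
    until no pair remains.  Returns the removed id set."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = kinship.loc[kinship["kinship"] > threshold, ["id1", "id2"]]
    removed: set = set()
    pending = list(edges.itertuples(index=False, name=None))
    for a, b in pending:
        if a in removed or b in removed:
            continue
        removed.add(a if rng.random() < 0.5 else b)
    return removed


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _reconcile_alleles(gm_variants: pd.DataFrame, weights: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match the weight table against genotype variants.

    Returns (genotype column indices, aligned weights, flip mask) where a
    flipped variant's effect allele in the weight table is the genotype's
    other allele (directly or as the strand complement), so its dosage enters
    as 2 - dosage.
    """
    w = weights.drop_duplicates(subset="variant_id").set_index("variant_id")
    idx, wts, flip = [], [], []
    eff = gm_variants["effect_allele"].to_numpy()
    oth = gm_variants["other_allele"].to_numpy()
    vid = gm_variants["variant_id"].to_numpy()
    for j, v in enumerate(vid):
        if v not in w.index:
            continue
        we = str(w.at[v, "effect_allele"]).upper()
        if we == eff[j] or we == complement(eff[j]):
            idx.append(j); wts.append(w.at[v, "weight"]); flip.append(False)
        elif we == oth[j] or we == complement(oth[j]):
            idx.append(j); wts.append(w.at[v, "weight"]); flip.append(True)
        # otherwise: irreconcilable alleles, variant dropped
    return np.array(idx, dtype=int), np.array(wts, dtype=float), np.array(flip, dtype=bool)


def score_prs(gm: GenotypeMatrix, weights: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Weighted dosage sum per individual.

    Missing dosages are imputed to the variant's mean; weight-table variants
    whose effect allele matches the genotype's other allele (or its strand
    complement) contribute 2 - dosage.  Unmatched variants are dropped and
    counted in the returned report.
    """
    idx, wts, flip = _reconcile_alleles(gm.variants, weights)
    if len(idx) == 0:
        raise PRSError("no overlapping variants between weights and genotypes")
    dos = gm.dosages[:, idx].astype(float)
    col_mean = np.nanmean(dos, axis=0)
    nan_pos = np.where(np.isnan(dos))
    dos[nan_pos] = np.take(col_mean, nan_pos[1])
    dos[:, flip] = 2.0 - dos[:, flip]
    prs = dos @ wts
    report = {
        "n_weights": int(len(weights)),
        "n_scored": int(len(idx)),
        "n_flipped": int(flip.sum()),
        "n_dropped": int(len(weights) - len(idx)),
    }
    return prs, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    gm: GenotypeMatrix,
    window: int = 500,
    step: int = 50,
    r2_threshold: float = 0.05,
) -> np.ndarray:
    """Sliding-window greedy pairwise pruning.

    Within each window, pairs with squared dosage correlation above the
    threshold lose the member with the greater missingness (ties: the later
    position).  Returns a boolean keep-mask in variant order.
    """
    m = gm.n_variants
    order = np.argsort(gm.variants["pos"].to_numpy(), kind="stable")
    miss = gm.variant_missingness()
    dos = gm.dosages.astype(float)
    col_mean = np.nanmean(dos, axis=0)
    nan_pos = np.where(np.isnan(dos))
    dos[nan_pos] = np.take(col_mean, nan_pos[1])
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        widx = order[start:start + window]
        alive = widx[keep[widx]]
        if len(alive) < 2:
            if start + window >= m:
                break
            continue
        sub = dos[:, alive]
        sd = sub.std(axis=0)
        sd[sd == 0] = np.nan
        z = (sub - sub.mean(axis=0)) / sd
        corr = np.nan_to_num((z.T @ z) / len(z))
        r2 = corr**2
        local_alive = np.ones(len(alive), dtype=bool)
        for i in range(len(alive)):
            if not local_alive[i]:
                continue
            for j in range(i + 1, len(alive)):
                if not local_alive[j]:
                    continue
                if r2[i, j] > r2_threshold:
                    mi, mj = miss[alive[i]], miss[alive[j]]
                    drop_local = j if (mj > mi or (mj == mi)) else i
                    local_alive[drop_local] = False
                    keep[alive[drop_local]] = False
                    if drop_local == i:
                        break
        if start + window >= m:
            break
    return keep


# ---------------------------------------------------------------------------
# reference PCA and projection
# ---------------------------------------------------------------------------

@dataclass
class AncestryModel:
    """Reference-panel PCA plus the PC-on-score regression used for
    adjustment."""

    variant_ids: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (m, k), orthonormal columns
    reference_scores: np.ndarray  # (n_ref, k)
    coef: Optional[np.ndarray] = None       # regression coefficients (k,)
    intercept: float = 0.0
    resid_sd: float = 1.0
    resid_var: float = 1.0
    scale: str = "sd"

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _standardise_matrix(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    col_mean = np.nanmean(dos, axis=0)
    nan_pos = np.where(np.isnan(dos))
    dos = dos.copy()
    dos[nan_pos] = np.take(col_mean, nan_pos[1])
    sd = dos.std(axis=0)
    keep = sd > 0
    z = (dos[:, keep] - col_mean[keep]) / sd[keep]
    return z, col_mean, sd, keep


def reference_pca(ref: GenotypeMatrix, k: int) -> AncestryModel:
    """Top-k principal components of the standardised reference dosage
    matrix.  Sign convention: each component's largest-magnitude loading is
    positive, so the decomposition is deterministic."""
    if k < 1:
        raise PRSError("k must be >= 1")
    z, means, sds, kept = _standardise_matrix(ref.dosages.astype(float))
    rank = min(z.shape)
    if k > rank:
        raise PRSError(f"k={k} exceeds matrix rank {rank}")
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = z @ loadings
    return AncestryModel(
        variant_ids=ref.variant_ids[kept],
        means=means[kept],
        sds=sds[kept],
        loadings=loadings,
        reference_scores=scores,
    )


def project_samples(gm: GenotypeMatrix, model: AncestryModel) -> np.ndarray:
    """Project target samples onto the reference components using the
    reference standardisation constants."""
    pos = {v: i for i, v in enumerate(gm.variant_ids)}
    missing = [v for v in model.variant_ids if v not in pos]
    if missing:
        raise PRSError(f"target is missing {len(missing)} model variants: {missing[:5]}...")
    cols = np.array([pos[v] for v in model.variant_ids])
    dos = gm.dosages[:, cols].astype(float)
    nan_pos = np.where(np.isnan(dos))
    dos[nan_pos] = np.take(model.means, nan_pos[1])
    z = (dos - model.means) / model.sds
    return z @ model.loadings


# ---------------------------------------------------------------------------
# ancestry adjustment
# ---------------------------------------------------------------------------

@dataclass
class PRSAdjuster:
    coef: np.ndarray
    intercept: float
    resid_sd: float
    resid_var: float
    scale: str = "sd"

    def apply(self, raw_prs: np.ndarray, pcs: np.ndarray) -> np.ndarray:
        predicted = self.intercept + pcs[:, : len(self.coef)] @ self.coef
        denom = self.resid_sd if self.scale == "sd" else self.resid_var
        return (np.asarray(raw_prs, dtype=float) - predicted) / denom


def ancestry_adjust(
    raw_prs: np.ndarray,
    pcs: np.ndarray,
    k: int = 5,
    scale: str = "sd",
) -> tuple[np.ndarray, PRSAdjuster]:
    """Fit raw score ~ PC1..PCk on the reference panel and return the
    adjusted (residual-standardised) scores plus the fitted adjuster.

    ``scale='sd'`` divides by the residual standard deviation (unit-variance
    adjusted scores); ``scale='var'`` divides by the residual variance.
    """
    raw_prs = np.asarray(raw_prs, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.shape[1] < k:
        raise PRSError(f"need {k} PCs, got {pcs.shape[1]}")
    if len(raw_prs) < k + 2:
        raise PRSError("too few reference samples for the PC regression")
    if scale not in ("sd", "var"):
        raise PRSError("scale must be 'sd' or 'var'")
    X = np.column_stack([np.ones(len(raw_prs)), pcs[:, :k]])
    beta, *_ = np.linalg.lstsq(X, raw_prs, rcond=None)
    resid = raw_prs - X @ beta
    resid_sd = float(resid.std())
    if resid_sd == 0:
        raise PRSError("degenerate fit: zero residual variance")
    adj = PRSAdjuster(
        coef=beta[1:], intercept=float(beta[0]),
        resid_sd=resid_sd, resid_var=resid_sd**2, scale=scale,
    )
    return adj.apply(raw_prs, pcs), adj
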