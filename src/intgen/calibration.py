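"""Simulation studies validating the pipeline's statistical machinery.

These are the package's own designed experiments: type-I-error calibration of
the overlapping-sample z-test, the Monte-Carlo oracle for the analytic
overlap correlation, parameter recovery of the generator's injected effects,
the union-phenotype prediction-accuracy property, and the two-population
ancestry-adjustment check.  Both the test suite and the acceptance script
drive them through one code path.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .association import logistic_irls, roc_auc
from .config import SimulationConfig
from .overlap import OverlapDesign, effect_difference_z, overlap_correlation
from .prs import ancestry_adjust, reference_pca, score_prs
from .simulate import (
    draw_true_effects,
    generate_genotypes,
    generate_liabilities_and_disorders,
    simulate_latent_cohort,
)


def _beta_se(X: np.ndarray, y: np.ndarray, col: int = 1) -> tuple[float, float]:
    fit = logistic_irls(X, y)
    return float(fit["beta"][col]), float(np.sqrt(fit["cov"][col, col]))


# ---------------------------------------------------------------------------
# overlapping-sample z-test calibration
# ---------------------------------------------------------------------------

def null_overlap_calibration(
    n_per_arm: int = 10_000,
    overlap_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.9),
    n_reps: int = 2_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rates of the effect-difference z-test under equal true
    effects, with and without the analytic overlap correction.

    Two analyses of ``n_per_arm`` subjects share a fraction of them; the
    predictor is pure noise, so any rejection is a type-I error.  The
    corrected test should reject at ~alpha for every overlap fraction; the
    naive (r = 0) test grows conservative as overlap rises.
    """
    rng = np.random.default_rng(seed)
    from scipy.stats import norm as _norm

    z_crit = _norm.isf(alpha / 2.0)
    rows = []
    for frac in overlap_fractions:
        n_shared = int(round(frac * n_per_arm))
        n_total = 2 * n_per_arm - n_shared
        rej_ls = rej_naive = 0
        for _ in range(n_reps):
            x = rng.standard_normal(n_total)
            y = (rng.random(n_total) < 0.5).astype(float)
            a1 = slice(0, n_per_arm)
            a2 = slice(n_total - n_per_arm, n_total)
            X1 = np.column_stack([np.ones(n_per_arm), x[a1]])
            X2 = np.column_stack([np.ones(n_per_arm), x[a2]])
            b1, s1 = _beta_se(X1, y[a1])
            b2, s2 = _beta_se(X2, y[a2])
            shared = y[n_total - n_per_arm:n_per_arm] if n_shared else np.empty(0)
            design = OverlapDesign(
                n1_case=int(y[a1].sum()),
                n1_control=int(n_per_arm - y[a1].sum()),
                n2_case=int(y[a2].sum()),
                n2_control=int(n_per_arm - y[a2].sum()),
                n_shared_case=int(shared.sum()),
                n_shared_control=int(len(shared) - shared.sum()),
            )
            r = overlap_correlation(design)
            z_ls, _ = effect_difference_z(b1, s1, b2, s2, r)
            z_nv, _ = effect_difference_z(b1, s1, b2, s2, 0.0)
            rej_ls += abs(z_ls) > z_crit
            rej_naive += abs(z_nv) > z_crit
        rows.append(
            {
                "overlap_fraction": frac,
                "reject_rate_corrected": rej_ls / n_reps,
                "reject_rate_naive": rej_naive / n_reps,
            }
        )
    return pd.DataFrame(rows)


def overlap_correlation_oracle(
    n_per_arm: int = 4_000,
    overlap_fraction: float = 0.5,
    n_reps: int = 5_000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo check of the analytic estimate correlation: the empirical
    correlation of the two effect estimates across replicates versus the
    mean analytic r."""
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap_fraction * n_per_arm))
    n_total = 2 * n_per_arm - n_shared
    b1s, b2s, rs = [], [], []
    for _ in range(n_reps):
        x = rng.standard_normal(n_total)
        y = (rng.random(n_total) < 0.5).astype(float)
        a1 = slice(0, n_per_arm)
        a2 = slice(n_total - n_per_arm, n_total)
        b1, _ = _beta_se(np.column_stack([np.ones(n_per_arm), x[a1]]), y[a1])
        b2, _ = _beta_se(np.column_stack([np.ones(n_per_arm), x[a2]]), y[a2])
        shared = y[n_total - n_per_arm:n_per_arm]
        design = OverlapDesign(
            n1_case=int(y[a1].sum()), n1_control=int(n_per_arm - y[a1].sum()),
            n2_case=int(y[a2].sum()), n2_control=int(n_per_arm - y[a2].sum()),
            n_shared_case=int(shared.sum()),
            n_shared_control=int(len(shared) - shared.sum()),
        )
        rs.append(overlap_correlation(design))
        b1s.append(b1)
        b2s.append(b2)
    r_emp = float(np.corrcoef(b1s, b2s)[0, 1])
    return {
        "r_analytic": float(np.mean(rs)),
        "r_empirical": r_emp,
        "abs_gap": abs(float(np.mean(rs)) - r_emp),
    }


# ---------------------------------------------------------------------------
# generator parameter recovery
# ---------------------------------------------------------------------------

def _recovery_config(seed: int) -> SimulationConfig:
    # single homogeneous population: the estimand is the marginal
    # covariate-adjusted logistic effect, free of ancestry confounding
    return SimulationConfig(
        n_individuals=2_000,
        n_variants=250,
        n_populations=1,
        population_weights=(1.0,),
        fst=0.0,
        seed=seed,
    )


def _design(latent_table: pd.DataFrame, predictor_col: str) -> tuple[np.ndarray, np.ndarray]:
    t = latent_table
    age_z = (t["age"].to_numpy() - 54.5) / 8.5
    X = np.column_stack(
        [np.ones(len(t)), t[predictor_col].to_numpy(dtype=float),
         t["female"].to_numpy(dtype=float), age_z]
    )
    return X, t["mood"].to_numpy(dtype=float)


def reference_effect_sizes(seed: int = 0, n_big: int = 1_000_000) -> dict:
    """Logistic-scale reference effects of the standardised polygenic score
    and of carrier status on mood disorder, from one large latent-level
    Monte-Carlo run (the liability-scale inputs have no closed-form logistic
    counterpart)."""
    config = _recovery_config(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).generate_state(1)[0])
    latent = simulate_latent_cohort(config, n_big, rng)
    out = {}
    for name, col in (("prs", "G_mood"), ("carrier", "any_pcnv")):
        X, y = _design(latent.table, col)
        b, se = _beta_se(X, y)
        out[name] = {"beta": b, "se": se}
    return out


def parameter_recovery(
    n_reps: int = 200,
    seed: int = 0,
    reference: dict | None = None,
) -> dict:
    """Wald 95% CI coverage of the generator-injected polygenic and carrier
    effects over replicate cohorts, each run through the full genotype →
    score → regression path."""
    reference = reference or reference_effect_sizes(seed)
    cover = {"prs": 0, "carrier": 0}
    est = {"prs": [], "carrier": []}
    ss = np.random.SeedSequence([seed, 11]).spawn(n_reps)
    for rep_seed in ss:
        rng = np.random.default_rng(rep_seed)
        config = _recovery_config(seed)
        gm, pops = generate_genotypes(config, rng)
        effects = draw_true_effects(config, gm.variants, rng)
        latent = generate_liabilities_and_disorders(gm, effects, config, rng, pops)
        raw, _ = score_prs(gm, effects[["variant_id", "effect_allele", "weight"]])
        prs = (raw - raw.mean()) / raw.std()
        t = latent.table.copy()
        t["prs"] = prs
        for name, col in (("prs", "prs"), ("carrier", "any_pcnv")):
            X, y = _design(t, col)
            if name == "carrier" and t["any_pcnv"].sum() == 0:
                continue
            b, se = _beta_se(X, y)
            truth = reference[name]["beta"]
            if b - 1.96 * se <= truth <= b + 1.96 * se:
                cover[name] += 1
            est[name].append(b)
    return {
        "coverage_prs": cover["prs"] / n_reps,
        "coverage_carrier": cover["carrier"] / n_reps,
        "mean_beta_prs": float(np.mean(est["prs"])),
        "mean_beta_carrier": float(np.mean(est["carrier"])),
        "true_beta_prs": reference["prs"]["beta"],
        "true_beta_carrier": reference["carrier"]["beta"],
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# union-phenotype prediction accuracy
# ---------------------------------------------------------------------------

def union_auc_experiment(
    n_reps: int = 100,
    n: int = 100_000,
    r_genetic: float = 0.8,
    seed: int = 0,
) -> dict:
    """Fraction of replicates in which the shared-factor polygenic score
    discriminates the union (internalising) phenotype at least as well as
    either component.

    The score is the standardised shared genetic factor (G_mood + G_anx),
    the latent quantity a mood-disorder PRS proxies when the genetic
    correlation between the disorders is high.  In that regime the union's
    control group is screened on both liabilities, so it is more strongly
    depleted of high-score individuals than either single-disorder control
    group; a disorder-specific score instead yields a union AUC between the
    two component AUCs.
    """
    config = replace(SimulationConfig(), r_genetic=r_genetic)
    ss = np.random.SeedSequence([seed, 23]).spawn(n_reps)
    wins = 0
    aucs = {"mood": [], "anxiety": [], "internalising": []}
    for rep_seed in ss:
        rng = np.random.default_rng(rep_seed)
        latent = simulate_latent_cohort(config, n, rng)
        t = latent.table
        g = t["G_mood"].to_numpy() + t["G_anx"].to_numpy()
        mood = t["mood"].to_numpy()
        anx = t["anxiety"].to_numpy()
        union = ((mood == 1) | (anx == 1)).astype(int)
        a_m = roc_auc(g, mood)
        a_a = roc_auc(g, anx)
        a_u = roc_auc(g, union)
        aucs["mood"].append(a_m)
        aucs["anxiety"].append(a_a)
        aucs["internalising"].append(a_u)
        wins += a_u >= max(a_m, a_a)
    return {
        "fraction_union_at_least_max": wins / n_reps,
        "mean_auc_mood": float(np.mean(aucs["mood"])),
        "mean_auc_anxiety": float(np.mean(aucs["anxiety"])),
        "mean_auc_internalising": float(np.mean(aucs["internalising"])),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# ancestry adjustment
# ---------------------------------------------------------------------------

def ancestry_adjustment_study(
    n_per_pop: int = 2_000,
    n_variants: int = 500,
    fst: float = 0.1,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Two diverged populations whose raw polygenic scores differ purely
    through ancestry: after PC-regression standardisation both populations
    should sit at mean ~0, variance ~1."""
    config = SimulationConfig(
        n_individuals=2 * n_per_pop,
        n_variants=n_variants,
        n_populations=2,
        population_weights=(0.5, 0.5),
        fst=fst,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    gm, pops = generate_genotypes(config, rng)
    effects = draw_true_effects(config, gm.variants, rng)
    raw, _ = score_prs(gm, effects[["variant_id", "effect_allele", "weight"]])
    model = reference_pca(gm, k)
    adjusted, _ = ancestry_adjust(raw, model.reference_scores, k=k)
    out = {"k": k}
    for p in (0, 1):
        sel = pops == p
        out[f"raw_mean_pop{p}"] = float(raw[sel].mean())
        out[f"adjusted_mean_pop{p}"] = float(adjusted[sel].mean())
        out[f"adjusted_var_pop{p}"] = float(adjusted[sel].var())
    out["raw_mean_gap"] = abs(out["raw_mean_pop0"] - out["raw_mean_pop1"]) / raw.std()
    out["max_abs_adjusted_mean"] = max(
        abs(out["adjusted_mean_pop0"]), abs(out["adjusted_mean_pop1"])
    )
    out["max_abs_var_dev"] = max(
        abs(out["adjusted_var_pop0"] - 1.0), abs(out["adjusted_var_pop1"] - 1.0)
    )
    return out


# ---------------------------------------------------------------------------
# logistic / interaction calibration
# ---------------------------------------------------------------------------

def logistic_null_calibration(
    n_reps: int = 500, n: int = 2_000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the Wald test for a noise predictor."""
    rng = np.random.default_rng(seed)
    from scipy.stats import norm as _norm

    z_crit = _norm.isf(alpha / 2.0)
    rej = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(float)
        b, se = _beta_se(np.column_stack([np.ones(n), x]), y)
        rej += abs(b / se) > z_crit
    return rej / n_reps


def interaction_power_study(
    n_reps: int = 40,
    n: int = 50_000,
    beta_int: float = 0.5,
    carrier_freq: float = 0.02,
    seed: int = 0,
) -> dict:
    """Power and CI coverage for a product term between a standardised score
    and a rare carrier indicator, at the generative effect ``beta_int``."""
    rng = np.random.default_rng(seed)
    power = cover = 0
    for _ in range(n_reps):
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < carrier_freq).astype(float)
        eta = -1.5 + 0.3 * x1 + 0.4 * x2 + beta_int * x1 * x2
        y = (rng.random(n) < expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x1 * x2, x1, x2])
        b, se = _beta_se(X, y)
        power += abs(b / se) > 1.96
        cover += (b - 1.96 * se) <= beta_int <= (b + 1.96 * se)
    return {"power": power / n_reps, "coverage": cover / n_reps, "n_reps": n_reps}
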