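"""Synthetic biobank generator.

Produces a cohort with the statistical structure the downstream analysis
assumes: two or more ancestral populations with Balding–Nichols allele-
frequency divergence, a shared polygenic liability for mood and anxiety
disorder plus rare CNV carrier shifts, correlated environments, female-biased
prevalence, and a multi-source observation layer (touchscreen questionnaire,
nurse interview, hospital and primary-care records, online mental-health
questionnaire) with per-source coverage, per-definition sensitivity and
specificity, and lower questionnaire uptake among CNV carriers.

Everything is reproducible byte-for-byte under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtri

from .config import (
    ConfigurationError,
    PCNVLocus,
    SimulationConfig,
)
from .genotypes import GenotypeMatrix

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LatentState:
    """Per-individual latent truth: polygenic scores, liabilities, carrier
    flags and true disorder indicators."""

    table: pd.DataFrame
    locus_cols: list[str]

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


@dataclass
class PhenotypeRecords:
    """Raw multi-source phenotype records plus per-source availability."""

    availability: pd.DataFrame          # id + one boolean column per source
    touchscreen: pd.DataFrame           # id, seen_gp, seen_psychiatrist, low_mood_2wk
    interview_diag: pd.DataFrame        # id, code
    interview_med: pd.DataFrame         # id, code
    ehr: pd.DataFrame                   # id, code, source, system
    mhq_items: pd.DataFrame             # id, gad7_* and cidi_* items
    mhq_diag: pd.DataFrame              # id, code

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "availability": self.availability,
            "touchscreen": self.touchscreen,
            "interview_diag": self.interview_diag,
            "interview_med": self.interview_med,
            "ehr": self.ehr,
            "mhq_items": self.mhq_items,
            "mhq_diag": self.mhq_diag,
        }


@dataclass
class CNVData:
    calls: pd.DataFrame            # sample_id, locus, cnv_type, n_probes, length_bp, confidence
    sample_metrics: pd.DataFrame   # sample_id, n_cnvs, waviness, call_rate, lrr_sd


@dataclass
class SyntheticBiobank:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    populations: np.ndarray
    weights: dict[str, pd.DataFrame]
    latent: LatentState
    records: PhenotypeRecords
    cnv: CNVData
    kinship: pd.DataFrame
    reference: GenotypeMatrix
    reference_populations: np.ndarray


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _population_sizes(n: int, weights: Optional[tuple], k: int) -> np.ndarray:
    if weights is None:
        weights = tuple(1.0 / k for _ in range(k))
    sizes = np.floor(np.asarray(weights) * n).astype(int)
    for i in range(n - sizes.sum()):
        sizes[i % k] += 1
    return sizes


def _draw_variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_variants
    ids = np.array([f"var{i + 1:06d}" for i in range(m)])
    pos = (np.arange(m) + 1) * 10_000
    eff = rng.choice(_BASES, size=m)
    # other allele distinct from the effect allele
    shift = rng.integers(1, 4, size=m)
    base_idx = np.searchsorted(_BASES, eff)
    oth = _BASES[(base_idx + shift) % 4]
    info = rng.uniform(0.92, 1.0, size=m)
    low = rng.random(m) < config.low_info_fraction
    info[low] = rng.uniform(0.5, 0.9, size=low.sum())
    miss = np.zeros(m)
    some_miss = rng.random(m) < 0.3
    miss[some_miss] = rng.uniform(0.0, 0.02, size=some_miss.sum())
    high = rng.random(m) < config.high_missing_fraction
    miss[high] = rng.uniform(0.06, 0.15, size=high.sum())
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": eff,
            "other_allele": oth,
            "info_score": info,
            "_miss_rate": miss,
        }
    )


def _draw_population_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(k, m) per-population effect-allele frequencies under a
    Balding–Nichols divergence model with parameter ``fst``."""
    lo, hi = config.maf_range
    m, k, fst = config.n_variants, config.n_populations, config.fst
    p_anc = rng.uniform(lo, hi, size=m)
    if fst <= 0:
        return np.tile(p_anc, (k, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    freqs = rng.beta(np.tile(a, (k, 1)), np.tile(b, (k, 1)))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _draw_dosages(
    freqs: np.ndarray,
    labels: np.ndarray,
    miss_rate: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(labels)
    dosages = rng.binomial(2, freqs[labels, :]).astype(np.float32)
    if miss_rate.max() > 0:
        mask = rng.random((n, len(miss_rate))) < miss_rate[None, :]
        dosages[mask] = np.nan
    return dosages


def generate_genotypes(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    freqs: Optional[np.ndarray] = None,
    variants: Optional[pd.DataFrame] = None,
    n: Optional[int] = None,
    id_prefix: str = "ind",
    population_weights: Optional[tuple] = "config",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a genotype matrix plus population labels.

    Allele frequencies diverge between populations under a Balding–Nichols
    model; dosages are binomial draws from the individual's population
    frequency, with per-variant missingness applied afterwards.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if variants is None:
        variants = _draw_variant_table(config, rng)
    if freqs is None:
        freqs = _draw_population_freqs(config, rng)
    n = config.n_individuals if n is None else n
    if population_weights == "config":
        population_weights = config.population_weights
    sizes = _population_sizes(n, population_weights, config.n_populations)
    labels = np.repeat(np.arange(config.n_populations), sizes)
    dosages = _draw_dosages(freqs, labels, variants["_miss_rate"].to_numpy(), rng)
    samples = np.array([f"{id_prefix}{i + 1:07d}" for i in range(n)])
    meta = variants.drop(columns=["_miss_rate"]).copy()
    # population-specific frequencies as metadata columns
    for k in range(config.n_populations):
        meta[f"freq_pop{k}"] = freqs[k]
    return GenotypeMatrix(dosages, samples, meta), labels


# ---------------------------------------------------------------------------
# effects and weight tables
# ---------------------------------------------------------------------------

def draw_true_effects(config: SimulationConfig, variants: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-variant true liability effects for the shared/mood factor and a
    correlated anxiety factor (corr ~ r_genetic across many variants)."""
    m = len(variants)
    scale = 1.0 / np.sqrt(m)
    u = rng.normal(0.0, scale, size=m)
    e = rng.normal(0.0, scale, size=m)
    v = config.r_genetic * u + np.sqrt(max(0.0, 1.0 - config.r_genetic**2)) * e
    return pd.DataFrame(
        {
            "variant_id": variants["variant_id"],
            "effect_allele": variants["effect_allele"],
            "weight": u,
            "weight_anx": v,
        }
    )


def make_weight_tables(config: SimulationConfig, effects: pd.DataFrame,
                       rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Noisy 'GWAS posterior' weight tables: the mood table emulates a large
    discovery sample (small noise), the anxiety table a small one."""
    m = len(effects)
    scale = 1.0 / np.sqrt(m)
    out = {}
    for name, truth_col in (("mdd", "weight"), ("anx", "weight_anx")):
        noise_sd = config.gwas_noise[name] * scale
        w = effects[truth_col].to_numpy() + rng.normal(0.0, noise_sd, size=m)
        out[name] = pd.DataFrame(
            {
                "variant_id": effects["variant_id"],
                "effect_allele": effects["effect_allele"],
                "weight": w,
            }
        )
    return out


# ---------------------------------------------------------------------------
# liabilities and disorders
# ---------------------------------------------------------------------------

def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance polygenic score")
    return (x - x.mean()) / sd


def _polygenic(gm: GenotypeMatrix, w: np.ndarray) -> np.ndarray:
    dos = gm.dosages.astype(float)
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        idx = np.where(np.isnan(dos))
        dos[idx] = np.take(col_mean, idx[1])
    return _standardise(dos @ w)


def gender_prevalences(prev: float, female_or: float, female_fraction: float) -> tuple[float, float]:
    """Female/male prevalences whose mixture hits ``prev`` with the requested
    prevalence odds ratio (female vs male)."""
    if abs(female_or - 1.0) < 1e-12:
        return prev, prev
    f = female_fraction

    def gap(pm: float) -> float:
        odds_f = female_or * pm / (1.0 - pm)
        pf = odds_f / (1.0 + odds_f)
        return f * pf + (1.0 - f) * pm - prev

    pm = brentq(gap, 1e-9, 1.0 - 1e-9)
    odds_f = female_or * pm / (1.0 - pm)
    return odds_f / (1.0 + odds_f), pm


def _carrier_variance(loci: tuple[PCNVLocus, ...]) -> float:
    return float(sum(l.liability_shift**2 * l.carrier_freq * (1 - l.carrier_freq) for l in loci))


def _locus_col(locus: PCNVLocus) -> str:
    return f"carrier_{locus.name}_{locus.cnv_type[:3]}"


def assemble_latent(
    config: SimulationConfig,
    rng: np.random.Generator,
    ids: np.ndarray,
    female: np.ndarray,
    age: np.ndarray,
    G_mood: np.ndarray,
    G_anx: np.ndarray,
    carriers: dict[str, np.ndarray],
    population: Optional[np.ndarray] = None,
) -> LatentState:
    """Turn polygenic scores and carrier flags into liabilities and disorder
    indicators under the liability-threshold model."""
    for name, h2 in (("h2_mood", config.h2_mood), ("h2_anx", config.h2_anx)):
        if h2 + _carrier_variance(config.pcnv_loci) >= 1.0:
            raise ConfigurationError(
                f"{name} plus carrier liability variance reaches 1; no room for environment"
            )
    n = len(ids)
    shift = np.zeros(n)
    for locus in config.pcnv_loci:
        col = _locus_col(locus)
        shift = shift + locus.liability_shift * carriers[col].astype(float)
    z = rng.standard_normal((n, 2))
    e_mood = z[:, 0]
    e_anx = config.r_env * z[:, 0] + np.sqrt(max(0.0, 1.0 - config.r_env**2)) * z[:, 1]
    age_z = (age - np.mean(config.age_range)) / ((config.age_range[1] - config.age_range[0]) / np.sqrt(12))
    liab_mood = (
        np.sqrt(config.h2_mood) * G_mood + shift + config.age_beta * age_z
        + np.sqrt(1.0 - config.h2_mood) * e_mood
    )
    liab_anx = (
        np.sqrt(config.h2_anx) * G_anx + shift + config.age_beta * age_z
        + np.sqrt(1.0 - config.h2_anx) * e_anx
    )
    pf_mood, pm_mood = gender_prevalences(config.prevalence_mood, config.female_or, config.female_fraction)
    pf_anx, pm_anx = gender_prevalences(config.prevalence_anx, config.female_or, config.female_fraction)
    tau_mood = np.where(female, ndtri(1.0 - pf_mood), ndtri(1.0 - pm_mood))
    tau_anx = np.where(female, ndtri(1.0 - pf_anx), ndtri(1.0 - pm_anx))
    table = pd.DataFrame(
        {
            "id": ids,
            "female": female.astype(np.int8),
            "age": age,
            "population": population if population is not None else np.zeros(n, dtype=int),
            "G_mood": G_mood,
            "G_anx": G_anx,
            "liability_mood": liab_mood,
            "liability_anx": liab_anx,
            "mood": (liab_mood > tau_mood).astype(np.int8),
            "anxiety": (liab_anx > tau_anx).astype(np.int8),
        }
    )
    locus_cols = []
    any_c = np.zeros(n, dtype=bool)
    for locus in config.pcnv_loci:
        col = _locus_col(locus)
        table[col] = carriers[col].astype(np.int8)
        any_c |= carriers[col].astype(bool)
        locus_cols.append(col)
    table["any_pcnv"] = any_c.astype(np.int8)
    return LatentState(table, locus_cols)


def generate_liabilities_and_disorders(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    populations: Optional[np.ndarray] = None,
) -> LatentState:
    """Liability-threshold phenotypes from genotypes and true effect weights.

    ``weights`` must align to the genotype variants (column ``weight`` for the
    shared/mood factor; optional ``weight_anx`` for the anxiety factor —
    otherwise an anxiety factor correlated at ``r_genetic`` is synthesised).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = weights.set_index("variant_id")
    missing = [v for v in genotypes.variant_ids if v not in w.index]
    if missing:
        raise ValueError(f"{len(missing)} genotype variants absent from weight table")
    w = w.loc[genotypes.variant_ids]
    u = w["weight"].to_numpy()
    G_mood = _polygenic(genotypes, u)
    if "weight_anx" in w.columns:
        G_anx = _polygenic(genotypes, w["weight_anx"].to_numpy())
    else:
        e = rng.standard_normal(genotypes.n_samples)
        G_anx = config.r_genetic * G_mood + np.sqrt(max(0.0, 1 - config.r_genetic**2)) * e
    n = genotypes.n_samples
    female = rng.random(n) < config.female_fraction
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    carriers = {
        _locus_col(l): rng.random(n) < l.carrier_freq for l in config.pcnv_loci
    }
    return assemble_latent(
        config, rng, genotypes.samples, female, age, G_mood, G_anx, carriers,
        populations,
    )


def simulate_latent_cohort(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> LatentState:
    """Latent-level cohort without genotypes: polygenic scores drawn directly
    as standard normals with correlation ``r_genetic``.  Distributionally
    identical to the genotype path with the same standardised scores; used
    for large Monte-Carlo reference runs."""
    z = rng.standard_normal((n, 2))
    G_mood = z[:, 0]
    G_anx = config.r_genetic * z[:, 0] + np.sqrt(max(0.0, 1 - config.r_genetic**2)) * z[:, 1]
    female = rng.random(n) < config.female_fraction
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    ids = np.array([f"lat{i + 1:07d}" for i in range(n)])
    carriers = {_locus_col(l): rng.random(n) < l.carrier_freq for l in config.pcnv_loci}
    return assemble_latent(config, rng, ids, female, age, G_mood, G_anx, carriers)


# ---------------------------------------------------------------------------
# phenotype records
# ---------------------------------------------------------------------------

def _noisy(truth: np.ndarray, sens: float, spec: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli observation of a binary truth at given sensitivity and
    specificity."""
    truth = truth.astype(bool)
    u = rng.random(len(truth))
    return np.where(truth, u < sens, u < (1.0 - spec))


def _gad7_items(total: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Distribute per-person totals over seven 0-3 items."""
    n = len(total)
    base = total // 7
    rem = total - base * 7
    ranks = np.argsort(rng.random((n, 7)), axis=1)
    items = np.tile(base[:, None], (1, 7)) + (ranks < rem[:, None])
    return items.astype(int)


def generate_phenotype_records(
    latent: LatentState,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeRecords:
    """Raw multi-source records realising the configured observation model.

    Conditional on source availability, each definition's qualifying records
    are generated so that 'observing a case' has the configured sensitivity
    and specificity with respect to the true disorder.  Questionnaire
    completion for CNV carriers is down-weighted by ``mhq_uptake_pcnv_ratio``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    t = latent.table
    n = len(t)
    ids = t["id"].to_numpy()
    mood = t["mood"].to_numpy().astype(bool)
    anx = t["anxiety"].to_numpy().astype(bool)
    union = mood | anx
    obs = config.obs_model

    # availability -------------------------------------------------------
    avail = {"id": ids}
    for src in ("touchscreen", "interview", "hospital", "primary_care"):
        cov = config.source_availability.get(src, 1.0)
        avail[src] = rng.random(n) < cov
    mhq_cov = config.source_availability.get("mhq", 0.31)
    carrier = t["any_pcnv"].to_numpy().astype(bool)
    p_mhq = np.where(carrier, min(1.0, mhq_cov * config.mhq_uptake_pcnv_ratio), mhq_cov)
    avail["mhq"] = rng.random(n) < p_mhq
    availability = pd.DataFrame(avail)

    a_ts = availability["touchscreen"].to_numpy()
    a_iv = availability["interview"].to_numpy()
    a_ho = availability["hospital"].to_numpy()
    a_pc = availability["primary_care"].to_numpy()
    a_mh = availability["mhq"].to_numpy()

    # touchscreen: help-seeking (asked once, about either disorder) and the
    # two-week low-mood item of the broad probable-mood-disorder rule
    hs = _noisy(union, *obs[("help_seeking", "internalising")], rng)
    gp = hs & (rng.random(n) < 0.9)
    psych = hs & (rng.random(n) < 0.35)
    neither = hs & ~gp & ~psych
    gp = gp | neither
    low_mood = _noisy(mood, *obs[("minimal", "mood")], rng)
    touchscreen = pd.DataFrame(
        {
            "id": ids[a_ts],
            "seen_gp": gp[a_ts].astype(int),
            "seen_psychiatrist": psych[a_ts].astype(int),
            "low_mood_2wk": low_mood[a_ts].astype(int),
        }
    )

    # nurse interview: self-reported diagnoses and current medication -----
    diag_rows: list[tuple] = []
    isr_mood = _noisy(mood, *obs[("initial_self_report", "mood")], rng) & a_iv
    isr_anx = _noisy(anx, *obs[("initial_self_report", "anxiety")], rng) & a_iv
    female = t["female"].to_numpy().astype(bool)
    postnatal = isr_mood & female & (rng.random(n) < 0.10)
    for i in np.where(isr_mood)[0]:
        diag_rows.append((ids[i], "SR_POSTNATAL_DEPRESSION" if postnatal[i] else "SR_DEPRESSION"))
    for i in np.where(isr_anx)[0]:
        diag_rows.append((ids[i], "SR_ANXIETY_PANIC"))

    med_rows: list[tuple] = []
    antidep = np.array(["MED_SERTRALINE", "MED_FLUOXETINE", "MED_CITALOPRAM", "MED_AMITRIPTYLINE"])
    benzo = np.array(["MED_DIAZEPAM", "MED_LORAZEPAM"])
    med_mood = _noisy(mood, *obs[("medication_self_report", "mood")], rng) & a_iv
    med_anx = _noisy(anx, *obs[("medication_self_report", "anxiety")], rng) & a_iv
    for i in np.where(med_mood)[0]:
        med_rows.append((ids[i], rng.choice(antidep)))
    for i in np.where(med_anx & ~med_mood)[0]:
        pool = antidep if rng.random() < 0.6 else benzo
        med_rows.append((ids[i], rng.choice(pool)))
    # temazepam red herring: hypnotic use unrelated to the anxiety definition
    temaz = a_iv & (rng.random(n) < config.temazepam_rate)
    for i in np.where(temaz)[0]:
        med_rows.append((ids[i], "MED_TEMAZEPAM"))

    # EHR events ----------------------------------------------------------
    hosp_codes = {"mood": ["F32.0", "F32.1", "F32.9", "F33.0", "F33.1"],
                  "anxiety": ["F40.0", "F41.0", "F41.1", "F41.9"]}
    pc_codes = {"mood": ["E112.", "E113.", "E2B0.", "E2B1."],
                "anxiety": ["E200.", "E2000", "E202."]}
    ehr_rows: list[tuple] = []
    for disorder, truth in (("mood", mood), ("anxiety", anx)):
        flag_h = _noisy(truth, *obs[("hospital", disorder)], rng) & a_ho
        for i in np.where(flag_h)[0]:
            ehr_rows.append((ids[i], rng.choice(hosp_codes[disorder]), "hospital", "icd10-like"))
        flag_p = _noisy(truth, *obs[("primary_care", disorder)], rng) & a_pc
        for i in np.where(flag_p)[0]:
            ehr_rows.append((ids[i], rng.choice(pc_codes[disorder]), "primary_care", "read-like"))

    # MHQ: GAD-7 items, CIDI-SF items, self-reported diagnoses ------------
    gad7_flag = _noisy(anx, *obs[("minimal", "anxiety")], rng)
    total = np.where(gad7_flag, rng.integers(10, 22, size=n), rng.integers(0, 10, size=n))
    gad7 = _gad7_items(total, rng)

    cidi_mdd = _noisy(mood, *obs[("cidi_sf", "mood")], rng)
    dep_card_mood = np.where(cidi_mdd, (rng.random(n) < 0.85).astype(int), 0)
    dep_card_anh = np.where(cidi_mdd, (rng.random(n) < 0.60).astype(int), 0)
    none_card = cidi_mdd & (dep_card_mood == 0) & (dep_card_anh == 0)
    dep_card_mood = np.where(none_card, 1, dep_card_mood)
    dep_count = np.where(cidi_mdd, rng.integers(5, 10, size=n), rng.integers(0, 5, size=n))
    dep_dur = np.where(cidi_mdd, rng.integers(2, 53, size=n), rng.integers(0, 53, size=n))
    dep_imp = np.where(cidi_mdd, 1, rng.integers(0, 2, size=n))
    # non-cases must fail at least one criterion; pick a failure mode
    fail_mode = rng.integers(0, 3, size=n)
    nc = ~cidi_mdd
    dep_card_mood = np.where(nc & (fail_mode == 0), 0, dep_card_mood)
    dep_card_anh = np.where(nc & (fail_mode == 0), 0, dep_card_anh)
    dep_card_mood = np.where(nc & (fail_mode != 0), 1, dep_card_mood)
    dep_count = np.where(nc & (fail_mode == 1), rng.integers(0, 5, size=n), dep_count)
    dep_count = np.where(nc & (fail_mode == 2), rng.integers(5, 10, size=n), dep_count)
    dep_dur = np.where(nc & (fail_mode == 2), rng.integers(2, 53, size=n), dep_dur)
    dep_imp = np.where(nc & (fail_mode == 2), 0, dep_imp)
    dep_imp = np.where(nc & (fail_mode == 1), 1, dep_imp)
    dep_dur = np.where(nc & (fail_mode == 1), rng.integers(2, 53, size=n), dep_dur)

    cidi_gad = _noisy(anx, *obs[("cidi_sf", "anxiety")], rng)
    gad_worry = np.where(cidi_gad, 1, 0)
    gad_dur = np.where(cidi_gad, rng.integers(6, 25, size=n), 0)
    gad_count = np.where(cidi_gad, rng.integers(3, 7, size=n), 0)
    gfail = rng.integers(0, 3, size=n)
    ngc = ~cidi_gad
    gad_worry = np.where(ngc & (gfail != 0), 1, gad_worry)
    gad_dur = np.where(ngc & (gfail == 1), rng.integers(0, 6, size=n), gad_dur)
    gad_dur = np.where(ngc & (gfail == 2), rng.integers(6, 25, size=n), gad_dur)
    gad_count = np.where(ngc & (gfail == 2), rng.integers(0, 3, size=n), gad_count)
    gad_count = np.where(ngc & (gfail == 1), rng.integers(3, 7, size=n), gad_count)

    mhq_items = pd.DataFrame({"id": ids[a_mh]})
    for j in range(7):
        mhq_items[f"gad7_i{j + 1}"] = gad7[a_mh, j]
    mhq_items["dep_cardinal_mood"] = dep_card_mood[a_mh]
    mhq_items["dep_cardinal_anhedonia"] = dep_card_anh[a_mh]
    mhq_items["dep_symptom_count"] = dep_count[a_mh]
    mhq_items["dep_duration_weeks"] = dep_dur[a_mh]
    mhq_items["dep_impairment"] = dep_imp[a_mh]
    mhq_items["gad_worry"] = gad_worry[a_mh]
    mhq_items["gad_duration_months"] = gad_dur[a_mh]
    mhq_items["gad_symptom_count"] = gad_count[a_mh]

    anx_sr_codes = np.array(
        ["MHQ_SOCIAL_ANXIETY", "MHQ_AGORAPHOBIA", "MHQ_PANIC_ATTACKS",
         "MHQ_ANXIETY", "MHQ_NERVES", "MHQ_GAD"]
    )
    mhq_rows: list[tuple] = []
    sr_mood = _noisy(mood, *obs[("mhq_self_report", "mood")], rng) & a_mh
    sr_anx = _noisy(anx, *obs[("mhq_self_report", "anxiety")], rng) & a_mh
    for i in np.where(sr_mood)[0]:
        mhq_rows.append((ids[i], "MHQ_DEPRESSION"))
    for i in np.where(sr_anx)[0]:
        mhq_rows.append((ids[i], rng.choice(anx_sr_codes)))

    # exclusion diagnoses (schizophrenia / bipolar) across sources --------
    excl = rng.random(n) < config.exclusion_rate
    excl_hosp = ["F20.0", "F20.9", "F31.0", "F31.9"]
    excl_pc = ["EU20.", "E110.", "E111."]
    excl_iv = ["SR_SCHIZOPHRENIA", "SR_BIPOLAR"]
    excl_mhq = ["MHQ_SCHIZOPHRENIA", "MHQ_BIPOLAR"]
    for i in np.where(excl)[0]:
        routes = []
        if a_ho[i]:
            routes.append("hospital")
        if a_pc[i]:
            routes.append("primary_care")
        if a_iv[i]:
            routes.append("interview")
        if a_mh[i]:
            routes.append("mhq")
        if not routes:
            continue
        route = routes[rng.integers(0, len(routes))]
        if route == "hospital":
            ehr_rows.append((ids[i], rng.choice(excl_hosp), "hospital", "icd10-like"))
        elif route == "primary_care":
            ehr_rows.append((ids[i], rng.choice(excl_pc), "primary_care", "read-like"))
        elif route == "interview":
            diag_rows.append((ids[i], rng.choice(excl_iv)))
        else:
            mhq_rows.append((ids[i], rng.choice(excl_mhq)))

    return PhenotypeRecords(
        availability=availability,
        touchscreen=touchscreen,
        interview_diag=pd.DataFrame(diag_rows, columns=["id", "code"]),
        interview_med=pd.DataFrame(med_rows, columns=["id", "code"]),
        ehr=pd.DataFrame(ehr_rows, columns=["id", "code", "source", "system"]),
        mhq_items=mhq_items,
        mhq_diag=pd.DataFrame(mhq_rows, columns=["id", "code"]),
    )


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------

def generate_cnv_calls(
    latent: LatentState,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> CNVData:
    """Per-call records for every carrier plus per-sample array QC metrics.

    A configurable fraction of calls is made QC-failing (few probes, sparse
    probe coverage, or low confidence), as is a configurable fraction of
    samples (too many CNVs, wavy intensity profile, low call rate, or noisy
    log-R ratio)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    t = latent.table
    ids = t["id"].to_numpy()
    n = len(ids)

    rows: list[tuple] = []
    for locus in config.pcnv_loci:
        col = _locus_col(locus)
        for i in np.where(t[col].to_numpy().astype(bool))[0]:
            n_probes = int(rng.integers(25, 150))
            length = int(n_probes * rng.uniform(2_000, 15_000))
            conf = float(rng.uniform(12, 80))
            if rng.random() < config.cnv_call_fail_rate:
                mode = rng.integers(0, 3)
                if mode == 0:
                    n_probes = int(rng.integers(5, 20))
                elif mode == 1:
                    length = int(n_probes * rng.uniform(25_000, 60_000))
                else:
                    conf = float(rng.uniform(0, 9.9))
            rows.append((ids[i], locus.name, locus.cnv_type, n_probes, length, conf))
    # background calls at non-pathogenic loci
    n_bg = min(config.n_background_cnvs, 5 * n)
    bg_idx = rng.integers(0, n, size=n_bg)
    for i in bg_idx:
        n_probes = int(rng.integers(20, 80))
        rows.append(
            (
                ids[i],
                f"bg_{rng.integers(1, 200):03d}",
                "deletion" if rng.random() < 0.5 else "duplication",
                n_probes,
                int(n_probes * rng.uniform(2_000, 15_000)),
                float(rng.uniform(10, 60)),
            )
        )
    calls = pd.DataFrame(
        rows, columns=["sample_id", "locus", "cnv_type", "n_probes", "length_bp", "confidence"]
    )

    n_cnvs = rng.poisson(5, size=n).clip(max=25)
    waviness = rng.normal(0.0, 0.01, size=n).clip(-0.029, 0.029)
    call_rate = rng.uniform(0.965, 0.999, size=n)
    lrr_sd = rng.uniform(0.10, 0.30, size=n)
    fail = rng.random(n) < config.cnv_sample_fail_rate
    fmode = rng.integers(0, 4, size=n)
    n_cnvs = np.where(fail & (fmode == 0), rng.integers(30, 60, size=n), n_cnvs)
    waviness = np.where(
        fail & (fmode == 1),
        rng.uniform(0.031, 0.08, size=n) * np.sign(rng.random(n) - 0.5),
        waviness,
    )
    call_rate = np.where(fail & (fmode == 2), rng.uniform(0.90, 0.9599, size=n), call_rate)
    lrr_sd = np.where(fail & (fmode == 3), rng.uniform(0.36, 0.50, size=n), lrr_sd)
    sample_metrics = pd.DataFrame(
        {
            "sample_id": ids,
            "n_cnvs": n_cnvs.astype(int),
            "waviness": waviness,
            "call_rate": call_rate,
            "lrr_sd": lrr_sd,
        }
    )
    return CNVData(calls, sample_metrics)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def generate_kinship(
    latent: LatentState, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Sparse pairwise kinship table (only reported pairs), with a configured
    fraction of individuals in second-degree-or-closer pairs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    ids = latent.ids
    n = len(ids)
    n_rel = int(n * config.related_pair_fraction) // 2
    n_unrel = n_rel  # same number of sub-threshold reported pairs
    perm = rng.permutation(n)
    rows = []
    k = 0
    for _ in range(n_rel):
        a, b = perm[k], perm[k + 1]
        k += 2
        rows.append((ids[a], ids[b], float(rng.uniform(0.09, 0.25))))
    for _ in range(n_unrel):
        if k + 1 >= n:
            break
        a, b = perm[k], perm[k + 1]
        k += 2
        rows.append((ids[a], ids[b], float(rng.uniform(0.01, 0.08))))
    return pd.DataFrame(rows, columns=["id1", "id2", "kinship"])


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SyntheticBiobank:
    """Generate a complete synthetic biobank: cohort genotypes, an external
    multi-ancestry reference panel sharing the same population frequencies,
    weight tables, latent truth, phenotype records, CNV calls and kinship."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in seeds]

    variants = _draw_variant_table(config, rngs[0])
    freqs = _draw_population_freqs(config, rngs[0])
    genotypes, populations = generate_genotypes(
        config, rngs[1], freqs=freqs, variants=variants
    )
    reference, ref_pops = generate_genotypes(
        config,
        rngs[2],
        freqs=freqs,
        variants=variants,
        n=config.n_reference,
        id_prefix="ref",
        population_weights=None,  # balanced multi-ancestry reference
    )
    effects = draw_true_effects(config, variants, rngs[3])
    weights = make_weight_tables(config, effects, rngs[3])
    latent = generate_liabilities_and_disorders(
        genotypes, effects, config, rngs[4], populations
    )
    records = generate_phenotype_records(latent, config, rngs[5])
    cnv = generate_cnv_calls(latent, config, rngs[6])
    kinship = generate_kinship(latent, config, rngs[7])
    return SyntheticBiobank(
        config=config,
        genotypes=genotypes,
        populations=populations,
        weights={"mdd": weights["mdd"], "anx": weights["anx"], "true": effects},
        latent=latent,
        records=records,
        cnv=cnv,
        kinship=kinship,
        reference=reference,
        reference_populations=ref_pops,
    )
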