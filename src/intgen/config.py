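"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator draws a liability-threshold cohort: a shared polygenic factor,
rare high-penetrance CNV carrier shifts, correlated environments, and a
multi-source observation layer (touchscreen, nurse interview, hospital and
primary-care records, online mental-health questionnaire) with per-source
coverage and per-definition sensitivity/specificity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

DEFINITIONS = (
    "initial_self_report",
    "medication_self_report",
    "help_seeking",
    "minimal",
    "cidi_sf",
    "mhq_self_report",
    "hospital",
    "primary_care",
)
DISORDERS = ("mood", "anxiety", "internalising")
SOURCES = ("touchscreen", "interview", "hospital", "primary_care", "mhq")


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid range."""


@dataclass(frozen=True)
class PCNVLocus:
    """A pathogenic CNV locus: name, dosage type, carrier frequency and the
    shift it adds to the liability of both disorders (liability SD units)."""

    name: str
    cnv_type: str  # "deletion" | "duplication"
    carrier_freq: float
    liability_shift: float

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ConfigurationError(f"bad cnv_type {self.cnv_type!r}")
        if not 0.0 < self.carrier_freq < 0.5:
            raise ConfigurationError(f"carrier_freq out of range: {self.carrier_freq}")


# Carrier frequencies sum to ~1.6% so that the default cohort reproduces the
# observed overall carrier fraction of large population biobanks.
DEFAULT_PCNV_LOCI = (
    PCNVLocus("15q11.2", "deletion", 0.0040, 0.22),
    PCNVLocus("15q11.2", "duplication", 0.0032, 0.15),
    PCNVLocus("16p13.11", "deletion", 0.0016, 0.30),
    PCNVLocus("16p13.11", "duplication", 0.0022, 0.20),
    PCNVLocus("1q21.1", "deletion", 0.0010, 0.30),
    PCNVLocus("2p16.3", "deletion", 0.0006, 0.35),
    PCNVLocus("17p12", "deletion", 0.0008, 0.12),
    PCNVLocus("22q11.2", "deletion", 0.0004, 0.50),
    PCNVLocus("16p11.2", "duplication", 0.0012, 0.28),
    PCNVLocus("15q13.3", "deletion", 0.0006, 0.32),
)

# Observation model: probability of an affirmative raw record given the true
# disorder state, per (definition, disorder).  Chosen once so the default
# cohort reproduces the field-typical prevalence ordering: help-seeking is the
# broadest measure, hospital admission the narrowest, questionnaire-derived
# definitions in between.
DEFAULT_OBS_MODEL: dict[tuple[str, str], tuple[float, float]] = {
    ("initial_self_report", "mood"): (0.30, 0.995),
    ("initial_self_report", "anxiety"): (0.20, 0.995),
    ("medication_self_report", "mood"): (0.35, 0.99),
    ("medication_self_report", "anxiety"): (0.25, 0.99),
    # help-seeking is asked once, about either disorder
    ("help_seeking", "internalising"): (0.85, 0.83),
    ("minimal", "mood"): (0.55, 0.97),
    ("minimal", "anxiety"): (0.50, 0.97),
    ("cidi_sf", "mood"): (0.75, 0.93),
    ("cidi_sf", "anxiety"): (0.60, 0.95),
    ("mhq_self_report", "mood"): (0.80, 0.90),
    ("mhq_self_report", "anxiety"): (0.70, 0.92),
    ("hospital", "mood"): (0.12, 0.999),
    ("hospital", "anxiety"): (0.08, 0.999),
    ("primary_care", "mood"): (0.55, 0.96),
    ("primary_care", "anxiety"): (0.40, 0.97),
}

DEFAULT_SOURCE_AVAILABILITY = {
    "touchscreen": 1.0,
    "interview": 1.0,
    "hospital": 1.0,
    "primary_care": 0.40,
    "mhq": 0.3161,
}


@dataclass
class CidiConfig:
    """Thresholds of the short-form diagnostic interview scoring.

    Defaults follow the standard instrument: lifetime major depression needs a
    cardinal symptom (depressed mood or anhedonia), at least ``mdd_min_symptoms``
    of the symptom checklist, a two-week episode and functional impairment;
    lifetime generalised anxiety needs excessive worry lasting at least six
    months with at least three associated symptoms.  All are overridable.
    """

    mdd_min_symptoms: int = 5
    mdd_min_duration_weeks: int = 2
    mdd_require_impairment: bool = True
    gad_min_duration_months: int = 6
    gad_min_symptoms: int = 3


@dataclass
class SimulationConfig:
    n_individuals: int = 50_000
    n_variants: int = 2_000
    n_populations: int = 2
    population_weights: Optional[tuple[float, ...]] = (0.9, 0.1)
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_mood: float = 0.30
    h2_anx: float = 0.25
    r_genetic: float = 0.8
    r_env: float = 0.30
    prevalence_mood: float = 0.20
    prevalence_anx: float = 0.15
    female_or: float = 1.8
    female_fraction: float = 0.5
    age_range: tuple[int, int] = (40, 69)
    age_beta: float = 0.05  # liability per SD of age; small positive default
    pcnv_loci: tuple[PCNVLocus, ...] = DEFAULT_PCNV_LOCI
    source_availability: dict = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_AVAILABILITY)
    )
    # carrier MHQ completion relative to non-carriers (26.16% vs 31.61%)
    mhq_uptake_pcnv_ratio: float = 0.2616 / 0.3161
    obs_model: dict = field(default_factory=lambda: dict(DEFAULT_OBS_MODEL))
    exclusion_rate: float = 0.0085
    temazepam_rate: float = 0.01
    # sd of weight-table noise relative to true effect sd: the "MDD" table
    # stands in for a large discovery GWAS, the "anxiety" table for a small one
    gwas_noise: dict = field(default_factory=lambda: {"mdd": 0.3, "anx": 1.5})
    related_pair_fraction: float = 0.005
    low_info_fraction: float = 0.05
    high_missing_fraction: float = 0.02
    cnv_call_fail_rate: float = 0.05
    cnv_sample_fail_rate: float = 0.02
    n_background_cnvs: int = 2_000
    n_reference: int = 2_500
    seed: int = 2026

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_populations < 1:
            raise ConfigurationError("n_populations must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        if not 0.0 <= self.fst <= 0.3:
            raise ConfigurationError(f"fst out of [0, 0.3]: {self.fst}")
        for name in ("h2_mood", "h2_anx"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} out of [0, 1): {v}")
        for name in ("r_genetic", "r_env"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} out of [-1, 1]: {v}")
        for name in ("prevalence_mood", "prevalence_anx"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} out of (0, 1): {v}")
        if not 0.0 < self.female_fraction < 1.0:
            raise ConfigurationError("female_fraction out of (0, 1)")
        if self.female_or <= 0:
            raise ConfigurationError("female_or must be positive")
        for src, frac in self.source_availability.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"coverage for {src} out of [0, 1]: {frac}")
        for key, (sens, spec) in self.obs_model.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise ConfigurationError(
                    f"sensitivity/specificity out of [0, 1] for {key}"
                )
        if not 0.0 <= self.mhq_uptake_pcnv_ratio:
            raise ConfigurationError("mhq_uptake_pcnv_ratio must be non-negative")
        if self.population_weights is not None:
            w = self.population_weights
            if len(w) != self.n_populations or abs(sum(w) - 1.0) > 1e-8:
                raise ConfigurationError("population_weights must sum to 1 and match n_populations")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pcnv_loci"] = [asdict(l) for l in self.pcnv_loci]
        d["obs_model"] = {f"{k[0]}|{k[1]}": list(v) for k, v in self.obs_model.items()}
        return d


@dataclass
class QCThresholds:
    """Variant-level QC cut-offs; defaults are the standard imputation-era
    filters (INFO >= 0.9, missingness <= 0.05, MAF >= 0.01, HWE p >= 1e-6)."""

    min_info: float = 0.9
    max_missingness: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
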