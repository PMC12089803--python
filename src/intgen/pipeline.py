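"""End-to-end orchestration: simulate → QC → phenotype → score → CNV →
associate → compare, as one configured, logged, reproducible run."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import association as assoc
from . import cnv as cnvmod
from . import overlap as ovl
from . import phenotyping as pheno
from . import prs as prsmod
from .config import DEFINITIONS, DISORDERS, ConfigurationError, QCThresholds, SimulationConfig
from .io import build_manifest, write_json, write_tsv
from .simulate import SyntheticBiobank, generate_dataset


@dataclass
class RunConfig:
    out_dir: str = "intgen_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    definitions: tuple = DEFINITIONS
    predictors: tuple = ("prs_mdd", "prs_anx", "any_pcnv")
    n_pcs_covariate: int = 10
    n_pcs_adjust: int = 5
    kinship_threshold: float = 0.0884
    min_locus_observations: int = 5
    prs_test_family: int = 16
    cnv_test_family: int = 24
    alpha: float = 0.05
    ld_window: int = 500
    ld_step: int = 50
    ld_r2: float = 0.05
    max_sample_missingness: float = 0.05
    write_genotypes: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        unknown = set(self.definitions) - set(DEFINITIONS)
        if unknown:
            raise ConfigurationError(f"unknown definitions: {sorted(unknown)}")
        unknown_p = set(self.predictors) - {"prs_mdd", "prs_anx", "any_pcnv"}
        if unknown_p:
            raise ConfigurationError(f"unknown predictors: {sorted(unknown_p)}")
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        if "pcnv_loci" in sim:
            from .config import PCNVLocus

            sim["pcnv_loci"] = tuple(PCNVLocus(**l) for l in sim["pcnv_loci"])
        for key in ("definitions", "predictors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=SimulationConfig(**sim), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: pd.DataFrame                 # analysis-ready covariate table
    flags: pd.DataFrame                  # long phenotype flags
    prevalence: pd.DataFrame
    tetrachoric: pd.DataFrame
    prs_results: pd.DataFrame            # Table-1-shaped
    cnv_results: pd.DataFrame            # Table-2-shaped
    conditional_results: pd.DataFrame
    interaction_results: pd.DataFrame
    pairwise: pd.DataFrame
    manifest: dict


def _pc_columns(k: int) -> list[str]:
    return [f"PC{i + 1}" for i in range(k)]


def _covariate_matrix(df: pd.DataFrame, k: int) -> np.ndarray:
    cols = ["female", "age"] + _pc_columns(k)
    return df[cols].to_numpy(dtype=float)


def _status_to_binary(flags: pd.DataFrame, definition: str, disorder: str) -> pd.Series:
    sel = flags[(flags["definition"] == definition) & (flags["disorder"] == disorder)]
    s = sel.set_index("id")["status"]
    return s.map({"case": 1.0, "control": 0.0, "missing": np.nan})


def run_pipeline(config: RunConfig, dataset: Optional[SyntheticBiobank] = None) -> PipelineResult:
    """Execute every stage on a synthetic (or pre-generated) dataset and
    return the results bundle; `write_results` persists it with a manifest."""
    stages: dict = {}
    ds = dataset if dataset is not None else generate_dataset(config.simulation)
    sim = ds.config

    # --- genetic QC -----------------------------------------------------
    # HWE within the largest population: pooled-sample HWE in a structured
    # cohort rejects on divergence alone (Wahlund effect), not genotyping error
    largest = np.bincount(ds.populations).argmax()
    keep_var, qc_report = prsmod.variant_qc(
        ds.genotypes, QCThresholds(), hwe_sample_mask=ds.populations == largest
    )
    gm = ds.genotypes.subset_variants(keep_var)
    miss_ok = gm.sample_missingness() <= config.max_sample_missingness
    removed_related = prsmod.relatedness_prune(
        ds.kinship, config.kinship_threshold, seed=sim.seed + 101
    )
    sample_keep = miss_ok & ~np.isin(gm.samples, list(removed_related))
    gm = gm.subset_samples(sample_keep)
    stages["genetic_qc"] = {
        **qc_report,
        "fail_sample_missingness": int((~miss_ok).sum()),
        "removed_related": len(removed_related),
        "n_samples_retained": gm.n_samples,
    }

    # --- PRS scoring and ancestry adjustment ----------------------------
    ref = ds.reference.subset_variants(keep_var)
    keep_ld = prsmod.ld_prune(
        ref, config.ld_window, config.ld_step, config.ld_r2
    )
    ref_pruned = ref.subset_variants(keep_ld)
    k_adj = min(config.n_pcs_adjust, ref_pruned.n_variants - 1, ref_pruned.n_samples - 2)
    anc_model = prsmod.reference_pca(ref_pruned, k_adj)
    cohort_pcs_adj = prsmod.project_samples(gm.subset_variants(keep_ld), anc_model)

    prs_cols: dict[str, np.ndarray] = {}
    for name in ("mdd", "anx"):
        raw_ref, _ = prsmod.score_prs(ref, ds.weights[name])
        raw_cohort, score_report = prsmod.score_prs(gm, ds.weights[name])
        _, adjuster = prsmod.ancestry_adjust(raw_ref, anc_model.reference_scores, k=k_adj)
        prs_cols[f"prs_{name}"] = adjuster.apply(raw_cohort, cohort_pcs_adj)
        stages[f"prs_{name}"] = score_report

    # association-model PCs: recomputed on the analysed cohort itself
    gm_pruned = gm.subset_variants(keep_ld)
    k_cov = min(config.n_pcs_covariate, gm_pruned.n_variants - 1, gm_pruned.n_samples - 2)
    cohort_model = prsmod.reference_pca(gm_pruned, k_cov)
    cohort_pcs = cohort_model.reference_scores
    stages["ancestry"] = {
        "n_pruned_variants": int(keep_ld.sum()),
        "k_adjust": k_adj,
        "k_covariate": k_cov,
    }

    # --- phenotyping ----------------------------------------------------
    code_lists = pheno.load_default_code_lists()
    flags = pheno.derive_all(ds.records, code_lists, definitions=config.definitions)
    flags = flags[flags["id"].isin(set(gm.samples))].reset_index(drop=True)
    n_excluded = len(pheno.apply_exclusions(ds.records, code_lists))
    stages["phenotyping"] = {"n_excluded_diagnoses": n_excluded}

    # --- CNV ------------------------------------------------------------
    locus_list = pd.DataFrame(
        [(l.name, l.cnv_type) for l in sim.pcnv_loci], columns=["locus", "cnv_type"]
    )
    carrier, cnv_report = cnvmod.run_cnv_qc(
        ds.cnv.calls, ds.cnv.sample_metrics, locus_list, config.min_locus_observations
    )
    stages["cnv_qc"] = cnv_report

    # --- analysis-ready cohort table ------------------------------------
    latent = ds.latent.table.set_index("id")
    cohort = pd.DataFrame({"id": gm.samples}).set_index("id")
    cohort["female"] = latent["female"]
    cohort["age"] = latent["age"]
    cohort["population"] = latent["population"]
    for i in range(k_cov):
        cohort[f"PC{i + 1}"] = cohort_pcs[:, i]
    for name, col in prs_cols.items():
        cohort[name] = col
    any_pcnv = carrier.any_pcnv
    cohort["any_pcnv"] = any_pcnv.reindex(cohort.index)  # NaN: failed CNV QC
    locus_cols = [c for c in carrier.table.columns if c not in ("sample_id", "any_pcnv")]
    carrier_idx = carrier.table.set_index("sample_id")
    for c in locus_cols:
        cohort[c] = carrier_idx[c].reindex(cohort.index)
    cohort = cohort.reset_index()

    # --- association models ----------------------------------------------
    covars = _covariate_matrix(cohort, k_cov)
    prs_rows, cnv_rows, cond_rows, inter_rows = [], [], [], []
    id_sets: dict[str, dict[str, tuple[set, set]]] = {p: {} for p in config.predictors}
    results_by_pred: dict[str, list] = {p: [] for p in config.predictors}
    prs_thr = assoc.bonferroni_threshold(config.alpha, config.prs_test_family)
    cnv_thr = assoc.bonferroni_threshold(config.alpha, config.cnv_test_family)

    for definition in config.definitions:
        y_by_disorder = {}
        for disorder in DISORDERS:
            y = _status_to_binary(flags, definition, disorder).reindex(cohort["id"])
            y_by_disorder[disorder] = y.to_numpy()
            label = f"{definition}:{disorder}"
            for predictor in config.predictors:
                x = cohort[predictor].to_numpy(dtype=float)
                try:
                    res = assoc.fit_logistic(
                        y.to_numpy(), x, covars, outcome=label, predictor=predictor
                    )
                except assoc.AssociationError as exc:
                    stages.setdefault("model_failures", []).append(f"{label}/{predictor}: {exc}")
                    continue
                row = res.to_dict()
                row.update({"definition": definition, "disorder": disorder})
                if predictor.startswith("prs"):
                    row["significant"] = bool(res.p < prs_thr) if np.isfinite(res.p) else False
                    prs_rows.append(row)
                else:
                    row["significant"] = bool(res.p < cnv_thr) if np.isfinite(res.p) else False
                    cnv_rows.append(row)
                if disorder == "internalising" or definition == "help_seeking":
                    ok = ~np.isnan(np.column_stack([y.to_numpy(), x, covars])).any(axis=1)
                    ids_ok = cohort["id"].to_numpy()[ok]
                    yv = y.to_numpy()[ok]
                    if disorder == "internalising":
                        id_sets[predictor][label] = (
                            set(ids_ok[yv == 1]), set(ids_ok[yv == 0])
                        )
                        results_by_pred[predictor].append(res)

        # conditional anxiety-on-mood carrier models
        if "any_pcnv" in config.predictors:
            try:
                res = assoc.conditional_test(
                    y_by_disorder["anxiety"],
                    cohort["any_pcnv"].to_numpy(dtype=float),
                    y_by_disorder["mood"],
                    covars,
                    outcome=f"{definition}:anxiety",
                )
                row = res.to_dict()
                row.update({"definition": definition})
                cond_rows.append(row)
            except assoc.AssociationError as exc:
                stages.setdefault("model_failures", []).append(f"{definition}/conditional: {exc}")

        # gender and PRSxCNV interactions on the internalising outcome
        y_int = y_by_disorder["internalising"]
        female = cohort["female"].to_numpy(dtype=float)
        age_pcs = cohort[["age"] + _pc_columns(k_cov)].to_numpy(dtype=float)
        for predictor in config.predictors:
            x = cohort[predictor].to_numpy(dtype=float)
            try:
                res = assoc.interaction_test(
                    y_int, x, female, age_pcs,
                    outcome=f"{definition}:internalising", label=f"{predictor}*gender",
                )
            except assoc.AssociationError as exc:
                stages.setdefault("model_failures", []).append(
                    f"{definition}/{predictor}*gender: {exc}"
                )
                continue
            row = res.to_dict()
            row.update({"definition": definition, "kind": "gender"})
            inter_rows.append(row)
        if "any_pcnv" in config.predictors:
            pcnv = cohort["any_pcnv"].to_numpy(dtype=float)
            for prs_name in [p for p in config.predictors if p.startswith("prs")]:
                try:
                    res = assoc.interaction_test(
                        y_int, cohort[prs_name].to_numpy(dtype=float), pcnv, covars,
                        outcome=f"{definition}:internalising", label=f"{prs_name}*any_pcnv",
                    )
                except assoc.AssociationError as exc:
                    stages.setdefault("model_failures", []).append(
                        f"{definition}/{prs_name}*any_pcnv: {exc}"
                    )
                    continue
                row = res.to_dict()
                row.update({"definition": definition, "kind": "prs_x_pcnv"})
                inter_rows.append(row)

    # --- pairwise effect-size comparisons (internalising outcome) -------
    pair_frames = []
    for predictor in config.predictors:
        results = results_by_pred[predictor]
        usable = [r for r in results if r.converged and np.isfinite(r.beta)]
        if len(usable) >= 2:
            pw = ovl.pairwise_compare(usable, id_sets[predictor], alpha=config.alpha)
            pw.insert(0, "predictor", predictor)
            pair_frames.append(pw)
    pairwise = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["predictor", "label1", "label2", "overlap_r", "z", "p", "significant", "note"])
    )

    # --- summary statistics ----------------------------------------------
    gender = cohort.set_index("id")["female"]
    prevalence = pheno.prevalence_report(flags, gender)
    tet_rows = []
    import itertools as _it

    for a, b in _it.combinations(config.definitions, 2):
        ya = _status_to_binary(flags, a, "internalising").reindex(cohort["id"]).to_numpy()
        yb = _status_to_binary(flags, b, "internalising").reindex(cohort["id"]).to_numpy()
        ok = ~(np.isnan(ya) | np.isnan(yb))
        if ok.sum() < 10:
            continue
        tab = np.zeros((2, 2))
        for i in (0, 1):
            for j in (0, 1):
                tab[i, j] = np.sum((ya[ok] == i) & (yb[ok] == j))
        try:
            rho = assoc.tetrachoric(tab)
        except assoc.AssociationError:
            rho = np.nan
        tet_rows.append({"definition1": a, "definition2": b, "rho": rho, "n": int(ok.sum())})
    tetrachoric = pd.DataFrame(tet_rows)

    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "bonferroni": {"prs_threshold": prs_thr, "cnv_threshold": cnv_thr},
    }
    return PipelineResult(
        config=config,
        cohort=cohort,
        flags=flags,
        prevalence=prevalence,
        tetrachoric=tetrachoric,
        prs_results=pd.DataFrame(prs_rows),
        cnv_results=pd.DataFrame(cnv_rows),
        conditional_results=pd.DataFrame(cond_rows),
        interaction_results=pd.DataFrame(inter_rows),
        pairwise=pairwise,
        manifest=manifest,
    )


def write_results(result: PipelineResult, out_dir=None) -> Path:
    """Persist the bundle as TSV/JSON under the run directory with a
    content-hash manifest."""
    out = Path(out_dir if out_dir is not None else result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(result.cohort, out / "cohort.tsv")
    write_tsv(result.flags, out / "phenotype_flags.tsv")
    write_tsv(result.prevalence, out / "prevalence.tsv")
    write_tsv(result.tetrachoric, out / "tetrachoric.tsv")
    write_tsv(result.prs_results, out / "prs_associations.tsv")
    write_tsv(result.cnv_results, out / "cnv_associations.tsv")
    write_tsv(result.conditional_results, out / "conditional_associations.tsv")
    write_tsv(result.interaction_results, out / "interaction_tests.tsv")
    write_tsv(result.pairwise, out / "pairwise_comparisons.tsv")
    (out / "summary_report.txt").write_text(summary_report(result))
    manifest = build_manifest(out, result.manifest["config"], result.manifest["stages"])
    manifest["bonferroni"] = result.manifest["bonferroni"]
    write_json(manifest, out / "manifest.json")
    return out


def _fmt_assoc_block(df: pd.DataFrame, value_cols: list[str]) -> str:
    if df.empty:
        return "  (absent)\n"
    cols = ["definition"] + (["disorder"] if "disorder" in df.columns else []) + value_cols
    return df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}") + "\n"


def summary_report(result: PipelineResult) -> str:
    """Human-readable report with the four result sections: prevalence and
    phenotype correlations, polygenic-score associations, carrier
    associations, and interaction/joint models."""
    lines = ["# Synthetic cohort analysis report", ""]
    lines.append("## 1. Prevalence and phenotype correlations")
    if result.prevalence.empty:
        lines.append("  (absent)")
    else:
        lines.append(result.prevalence.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        lines.append("")
        lines.append("Tetrachoric correlations between internalising definitions:")
        lines.append(
            result.tetrachoric.to_string(index=False, float_format=lambda v: f"{v:.3f}")
            if not result.tetrachoric.empty else "  (absent)"
        )
    lines.append("")
    lines.append("## 2. Polygenic risk score associations (odds ratio, AUC, Nagelkerke dR2)")
    lines.append(
        _fmt_assoc_block(result.prs_results, ["predictor", "or_", "p", "auc", "r2_nagelkerke", "significant"])
        if not result.prs_results.empty else "  (absent)"
    )
    lines.append("## 3. Pathogenic-CNV carrier associations")
    lines.append(
        _fmt_assoc_block(result.cnv_results, ["predictor", "or_", "p", "n_case", "significant"])
        if not result.cnv_results.empty else "  (absent)"
    )
    if not result.conditional_results.empty:
        lines.append("Anxiety models conditioned on mood disorder:")
        lines.append(_fmt_assoc_block(result.conditional_results, ["predictor", "or_", "p"]))
    if not result.pairwise.empty:
        lines.append("Pairwise effect-size comparisons (overlap-corrected z):")
        lines.append(result.pairwise.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    lines.append("## 4. Interaction and joint models")
    lines.append(
        _fmt_assoc_block(result.interaction_results, ["predictor", "or_", "p", "kind"])
        if not result.interaction_results.empty else "  (absent)"
    )
    return "\n".join(lines) + "\n"
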