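"""CNV call/sample QC filters and pathogenic-CNV carrier status.

Boundary semantics follow the standard array-QC conventions exactly: a sample
fails with 30 or more CNVs, a waviness factor strictly beyond ±0.03, a call
rate strictly below 96%, or a log-R-ratio SD strictly above 0.35; a call
fails with fewer than 20 probes, probe density below 1 per 20 kb, or a
confidence score below 10.  Loci observed fewer than five times after QC are
dropped from every downstream analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_CNVS = 30              # fail at >= 30
MAX_ABS_WAVINESS = 0.03    # fail strictly beyond
MIN_CALL_RATE = 0.96       # fail strictly below
MAX_LRR_SD = 0.35          # fail strictly above
MIN_PROBES = 20
MIN_PROBE_DENSITY = 1.0 / 20_000
MIN_CONFIDENCE = 10.0
MIN_OBSERVATIONS = 5

SAMPLE_METRICS = ("n_cnvs", "waviness", "call_rate", "lrr_sd")


class CNVError(ValueError):
    pass


def qc_samples(sample_metrics: pd.DataFrame) -> tuple[set, pd.DataFrame]:
    """Samples passing array-level QC.

    Returns the passing id set and a per-sample report with failure reasons;
    a missing metric fails the sample with reason ``missing_metric``.
    """
    t = sample_metrics.copy()
    for col in SAMPLE_METRICS:
        if col not in t.columns:
            raise CNVError(f"sample metrics missing column {col!r}")
    reasons = []
    for _, row in t.iterrows():
        r = []
        if any(pd.isna(row[c]) for c in SAMPLE_METRICS):
            r.append("missing_metric")
        else:
            if row["n_cnvs"] >= MAX_CNVS:
                r.append("n_cnvs")
            if abs(row["waviness"]) > MAX_ABS_WAVINESS:
                r.append("waviness")
            if row["call_rate"] < MIN_CALL_RATE:
                r.append("call_rate")
            if row["lrr_sd"] > MAX_LRR_SD:
                r.append("lrr_sd")
        reasons.append(",".join(r))
    t["fail_reasons"] = reasons
    t["pass"] = t["fail_reasons"] == ""
    passing = set(t.loc[t["pass"], "sample_id"])
    return passing, t


def qc_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls passing probe-count, probe-density and confidence filters.

    A zero-length call is rejected (density undefined).
    """
    t = calls.copy()
    length = t["length_bp"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(length > 0, t["n_probes"].to_numpy(dtype=float) / length, np.nan)
    ok = (
        (t["n_probes"] >= MIN_PROBES)
        & (length > 0)
        & (density >= MIN_PROBE_DENSITY)
        & (t["confidence"] >= MIN_CONFIDENCE)
    )
    return t.loc[ok.to_numpy()].reset_index(drop=True)


@dataclass
class CarrierStatus:
    """Per-sample carrier flags over the retained pathogenic loci."""

    table: pd.DataFrame               # sample_id, any_pcnv, one column per retained locus
    retained_loci: pd.DataFrame       # locus, cnv_type, n_carriers
    dropped_loci: pd.DataFrame        # locus, cnv_type, n_carriers (below threshold)

    @property
    def any_pcnv(self) -> pd.Series:
        return self.table.set_index("sample_id")["any_pcnv"]


def _locus_key(locus: str, cnv_type: str) -> str:
    return f"{locus}_{cnv_type[:3]}"


def carrier_status(
    calls: pd.DataFrame,
    pcnv_locus_list: pd.DataFrame,
    samples: np.ndarray,
    min_observations: int = MIN_OBSERVATIONS,
) -> CarrierStatus:
    """Carrier flags per (locus, dosage-type) over QC-passing samples.

    ``pcnv_locus_list`` needs columns ``locus`` and ``cnv_type``; loci with
    fewer than ``min_observations`` carriers are dropped from the retained
    list and from the any-carrier flag.  Unknown loci yield zero carriers.
    """
    required = {"locus", "cnv_type"}
    if not required.issubset(pcnv_locus_list.columns):
        raise CNVError(f"locus list missing columns {required - set(pcnv_locus_list.columns)}")
    samples = np.asarray(samples)
    sample_set = set(samples)
    table = pd.DataFrame({"sample_id": samples})
    retained_rows, dropped_rows = [], []
    any_flag = np.zeros(len(samples), dtype=bool)
    idx = {s: i for i, s in enumerate(samples)}
    for _, row in pcnv_locus_list.drop_duplicates(subset=["locus", "cnv_type"]).iterrows():
        sel = (calls["locus"] == row["locus"]) & (calls["cnv_type"] == row["cnv_type"])
        carriers = {s for s in calls.loc[sel, "sample_id"] if s in sample_set}
        count = len(carriers)
        key = _locus_key(row["locus"], row["cnv_type"])
        if count >= min_observations:
            flags = np.zeros(len(samples), dtype=bool)
            for s in carriers:
                flags[idx[s]] = True
            table[key] = flags.astype(np.int8)
            any_flag |= flags
            retained_rows.append((row["locus"], row["cnv_type"], count))
        else:
            dropped_rows.append((row["locus"], row["cnv_type"], count))
    table["any_pcnv"] = any_flag.astype(np.int8)
    cols = ["sample_id", "any_pcnv"] + [c for c in table.columns if c not in ("sample_id", "any_pcnv")]
    return CarrierStatus(
        table=table[cols],
        retained_loci=pd.DataFrame(retained_rows, columns=["locus", "cnv_type", "n_carriers"]),
        dropped_loci=pd.DataFrame(dropped_rows, columns=["locus", "cnv_type", "n_carriers"]),
    )


def run_cnv_qc(
    calls: pd.DataFrame,
    sample_metrics: pd.DataFrame,
    pcnv_locus_list: pd.DataFrame,
    min_observations: int = MIN_OBSERVATIONS,
) -> tuple[CarrierStatus, dict]:
    """Full CNV stage: sample QC, call QC, carrier derivation; returns the
    carrier status and a QC report of removal counts."""
    passing, sample_report = qc_samples(sample_metrics)
    good_calls = qc_calls(calls)
    good_calls = good_calls[good_calls["sample_id"].isin(passing)].reset_index(drop=True)
    keep_samples = np.array([s for s in sample_metrics["sample_id"] if s in passing])
    status = carrier_status(good_calls, pcnv_locus_list, keep_samples, min_observations)
    report = {
        "n_samples": int(len(sample_metrics)),
        "n_samples_pass": int(len(passing)),
        "n_calls": int(len(calls)),
        "n_calls_pass_qc": int(len(good_calls)),
        "n_loci_retained": int(len(status.retained_loci)),
        "n_loci_dropped": int(len(status.dropped_loci)),
        "n_any_pcnv": int(status.table["any_pcnv"].sum()),
    }
    return status, report
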