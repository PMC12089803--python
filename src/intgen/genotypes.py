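"""Dosage-matrix container and plain-text genotype I/O.

Dosages are expected allele counts in [0, 2] (imputation-style), stored as a
dense float array with NaN marking missing calls.  Variant metadata rides in a
DataFrame aligned with the columns of the dosage matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "info_score"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


@dataclass
class GenotypeMatrix:
    """individuals x variants dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        (n_samples, n_variants) float array, values in [0, 2] or NaN.
    samples
        sample identifiers, length n_samples.
    variants
        DataFrame with at least ``VARIANT_COLUMNS``; one row per column of
        ``dosages``, in order.
    """

    dosages: np.ndarray
    samples: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} dosage columns")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{bad} dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    # --- summaries -------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Observed effect-allele frequency per variant (missing ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to {0,1,2}; NaN preserved (float array)."""
        return np.round(self.dosages)

    # --- subsetting ------------------------------------------------------
    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, set, frozenset, pd.Index)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "UOS"
        ):
            wanted = set(mask_or_ids)
            mask = self.variants["variant_id"].isin(wanted).to_numpy()
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            self.dosages[:, mask], self.samples, self.variants.loc[mask].copy()
        )

    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, set, frozenset, pd.Index)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "UOS"
        ):
            wanted = set(mask_or_ids)
            mask = np.array([s in wanted for s in self.samples])
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(self.dosages[mask], self.samples[mask], self.variants.copy())


# --- plain-text I/O -------------------------------------------------------

def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Write a .traw-style table: variant metadata columns then one dosage
    column per sample (missing as NA)."""
    meta = gm.variants[VARIANT_COLUMNS].copy()
    dos = pd.DataFrame(gm.dosages.T, columns=[str(s) for s in gm.samples])
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.4g"
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = df[VARIANT_COLUMNS].copy()
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, np.array(sample_cols), meta)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with a DS (dosage) FORMAT field."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.samples) + "\n")
        for j, row in gm.variants.iterrows():
            ds = gm.dosages[:, j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["variant_id"]),
                str(row["other_allele"]), str(row["effect_allele"]), ".", "PASS",
                f"INFO={row['info_score']:.3f}", "DS",
            ]
            fields += ["." if np.isnan(d) else f"{d:.3f}" for d in ds]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a dosage VCF (DS FORMAT field) via cyvcf2."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, dos = [], []
    for rec in vcf:
        info = rec.INFO.get("INFO")
        rows.append(
            {
                "variant_id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "effect_allele": rec.ALT[0],
                "other_allele": rec.REF,
                "info_score": float(info) if info is not None else np.nan,
            }
        )
        d = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        dos.append(d)
    variants = pd.DataFrame(rows)
    dosages = np.vstack(dos).T if dos else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, variants)
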