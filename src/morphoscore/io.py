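"""Readers and writers for the interchange formats around the pipeline.

Covers: plain-text dosage tables, phenotype/covariate tables, the planted
truth record, PLINK bed/bim/fam, GCTA GRM text (grm.gz triplets + grm.id),
PLINK-style summary statistics, and CAVIAR-convention Z-score / LD files.

The .bed writer packs hard calls (dosages rounded to 0/1/2); exact dosages
belong in the dosage table, which is the lossless interchange format here.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Genotypes, SnpPanel, SyntheticTruth, CovariateTable
from .heritability import Grm

__all__ = [
    "write_dosage_table", "read_dosage_table", "write_covariate_table",
    "read_covariate_table", "write_phenotype", "read_phenotype",
    "write_truth", "read_truth", "write_plink", "write_grm", "read_grm",
    "write_summary_stats", "read_summary_stats", "write_caviar_inputs",
]


# --- tab-separated tables --------------------------------------------------

def write_dosage_table(genotypes: Genotypes, path) -> None:
    df = pd.DataFrame(genotypes.dosage, columns=list(genotypes.panel.snp_id))
    df.insert(0, "subject_id", genotypes.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_table(path, panel: SnpPanel) -> Genotypes:
    df = pd.read_csv(path, sep="\t")
    ids = df["subject_id"].to_numpy(dtype=object)
    dosage = df[list(panel.snp_id)].to_numpy(dtype=float)
    return Genotypes(ids, panel, dosage)


def write_covariate_table(covariates: CovariateTable, path) -> None:
    covariates.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_covariate_table(path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t")
    pcs = df[[f"pc{k + 1}" for k in range(7)]].to_numpy(dtype=float)
    return CovariateTable(df["subject_id"].to_numpy(dtype=object),
                          df["age"].to_numpy(dtype=float),
                          df["sex"].to_numpy(dtype=float), pcs,
                          df["icv"].to_numpy(dtype=float),
                          df["cohort"].to_numpy(dtype=object))


def write_phenotype(subject_ids, values, path, name: str = "score") -> None:
    pd.DataFrame({"subject_id": subject_ids, name: values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_phenotype(path):
    df = pd.read_csv(path, sep="\t")
    return df["subject_id"].to_numpy(dtype=object), df.iloc[:, 1].to_numpy(dtype=float)


# --- truth record ----------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"causal_snp_id\t{truth.causal_snp_id}\n")
        fh.write(f"beta_causal\t{truth.beta_causal:.12g}\n")
        fh.write(f"h2_true\t{truth.h2_true:.12g}\n")
        fh.write(f"delta_case\t{truth.delta_case:.12g}\n")
        fh.write(f"seed\t{truth.seed}\n")
        fh.write("w_true\t" + ",".join(f"{v:.10g}" for v in truth.w_true) + "\n")


def read_truth(path) -> SyntheticTruth:
    kv = {}
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("\t", 1)
            kv[key] = val
    return SyntheticTruth(
        w_true=np.array([float(v) for v in kv["w_true"].split(",")]),
        causal_snp_id=kv["causal_snp_id"], beta_causal=float(kv["beta_causal"]),
        h2_true=float(kv["h2_true"]), delta_case=float(kv["delta_case"]),
        seed=int(kv["seed"]))


# --- PLINK bed/bim/fam -----------------------------------------------------

_BED_CODES = {0: 0b00, 1: 0b10, 2: 0b11}   # hom A1, het, hom A2 (SNP-major)


def write_plink(genotypes: Genotypes, prefix) -> None:
    """Write <prefix>.bed/.bim/.fam with dosages rounded to hard calls."""
    prefix = Path(prefix)
    panel = genotypes.panel
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(len(panel)):
            fh.write(f"{panel.chrom[j]}\t{panel.snp_id[j]}\t0\t{panel.pos[j]}"
                     f"\t{panel.alt_allele[j]}\t{panel.ref_allele[j]}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in genotypes.subject_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    hard = np.rint(genotypes.dosage).astype(int)
    n = hard.shape[0]
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        for j in range(hard.shape[1]):
            row = bytearray(nbytes)
            for i in range(n):
                code = _BED_CODES[int(hard[i, j])]
                row[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(row))


# --- GCTA GRM --------------------------------------------------------------

def write_grm(grm: Grm, prefix) -> None:
    """GCTA text format: <prefix>.grm.gz triplet rows and <prefix>.grm.id."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.subject_ids:
            fh.write(f"{sid}\t{sid}\n")
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        a = grm.matrix
        for i in range(a.shape[0]):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{a[i, j]:.10g}\n")


def read_grm(prefix) -> Grm:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    a = np.zeros((n, n))
    m = 0
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i, j, mm, v = line.split()
            a[int(i) - 1, int(j) - 1] = a[int(j) - 1, int(i) - 1] = float(v)
            m = int(mm)
    return Grm(np.asarray(ids, dtype=object), a, m)


# --- summary statistics ----------------------------------------------------

def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- CAVIAR file conventions ----------------------------------------------

def write_caviar_inputs(snp_ids, z: np.ndarray, ld: np.ndarray, prefix) -> None:
    """<prefix>.z: two columns SNP, Z;  <prefix>.ld: whitespace m x m matrix."""
    prefix = Path(prefix)
    with open(f"{prefix}.z", "w") as fh:
        for s, zz in zip(snp_ids, z):
            fh.write(f"{s}\t{zz:.8g}\n")
    np.savetxt(f"{prefix}.ld", ld, fmt="%.6g")
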