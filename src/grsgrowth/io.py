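"""Readers/writers for the delimited pipeline inputs and outputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import InputError

__all__ = ["read_pedigree", "read_anthro", "read_genotypes", "read_snp_panel",
           "write_tsv"]

_PED_REQUIRED = {"individual_id", "mother_id", "sex", "birth_date", "village"}
_ANTHRO_REQUIRED = {"individual_id", "age", "sex", "weight_kg", "height_m"}


def read_pedigree(path):
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str,
                                            "mother_id": str,
                                            "twin_id": str})
    missing = _PED_REQUIRED - set(df.columns)
    if missing:
        raise InputError(f"pedigree table missing columns: {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        raise InputError("pedigree has duplicate individual ids")
    if "twin_id" in df.columns:
        df["twin_id"] = df["twin_id"].fillna("")
    else:
        df["twin_id"] = ""
    return df


def read_anthro(path):
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = _ANTHRO_REQUIRED - set(df.columns)
    if missing:
        raise InputError(f"anthropometry table missing columns: {sorted(missing)}")
    return df


def read_snp_panel(path):
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "risk_allele": str})
    if "snp_id" not in df.columns or "risk_allele" not in df.columns:
        raise InputError("SNP panel needs snp_id and risk_allele columns")
    return df


def read_genotypes(path):
    """Wide genotype table: first column individual_id, remaining SNPs."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise InputError("genotype table needs an individual_id column")
    return df.set_index("individual_id")


def write_tsv(df, path, index=False):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
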