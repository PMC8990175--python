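"""Tab-delimited readers/writers for the pipeline's on-disk formats."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .assoc import SUMMARY_COLUMNS
from .ld import LdMatrix


def write_summary(df: pd.DataFrame, path: str) -> None:
    """Write a summary-statistics frame (SNP CHR POS EA OA EAF BETA SE P N
    INFO MAC); missing values become 'NA'."""
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_summary(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = {"SNP", "BETA", "SE", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"summary file {path} lacks columns {sorted(missing)}")
    return df


def read_known_index(path: str) -> pd.DataFrame:
    """Known-index SNP list: trait, rsid, chr, pos, EA, OA (tab-delimited),
    optionally a published BETA column for directional consistency."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.upper() if c.lower() != "trait" else "trait" for c in df.columns]
    return df


def write_ld(ld: LdMatrix, prefix: str) -> None:
    """Write an LD matrix as <prefix>.vars.tsv + <prefix>.r.tsv."""
    meta = pd.DataFrame({"SNP": ld.variants})
    if ld.geno_var is not None:
        meta["GENO_VAR"] = ld.geno_var
    meta.to_csv(f"{prefix}.vars.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.r.tsv", ld.r, delimiter="\t", fmt="%.10g")
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump({"ref_n": ld.ref_n, "provenance": ld.provenance}, fh)


def read_ld(prefix: str) -> LdMatrix:
    meta = pd.read_csv(f"{prefix}.vars.tsv", sep="\t")
    r = np.loadtxt(f"{prefix}.r.tsv", delimiter="\t", ndmin=2)
    try:
        with open(f"{prefix}.meta.json") as fh:
            extra = json.load(fh)
    except FileNotFoundError:
        extra = {"ref_n": 0, "provenance": ""}
    return LdMatrix(
        variants=meta["SNP"].tolist(),
        r=r,
        ref_n=int(extra.get("ref_n", 0)),
        provenance=str(extra.get("provenance", "")),
        geno_var=meta["GENO_VAR"].to_numpy() if "GENO_VAR" in meta.columns else None,
    )
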