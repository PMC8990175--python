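"""Fixed-effect inverse-variance meta-analysis with genomic control.

Implements the METAL-style workflow: per-study genomic-control correction
(SE inflation by sqrt(lambda) when lambda > 1), allele harmonization to a
common effect allele, inverse-variance pooling, Cochran's Q and I^2
heterogeneity, and two-stage (discovery + replication) combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import SummaryRecord, Variant

# Median of a 1-df chi-square; the genomic-control denominator.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class MetaRecord:
    """Pooled estimate for one variant with heterogeneity statistics."""

    variant: Variant
    beta: float
    se: float
    p: float
    eaf: float
    n: float
    q: float
    i2: float
    direction: str
    k: int


def genomic_lambda(records: pd.DataFrame | np.ndarray) -> float:
    """Genomic-control inflation factor: median((beta/se)^2) / chi2_median.

    Accepts a summary-statistics DataFrame (BETA/SE columns) or an array of
    chi-square statistics.
    """
    if isinstance(records, pd.DataFrame):
        z = records["BETA"].to_numpy() / records["SE"].to_numpy()
        chisq = z**2
    else:
        chisq = np.asarray(records, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no finite association statistics")
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def apply_gc(records: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Apply genomic control: inflate SEs by sqrt(lambda) when lambda > 1.

    Betas are never altered; p-values are recomputed from the corrected z.
    Lambda <= 1 leaves records unchanged (the METAL convention).
    """
    if not np.isfinite(lam):
        raise ValueError("lambda must be finite")
    if lam <= 1.0:
        return records.copy()
    out = records.copy()
    out["SE"] = out["SE"] * np.sqrt(lam)
    z = out["BETA"] / out["SE"]
    out["P"] = 2.0 * stats.norm.sf(np.abs(z))
    return out


def harmonize(
    df: pd.DataFrame,
    ref: pd.DataFrame,
    ambiguous_eaf_margin: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a study's effect alleles to a reference allele assignment.

    ``ref`` maps SNP -> (EA, OA).  Matching (EA, OA) passes through; swapped
    alleles flip beta sign and EAF.  Strand-ambiguous A/T / C/G variants are
    resolved by allele frequency only when |EAF - 0.5| > margin in both
    sources, otherwise dropped.  Irreconcilable alleles are dropped.
    Returns (harmonized records, drop log).
    """
    ref_idx = ref.set_index("SNP")
    rows, dropped = [], []
    for r in df.itertuples(index=False):
        if r.SNP not in ref_idx.index:
            dropped.append({"SNP": r.SNP, "reason": "absent"})
            continue
        rea, roa = ref_idx.loc[r.SNP, "EA"], ref_idx.loc[r.SNP, "OA"]
        rec = r._asdict()
        ambiguous = (r.EA, r.OA) in AMBIGUOUS_PAIRS
        if (r.EA, r.OA) == (rea, roa):
            pass
        elif (r.EA, r.OA) == (roa, rea):
            rec["EA"], rec["OA"] = rea, roa
            rec["BETA"] = -rec["BETA"]
            rec["EAF"] = 1.0 - rec["EAF"]
        else:
            dropped.append({"SNP": r.SNP, "reason": "allele_mismatch"})
            continue
        if ambiguous:
            ref_eaf = ref_idx.loc[r.SNP, "EAF"] if "EAF" in ref_idx.columns else None
            if (
                abs(rec["EAF"] - 0.5) <= ambiguous_eaf_margin
                or ref_eaf is None
                or abs(float(ref_eaf) - 0.5) <= ambiguous_eaf_margin
            ):
                dropped.append({"SNP": r.SNP, "reason": "strand_ambiguous"})
                continue
            # frequencies on opposite sides of 0.5 indicate a strand flip
            if (rec["EAF"] - 0.5) * (float(ref_eaf) - 0.5) < 0:
                rec["BETA"] = -rec["BETA"]
                rec["EAF"] = 1.0 - rec["EAF"]
        rows.append(rec)
    return (
        pd.DataFrame(rows, columns=list(df.columns)),
        pd.DataFrame(dropped, columns=["SNP", "reason"]),
    )


def ivw_meta(per_study: list[SummaryRecord]) -> MetaRecord:
    """Fixed-effect inverse-variance meta-analysis of one variant.

    Weights are 1/se^2; the pooled beta is the weighted mean, pooled
    se = 1/sqrt(sum w), p is the two-sided normal p, Q = sum w (b - beta)^2
    and I^2 = max(0, 100 (Q - (k-1))/Q) for k > 1.  EAF is pooled as the
    N-weighted mean.  Studies with non-finite beta/se (or infinite se)
    contribute '?' to the direction string and nothing to the pool.
    """
    if not per_study:
        raise ValueError("ivw_meta needs at least one study record")
    betas, ses, ns, eafs, direction = [], [], [], [], []
    for rec in per_study:
        if not (np.isfinite(rec.beta) and np.isfinite(rec.se)) or rec.se <= 0:
            direction.append("?")
            continue
        direction.append("+" if rec.beta > 0 else ("-" if rec.beta < 0 else "0"))
        betas.append(rec.beta)
        ses.append(rec.se)
        ns.append(rec.n)
        eafs.append(rec.eaf)
    if not betas:
        raise ValueError("no informative studies")
    b = np.array(betas)
    w = 1.0 / np.array(ses) ** 2
    n_arr = np.array(ns, dtype=float)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    k = len(b)
    q = float(np.sum(w * (b - beta) ** 2))
    i2 = float(max(0.0, 100.0 * (q - (k - 1)) / q)) if (k > 1 and q > 0) else 0.0
    eaf = float(np.sum(n_arr * np.array(eafs)) / np.sum(n_arr))
    return MetaRecord(
        variant=per_study[0].variant,
        beta=beta,
        se=se,
        p=p,
        eaf=eaf,
        n=float(np.sum(n_arr)),
        q=q,
        i2=i2,
        direction="".join(direction),
        k=k,
    )


def combine_stages(
    stage1: MetaRecord | SummaryRecord,
    stage2_records: list[SummaryRecord],
) -> MetaRecord:
    """Combine a pooled discovery result with replication-stage studies.

    Stage 2 records are first meta-analyzed, then pooled with stage 1 by
    inverse-variance weighting (the two-row mode of a two-stage METAL run).
    Missing stage 2 passes stage 1 through with a '?' direction appended.
    """
    s1 = SummaryRecord(
        variant=stage1.variant,
        eaf=stage1.eaf,
        beta=stage1.beta,
        se=stage1.se,
        p=stage1.p,
        n=int(stage1.n),
    )
    informative = [
        r
        for r in stage2_records
        if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0
    ]
    if not informative:
        out = ivw_meta([s1])
        return MetaRecord(
            **{**out.__dict__, "direction": out.direction + "?"}
        )
    s2 = ivw_meta(informative)
    s2_rec = SummaryRecord(
        variant=s2.variant, eaf=s2.eaf, beta=s2.beta, se=s2.se, p=s2.p, n=int(s2.n)
    )
    return ivw_meta([s1, s2_rec])


def meta_analyze(
    study_frames: list[pd.DataFrame],
    gc: bool = True,
    gc_on_pooled: bool = False,
) -> pd.DataFrame:
    """Genome-wide IVW meta-analysis over several studies' summary frames.

    Each study is optionally genomic-control corrected first, harmonized to
    the first study's allele assignment, then pooled variant by variant.
    Returns a meta summary frame with BETA/SE/P/EAF/N/Q/I2/DIRECTION/K.
    A second, pooled-level GC pass is off by default.
    """
    if not study_frames:
        raise ValueError("no studies supplied")
    frames = []
    for df in study_frames:
        cur = apply_gc(df, genomic_lambda(df)) if gc else df.copy()
        frames.append(cur)
    ref = frames[0][["SNP", "EA", "OA"] + (["EAF"] if "EAF" in frames[0] else [])]
    harmonized = [frames[0]]
    for df in frames[1:]:
        h, _ = harmonize(df, ref)
        harmonized.append(h)

    k_studies = len(harmonized)
    snp_meta = frames[0].set_index("SNP")
    tables = [df.set_index("SNP") for df in harmonized]
    common = set(tables[0].index)
    all_snps = list(frames[0]["SNP"])

    rows = []
    for snp in all_snps:
        recs = []
        for t in tables:
            if snp in t.index:
                r = t.loc[snp]
                recs.append(
                    SummaryRecord(
                        variant=Variant(snp, str(r["CHR"]), int(r["POS"]), r["EA"], r["OA"]),
                        eaf=float(r["EAF"]),
                        beta=float(r["BETA"]),
                        se=float(r["SE"]),
                        p=float(r["P"]),
                        n=int(r["N"]),
                    )
                )
            else:
                recs.append(
                    SummaryRecord(
                        variant=Variant(snp, "0", 0, "N", "M"),
                        eaf=np.nan, beta=np.nan, se=np.nan, p=np.nan, n=0,
                    )
                )
        try:
            m = ivw_meta(recs)
        except ValueError:
            continue
        base = snp_meta.loc[snp]
        rows.append(
            {
                "SNP": snp,
                "CHR": base["CHR"],
                "POS": base["POS"],
                "EA": base["EA"],
                "OA": base["OA"],
                "EAF": m.eaf,
                "BETA": m.beta,
                "SE": m.se,
                "P": m.p,
                "N": m.n,
                "Q": m.q,
                "I2": m.i2,
                "DIRECTION": m.direction,
                "K": m.k,
            }
        )
    out = pd.DataFrame(rows)
    if gc_on_pooled and len(out):
        out = apply_gc(out, genomic_lambda(out))
    return out


def meta_analyze_arrays(
    betas: np.ndarray,
    ses: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IVW pooling of aligned per-study beta/SE arrays.

    ``betas`` and ``ses`` are studies x variants.  Returns (beta, se, p)
    arrays over variants; used by the genome-scale drivers where building
    per-variant record objects would dominate runtime.
    """
    w = 1.0 / ses**2
    wsum = w.sum(axis=0)
    beta = (w * betas).sum(axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, p
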