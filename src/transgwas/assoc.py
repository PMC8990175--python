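"""Per-study association analysis: trait preparation, additive-model GWAS,
summary-statistic QC, and the cis-eQTL scan.

Trait values are residualized on age, age^2 (optionally BMI and further
covariates) within sex strata, then either rank-inverse-normal transformed
(Phi^-1((rank-0.5)/n), average ranks on ties) or standardized to Z scores
(residual / SD of all residuals).  Association is ordinary least squares of
the prepared trait on dosage plus covariates and leading genotype PCs, with
two-sided normal p-values, which is what the summary-statistic machinery
downstream assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypePanel

SUMMARY_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO", "MAC",
]


@dataclass(frozen=True)
class Variant:
    id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association result in one study."""

    variant: Variant
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    info: float = 1.0
    mac: float = np.inf


@dataclass(frozen=True)
class TraitConfig:
    """How a raw anthropometric trait becomes the analysis-ready phenotype."""

    trait: str = "BMI"
    transformation: str = "inverse-normal"  # or "z-score"
    adjust_bmi: bool = False
    sex_stratified: bool = True
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.transformation not in ("inverse-normal", "z-score"):
            raise ValueError(f"unknown transformation {self.transformation!r}")
        if self.adjust_bmi and self.trait != "WHRadjBMI":
            raise ValueError("adjust_bmi is only meaningful for WHRadjBMI")


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5)/n).

    Ties get average ranks, so the transform is symmetric under negation of
    the input.
    """
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def prepare_trait(raw: pd.DataFrame, config: TraitConfig) -> pd.Series:
    """Residualize and transform a raw trait into the analysis phenotype.

    ``raw`` needs columns sample_id, value, age, sex, plus any
    ``config.covariates`` (and ``bmi`` when ``config.adjust_bmi``).
    Residuals come from OLS of the trait on [1, age, age^2, covariates
    (, BMI)], computed within sex stratum when ``sex_stratified``; the
    residuals are then inverse-normal transformed or divided by the overall
    residual SD per ``config.transformation``.
    """
    required = {"sample_id", "value", "age", "sex"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw trait table missing columns {sorted(missing)}")
    if raw["value"].isna().any():
        raise ValueError("missing trait values are not allowed")

    def _stratum_residuals(df: pd.DataFrame) -> pd.Series:
        if len(df) < 3:
            raise ValueError(f"stratum has {len(df)} samples; need >= 3")
        y = df["value"].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("trait is constant within stratum")
        cols = [np.ones(len(df)), df["age"].to_numpy(dtype=float),
                df["age"].to_numpy(dtype=float) ** 2]
        for cov in config.covariates:
            cols.append(df[cov].to_numpy(dtype=float))
        if config.adjust_bmi:
            cols.append(df["bmi"].to_numpy(dtype=float))
        X = np.column_stack(cols)
        return pd.Series(_residualize(y, X), index=df.index)

    if config.sex_stratified:
        resid = pd.concat(
            [_stratum_residuals(sub) for _, sub in raw.groupby("sex", sort=False)]
        ).reindex(raw.index)
    else:
        resid = _stratum_residuals(raw)

    if config.transformation == "inverse-normal":
        out = inverse_normal_transform(resid.to_numpy())
    else:
        out = resid.to_numpy() / resid.to_numpy().std(ddof=0)
    return pd.Series(out, index=raw["sample_id"].to_numpy(), name=config.trait)


def genotype_pcs(panel: GenotypePanel, n_pcs: int) -> np.ndarray:
    """Leading principal components of the frequency-standardized dosages."""
    from .stratbias import run_pca

    pcs, _ = run_pca(panel, n_pcs=n_pcs)
    return pcs


def run_gwas(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Additive-model association of a prepared trait against every variant.

    Per variant, OLS of trait on [dosage, 1, covariates, leading PCs];
    computed via projection onto the covariate complement (exactly equal to
    the full-design least-squares solve).  The effect allele is the ALT
    allele.  Returns a summary-statistics DataFrame with columns
    ``SUMMARY_COLUMNS``; monomorphic variants get NaN beta/SE/P.
    """
    y = np.asarray(trait, dtype=float)
    n = panel.n_samples
    if y.shape[0] != n:
        raise ValueError("trait is not aligned with the panel samples")

    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    if n_pcs > 0:
        cols.append(genotype_pcs(panel, n_pcs))
    X = np.column_stack(cols)
    Q, _ = np.linalg.qr(X)
    p_cov = X.shape[1]

    y_r = y - Q @ (Q.T @ y)
    G = panel.dosages
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = float(y_r @ y_r)

    mono = gg <= 1e-12
    gg_safe = np.where(mono, 1.0, gg)
    beta = gy / gg_safe
    rss = yy - beta**2 * gg_safe
    dof = n - p_cov - 1
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan

    eaf = G.mean(axis=0) / 2.0
    alt_count = G.sum(axis=0)
    mac = np.minimum(alt_count, 2 * n - alt_count)

    out = pd.DataFrame(
        {
            "SNP": panel.variants["SNP"].to_numpy(),
            "CHR": panel.variants["CHR"].to_numpy(),
            "POS": panel.variants["POS"].to_numpy(),
            "EA": panel.variants["ALT"].to_numpy(),
            "OA": panel.variants["REF"].to_numpy(),
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
            "INFO": panel.info,
            "MAC": mac,
        }
    )
    return out


def qc_filter(
    records: pd.DataFrame,
    info_min: float = 0.4,
    mac_min: float = 5,
    n_min: float = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality summary records.

    Removal is by strict inequality -- info < info_min, MAC < mac_min or
    N < n_min -- so records exactly at a threshold are retained.  Returns
    (kept records, removal log with one row per removed variant listing all
    failing reasons).
    """
    reasons = []
    fail_info = records["INFO"].to_numpy() < info_min
    fail_mac = records["MAC"].to_numpy() < mac_min
    fail_n = records["N"].to_numpy() < n_min
    removed_mask = fail_info | fail_mac | fail_n
    for i in np.flatnonzero(removed_mask):
        tags = []
        if fail_info[i]:
            tags.append("info")
        if fail_mac[i]:
            tags.append("mac")
        if fail_n[i]:
            tags.append("n")
        reasons.append({"SNP": records["SNP"].iloc[i], "reason": ";".join(tags)})
    kept = records.loc[~removed_mask].reset_index(drop=True)
    log = pd.DataFrame(reasons, columns=["SNP", "reason"])
    return kept, log


def eqtl_scan(
    expression: pd.DataFrame,
    panel: GenotypePanel,
    lead: Variant,
    window: int = 1_000_000,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_pcs: int = 3,
    gene_positions: dict[str, tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """cis-eQTL scan around a lead variant.

    Tests every panel variant within ``window`` of the lead against every
    gene (restricted to genes whose TSS falls in the window when
    ``gene_positions`` is given).  Expression is inverse-normal transformed
    per gene, then regressed on dosage plus covariates and leading genotype
    PCs.  The regionwise Bonferroni threshold is 0.05 / (number of SNPs
    tested).  Returns (results, threshold); results are empty when no gene
    is in the window.
    """
    chrom, pos = lead.chromosome, lead.position
    in_win = (panel.variants["CHR"].astype(str) == str(chrom)) & (
        (panel.variants["POS"] - pos).abs() <= window
    )
    snp_idx = np.flatnonzero(in_win.to_numpy())
    genes = list(expression.index)
    if gene_positions is not None:
        genes = [
            g
            for g in genes
            if g in gene_positions
            and str(gene_positions[g][0]) == str(chrom)
            and abs(gene_positions[g][1] - pos) <= window
        ]
    if not genes or len(snp_idx) == 0:
        return (
            pd.DataFrame(columns=["SNP", "gene", "SLOPE", "SE", "P"]),
            np.nan,
        )

    n = panel.n_samples
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    if n_pcs > 0:
        cols.append(genotype_pcs(panel, n_pcs))
    X = np.column_stack(cols)
    Q, _ = np.linalg.qr(X)
    p_cov = X.shape[1]
    dof = n - p_cov - 1

    rows = []
    for j in snp_idx:
        g = panel.dosages[:, j]
        g_r = g - Q @ (Q.T @ g)
        gg = float(g_r @ g_r)
        if gg <= 1e-12:
            continue
        for gene in genes:
            e = inverse_normal_transform(expression.loc[gene].to_numpy())
            e_r = e - Q @ (Q.T @ e)
            slope = float(g_r @ e_r) / gg
            rss = float(e_r @ e_r) - slope**2 * gg
            se = np.sqrt(max(rss, 0.0) / dof / gg)
            z = slope / se if se > 0 else np.inf * np.sign(slope)
            rows.append(
                {
                    "SNP": panel.variants["SNP"].iloc[j],
                    "gene": gene,
                    "SLOPE": slope,
                    "SE": se,
                    "P": 2.0 * stats.norm.sf(abs(z)),
                }
            )
    threshold = 0.05 / len(snp_idx)
    return pd.DataFrame(rows), threshold


def records_from_frame(df: pd.DataFrame) -> list[SummaryRecord]:
    """Convert a summary-statistics DataFrame into SummaryRecord objects."""
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SummaryRecord(
                variant=Variant(r.SNP, str(r.CHR), int(r.POS), r.EA, r.OA),
                eaf=float(r.EAF),
                beta=float(r.BETA),
                se=float(r.SE),
                p=float(r.P),
                n=int(r.N),
                info=float(getattr(r, "INFO", 1.0)),
                mac=float(getattr(r, "MAC", np.inf)),
            )
        )
    return out
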