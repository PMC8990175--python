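"""Residual population-stratification diagnostics for GWAS summary statistics.

The diagnostic correlates per-variant GWAS effect sizes with the loadings of
reference-panel principal components: under an unconfounded GWAS the
correlation is zero, while residual stratification along an axis of genetic
structure induces a nonzero correlation.  Inference uses a block jackknife
over consecutive genome blocks with equal variant counts (robust to local
LD), and the cross-dataset comparison tests the difference of two
correlations computed on the identical variant set with the same blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypePanel

DEFAULT_N_BLOCKS = 1000


@dataclass(frozen=True)
class PruneConfig:
    """Variant-thinning protocol applied before the reference PCA."""

    maf_min: float = 0.05  # strict >
    min_distance_bp: int = 2000
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.2
    exclusion_regions: tuple[tuple[str, int, int], ...] = ()  # half-open [start, end)

    def __post_init__(self) -> None:
        if min(self.maf_min, self.min_distance_bp, self.ld_window_snps,
               self.ld_step_snps, self.ld_r2_max) <= 0:
            raise ValueError("prune thresholds must be positive")


@dataclass
class StratReport:
    """Per-PC stratification diagnostics for one or two GWAS datasets."""

    rho: pd.DataFrame  # columns: dataset, pc, rho, se, p
    delta: pd.DataFrame | None  # columns: pc, delta_rho, se, p
    n_variants: int
    n_blocks: int


def prune_variants(panel: GenotypePanel, cfg: PruneConfig = PruneConfig()) -> list[str]:
    """Thin a panel's variants for PCA.

    Stages: (1) keep variants with MAF strictly above ``maf_min``;
    (2) greedy left-to-right distance pruning dropping any variant closer
    than ``min_distance_bp`` to the last kept one; (3) windowed LD pruning
    (windows of ``ld_window_snps`` advancing by ``ld_step_snps``; within a
    window, while any pair has r^2 > ``ld_r2_max``, remove the larger-index
    member of the worst pair); (4) drop variants inside exclusion regions.
    Raises with stage-by-stage counts if nothing survives.
    """
    snps = panel.variants["SNP"].to_numpy()
    chrom = panel.variants["CHR"].astype(str).to_numpy()
    pos = panel.variants["POS"].to_numpy()
    freqs = panel.alt_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    counts = {"input": len(snps)}

    keep = maf > cfg.maf_min
    counts["maf"] = int(keep.sum())

    idx = np.flatnonzero(keep)
    kept_dist = []
    last_chr, last_pos = None, None
    for i in idx:
        if chrom[i] != last_chr or pos[i] - last_pos >= cfg.min_distance_bp:
            kept_dist.append(i)
            last_chr, last_pos = chrom[i], pos[i]
    counts["distance"] = len(kept_dist)

    alive = set(kept_dist)
    order = list(kept_dist)
    G = panel.dosages
    start = 0
    while start < len(order):
        window = [i for i in order[start : start + cfg.ld_window_snps] if i in alive]
        if len(window) > 1:
            sub = G[:, window]
            sd = sub.std(axis=0, ddof=0)
            ok = sd > 0
            sub = (sub - sub.mean(axis=0)) / np.where(ok, sd, 1.0)
            r = (sub.T @ sub) / sub.shape[0]
            r2 = r**2
            np.fill_diagonal(r2, 0.0)
            local = list(range(len(window)))
            while True:
                mx = r2[np.ix_(local, local)].max() if len(local) > 1 else 0.0
                if mx <= cfg.ld_r2_max:
                    break
                sub_r2 = r2[np.ix_(local, local)]
                a, b = np.unravel_index(np.argmax(sub_r2), sub_r2.shape)
                drop_local = local[max(a, b)]
                alive.discard(window[drop_local])
                local = [l for l in local if l != drop_local]
        start += cfg.ld_step_snps
    counts["ld"] = len(alive)

    final = []
    for i in sorted(alive):
        excluded = any(
            chrom[i] == str(c) and s <= pos[i] < e
            for c, s, e in cfg.exclusion_regions
        )
        if not excluded:
            final.append(i)
    counts["exclusion"] = len(final)
    if not final:
        raise ValueError(f"no variants survive pruning; stage counts {counts}")
    return [snps[i] for i in final]


def run_pca(
    panel: GenotypePanel,
    variant_ids: list[str] | None = None,
    n_pcs: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered, frequency-standardized genotype matrix.

    Returns (sample scores n x n_pcs, eigenvalues).  Each PC is oriented so
    its largest-magnitude sample score is positive; rank-deficient panels
    return fewer PCs.
    """
    if panel.n_samples < 2 or panel.n_variants < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 variants")
    if variant_ids is not None:
        lookup = {s: i for i, s in enumerate(panel.variants["SNP"])}
        cols = [lookup[v] for v in variant_ids]
        G = panel.dosages[:, cols]
    else:
        G = panel.dosages
    freqs = G.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    ok = sd > 0
    Z = (np.asarray(G[:, ok], dtype=np.float64) - 2.0 * freqs[ok]) / sd[ok]
    # sample-space Gram trick: cheap when samples << variants
    gram = Z @ Z.T
    w, U = np.linalg.eigh(gram)
    w, U = w[::-1], U[:, ::-1]
    s = np.sqrt(np.clip(w, 0.0, None))
    tol = (s.max() if s.size else 0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    n_pcs = min(n_pcs, rank)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    eigvals = s[:n_pcs] ** 2 / (Z.shape[0] - 1)
    for j in range(n_pcs):
        i_max = np.argmax(np.abs(pcs[:, j]))
        if pcs[i_max, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs, eigvals


def pc_loadings(
    panel: GenotypePanel,
    pcs: np.ndarray,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant PC loadings: OLS slope of each PC score on allelic count.

    The counted allele is the panel's ALT allele, recorded in the output so
    GWAS betas can be harmonized before correlation.  Monomorphic variants
    are excluded.
    """
    if variant_ids is not None:
        lookup = {s: i for i, s in enumerate(panel.variants["SNP"])}
        cols = np.array([lookup[v] for v in variant_ids])
    else:
        cols = np.arange(panel.n_variants)
    G = panel.dosages[:, cols]
    gc = G - G.mean(axis=0)
    denom = np.einsum("ij,ij->j", gc, gc)
    poly = denom > 0
    pcs_c = pcs - pcs.mean(axis=0)
    slopes = (gc[:, poly].T @ pcs_c) / denom[poly, None]
    sub = panel.variants.iloc[cols[poly]]
    out = pd.DataFrame(
        slopes, columns=[f"PC{j + 1}" for j in range(pcs.shape[1])]
    )
    out.insert(0, "SNP", sub["SNP"].to_numpy())
    out.insert(1, "COUNTED", sub["ALT"].to_numpy())
    out.insert(2, "OTHER", sub["REF"].to_numpy())
    out.insert(3, "MAF", np.minimum(G.mean(axis=0)[poly] / 2, 1 - G.mean(axis=0)[poly] / 2))
    return out.reset_index(drop=True)


def _harmonized_betas(loadings: pd.DataFrame, gwas: pd.DataFrame,
                      maf_min: float) -> tuple[pd.DataFrame, np.ndarray]:
    """Inner-join loadings with a GWAS frame, flipping beta when the GWAS
    effect allele is the loading's other allele; returns (joined loadings,
    aligned betas) restricted to MAF > maf_min."""
    merged = loadings.merge(gwas[["SNP", "EA", "OA", "BETA"]], on="SNP", how="inner")
    same = (merged["EA"] == merged["COUNTED"]) & (merged["OA"] == merged["OTHER"])
    flipped = (merged["EA"] == merged["OTHER"]) & (merged["OA"] == merged["COUNTED"])
    merged = merged.loc[same | flipped].copy()
    sign = np.where(merged["EA"] == merged["COUNTED"], 1.0, -1.0)
    merged["BETA_H"] = merged["BETA"].to_numpy() * sign
    merged = merged.loc[merged["MAF"] > maf_min]
    return merged.reset_index(drop=True), merged["BETA_H"].to_numpy()


def loading_effect_correlation(
    loadings: pd.DataFrame,
    gwas: pd.DataFrame,
    maf_min: float = 0.01,
) -> pd.Series:
    """Pearson correlation of PC loadings with harmonized GWAS effect sizes,
    per PC, over intersecting variants with MAF > ``maf_min``."""
    merged, betas = _harmonized_betas(loadings, gwas, maf_min)
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} intersecting variants; need >= 10")
    pcs = [c for c in loadings.columns if c.startswith("PC")]
    return pd.Series(
        {pc: float(np.corrcoef(merged[pc], betas)[0, 1]) for pc in pcs}
    )


def default_n_blocks(m: int, requested: int = DEFAULT_N_BLOCKS) -> int:
    """Genome-scale runs use the requested block count; for small variant
    sets the count scales down to max(20, m // 100) so block sizes stay
    usable."""
    if m < 10_000:
        return min(max(20, m // 100), m)
    return min(requested, m)


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    """Consecutive blocks with equal variant counts, the remainder spread
    over the leading blocks."""
    base, rem = divmod(m, n_blocks)
    bounds, start = [], 0
    for b in range(n_blocks):
        size = base + (1 if b < rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def _jackknife_stat(x: np.ndarray, y: np.ndarray, n_blocks: int,
                    stat2: tuple[np.ndarray, np.ndarray] | None = None):
    """Delete-one-block jackknife of a Pearson correlation (or a difference
    of two correlations over the same blocks).

    Uses block partial sums so each leave-one-out correlation is O(1).
    Returns (estimate, jackknife SE, normal two-sided p).
    """
    m = len(x)
    if n_blocks > m:
        raise ValueError("more blocks than variants")
    bounds = _block_bounds(m, n_blocks)
    if min(e - s for s, e in bounds) < 1:
        raise ValueError("empty jackknife block")
    if m - max(e - s for s, e in bounds) < 10:
        raise ValueError("block deletion leaves < 10 variants")

    def corr_parts(a, b):
        S = {"n": float(m), "a": a.sum(), "b": b.sum(), "aa": (a * a).sum(),
             "bb": (b * b).sum(), "ab": (a * b).sum()}
        blocks = []
        for s, e in bounds:
            blocks.append(
                (e - s, a[s:e].sum(), b[s:e].sum(), (a[s:e] ** 2).sum(),
                 (b[s:e] ** 2).sum(), (a[s:e] * b[s:e]).sum())
            )
        return S, blocks

    def corr_from(S):
        cov = S["ab"] - S["a"] * S["b"] / S["n"]
        va = S["aa"] - S["a"] ** 2 / S["n"]
        vb = S["bb"] - S["b"] ** 2 / S["n"]
        if va <= 0 or vb <= 0:
            return 0.0
        return cov / np.sqrt(va * vb)

    def loo_stats(a, b):
        S, blocks = corr_parts(a, b)
        full = corr_from(S)
        loo = np.empty(n_blocks)
        for i, (cnt, sa, sb, saa, sbb, sab) in enumerate(blocks):
            Sd = {"n": S["n"] - cnt, "a": S["a"] - sa, "b": S["b"] - sb,
                  "aa": S["aa"] - saa, "bb": S["bb"] - sbb, "ab": S["ab"] - sab}
            loo[i] = corr_from(Sd)
        return full, loo

    full, loo = loo_stats(x, y)
    if stat2 is not None:
        full2, loo2 = loo_stats(*stat2)
        full, loo = full - full2, loo - loo2

    g = n_blocks
    se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
    if se == 0.0:
        p = 1.0 if full == 0.0 else np.finfo(float).tiny
    else:
        p = float(2.0 * stats.norm.sf(abs(full / se)))
    return float(full), se, max(p, np.finfo(float).tiny)


def jackknife_test(
    loadings: pd.DataFrame,
    gwas: pd.DataFrame,
    n_blocks: int = DEFAULT_N_BLOCKS,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Loading/effect-size correlation per PC with block-jackknife SE and p.

    Variants must be genome-ordered; blocks are consecutive runs with equal
    variant counts (remainder spread over leading blocks).
    """
    merged, betas = _harmonized_betas(loadings, gwas, maf_min)
    m = len(merged)
    if m < 10:
        raise ValueError("too few intersecting variants")
    g = default_n_blocks(m, n_blocks)
    pcs = [c for c in loadings.columns if c.startswith("PC")]
    rows = []
    for pc in pcs:
        rho, se, p = _jackknife_stat(merged[pc].to_numpy(), betas, g)
        rows.append({"pc": pc, "rho": rho, "se": se, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["n_variants"] = m
    out.attrs["n_blocks"] = g
    return out


def compare_correlations(
    gwas_a: pd.DataFrame,
    gwas_b: pd.DataFrame,
    loadings: pd.DataFrame,
    n_blocks: int = DEFAULT_N_BLOCKS,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Difference of loading/effect correlations between two GWAS datasets.

    Both datasets are restricted to the shared harmonized variant set; the
    jackknife deletes the same blocks from both correlations, so the SE of
    the difference accounts for their dependence.
    """
    shared = sorted(set(gwas_a["SNP"]) & set(gwas_b["SNP"]))
    a = gwas_a.loc[gwas_a["SNP"].isin(shared)]
    b = gwas_b.loc[gwas_b["SNP"].isin(shared)]
    ma, beta_a = _harmonized_betas(loadings, a, maf_min)
    mb, beta_b = _harmonized_betas(loadings, b, maf_min)
    common = sorted(set(ma["SNP"]) & set(mb["SNP"]))
    ma = ma.set_index("SNP").loc[common]
    mb = mb.set_index("SNP").loc[common]
    m = len(common)
    g = default_n_blocks(m, n_blocks)
    if m < max(10, 10 * g // DEFAULT_N_BLOCKS):
        raise ValueError("shared variant set too small for the block count")
    pcs = [c for c in loadings.columns if c.startswith("PC")]
    rows = []
    for pc in pcs:
        d, se, p = _jackknife_stat(
            ma[pc].to_numpy(), ma["BETA_H"].to_numpy(), g,
            stat2=(mb[pc].to_numpy(), mb["BETA_H"].to_numpy()),
        )
        rows.append({"pc": pc, "delta_rho": d, "se": se, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["n_variants"] = m
    out.attrs["n_blocks"] = g
    return out


def strat_report(
    panel: GenotypePanel,
    gwas_frames: dict[str, pd.DataFrame],
    n_pcs: int = 5,
    n_blocks: int = DEFAULT_N_BLOCKS,
    prune: PruneConfig | None = PruneConfig(),
    compare: tuple[str, str] | None = None,
) -> StratReport:
    """End-to-end stratification diagnostic over a reference panel.

    Prunes the panel, runs PCA, computes loadings, then the per-PC
    jackknifed correlation for every supplied GWAS frame; optionally the
    jackknifed difference between a named pair of datasets.
    """
    ids = prune_variants(panel, prune) if prune is not None else None
    pcs, _ = run_pca(panel, variant_ids=ids, n_pcs=n_pcs)
    loadings = pc_loadings(panel, pcs)  # loadings over all polymorphic variants
    rho_rows = []
    n_variants = 0
    g = n_blocks
    for name, frame in gwas_frames.items():
        res = jackknife_test(loadings, frame, n_blocks=n_blocks)
        n_variants = res.attrs["n_variants"]
        g = res.attrs["n_blocks"]
        for r in res.itertuples(index=False):
            rho_rows.append({"dataset": name, "pc": r.pc, "rho": r.rho,
                             "se": r.se, "p": r.p})
    delta = None
    if compare is not None:
        delta = compare_correlations(
            gwas_frames[compare[0]], gwas_frames[compare[1]], loadings,
            n_blocks=n_blocks,
        )
    return StratReport(
        rho=pd.DataFrame(rho_rows), delta=delta,
        n_variants=n_variants, n_blocks=g,
    )
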