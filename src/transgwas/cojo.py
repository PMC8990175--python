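"""Approximate joint and conditional analysis from GWAS summary statistics.

Reconstructs multiple-regression normal equations from marginal per-variant
betas, SEs, allele frequencies and sample sizes plus a reference LD matrix
(optionally a sample-size-weighted average of per-ancestry matrices):

    X'X[j,k] ~= r_jk * sqrt(D_j D_k),   D_j = n_j * var(x_j),
    X'y[j]   =  D_j * beta_j,

with var(x_j) = 2 p_j (1 - p_j) under Hardy-Weinberg unless the LD matrix
carries observed genotype variances.  The phenotypic variance is estimated
as the median of se_j^2 * n_j * var(x_j) across variants.  Forward stepwise
selection at a p-value threshold and conditioning of target variants on a
known-SNP set both reuse the same reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LdMatrix, psd_repair

GW_THRESHOLD = 5e-8


@dataclass
class JointModelResult:
    selected: list[str]
    joint_beta: np.ndarray
    joint_se: np.ndarray
    joint_p: np.ndarray
    log: list[str] = field(default_factory=list)


def weighted_ld(mats: list[LdMatrix], weights: list[float]) -> LdMatrix:
    """Elementwise sample-size-weighted mean of LD matrices over identical
    variant lists; diagonal reset to 1 and PSD repair applied."""
    if not mats:
        raise ValueError("no LD matrices supplied")
    vlist = mats[0].variants
    for m in mats[1:]:
        if m.variants != vlist:
            raise ValueError("LD matrices must cover identical variant lists")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    r = sum(wi * m.r for wi, m in zip(w, mats))
    np.fill_diagonal(r, 1.0)
    r = psd_repair(r) if np.linalg.eigvalsh(r).min() < -1e-6 else r
    gv = None
    if all(m.geno_var is not None for m in mats):
        gv = sum(wi * m.geno_var for wi, m in zip(w, mats))
    return LdMatrix(
        variants=list(vlist),
        r=np.clip(r, -1.0, 1.0),
        ref_n=int(sum(m.ref_n for m in mats)),
        provenance="+".join(m.provenance for m in mats),
        geno_var=gv,
    )


class _Region:
    """Aligned summary statistics + LD for one region."""

    def __init__(self, records: pd.DataFrame, ld: LdMatrix):
        order = {v: i for i, v in enumerate(ld.variants)}
        missing = [s for s in records["SNP"] if s not in order]
        self.dropped = missing
        df = records.loc[records["SNP"].isin(order)].copy()
        df["_ld"] = df["SNP"].map(order)
        df = df.sort_values("_ld")
        self.snps = df["SNP"].tolist()
        idx = df["_ld"].to_numpy()
        self.r = ld.r[np.ix_(idx, idx)]
        self.beta = df["BETA"].to_numpy(dtype=float)
        self.se = df["SE"].to_numpy(dtype=float)
        self.n = df["N"].to_numpy(dtype=float)
        eaf = df["EAF"].to_numpy(dtype=float)
        if ld.geno_var is not None:
            self.var_x = np.asarray(ld.geno_var)[idx]
        else:
            self.var_x = 2.0 * eaf * (1.0 - eaf)
        self.D = self.n * self.var_x
        self.var_y = float(np.median(self.se**2 * self.D))
        self.p = df["P"].to_numpy(dtype=float)
        self.pos = {s: i for i, s in enumerate(self.snps)}

    def joint_fit(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Approximate joint estimates for a set of variants."""
        idx = np.array([self.pos[s] for s in ids])
        D = self.D[idx]
        XtX = self.r[np.ix_(idx, idx)] * np.sqrt(np.outer(D, D))
        Xty = D * self.beta[idx]
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular joint-model reconstruction")
        b = XtX_inv @ Xty
        n_eff = float(np.median(self.n[idx]))
        dof = max(n_eff - len(ids) - 1, 1.0)
        sigma2 = (self.var_y * n_eff - float(b @ Xty)) / dof
        sigma2 = max(sigma2, 1e-12)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        p = 2.0 * stats.norm.sf(np.abs(b / se))
        return b, se, p


def stepwise_select(
    records: pd.DataFrame,
    ld: LdMatrix,
    p_enter: float = GW_THRESHOLD,
    collinearity_r2: float = 0.9,
) -> JointModelResult:
    """Forward stepwise model selection from summary statistics.

    Starts from the smallest marginal p-value; at each step refits the
    joint model of the selected set plus each candidate, admitting the
    candidate with the smallest joint p if it is below ``p_enter`` and its
    reference r^2 with every selected variant is below ``collinearity_r2``.
    After each admission the joint model is refit; any previously selected
    variant whose joint p rises above ``p_enter`` is dropped (backward
    step).  Output is invariant to the input record order.
    """
    reg = _Region(records, ld)
    log = [f"dropped_from_ld:{s}" for s in reg.dropped]
    selected: list[str] = []
    if not reg.snps:
        return JointModelResult(selected, np.array([]), np.array([]), np.array([]), log)

    order = np.argsort(reg.p, kind="mergesort")
    start = order[0]
    if reg.p[start] >= p_enter:
        return JointModelResult(selected, np.array([]), np.array([]), np.array([]), log)
    selected.append(reg.snps[start])

    while True:
        sel_idx = [reg.pos[s] for s in selected]
        best = None
        for j, snp in enumerate(reg.snps):
            if snp in selected:
                continue
            r2 = reg.r[j, sel_idx] ** 2
            if r2.max() >= collinearity_r2:
                continue
            try:
                b, se, p = reg.joint_fit(selected + [snp])
            except np.linalg.LinAlgError:
                log.append(f"singular_skip:{snp}")
                continue
            if p[-1] < p_enter and (best is None or p[-1] < best[1]):
                best = (snp, p[-1])
        if best is None:
            break
        selected.append(best[0])
        # backward pass: drop anything no longer significant jointly
        while len(selected) > 1:
            b, se, p = reg.joint_fit(selected)
            worst = int(np.argmax(p))
            if p[worst] >= p_enter:
                log.append(f"backward_drop:{selected[worst]}")
                selected.pop(worst)
            else:
                break

    b, se, p = reg.joint_fit(selected)
    ord_sel = sorted(range(len(selected)), key=lambda i: reg.pos[selected[i]])
    selected = [selected[i] for i in ord_sel]
    return JointModelResult(selected, b[ord_sel], se[ord_sel], p[ord_sel], log)


def condition_on_known(
    targets: list[str],
    known: list[str],
    ld: LdMatrix,
    records: pd.DataFrame,
    collinearity_r2: float = 0.9,
    gw_threshold: float = GW_THRESHOLD,
) -> pd.DataFrame:
    """Approximate conditional estimates of target variants given known SNPs.

    Each target is added to the joint model of the known set; its joint
    coefficient is the conditional estimate.  Targets collinear with the
    known set (r^2 >= ``collinearity_r2``) are flagged and get NaN
    estimates; a target that is itself in the known set is flagged
    'in_known'.  ``new_signal`` marks conditioned p < genome-wide
    significance.  Conditioning on an empty known set is the identity.
    """
    reg = _Region(records, ld)
    known_in = [kv for kv in known if kv in reg.pos]
    rows = []
    for t in targets:
        if t in known_in:
            rows.append(
                {"SNP": t, "BETA_C": np.nan, "SE_C": np.nan, "P_C": np.nan,
                 "flag": "in_known", "new_signal": False}
            )
            continue
        if t not in reg.pos:
            rows.append(
                {"SNP": t, "BETA_C": np.nan, "SE_C": np.nan, "P_C": np.nan,
                 "flag": "absent", "new_signal": False}
            )
            continue
        if not known_in:
            j = reg.pos[t]
            rows.append(
                {"SNP": t, "BETA_C": reg.beta[j], "SE_C": reg.se[j],
                 "P_C": reg.p[j], "flag": "", "new_signal": reg.p[j] < gw_threshold}
            )
            continue
        j = reg.pos[t]
        kidx = [reg.pos[kv] for kv in known_in]
        if (reg.r[j, kidx] ** 2).max() >= collinearity_r2:
            rows.append(
                {"SNP": t, "BETA_C": np.nan, "SE_C": np.nan, "P_C": np.nan,
                 "flag": "collinear", "new_signal": False}
            )
            continue
        try:
            b, se, p = reg.joint_fit(known_in + [t])
        except np.linalg.LinAlgError:
            rows.append(
                {"SNP": t, "BETA_C": np.nan, "SE_C": np.nan, "P_C": np.nan,
                 "flag": "singular", "new_signal": False}
            )
            continue
        rows.append(
            {"SNP": t, "BETA_C": float(b[-1]), "SE_C": float(se[-1]),
             "P_C": float(p[-1]), "flag": "", "new_signal": bool(p[-1] < gw_threshold)}
        )
    return pd.DataFrame(rows)


def read_ma(path: str) -> pd.DataFrame:
    """Read a GCTA '.ma'-style file (SNP A1 A2 freq b se p N) into the
    package's summary-statistics column convention."""
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    return pd.DataFrame(
        {
            "SNP": df["snp"],
            "EA": df["a1"],
            "OA": df["a2"],
            "EAF": df["freq"],
            "BETA": df["b"],
            "SE": df["se"],
            "P": df["p"],
            "N": df["n"],
        }
    )
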