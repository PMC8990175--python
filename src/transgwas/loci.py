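"""Locus-level decision rules: lead/proxy selection, novel-vs-established
classification, replication and transferability verdicts, and the
directional-consistency binomial test.

A locus is "established" when the lead falls within +-500 kb (inclusive) of
any previously published index SNP for the same trait; otherwise it is a
newly discovered locus.  Replication of a two-stage discovery requires
genome-wide significance in stage 1, directional consistency in stage 2,
and an improved p-value after combining the stages.  Transferability of a
known signal to another ancestry requires directional consistency, nominal
significance, and cross-study heterogeneity I^2 < 75%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import SummaryRecord, Variant
from .ld import LdMatrix
from .meta import MetaRecord

GW_THRESHOLD = 5e-8


@dataclass(frozen=True)
class KnownIndex:
    """A previously published trait-specific index SNP."""

    trait: str
    variant: Variant
    source: str = ""


@dataclass
class LocusCall:
    lead: MetaRecord
    locus_class: str  # "novel" | "established"
    novelty_status: str  # "novel" | "not-novel" | "untested"
    transfer_flags: dict[str, str]


def select_leads(
    records: pd.DataFrame,
    gw_threshold: float = GW_THRESHOLD,
    ld: LdMatrix | None = None,
    window: int = 500_000,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy selection of independent genome-wide-significant lead variants.

    Repeatedly takes the smallest-p GWS record (ties broken by smaller
    position) and removes all GWS records on the same chromosome within
    ``window`` bp of it, or with reference r^2 >= ``r2_max`` to it.
    """
    gws = records.loc[records["P"] < gw_threshold].copy()
    gws = gws.sort_values(["P", "POS"], kind="mergesort")
    leads: list[str] = []
    r2 = None
    if ld is not None:
        r2 = pd.DataFrame(ld.r**2, index=ld.variants, columns=ld.variants)
    while len(gws):
        top = gws.iloc[0]
        leads.append(top["SNP"])
        same_chr = gws["CHR"].astype(str) == str(top["CHR"])
        near = same_chr & ((gws["POS"] - top["POS"]).abs() <= window)
        linked = pd.Series(False, index=gws.index)
        if r2 is not None and top["SNP"] in r2.index:
            in_ld = gws["SNP"].isin(r2.index)
            linked.loc[in_ld] = (
                r2.loc[top["SNP"], gws.loc[in_ld, "SNP"]].to_numpy() >= r2_max
            )
        gws = gws.loc[~(near | linked) & (gws["SNP"] != top["SNP"])]
    return leads


def select_proxies(
    lead: str,
    ld: LdMatrix,
    positions: dict[str, int] | None = None,
    r2_min: float = 0.9,
    k: int = 2,
) -> list[str]:
    """Up to ``k`` best proxies with r^2 >= ``r2_min`` to the lead.

    The lead itself is excluded; ties on r^2 are broken by distance to the
    lead (when positions are supplied) then by variant id.
    """
    i = ld.index_of(lead)
    r2 = ld.r[i] ** 2
    cands = []
    for j, v in enumerate(ld.variants):
        if v == lead or r2[j] < r2_min:
            continue
        dist = abs(positions[v] - positions[lead]) if positions else 0
        cands.append((-r2[j], dist, v))
    cands.sort()
    return [v for _, _, v in cands[:k]]


def classify_locus(
    lead: Variant,
    known: list[KnownIndex],
    window: int = 500_000,
) -> str:
    """'established' iff any same-trait known index SNP lies on the same
    chromosome within +-window bp (inclusive); otherwise 'novel'."""
    for ki in known:
        if str(ki.variant.chromosome) == str(lead.chromosome) and abs(
            ki.variant.position - lead.position
        ) <= window:
            return "established"
    return "novel"


def _sign(x: float) -> int:
    return int(np.sign(x))


def assess_novelty_two_stage(
    stage1: MetaRecord | SummaryRecord,
    stage2: MetaRecord | SummaryRecord | None,
    combined: MetaRecord | SummaryRecord | None,
    gw_threshold: float = GW_THRESHOLD,
) -> str:
    """Two-stage replication verdict: 'novel' iff stage 1 is genome-wide
    significant, stage 2 is directionally consistent, and adding stage 2
    improves the p-value."""
    if stage2 is None or combined is None or not np.isfinite(getattr(stage2, "beta", np.nan)):
        return "untested"
    ok = (
        stage1.p < gw_threshold
        and _sign(stage1.beta) == _sign(stage2.beta)
        and combined.p < stage1.p
    )
    return "novel" if ok else "not-novel"


def assess_novelty_transancestral(
    conditioned: MetaRecord | SummaryRecord,
    replication: SummaryRecord | None,
    gw_threshold: float = GW_THRESHOLD,
    rep_threshold: float = 5e-2,
) -> str:
    """Trans-ancestral novelty verdict: conditioned meta-analysis result at
    genome-wide significance plus a directionally consistent, nominally
    significant independent replication."""
    if replication is None or not np.isfinite(getattr(replication, "beta", np.nan)):
        return "untested"
    ok = (
        conditioned.p < gw_threshold
        and _sign(conditioned.beta) == _sign(replication.beta)
        and replication.p < rep_threshold
    )
    return "novel" if ok else "not-novel"


def assess_transferability(
    ref: MetaRecord | SummaryRecord,
    target: SummaryRecord | None,
    i2_target: float = 0.0,
    alpha: float = 0.05,
    i2_max: float = 75.0,
) -> str:
    """Transferability of a reference signal into a target population:
    same effect direction, target p < alpha, and I^2 < i2_max."""
    if target is None or not np.isfinite(getattr(target, "beta", np.nan)):
        return "untested"
    ok = (
        _sign(ref.beta) == _sign(target.beta)
        and target.p < alpha
        and i2_target < i2_max
    )
    return "transferable" if ok else "not-transferable"


def tally_transferability(
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    i2_max: float = 75.0,
) -> dict[str, float]:
    """Tally transferable known index SNPs in a lookup population.

    ``stats_df`` has one row per tested known index SNP, harmonized to the
    published effect allele, with columns BETA (lookup effect), KNOWN_SIGN
    (published direction, +-1), P, and optionally I2 (default 0).  A SNP is
    nominally transferable when directionally consistent with the published
    direction, p < alpha, and I^2 < i2_max; Bonferroni-transferable when
    additionally p < alpha / tested.  The percentage is 100*nominal/tested
    rounded to 1 decimal.
    """
    tested = len(stats_df)
    if tested == 0:
        raise ValueError("no known index SNPs tested")
    i2 = stats_df["I2"].to_numpy() if "I2" in stats_df.columns else np.zeros(tested)
    consistent = np.sign(stats_df["BETA"].to_numpy()) == np.sign(
        stats_df["KNOWN_SIGN"].to_numpy()
    )
    nominal_mask = consistent & (stats_df["P"].to_numpy() < alpha) & (i2 < i2_max)
    bonf_mask = nominal_mask & (stats_df["P"].to_numpy() < alpha / tested)
    nominal = int(nominal_mask.sum())
    return {
        "tested": tested,
        "nominal": nominal,
        "bonferroni": int(bonf_mask.sum()),
        "percentage": transferability_percentage(nominal, tested),
    }


def transferability_percentage(nominal: int, tested: int) -> float:
    """Percentage of tested known loci that transferred, to 1 decimal."""
    if tested == 0:
        raise ValueError("tested must be >= 1")
    return round(100.0 * nominal / tested, 1)


def binomial_consistency(n_consistent: int, n_total: int) -> float:
    """Exact two-sided binomial test of directional consistency at p0 = 0.5.

    Sums all outcome probabilities no larger than that of the observed
    count (the standard exact two-sided construction).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_consistent <= n_total):
        raise ValueError("n_consistent out of range")
    return float(stats.binomtest(n_consistent, n_total, 0.5).pvalue)
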