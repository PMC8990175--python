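"""Bayesian fine-mapping of association regions from summary statistics.

For a region with marginal z-scores z and reference LD R, a causal
configuration S has

    z | S  ~  N(0, R_SS + n * w * R_SS @ R_SS)   restricted to S,

versus z | null ~ N(0, R_SS): the standard summary-statistic Bayesian
variable-selection likelihood, evaluated on the |S|-dimensional system by
Cholesky factorization.  For a single variant in LD-free surroundings this
reduces to the familiar approximate Bayes factor with shrinkage factor
n*w/(1 + n*w).  Configuration priors are binomial on the number of causal
variants (expected one causal per region), uniform over subsets of a given
size.  Posteriors come either from exhaustive enumeration (small regions)
or from a shotgun stochastic search over add/delete/swap neighborhoods
that retains every evaluated configuration's score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .ld import LdMatrix, psd_repair


@dataclass
class RegionData:
    """One fine-mapping region: z-scores, LD, effective n, prior settings."""

    variants: list[str]
    z: np.ndarray
    ld: LdMatrix
    n: float
    max_k: int = 10
    prior_w: float = 0.05**2  # prior variance of standardized effects

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) != len(self.variants) or len(self.variants) != len(self.ld.variants):
            raise ValueError("z, variants and LD dimensions disagree")
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")

    @property
    def p(self) -> int:
        return len(self.variants)


@dataclass
class FinemapResult:
    configs: list[tuple[tuple[int, ...], float]]  # sorted by posterior, desc
    pip: np.ndarray
    credible_sets: list[list[int]]
    k_posterior: np.ndarray
    converged: bool = True
    cs_complete: bool = True

    def top_config(self) -> tuple[int, ...]:
        return self.configs[0][0]


def _log_prior_k(p: int, max_k: int) -> np.ndarray:
    """Truncated Binomial(p, 1/p) prior over the number of causal variants."""
    ks = np.arange(0, max_k + 1)
    logpmf = stats.binom.logpmf(ks, p, 1.0 / p)
    return logpmf - logsumexp(logpmf)


def _log_choose(p: int, k: int) -> float:
    return float(gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1))


def config_log_bf(region: RegionData, subset: tuple[int, ...]) -> float:
    """Log Bayes factor of a causal configuration against the null.

    ``subset`` indexes region variants.  Empty subsets give 0 by definition.
    Singular LD submatrices are repaired by eigenvalue clipping.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    if k > region.max_k:
        raise ValueError("subset larger than max_k")
    idx = np.asarray(subset)
    R = region.ld.r[np.ix_(idx, idx)]
    zs = region.z[idx]
    nw = region.n * region.prior_w
    cov0 = R
    cov1 = R + nw * (R @ R)

    def _logpdf(x: np.ndarray, cov: np.ndarray) -> float:
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = psd_repair(cov) + 1e-8 * np.eye(len(x))
            L = np.linalg.cholesky(cov)
        u = np.linalg.solve(L, x)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return float(-0.5 * (len(x) * np.log(2 * np.pi) + logdet + u @ u))

    return _logpdf(zs, cov1) - _logpdf(zs, cov0)


def _log_posterior_unnorm(region: RegionData, subset: tuple[int, ...],
                          log_prior_k: np.ndarray) -> float:
    k = len(subset)
    return config_log_bf(region, subset) + log_prior_k[k] - _log_choose(region.p, k)


def _result_from_scores(
    region: RegionData,
    scores: dict[tuple[int, ...], float],
    converged: bool = True,
) -> FinemapResult:
    configs = list(scores.keys())
    logs = np.array([scores[c] for c in configs])
    post = np.exp(logs - logsumexp(logs))
    order = np.argsort(-post, kind="mergesort")
    sorted_configs = [(configs[i], float(post[i])) for i in order]

    pip = np.zeros(region.p)
    k_post = np.zeros(region.max_k + 1)
    for c, pr in zip(configs, post):
        for j in c:
            pip[j] += pr
        k_post[len(c)] += pr

    top = sorted_configs[0][0]
    credible_sets, complete = _signal_credible_sets(region, scores, top)
    return FinemapResult(
        configs=sorted_configs,
        pip=pip,
        credible_sets=credible_sets,
        k_posterior=k_post,
        converged=converged,
        cs_complete=complete,
    )


def _signal_credible_sets(
    region: RegionData,
    scores: dict[tuple[int, ...], float],
    top: tuple[int, ...],
) -> tuple[list[list[int]], bool]:
    """95% credible set per signal of the top configuration.

    For each slot s of the top configuration, the posterior over which
    variant fills it -- conditional on the remaining top-configuration
    variants -- is read off the evaluated configurations; the credible set
    is the smallest posterior-sorted prefix reaching 0.95.
    """
    if len(top) == 0:
        return [], True
    sets, complete = [], True
    for s in top:
        others = tuple(sorted(set(top) - {s}))
        probs = np.zeros(region.p)
        for c, lp in scores.items():
            if len(c) == len(top) and set(others) <= set(c):
                extra = set(c) - set(others)
                if len(extra) == 1:
                    probs[extra.pop()] += np.exp(lp)
        if probs.sum() <= 0:
            sets.append([s])
            continue
        probs = probs / probs.sum()
        cs, ok = credible_set(probs, threshold=0.95)
        sets.append(cs)
        complete &= ok
    return sets, complete


def credible_set(
    posteriors: np.ndarray,
    threshold: float = 0.95,
) -> tuple[list[int], bool]:
    """Smallest posterior-sorted prefix whose cumulative mass reaches the
    threshold.  Returns (member indices, reached_threshold); when the total
    mass falls short, the whole support is returned flagged."""
    p = np.asarray(posteriors, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    order = np.argsort(-p, kind="mergesort")
    cum = np.cumsum(p[order])
    if cum[-1] < threshold:
        return [int(i) for i in order if p[i] > 0], False
    stop = int(np.searchsorted(cum, threshold) + 1)
    return [int(i) for i in order[:stop]], True


def exhaustive_posterior(region: RegionData, enum_limit: int = 20) -> FinemapResult:
    """Posterior over all configurations with |S| <= max_k by enumeration.

    Only feasible for small regions (p <= ``enum_limit``); larger regions
    should use :func:`shotgun_search`.
    """
    if region.p > enum_limit:
        raise ValueError(
            f"{region.p} variants exceed the enumeration limit {enum_limit}; "
            "use shotgun_search"
        )
    lpk = _log_prior_k(region.p, region.max_k)
    scores: dict[tuple[int, ...], float] = {}
    for k in range(0, min(region.max_k, region.p) + 1):
        for subset in itertools.combinations(range(region.p), k):
            scores[subset] = _log_posterior_unnorm(region, subset, lpk)
    return _result_from_scores(region, scores)


def shotgun_search(
    region: RegionData,
    iterations: int = 20_000,
    seed: int = 0,
    fixed_k: int | None = None,
) -> FinemapResult:
    """Shotgun stochastic search over causal configurations.

    Moves add, delete, or swap one variant; every evaluated configuration's
    score is retained and the posterior is renormalized over the evaluated
    set.  The next configuration is sampled from the current neighborhood
    proportionally to posterior mass.  Deterministic given the seed.  The
    search is flagged unconverged when the top configuration changes during
    the final quarter of the iterations (or when iterations == 0, where
    only the null and single-variant configurations are scored).
    ``fixed_k`` restricts the search to configurations of exactly that size
    (plus the seeded null/singles), supporting the conditional fallback.
    """
    rng = np.random.default_rng(seed)
    lpk = _log_prior_k(region.p, region.max_k)
    scores: dict[tuple[int, ...], float] = {}

    def score(c: tuple[int, ...]) -> float:
        if c not in scores:
            scores[c] = _log_posterior_unnorm(region, c, lpk)
        return scores[c]

    score(())
    for j in range(region.p):
        score((j,))

    if region.p == 0:
        return _result_from_scores(region, scores, converged=True)

    current = max(scores, key=scores.get)
    if fixed_k is not None and fixed_k > 0:
        base = max(((j,) for j in range(region.p)), key=lambda c: scores[c])
        cur = set(base)
        remaining = [j for j in range(region.p) if j not in cur]
        extra = rng.permutation(remaining)[: max(0, fixed_k - 1)]
        current = tuple(sorted(cur | set(int(e) for e in extra)))
        score(current)

    top = max(scores, key=scores.get)
    last_top_change = 0
    for it in range(iterations):
        cur = set(current)
        neighbors: list[tuple[int, ...]] = []
        k = len(cur)
        allow_resize = fixed_k is None
        if allow_resize and k < min(region.max_k, region.p):
            for j in range(region.p):
                if j not in cur:
                    neighbors.append(tuple(sorted(cur | {j})))
        if allow_resize and k > 0:
            for j in cur:
                neighbors.append(tuple(sorted(cur - {j})))
        if k > 0:
            for j in cur:
                without = cur - {j}
                for l in range(region.p):
                    if l not in cur:
                        neighbors.append(tuple(sorted(without | {l})))
        if not neighbors:
            break
        logs = np.array([score(c) for c in neighbors])
        probs = np.exp(logs - logsumexp(logs))
        current = neighbors[rng.choice(len(neighbors), p=probs)]
        new_top = max(scores, key=scores.get)
        if new_top != top:
            top = new_top
            last_top_change = it + 1

    converged = iterations > 0 and last_top_change < (3 * iterations) // 4
    return _result_from_scores(region, scores, converged=converged)


def conditional_fallback(
    region: RegionData,
    p_enter: float = 5e-8,
    collinearity_r2: float = 0.9,
) -> int:
    """Number of causal variants by stepwise conditioning inside the region.

    Greedy selection on conditional z-scores at the genome-wide threshold:
    the count of selected variants is the k at which a fixed-size search
    can then be run.
    """
    z = region.z.copy()
    R = region.ld.r
    selected: list[int] = []
    z_thresh = stats.norm.isf(p_enter / 2.0)
    while len(selected) < min(region.max_k, region.p):
        cond_z = _conditional_z(z, R, selected, collinearity_r2)
        j = int(np.nanargmax(np.abs(cond_z))) if np.any(np.isfinite(cond_z)) else -1
        if j < 0 or not np.isfinite(cond_z[j]) or abs(cond_z[j]) < z_thresh:
            break
        selected.append(j)
    return len(selected)


def _conditional_z(
    z: np.ndarray,
    R: np.ndarray,
    selected: list[int],
    collinearity_r2: float,
) -> np.ndarray:
    """z-scores of all variants conditional on a selected set."""
    p = len(z)
    out = np.full(p, np.nan)
    if not selected:
        out[:] = z
        return out
    S = np.asarray(selected)
    Rss = R[np.ix_(S, S)] + 1e-10 * np.eye(len(S))
    Rss_inv = np.linalg.inv(Rss)
    zs = z[S]
    for j in range(p):
        if j in selected:
            continue
        rj = R[j, S]
        if np.max(rj**2) >= collinearity_r2:
            continue
        resid_var = 1.0 - float(rj @ Rss_inv @ rj)
        if resid_var <= 1e-8:
            continue
        out[j] = (z[j] - float(rj @ Rss_inv @ zs)) / np.sqrt(resid_var)
    return out
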