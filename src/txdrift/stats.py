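"""Statistical tests applied to drift and phenotype tables.

The dispersion comparison at the heart of drift analysis is the robust
Levene (Brown-Forsythe family) test: each observation is replaced by its
absolute deviation from a robust group center — by default a 10% trimmed
mean, which discards the most extreme drift values before centering — and a
one-way ANOVA on those deviations tests equality of spread.  The remaining
machinery (Welch t, exact binomial, Spearman, Benjamini-Hochberg) is the
standard toolkit used around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .drift import DriftMatrix
from .io import DataError

P_FLOOR = 1e-300  # smallest p reported; extreme tails are floored, never 0


class StatsError(ValueError):
    """A statistical operation received unusable input."""


@dataclass
class LeveneResult:
    W: float
    df_between: int
    df_within: int
    p_value: float
    center: str
    trim_fraction: float


@dataclass
class TTestResult:
    t: float
    df: float
    p_value: float
    variant: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    degenerate: bool = False


@dataclass
class AttenuationResult:
    """Per-gene attenuation calls for a treated vs control contrast."""

    per_gene_calls: dict[str, bool]  # True = attenuated
    k_attenuated: int
    n_total: int
    binomial_p: float
    rule: str
    ages_aggregated: list[float]


@dataclass
class OverlapResult:
    k_both: int
    n_shared: int
    binomial_p: float


def _center(values: np.ndarray, center: str, trim_fraction: float) -> float:
    if center == "mean":
        return float(values.mean())
    if center == "median":
        return float(np.median(values))
    if center == "trimmed_mean":
        # trim_fraction removed from EACH tail before averaging
        if int(len(values) * trim_fraction) * 2 >= len(values):
            raise StatsError("trim fraction empties a group")
        return float(scipy.stats.trim_mean(values, trim_fraction))
    raise StatsError(f"unknown center {center!r}")


def robust_levene(
    groups: Sequence[Sequence[float]],
    center: Literal["trimmed_mean", "median", "mean"] = "trimmed_mean",
    trim_fraction: float = 0.10,
) -> LeveneResult:
    """Robust Levene test of equal dispersion across groups.

    ``center='median'`` with ``trim_fraction=0`` is the classical
    Brown-Forsythe test; ``center='mean'`` the classical Levene test.  The
    default 10% trimmed-mean center removes large outliers from the center
    estimate while keeping every observation in the deviations, making the
    test robust for long-tailed drift distributions.
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise StatsError("every group needs at least 2 values")
    if not 0 <= trim_fraction < 0.5:
        raise StatsError("trim_fraction must be in [0, 0.5)")
    devs = [np.abs(a - _center(a, center, trim_fraction)) for a in arrays]
    k = len(devs)
    n = sum(len(d) for d in devs)
    grand = np.concatenate(devs).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        w = 0.0 if ss_between == 0 else math.inf
    else:
        w = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(w, df_b, df_w)) if math.isfinite(w) else 0.0
    return LeveneResult(
        W=float(w),
        df_between=df_b,
        df_within=df_w,
        p_value=max(p, P_FLOOR) if w > 0 else 1.0,
        center=center,
        trim_fraction=trim_fraction,
    )


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: Literal["welch", "pooled"] = "welch",
) -> TTestResult:
    """Two-sided unpaired t-test (Welch unequal-variance by default)."""
    x, y = np.asarray(a, float), np.asarray(b, float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs at least 2 values")
    if variant not in ("welch", "pooled"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = len(x) + len(y) - 2
        return TTestResult(0.0, df, 1.0, variant, x.mean(), y.mean(), 0.0, 0.0, degenerate=True)
    res = scipy.stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        sd_a=float(x.std(ddof=1)),
        sd_b=float(y.std(ddof=1)),
    )


def _log_binom_tails(k: int, n: int, p0: float) -> tuple[float, float]:
    """log P(X <= k) and log P(X >= k) by log-space summation of the pmf."""
    ks = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * math.log(p0)
        + (n - ks) * math.log1p(-p0)
    )
    lower = float(logsumexp(logpmf[: k + 1]))
    upper = float(logsumexp(logpmf[k:]))
    return min(lower, 0.0), min(upper, 0.0)


def binomial_test_exact(
    k: int,
    n: int,
    p0: float = 0.5,
    sided: Literal["two", "one"] = "two",
) -> float:
    """Exact binomial test, computed in log space so extreme tails never
    underflow to zero (p-values are floored at 1e-300).

    Two-sided p is twice the smaller exact tail, capped at 1 — which at
    p0 = 0.5 coincides with summing all outcomes as or less likely than k.
    One-sided p is the smaller tail.
    """
    if not (0 <= k <= n):
        raise StatsError(f"k={k} outside [0, n={n}]")
    if not 0 < p0 < 1:
        raise StatsError("p0 must be in (0, 1)")
    lo, hi = _log_binom_tails(int(k), int(n), p0)
    log_tail = min(lo, hi)
    log_p = log_tail + (math.log(2) if sided == "two" else 0.0)
    log_p = min(log_p, 0.0)
    return max(math.exp(log_p), P_FLOOR)


def _per_age_mean_abs(
    d: DriftMatrix, sample_ages: Mapping[str, float], ages: Sequence[float]
) -> np.ndarray:
    """|mean td| per gene per age, averaging replicates within each age."""
    frame = d.to_frame()
    cols = []
    for age in ages:
        members = [s for s in d.sample_ids if sample_ages.get(s) == age]
        if not members:
            raise StatsError(f"no samples at age {age}")
        cols.append(np.abs(frame[members].mean(axis=1).to_numpy(float)))
    return np.column_stack(cols)  # genes x ages


def classify_attenuation(
    d_control: DriftMatrix,
    d_treated: DriftMatrix,
    ages_control: Mapping[str, float],
    ages_treated: Mapping[str, float],
    ages: Sequence[float] | None = None,
    rule: Literal["mean_abs_td", "per_age_majority"] = "mean_abs_td",
) -> AttenuationResult:
    """Call each gene attenuated or not under treatment, and test the split.

    A treatment attenuates a gene's age-associated change when the treated
    arm stays closer to the young reference than the age-matched control.
    Under ``mean_abs_td`` a gene is attenuated iff its |mean td| averaged
    over the shared ages is smaller in the treated arm; ``per_age_majority``
    instead requires the treated |mean td| to be smaller at a majority of
    ages.  The attenuated count k out of n genes is tested against the
    coin-flip null with the exact binomial test (p0 = 0.5, two-sided).
    """
    shared_genes = [g for g in d_control.gene_ids if g in set(d_treated.gene_ids)]
    if not shared_genes:
        raise StatsError("control and treated drift matrices share no genes")
    if ages is None:
        ages = sorted(
            {ages_control[s] for s in d_control.sample_ids if s in ages_control}
            & {ages_treated[s] for s in d_treated.sample_ids if s in ages_treated}
        )
    if not ages:
        raise StatsError("no shared ages between control and treated arms")
    idx_c = d_control.to_frame().index.get_indexer(shared_genes)
    idx_t = d_treated.to_frame().index.get_indexer(shared_genes)
    abs_c = _per_age_mean_abs(d_control, ages_control, ages)[idx_c]
    abs_t = _per_age_mean_abs(d_treated, ages_treated, ages)[idx_t]
    if rule == "mean_abs_td":
        attenuated = abs_t.mean(axis=1) < abs_c.mean(axis=1)
    elif rule == "per_age_majority":
        attenuated = (abs_t < abs_c).sum(axis=1) * 2 > len(ages)
    else:
        raise StatsError(f"unknown attenuation rule {rule!r}")
    calls = dict(zip(shared_genes, (bool(x) for x in attenuated)))
    k = int(attenuated.sum())
    n = len(shared_genes)
    return AttenuationResult(
        per_gene_calls=calls,
        k_attenuated=k,
        n_total=n,
        binomial_p=binomial_test_exact(k, n, 0.5, "two"),
        rule=rule,
        ages_aggregated=[float(a) for a in ages],
    )


def overlap_attenuation(res_a: AttenuationResult, res_b: AttenuationResult) -> OverlapResult:
    """Count genes attenuated in both contrasts over the shared gene universe
    and test that overlap against the coin-flip null."""
    shared = set(res_a.per_gene_calls) & set(res_b.per_gene_calls)
    if not shared:
        raise StatsError("attenuation results share no genes")
    k = sum(1 for g in shared if res_a.per_gene_calls[g] and res_b.per_gene_calls[g])
    n = len(shared)
    return OverlapResult(k_both=k, n_shared=n, binomial_p=binomial_test_exact(k, n, 0.5, "two"))


def spearman_age_correlation(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Spearman rank correlation of drift-variance against age.

    Returns ``(rho, p)`` with the tie-corrected t-approximation p-value.
    A constant variance vector leaves rho undefined and raises.
    """
    if len(pairs) < 4:
        raise StatsError("need at least 4 (age, variance) pairs")
    ages, dv = zip(*pairs)
    if len(set(dv)) == 1 or len(set(ages)) == 1:
        raise StatsError("rank correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(ages, dv)
    return float(rho), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
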