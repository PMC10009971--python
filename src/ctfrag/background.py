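"""White-blood-cell variant background model.

Plasma cfDNA carries abundant clonal-hematopoiesis and germline variants
that are also present in paired WBC gDNA. To flag plasma variants that are
*inconsistent* with that background without sequencing a matched buffy coat,
the pooled WBC variant allele frequencies are modelled as a zero-inflated
beta distribution:

    VAF = 0                 with probability pi0
    VAF ~ Beta(a, b)        otherwise

A plasma call with allele depth AD out of total depth DP is scored by the
upper tail of the compound background law (point mass at zero mixed with a
beta-binomial):

    p = P(X >= AD | DP) = (1 - pi0) * SF_BetaBinom(AD - 1; DP, a, b)

with p = 1 when AD = 0. Variants with p below the significance level are
"LB-unique" (candidate tumor or unknown origin); the rest are
"LB-share-WBC" (consistent with hematopoietic background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import variant_key

_EPS = 1e-9


@dataclass(frozen=True)
class ZIBParams:
    """Fitted zero-inflated beta background."""

    pi0: float
    a: float
    b: float
    n_fit: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in [0,1], got {self.pi0}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"beta shapes must be positive, got a={self.a}, b={self.b}")


@dataclass
class VariantPartition:
    """Disjoint, exhaustive split of plasma variants by background consistency.

    Both frames carry a ``pvalue`` column; ``pvalues`` indexes every input
    variant by (sample_id, variant_key).
    """

    lb_unique: pd.DataFrame
    lb_share_wbc: pd.DataFrame
    pvalues: pd.Series
    params: ZIBParams | None = None


def fit_background(wbc_vafs: np.ndarray | pd.Series, min_obs: int = 10) -> ZIBParams:
    """Fit the zero-inflated beta to pooled WBC VAFs.

    ``pi0`` is the exact-zero fraction; the beta shapes are maximum
    likelihood over the strictly positive VAFs (L-BFGS-B on log-shapes with
    analytic gradient, method-of-moments start, tolerance 1e-8).
    """
    v = np.asarray(wbc_vafs, dtype=float)
    if v.ndim != 1 or v.size < min_obs:
        raise ValueError(f"need >= {min_obs} pooled observations, got {v.size}")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("VAFs must lie in [0,1]")
    pi0 = float(np.mean(v == 0.0))
    pos = v[v > 0.0]
    if pos.size == 0:
        raise ValueError("background degenerate: all pooled WBC VAFs are zero")
    pos = np.clip(pos, _EPS, 1.0 - _EPS)

    m, s2 = float(np.mean(pos)), float(np.var(pos))
    if s2 < 1e-12:
        # all positives identical: moment system is singular, use a flat start
        a0, b0 = 1.0, 1.0
    else:
        common = max(m * (1.0 - m) / s2 - 1.0, 1e-3)
        a0, b0 = max(m * common, 1e-3), max((1.0 - m) * common, 1e-3)

    slog, slog1m = np.sum(np.log(pos)), np.sum(np.log1p(-pos))
    n = pos.size

    def nll_grad(theta: np.ndarray):
        a, b = np.exp(theta)
        nll = -(n * (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b))
                + (a - 1.0) * slog + (b - 1.0) * slog1m)
        da = -(n * (special.psi(a + b) - special.psi(a)) + slog)
        db = -(n * (special.psi(a + b) - special.psi(b)) + slog1m)
        return nll, np.array([da * a, db * b])

    res = optimize.minimize(
        nll_grad, np.log([a0, b0]), jac=True, method="L-BFGS-B",
        options={"ftol": 1e-8, "gtol": 1e-8, "maxiter": 500},
    )
    a, b = np.exp(res.x)
    return ZIBParams(pi0=pi0, a=float(a), b=float(b), n_fit=int(v.size))


def variant_pvalue(ad, dp, params: ZIBParams):
    """Upper-tail background p-value, vectorized over (ad, dp).

    ``p = P(X >= ad)`` under the compound law; p = 1 at ad = 0 and is
    non-increasing in ad at fixed dp.
    """
    ad = np.asarray(ad)
    dp = np.asarray(dp)
    if np.any(dp < 1):
        raise ValueError("dp must be >= 1")
    if np.any(ad > dp) or np.any(ad < 0):
        raise ValueError("requires 0 <= ad <= dp")
    tail = (1.0 - params.pi0) * stats.betabinom.sf(ad - 1, dp, params.a, params.b)
    p = np.where(ad == 0, 1.0, tail)
    return float(p) if p.ndim == 0 else p


def select_lb_unique(
    plasma_variants: pd.DataFrame, params: ZIBParams, alpha: float = 0.05
) -> VariantPartition:
    """Partition plasma variants: p < alpha (strict) => LB-unique."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    df = plasma_variants.copy().reset_index(drop=True)
    if len(df) == 0:
        empty = df.assign(pvalue=pd.Series(dtype=float))
        return VariantPartition(empty, empty.copy(), pd.Series(dtype=float), params)
    df["pvalue"] = variant_pvalue(df["ad"].to_numpy(), df["dp"].to_numpy(), params)
    unique_mask = df["pvalue"] < alpha
    pvalues = pd.Series(
        df["pvalue"].to_numpy(),
        index=pd.MultiIndex.from_arrays(
            [df["sample_id"], variant_key(df)], names=["sample_id", "variant_key"]
        ),
    )
    return VariantPartition(
        lb_unique=df[unique_mask].reset_index(drop=True),
        lb_share_wbc=df[~unique_mask].reset_index(drop=True),
        pvalues=pvalues,
        params=params,
    )


def concordance_rate(partition: VariantPartition, truth: pd.DataFrame) -> float:
    """Fraction of plasma variants whose predicted origin class matches truth.

    ``truth`` has columns (sample_id, variant_key, source) where source is
    wbc_shared / tumor_derived / benign_unique; predicted LB-share-WBC is
    scored against source == wbc_shared.
    """
    truth_map = truth.set_index(["sample_id", "variant_key"])["source"]
    if truth_map.index.has_duplicates:
        raise ValueError("duplicate (sample_id, variant_key) in truth labels")
    n_match = 0
    n_total = 0
    for frame, predicted_shared in ((partition.lb_share_wbc, True), (partition.lb_unique, False)):
        if len(frame) == 0:
            continue
        idx = pd.MultiIndex.from_arrays([frame["sample_id"], variant_key(frame)])
        try:
            src = truth_map.loc[idx]
        except KeyError as e:
            raise ValueError(f"variant missing from truth labels: {e}") from None
        n_match += int(((src == "wbc_shared") == predicted_shared).sum())
        n_total += len(frame)
    if n_total == 0:
        raise ValueError("empty partition")
    return n_match / n_total


def vaf_correlation(
    shared_plasma: np.ndarray | pd.Series, matched_wbc: np.ndarray | pd.Series
) -> tuple[float, tuple[float, float], float]:
    """Pearson r between paired plasma and WBC VAFs with Fisher-z 95% CI
    and two-sided p."""
    x = np.asarray(shared_plasma, dtype=float)
    y = np.asarray(matched_wbc, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need paired 1-d arrays of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the paired VAF lists")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)
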