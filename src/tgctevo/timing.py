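"""Mutation multiplicity, CCF assignment and molecular timing of gains.

The timing substrate is the number of genome copies carrying each
somatic mutation.  In a region gained once, a mutation present before
the gain was duplicated with it (multiplicity 2) while later mutations
sit on a single copy; the ratio of the two count classes dates the gain
on the mutational (molecular) timescale, scaled to [0, 1].

Closed-form estimators are restricted to the single-gain states
``2:0``, ``2:1`` and ``2:2``; higher amplifications are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import GenomicSegment, SomaticVariant, ValidationError

TIMEABLE_STATES = ("2:0", "2:1", "2:2")
CCF_CLIP = 1.5
CI_LEVEL = 0.95


def expected_vaf(m: int, ccf: float, purity: float, tumour_total_cn: int) -> float:
    """Expected variant allele fraction of a mutation on ``m`` copies.

    ``f = m * ccf * rho / (2 (1 - rho) + n_t rho)`` for tumour purity
    rho and local tumour total copy number ``n_t`` (normal cells
    contribute two reference copies).
    """
    if not 0.0 <= purity <= 1.0:
        raise ValidationError(f"purity {purity} outside [0, 1]")
    if tumour_total_cn < 1:
        raise ValidationError("tumour_total_cn must be >= 1")
    if not 1 <= m <= tumour_total_cn:
        raise ValidationError(f"multiplicity {m} outside [1, {tumour_total_cn}]")
    if not 0.0 <= ccf <= CCF_CLIP:
        raise ValidationError(f"ccf {ccf} outside [0, {CCF_CLIP}]")
    denom = 2.0 * (1.0 - purity) + tumour_total_cn * purity
    return m * ccf * purity / denom


@dataclass(frozen=True)
class MultiplicityCall:
    """Inferred multiplicity, CCF and gain-timing class of one variant."""

    variant: SomaticVariant
    multiplicity: int
    ccf: float
    ccf_low: float
    ccf_high: float
    clonal: bool
    timing_class: str  # early | late | not_informative
    segment_state: str | None = None


def _timing_class(m: int, state: str | None) -> str:
    if state not in TIMEABLE_STATES:
        return "not_informative"
    return "early" if m >= 2 else "late"


def assign_multiplicities(
    variants: Sequence[SomaticVariant],
    segment: GenomicSegment | None,
    purity: float,
) -> list[MultiplicityCall]:
    """Vectorised multiplicity/CCF assignment for variants in one segment.

    The multiplicity maximises the binomial likelihood of the tumour alt
    count given ``expected_vaf(m, ccf=1)`` over ``m in 1..major_cn``;
    likelihood ties break toward smaller m (conservative toward "late").
    The CCF is the m-conditional moment estimate clipped to
    ``[0, 1.5]``; a variant is clonal when its CCF confidence interval
    (Clopper-Pearson on the VAF, transformed) reaches 1.
    """
    if segment is None or segment.major_cn == 0:
        return [
            MultiplicityCall(v, 1, float("nan"), float("nan"), float("nan"),
                             False, "not_informative", None)
            for v in variants
        ]
    if not variants:
        return []
    n_t = segment.total_cn
    denom = 2.0 * (1.0 - purity) + n_t * purity
    alt = np.array([v.tumour_alt_depth for v in variants])
    depth = np.array([v.tumour_depth for v in variants])
    if (depth == 0).any():
        bad = int(np.flatnonzero(depth == 0)[0])
        v = variants[bad]
        raise ValidationError(f"variant {v.chrom}:{v.pos}: zero tumour depth")
    m_grid = np.arange(1, segment.major_cn + 1)
    f_grid = np.clip(m_grid * purity / denom, 1e-12, 1 - 1e-12)
    # log-likelihood matrix (n_variants x n_m); argmax picks the first
    # (smallest) m on ties
    loglik = stats.binom.logpmf(alt[:, None], depth[:, None], f_grid[None, :])
    m_hat = m_grid[np.argmax(loglik, axis=1)]

    f_obs = alt / depth
    scale = denom / (m_hat * purity)
    ccf = np.clip(f_obs * scale, 0.0, CCF_CLIP)
    a = (1 - CI_LEVEL) / 2
    with np.errstate(invalid="ignore"):
        f_lo = np.where(alt == 0, 0.0, stats.beta.ppf(a, alt, depth - alt + 1))
        f_hi = np.where(alt == depth, 1.0, stats.beta.ppf(1 - a, alt + 1, depth - alt))
    ccf_lo = np.clip(f_lo * scale, 0.0, CCF_CLIP)
    ccf_hi = np.clip(f_hi * scale, 0.0, CCF_CLIP)
    clonal = ccf_hi >= 1.0

    state = segment.state
    return [
        MultiplicityCall(
            variant=v,
            multiplicity=int(m_hat[i]),
            ccf=float(ccf[i]),
            ccf_low=float(ccf_lo[i]),
            ccf_high=float(ccf_hi[i]),
            clonal=bool(clonal[i]),
            timing_class=_timing_class(int(m_hat[i]), state),
            segment_state=state,
        )
        for i, v in enumerate(variants)
    ]


def assign_multiplicity(
    variant: SomaticVariant, segment: GenomicSegment | None, purity: float
) -> MultiplicityCall:
    """Single-variant convenience wrapper around ``assign_multiplicities``."""
    return assign_multiplicities([variant], segment, purity)[0]


# ---------------------------------------------------------------------------
# CCF clustering (DPClust stand-in): 1-D binomial mixture selected by BIC

@dataclass(frozen=True)
class CcfClustering:
    assignments: np.ndarray  # cluster index per call
    centres: np.ndarray      # CCF centre per cluster
    weights: np.ndarray
    clonal_cluster: int      # index of the cluster with centre nearest 1
    bic: float


def cluster_ccf(
    calls: Sequence[MultiplicityCall],
    purity: float,
    k_max: int = 5,
    n_em_iter: int = 200,
    seed: int = 0,
) -> CcfClustering:
    """Cluster mutations by CCF with a binomial mixture.

    Each candidate cluster has a CCF centre c_k; the expected VAF of
    variant i under cluster k follows the multiplicity-aware formula, so
    variants of different multiplicity and local copy number share
    clusters on the CCF scale.  The number of clusters (1..k_max) is
    chosen by BIC; the clonal cluster is the one with centre nearest 1.
    """
    calls = [c for c in calls if np.isfinite(c.ccf)]
    if not calls:
        raise ValidationError("no calls with finite CCF to cluster")
    alt = np.array([c.variant.tumour_alt_depth for c in calls])
    depth = np.array([c.variant.tumour_depth for c in calls])
    if (depth == 0).all():
        raise ValidationError("all depths zero")
    # per-variant linear factor a_i with E[vaf_i] = a_i * ccf
    ccf_obs = np.array([c.ccf for c in calls])

    def _ntot(state: str | None) -> int:
        return sum(int(x) for x in state.split(":")) if state else 2

    a_i = np.array(
        [
            c.multiplicity * purity
            / (2.0 * (1.0 - purity) + _ntot(c.segment_state) * purity)
            for c in calls
        ]
    )
    rng = np.random.default_rng(seed)
    n = len(calls)

    best: CcfClustering | None = None
    for k in range(1, min(k_max, n) + 1):
        centres = np.quantile(ccf_obs, (np.arange(k) + 0.5) / k)
        centres = np.clip(centres + rng.normal(0, 1e-3, k), 0.01, CCF_CLIP)
        weights = np.full(k, 1.0 / k)
        loglik = -np.inf
        for _ in range(n_em_iter):
            f = np.clip(a_i[:, None] * centres[None, :], 1e-9, 1 - 1e-9)
            logp = (
                np.log(weights)[None, :]
                + alt[:, None] * np.log(f)
                + (depth - alt)[:, None] * np.log1p(-f)
            )
            mx = logp.max(axis=1, keepdims=True)
            resp = np.exp(logp - mx)
            resp /= resp.sum(axis=1, keepdims=True)
            new_loglik = float((mx.squeeze(1) + np.log(np.exp(logp - mx).sum(axis=1))).sum())
            weights = resp.mean(axis=0)
            num = resp.T @ alt
            den = resp.T @ (depth * a_i)
            centres = np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), centres),
                              1e-3, CCF_CLIP)
            if abs(new_loglik - loglik) < 1e-8:
                loglik = new_loglik
                break
            loglik = new_loglik
        n_params = 2 * k - 1
        bic = -2.0 * loglik + n_params * np.log(n)
        if best is None or bic < best.bic:
            f = np.clip(a_i[:, None] * centres[None, :], 1e-9, 1 - 1e-9)
            logp = (
                np.log(weights)[None, :]
                + alt[:, None] * np.log(f)
                + (depth - alt)[:, None] * np.log1p(-f)
            )
            best = CcfClustering(
                assignments=np.argmax(logp, axis=1),
                centres=centres.copy(),
                weights=weights.copy(),
                clonal_cluster=int(np.argmin(np.abs(centres - 1.0))),
                bic=float(bic),
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# gain timing

@dataclass(frozen=True)
class GainTiming:
    """Molecular-time estimate of one copy-number gain."""

    segment: GenomicSegment
    state: str
    n_early: int
    n_late: int
    t_hat: float
    ci_low: float
    ci_high: float


def _t_estimate(state: str, n2: float, n1: float) -> float:
    # one parental copy is duplicated in 2:0/2:1 (k = 2 resp. 3 accounts
    # for the differing number of late-accruing copies); both are in 2:2
    k = 3.0 if state == "2:1" else 2.0
    denom = 2.0 * n2 + n1
    if denom == 0:
        return float("nan")
    return float(np.clip(k * n2 / denom, 0.0, 1.0))


def time_gain(
    segment: GenomicSegment,
    calls: Sequence[MultiplicityCall],
    n_boot: int = 200,
    seed: int = 0,
) -> GainTiming | None:
    """Date a single gain from clonal mutation multiplicities.

    ``t_hat = k * n2 / (2 n2 + n1)`` with ``k = 3`` for 2:1 and
    ``k = 2`` for 2:0 and 2:2, clipped to [0, 1]; n2/n1 count clonal
    SNVs at multiplicity 2 / 1.  The CI is a percentile bootstrap over
    the segment's mutations.  Returns None when no informative mutation
    is available.
    """
    state = segment.state
    if state not in TIMEABLE_STATES:
        raise ValidationError(f"state {state} is not timeable (need 2:0/2:1/2:2)")
    labels = np.array(
        [
            c.multiplicity >= 2
            for c in calls
            if c.clonal and c.variant.is_snv and c.timing_class != "not_informative"
        ],
        dtype=bool,
    )
    n = labels.size
    if n == 0:
        return None
    n2 = int(labels.sum())
    n1 = n - n2
    t_hat = _t_estimate(state, n2, n1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot2 = labels[idx].sum(axis=1)
    boots = np.array([_t_estimate(state, b2, n - b2) for b2 in boot2])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = min(lo, t_hat)
    hi = max(hi, t_hat)
    return GainTiming(
        segment=segment, state=state, n_early=n2, n_late=n1,
        t_hat=t_hat, ci_low=float(lo), ci_high=float(hi),
    )
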