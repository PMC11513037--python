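"""Whole-genome duplication: classification, molecular timing, pre-WGD
burden, developmental cell-division estimates, and sync/async gains.

Classification places each sample in the plane of average tumour ploidy
(y) versus fraction of genome with LOH (x); samples above the line
``y = 2.9 - 2x`` are called WGD.  Timing uses the ratio of clonal
mutations duplicated by the doubling (multiplicity 2) to those accrued
afterwards (multiplicity 1), pooled over WGD-consistent segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import SamplePurityPloidy, ValidationError
from .timing import GainTiming, MultiplicityCall

# decision boundary in the (LOH fraction, ploidy) plane
WGD_INTERCEPT = 2.9
WGD_SLOPE = -2.0

# CpG trinucleotide contexts whose C>T channel behaves clock-like (SBS1)
_CPG_CT = {"ACG", "CCG", "GCG", "TCG"}


@dataclass(frozen=True)
class WgdCall:
    """Per-sample WGD status and derived timing quantities."""

    is_wgd: bool
    t_wgd: float | None = None
    t_wgd_ci: tuple[float, float] | None = None
    pre_wgd_burden: int | None = None
    pre_wgd_burden_extrapolated: float | None = None
    n_divisions: float | None = None
    gain_pattern: str = "uninformative"


def classify_wgd(pp: SamplePurityPloidy) -> bool:
    """WGD iff ploidy strictly exceeds ``2.9 - 2 * loh_fraction``.

    Boundary equality counts as non-WGD (strict inequality).
    """
    return pp.ploidy > WGD_INTERCEPT + WGD_SLOPE * pp.loh_fraction


def wgd_boundary_ploidy(loh_fraction: float) -> float:
    """Ploidy on the WGD decision boundary at a given LOH fraction."""
    return WGD_INTERCEPT + WGD_SLOPE * loh_fraction


def _is_clock_like(call: MultiplicityCall) -> bool:
    tnc = call.variant.trinucleotide_class
    if tnc is None:
        return False
    # 96-channel label like 'A[C>T]G'; clock-like = C>T at CpG plus the
    # flat SBS5-like remainder approximated by all C>T/T>C channels
    if len(tnc) == 7 and tnc[2] == ">":
        ctx = tnc[0] + tnc[1] + tnc[6]
        sub = tnc[1] + ">" + tnc[5]
    else:
        return False
    return (sub == "C>T" and ctx in _CPG_CT) or sub in ("C>T", "T>C")


def time_wgd(
    gain_timings: Sequence[GainTiming],
    calls_by_segment: Sequence[Sequence[MultiplicityCall]] | None = None,
    include_cnloh: bool = False,
    clock_like_only: bool = False,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float]] | None:
    """Pooled WGD molecular time from multiplicity-2 / multiplicity-1
    clonal mutation counts over WGD-consistent segments.

    ``t_wgd = 2 N2 / (2 N2 + N1)`` with N2/N1 summed over 2:2 segments
    (and 2:0 when ``include_cnloh``).  The CI is a bootstrap over
    segments (segments, not mutations, are the exchangeable unit: gains
    share the single doubling event).  ``clock_like_only`` restricts the
    counts to clock-like substitution channels, in which case
    ``calls_by_segment`` (aligned with ``gain_timings``) must be given.

    Returns None when no informative segment is available.
    """
    states = ("2:2", "2:0") if include_cnloh else ("2:2",)
    n2s: list[int] = []
    n1s: list[int] = []
    for i, gt in enumerate(gain_timings):
        if gt is None or gt.state not in states:
            continue
        if clock_like_only:
            if calls_by_segment is None:
                raise ValidationError(
                    "clock_like_only requires per-segment multiplicity calls"
                )
            calls = [
                c
                for c in calls_by_segment[i]
                if c.clonal and c.variant.is_snv
                and c.timing_class != "not_informative"
                and _is_clock_like(c)
            ]
            n2 = sum(c.multiplicity >= 2 for c in calls)
            n1 = len(calls) - n2
        else:
            n2, n1 = gt.n_early, gt.n_late
        if n2 + n1 == 0:
            continue
        n2s.append(n2)
        n1s.append(n1)
    if not n2s:
        return None
    n2a = np.array(n2s)
    n1a = np.array(n1s)

    def estimate(idx: np.ndarray) -> float:
        N2 = n2a[idx].sum()
        N1 = n1a[idx].sum()
        if 2 * N2 + N1 == 0:
            return float("nan")
        return float(np.clip(2.0 * N2 / (2.0 * N2 + N1), 0.0, 1.0))

    t_hat = estimate(np.arange(len(n2s)))
    rng = np.random.default_rng(seed)
    k = len(n2s)
    boots = np.array(
        [estimate(rng.integers(0, k, size=k)) for _ in range(n_boot)]
    )
    boots = boots[np.isfinite(boots)]
    if boots.size:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = t_hat
    return t_hat, (float(min(lo, t_hat)), float(max(hi, t_hat)))


def pre_wgd_burden(
    calls_by_segment: Sequence[Sequence[MultiplicityCall]],
    gain_timings: Sequence[GainTiming],
    assessable_length: float | None = None,
    include_cnloh: bool = True,
) -> tuple[int, float | None]:
    """Count clonal SNVs that predate the doubling (multiplicity 2 in
    WGD-consistent segments), raw and genome-extrapolated.

    The extrapolated value scales the raw count by assessable genome
    length over the informative segment length; when the informative
    length is zero (or no assessable length is given and no segment is
    informative) the extrapolated value is None.
    """
    states = ("2:2", "2:0") if include_cnloh else ("2:2",)
    raw = 0
    informative_length = 0.0
    for gt, calls in zip(gain_timings, calls_by_segment):
        if gt is None or gt.state not in states:
            continue
        informative_length += gt.segment.length
        raw += sum(
            1
            for c in calls
            if c.clonal and c.variant.is_snv and c.multiplicity >= 2
        )
    if assessable_length is None:
        assessable_length = informative_length
    if informative_length <= 0:
        return raw, None
    return raw, raw * assessable_length / informative_length


def divisions_to_wgd(burden: float, mu_division: float) -> float:
    """Post-PGC cell divisions elapsed before the doubling.

    ``n = burden / mu_division`` where ``mu_division`` is the mutation
    rate per cell division in primordial germ cells; this constant must
    be supplied by the caller (with its provenance) — there is no
    default.
    """
    if mu_division <= 0:
        raise ValidationError(f"mu_division {mu_division} must be positive")
    if burden < 0:
        raise ValidationError("burden must be non-negative")
    return burden / mu_division


def classify_gain_pattern(
    gain_timings: Sequence[GainTiming],
    t_wgd: float | tuple[float, float] | None,
    is_wgd: bool = True,
    min_segments: int = 3,
    min_mutations: int = 20,
    sync_fraction: float = 0.75,
) -> str:
    """Classify a WGD sample's chromosomal gains as synchronous (one
    shared time point, the doubling) or asynchronous (spread in time).

    A sample is uninformative with fewer than ``min_segments`` timed
    gained segments or fewer than ``min_mutations`` informative
    mutations in them.  Otherwise the sample is synchronous when the
    length-weighted fraction of gained genome whose timing CI overlaps
    the WGD time reaches ``sync_fraction``.  Non-WGD samples are
    labelled near-diploid.
    """
    if not is_wgd:
        return "near_diploid"
    timings = [gt for gt in gain_timings if gt is not None]
    total_muts = sum(gt.n_early + gt.n_late for gt in timings)
    if len(timings) < min_segments or total_muts < min_mutations or t_wgd is None:
        return "uninformative"
    if isinstance(t_wgd, tuple):
        w_lo, w_hi = t_wgd
    else:
        w_lo = w_hi = float(t_wgd)
    total_len = sum(gt.segment.length for gt in timings)
    overlap_len = sum(
        gt.segment.length
        for gt in timings
        if gt.ci_low <= w_hi and gt.ci_high >= w_lo
    )
    return "synchronous" if overlap_len / total_len >= sync_fraction else "asynchronous"


def call_wgd(
    pp: SamplePurityPloidy,
    gain_timings: Sequence[GainTiming],
    calls_by_segment: Sequence[Sequence[MultiplicityCall]],
    mu_division: float | None = None,
    assessable_length: float | None = None,
    include_cnloh: bool = False,
    seed: int = 0,
) -> WgdCall:
    """Assemble the per-sample WGD report (status, time, burden,
    cell-division estimate, gain pattern)."""
    is_wgd = classify_wgd(pp)
    if not is_wgd:
        return WgdCall(is_wgd=False, gain_pattern="near_diploid")
    timed = time_wgd(
        gain_timings, calls_by_segment, include_cnloh=include_cnloh, seed=seed
    )
    t_wgd, ci = timed if timed is not None else (None, None)
    raw, extrapolated = pre_wgd_burden(
        calls_by_segment, gain_timings,
        assessable_length=assessable_length,
        include_cnloh=True,
    )
    n_div = None
    if mu_division is not None:
        n_div = divisions_to_wgd(raw, mu_division)
    pattern = classify_gain_pattern(gain_timings, ci if ci else t_wgd, is_wgd=True)
    return WgdCall(
        is_wgd=True,
        t_wgd=t_wgd,
        t_wgd_ci=ci,
        pre_wgd_burden=raw,
        pre_wgd_burden_extrapolated=extrapolated,
        n_divisions=n_div,
        gain_pattern=pattern,
    )
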