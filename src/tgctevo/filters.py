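"""Bespoke somatic-variant filters and clonality-aware signature activity.

Three post-caller filters are provided: a panel-of-normals (PoN) Fisher
test that removes recurrent sequencing/mapping artefacts, hard
annotation thresholds (population germline allele frequency, cohort
somatic frequency, indel-window noise), and the per-cluster mutational
signature activity computation used downstream of CCF clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .model import SomaticVariant, ValidationError

# Annotation thresholds; inclusive per their definitions (>= 1% germline
# AF, >= 5% cohort somatic frequency, >= 10% flagged calls in the
# 50-base window around an indel).
GERMLINE_AF_MAX = 0.01
SOMATIC_FREQ_MAX = 0.05
INDEL_NOISE_MAX = 0.10

# The PoN test has no published alpha; default reflects genome-wide
# multiplicity of tested sites.
DEFAULT_PON_ALPHA = 1e-5


@dataclass(frozen=True)
class PonSiteCounts:
    """Aggregate allele depths at one site over panel-of-normals genomes
    (only individuals not carrying the alternate allele contribute)."""

    chrom: str
    pos: int
    ref_depth_total: int
    alt_depth_total: int
    n_individuals: int = 0

    def __post_init__(self) -> None:
        if self.ref_depth_total < 0 or self.alt_depth_total < 0:
            raise ValidationError("PoN depths must be non-negative")


@dataclass(frozen=True)
class PonDecision:
    keep: bool
    p_value: float


def pon_fisher_filter(
    variant: SomaticVariant,
    pon: PonSiteCounts,
    alpha: float = DEFAULT_PON_ALPHA,
) -> PonDecision:
    """Keep a variant when its tumour allele-depth ratio differs
    significantly from the PoN ratio at the same site.

    Two-sided Fisher exact test on ``[[tumour_ref, tumour_alt],
    [pon_ref, pon_alt]]``; a significant difference (p < alpha) means
    the signal is tumour-specific rather than a recurrent artefact, so
    the variant is KEPT.  Variants without any tumour alt reads are
    filtered outright.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    table = [
        [variant.tumour_ref_depth, variant.tumour_alt_depth],
        [pon.ref_depth_total, pon.alt_depth_total],
    ]
    if sum(table[0]) + sum(table[1]) == 0:
        raise ValidationError(
            f"uninformative site {variant.chrom}:{variant.pos}: all depths zero"
        )
    _, p = fisher_exact(table, alternative="two-sided")
    if variant.tumour_alt_depth == 0:
        return PonDecision(keep=False, p_value=float(p))
    return PonDecision(keep=p < alpha, p_value=float(p))


def threshold_filters(
    variants: Sequence[SomaticVariant],
    germline_af: Mapping[tuple[str, int], float] | None = None,
    somatic_freq: Mapping[tuple[str, int], float] | None = None,
    window_flags: Iterable[tuple[str, int]] | None = None,
) -> tuple[list[SomaticVariant], dict[str, int]]:
    """Apply hard annotation filters; returns survivors plus an audit of
    removals per filter, counted in application order (germline AF, then
    cohort somatic frequency, then indel-window noise).

    Missing annotation tables simply mean that filter is not applied.
    """
    flags = set(window_flags) if window_flags is not None else None
    audit = {"germline_af": 0, "somatic_freq": 0, "indel_noise": 0}
    kept: list[SomaticVariant] = []
    for v in variants:
        key = (v.chrom, v.pos)
        if germline_af is not None and germline_af.get(key, 0.0) >= GERMLINE_AF_MAX:
            audit["germline_af"] += 1
            continue
        if somatic_freq is not None and somatic_freq.get(key, 0.0) >= SOMATIC_FREQ_MAX:
            audit["somatic_freq"] += 1
            continue
        if flags is not None and key in flags:
            audit["indel_noise"] += 1
            continue
        kept.append(v)
    return kept, audit


@dataclass(frozen=True)
class ClusterSpectrum:
    """Mutation-type proportions of one CCF cluster (sums to 1)."""

    cluster_id: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        values = np.array(list(self.proportions.values()), dtype=float)
        if (values < 0).any():
            raise ValidationError("cluster proportions must be non-negative")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"cluster {self.cluster_id} proportions sum to {values.sum()}"
            )


def assign_cluster_signature_activity(cluster: ClusterSpectrum, signatures):
    """Per-signature activity of one cluster.

    ``activity[s] = sum_types proportion[type] * P(s | type)`` where the
    signature matrix (DataFrame: mutation type x signature) carries the
    decomposed probability of each signature given the mutation type.
    With a row-stochastic matrix the activities are a convex
    combination (non-negative, summing to 1).
    """
    types = list(cluster.proportions)
    missing = [t for t in types if t not in signatures.index]
    if missing:
        raise ValidationError(
            f"mutation types missing from signature matrix: {missing}"
        )
    weights = np.array([cluster.proportions[t] for t in types], dtype=float)
    probs = signatures.loc[types].to_numpy(dtype=float)
    activity = weights @ probs
    return dict(zip(signatures.columns, activity.tolist()))
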