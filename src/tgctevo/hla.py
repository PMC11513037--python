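"""HLA allelic imbalance / LOH classification and lost-vs-kept binders.

Works from LOHHLA-style per-gene allele copy-number estimates.  A gene
shows allelic imbalance (AI) when the p-value contrasting the evidence
for its two alleles is < 0.01; an AI gene is called LOH when, in
addition, the lost allele's copy number is below 0.5 with its
confidence interval strictly below 0.7, the kept allele's copy number
is above 0.75, and more than 10 mismatched sites distinguish the
alleles.  All five thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import ValidationError

HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")

P_AI_MAX = 0.01
LOST_CN_MAX = 0.5
LOST_CI_MAX = 0.7
KEPT_CN_MIN = 0.75
MISMATCH_MIN = 10


@dataclass(frozen=True)
class HlaGeneReport:
    """Allele-specific copy-number estimates for one HLA gene."""

    sample_id: str
    gene: str
    allele1: str
    allele2: str
    cn1: float
    cn2: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    n_mismatch_sites: int
    p_ai: float


@dataclass(frozen=True)
class HlaGeneCall:
    report: HlaGeneReport
    classification: str  # balanced | AI | LOH | non_evaluable
    lost_allele: str | None = None
    kept_allele: str | None = None


@dataclass(frozen=True)
class SampleHlaLabel:
    sample_id: str
    label: str  # 'HLA LOH' | 'HLA imbalance' | 'intact'
    n_evaluable: int


def classify_hla_gene(report: HlaGeneReport) -> HlaGeneCall:
    """Classify one gene as balanced, AI, or LOH.

    Homozygous genes (identical allele names) cannot be evaluated —
    allele-specific evidence is undefined when the haplotypes coincide.
    The lost allele is the one with the smaller copy-number estimate.
    """
    if report.allele1 == report.allele2:
        return HlaGeneCall(report, "non_evaluable")
    if not report.p_ai < P_AI_MAX:
        return HlaGeneCall(report, "balanced")
    if report.cn1 <= report.cn2:
        lost_cn, lost_ci, lost = report.cn1, report.ci1, report.allele1
        kept_cn, kept = report.cn2, report.allele2
    else:
        lost_cn, lost_ci, lost = report.cn2, report.ci2, report.allele2
        kept_cn, kept = report.cn1, report.allele1
    is_loh = (
        lost_cn < LOST_CN_MAX
        and lost_ci[1] < LOST_CI_MAX
        and kept_cn > KEPT_CN_MIN
        and report.n_mismatch_sites > MISMATCH_MIN
    )
    if is_loh:
        return HlaGeneCall(report, "LOH", lost_allele=lost, kept_allele=kept)
    return HlaGeneCall(report, "AI")


def label_sample(gene_calls: Sequence[HlaGeneCall]) -> SampleHlaLabel:
    """Sample label: 'HLA LOH' with >= 1 LOH gene, else 'HLA imbalance'
    with >= 1 AI gene, else 'intact' (also when nothing is evaluable)."""
    if not gene_calls:
        raise ValidationError("no gene calls for sample")
    sample_id = gene_calls[0].report.sample_id
    evaluable = [c for c in gene_calls if c.classification != "non_evaluable"]
    if any(c.classification == "LOH" for c in evaluable):
        label = "HLA LOH"
    elif any(c.classification == "AI" for c in evaluable):
        label = "HLA imbalance"
    else:
        label = "intact"
    return SampleHlaLabel(sample_id=sample_id, label=label, n_evaluable=len(evaluable))


def recompute_ai_pvalue(
    site_coverage_allele1: Sequence[float],
    site_coverage_allele2: Sequence[float],
) -> float:
    """Optional AI p-value from site-level coverage: paired t-test on
    per-mismatch-site log coverage ratios against zero."""
    a = np.asarray(site_coverage_allele1, dtype=float)
    b = np.asarray(site_coverage_allele2, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need >= 2 paired site coverages")
    ratios = np.log(np.maximum(a, 0.5)) - np.log(np.maximum(b, 0.5))
    return float(stats.ttest_1samp(ratios, 0.0).pvalue)


@dataclass(frozen=True)
class LostKeptComparison:
    sample_id: str
    gene: str
    lost_allele: str
    kept_allele: str
    n_lost_binders: int
    n_kept_binders: int
    p_value: float | None


def compare_lost_kept_binders(
    binding: Mapping[tuple[str, str], bool] | Sequence[tuple[str, str, bool]],
    gene_calls: Sequence[HlaGeneCall],
) -> list[LostKeptComparison]:
    """Per LOH gene, count antigenic peptides predicted to bind the lost
    versus the kept allele, with a two-sided exact binomial sign test
    (null: a binder is equally likely to target either allele).

    ``binding`` maps (peptide, allele) to a binder flag.  Genes without
    any binder on either allele carry ``p_value=None`` (test skipped).
    """
    if not isinstance(binding, Mapping):
        binding = {(p, a): flag for p, a, flag in binding}
    binder_count: dict[str, int] = {}
    for (_, allele), flag in binding.items():
        if flag:
            binder_count[allele] = binder_count.get(allele, 0) + 1
    results = []
    for call in gene_calls:
        if call.classification != "LOH":
            continue
        n_lost = binder_count.get(call.lost_allele, 0)
        n_kept = binder_count.get(call.kept_allele, 0)
        if n_lost + n_kept == 0:
            p = None
        else:
            p = float(stats.binomtest(n_lost, n_lost + n_kept, 0.5).pvalue)
        results.append(
            LostKeptComparison(
                sample_id=call.report.sample_id,
                gene=call.report.gene,
                lost_allele=call.lost_allele,
                kept_allele=call.kept_allele,
                n_lost_binders=n_lost,
                n_kept_binders=n_kept,
                p_value=p,
            )
        )
    return results
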