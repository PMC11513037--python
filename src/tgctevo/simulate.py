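"""Synthetic tumour genomes with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* somatic mutations accrue independently on each genome copy, uniformly
  in molecular time on [0, 1] (tumour-lineage origin to the last clonal
  time point);
* a mutation present on a copy when that copy is duplicated (by a gain
  or by WGD) is itself duplicated, giving multiplicity 2;
* read counts are binomial around the expected VAF
  ``f = m * ccf * rho / (2 (1 - rho) + n_t rho)`` at Poisson-distributed
  per-site depth.

Copy-number states are restricted to the five timing-relevant states
1:0, 1:1, 2:0, 2:1, 2:2 (plus homozygous deletion 0:0); each simulated
chromosome experiences at most one copy-number event, so the closed-form
timing estimators apply exactly.  Defaults mirror a TGCT-like cohort:
near-ubiquitous early WGD, ~0.5 substitutions/Mb total burden and
~100x tumour coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .filters import PonSiteCounts
from .genome import AUTOSOMES, GRCH38_LENGTHS
from .hla import HLA_GENES, HlaGeneReport
from .model import GenomicSegment, SamplePurityPloidy, SomaticVariant, SvCall
from .model import ValidationError

_BASES = np.array(list("ACGT"))
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# expected per-Mb mutation-count weights by state: (early, late) factors
# multiplying mu*t resp. mu*(1-t); None marks states without an event time
_STATE_WEIGHTS = {
    "1:1": (0.0, 2.0),
    "1:0": (0.0, 1.0),
    "2:1": (1.0, None),  # late weight is 3 - 2t, handled explicitly
    "2:0": (1.0, 2.0),
    "2:2": (2.0, 4.0),
    "0:0": (0.0, 0.0),
}


@dataclass(frozen=True)
class SegmentPlan:
    """Planned final state of one genomic interval with its event time."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    event_time: float | None = None  # molecular time of the gain/WGD/LOH

    @property
    def state(self) -> str:
        return f"{self.major_cn}:{self.minor_cn}"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the tumour simulator (cohort-level defaults).

    ``mu`` is the clonal mutation rate per Mb per genome copy per unit
    molecular time; with a whole-genome 2:2 state and early WGD this
    yields ~4*mu substitutions/Mb, so the default 0.12 reproduces a
    TGCT-like ~0.5/Mb total burden.
    """

    seed: int = 0
    n_samples: int = 10
    purity_range: tuple[float, float] = (0.4, 0.9)
    mu: float = 0.12
    subclonal_mu: float = 0.02
    subclone_ccfs: tuple[float, ...] = (0.4,)
    depth: float = 100.0
    normal_depth: float = 40.0
    wgd_probability: float = 0.95
    t_wgd: float = 0.05
    cnloh_rate: float = 0.1     # per-chromosome pre-WGD copy-neutral LOH
    gain_rate: float = 0.15     # per-chromosome single gains (non-WGD genomes)
    chromosomes: tuple[str, ...] = AUTOSOMES
    pon_size: int = 7000
    pon_artefact_rate: float = 0.05
    hla_state_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    hla_noise_sd: float = 0.05
    sv_n_true: int = 20
    sv_detection_prob: float = 0.9
    sv_jitter_sd: float = 50.0
    sv_false_per_caller: float = 3.0
    sv_callers: tuple[str, ...] = ("delly", "lumpy", "manta")


@dataclass(frozen=True)
class VariantTruth:
    multiplicity: int
    ccf: float
    clonal: bool
    pre_wgd: bool


@dataclass
class TumourSim:
    """One simulated tumour: observables plus aligned ground truth."""

    sample_id: str
    purity: float
    segments: list[GenomicSegment]
    plans: list[SegmentPlan]
    variants: list[SomaticVariant]
    truth: dict[tuple[str, int], VariantTruth]
    is_wgd: bool
    t_wgd: float | None
    n_pre_wgd: int

    @property
    def purity_ploidy(self) -> SamplePurityPloidy:
        return SamplePurityPloidy.from_segments(self.purity, self.segments)


def expected_vaf_of(m: int, ccf: float, purity: float, n_t: int) -> float:
    return m * ccf * purity / (2.0 * (1.0 - purity) + n_t * purity)


def simulate_segment_variants(
    plan: SegmentPlan,
    purity: float,
    rng: np.random.Generator,
    mu: float = 0.12,
    subclonal_mu: float = 0.02,
    subclone_ccfs: Sequence[float] = (0.4,),
    depth: float = 100.0,
    normal_depth: float = 40.0,
    n_informative: int | None = None,
) -> tuple[list[SomaticVariant], list[VariantTruth]]:
    """Draw the somatic SNVs of one segment with their ground truth.

    Clonal early/late counts are Poisson with the state-specific
    molecular-clock rates; ``n_informative`` instead fixes the total
    clonal count (split binomially between early and late), which the
    recovery experiments use to control information content exactly.
    """
    state = plan.state
    if state not in _STATE_WEIGHTS:
        raise ValidationError(f"cannot simulate state {state}")
    L_mb = (plan.end - plan.start + 1) / 1e6
    t = plan.event_time if plan.event_time is not None else 0.0
    w_early, w_late = _STATE_WEIGHTS[state]
    if state == "2:1":
        w_late = 3.0 - 2.0 * t
        rate_early, rate_late = mu * L_mb * t, mu * L_mb * w_late
    else:
        rate_early = mu * L_mb * w_early * t
        rate_late = mu * L_mb * w_late * (1.0 - t)
    if n_informative is not None:
        tot = rate_early + rate_late
        p_early = rate_early / tot if tot > 0 else 0.0
        n_early = int(rng.binomial(n_informative, p_early))
        n_late = n_informative - n_early
    else:
        n_early = int(rng.poisson(rate_early))
        n_late = int(rng.poisson(rate_late))
    n_sub = (
        int(rng.poisson(subclonal_mu * L_mb * max(plan.major_cn + plan.minor_cn, 0)))
        if subclone_ccfs
        else 0
    )
    n_t = plan.major_cn + plan.minor_cn
    wgd_like = state in ("2:2", "2:0")

    specs: list[tuple[int, float, bool]] = []  # (multiplicity, ccf, clonal)
    specs += [(2, 1.0, True)] * n_early
    specs += [(1, 1.0, True)] * n_late
    for _ in range(n_sub):
        specs.append((1, float(rng.choice(subclone_ccfs)), False))
    if not specs:
        return [], []

    n = len(specs)
    span = plan.end - plan.start + 1
    n_pos = min(n, span)
    # draw-with-rejection instead of materialising the position range
    pos_set = np.unique(rng.integers(plan.start, plan.end + 1, size=n_pos))
    while pos_set.size < n_pos:
        extra = rng.integers(plan.start, plan.end + 1, size=n_pos - pos_set.size)
        pos_set = np.unique(np.concatenate([pos_set, extra]))
    positions = np.sort(pos_set)
    order = rng.permutation(n)[: positions.size]
    variants: list[SomaticVariant] = []
    truths: list[VariantTruth] = []
    for pos, k in zip(positions, order):
        m, ccf, clonal = specs[k]
        f = expected_vaf_of(m, ccf, purity, n_t)
        d = max(int(rng.poisson(depth)), 1)
        alt = int(rng.binomial(d, f))
        nd = max(int(rng.poisson(normal_depth)), 1)
        sub = _SUBS[rng.integers(len(_SUBS))]
        ref = sub[0]
        alt_base = sub[2]
        tnc = f"{rng.choice(_BASES)}[{sub}]{rng.choice(_BASES)}"
        variants.append(
            SomaticVariant(
                chrom=plan.chrom,
                pos=int(pos),
                ref=ref,
                alt=alt_base,
                tumour_ref_depth=d - alt,
                tumour_alt_depth=alt,
                normal_ref_depth=nd,
                normal_alt_depth=0,
                trinucleotide_class=tnc,
            )
        )
        truths.append(
            VariantTruth(
                multiplicity=m, ccf=ccf, clonal=clonal,
                pre_wgd=bool(wgd_like and m == 2 and clonal),
            )
        )
    return variants, truths


def _default_plan(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[SegmentPlan], bool, float | None]:
    """Whole-chromosome segment plan for one tumour."""
    is_wgd = bool(rng.random() < config.wgd_probability)
    t_wgd = config.t_wgd if is_wgd else None
    plans: list[SegmentPlan] = []
    for chrom in config.chromosomes:
        end = GRCH38_LENGTHS[chrom]
        if is_wgd:
            if rng.random() < config.cnloh_rate:
                # LOH before the doubling: both copies from one parent
                plans.append(SegmentPlan(chrom, 1, end, 2, 0, t_wgd))
            else:
                plans.append(SegmentPlan(chrom, 1, end, 2, 2, t_wgd))
        else:
            u = rng.random()
            if u < config.gain_rate:
                plans.append(
                    SegmentPlan(chrom, 1, end, 2, 1, float(rng.uniform(0.1, 0.9)))
                )
            elif u < config.gain_rate + config.cnloh_rate:
                plans.append(
                    SegmentPlan(chrom, 1, end, 2, 0, float(rng.uniform(0.1, 0.9)))
                )
            else:
                plans.append(SegmentPlan(chrom, 1, end, 1, 1, None))
    return plans, is_wgd, t_wgd


def simulate_tumour(
    config: SimulationConfig,
    sample_id: str = "SIM-0001",
    seed: int | None = None,
    plans: Sequence[SegmentPlan] | None = None,
) -> TumourSim:
    """Simulate one tumour genome (segments + somatic SNVs + truth).

    The same seed and config always produce the same tumour; an explicit
    ``plans`` sequence overrides the random whole-chromosome plan (used
    by the cohort generator to encode shared latent events).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    purity = float(rng.uniform(*config.purity_range))
    if plans is None:
        plan_list, is_wgd, t_wgd = _default_plan(config, rng)
    else:
        plan_list = list(plans)
        wgd_times = [
            p.event_time for p in plan_list if p.state == "2:2" and p.event_time is not None
        ]
        is_wgd = bool(wgd_times)
        t_wgd = wgd_times[0] if wgd_times else None

    segments = [
        GenomicSegment(p.chrom, p.start, p.end, p.major_cn, p.minor_cn, 1.0)
        for p in plan_list
    ]
    variants: list[SomaticVariant] = []
    truth: dict[tuple[str, int], VariantTruth] = {}
    n_pre = 0
    for p in plan_list:
        vs, ts = simulate_segment_variants(
            p, purity, rng,
            mu=config.mu, subclonal_mu=config.subclonal_mu,
            subclone_ccfs=config.subclone_ccfs,
            depth=config.depth, normal_depth=config.normal_depth,
        )
        for v, tr in zip(vs, ts):
            variants.append(v)
            truth[(v.chrom, v.pos)] = tr
            n_pre += tr.pre_wgd
    return TumourSim(
        sample_id=sample_id, purity=purity, segments=segments,
        plans=plan_list, variants=variants, truth=truth,
        is_wgd=is_wgd, t_wgd=t_wgd, n_pre_wgd=n_pre,
    )


def write_tumour(sim: TumourSim, outdir) -> dict[str, str]:
    """Write one tumour's observables (segment TSV + VCF); returns paths."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_path = outdir / f"{sim.sample_id}.segments.tsv"
    vcf_path = outdir / f"{sim.sample_id}.somatic.vcf"
    _io.write_segments(seg_path, sim.segments, purity=sim.purity)
    _io.write_somatic_vcf(vcf_path, sim.variants)
    return {"segments": str(seg_path), "vcf": str(vcf_path)}


# ---------------------------------------------------------------------------
# cohort with shared latent event order

@dataclass(frozen=True)
class CohortEvent:
    """A recurrent genomic event with a latent cohort-level time."""

    name: str
    kind: str            # 'gain' (2:1), 'cnloh' (2:0) or 'wgd' (2:2 genome-wide)
    chrom: str | None    # event chromosome; None for wgd
    latent_time: float
    presence_prob: float = 1.0


@dataclass
class CohortSim:
    samples: list[TumourSim]
    events: list[CohortEvent]
    carried: dict[str, list[str]]  # sample_id -> event names present

    @property
    def true_order(self) -> list[str]:
        return [e.name for e in sorted(self.events, key=lambda e: e.latent_time)]


def simulate_cohort(
    config: SimulationConfig,
    events: Sequence[CohortEvent] | None = None,
) -> CohortSim:
    """Simulate a cohort sharing a latent event order.

    Each event occupies its own chromosome (WGD takes all remaining
    chromosomes), so every carried event is independently timeable; a
    sample carries an event with ``presence_prob``.  Per-sample event
    times equal the latent times, so the truth order holds within every
    sample by construction.
    """
    if events is None:
        events = []
    if config.n_samples < 2 and events:
        import warnings

        warnings.warn("fewer than 2 samples gives no cohort-level ordering signal")
    rng = np.random.default_rng(config.seed)
    event_chroms = {e.chrom for e in events if e.chrom is not None}
    free_chroms = [c for c in config.chromosomes if c not in event_chroms]
    samples: list[TumourSim] = []
    carried: dict[str, list[str]] = {}
    for i in range(config.n_samples):
        sample_id = f"SIM-{i + 1:04d}"
        if not events:
            # no shared latent events: fall back to the per-sample plan
            sim = simulate_tumour(
                config, sample_id=sample_id, seed=int(rng.integers(0, 2**31 - 1))
            )
            samples.append(sim)
            carried[sample_id] = []
            continue
        present = [e for e in events if rng.random() < e.presence_prob]
        plans: list[SegmentPlan] = []
        has_wgd = any(e.kind == "wgd" for e in present)
        t_wgd = next((e.latent_time for e in present if e.kind == "wgd"), None)
        for e in present:
            if e.kind == "wgd":
                continue
            end = GRCH38_LENGTHS[e.chrom]
            if e.kind == "gain":
                plans.append(SegmentPlan(e.chrom, 1, end, 2, 1, e.latent_time))
            elif e.kind == "cnloh":
                plans.append(SegmentPlan(e.chrom, 1, end, 2, 0, e.latent_time))
            else:
                raise ValidationError(f"unknown cohort event kind {e.kind!r}")
        absent_chroms = [
            e.chrom for e in events
            if e.chrom is not None and e not in present
        ]
        for chrom in free_chroms + absent_chroms:
            end = GRCH38_LENGTHS[chrom]
            if has_wgd:
                plans.append(SegmentPlan(chrom, 1, end, 2, 2, t_wgd))
            else:
                plans.append(SegmentPlan(chrom, 1, end, 1, 1, None))
        sim = simulate_tumour(
            config, sample_id=sample_id,
            seed=int(rng.integers(0, 2**31 - 1)), plans=plans,
        )
        samples.append(sim)
        carried[sample_id] = [e.name for e in present]
    return CohortSim(samples=samples, events=list(events), carried=carried)


def write_cohort(cohort: CohortSim, outdir) -> str:
    """Write per-sample files plus a manifest and the latent-order truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sim in cohort.samples:
        paths = write_tumour(sim, outdir)
        rows.append({"sample_id": sim.sample_id, **paths})
    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "samples": rows,
                "true_order": cohort.true_order,
                "carried": cohort.carried,
            },
            fh, indent=2,
        )
        fh.write("\n")
    return str(manifest)


# ---------------------------------------------------------------------------
# HLA gene tables

HLA_TRUTH_STATES = ("balanced", "imbalance", "loh")


def simulate_hla(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[HlaGeneReport], dict[tuple[str, str], str]]:
    """Per-sample, per-gene HLA allele copy-number reports around known
    truth states; returns reports plus truth keyed by (sample, gene)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sd = config.hla_noise_sd
    reports: list[HlaGeneReport] = []
    truth: dict[tuple[str, str], str] = {}
    probs = np.asarray(config.hla_state_probs, dtype=float)
    probs = probs / probs.sum()
    for i in range(config.n_samples):
        sample_id = f"SIM-{i + 1:04d}"
        for gene in HLA_GENES:
            state = HLA_TRUTH_STATES[int(rng.choice(3, p=probs))]
            truth[(sample_id, gene)] = state
            g = gene.split("-")[1]
            a1, a2 = f"{g}*01:01", f"{g}*02:01"
            if state == "balanced":
                cn1 = float(rng.normal(1.0, sd))
                cn2 = float(rng.normal(1.0, sd))
                p_ai = float(rng.uniform(0.05, 1.0))
                mism = int(rng.poisson(25))
            elif state == "imbalance":
                cn1 = float(rng.normal(1.6, sd))
                cn2 = float(rng.normal(0.9, sd))
                p_ai = float(rng.uniform(1e-6, 5e-3))
                mism = 11 + int(rng.poisson(20))
            else:  # loh
                cn1 = float(rng.normal(1.3, sd))
                cn2 = float(max(rng.normal(0.2, sd), 0.0))
                p_ai = float(rng.uniform(1e-9, 1e-4))
                mism = 11 + int(rng.poisson(20))
            reports.append(
                HlaGeneReport(
                    sample_id=sample_id, gene=gene,
                    allele1=a1, allele2=a2,
                    cn1=cn1, cn2=cn2,
                    ci1=(cn1 - 2 * sd, cn1 + 2 * sd),
                    ci2=(cn2 - 2 * sd, cn2 + 2 * sd),
                    n_mismatch_sites=mism,
                    p_ai=p_ai,
                )
            )
    return reports, truth


# ---------------------------------------------------------------------------
# multi-caller SV call sets

@dataclass
class SvSim:
    callsets: dict[str, list[SvCall]]
    true_svs: list[SvCall]
    cna_boundaries: list[tuple[str, int]]


def simulate_sv_callsets(
    config: SimulationConfig, seed: int | None = None
) -> SvSim:
    """True SVs observed by each caller with breakpoint jitter plus
    caller-private false calls placed away from CNA boundaries."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = list(config.chromosomes)
    types = ("DEL", "TD", "H2HINV", "T2TINV")
    true_svs: list[SvCall] = []
    boundaries: list[tuple[str, int]] = []
    for i in range(config.sv_n_true):
        chrom = chroms[int(rng.integers(len(chroms)))]
        end = GRCH38_LENGTHS[chrom]
        if rng.random() < 0.1:  # interchromosomal
            chrom2 = chroms[int(rng.integers(len(chroms)))]
            p1 = int(rng.integers(1_000_000, end - 1_000_000))
            p2 = int(rng.integers(1_000_000, GRCH38_LENGTHS[chrom2] - 1_000_000))
            sv = SvCall(chrom, p1, chrom2, p2, "TRANS", "truth", call_id=f"true{i}")
        else:
            size = int(10 ** rng.uniform(3.5, 6.5))
            p1 = int(rng.integers(1_000_000, max(end - size - 1_000_000, 2_000_000)))
            sv = SvCall(
                chrom, p1, chrom, p1 + size,
                types[int(rng.integers(len(types)))], "truth", call_id=f"true{i}",
            )
        true_svs.append(sv)
        boundaries.append((sv.chrom1, sv.pos1))
    callsets: dict[str, list[SvCall]] = {}
    for caller in config.sv_callers:
        calls: list[SvCall] = []
        for sv in true_svs:
            if rng.random() >= config.sv_detection_prob:
                continue
            j1 = int(round(rng.normal(0, config.sv_jitter_sd)))
            j2 = int(round(rng.normal(0, config.sv_jitter_sd)))
            depth = max(int(rng.poisson(config.depth)), 1)
            support = max(int(rng.binomial(depth, rng.uniform(0.1, 0.4))), 3)
            pos1, pos2 = sv.pos1 + j1, sv.pos2 + j2
            if sv.chrom1 == sv.chrom2 and pos1 > pos2:
                pos1, pos2 = pos2, pos1
            calls.append(
                SvCall(
                    sv.chrom1, pos1, sv.chrom2, pos2, sv.sv_type, caller,
                    tumour_support=support, tumour_depth=depth,
                    normal_support=0, call_id=f"{caller}:{sv.call_id}",
                )
            )
        n_false = int(rng.poisson(config.sv_false_per_caller))
        for k in range(n_false):
            chrom = chroms[int(rng.integers(len(chroms)))]
            end = GRCH38_LENGTHS[chrom]
            size = int(10 ** rng.uniform(4, 6))
            p1 = int(rng.integers(1_000_000, max(end - size - 1_000_000, 2_000_000)))
            depth = max(int(rng.poisson(config.depth)), 1)
            support = max(int(rng.binomial(depth, 0.1)), 3)
            calls.append(
                SvCall(
                    chrom, p1, chrom, p1 + size,
                    types[int(rng.integers(len(types)))], caller,
                    tumour_support=support, tumour_depth=depth,
                    normal_support=0, call_id=f"{caller}:false{k}",
                )
            )
        callsets[caller] = calls
    return SvSim(callsets=callsets, true_svs=true_svs, cna_boundaries=boundaries)


# ---------------------------------------------------------------------------
# panel of normals

def simulate_pon_sites(
    config: SimulationConfig,
    n_sites: int = 100,
    seed: int | None = None,
    depth_per_individual: float = 40.0,
) -> list[tuple[SomaticVariant, PonSiteCounts, bool]]:
    """Tumour variants with matched PoN depth summaries.

    A fraction ``pon_artefact_rate`` of sites are recurrent artefacts:
    the PoN carries the alternate allele at a similar ratio to the
    tumour, so the Fisher test cannot distinguish them.  Clean somatic
    sites show essentially no PoN alt depth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    pon_depth_total = int(config.pon_size * depth_per_individual)
    for i in range(n_sites):
        is_artefact = bool(rng.random() < config.pon_artefact_rate)
        vaf = float(rng.uniform(0.05, 0.5))
        d = max(int(rng.poisson(config.depth)), 1)
        alt = int(rng.binomial(d, vaf))
        if is_artefact:
            pon_alt = int(rng.binomial(pon_depth_total, vaf))
        else:
            pon_alt = int(rng.binomial(pon_depth_total, 1e-6))
        chrom = "1"
        pos = 1_000_000 + i * 1000
        v = SomaticVariant(
            chrom=chrom, pos=pos, ref="C", alt="T",
            tumour_ref_depth=d - alt, tumour_alt_depth=alt,
        )
        pon = PonSiteCounts(
            chrom=chrom, pos=pos,
            ref_depth_total=pon_depth_total - pon_alt,
            alt_depth_total=pon_alt,
            n_individuals=config.pon_size,
        )
        out.append((v, pon, is_artefact))
    return out
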