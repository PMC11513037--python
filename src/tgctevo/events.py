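"""Cohort-level event extraction and permutation enrichment of CNAs.

Events (gain / LOH / homozygous deletion, driver mutations, WGD) are
pulled from per-sample copy-number profiles; recurrence per genomic bin
is compared against a permutation null in which each event is
repositioned uniformly at random on its own chromosome, preserving its
length and each sample's event count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control

from .genome import AUTOSOMES, GRCH38_LENGTHS, normalise_contig
from .model import GenomicSegment, ValidationError
from .timing import GainTiming, MultiplicityCall
from .wgd import WgdCall

DEFAULT_BIN_WIDTH = 1_000_000
CNA_KINDS = ("gain", "LOH", "HD")


@dataclass(frozen=True)
class EventRecord:
    """One genomic event in one sample, with optional timing."""

    sample_id: str
    kind: str              # gain | LOH | HD | driver_mutation | WGD
    chrom: str | None
    start: int | None
    end: int | None
    gene: str | None = None
    t_hat: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    clonal: bool | None = None
    timing_class: str | None = None  # for driver mutations: early/late

    @property
    def name(self) -> str:
        if self.kind == "WGD":
            return "WGD"
        if self.gene is not None:
            return f"{self.gene} ({self.kind})"
        return f"{self.kind} {self.chrom}:{self.start}-{self.end}"


def extract_events(
    sample_id: str,
    segments: Sequence[GenomicSegment],
    ploidy: float,
    wgd_call: WgdCall | None = None,
    gain_timings: Mapping[tuple[str, int], GainTiming] | None = None,
    driver_calls: Sequence[tuple[str, MultiplicityCall]] | None = None,
) -> list[EventRecord]:
    """Turn a sample's profile into cohort-comparable event records.

    A segment is a gain when its total copy number reaches the
    ploidy-adjusted baseline plus one (``>= round(ploidy) + 1``), LOH
    when the minor allele is absent but the locus retained, HD when
    fully deleted.  ``gain_timings`` (keyed by (chrom, start)) attaches
    molecular-time estimates; ``driver_calls`` are (gene, multiplicity
    call) pairs from an externally supplied driver list.
    """
    gain_timings = gain_timings or {}
    baseline = int(round(ploidy))
    records: list[EventRecord] = []
    for seg in segments:
        kind = None
        if seg.total_cn == 0:
            kind = "HD"
        elif seg.minor_cn == 0:
            kind = "LOH"
        elif seg.total_cn >= baseline + 1:
            kind = "gain"
        if kind is None:
            continue
        gt = gain_timings.get((seg.chrom, seg.start))
        records.append(
            EventRecord(
                sample_id=sample_id, kind=kind,
                chrom=seg.chrom, start=seg.start, end=seg.end,
                t_hat=gt.t_hat if gt else None,
                ci_low=gt.ci_low if gt else None,
                ci_high=gt.ci_high if gt else None,
                clonal=seg.clonal_fraction >= 0.95,
            )
        )
    if wgd_call is not None and wgd_call.is_wgd:
        ci = wgd_call.t_wgd_ci
        records.append(
            EventRecord(
                sample_id=sample_id, kind="WGD",
                chrom=None, start=None, end=None,
                t_hat=wgd_call.t_wgd,
                ci_low=ci[0] if ci else None,
                ci_high=ci[1] if ci else None,
                clonal=True,
            )
        )
    for gene, call in driver_calls or ():
        records.append(
            EventRecord(
                sample_id=sample_id, kind="driver_mutation",
                chrom=call.variant.chrom, start=call.variant.pos,
                end=call.variant.pos, gene=gene,
                clonal=call.clonal, timing_class=call.timing_class,
            )
        )
    return records


@dataclass(frozen=True)
class EnrichmentResult:
    chrom: str
    start: int
    end: int
    kind: str
    observed: int
    null_mean: float
    p_enrich: float
    p_deplete: float
    q_enrich: float
    q_deplete: float
    direction: str  # enriched | depleted | none


def _bin_grid(chromosomes, bin_width):
    grid = {}
    for chrom in chromosomes:
        n = -(-GRCH38_LENGTHS[chrom] // bin_width)
        grid[chrom] = n
    return grid


def _recurrence(events_by_sample, grid, bin_width, kinds=CNA_KINDS):
    """Per (chrom, kind): number of distinct samples hitting each bin."""
    counts = {
        (chrom, kind): np.zeros(n, dtype=np.int32)
        for chrom, n in grid.items()
        for kind in kinds
    }
    for sample_events in events_by_sample.values():
        seen = {}
        for ev in sample_events:
            chrom = normalise_contig(ev.chrom)
            b1 = (ev.start - 1) // bin_width
            b2 = (ev.end - 1) // bin_width
            key = (chrom, ev.kind)
            mask = seen.setdefault(key, np.zeros(grid[chrom], dtype=bool))
            mask[b1 : b2 + 1] = True
        for key, mask in seen.items():
            counts[key] += mask
    return counts


def permutation_enrichment(
    events: Sequence[EventRecord],
    n_perm: int = 1000,
    seed: int = 0,
    bin_width: int = DEFAULT_BIN_WIDTH,
    chromosomes: Sequence[str] = AUTOSOMES,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Permutation enrichment/depletion of CNA events over genomic bins.

    The null repositions each event uniformly on its own chromosome
    (length preserved, per sample, per permutation); per-bin recurrence
    (number of distinct samples) is recomputed each time.
    ``p_enrich = (1 + #{perm >= obs}) / (n_perm + 1)`` and analogously
    with <= for depletion; BH adjustment is applied within event kind.
    Reproducible bit-for-bit given (seed, n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    cna = [e for e in events if e.kind in CNA_KINDS]
    if not cna:
        return []
    chromset = [normalise_contig(c) for c in chromosomes]
    for ev in cna:
        chrom = normalise_contig(ev.chrom)
        if chrom not in chromset:
            raise ValidationError(f"event on chromosome {ev.chrom} outside grid")
        if ev.end - ev.start + 1 > GRCH38_LENGTHS[chrom]:
            raise ValidationError(
                f"event {ev.chrom}:{ev.start}-{ev.end} longer than its chromosome"
            )
    grid = _bin_grid(chromset, bin_width)
    kinds_present = tuple(sorted({e.kind for e in cna}))
    by_sample: dict[str, list[EventRecord]] = {}
    for ev in cna:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    observed = _recurrence(by_sample, grid, bin_width, kinds_present)

    rng = np.random.default_rng(seed)
    # exceedance counters per (chrom, kind)
    ge_obs = {k: np.zeros_like(v) for k, v in observed.items()}
    le_obs = {k: np.zeros_like(v) for k, v in observed.items()}
    null_sum = {k: np.zeros(v.shape, dtype=np.float64) for k, v in observed.items()}

    # vectorised over permutations: per sample, build a (n_perm x n_bins)
    # presence matrix per (chrom, kind) via range-diff accumulation
    perm_counts = {
        k: np.zeros((n_perm, v.size), dtype=np.int16) for k, v in observed.items()
    }
    for sample_events in by_sample.values():
        presence: dict[tuple[str, str], np.ndarray] = {}
        for ev in sample_events:
            chrom = normalise_contig(ev.chrom)
            length = ev.end - ev.start + 1
            clen = GRCH38_LENGTHS[chrom]
            starts = rng.integers(1, clen - length + 2, size=n_perm)
            b1 = (starts - 1) // bin_width
            b2 = (starts + length - 2) // bin_width
            key = (chrom, ev.kind)
            diff = presence.setdefault(
                key, np.zeros((n_perm, grid[chrom] + 1), dtype=np.int16)
            )
            rows = np.arange(n_perm)
            np.add.at(diff, (rows, b1), 1)
            np.add.at(diff, (rows, b2 + 1), -1)
        for key, diff in presence.items():
            cov = np.cumsum(diff[:, :-1], axis=1) > 0
            perm_counts[key] += cov
    for key, mat in perm_counts.items():
        obs = observed[key][None, :]
        ge_obs[key] = (mat >= obs).sum(axis=0)
        le_obs[key] = (mat <= obs).sum(axis=0)
        null_sum[key] = mat.sum(axis=0, dtype=np.float64)

    # assemble results with BH within kind
    rows_by_kind: dict[str, list] = {k: [] for k in CNA_KINDS}
    for (chrom, kind), obs in sorted(observed.items()):
        for b in range(obs.size):
            p_e = (1 + ge_obs[(chrom, kind)][b]) / (n_perm + 1)
            p_d = (1 + le_obs[(chrom, kind)][b]) / (n_perm + 1)
            rows_by_kind[kind].append(
                (
                    chrom,
                    b * bin_width + 1,
                    min((b + 1) * bin_width, GRCH38_LENGTHS[chrom]),
                    int(obs[b]),
                    null_sum[(chrom, kind)][b] / n_perm,
                    float(p_e),
                    float(p_d),
                )
            )
    results: list[EnrichmentResult] = []
    for kind, rows in rows_by_kind.items():
        if not rows:
            continue
        q_e = false_discovery_control([r[5] for r in rows])
        q_d = false_discovery_control([r[6] for r in rows])
        for r, qe, qd in zip(rows, q_e, q_d):
            direction = "none"
            if qe < alpha and r[3] > r[4]:
                direction = "enriched"
            elif qd < alpha and r[3] < r[4]:
                direction = "depleted"
            results.append(
                EnrichmentResult(
                    chrom=r[0], start=r[1], end=r[2], kind=kind,
                    observed=r[3], null_mean=float(r[4]),
                    p_enrich=r[5], p_deplete=r[6],
                    q_enrich=float(qe), q_deplete=float(qd),
                    direction=direction,
                )
            )
    results.sort(key=lambda r: (r.kind, _ckey(r.chrom), r.start))
    return results


def _ckey(chrom: str):
    c = normalise_contig(chrom)
    return (int(c), "") if c.isdigit() else (100, c)


def merge_significant_bins(
    results: Sequence[EnrichmentResult],
) -> list[tuple[str, int, int, str, str]]:
    """Merge adjacent significant bins of the same kind and direction
    into regions; returns (chrom, start, end, kind, direction) tuples."""
    sig = [r for r in results if r.direction != "none"]
    sig.sort(key=lambda r: (r.kind, r.direction, _ckey(r.chrom), r.start))
    regions: list[list] = []
    for r in sig:
        if (
            regions
            and regions[-1][3] == r.kind
            and regions[-1][4] == r.direction
            and regions[-1][0] == r.chrom
            and regions[-1][2] + 1 == r.start
        ):
            regions[-1][2] = r.end
        else:
            regions.append([r.chrom, r.start, r.end, r.kind, r.direction])
    return [tuple(r) for r in regions]
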