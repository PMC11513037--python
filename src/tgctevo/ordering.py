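"""Probabilistic ordering of cohort events with a Plackett-Luce model.

Per-sample timing estimates (with confidence intervals) only partially
constrain the order of events within that tumour's history.  The
orderings consistent with the evidence are explored by sampling random
linear extensions of each sample's constraint DAG; each draw yields one
ranking per sample, a Plackett-Luce model is fitted to the rankings,
and the events' normalised ranks are accumulated over iterations into a
relative-timing distribution on [0, 1] (0 = earliest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .events import EventRecord
from .model import ValidationError


@dataclass
class PartialOrder:
    """Per-sample order constraints over the events the sample carries."""

    sample_id: str
    events: list[str]
    constraints: set[tuple[str, str]] = field(default_factory=set)  # (before, after)

    def validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.events)
        g.add_edges_from(self.constraints)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(
                f"sample {self.sample_id}: cyclic order constraints {cycle}"
            )


def build_partial_orders(
    events_by_sample: Mapping[str, Sequence[EventRecord]],
) -> list[PartialOrder]:
    """Construct per-sample constraint DAGs from event timings.

    Rules: two timed events (gains/WGD) are ordered when their timing
    CIs are disjoint; a clonal driver mutation of early timing class
    precedes its own segment's gain; every subclonal event follows every
    clonal event.  Pairs not covered by a rule remain free.
    """
    orders: list[PartialOrder] = []
    for sample_id, records in events_by_sample.items():
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            raise ValidationError(f"sample {sample_id}: duplicate event names")
        constraints: set[tuple[str, str]] = set()
        timed = [r for r in records if r.ci_low is not None and r.ci_high is not None]
        for a in timed:
            for b in timed:
                if a is not b and a.ci_high < b.ci_low:
                    constraints.add((a.name, b.name))
        by_region: dict[tuple, EventRecord] = {
            (r.chrom, r.kind): r for r in records if r.kind == "gain"
        }
        for r in records:
            if (
                r.kind == "driver_mutation"
                and r.clonal
                and r.timing_class == "early"
            ):
                host = by_region.get((r.chrom, "gain"))
                if host is not None:
                    constraints.add((r.name, host.name))
        clonal = [r.name for r in records if r.clonal]
        subclonal = [r.name for r in records if r.clonal is False]
        for c in clonal:
            for s in subclonal:
                constraints.add((c, s))
        po = PartialOrder(sample_id=sample_id, events=names, constraints=constraints)
        po.validate_acyclic()
        orders.append(po)
    return orders


def sample_total_orders(
    partial_order: PartialOrder, rng: np.random.Generator
) -> list[str]:
    """One random linear extension of the constraint DAG: a topological
    sort choosing uniformly among the currently available events."""
    indeg = {e: 0 for e in partial_order.events}
    succ: dict[str, list[str]] = {e: [] for e in partial_order.events}
    for a, b in partial_order.constraints:
        indeg[b] += 1
        succ[a].append(b)
    avail = sorted(e for e, d in indeg.items() if d == 0)
    out: list[str] = []
    while avail:
        i = int(rng.integers(len(avail)))
        e = avail.pop(i)
        out.append(e)
        for nxt in sorted(succ[e]):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                avail.append(nxt)
        avail.sort()
    if len(out) != len(partial_order.events):
        raise ValidationError(
            f"sample {partial_order.sample_id}: constraints are cyclic"
        )
    return out


def plackett_luce_loglik(
    rankings: Sequence[Sequence[int]], worths: np.ndarray
) -> float:
    """Log-likelihood of rankings (sequences of item indices, first =
    earliest/chosen first) under Plackett-Luce worths."""
    ll = 0.0
    for r in rankings:
        w = worths[list(r)]
        suffix = np.cumsum(w[::-1])[::-1]
        ll += float(np.sum(np.log(w[:-1]) - np.log(suffix[:-1])))
    return ll


def fit_plackett_luce(
    rankings: Sequence[Sequence[int]],
    n_items: int,
    prior: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Maximum-likelihood Plackett-Luce worths via MM iterations.

    Rankings are sequences of item indices (0..n_items-1), first item
    ranked first.  ``prior`` adds Dirichlet-style pseudo-wins so items
    never chosen ahead of any other keep a small positive worth.
    Worths are normalised to sum to 1; iteration stops when the maximum
    relative change drops below ``tol``.
    """
    if n_items < 1:
        raise ValidationError("need at least one item")
    lens = np.array([len(r) for r in rankings], dtype=int)
    if lens.size == 0 or (lens < 2).all():
        return np.full(n_items, 1.0 / n_items)
    Lmax = int(lens.max())
    R = np.zeros((len(rankings), Lmax), dtype=int)
    mask = np.zeros((len(rankings), Lmax), dtype=bool)
    for i, r in enumerate(rankings):
        R[i, : len(r)] = r
        mask[i, : len(r)] = True
    # win counts: appearances in non-terminal positions
    win = np.zeros(n_items)
    nonterm = mask.copy()
    rows = np.arange(len(rankings))
    nonterm[rows, lens - 1] = False
    np.add.at(win, R[nonterm], 1)

    w = np.full(n_items, 1.0 / n_items)
    pos_idx = np.arange(Lmax)
    stage_mask = nonterm  # stages 0..len-2 contribute a denominator term
    for _ in range(max_iter):
        vals = np.where(mask, w[R], 0.0)
        suffix = np.cumsum(vals[:, ::-1], axis=1)[:, ::-1]
        inv = np.where(stage_mask, 1.0 / np.where(suffix > 0, suffix, 1.0), 0.0)
        cum = np.cumsum(inv, axis=1)
        # item at position p contributes to stages t <= min(p, len-2)
        upto = np.minimum(pos_idx[None, :], (lens - 2)[:, None])
        contrib = np.where(
            mask & (upto >= 0), np.take_along_axis(cum, np.maximum(upto, 0), axis=1), 0.0
        )
        denom = np.zeros(n_items)
        np.add.at(denom, R[mask], contrib[mask])
        w_new = (win + prior) / np.where(denom + prior > 0, denom + prior, 1.0)
        w_new /= w_new.sum()
        delta = np.max(np.abs(w_new - w) / np.maximum(w, 1e-300))
        w = w_new
        if delta < tol:
            break
    return w


@dataclass(frozen=True)
class OrderingResult:
    """Relative-timing distribution of one event across iterations."""

    event: str
    mean_time: float
    sd_time: float
    min_time: float
    max_time: float
    n_samples: int


def order_events(
    partial_orders: Sequence[PartialOrder],
    n_iter: int = 1000,
    seed: int = 0,
    prior: float = 0.1,
) -> list[OrderingResult]:
    """Cohort-level relative timing of events, early to late.

    Each iteration draws one random linear extension per sample, fits a
    Plackett-Luce model to the resulting rankings, and records each
    event's normalised rank (rank / (E - 1)) in the worth ordering; the
    per-event mean, sd and range over iterations summarise the timing
    distribution.  Deterministic given the seed.
    """
    universe = sorted({e for po in partial_orders for e in po.events})
    if len(universe) < 2:
        raise ValidationError("need at least two events to order")
    index = {e: i for i, e in enumerate(universe)}
    n_events = len(universe)
    n_carrying = {
        e: sum(e in po.events for po in partial_orders) for e in universe
    }
    rng = np.random.default_rng(seed)
    times = np.full((n_iter, n_events), np.nan)
    for it in range(n_iter):
        rankings = [
            [index[e] for e in sample_total_orders(po, rng)]
            for po in partial_orders
            if len(po.events) >= 2
        ]
        worths = fit_plackett_luce(rankings, n_events, prior=prior)
        # events absent from every ranking this iteration carry no signal
        seen = np.zeros(n_events, dtype=bool)
        for r in rankings:
            seen[r] = True
        idx = np.flatnonzero(seen)
        if idx.size < 2:
            continue
        # highest worth = chosen first = earliest
        order = idx[np.argsort(-worths[idx], kind="stable")]
        times[it, order] = np.arange(idx.size) / (idx.size - 1)
    results = [
        OrderingResult(
            event=e,
            mean_time=float(np.nanmean(times[:, i])),
            sd_time=float(np.nanstd(times[:, i])),
            min_time=float(np.nanmin(times[:, i])),
            max_time=float(np.nanmax(times[:, i])),
            n_samples=n_carrying[e],
        )
        for e, i in index.items()
    ]
    results.sort(key=lambda r: r.mean_time)
    return results
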