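"""Multi-caller structural-variant consensus with CNA-boundary rescue.

Per-caller call sets are pre-filtered (matched-normal support, minimum
tumour support fraction, masked/non-standard regions), merged with a
graph in which calls of the same type whose paired breakpoints both lie
within 400 bp connect, and retained when seen by at least two callers
or, for single-caller calls, when a breakpoint falls within 3 kb of a
copy-number segment boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome import is_standard_contig, normalise_contig
from .model import GenomicSegment, SvCall

DEFAULT_SLOP = 400
DEFAULT_RESCUE_WINDOW = 3000
MIN_SUPPORT_FRACTION = 0.02

SIZE_BINS = ("<10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SIZE_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)


def prefilter_calls(
    calls: Sequence[SvCall],
    mask: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[list[SvCall], Counter]:
    """Remove unreliable raw calls; returns survivors + audit counts.

    Removal reasons (first matching one is recorded): any supporting
    read in the matched normal; zero tumour depth; tumour support
    fraction strictly below 2%; either breakpoint on a non-standard
    contig (not 1-22/X/Y); either breakpoint inside the telomere/
    centromere mask.
    """
    masked = [(normalise_contig(c), s, e) for c, s, e in (mask or ())]

    def in_mask(chrom: str, pos: int) -> bool:
        c = normalise_contig(chrom)
        return any(mc == c and s <= pos <= e for mc, s, e in masked)

    audit: Counter = Counter()
    kept: list[SvCall] = []
    for call in calls:
        if call.normal_support > 0:
            audit["normal_support"] += 1
        elif call.tumour_depth == 0:
            audit["zero_depth"] += 1
        elif call.tumour_support / call.tumour_depth < MIN_SUPPORT_FRACTION:
            audit["low_support"] += 1
        elif not (is_standard_contig(call.chrom1) and is_standard_contig(call.chrom2)):
            audit["non_standard_contig"] += 1
        elif in_mask(call.chrom1, call.pos1) or in_mask(call.chrom2, call.pos2):
            audit["masked_region"] += 1
        else:
            kept.append(call)
    audit["kept"] = len(kept)
    return kept, audit


@dataclass(frozen=True)
class ConsensusSV:
    """A merged structural variant (median breakpoints of its members)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    caller_set: frozenset[str]
    members: tuple[SvCall, ...]
    rescue: bool = False

    @property
    def size(self) -> int | None:
        if normalise_contig(self.chrom1) != normalise_contig(self.chrom2):
            return None
        return abs(self.pos2 - self.pos1)


def merge_calls(
    calls: Sequence[SvCall], slop: int = DEFAULT_SLOP
) -> list[ConsensusSV]:
    """Merge calls into candidate consensus SVs.

    Two calls connect when they share sv_type, both breakpoint
    chromosomes match, and both breakpoint distances are <= slop;
    connected components become candidates with median breakpoints.
    Output is independent of input order.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        a = calls[i]
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if (
                a.sv_type == b.sv_type
                and normalise_contig(a.chrom1) == normalise_contig(b.chrom1)
                and normalise_contig(a.chrom2) == normalise_contig(b.chrom2)
                and abs(a.pos1 - b.pos1) <= slop
                and abs(a.pos2 - b.pos2) <= slop
            ):
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = tuple(sorted((calls[i] for i in comp),
                               key=lambda c: (c.caller, c.pos1, c.pos2)))
        pos1 = int(np.median([c.pos1 for c in members]))
        pos2 = int(np.median([c.pos2 for c in members]))
        first = members[0]
        out.append(
            ConsensusSV(
                chrom1=first.chrom1, pos1=pos1,
                chrom2=first.chrom2, pos2=pos2,
                sv_type=first.sv_type,
                caller_set=frozenset(c.caller for c in members),
                members=members,
            )
        )
    out.sort(key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2, c.sv_type))
    return out


def apply_retention(
    candidates: Sequence[ConsensusSV],
    segments: Sequence[GenomicSegment],
    rescue_window: int = DEFAULT_RESCUE_WINDOW,
) -> list[ConsensusSV]:
    """Keep multi-caller candidates; rescue single-caller ones whose
    merged breakpoint (either end) lies within ``rescue_window`` bp of a
    copy-number segment start or end."""
    boundaries: dict[str, list[int]] = {}
    for seg in segments:
        boundaries.setdefault(normalise_contig(seg.chrom), []).extend(
            (seg.start, seg.end)
        )

    def near_boundary(chrom: str, pos: int) -> bool:
        return any(
            abs(pos - b) <= rescue_window
            for b in boundaries.get(normalise_contig(chrom), ())
        )

    kept = []
    for c in candidates:
        if len(c.caller_set) >= 2:
            kept.append(c)
        elif near_boundary(c.chrom1, c.pos1) or near_boundary(c.chrom2, c.pos2):
            kept.append(
                ConsensusSV(
                    chrom1=c.chrom1, pos1=c.pos1, chrom2=c.chrom2, pos2=c.pos2,
                    sv_type=c.sv_type, caller_set=c.caller_set,
                    members=c.members, rescue=True,
                )
            )
    return kept


def consensus_pipeline(
    callsets: dict[str, Sequence[SvCall]],
    segments: Sequence[GenomicSegment],
    mask: Iterable[tuple[str, int, int]] | None = None,
    slop: int = DEFAULT_SLOP,
    rescue_window: int = DEFAULT_RESCUE_WINDOW,
) -> tuple[list[ConsensusSV], Counter]:
    """Prefilter each caller's calls, merge across callers, retain."""
    all_calls: list[SvCall] = []
    audit: Counter = Counter()
    for caller in sorted(callsets):
        kept, a = prefilter_calls(callsets[caller], mask=mask)
        all_calls.extend(kept)
        audit.update({f"{caller}:{k}": v for k, v in a.items()})
    candidates = merge_calls(all_calls, slop=slop)
    final = apply_retention(candidates, segments, rescue_window=rescue_window)
    return final, audit


def build_catalogue(consensus: Sequence[ConsensusSV]) -> pd.DataFrame:
    """SV count matrix: type x size bin (translocations unbinned)."""
    types = ("DEL", "TD", "H2HINV", "T2TINV", "TRANS")
    cols = SIZE_BINS + ("TRANS",)
    table = pd.DataFrame(0, index=list(types), columns=list(cols))
    for sv in consensus:
        if sv.size is None:
            table.loc["TRANS", "TRANS"] += 1
            continue
        b = int(np.searchsorted(_SIZE_EDGES, sv.size, side="right"))
        table.loc[sv.sv_type, SIZE_BINS[b]] += 1
    return table
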