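"""Core domain types shared across the pipeline.

All genomic coordinates are 1-based and intervals are closed
``[start, end]`` (VCF/Battenberg convention); BEDPE input is converted on
read.  Copy-number states are written ``major:minor``, e.g. ``2:1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import AUTOSOMES, normalise_contig

SV_TYPES = ("DEL", "TD", "H2HINV", "T2TINV", "TRANS")


class ValidationError(ValueError):
    """Raised when an input record violates a model invariant."""


@dataclass(frozen=True)
class GenomicSegment:
    """One allele-specific copy-number segment.

    ``major_cn``/``minor_cn`` count copies of the two parental alleles
    (major >= minor); ``clonal_fraction`` is the fraction of tumour cells
    carrying this state.
    """

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.minor_cn > self.major_cn:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn}"
            )
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValidationError("copy numbers must be non-negative")
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise ValidationError(
                f"clonal_fraction {self.clonal_fraction} outside [0, 1]"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        """Segment length in bp (closed interval)."""
        return self.end - self.start + 1

    @property
    def state(self) -> str:
        return f"{self.major_cn}:{self.minor_cn}"

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            normalise_contig(chrom) == normalise_contig(self.chrom)
            and self.start <= pos <= self.end
        )


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic SNV or indel with tumour/normal allelic depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumour_ref_depth: int
    tumour_alt_depth: int
    normal_ref_depth: int = 0
    normal_alt_depth: int = 0
    trinucleotide_class: str | None = None

    def __post_init__(self) -> None:
        for d in (
            self.tumour_ref_depth,
            self.tumour_alt_depth,
            self.normal_ref_depth,
            self.normal_alt_depth,
        ):
            if d < 0:
                raise ValidationError(
                    f"variant {self.chrom}:{self.pos}: negative depth"
                )

    @property
    def tumour_depth(self) -> int:
        return self.tumour_ref_depth + self.tumour_alt_depth

    @property
    def vaf(self) -> float:
        d = self.tumour_depth
        return self.tumour_alt_depth / d if d > 0 else float("nan")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def validate_segments(segments: Sequence[GenomicSegment]) -> None:
    """Check that segments are non-overlapping within each chromosome."""
    by_chrom: dict[str, list[GenomicSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(normalise_contig(seg.chrom), []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def compute_loh_fraction(
    segments: Iterable[GenomicSegment],
    min_clonal_fraction: float = 0.5,
    autosomes_only: bool = True,
) -> float:
    """Fraction of the (autosomal) genome with minor copy number zero.

    Only segments whose state is the majority state of the locus
    (``clonal_fraction >= min_clonal_fraction``) are counted; subclonal
    minority states do not contribute.
    """
    loh = total = 0
    for seg in segments:
        if autosomes_only and normalise_contig(seg.chrom) not in AUTOSOMES:
            continue
        if seg.clonal_fraction < min_clonal_fraction:
            continue
        total += seg.length
        if seg.minor_cn == 0:
            loh += seg.length
    return loh / total if total else 0.0


def compute_ploidy(
    segments: Iterable[GenomicSegment], autosomes_only: bool = True
) -> float:
    """Length-weighted mean total copy number (average tumour ploidy)."""
    num = den = 0.0
    for seg in segments:
        if autosomes_only and normalise_contig(seg.chrom) not in AUTOSOMES:
            continue
        w = seg.length * seg.clonal_fraction
        num += w * seg.total_cn
        den += w
    return num / den if den else float("nan")


@dataclass(frozen=True)
class SamplePurityPloidy:
    """Sample purity rho, average ploidy psi, and genome LOH fraction x."""

    purity: float
    ploidy: float
    loh_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValidationError(f"ploidy {self.ploidy} must be positive")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ValidationError(
                f"loh_fraction {self.loh_fraction} outside [0, 1]"
            )

    @classmethod
    def from_segments(
        cls, purity: float, segments: Sequence[GenomicSegment]
    ) -> "SamplePurityPloidy":
        return cls(
            purity=purity,
            ploidy=compute_ploidy(segments),
            loh_fraction=compute_loh_fraction(segments),
        )


@dataclass(frozen=True)
class SvCall:
    """A single-caller structural-variant call (paired breakpoints)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    caller: str
    tumour_support: int = 0
    tumour_depth: int = 0
    normal_support: int = 0
    call_id: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(
                f"unknown sv_type {self.sv_type!r}; allowed: {', '.join(SV_TYPES)}"
            )
        if (
            normalise_contig(self.chrom1) == normalise_contig(self.chrom2)
            and self.pos1 > self.pos2
        ):
            raise ValidationError(
                f"intra-chromosomal call {self.chrom1}:{self.pos1}-{self.pos2}: "
                "pos1 > pos2"
            )
        if 0 < self.tumour_depth < self.tumour_support:
            raise ValidationError("tumour_support exceeds tumour_depth")

    @property
    def is_interchromosomal(self) -> bool:
        return normalise_contig(self.chrom1) != normalise_contig(self.chrom2)

    @property
    def size(self) -> int | None:
        """Breakpoint span in bp for intra-chromosomal calls, else None."""
        if self.is_interchromosomal:
            return None
        return abs(self.pos2 - self.pos1)


def validate_signature_matrix(matrix, atol: float = 1e-9) -> None:
    """Check a mutation-type x signature probability matrix (DataFrame).

    Each row holds P(signature | mutation type) and must sum to 1.
    """
    values = np.asarray(matrix, dtype=float)
    if (values < -atol).any() or (values > 1 + atol).any():
        raise ValidationError("signature probabilities outside [0, 1]")
    rows = values.sum(axis=1)
    bad = np.flatnonzero(np.abs(rows - 1.0) > atol)
    if bad.size:
        raise ValidationError(
            f"signature matrix rows {bad.tolist()} do not sum to 1"
        )
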