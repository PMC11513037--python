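"""Readers and writers for the file formats the pipeline consumes and emits.

Formats
-------
* allele-specific copy-number segments: Battenberg-style TSV with columns
  ``chrom  start  end  major_cn  minor_cn  clonal_fraction`` and purity /
  ploidy carried in ``##key=value`` header comments;
* somatic SNV/indel calls: VCF 4.2 with per-sample ``AD`` depths
  (pysam-backed); multi-allelic records are decomposed on read;
* structural variants: BEDPE (0-based half-open on disk, converted to
  1-based breakpoint positions in memory);
* generic result tables: TSV with deterministic column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .genome import GRCH38_LENGTHS, normalise_contig
from .model import (
    GenomicSegment,
    SamplePurityPloidy,
    SomaticVariant,
    SvCall,
    ValidationError,
    compute_loh_fraction,
    compute_ploidy,
    validate_segments,
)

SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn", "clonal_fraction"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "sv_type", "caller", "tumour_support", "tumour_depth", "normal_support",
]


# ---------------------------------------------------------------------------
# segment tables

def read_segments(path) -> tuple[list[GenomicSegment], SamplePurityPloidy]:
    """Read a segment TSV; returns validated, sorted segments plus
    purity/ploidy (ploidy and LOH fraction recomputed from the segments
    when not present in the header comments)."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            key, _, value = line[2:].strip().partition("=")
            try:
                meta[key] = float(value)
            except ValueError:
                pass
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing segment columns {missing}")
    segments = [
        GenomicSegment(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            major_cn=int(row.major_cn),
            minor_cn=int(row.minor_cn),
            clonal_fraction=float(row.clonal_fraction),
        )
        for row in table.itertuples()
    ]
    validate_segments(segments)
    segments.sort(key=lambda s: (_chrom_key(s.chrom), s.start))
    if "purity" not in meta:
        raise ValidationError(f"{path}: no ##purity header comment")
    pp = SamplePurityPloidy(
        purity=meta["purity"],
        ploidy=meta.get("ploidy", compute_ploidy(segments)),
        loh_fraction=compute_loh_fraction(segments),
    )
    return segments, pp


def write_segments(path, segments: Sequence[GenomicSegment], purity: float,
                   ploidy: float | None = None) -> None:
    validate_segments(segments)
    if ploidy is None:
        ploidy = compute_ploidy(segments)
    ordered = sorted(segments, key=lambda s: (_chrom_key(s.chrom), s.start))
    table = pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.major_cn, s.minor_cn, s.clonal_fraction)
            for s in ordered
        ],
        columns=SEGMENT_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write(f"##purity={purity}\n##ploidy={ploidy}\n")
        table.to_csv(fh, sep="\t", index=False)


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = normalise_contig(chrom)
    return (int(c), "") if c.isdigit() else (100, c)


# ---------------------------------------------------------------------------
# somatic VCF

def read_somatic_vcf(
    path, tumour_sample: str = "TUMOUR", normal_sample: str = "NORMAL"
) -> list[SomaticVariant]:
    """Read somatic calls from a tumour/normal VCF with AD depths.

    One ``SomaticVariant`` is emitted per ALT allele (multi-allelic
    records decomposed); the ref depth of each decomposed variant is the
    AD reference count of the original record.
    """
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if tumour_sample not in samples or normal_sample not in samples:
            raise ValidationError(
                f"{path}: expected samples {tumour_sample!r}, {normal_sample!r}; "
                f"found {samples}"
            )
        for rec in vcf:
            t_ad = rec.samples[tumour_sample].get("AD")
            n_ad = rec.samples[normal_sample].get("AD")
            if t_ad is None or n_ad is None or t_ad[0] is None:
                raise ValidationError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD depths"
                )
            tnc = rec.info.get("TNC")
            for i, alt in enumerate(rec.alts or ()):
                variants.append(
                    SomaticVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        tumour_ref_depth=int(t_ad[0]),
                        tumour_alt_depth=int(t_ad[i + 1]),
                        normal_ref_depth=int(n_ad[0]),
                        normal_alt_depth=int(n_ad[i + 1]),
                        trinucleotide_class=tnc,
                    )
                )
    return variants


def write_somatic_vcf(
    path,
    variants: Iterable[SomaticVariant],
    tumour_sample: str = "TUMOUR",
    normal_sample: str = "NORMAL",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNV/indel calls as a minimal two-sample VCF 4.2 with AD."""
    lengths = contig_lengths or GRCH38_LENGTHS
    header = pysam.VariantHeader()
    for contig, length in lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line(
        '##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide class">'
    )
    header.add_samples([normal_sample, tumour_sample])
    ordered = sorted(
        variants, key=lambda v: (_chrom_key(v.chrom), v.pos, v.ref, v.alt)
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.trinucleotide_class:
                rec.info["TNC"] = v.trinucleotide_class
            rec.samples[normal_sample]["AD"] = (v.normal_ref_depth, v.normal_alt_depth)
            rec.samples[tumour_sample]["AD"] = (v.tumour_ref_depth, v.tumour_alt_depth)
            out.write(rec)


# ---------------------------------------------------------------------------
# SV BEDPE

def read_sv_bedpe(path) -> list[SvCall]:
    """Read per-caller SV calls from BEDPE (0-based half-open on disk).

    Breakpoint positions become 1-based: ``pos = bedpe_start + 1``.
    """
    table = pd.read_csv(
        path, sep="\t", names=BEDPE_COLUMNS, dtype={"chrom1": str, "chrom2": str},
        comment="#",
    )
    calls = []
    for row in table.itertuples():
        calls.append(
            SvCall(
                chrom1=str(row.chrom1),
                pos1=int(row.start1) + 1,
                chrom2=str(row.chrom2),
                pos2=int(row.start2) + 1,
                sv_type=str(row.sv_type),
                caller=str(row.caller),
                tumour_support=int(row.tumour_support),
                tumour_depth=int(row.tumour_depth),
                normal_support=int(row.normal_support),
                call_id=None if pd.isna(row.name) else str(row.name),
            )
        )
    return calls


def write_sv_bedpe(path, calls: Sequence[SvCall]) -> None:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            (
                c.chrom1, c.pos1 - 1, c.pos1, c.chrom2, c.pos2 - 1, c.pos2,
                c.call_id or f"sv{i}", ".", "+", "-",
                c.sv_type, c.caller, c.tumour_support, c.tumour_depth,
                c.normal_support,
            )
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# generic results

def write_table(path, table: pd.DataFrame, columns: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with a fixed column order."""
    if columns is not None:
        table = table[list(columns)]
    table.to_csv(path, sep="\t", index=False)


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
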