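"""GRCh38 chromosome lengths and contig helpers.

Lengths are the primary-assembly chromosome sizes (bp); bundled so that
simulated genomes and bin grids can be laid out without touching a
reference FASTA.
"""

from __future__ import annotations

GRCH38_LENGTHS: dict[str, int] = {
    "1": 248956422,
    "2": 242193529,
    "3": 198295559,
    "4": 190214555,
    "5": 181538259,
    "6": 170805979,
    "7": 159345973,
    "8": 145138636,
    "9": 138394717,
    "10": 133797422,
    "11": 135086622,
    "12": 133275309,
    "13": 114364328,
    "14": 107043718,
    "15": 101991189,
    "16": 90338345,
    "17": 83257441,
    "18": 80373285,
    "19": 58617616,
    "20": 64444167,
    "21": 46709983,
    "22": 50818468,
    "X": 156040895,
    "Y": 57227415,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
STANDARD_CONTIGS: frozenset[str] = frozenset(GRCH38_LENGTHS)


def normalise_contig(name: str) -> str:
    """Strip a leading 'chr' prefix so '1', 'chr1' and 'chrX' compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


def is_standard_contig(name: str) -> bool:
    """True for chromosomes 1-22, X and Y (with or without 'chr' prefix)."""
    return normalise_contig(name) in STANDARD_CONTIGS
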