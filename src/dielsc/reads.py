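"""Tagged read alignments: the in-memory type and SAM/TSV round-trips.

A :class:`TaggedRead` is one aligned fragment carrying the droplet cell
barcode and UMI, as produced by Drop-seq-style tagging.  SAM files use the
standard ``CB`` (cell barcode) and ``UB`` (UMI) tags; the TSV dialect is a
plain table with columns ``cell, umi, chrom, strand, block_starts,
block_ends`` where the block columns are comma-separated 0-based half-open
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = ["TaggedRead", "write_sam", "read_sam", "write_tsv", "read_tsv"]


@dataclass(frozen=True)
class TaggedRead:
    """An aligned read with cell barcode, UMI, strand and aligned blocks.

    ``blocks`` are sorted, non-overlapping (start, end) half-open intervals;
    a spliced or junction-spanning alignment has more than one block or one
    block spanning the junction.
    """

    cell: str
    umi: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.blocks:
            raise ValueError("blocks must be non-empty")
        prev_end = None
        for s, e in self.blocks:
            if not s < e:
                raise ValueError("each block needs start < end")
            if prev_end is not None and s < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        """Outermost aligned coordinates (first block start, last block end)."""
        return self.blocks[0][0], self.blocks[-1][1]


# ---------------------------------------------------------------------- SAM

def write_sam(reads: Iterable[TaggedRead], path: str, chrom_lengths: dict[str, int]) -> None:
    """Write reads as a headered SAM file with CB/UB tags.

    Intron-separated blocks become N operations in the CIGAR; the read
    "sequence" is a placeholder run of N bases of the aligned length.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    refs = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.reference_id = refs[r.chrom]
            a.reference_start = r.blocks[0][0]
            a.is_reverse = r.strand == "-"
            a.mapping_quality = 255
            cigar = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N: skipped region
                cigar.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cigar
            aligned = sum(e - s for s, e in r.blocks)
            a.query_sequence = "N" * aligned
            a.set_tag("CB", r.cell)
            a.set_tag("UB", r.umi)
            out.write(a)


def read_sam(path: str) -> Iterator[TaggedRead]:
    """Yield TaggedRead from a SAM/BAM file carrying CB/UB tags.

    Unmapped reads and reads missing either tag are skipped.
    """
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped or not a.has_tag("CB") or not a.has_tag("UB"):
                continue
            blocks = _merge_adjacent(a.get_blocks())
            yield TaggedRead(
                cell=a.get_tag("CB"),
                umi=a.get_tag("UB"),
                chrom=a.reference_name,
                strand="-" if a.is_reverse else "+",
                blocks=tuple(blocks),
            )


def _merge_adjacent(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    # pysam splits on I/D as well as N; merge abutting blocks back together
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------- TSV

_TSV_HEADER = "cell\tumi\tchrom\tstrand\tblock_starts\tblock_ends\n"


def write_tsv(reads: Iterable[TaggedRead], path: str) -> None:
    """Write the documented tabular dialect (one read per row)."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for r in reads:
            starts = ",".join(str(s) for s, _ in r.blocks)
            ends = ",".join(str(e) for _, e in r.blocks)
            fh.write(f"{r.cell}\t{r.umi}\t{r.chrom}\t{r.strand}\t{starts}\t{ends}\n")


def read_tsv(path: str) -> Iterator[TaggedRead]:
    with open(path) as fh:
        header = fh.readline()
        if header != _TSV_HEADER:
            raise ValueError("unrecognized read-TSV header")
        for line in fh:
            cell, umi, chrom, strand, starts, ends = line.rstrip("\n").split("\t")
            blocks = tuple(
                (int(s), int(e))
                for s, e in zip(starts.split(","), ends.split(","))
            )
            yield TaggedRead(cell=cell, umi=umi, chrom=chrom, strand=strand, blocks=blocks)
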