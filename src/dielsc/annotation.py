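"""Gene models and annotation sets.

Coordinates are 0-based, half-open internally.  GFF3 I/O converts to and
from the format's 1-based, closed convention at the boundary, so a GFF3
line ``start=101 end=200`` becomes ``GeneModel(start=100, end=200)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = ["GeneModel", "AnnotationSet"]

_BIOTYPES = {"protein_coding", "non_coding", "tRNA"}


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware genomic interval with a biotype and a plastid flag."""

    id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    biotype: str = "protein_coding"
    plastid: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.biotype not in _BIOTYPES:
            raise ValueError(f"gene {self.id}: unknown biotype {self.biotype!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """Any-overlap (>=1 bp) with a half-open interval."""
        return self.start < end and start < self.end


class AnnotationSet:
    """An indexed collection of :class:`GeneModel` with interval queries.

    Parameters
    ----------
    genes
        Gene models; ids must be unique.

    Notes
    -----
    Interval queries are backed by one :class:`intervaltree.IntervalTree`
    per chromosome, so overlap lookups are O(log n + k).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        self._by_id = {g.id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        """Genes overlapping [start, end) on ``chrom``; optionally strand-matched."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.id))

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path: str) -> None:
        """Write genes as GFF3 (1-based, closed; biotype and plastid in column 9)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = f"ID={g.id};biotype={g.biotype};plastid={str(g.plastid).lower()}"
                fh.write(
                    f"{g.chrom}\tdielsc\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str) -> "AnnotationSet":
        """Read gene features from a GFF3 file written by :meth:`to_gff3`.

        Only ``gene`` rows are used; ``biotype`` defaults to protein_coding
        and ``plastid`` to false when absent from column 9.
        """
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                genes.append(
                    GeneModel(
                        id=attrs["ID"],
                        chrom=f[0],
                        strand=f[6],
                        start=int(f[3]) - 1,
                        end=int(f[4]),
                        biotype=attrs.get("biotype", "protein_coding"),
                        plastid=attrs.get("plastid", "false") == "true",
                    )
                )
        return cls(genes)
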