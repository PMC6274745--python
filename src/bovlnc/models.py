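"""Transcript and annotation containers.

Coordinates are 0-based, half-open throughout the library; GTF I/O converts
to and from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain on one strand.

    Exons are (start, end) pairs in 0-based half-open coordinates, sorted,
    non-overlapping and separated by introns of at least 1 bp.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s < 0 or e <= s:
                raise ValidationError(f"{self.id}: malformed exon ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"{self.id}: exons must be sorted with introns >= 1 bp "
                    f"(exon starting at {s} follows end {prev_end})"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def splice_sites(self) -> frozenset[int]:
        """All internal splice positions (intron boundaries)."""
        sites = []
        for a, b in self.introns:
            sites.extend((a, b))
        return frozenset(sites)


BIOTYPES = ("protein_coding", "lncRNA", "other_ncRNA")


class AnnotationSet:
    """A set of transcript models with gene grouping and gene biotypes."""

    def __init__(self):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.gene_of: dict[str, str] = {}
        self.biotype: dict[str, str] = {}
        self._by_chrom: dict[str, list[TranscriptModel]] | None = None

    def add(self, tx: TranscriptModel, gene_id: str, biotype: str = "protein_coding") -> None:
        if tx.id in self.transcripts:
            raise ValidationError(f"duplicate transcript id {tx.id}")
        if biotype not in BIOTYPES:
            raise ValidationError(f"unknown biotype {biotype!r}")
        existing = self.biotype.get(gene_id)
        if existing is not None and existing != biotype:
            raise ValidationError(f"gene {gene_id}: conflicting biotypes {existing} / {biotype}")
        self.transcripts[tx.id] = tx
        self.gene_of[tx.id] = gene_id
        self.biotype[gene_id] = biotype
        self._by_chrom = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def by_chrom(self, chrom: str) -> list[TranscriptModel]:
        if self._by_chrom is None:
            idx: dict[str, list[TranscriptModel]] = {}
            for tx in self.transcripts.values():
                idx.setdefault(tx.chrom, []).append(tx)
            for lst in idx.values():
                lst.sort(key=lambda t: (t.start, t.end, t.id))
            self._by_chrom = idx
        return self._by_chrom.get(chrom, [])

    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t, g in sorted(self.gene_of.items()) if g == gene_id]

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """Union span (chrom, start, end) of all transcripts of a gene."""
        txs = self.transcripts_of_gene(gene_id)
        if not txs:
            raise KeyError(gene_id)
        chroms = {t.chrom for t in txs}
        if len(chroms) > 1:
            raise ValidationError(f"gene {gene_id} spans multiple chromosomes")
        return txs[0].chrom, min(t.start for t in txs), max(t.end for t in txs)

    def gene_strand(self, gene_id: str) -> str:
        return self.transcripts_of_gene(gene_id)[0].strand

    def subset_biotypes(self, biotypes: Iterable[str]) -> "AnnotationSet":
        """New AnnotationSet restricted to genes of the given biotypes."""
        keep = set(biotypes)
        out = AnnotationSet()
        for tid, tx in self.transcripts.items():
            gid = self.gene_of[tid]
            if self.biotype[gid] in keep:
                out.add(tx, gid, self.biotype[gid])
        return out
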