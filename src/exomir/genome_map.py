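"""Exact-match, multi-locus, strand-aware tag mapping.

A k-mer hash index over the genome's plus strand; minus-strand hits are
found by looking up the reverse complement of the query, so every exact
occurrence on either strand is reported.  Designed for toy genomes
(hundreds of kb), not chromosome-scale inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .config import ConfigError
from .io import SequenceRecord, revcomp


@dataclass
class TagAlignment:
    tag_id: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str
    n_hits: int = 1
    multi: bool = False


class GenomeIndex:
    """Plus-strand k-mer positions; both strands retrievable by lookup."""

    def __init__(self, genome: Sequence[SequenceRecord] | Mapping[str, str],
                 k: int = 12):
        if k < 8:
            raise ConfigError("index k < 8 would blow up on collisions")
        if isinstance(genome, Mapping):
            self.chroms = dict(genome)
        else:
            self.chroms = {rec.id: rec.seq for rec in genome}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.chroms):
            seq = self.chroms[chrom]
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], []).append((chrom, pos))

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())

    def lookup(self, kmer: str, strand: str = "+") -> list[tuple[str, int]]:
        """Loci whose ``strand`` sequence reads ``kmer`` (start of the
        plus-strand interval in both cases)."""
        if len(kmer) != self.k:
            raise ValueError(f"lookup requires a {self.k}-mer")
        if strand == "+":
            return list(self._index.get(kmer, []))
        return list(self._index.get(revcomp(kmer), []))

    def find(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``query`` on both strands."""
        if len(query) < self.k:
            raise ValueError("query shorter than index k")
        hits = []
        for oriented, strand in ((query, "+"), (revcomp(query), "-")):
            for chrom, pos in self._index.get(oriented[:self.k], ()):
                if self.chroms[chrom][pos:pos + len(query)] == oriented:
                    hits.append((chrom, pos, strand))
        hits.sort()
        return hits


def build_index(genome, k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k)


def map_tags(tags: Iterable, index: GenomeIndex,
             max_hits: int = 20) -> list[TagAlignment]:
    """Map tags to all exact genomic loci on both strands.

    Tags exceeding ``max_hits`` loci are flagged ``multi`` but kept, so
    multi-copy precursor accounting stays complete.  Output order is
    (chrom, start, strand), independent of input order.
    """
    alignments: list[TagAlignment] = []
    for tag in sorted(tags, key=lambda t: (t.seq, getattr(t, "tag_id", ""))):
        seq = tag.seq
        hits = index.find(seq)
        if not hits:
            continue
        n = len(hits)
        for chrom, start, strand in hits:
            alignments.append(
                TagAlignment(
                    tag_id=getattr(tag, "tag_id", tag.seq),
                    chrom=chrom,
                    start=start,
                    end=start + len(seq),
                    strand=strand,
                    n_hits=n,
                    multi=n > max_hits,
                )
            )
    alignments.sort(key=lambda a: (a.chrom, a.start, a.strand, a.tag_id))
    return alignments
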