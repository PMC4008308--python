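"""Genomic clustering, seed families, copy numbers, densities, shares.

A cluster is a maximal single-linkage chain of same-chromosome
precursor loci whose nearest ends are strictly less than ``cluster_gap``
(default 10 kb) apart; singletons are not reported.  A family is the set
of matures sharing the identical 7-nt seed (positions 2-8); families
need at least two members to be reported.  Clustering ignores strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import ConfigError
from .preprocess import round_half_up

Locus = tuple[str, int, int, str]  # chrom, start, end, strand


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    members: list[tuple[str, Locus]]  # (name, locus), ordered by start

    @property
    def span(self) -> int:
        return max(l[2] for _, l in self.members) - min(l[1] for _, l in self.members)


@dataclass
class Family:
    family_id: str
    seed: str
    members: list[str]


def build_clusters(
    loci: Sequence[tuple[str, Locus]], cluster_gap: int = 10_000
) -> list[Cluster]:
    """Single-linkage chaining of loci with end-gap < ``cluster_gap``.

    The gap is measured between nearest precursor ends (previous end to
    next start after sorting); chaining is transitive, so A-B close and
    B-C close puts all three in one cluster.  Output is independent of
    input order; singleton chains are dropped.
    """
    by_chrom: dict[str, list[tuple[str, Locus]]] = defaultdict(list)
    for name, locus in loci:
        by_chrom[locus[0]].append((name, locus))
    clusters = []
    n = 0
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda m: (m[1][1], m[1][2], m[0]))
        chain = [members[0]]
        for item in members[1:]:
            prev_end = max(l[2] for _, l in chain)
            if item[1][1] - prev_end < cluster_gap:
                chain.append(item)
            else:
                if len(chain) >= 2:
                    n += 1
                    clusters.append(Cluster(f"cluster-{n}", chrom, chain))
                chain = [item]
        if len(chain) >= 2:
            n += 1
            clusters.append(Cluster(f"cluster-{n}", chrom, chain))
    return clusters


def assign_families(
    matures: Sequence[tuple[str, str]],
    seed_start: int = 2,
    seed_end: int = 8,
    min_members: int = 2,
) -> list[Family]:
    """Group matures by the identical seed (1-based positions 2-8).

    ``matures`` is (name, mature sequence).  Matures shorter than the
    seed window are excluded; the 5p and 3p products of one precursor
    fall into different families whenever their seeds differ.
    """
    by_seed: dict[str, list[str]] = defaultdict(list)
    for name, seq in matures:
        if len(seq) < seed_end:
            continue
        by_seed[seq[seed_start - 1: seed_end]].append(name)
    families = []
    idx = 0
    for seed in sorted(by_seed):
        members = sorted(by_seed[seed])
        if len(members) >= min_members:
            idx += 1
            families.append(Family(f"family-{idx}", seed, members))
    return families


def copy_number_summary(
    loci_by_precursor: Mapping[str, Sequence[Locus]]
) -> tuple[dict[int, int], int]:
    """Histogram of genomic copies per distinct precursor.

    Returns ``(histogram, total_loci)`` where histogram maps a copy
    count to the number of precursors having it; the total is
    sum(copies x multiplicity) and always equals the raw locus count.
    """
    hist: dict[int, int] = defaultdict(int)
    for locs in loci_by_precursor.values():
        unique = {(l[0], l[1], l[2]) for l in locs}
        hist[len(unique)] += 1
    total = sum(copies * n for copies, n in hist.items())
    return dict(sorted(hist.items())), total


def copy_number_total(histogram: Mapping[int, int]) -> int:
    """Total loci implied by a copies->precursors histogram."""
    return sum(copies * n for copies, n in histogram.items())


def chromosome_density(
    counts: Mapping[str, int], lengths_mbp: Mapping[str, float]
) -> pd.DataFrame:
    """Pre-miRNA loci per Mb per chromosome, rounded half-up to 2
    decimals, sorted by decreasing density."""
    rows = []
    for chrom, count in counts.items():
        length = lengths_mbp.get(chrom)
        if length is None:
            raise ConfigError(f"no length for chromosome {chrom!r}")
        if length <= 0:
            raise ConfigError(f"non-positive length for chromosome {chrom!r}")
        rows.append(
            {
                "chrom": chrom,
                "loci": count,
                "length_mbp": length,
                "density": round_half_up(count / length, 2),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["density", "chrom"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def topn_share(counts: Mapping[str, int] | Sequence[tuple[str, int]],
               n: int) -> float | None:
    """Cumulative percent of total counts held by the top-n entries
    (count-descending, names break ties), one decimal; None when all
    counts are zero."""
    items = list(counts.items()) if isinstance(counts, Mapping) else list(counts)
    total = sum(c for _, c in items)
    if total == 0:
        return None
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    top = sum(c for _, c in ranked[:n])
    return round_half_up(100.0 * top / total, 1)
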