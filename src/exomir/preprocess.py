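"""Read cleaning, tag collapsing, ncRNA annotation and stage accounting.

Inputs are assumed adaptor-trimmed; cleaning is a length / ambiguity /
optional mean-quality filter.  Unique sequences become tags carrying a
count, tags matching a labeled ncRNA library (exact substring, either
strand) are classified and excluded from miRNA discovery, and every
stage records its read bookkeeping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .config import ConfigError
from .io import SequenceRecord, revcomp

#: ncRNA classes in priority order; a tag hitting several library
#: classes is assigned the first one.
NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "srpRNA", "repeat")
UNANNOTATED = "unannotated"


@dataclass
class SmallRNATag:
    tag_id: str
    seq: str
    count: int
    annotation: str = UNANNOTATED


@dataclass
class StageAccount:
    stage_name: str
    read_count: int
    unique_count: int | None = None
    parent: str | None = None
    percent_of_parent: float | None = None


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (what the report tables print)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(child: int, parent: int, ndigits: int = 2) -> float | None:
    """100*child/parent rounded half-up; None when the parent is empty."""
    if parent == 0:
        return None
    return round_half_up(100.0 * child / parent, ndigits)


def clean_reads(
    reads: Sequence[SequenceRecord],
    read_len_min: int = 18,
    read_len_max: int = 30,
    min_mean_quality: float | None = None,
) -> tuple[list[SequenceRecord], StageAccount]:
    """Retain reads inside the length window, without N bases, and (when
    qualities are present and a threshold is set) with sufficient mean
    phred quality.  Empty input yields an empty, zero-count account."""
    kept = []
    for read in reads:
        n = len(read.seq)
        if not (read_len_min <= n <= read_len_max):
            continue
        if "N" in read.seq:
            continue
        if (min_mean_quality is not None and read.quality is not None
                and sum(read.quality) / n < min_mean_quality):
            continue
        kept.append(read)
    account = StageAccount(
        stage_name="clean",
        read_count=len(kept),
        unique_count=len({r.seq for r in kept}),
        parent="input",
        percent_of_parent=percent(len(kept), len(reads)),
    )
    return kept, account


def collapse_tags(reads: Sequence[SequenceRecord]) -> list[SmallRNATag]:
    """One tag per distinct sequence; counts conserve the read total.

    Order: count descending, then sequence lexicographic — so the
    operation is deterministic and idempotent under re-collapse.
    """
    counts = Counter(r.seq for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRNATag(tag_id=f"t{idx + 1:06d}", seq=seq, count=count)
        for idx, (seq, count) in enumerate(ordered)
    ]


def annotate_ncrna(
    tags: Iterable[SmallRNATag],
    ncrna_library: Sequence[SequenceRecord],
) -> list[SmallRNATag]:
    """Classify tags that match a labeled ncRNA library record.

    A tag matches when it is an exact substring of a library sequence on
    either strand.  Multi-class hits resolve by the fixed priority
    ``rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA > repeat``; tags
    with no hit stay unannotated (and only those feed miRNA discovery).
    """
    classed: list[tuple[str, str]] = []
    for rec in ncrna_library:
        label = rec.attributes.get("class")
        if label is None:
            raise ConfigError(f"ncRNA library record {rec.id!r} lacks class=")
        if label not in NCRNA_PRIORITY:
            raise ConfigError(f"unknown ncRNA class {label!r} on {rec.id!r}")
        classed.append((rec.seq, label))
    out = []
    for tag in tags:
        hit_classes = {
            label
            for seq, label in classed
            if tag.seq in seq or revcomp(tag.seq) in seq
        }
        annotation = UNANNOTATED
        for label in NCRNA_PRIORITY:
            if label in hit_classes:
                annotation = label
                break
        out.append(SmallRNATag(tag.tag_id, tag.seq, tag.count, annotation))
    return out


def summarize_counts(accounts: Sequence[StageAccount]) -> pd.DataFrame:
    """Stage-accounting report; percentages re-derived from the declared
    parent stage, rounded half-up to 2 decimals (None if undefined)."""
    by_name = {a.stage_name: a for a in accounts}
    rows = []
    for acc in accounts:
        pct = None
        if acc.parent is not None and acc.parent in by_name:
            parent = by_name[acc.parent]
            if acc.read_count > parent.read_count:
                raise ValueError(
                    f"stage {acc.stage_name} exceeds parent {acc.parent}"
                )
            pct = percent(acc.read_count, parent.read_count)
        elif acc.percent_of_parent is not None:
            pct = acc.percent_of_parent
        rows.append(
            {
                "stage": acc.stage_name,
                "reads": acc.read_count,
                "unique": acc.unique_count,
                "parent": acc.parent,
                "percent_of_parent": pct,
            }
        )
    return pd.DataFrame(rows)


def length_distribution(
    items: Sequence, lo: int = 18, hi: int = 25
) -> tuple[pd.Series, float]:
    """Histogram of sequence lengths (weighted by tag count where
    present) and the fraction of mass inside [lo, hi]."""
    weights: Counter = Counter()
    for item in items:
        weights[len(item.seq)] += getattr(item, "count", 1)
    hist = pd.Series(weights, dtype=int).sort_index()
    total = int(hist.sum())
    if total == 0:
        return hist, 0.0
    inside = int(hist[(hist.index >= lo) & (hist.index <= hi)].sum())
    return hist, inside / total


def tag_table(tags: Sequence[SmallRNATag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [t.tag_id for t in tags],
            "seq": [t.seq for t in tags],
            "length": [len(t.seq) for t in tags],
            "count": [t.count for t in tags],
            "annotation": [t.annotation for t in tags],
        }
    )
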