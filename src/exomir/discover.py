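"""Hairpin candidate discovery, filtering, status calls and profiling.

The discovery rules follow the MIREAP-style excision criteria: a mature
of 18-26 nt, precursor fold energy at most -18 kcal/mol (this package's
energy model), mature/star spacing at most 35 nt, at least 10 nt of
genomic flank, and a mature arm predominantly paired to its star.
Surviving candidates then face a pseudo-hairpin filter in the MiPred
spirit — a candidate is discarded when its fold energy is above
-20 kcal/mol or its dinucleotide-shuffle randomization p-value exceeds
0.05 — and are finally matched against same-species and foreign
reference matures to call known / conserved-novel (PS) / novel (PC)
status.

Reads stacked on a precursor are classified into arm, loop-derived and
miRNA-offset (moRNA) classes by interval overlap, mirroring how
published precursor read maps are grouped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .config import ConfigError, PipelineConfig
from .genome_map import TagAlignment
from .io import revcomp
from .preprocess import SmallRNATag
from .rnafold import (FoldResult, duplex_mfe, fold_energy, fold_mfe,
                      randfold_pvalue)

log = logging.getLogger(__name__)

STAR_OVERHANG = 2       # Dicer-style 2-nt 3' overhang on the inferred star
MIN_MATURE_PAIRED = 0.75


@dataclass
class Decision:
    criterion: str
    passed: bool
    value: object = None


@dataclass
class HairpinCandidate:
    """An excised genomic window with the read stack that produced it.

    ``seq`` is in transcribed orientation; tag placements use hairpin
    coordinates on ``seq``.
    """

    candidate_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq: str
    placements: list[tuple[SmallRNATag, int, int]]
    mature_tag: SmallRNATag
    mature_interval: tuple[int, int]
    fold: FoldResult | None = None
    star_interval: tuple[int, int] | None = None
    decisions: list[Decision] = field(default_factory=list)
    passed: bool | None = None

    @property
    def flank_left(self) -> int:
        intervals = [self.mature_interval] + ([self.star_interval] if self.star_interval else [])
        return min(iv[0] for iv in intervals)

    @property
    def flank_right(self) -> int:
        intervals = [self.mature_interval] + ([self.star_interval] if self.star_interval else [])
        return len(self.seq) - max(iv[1] for iv in intervals)


@dataclass
class PrecursorProfile:
    precursor_id: str
    counts: dict[str, int]
    dominant_arm: str
    coupled: bool
    tag_classes: dict[str, str] = field(default_factory=dict)  # tag seq -> class

    @property
    def arm_class(self) -> str:
        has5 = self.counts.get("arm5p", 0) > 0
        has3 = self.counts.get("arm3p", 0) > 0
        if has5 and has3:
            return "both"
        return "5p" if has5 else "3p"


@dataclass
class MatchResult:
    status: str        # known | PS | PC
    ref_name: str | None
    description: str   # Table-style edit summary, e.g. "1nt sub"


@dataclass
class MiRNARecord:
    name: str
    status: str
    mature: str
    seed: str
    count: int
    loci: list[tuple[str, int, int, str]]
    star: str | None = None
    ref_name: str | None = None
    match_description: str = ""
    profile: PrecursorProfile | None = None


# ---------------------------------------------------------------------------
# excision


def excise_candidates(
    alignments: Sequence[TagAlignment],
    tags_by_id: Mapping[str, SmallRNATag],
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> list[HairpinCandidate]:
    """Group stacked alignments into loci and excise folding windows.

    Alignments on one strand whose gap is at most ``excise_merge_gap``
    (default 35 nt, the maximal mature/star spacing) chain into one
    locus; the locus is widened symmetrically to ``excise_window`` and
    then extended by ``flank_len`` of genomic flank on each side,
    truncating with a warning at chromosome ends.  The candidate mature
    is the locus's most abundant tag.
    """
    config = config or PipelineConfig()
    groups: dict[tuple[str, str], list[list[TagAlignment]]] = defaultdict(list)
    for aln in sorted(alignments, key=lambda a: (a.chrom, a.strand, a.start, a.end)):
        lanes = groups[(aln.chrom, aln.strand)]
        if lanes and aln.start - max(a.end for a in lanes[-1]) <= config.excise_merge_gap:
            lanes[-1].append(aln)
        else:
            lanes.append([aln])
    candidates = []
    idx = 0
    for (chrom, strand), lanes in sorted(groups.items()):
        chrom_len = len(genome[chrom])
        for lane in lanes:
            lo = min(a.start for a in lane)
            hi = max(a.end for a in lane)
            if hi - lo < config.excise_window:
                pad = config.excise_window - (hi - lo)
                lo -= pad // 2
                hi += pad - pad // 2
            lo -= config.flank_len
            hi += config.flank_len
            if lo < 0 or hi > chrom_len:
                log.warning("candidate window truncated at %s:%d-%d", chrom, lo, hi)
                lo, hi = max(lo, 0), min(hi, chrom_len)
            seq = genome[chrom][lo:hi]
            if strand == "-":
                seq = revcomp(seq)
            placements = []
            for aln in lane:
                if strand == "+":
                    hs = aln.start - lo
                else:
                    hs = hi - aln.end
                placements.append((tags_by_id[aln.tag_id], hs, hs + (aln.end - aln.start)))
            mature_tag, ms, me = max(
                placements, key=lambda p: (p[0].count, p[0].seq)
            )
            idx += 1
            candidates.append(
                HairpinCandidate(
                    candidate_id=f"cand-{idx:04d}",
                    chrom=chrom,
                    start=lo,
                    end=hi,
                    strand=strand,
                    seq=seq,
                    placements=sorted(placements, key=lambda p: (p[1], p[2])),
                    mature_tag=mature_tag,
                    mature_interval=(ms, me),
                )
            )
    candidates.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return candidates


# ---------------------------------------------------------------------------
# evaluation


def _infer_star(fold: FoldResult, mature: tuple[int, int]) -> tuple[int, int] | None:
    """Pairing partner of the mature arm plus a 2-nt 3' overhang.

    In an antiparallel duplex every mature base b pairs position
    ``star_hi - 1 - (b - ms)``, so ``partner(b) + (b - ms)`` is constant
    on the true helix register; the median of that offset over all
    paired mature bases picks the dominant register and ignores stray
    pairs the fold may form with flanking sequence.
    """
    partner = {}
    for i, j in fold.pairs:
        partner[i] = j
        partner[j] = i
    ms, me = mature
    offsets = [partner[b] + (b - ms) for b in range(ms, me) if b in partner]
    if not offsets:
        return None
    star_hi = int(np.median(offsets)) + 1
    star_lo = star_hi - (me - ms)
    return (star_lo, star_hi + STAR_OVERHANG)


def evaluate_candidate(
    candidate: HairpinCandidate, config: PipelineConfig | None = None
) -> HairpinCandidate:
    """Apply the precursor-excision criteria; records one Decision per
    criterion and sets ``passed`` to their conjunction."""
    config = config or PipelineConfig()
    if candidate.fold is None:
        candidate.fold = fold_mfe(candidate.seq)
    fold = candidate.fold
    ms, me = candidate.mature_interval
    decisions = [
        Decision("mature_length", config.mature_len_min <= me - ms <= config.mature_len_max,
                 me - ms),
        Decision("precursor_mfe", fold.energy <= config.hairpin_mfe_max,
                 round(fold.energy, 2)),
    ]
    star = _infer_star(fold, (ms, me))
    candidate.star_interval = star
    if star is None:
        decisions.append(Decision("mature_pairing", False, 0.0))
        decisions.append(Decision("arm_gap", False, None))
        decisions.append(Decision("flanks", False, None))
    else:
        ss, se = max(star[0], 0), min(star[1], len(candidate.seq))
        candidate.star_interval = (ss, se)
        # the mature/star duplex itself decides the pairing criterion;
        # this is robust to stray flank pairs in the global fold
        dup = duplex_mfe(candidate.seq[ms:me], candidate.seq[ss:se])
        frac = len(dup.pairing) / (me - ms)
        gap = ss - me if ss >= me else ms - se
        decisions.append(Decision("mature_pairing", frac >= MIN_MATURE_PAIRED,
                                  round(frac, 3)))
        decisions.append(Decision("arm_gap", -STAR_OVERHANG <= gap <= config.arm_gap_max,
                                  gap))
        flanks_ok = (candidate.flank_left >= config.flank_len
                     and candidate.flank_right >= config.flank_len)
        decisions.append(Decision("flanks", flanks_ok,
                                  (candidate.flank_left, candidate.flank_right)))
    candidate.decisions = decisions
    candidate.passed = all(d.passed for d in decisions)
    return candidate


def mipred_filter(
    candidate: HairpinCandidate,
    n_shuffles: int | None = None,
    rng_seed: int | None = None,
    config: PipelineConfig | None = None,
) -> tuple[bool, str | None, float | None]:
    """Pseudo-hairpin filter: discard when the fold energy is above the
    pseudo cutoff OR the randomization p-value exceeds the cap.

    Returns ``(keep, reason, pvalue)``; the p-value is not computed when
    the energy test already discards.
    """
    config = config or PipelineConfig()
    n_shuffles = n_shuffles if n_shuffles is not None else config.n_shuffles
    rng_seed = rng_seed if rng_seed is not None else config.rng_seed
    if candidate.fold is None:
        candidate.fold = fold_mfe(candidate.seq)
    # the test applies to the precursor proper (mature + loop + star
    # with flank_len of context), not the whole padded excision window,
    # whose extra random flanks would dominate a shuffle of its length
    ms, me = candidate.mature_interval
    lo, hi = ms, me
    if candidate.star_interval is not None:
        lo = min(lo, candidate.star_interval[0])
        hi = max(hi, candidate.star_interval[1])
    precursor = candidate.seq[max(0, lo - config.flank_len):
                              min(len(candidate.seq), hi + config.flank_len)]
    energy = fold_energy(precursor)
    if energy > config.pseudo_mfe_max:
        return False, "mfe", None
    pvalue = randfold_pvalue(precursor, n_shuffles, rng_seed)
    if pvalue > config.pseudo_p_max:
        return False, "pvalue", pvalue
    return True, None, pvalue


# ---------------------------------------------------------------------------
# known / PS / PC status


def _end_shift_match(query: str, ref: str, max_shift: int = 2) -> bool:
    """True when one sequence sits inside the other with both end
    offsets at most ``max_shift`` (isomiR-style end variation)."""
    short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
    pos = long_.find(short)
    while pos != -1:
        if pos <= max_shift and (len(long_) - pos - len(short)) <= max_shift:
            return True
        pos = long_.find(short, pos + 1)
    return False


def _describe_edits(query: str, ref: str) -> tuple[int, str]:
    aln = edlib.align(query, ref, task="path")
    dist = aln["editDistance"]
    if dist == 0:
        return 0, "perfect"
    counts = {"sub": 0, "insert": 0, "delete": 0}
    num = ""
    for ch in aln["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch == "X":
                counts["sub"] += n
            elif ch == "I":   # base present in query, absent from reference
                counts["insert"] += n
            elif ch == "D":   # base missing from query
                counts["delete"] += n
    parts = [f"{n}nt {kind}" for kind, n in counts.items() if n > 0]
    return dist, ", ".join(parts)


def load_toy_references() -> tuple[list, list]:
    """Shipped toy (same-species, foreign-species) mature references."""
    from importlib import resources

    from .io import read_fasta

    base = resources.files("exomir")
    return (
        read_fasta(str(base.joinpath("data/mirna_ref_ssc_toy.fasta"))),
        read_fasta(str(base.joinpath("data/mirna_ref_foreign_toy.fasta"))),
    )


def match_known(
    mature_seq: str,
    same_species_ref: Sequence,
    foreign_ref: Sequence,
    max_edit: int = 4,
) -> MatchResult:
    """Status call against reference matures.

    known: identical to a same-species mature (or an end-shift of at
    most 2 nt of one, which collapses to that miRNA).  PS: within
    ``max_edit`` edits of a foreign-species mature.  PC otherwise.
    """
    if not same_species_ref and not foreign_ref:
        raise ConfigError("empty miRNA references")
    for rec in same_species_ref:
        if mature_seq == rec.seq or _end_shift_match(mature_seq, rec.seq):
            return MatchResult("known", rec.id, "perfect")
    best: tuple[int, str, str] | None = None
    for rec in foreign_ref:
        dist, desc = _describe_edits(mature_seq, rec.seq)
        if dist <= max_edit and (best is None or dist < best[0]):
            best = (dist, rec.id, desc)
    if best is not None:
        return MatchResult("PS", best[1], best[2])
    return MatchResult("PC", None, "")


# ---------------------------------------------------------------------------
# read-class profiling


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


MORNA_GAP = 2
CLASS_FRACTION = 0.8


def profile_precursor(
    candidate: HairpinCandidate, config: PipelineConfig | None = None
) -> PrecursorProfile:
    """Classify the candidate's read stack into precursor classes.

    Each tag takes the class it maximally overlaps: a read placing more
    than 20% of its length on a mature/star arm is an arm read (the arm
    with the larger overlap; ties favor 5p); otherwise a read with at
    least 80% of its length in the inter-arm region is loop-derived; a
    read at least 80% outside both arms lying between a precursor end
    and the adjacent arm (gap <= 2 nt) is a moRNA; anything else is
    'other'.  Counts are read counts (tag counts summed).
    """
    ms, me = candidate.mature_interval
    star = candidate.star_interval
    if star is None:
        arm5, arm3 = (ms, me), None
    elif star[0] >= me:
        arm5, arm3 = (ms, me), star
    else:
        arm5, arm3 = star, (ms, me)
    counts = {"arm5p": 0, "arm3p": 0, "loop": 0, "moRNA5": 0, "moRNA3": 0, "other": 0}
    tag_classes: dict[str, str] = {}
    for tag, hs, he in candidate.placements:
        if not (0 <= hs and he <= len(candidate.seq)):
            raise ValueError(f"tag {tag.tag_id} outside candidate {candidate.candidate_id}")
        length = he - hs
        ov5 = _overlap((hs, he), arm5)
        ov3 = _overlap((hs, he), arm3) if arm3 else 0
        loop_iv = (arm5[1], arm3[0]) if arm3 else None
        if (ov5 + ov3) > (1 - CLASS_FRACTION) * length:
            cls = "arm5p" if ov5 >= ov3 else "arm3p"
        elif loop_iv and _overlap((hs, he), loop_iv) >= CLASS_FRACTION * length:
            cls = "loop"
        elif he <= arm5[0] + (1 - CLASS_FRACTION) * length and arm5[0] - he <= MORNA_GAP:
            cls = "moRNA5"
        elif arm3 and hs >= arm3[1] - (1 - CLASS_FRACTION) * length and hs - arm3[1] <= MORNA_GAP:
            cls = "moRNA3"
        else:
            cls = "other"
        counts[cls] += tag.count
        tag_classes[tag.seq] = cls
    dominant = "5p" if counts["arm5p"] >= counts["arm3p"] else "3p"
    return PrecursorProfile(
        precursor_id=candidate.candidate_id,
        counts=counts,
        dominant_arm=dominant,
        coupled=counts["arm5p"] > 0 and counts["arm3p"] > 0,
        tag_classes=tag_classes,
    )


def arm_table(counts_by_status: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Arm-usage summary with a computed, column-wise totals row.

    ``counts_by_status`` maps 'known'/'novel' to a mapping with keys
    among {'pre_mirnas', '5p', '3p', 'both', 'mature'}.
    """
    df = pd.DataFrame(counts_by_status).T.fillna(0).astype(int)
    df.loc["total"] = df.sum(axis=0)
    return df


def arm_accounting(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    """Tabulate 5p-only / 3p-only / both-arm precursors by status."""
    counts: dict[str, dict[str, int]] = {
        "known": defaultdict(int), "novel": defaultdict(int)
    }
    for rec in records:
        status = "known" if rec.status == "known" else "novel"
        row = counts[status]
        row["pre_mirnas"] += len(rec.loci)
        row["mature"] += 1
        if rec.profile is not None:
            row[rec.profile.arm_class] += 1
    table = arm_table({k: dict(v) for k, v in counts.items()})
    for col in ("pre_mirnas", "5p", "3p", "both", "mature"):
        if col not in table.columns:
            table[col] = 0
    return table[["pre_mirnas", "5p", "3p", "both", "mature"]]


# ---------------------------------------------------------------------------
# record assembly (isomiR collapsing, naming)


def _is_isomir(tag_iv: tuple[int, int], ref_iv: tuple[int, int],
               max5: int = 1, max3: int = 2) -> bool:
    return (abs(tag_iv[0] - ref_iv[0]) <= max5
            and abs(tag_iv[1] - ref_iv[1]) <= max3)


def build_records(
    kept: Sequence[HairpinCandidate],
    same_species_ref: Sequence,
    foreign_ref: Sequence,
    config: PipelineConfig | None = None,
) -> list[MiRNARecord]:
    """Collapse kept candidates into mature miRNA records.

    Candidates with identical excised sequence are copies of one
    precursor; all isomiRs of the dominant arm (5' shift <= 1 nt,
    3' shift <= 2 nt) collapse into one record whose count is their
    summed tag count.  Status and naming follow the reference match.
    """
    config = config or PipelineConfig()
    # candidates sharing a mature sequence are genomic copies of one
    # precursor (the windows may differ by a few flanking nt)
    by_mature: dict[str, list[HairpinCandidate]] = defaultdict(list)
    for cand in kept:
        by_mature[cand.mature_tag.seq].append(cand)
    records = []
    counters = {"PS": 0, "PC": 0, "known": 0}
    for seq in sorted(by_mature, key=lambda s: (-by_mature[s][0].mature_tag.count, s)):
        group = by_mature[seq]
        cand = group[0]
        profile = profile_precursor(cand, config)
        mature_iv = cand.mature_interval
        count = 0
        seen = set()
        for tag, hs, he in cand.placements:
            if tag.seq in seen:
                continue
            if _is_isomir((hs, he), mature_iv):
                count += tag.count
                seen.add(tag.seq)
        star_seq = None
        if cand.star_interval is not None and profile.coupled:
            ss, se = cand.star_interval
            star_seq = cand.seq[ss:se]
        match = match_known(cand.mature_tag.seq, same_species_ref, foreign_ref,
                            config.max_edit)
        counters[match.status] += 1
        if match.status == "known":
            name = match.ref_name
        else:
            name = f"{match.status}-{counters[match.status]}"
        records.append(
            MiRNARecord(
                name=name,
                status=match.status,
                mature=cand.mature_tag.seq,
                seed=cand.mature_tag.seq[config.seed_start - 1: config.seed_end],
                count=count,
                loci=[(c.chrom, c.start, c.end, c.strand) for c in group],
                star=star_seq,
                ref_name=match.ref_name,
                match_description=match.description,
                profile=profile,
            )
        )
    return records
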