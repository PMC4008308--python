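"""Synthetic genome + small-RNA read generator with ground truth.

Plants hairpin precursors (two near-reverse-complement arms around a
short loop, with genomic flanks) in a random background genome, then
draws reads of known provenance from them: dominant-arm matures, star
arms, loop-derived fragments, miRNA-offset RNAs (moRNAs) abutting the
precursor ends, isomiR end-variants, and ncRNA contaminants.  Every
read's true class is recorded, so downstream discovery, profiling,
clustering and family assignment can be scored exactly.

The generator is deterministic: one seed fixes the genome bytes, the
read set and the provenance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import SequenceRecord, read_fasta, revcomp
from .rnafold import duplex_mfe, fold_energy, randfold_pvalue

_CTX = 25  # genomic context kept on each side of a planted hairpin

READ_CLASSES = ("arm5p", "arm3p", "loop", "moRNA5", "moRNA3", "contaminant")


class SimulationError(RuntimeError):
    pass


@dataclass
class PlantedLocus:
    chrom: str
    start: int   # hairpin interval on the genome, 0-based half-open
    end: int
    strand: str
    context: str = ""      # transcribed orientation, hairpin +- _CTX nt
    ctx_offset: int = _CTX  # hairpin start within context


@dataclass
class PlantedPrecursor:
    precursor_id: str
    hairpin: str                 # transcribed orientation
    arm5: tuple[int, int]        # hairpin coordinates
    arm3: tuple[int, int]
    mature_arm: str              # "5p" | "3p"
    mature: str
    star: str
    copies: int = 1
    loci: list[PlantedLocus] = field(default_factory=list)

    @property
    def loop(self) -> tuple[int, int]:
        return (self.arm5[1], self.arm3[0])

    @property
    def seed(self) -> str:
        return self.mature[1:8]


@dataclass
class SimTruth:
    precursors: list[PlantedPrecursor]
    family_plan: list[list[int]]
    cluster_plan: list[list[int]]
    copy_plan: dict[int, int]

    def loci(self) -> list[tuple[str, PlantedLocus]]:
        return [(p.precursor_id, loc) for p in self.precursors for loc in p.loci]


@dataclass
class DepthPlan:
    """Per-class read budget.

    ``arm_ratio`` is the dominant:star abundance ratio; loop and moRNA
    fractions apply to each precursor's miRNA-derived budget (loop reads
    only where the loop is long enough to host one).
    """

    total_reads: int = 50_000
    arm_ratio: float = 10.0
    loop_frac: float = 0.05
    mor5_frac: float = 0.04
    mor3_frac: float = 0.03


@dataclass
class IsomirPlan:
    """End-variant model: with probability ``p_isomir`` a mature-arm read
    shifts its 3' end within ``off3`` and its 5' end within ``off5``; a
    5' shift is kept only when it preserves nucleotides 2-8."""

    p_isomir: float = 0.25
    off5: tuple[int, ...] = (-1, 0, 1)
    off3: tuple[int, ...] = (-2, -1, 1, 2)


def default_plans(n_precursors: int) -> tuple[list[list[int]], list[list[int]], dict[int, int]]:
    """Canonical family / cluster / copy layout, scaled to the count."""
    families: list[list[int]] = []
    clusters: list[list[int]] = []
    copies: dict[int, int] = {}
    if n_precursors >= 3:
        families.append([0, 1, 2])
    if n_precursors >= 5:
        families.append([3, 4])
    if n_precursors >= 8:
        clusters.append([5, 6, 7])
    if n_precursors >= 10:
        clusters.append([8, 9])
    if n_precursors >= 11:
        copies[10] = 3
    if n_precursors >= 12:
        copies[11] = 2
    return families, clusters, copies


def load_toy_ncrna() -> list[SequenceRecord]:
    """The shipped synthetic labeled ncRNA library."""
    path = resources.files("exomir").joinpath("data/ncrna_synthetic.fasta")
    return read_fasta(str(path))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _mutate_interior(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute ``n_mut`` interior positions (ends stay paired).

    Mismatch sites keep >= 5 nt of separation so the duplex stays a run
    of well-stacked helices interrupted by single-nt loops, as in real
    mature/star duplexes.
    """
    if n_mut == 0 or len(seq) < 6:
        return seq
    chars = list(seq)
    for _ in range(50):
        positions = rng.choice(np.arange(2, len(seq) - 2), size=n_mut, replace=False)
        if n_mut == 1 or np.diff(np.sort(positions)).min() >= 5:
            break
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_genome(
    n_precursors: int = 20,
    genome_len: int = 500_000,
    family_plan: list[list[int]] | None = None,
    cluster_plan: list[list[int]] | None = None,
    copy_plan: dict[int, int] | None = None,
    rng_seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Build a toy genome with planted precursor hairpins.

    Arms are near-reverse complements (0-3 interior mismatches) around
    an 8-15 nt loop; each hairpin is re-folded and resampled until its
    energy clears both the precursor and the pseudo-hairpin cutoffs, so
    planted loci are discoverable by construction.  Clustered loci are
    placed with pairwise gaps below ``cluster_gap``; all other loci are
    separated by more than ``cluster_gap``.  Multi-copy precursors are
    exact duplicates at distinct loci.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(rng_seed)
    if family_plan is None and cluster_plan is None and copy_plan is None:
        family_plan, cluster_plan, copy_plan = default_plans(n_precursors)
    family_plan = family_plan or []
    cluster_plan = cluster_plan or []
    copy_plan = copy_plan or {}

    seed_of_group: dict[int, str] = {}
    for g, members in enumerate(family_plan):
        seed_of_group.update({i: g for i in members})
    group_seeds = {}
    for g in range(len(family_plan)):
        while True:
            cand_seed = _random_seq(rng, 7)
            if _gc(cand_seed) <= 4 / 7:
                group_seeds[g] = cand_seed
                break

    energy_cut = min(config.hairpin_mfe_max, config.pseudo_mfe_max)
    precursors: list[PlantedPrecursor] = []
    used_seeds: set[str] = set(group_seeds.values())
    n_loop_eligible = max(2, n_precursors // 4)
    for i in range(n_precursors):
        for _attempt in range(80):
            arm_len = int(rng.integers(20, 25))
            mature = _random_seq(rng, arm_len)
            if i in seed_of_group:
                seed = group_seeds[seed_of_group[i]]
            else:
                seed = mature[1:8]
                if seed in used_seeds:
                    continue  # avoid accidental family collisions
            mature = mature[0] + seed + mature[8:]
            # GC-rich matures fold well even after a dinucleotide
            # shuffle (CG doublets survive), blurring the p-value
            # margin; keep the generator in the unambiguous regime
            if _gc(mature) > 0.55:
                continue
            # the first few precursors carry a loop long enough for a
            # loop-derived read; the rest draw shorter loops
            loop_len = 15 if i < n_loop_eligible else int(rng.integers(8, 16))
            loop = _random_seq(rng, loop_len)
            # 1-3 interior mismatches: real mature/star duplexes are
            # imperfect, and a perfect inverted repeat would make every
            # arm read map to both strands of its own locus
            n_mut = int(rng.integers(1, 4))
            mature_arm = "5p" if rng.random() < 0.5 else "3p"
            if mature_arm == "5p":
                arm5_seq = mature
                arm3_seq = _mutate_interior(rng, revcomp(mature), n_mut)
                star = arm3_seq
            else:
                arm3_seq = mature
                arm5_seq = _mutate_interior(rng, revcomp(mature), n_mut)
                star = arm5_seq
            hairpin = arm5_seq + loop + arm3_seq
            duplex = duplex_mfe(mature, star)
            well_paired = len(duplex.pairing) >= 0.8 * len(mature)
            if not (well_paired and fold_energy(hairpin) <= energy_cut):
                continue
            # pre-screen with a small randomization so the planted fold
            # also stands out against its own dinucleotide background,
            # padded with throwaway flanks to mimic the excised precursor
            padded = _random_seq(rng, 10) + hairpin + _random_seq(rng, 10)
            if randfold_pvalue(padded, 99, rng) <= 0.02:
                break
        else:
            raise SimulationError(f"could not sample a passing hairpin for #{i}")
        if i not in seed_of_group:
            used_seeds.add(mature[1:8])
        precursors.append(
            PlantedPrecursor(
                precursor_id=f"pre-{i + 1:03d}",
                hairpin=hairpin,
                arm5=(0, len(arm5_seq)),
                arm3=(len(arm5_seq) + loop_len, len(hairpin)),
                mature_arm=mature_arm,
                mature=mature,
                star=star,
                copies=copy_plan.get(i, 1),
            )
        )

    # placement units: a cluster is placed as one block with small
    # internal gaps; everything else gets > cluster_gap of separation
    clustered = {i for group in cluster_plan for i in group}
    units: list[list[int]] = [list(group) for group in cluster_plan]
    units += [[i] for i in range(n_precursors) if i not in clustered]
    extra_copies = [i for i in range(n_precursors)
                    for _ in range(precursors[i].copies - 1)]
    units += [[i] for i in extra_copies]
    order = list(rng.permutation(len(units)))

    chrom = "chr1"
    genome_arr = rng.integers(0, 4, genome_len)
    genome_seq = list("".join("ACGT"[b] for b in genome_arr))
    cursor = int(rng.integers(1000, 3000))
    for unit_idx in order:
        unit = units[unit_idx]
        for pos_in_unit, i in enumerate(unit):
            prec = precursors[i]
            hp = prec.hairpin
            if cursor + len(hp) + _CTX >= genome_len:
                raise SimulationError("genome_len too small for the requested loci")
            strand = "+" if rng.random() < 0.5 else "-"
            insert = hp if strand == "+" else revcomp(hp)
            genome_seq[cursor:cursor + len(hp)] = insert
            prec.loci.append(
                PlantedLocus(chrom, cursor, cursor + len(hp), strand)
            )
            if pos_in_unit < len(unit) - 1:  # intra-cluster gap, < cluster_gap
                cursor += len(hp) + int(rng.integers(1000, 8000))
            else:
                cursor += len(hp) + config.cluster_gap + int(rng.integers(2000, 8000))

    genome = [SequenceRecord(chrom, "".join(genome_seq))]
    for prec in precursors:
        for loc in prec.loci:
            ctx = genome[0].seq[loc.start - _CTX: loc.end + _CTX]
            loc.context = ctx if loc.strand == "+" else revcomp(ctx)
            loc.ctx_offset = _CTX
    truth = SimTruth(precursors, family_plan, cluster_plan, dict(copy_plan))
    return genome, truth


def simulate_reads(
    truth: SimTruth,
    depth_plan: DepthPlan | None = None,
    isomir_plan: IsomirPlan | None = None,
    contaminant_fraction: float = 0.15,
    ncrna_library: Sequence[SequenceRecord] | None = None,
    rng_seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw a read set of known provenance from planted precursors.

    Emits exactly ``depth_plan.total_reads`` reads; the provenance table
    records each read's true class, source precursor and end offsets.
    moRNA reads abut the mature-arm-distal precursor end with a 0-2 nt
    gap; loop reads are drawn only from precursors whose loop can host
    at least 80% of a minimum-length read.
    """
    config = config or PipelineConfig()
    depth_plan = depth_plan or DepthPlan()
    isomir_plan = isomir_plan or IsomirPlan()
    if ncrna_library is None:
        ncrna_library = load_toy_ncrna()
    rng = np.random.default_rng(rng_seed)

    min_loop = int(np.ceil(0.8 * config.read_len_min))
    for prec in truth.precursors:
        if min(len(prec.mature), len(prec.star)) < config.read_len_min:
            raise SimulationError(f"{prec.precursor_id}: arm shorter than read_len_min")

    total = depth_plan.total_reads
    n_cont = int(round(total * contaminant_fraction))
    n_mirna = total - n_cont
    n_prec = len(truth.precursors)
    weights = rng.lognormal(0.0, 1.0, n_prec)
    weights /= weights.sum()
    per_prec = rng.multinomial(n_mirna, weights)

    reads: list[SequenceRecord] = []
    rows: list[dict] = []

    def emit(seq: str, cls: str, source: str, off5: int = 0, off3: int = 0) -> None:
        rid = f"r{len(reads) + 1:07d}"
        reads.append(SequenceRecord(rid, seq, quality=[40] * len(seq)))
        rows.append({"read_id": rid, "seq": seq, "class": cls,
                     "source": source, "off5": off5, "off3": off3})

    for i, prec in enumerate(truth.precursors):
        budget = int(per_prec[i])
        if budget == 0:
            continue
        loop_len = prec.loop[1] - prec.loop[0]
        loop_frac = depth_plan.loop_frac if loop_len >= min_loop else 0.0
        fracs = np.array([loop_frac, depth_plan.mor5_frac, depth_plan.mor3_frac])
        n_loop, n_mor5, n_mor3 = rng.multinomial(budget, np.append(fracs, 1 - fracs.sum()))[:3]
        n_arms = budget - n_loop - n_mor5 - n_mor3
        n_star = int(round(n_arms / (depth_plan.arm_ratio + 1)))
        n_dom = n_arms - n_star
        dom_arm = prec.arm5 if prec.mature_arm == "5p" else prec.arm3
        star_arm = prec.arm3 if prec.mature_arm == "5p" else prec.arm5
        dom_cls = "arm5p" if prec.mature_arm == "5p" else "arm3p"
        star_cls = "arm3p" if prec.mature_arm == "5p" else "arm5p"
        for _ in range(n_dom):
            loc = prec.loci[rng.integers(len(prec.loci))]
            ho = loc.ctx_offset
            s, e = dom_arm[0] + ho, dom_arm[1] + ho
            off5 = off3 = 0
            if rng.random() < isomir_plan.p_isomir:
                off3 = int(rng.choice(isomir_plan.off3))
                cand5 = int(rng.choice(isomir_plan.off5))
                shifted = loc.context[s + cand5: e]
                if shifted[1:8] == prec.mature[1:8]:  # seed must survive
                    off5 = cand5
            seq = loc.context[s + off5: e + off3]
            if not (config.read_len_min <= len(seq) <= config.read_len_max):
                seq, off5, off3 = loc.context[s:e], 0, 0
            emit(seq, dom_cls, prec.precursor_id, off5, off3)
        for _ in range(n_star):
            emit(prec.star, star_cls, prec.precursor_id)
        for _ in range(n_loop):
            loc = prec.loci[rng.integers(len(prec.loci))]
            ls = prec.loop[0] + loc.ctx_offset
            u = int(rng.integers(loop_len - config.read_len_min, 1))
            seq = loc.context[ls + u: ls + u + config.read_len_min]
            emit(seq, "loop", prec.precursor_id)
        for n_mor, cls in ((n_mor5, "moRNA5"), (n_mor3, "moRNA3")):
            for _ in range(n_mor):
                loc = prec.loci[rng.integers(len(prec.loci))]
                ho = loc.ctx_offset
                gap = int(rng.integers(0, 3))
                length = int(rng.integers(18, 21))
                if cls == "moRNA5":
                    end = ho + 0 - gap  # precursor 5' end is hairpin pos 0
                    seq = loc.context[end - length: end]
                else:
                    start = ho + len(prec.hairpin) + gap
                    seq = loc.context[start: start + length]
                emit(seq, cls, prec.precursor_id)
    for _ in range(n_cont):
        rec = ncrna_library[rng.integers(len(ncrna_library))]
        length = int(rng.integers(18, 26))
        pos = int(rng.integers(0, len(rec.seq) - length + 1))
        emit(rec.seq[pos: pos + length], "contaminant", rec.id)

    provenance = pd.DataFrame(rows)
    return reads, provenance


def simulate_dataset(
    n_precursors: int = 20,
    total_reads: int = 50_000,
    rng_seed: int = 0,
    config: PipelineConfig | None = None,
    isomir_plan: IsomirPlan | None = None,
    contaminant_fraction: float = 0.15,
):
    """Genome + truth + reads + provenance in one call (shared seed)."""
    genome, truth = simulate_genome(
        n_precursors=n_precursors, rng_seed=rng_seed, config=config
    )
    reads, provenance = simulate_reads(
        truth,
        depth_plan=DepthPlan(total_reads=total_reads),
        isomir_plan=isomir_plan,
        contaminant_fraction=contaminant_fraction,
        rng_seed=rng_seed + 1,
        config=config,
    )
    return genome, truth, reads, provenance


# ---------------------------------------------------------------------------
# scoring against ground truth


def match_mature_to_truth(seq: str, truth: SimTruth) -> str | None:
    """Planted precursor whose mature or star arm this sequence matches
    (placement on the hairpin context overlapping an arm by >= 15 nt)."""
    for prec in truth.precursors:
        for locus in prec.loci:
            pos = locus.context.find(seq)
            while pos != -1:
                ho = locus.ctx_offset
                for arm in (prec.arm5, prec.arm3):
                    lo = max(pos, arm[0] + ho)
                    hi = min(pos + len(seq), arm[1] + ho)
                    if hi - lo >= 15:
                        return prec.precursor_id
                pos = locus.context.find(seq, pos + 1)
    return None


def score_discovery(truth: SimTruth, mature_seqs: Sequence[str]) -> dict:
    """Recall of planted precursors and precision of reported matures."""
    hit: set[str] = set()
    n_match = 0
    for seq in mature_seqs:
        pid = match_mature_to_truth(seq, truth)
        if pid is not None:
            n_match += 1
            hit.add(pid)
    n_prec = len(truth.precursors)
    return {
        "recall": len(hit) / n_prec if n_prec else float("nan"),
        "precision": n_match / len(mature_seqs) if mature_seqs else float("nan"),
        "n_discovered": len(mature_seqs),
        "n_planted": n_prec,
    }


def score_read_classes(
    provenance: pd.DataFrame, tag_classes: dict[str, str]
) -> dict:
    """Accuracy of precursor read-class calls against true provenance.

    ``tag_classes`` maps tag sequence -> assigned class.  Scored over
    precursor-derived reads whose sequence was profiled at all (reads of
    precursors the pipeline missed are reported separately).
    """
    prec_reads = provenance[provenance["class"] != "contaminant"]
    assigned = prec_reads["seq"].map(tag_classes)
    covered = assigned.notna()
    correct = (assigned[covered] == prec_reads.loc[covered, "class"]).sum()
    n_covered = int(covered.sum())
    return {
        "accuracy": correct / n_covered if n_covered else float("nan"),
        "n_scored": n_covered,
        "coverage": n_covered / len(prec_reads) if len(prec_reads) else float("nan"),
    }
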