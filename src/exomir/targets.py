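"""Seed-constrained target-site prediction and reporter-construct math.

A site is a 7-mer on the 3'UTR exactly Watson-Crick complementary (no
G:U wobble) to miRNA positions 2-8; each site is then scored by the
duplex free energy of the full miRNA against the site plus flanking
context, and accepted when the energy clears the cutoff (default
-25 kcal/mol under this package's duplex model).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .config import PipelineConfig
from .io import read_fasta, revcomp
from .rnafold import DuplexResult, duplex_mfe

#: Strict Watson-Crick complement used for seed matching (N excluded).
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class TargetSite:
    mirna: str
    utr: str
    start: int           # seed-match interval on the UTR, 0-based half-open
    end: int
    seed_match: str      # the UTR 7-mer
    duplex: DuplexResult
    accepted: bool


def seed_site_motif(mirna_seq: str, seed_start: int = 2, seed_end: int = 8) -> str:
    """UTR motif complementary to the miRNA seed (reverse complement of
    positions ``seed_start``..``seed_end``, 1-based inclusive)."""
    seed = mirna_seq[seed_start - 1: seed_end]
    return "".join(_WC[b] for b in reversed(seed))


def find_seed_sites(
    utr_seq: str,
    mirna_seq: str | None = None,
    motif: str | None = None,
    seed_start: int = 2,
    seed_end: int = 8,
) -> list[int]:
    """All start positions of the seed-match motif on the UTR.

    Give either a miRNA (sites are exact Watson-Crick reverse
    complements of its seed) or a site motif directly.  Overlapping
    occurrences are all reported.
    """
    if (mirna_seq is None) == (motif is None):
        raise ValueError("provide exactly one of mirna_seq or motif")
    if motif is None:
        motif = seed_site_motif(mirna_seq, seed_start, seed_end)
    positions = []
    pos = utr_seq.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = utr_seq.find(motif, pos + 1)
    return positions


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    config: PipelineConfig | None = None,
) -> list[TargetSite]:
    """Predict and score target sites for each miRNA x UTR pair.

    For every seed site, the duplex energy of the full miRNA against
    the site extended by ``duplex_context`` nt on each side decides
    acceptance (energy <= ``duplex_mfe_max``).  Sorted by energy.
    """
    config = config or PipelineConfig()
    sites = []
    for mir_name in sorted(mirnas):
        mir_seq = mirnas[mir_name]
        for utr_name in sorted(utrs):
            utr_seq = utrs[utr_name]
            if len(utr_seq) < config.seed_end - config.seed_start + 1:
                continue
            for pos in find_seed_sites(utr_seq, mirna_seq=mir_seq,
                                       seed_start=config.seed_start,
                                       seed_end=config.seed_end):
                end = pos + (config.seed_end - config.seed_start + 1)
                ctx_lo = max(0, pos - config.duplex_context)
                ctx_hi = min(len(utr_seq), end + config.duplex_context)
                duplex = duplex_mfe(mir_seq, utr_seq[ctx_lo:ctx_hi])
                sites.append(
                    TargetSite(
                        mirna=mir_name,
                        utr=utr_name,
                        start=pos,
                        end=end,
                        seed_match=utr_seq[pos:end],
                        duplex=duplex,
                        accepted=duplex.energy <= config.duplex_mfe_max,
                    )
                )
    sites.sort(key=lambda s: (s.duplex.energy, s.mirna, s.utr, s.start))
    return sites


def build_construct(
    utr_seq: str, delete_interval: tuple[int, int]
) -> tuple[str, str, int]:
    """Reporter-insert pair: the wild-type UTR fragment and the same
    fragment with ``delete_interval`` removed.

    Returns ``(wild_insert, delete_insert, n_deleted)``; the lengths
    always reconcile as ``len(wild) - n_deleted == len(delete)``.
    """
    lo, hi = delete_interval
    if not (0 <= lo <= hi <= len(utr_seq)):
        raise ValueError(f"delete interval {delete_interval} outside the UTR")
    return utr_seq, utr_seq[:lo] + utr_seq[hi:], hi - lo


def load_igf1r_utr() -> dict[str, str]:
    """The shipped IGF-1R 3'UTR reporter fragments (wild type and the
    12-nt deletion variant)."""
    path = resources.files("exomir").joinpath("data/igf1r_utr.fasta")
    return {rec.id: rec.seq for rec in read_fasta(str(path))}
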