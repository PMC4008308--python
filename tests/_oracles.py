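"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or naive
scanning, sharing nothing with the dynamic programs / indexes it
checks except the published model parameters.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from exomir.io import revcomp
from exomir.rnafold import (
    HAIRPIN_PENALTY,
    INTERNAL_PENALTY,
    MIN_HAIRPIN,
    MULTILOOP_PENALTY,
    _PAIR_NAMES,
    load_stack_table,
)

_STACKS = load_stack_table()
_PAIRABLE = set(_PAIR_NAMES)


def _pairable(a: str, b: str) -> bool:
    return a + b in _PAIRABLE


def enumerate_structures(seq: str) -> list[frozenset]:
    """All nested pair sets over ``seq`` (min hairpin loop 3)."""

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple:
        if j - i + 1 <= 0:
            return (frozenset(),)
        out = list(structs(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if _pairable(seq[i], seq[k]):
                for s1 in structs(i + 1, k - 1):
                    for s2 in structs(k + 1, j):
                        out.append(s1 | s2 | {(i, k)})
        return tuple(out)

    return list(structs(0, len(seq) - 1))


def structure_energy(seq: str, pairs: frozenset) -> float:
    """Loop-decomposition energy of one structure under the model."""
    energy = 0.0
    by_start = sorted(pairs)
    for (i, j) in by_start:
        children = [(k, l) for (k, l) in by_start if i < k and l < j
                    and not any(k2 < k and l < l2 and i < k2
                                for (k2, l2) in by_start if i < k2 and l2 < j)]
        if not children:
            energy += HAIRPIN_PENALTY
        elif len(children) == 1:
            k, l = children[0]
            if k == i + 1 and l == j - 1:
                p = _PAIR_NAMES.index(seq[i] + seq[j])
                q = _PAIR_NAMES.index(seq[k] + seq[l])
                energy += _STACKS[p, q]
            else:
                energy += INTERNAL_PENALTY
        else:
            energy += MULTILOOP_PENALTY
    return energy


def oracle_fold_mfe(seq: str) -> float:
    """MFE by exhaustive enumeration of all nested structures."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        if pairs:
            best = min(best, structure_energy(seq, pairs))
    return best


def naive_scan(genome: dict[str, str], tag: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``tag`` on both strands, by string scan."""
    hits = []
    rc = revcomp(tag)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for query, strand in ((tag, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append((chrom, start, strand))
                start = seq.find(query, start + 1)
    hits.sort()
    return hits


def dinuc_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def enumerate_dinuc_permutations(seq: str) -> set[str]:
    """All strings with the same dinucleotide multiset and endpoints.

    Brute force over permutations of the interior characters; feasible
    for sequences of length <= 6.
    """
    ref = dinuc_counts(seq)
    interior = seq[1:-1]
    out = set()
    for perm in set(permutations(interior)):
        cand = seq[0] + "".join(perm) + seq[-1]
        if dinuc_counts(cand) == ref:
            out.add(cand)
    return out
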