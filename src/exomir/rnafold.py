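"""Thermodynamic cores: hairpin folding, duplex hybridization, shuffling.

The secondary-structure model is a Nussinov-style dynamic program
extended with nearest-neighbor stacking energies and simple loop
penalties — not the full Turner model.  Its rules:

* admissible pairs: Watson-Crick plus G:T (G:U) wobble, nested, no
  pseudoknots, hairpin loops of at least 3 nt;
* every stacked pair of pairs contributes the tabulated stacking free
  energy (``data/stack_energies.tsv``);
* loop terms are flat penalties: hairpin +4.0 kcal/mol, bulge/internal
  loop +3.0 per occurrence (at most 12 unpaired nt per internal loop),
  multibranch loop +4.5;
* the exterior loop is free, so the empty structure always has energy
  0 and reported energies are <= 0.

Absolute energies therefore differ from Mfold/RNAhybrid; all energy
thresholds in :class:`exomir.config.PipelineConfig` are relative to
this model.

The duplex model reuses the same stack table for intermolecular pairs
(antiparallel, bulges limited to 2 nt per side per interruption, +3.0
per interruption, no intramolecular structure), and the randomization
p-value uses exact dinucleotide-preserving shuffles built on Euler
paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

HAIRPIN_PENALTY = 4.0
INTERNAL_PENALTY = 3.0
MULTILOOP_PENALTY = 4.5
MIN_HAIRPIN = 3
MAX_INTERNAL_UNPAIRED = 12

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAIR_NAMES = ["AT", "TA", "CG", "GC", "GT", "TG"]
_EPS = 1e-7
_INF = 1e30


class FoldInputError(ValueError):
    """Sequence not over the {A,C,G,T,N} alphabet."""


def _pair_code_table() -> np.ndarray:
    table = np.full((5, 5), -1, dtype=np.int8)
    for idx, name in enumerate(_PAIR_NAMES):
        table[_BASE_CODE[name[0]], _BASE_CODE[name[1]]] = idx
    return table


_PAIR_CODE = _pair_code_table()


def load_stack_table(path: str | Path | None = None) -> np.ndarray:
    """6x6 stacking-energy matrix indexed by (outer pair, inner pair)."""
    if path is None:
        path = resources.files("exomir").joinpath("data/stack_energies.tsv")
    table = np.zeros((6, 6))
    seen = 0
    with open(str(path)) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("outer"):
                continue
            outer, inner, energy = line.split()
            table[_PAIR_NAMES.index(outer), _PAIR_NAMES.index(inner)] = float(energy)
            seen += 1
    if seen != 36:
        raise ValueError(f"stack table has {seen} entries, expected 36")
    return table


_STACKS = load_stack_table()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise FoldInputError(f"invalid base {exc.args[0]!r}") from None


@dataclass
class FoldResult:
    structure: str
    energy: float
    pairs: list[tuple[int, int]]


@dataclass
class DuplexResult:
    energy: float
    pairing: list[tuple[int, int]]  # (position in miRNA, position in target)
    site_interval: tuple[int, int]  # half-open interval covered on the target


# ---------------------------------------------------------------------------
# hairpin folding


@njit(cache=True)
def _fill(codes, stacks, pair_code, maxloop):  # pragma: no cover - jitted
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    M = np.full((n, n), _INF)   # >=1 helix branch inside [i, j]
    M2 = np.full((n, n), _INF)  # >=2 helix branches inside [i, j]
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if span > MIN_HAIRPIN:
                p = pair_code[codes[i], codes[j]]
                if p >= 0:
                    best = HAIRPIN_PENALTY
                    q = pair_code[codes[i + 1], codes[j - 1]]
                    if q >= 0 and V[i + 1, j - 1] < _INF / 2:
                        e = stacks[p, q] + V[i + 1, j - 1]
                        if e < best:
                            best = e
                    for d1 in range(0, maxloop + 1):
                        k = i + 1 + d1
                        if k >= j:
                            break
                        for d2 in range(0, maxloop + 1 - d1):
                            ll = j - 1 - d2
                            if ll <= k:
                                break
                            if d1 == 0 and d2 == 0:
                                continue
                            if V[k, ll] < _INF / 2:
                                e = INTERNAL_PENALTY + V[k, ll]
                                if e < best:
                                    best = e
                    if M2[i + 1, j - 1] < _INF / 2:
                        e = MULTILOOP_PENALTY + M2[i + 1, j - 1]
                        if e < best:
                            best = e
                    V[i, j] = best
            m = M[i, j - 1]
            m2 = M2[i, j - 1]
            if V[i, j] < m:
                m = V[i, j]
            for k in range(i + 1, j):
                if V[k, j] < _INF / 2:
                    if V[k, j] < m:
                        m = V[k, j]
                    if M[i, k - 1] < _INF / 2:
                        e = M[i, k - 1] + V[k, j]
                        if e < m:
                            m = e
                        if e < m2:
                            m2 = e
            M[i, j] = m
            M2[i, j] = m2
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for k in range(0, j):
            if V[k, j] < _INF / 2:
                left = W[k - 1] if k > 0 else 0.0
                e = left + V[k, j]
                if e < best:
                    best = e
        W[j] = best
    return V, M, M2, W


def fold_energy(seq: str) -> float:
    """Minimum free energy only (no structure), kcal/mol, <= 0."""
    if len(seq) <= MIN_HAIRPIN + 1:
        return 0.0
    codes = _encode(seq)
    _, _, _, W = _fill(codes, _STACKS, _PAIR_CODE, MAX_INTERNAL_UNPAIRED)
    return min(0.0, float(W[-1]))


def _trace_v(i, j, codes, V, M, M2):
    pairs = [(i, j)]
    p = _PAIR_CODE[codes[i], codes[j]]
    q = _PAIR_CODE[codes[i + 1], codes[j - 1]] if j - i >= 2 else -1
    target = V[i, j]
    # case order fixes the tie-break: extend the helix first, then the
    # 5'-most/shortest loop, then multiloop, finally close a hairpin
    if (q >= 0 and V[i + 1, j - 1] < _INF / 2
            and abs(_STACKS[p, q] + V[i + 1, j - 1] - target) < _EPS):
        return pairs + _trace_v(i + 1, j - 1, codes, V, M, M2)
    for d1 in range(0, MAX_INTERNAL_UNPAIRED + 1):
        k = i + 1 + d1
        if k >= j:
            break
        for d2 in range(0, MAX_INTERNAL_UNPAIRED + 1 - d1):
            ll = j - 1 - d2
            if ll <= k:
                break
            if d1 == 0 and d2 == 0:
                continue
            if V[k, ll] < _INF / 2 and abs(INTERNAL_PENALTY + V[k, ll] - target) < _EPS:
                return pairs + _trace_v(k, ll, codes, V, M, M2)
    if M2[i + 1, j - 1] < _INF / 2 and abs(MULTILOOP_PENALTY + M2[i + 1, j - 1] - target) < _EPS:
        return pairs + _trace_m(i + 1, j - 1, codes, V, M, M2, two=True)
    return pairs  # hairpin loop


def _trace_m(i, j, codes, V, M, M2, two=False):
    A = M2 if two else M
    if j - 1 >= i and A[i, j - 1] < _INF / 2 and abs(A[i, j - 1] - A[i, j]) < _EPS:
        return _trace_m(i, j - 1, codes, V, M, M2, two)
    if not two and abs(V[i, j] - M[i, j]) < _EPS:
        return _trace_v(i, j, codes, V, M, M2)
    for k in range(i + 1, j):
        if V[k, j] >= _INF / 2:
            continue
        if not two and abs(V[k, j] - M[i, j]) < _EPS:
            return _trace_v(k, j, codes, V, M, M2)
        if M[i, k - 1] < _INF / 2 and abs(M[i, k - 1] + V[k, j] - A[i, j]) < _EPS:
            return (_trace_m(i, k - 1, codes, V, M, M2, False)
                    + _trace_v(k, j, codes, V, M, M2))
    raise AssertionError("fold traceback failed")


def fold_mfe(seq: str) -> FoldResult:
    """Fold to the minimum-free-energy nested structure.

    Ties are broken deterministically: pairing the 5'-most admissible
    branch and extending helices in preference to opening loops.
    """
    n = len(seq)
    if n <= MIN_HAIRPIN + 1:
        return FoldResult("." * n, 0.0, [])
    codes = _encode(seq)
    V, M, M2, W = _fill(codes, _STACKS, _PAIR_CODE, MAX_INTERNAL_UNPAIRED)
    energy = min(0.0, float(W[-1]))
    pairs: list[tuple[int, int]] = []
    if energy < -_EPS:
        j = n - 1
        while j > 0:
            prev = W[j - 1] if j > 0 else 0.0
            if abs(W[j] - prev) < _EPS:
                j -= 1
                continue
            chosen = -1
            for k in range(0, j):  # 5'-most branch
                if V[k, j] >= _INF / 2:
                    continue
                left = W[k - 1] if k > 0 else 0.0
                if abs(left + V[k, j] - W[j]) < _EPS:
                    chosen = k
                    break
            if chosen < 0:
                raise AssertionError("external traceback failed")
            pairs.extend(_trace_v(chosen, j, codes, V, M, M2))
            j = chosen - 1
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult("".join(structure), energy, pairs)


# ---------------------------------------------------------------------------
# intermolecular duplex

_MAX_BULGE = 2


def duplex_mfe(mirna_seq: str, target_seq: str) -> DuplexResult:
    """Best intermolecular hybridization energy.

    The miRNA is read 5'->3' against the target 3'->5' (antiparallel).
    Only intermolecular pairs are formed; consecutive pairs stack, and
    each interruption of up to ``_MAX_BULGE`` nt per side costs the flat
    internal-loop penalty.  Energy 0 with empty pairing when no
    favorable duplex exists.
    """
    x = _encode(mirna_seq)
    y = _encode(target_seq)
    m, t = len(x), len(y)
    H = np.full((m, t), _INF)
    back: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(m):
        for j in range(t - 1, -1, -1):
            p = _PAIR_CODE[x[i], y[j]]
            if p < 0:
                continue
            best = 0.0  # open a new duplex at this pair
            for di in range(1, _MAX_BULGE + 2):
                ii = i - di
                if ii < 0:
                    break
                for dj in range(1, _MAX_BULGE + 2):
                    jj = j + dj
                    if jj >= t:
                        break
                    if H[ii, jj] >= _INF / 2:
                        continue
                    if di == 1 and dj == 1:
                        q = _PAIR_CODE[x[ii], y[jj]]
                        e = H[ii, jj] + _STACKS[q, p]
                    else:
                        e = H[ii, jj] + INTERNAL_PENALTY
                    if e < best - _EPS:
                        best = e
                        back[(i, j)] = (ii, jj)
            H[i, j] = best
    if not np.any(H < -_EPS):
        return DuplexResult(0.0, [], (0, 0))
    i, j = np.unravel_index(int(np.argmin(H)), H.shape)
    energy = float(H[i, j])
    pairing = [(int(i), int(j))]
    while (i, j) in back:
        i, j = back[(i, j)]
        pairing.append((int(i), int(j)))
    pairing.reverse()
    cols = [j for _, j in pairing]
    return DuplexResult(energy, pairing, (min(cols), max(cols) + 1))


# ---------------------------------------------------------------------------
# dinucleotide shuffling and the randomization p-value


def dinucleotide_shuffle(seq: str, rng_seed=None) -> str:
    """Shuffle preserving the exact dinucleotide multiset.

    Euler-path construction (Altschul-Erickson): the doublet graph of
    the sequence is rewired by drawing a random in-tree toward the last
    symbol, which guarantees the random walk uses every edge.  The
    first and last nucleotide are invariant.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(edges)
    for _ in range(10_000):
        # draw one outgoing edge per non-terminal vertex; keep only
        # draws that form an in-tree rooted at the terminal symbol
        chosen = {v: edges[v][rng.integers(len(edges[v]))]
                  for v in vertices if v != last}
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = chosen.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        ordered: dict[str, list[str]] = {}
        for v in vertices:
            rest = list(edges[v])
            if v != last:
                rest.remove(chosen[v])
            perm = list(rng.permutation(len(rest)))
            shuffled = [rest[k] for k in perm]
            if v != last:
                shuffled.append(chosen[v])  # the tree edge leaves last
            ordered[v] = shuffled
        out = [seq[0]]
        counters = {v: 0 for v in vertices}
        cur = seq[0]
        for _ in range(len(seq) - 1):
            nxt = ordered[cur][counters[cur]]
            counters[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to draw an in-tree")


def randfold_pvalue(seq: str, n_shuffles: int, rng_seed=None) -> float:
    """Randomization p-value for the fold energy.

    ``p = (1 + #{shuffles with MFE <= MFE(seq)}) / (n_shuffles + 1)``
    so that ties count and p is never 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ref = fold_energy(seq)
    hits = 0
    for _ in range(n_shuffles):
        if fold_energy(dinucleotide_shuffle(seq, rng)) <= ref + _EPS:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)
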