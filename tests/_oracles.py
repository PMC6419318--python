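"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the genetic code comes
from Biopython's codon tables, substitution counting enumerates pathways
explicitly, chain search enumerates every monotone anchor subset, and the
motif null distribution is built by enumerating (or meet-in-the-middle
combining) all residue words.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations, product

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_CODE = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    _CODE[stop] = "*"
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Nei-Gojobori enumeration oracle
# ---------------------------------------------------------------------------


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """(syn, nonsyn) sites by enumerating all nine single-base mutants."""
    syn = nonsyn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODE[mutant] == _CODE[codon]:
                syn += 1
            else:
                nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


def oracle_codon_subs(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over stop-free pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    valid = []
    everything = []
    for order in permutations(diff):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if _CODE[nxt] == "*" and nxt != cb:
                blocked = True
            cur = nxt
        everything.append(steps)
        if not blocked:
            valid.append(steps)
    paths = valid if valid else everything
    syn = nonsyn = 0.0
    for steps in paths:
        for c0, c1 in steps:
            if _CODE[c0] == _CODE[c1]:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(paths), nonsyn / len(paths)


def oracle_ng86(codons_a, codons_b) -> dict:
    """Full NG86 + Jukes-Cantor computation from scratch."""
    S = sum(oracle_codon_sites(c)[0] for c in codons_a)
    S += sum(oracle_codon_sites(c)[0] for c in codons_b)
    S /= 2.0
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s, n = oracle_codon_subs(ca, cb)
        Sd += s
        Nd += n
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ks, ka = jc(ps), jc(pn)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ka": ka, "ks": ks}


# ---------------------------------------------------------------------------
# exhaustive chain search oracle
# ---------------------------------------------------------------------------


def oracle_best_chain_score(
    points: list[tuple[int, int]],
    max_gap: int,
    anchor_score: float = 1.0,
    gap_penalty: float = 0.25,
) -> float:
    """Max chain score over every subset monotone in both coordinates."""
    best = 0.0
    n = len(points)
    idx = sorted(range(n), key=lambda i: points[i])
    for size in range(1, n + 1):
        for subset in combinations(idx, size):
            chain = [points[i] for i in subset]
            chain.sort()
            ok_inc = ok_dec = True
            for (a0, b0), (a1, b1) in zip(chain, chain[1:]):
                if a1 <= a0 or a1 - a0 - 1 > max_gap:
                    ok_inc = ok_dec = False
                    break
                if not (b1 > b0 and b1 - b0 - 1 <= max_gap):
                    ok_inc = False
                if not (b1 < b0 and b0 - b1 - 1 <= max_gap):
                    ok_dec = False
                if not (ok_inc or ok_dec):
                    break
            if not (ok_inc or ok_dec):
                continue
            score = anchor_score * size
            for (a0, b0), (a1, b1) in zip(chain, chain[1:]):
                score -= gap_penalty * ((a1 - a0 - 1) + (abs(b1 - b0) - 1))
            best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# motif null-distribution enumeration oracle
# ---------------------------------------------------------------------------


def oracle_null_pmf_small(column_ints: np.ndarray, background: np.ndarray):
    """Exact pmf of the integer window score by full 20**L enumeration (L<=3)."""
    L = column_ints.shape[0]
    assert L <= 3
    total = int(column_ints.max(axis=1).sum())
    pmf = np.zeros(total + 1)
    for word in product(range(20), repeat=L):
        s = int(sum(column_ints[j, r] for j, r in enumerate(word)))
        p = 1.0
        for r in word:
            p *= background[r]
        pmf[s] += p
    return pmf


def _half_sums(column_ints: np.ndarray, background: np.ndarray):
    """All (sum, prob) pairs for one block of columns, by enumeration."""
    L = column_ints.shape[0]
    sums = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for j in range(L):
        sums = (sums[:, None] + column_ints[j][None, :]).ravel()
        probs = (probs[:, None] * background[None, :]).ravel()
    return sums, probs


def oracle_null_pmf_mitm(column_ints: np.ndarray, background: np.ndarray):
    """pmf by meet-in-the-middle enumeration (handles L<=6 comfortably)."""
    L = column_ints.shape[0]
    half = L // 2
    s1, p1 = _half_sums(column_ints[:half], background)
    s2, p2 = _half_sums(column_ints[half:], background)
    total = int(column_ints.max(axis=1).sum())
    pmf = np.zeros(total + 1)
    chunk = max(1, 4_000_000 // max(1, len(s2)))
    for start in range(0, len(s1), chunk):
        ss = (s1[start : start + chunk, None] + s2[None, :]).ravel()
        pp = (p1[start : start + chunk, None] * p2[None, :]).ravel()
        pmf += np.bincount(ss, weights=pp, minlength=total + 1)
    return pmf
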