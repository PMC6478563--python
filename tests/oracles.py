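"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or naive scanning,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


# -- allele-set-intersection sharing oracle ---------------------------------

def alleles_carried(g: int) -> set:
    return {0: {"a"}, 1: {"a", "b"}, 2: {"b"}}[g]


def naive_sharing(genos, missing_policy="compatible") -> bool:
    """Explicit intersection of the per-individual carried-allele sets."""
    common = {"a", "b"}
    for g in genos:
        if g == MISSING:
            if missing_policy == "break":
                return False
            continue  # compatible with anything
        common &= alleles_carried(g)
    return len(common) > 0


def naive_segments(G, bp, chroms, members_rows, missing_policy="compatible",
                   min_markers=1):
    """O(n*m) scanner: maximal runs of marker-wise sharing per chromosome.

    Returns a list of (chrom, start_idx, end_idx) with global inclusive
    marker indices.
    """
    n_markers = G.shape[1]
    share = [
        naive_sharing([G[r, j] for r in members_rows], missing_policy)
        for j in range(n_markers)
    ]
    runs = []
    start = None
    for j in range(n_markers + 1):
        boundary = (
            j == n_markers
            or not share[j]
            or (j > 0 and chroms[j] != chroms[j - 1])
        )
        if j < n_markers and share[j] and (start is None):
            start = j
        if boundary and start is not None:
            end = j - 1
            if end - start + 1 >= min_markers:
                runs.append((chroms[start], start, end))
            start = None
            if j < n_markers and share[j] and chroms[j] != chroms[j - 1]:
                start = j
    return runs


# -- Hardy-Weinberg conditional exact enumeration ---------------------------

def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact-fraction enumeration over all heterozygote counts compatible
    with the observed allele counts."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        na1 = (n_a - h) // 2
        nb2 = (n_b - h) // 2
        probs[h] = (
            Fraction(math.factorial(n), math.factorial(na1) * math.factorial(h) * math.factorial(nb2))
            * Fraction(2**h)
            * Fraction(
                math.factorial(n_a) * math.factorial(n_b),
                math.factorial(2 * n),
            )
        )
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return float(sum(p for p in (v / total for v in probs.values()) if p <= p_obs))


# -- Fisher two-sided hypergeometric enumeration ----------------------------

def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided (minimum-likelihood) Fisher p by full enumeration of tables
    with the observed margins, in exact arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )
    p_obs = probs[a]
    # scipy tie tolerance: count tables with prob <= p_obs * (1 + 1e-7)
    cut = p_obs * Fraction(10**7 + 1, 10**7)
    return float(sum(p for p in probs.values() if p <= cut))


# -- Poisson upper tail by direct series ------------------------------------

def poisson_tail(k: int, lam: float, terms: int = 400) -> float:
    """P(X >= k) by direct series summation."""
    p = math.exp(-lam)
    total = 0.0
    for i in range(terms):
        if i >= k:
            total += p
        p *= lam / (i + 1)
    return total


# -- minimal connecting sub-pedigree by edge-subset enumeration -------------

def meioses_enumeration(individuals: dict, cases) -> int:
    """Minimum number of couple->child edges whose union lets some ancestor
    couple reach every case by descent.

    ``individuals`` maps id -> (father_id|None, mother_id|None).  Pure
    brute force over all subsets of transmission edges; only usable on tiny
    pedigrees.
    """
    edges = [
        ((f, m), child)
        for child, (f, m) in individuals.items()
        if f is not None
    ]
    couples = {e[0] for e in edges}
    cases = set(cases)
    best = None
    for mask in range(1 << len(edges)):
        subset = [edges[i] for i in range(len(edges)) if mask >> i & 1]
        if best is not None and len(subset) >= best:
            continue
        for anc in couples:
            reached = {anc[0], anc[1]}
            changed = True
            while changed:
                changed = False
                for (f, m), child in subset:
                    if child not in reached and (f in reached or m in reached):
                        reached.add(child)
                        changed = True
            if cases <= reached:
                best = len(subset)
                break
    return best
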