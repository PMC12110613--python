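"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — lookup tables built by exhaustive
enumeration, fraction-exact combinatorics, direct string scanning — and
shares no code with the package's classifiers or tests.
"""

from __future__ import annotations

import math
from fractions import Fraction

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


# --- SBS96: full 192-entry lookup built case by case -----------------------


def _build_sbs_lookup() -> dict[tuple[str, str, str, str], str]:
    table = {}
    for ref in "CT":
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    label = f"{five}[{ref}>{alt}]{three}"
                    table[(five, ref, alt, three)] = label
                    # same event on the opposite strand
                    table[(COMP[three], COMP[ref], COMP[alt], COMP[five])] = label
    assert len(table) == 192
    return table


_SBS_LOOKUP = _build_sbs_lookup()


def oracle_sbs(five: str, ref: str, alt: str, three: str) -> str:
    return _SBS_LOOKUP[(five, ref, alt, three)]


# --- DBS78: canonicalization table enumerated from the label set -----------


def _dbs_labels() -> set[str]:
    canonical = {"AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT"}
    labels = set()
    for ref in canonical:
        for a0 in BASES:
            for a1 in BASES:
                if a0 == ref[0] or a1 == ref[1]:
                    continue
                alt = a0 + a1
                if rc(ref) == ref and rc(alt) < alt:
                    alt = rc(alt)
                labels.add(f"{ref}>{alt}")
    return labels


_DBS_LABELS = _dbs_labels()


def _build_dbs_lookup() -> dict[tuple[str, str], str]:
    table = {}
    for r0 in BASES:
        for r1 in BASES:
            ref = r0 + r1
            for a0 in BASES:
                for a1 in BASES:
                    if a0 == r0 or a1 == r1:
                        continue
                    alt = a0 + a1
                    for cand in (f"{ref}>{alt}", f"{rc(ref)}>{rc(alt)}"):
                        if cand in _DBS_LABELS:
                            table[(ref, alt)] = cand
                            break
                    else:
                        raise AssertionError((ref, alt))
    return table


_DBS_LOOKUP = _build_dbs_lookup()


def oracle_dbs(ref: str, alt: str) -> str:
    return _DBS_LOOKUP[(ref, alt)]


# --- ID83: naive string scanning -------------------------------------------


def oracle_indel(kind: str, seq: str, context5: str, context3: str) -> str:
    """kind in {"INS", "DEL"}; seq is the inserted/deleted sequence."""
    L = len(seq)
    if L == 1:
        base = seq
        run = 0
        for ch in reversed(context5):
            if ch != base:
                break
            run += 1
        for ch in context3:
            if ch != base:
                break
            run += 1
        norm = base if base in "CT" else COMP[base]
        if kind == "DEL":
            run += 1
            return f"1:Del:{norm}:{min(run, 6) - 1}"
        return f"1:Ins:{norm}:{min(run, 5)}"

    copies = 0
    pos = 0
    while context3[pos : pos + L] == seq:
        copies += 1
        pos += L
    if kind == "INS":
        return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"
    copies += 1  # deleted copy
    if copies == 1:
        mh3 = 0
        for x, y in zip(seq, context3):
            if x != y:
                break
            mh3 += 1
        mh5 = 0
        for x, y in zip(reversed(seq), reversed(context5)):
            if x != y:
                break
            mh5 += 1
        mh = min(max(mh3, mh5), L - 1)
        if mh >= 1:
            return f"{min(L, 5)}:Del:M:{min(mh, 5)}"
    return f"{min(L, 5)}:Del:R:{min(copies, 6) - 1}"


# --- exact combinatorics ----------------------------------------------------


def hypergeom_tails_exact(N: int, n_a: int, n_b: int, k: int) -> tuple[Fraction, Fraction]:
    """Exact rational hypergeometric tails by direct summation."""
    denom = math.comb(N, n_b)
    lo, hi = max(0, n_a + n_b - N), min(n_a, n_b)
    pmf = {x: Fraction(math.comb(n_a, x) * math.comb(N - n_a, n_b - x), denom) for x in range(lo, hi + 1)}
    p_co = sum(pmf[x] for x in range(k, hi + 1))
    p_ex = sum(pmf[x] for x in range(lo, k + 1))
    return p_co, p_ex


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins (sum of probabilities <= the observed one)."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = sum(
        w
        for x in range(lo, hi + 1)
        if (w := math.comb(r1, x) * math.comb(r2, c1 - x)) <= obs
    )
    return Fraction(num, denom)


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values computed directly from the step-up formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q
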