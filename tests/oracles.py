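"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration (or exact
rational arithmetic) with no code shared with the implementation paths it
checks, beyond the published scoring constants.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration of tables with fixed margins,
    summing hypergeometric masses <= the observed table's.

    Masses share the denominator C(n, c1), so the mass comparison and the sum
    are exact integer arithmetic; the result is an exact rational.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    total = sum(
        num
        for x in range(lo, hi + 1)
        if (num := comb(r1, x) * comb(r2, c1 - x)) <= observed
    )
    return Fraction(total, comb(n, c1))


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exact rational summation of the closed form."""
    return sum(
        Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def seed_sites_brute(mirna: str, target: str, circular: bool = False) -> set[tuple[int, str]]:
    """All canonical sites as (1-based start, strongest type) by comparing
    every window of the (optionally wrapped) target against the explicit
    site strings of each type."""
    patterns = {
        "8mer": revcomp(mirna[1:8]) + "A",
        "7mer-m8": revcomp(mirna[1:8]),
        "7mer-A1": revcomp(mirna[1:7]) + "A",
        "6mer": revcomp(mirna[1:7]),
    }
    L = len(target)

    def window(p: int, w: int) -> str | None:
        if circular:
            return "".join(target[(p + i) % L] for i in range(w))
        if p < 0 or p + w > L:
            return None
        return target[p : p + w]

    out: set[tuple[int, str]] = set()
    for q in range(L):  # q = physical 0-based start of the 6mer core
        if window(q, 6) != patterns["6mer"]:
            continue
        has_m8 = window(q - 1, 7) == patterns["7mer-m8"]
        has_a1 = window(q, 7) == patterns["7mer-A1"]
        if has_m8 and has_a1:
            assert window(q - 1, 8) == patterns["8mer"]
            s0, stype = q - 1, "8mer"
        elif has_m8:
            s0, stype = q - 1, "7mer-m8"
        elif has_a1:
            s0, stype = q, "7mer-A1"
        else:
            s0, stype = q, "6mer"
        out.add((s0 % L + 1, stype))
    return out


# scoring constants (published contract of the duplex scorer)
WC, GU_SCORE, MISMATCH = 5, 2, -3
GAP_OPEN, GAP_EXTEND = -8, -2
E_PAIR = {"GC": -3.0, "AU": -2.0, "GU": -1.0}
E_MISMATCH, E_GAP = 2.0, 4.0


def _column(a: str, b: str, mi: int) -> tuple[float, float]:
    """(score, energy) of aligning miRNA base a (0-based index mi) with b."""
    if COMP[a] == b:
        cls = "GC" if a in "GC" else "AU"
        return WC, E_PAIR[cls]
    if {a, b} == {"G", "U"}:
        return GU_SCORE, E_PAIR["GU"]
    s = MISMATCH * (2 if 1 <= mi <= 7 else 1)
    return s, E_MISMATCH


def local_align_brute(mirna: str, window: str) -> tuple[float, float]:
    """(max score, min energy) over every local alignment, by enumerating all
    monotone sets of aligned columns; unaligned bases between consecutive
    columns are gap runs (affine for score, flat per column for energy)."""
    t = window[::-1]
    n, k = len(mirna), len(t)
    best_score, best_energy = 0.0, 0.0
    for size in range(1, min(n, k) + 1):
        for mi in combinations(range(n), size):
            for tj in combinations(range(k), size):
                score = energy = 0.0
                prev = None
                for i, j in zip(mi, tj):
                    s, e = _column(mirna[i], t[j], i)
                    score += s
                    energy += e
                    if prev is not None:
                        gm = i - prev[0] - 1
                        gt = j - prev[1] - 1
                        if gm:
                            score += GAP_OPEN + (gm - 1) * GAP_EXTEND
                        if gt:
                            score += GAP_OPEN + (gt - 1) * GAP_EXTEND
                        energy += E_GAP * (gm + gt)
                    prev = (i, j)
                best_score = max(best_score, score)
                best_energy = min(best_energy, energy)
    return best_score, best_energy


def triads_brute(edges) -> set[tuple[str, str, str]]:
    """(sponge, miRNA, mRNA) triples by a triple loop over all edge pairs."""
    out = set()
    for e1 in edges:
        for e2 in edges:
            if e1.mirna_id != e2.mirna_id:
                continue
            if e1.partner_class not in ("lncRNA", "circRNA"):
                continue
            if e2.partner_class != "mRNA":
                continue
            if e1.partner_direction != e2.partner_direction:
                continue
            out.add((e1.partner_id, e1.mirna_id, e2.partner_id))
    return out


def quads_brute(triads, require_shared_mrna: bool = True) -> set[tuple[str, str, str, str]]:
    """(lncRNA, circRNA, miRNA, mRNA) by pairwise check over all triads."""
    out = set()
    for a in triads:
        for b in triads:
            if a.sponge_class != "lncRNA" or b.sponge_class != "circRNA":
                continue
            if a.mirna_id != b.mirna_id:
                continue
            if require_shared_mrna:
                if a.mrna_id == b.mrna_id:
                    out.add((a.sponge_id, b.sponge_id, a.mirna_id, a.mrna_id))
            else:
                out.add((a.sponge_id, b.sponge_id, a.mirna_id, a.mrna_id))
                out.add((a.sponge_id, b.sponge_id, a.mirna_id, b.mrna_id))
    return out
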