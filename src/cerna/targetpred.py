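"""Dual miRNA-target prediction: canonical seed sites and duplex energy.

Two independent scorers are run per (miRNA, target) pair and intersected:

* a canonical seed-site scanner (6mer / 7mer-A1 / 7mer-m8 / 8mer taxonomy)
  with a 0-100 context-style score built from site type, local AU content,
  and position within the transcript;
* a local complementarity alignment (Watson-Crick and G:U wobble pairing,
  affine gaps, extra seed-region mismatch penalty) with an additive per-pair
  hybridization energy in kcal/mol convention.

A pair passes only when the best site clears the context cut-off AND the
best duplex clears the energy cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

RNA_ALPHABET = set("ACGU")
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_STRENGTH = {t: i for i, t in enumerate(reversed(SITE_TYPES))}  # 6mer=0 .. 8mer=3
BASE_SCORE = {"8mer": 75.0, "7mer-m8": 60.0, "7mer-A1": 50.0, "6mer": 35.0}

# alignment scoring (score units are arbitrary; energy is kcal/mol convention)
MATCH_WC = 5
MATCH_GU = 2
MISMATCH = -3
SEED_MISMATCH_FACTOR = 2  # applied to mismatches against miRNA positions 2-8
GAP_OPEN = -8
GAP_EXTEND = -2
ENERGY_PER_PAIR = {"GC": -3.0, "AU": -2.0, "GU": -1.0}
ENERGY_MISMATCH = 2.0
ENERGY_GAP = 4.0

MAX_WINDOW = 80
FLANK = 30

TARGET_PAIR_COLUMNS = [
    "mirna_id",
    "target_id",
    "target_class",
    "site_type",
    "start",
    "end",
    "context_score",
    "score",
    "energy",
    "passes",
]


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, validate alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"illegal RNA characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pair_class(a: str, b: str) -> str:
    """Classify a putative (miRNA base, target base) pairing."""
    if COMPLEMENT[a] == b:
        return "GC" if a in "GC" else "AU"
    if {a, b} == {"G", "U"}:
        return "GU"
    return "mismatch"


@dataclass
class SeedSite:
    target_id: str
    mirna_id: str
    start: int  # 1-based first base of the site on the target
    end: int  # half-open; may exceed target length for junction-spanning sites
    site_type: str
    site_seq: str
    context_score: float | None = None


@dataclass
class DuplexResult:
    target_id: str
    mirna_id: str
    alignment: list[tuple[int, int, str]] = field(default_factory=list)
    score: float = 0.0
    energy: float = 0.0


@dataclass
class TargetPair:
    mirna_id: str
    target_id: str
    target_class: str
    best_site: SeedSite
    best_duplex: DuplexResult
    passes_intersection: bool


def seed_core(mirna_seq: str) -> str:
    """Target-strand reverse complement of miRNA positions 2-7 (the 6mer core)."""
    return revcomp(mirna_seq[1:7])


def planted_site_8mer(mirna_seq: str) -> str:
    """The perfect 8mer site: revcomp of positions 2-8 followed by an A."""
    m = normalize_rna(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    return revcomp(m[1:8]) + "A"


def find_seed_sites(
    mirna_seq: str,
    target_seq: str,
    topology: str = "linear",
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[SeedSite]:
    """All canonical seed sites on the target, strongest type per site.

    Circular targets are scanned with a 7-nt wrap-around extension so sites
    spanning the back-splice junction are found; their start coordinate is
    reported modulo the target length (1-based, in [1, L]).
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology: {topology!r}")
    m = normalize_rna(mirna_seq)
    t = normalize_rna(target_seq)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    L = len(t)
    if L == 0:
        return []
    core = seed_core(m)  # 6 nt
    m8_comp = COMPLEMENT[m[7]]
    circular = topology == "circular"
    ext = t + t[:7] if circular else t

    sites: list[SeedSite] = []
    pos = ext.find(core)
    while pos != -1:
        if pos < L:  # wrapped duplicates start at >= L
            # base 5' of the core pairs miRNA position 8
            if pos > 0:
                has_m8 = ext[pos - 1] == m8_comp
            elif circular:
                has_m8 = t[L - 1] == m8_comp
            else:
                has_m8 = False
            a1_idx = pos + 6
            if a1_idx < len(ext):
                has_a1 = ext[a1_idx] == "A"
            else:
                has_a1 = False
            if has_m8 and has_a1:
                stype, s0, length = "8mer", pos - 1, 8
            elif has_m8:
                stype, s0, length = "7mer-m8", pos - 1, 7
            elif has_a1:
                stype, s0, length = "7mer-A1", pos, 7
            else:
                stype, s0, length = "6mer", pos, 6
            start0 = s0 % L if circular else s0
            if circular:
                seq = "".join(t[(start0 + k) % L] for k in range(length))
            else:
                seq = t[start0 : start0 + length]
            sites.append(
                SeedSite(
                    target_id=target_id,
                    mirna_id=mirna_id,
                    start=start0 + 1,
                    end=start0 + 1 + length,
                    site_type=stype,
                    site_seq=seq,
                )
            )
        pos = ext.find(core, pos + 1)
    # a circular target can yield the same physical site twice only via the
    # wrap guard above; still dedupe defensively on (start, type)
    seen: set[tuple[int, str]] = set()
    unique = []
    for s in sorted(sites, key=lambda s: (s.start, -SITE_STRENGTH[s.site_type])):
        key = (s.start, s.site_type)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


def context_score(site_type: str, au_fraction: float, near_end: bool) -> float:
    """0-100 site score: type base + 20*AU fraction + 5 near-end bonus."""
    if site_type not in BASE_SCORE:
        raise ValueError(f"unknown site type: {site_type!r}")
    if not 0.0 <= au_fraction <= 1.0:
        raise ValueError("AU fraction must lie in [0, 1]")
    score = BASE_SCORE[site_type] + 20.0 * au_fraction + (5.0 if near_end else 0.0)
    return float(min(max(score, 0.0), 100.0))


def site_features(site: SeedSite, target_seq: str, circular: bool = False) -> tuple[float, bool]:
    """(AU fraction of the 30-nt flanks, near-end bonus flag) for a site."""
    t = normalize_rna(target_seq)
    L = len(t)
    length = site.end - site.start
    s0 = site.start - 1
    if circular:
        flank_idx = [(s0 - k) % L for k in range(1, FLANK + 1)]
        flank_idx += [(s0 + length - 1 + k) % L for k in range(1, FLANK + 1)]
        flank = [t[i] for i in flank_idx]
        near_end = False  # a circle has no ends
    else:
        left = t[max(0, s0 - FLANK) : s0]
        right = t[s0 + length : s0 + length + FLANK]
        flank = list(left + right)
        dist5 = s0
        dist3 = L - (s0 + length)
        near_end = 1 <= min(dist5, dist3) <= 15
    if not flank:
        return 0.0, near_end
    au = sum(1 for b in flank if b in "AU") / len(flank)
    return au, near_end


def score_site(site: SeedSite, target_seq: str, circular: bool = False) -> SeedSite:
    au, near_end = site_features(site, target_seq, circular)
    site.context_score = context_score(site.site_type, au, near_end)
    return site


def _sub_score(mi: int, a: str, b: str) -> int:
    """Substitution score for miRNA base at 0-based index mi against target base."""
    cls = pair_class(a, b)
    if cls in ("GC", "AU"):
        return MATCH_WC
    if cls == "GU":
        return MATCH_GU
    penalty = MISMATCH
    if 1 <= mi <= 7:  # miRNA positions 2-8
        penalty *= SEED_MISMATCH_FACTOR
    return penalty


def alignment_energy(columns: Iterable[tuple[int, int, str]]) -> float:
    """Additive energy of an alignment; gaps and internal mismatches cost."""
    energy = 0.0
    for _, _, cls in columns:
        if cls == "gap":
            energy += ENERGY_GAP
        elif cls == "mismatch":
            energy += ENERGY_MISMATCH
        else:
            energy += ENERGY_PER_PAIR[cls]
    return energy


def _min_energy(m: str, t: str) -> float:
    """Minimum additive energy over all local alignments of m vs t.

    The energy model (pairs favorable, gaps +4, mismatches +2) is optimized
    directly: this is the most stable duplex segment in the window, which can
    differ from the score-optimal alignment when score-positive extensions
    carry an energy cost.  Returns <= 0 (0 means no stable duplex).
    """
    n, k = len(m), len(t)
    POS = float("inf")
    # gap columns cost a flat +4, so a single running matrix with linear gap
    # moves covers every alignment; optimal alignments end in a pair column
    B = [[POS] * (k + 1) for _ in range(n + 1)]  # ends in a pair/mismatch column
    C = [[POS] * (k + 1) for _ in range(n + 1)]  # B plus any trailing gap columns
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            cls = pair_class(m[i - 1], t[j - 1])
            e = ENERGY_MISMATCH if cls == "mismatch" else ENERGY_PER_PAIR[cls]
            B[i][j] = e + min(0.0, C[i - 1][j - 1])
            C[i][j] = min(B[i][j], C[i - 1][j] + ENERGY_GAP, C[i][j - 1] + ENERGY_GAP)
            if B[i][j] < best:
                best = B[i][j]
    return best


def duplex_align(
    mirna_seq: str,
    target_window: str,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> DuplexResult:
    """Optimal local complementarity alignment miRNA vs. reversed window.

    Smith-Waterman with affine gaps; the target window is reversed so the
    antiparallel duplex becomes a left-to-right alignment.  Alignment columns
    are (miRNA 0-based index, window 0-based index, pair class) with -1 for
    the gapped side.  A non-positive optimum means no duplex (energy 0).

    The reported energy is the minimum of the additive energy model over all
    local alignments in the window (the most stable duplex segment), computed
    by a second dynamic program: score-positive extensions of the alignment
    (e.g. long bulges bridging extra pairs) must not mask a stable core.
    """
    m = normalize_rna(mirna_seq)
    w = normalize_rna(target_window)
    if not m or not w:
        raise ValueError("empty sequence")
    if len(w) > MAX_WINDOW:
        raise ValueError(f"window longer than {MAX_WINDOW} nt")
    t = w[::-1]
    n, k = len(m), len(t)
    NEG = float("-inf")
    # M: ends in a pair/mismatch column; X: gap in target (miRNA base unpaired);
    # Y: gap in miRNA (target base unpaired)
    M = [[0.0] * (k + 1) for _ in range(n + 1)]
    X = [[NEG] * (k + 1) for _ in range(n + 1)]
    Y = [[NEG] * (k + 1) for _ in range(n + 1)]
    best, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            s = _sub_score(i - 1, m[i - 1], t[j - 1])
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN,
                X[i - 1][j] + GAP_EXTEND,
                Y[i - 1][j] + GAP_OPEN,
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN,
                Y[i][j - 1] + GAP_EXTEND,
                X[i][j - 1] + GAP_OPEN,
            )
            if M[i][j] > best:
                best, best_cell = M[i][j], (i, j)
    result = DuplexResult(target_id=target_id, mirna_id=mirna_id)
    if best_cell is None or best <= 0:
        return result
    # traceback from the best M cell
    cols: list[tuple[int, int, str]] = []
    i, j = best_cell
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            cls = pair_class(m[i - 1], t[j - 1])
            cols.append((i - 1, k - j, cls))  # map back to original window coords
            prev = M[i][j] - _sub_score(i - 1, m[i - 1], t[j - 1])
            i, j = i - 1, j - 1
            if prev == 0.0:
                break  # local alignment starts at this column
            if M[i][j] == prev:
                state = "M"
            elif X[i][j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cols.append((i - 1, -1, "gap"))
            if X[i][j] == M[i - 1][j] + GAP_OPEN:
                state = "M"
            elif X[i][j] == X[i - 1][j] + GAP_EXTEND:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            cols.append((-1, k - j, "gap"))
            if Y[i][j] == M[i][j - 1] + GAP_OPEN:
                state = "M"
            elif Y[i][j] == Y[i][j - 1] + GAP_EXTEND:
                state = "Y"
            else:
                state = "X"
            j -= 1
    cols.reverse()
    result.alignment = cols
    result.score = best
    result.energy = _min_energy(m, t)
    return result


def _window(target_seq: str, site: SeedSite, circular: bool) -> str:
    """Window of the target centered on a seed site (site +/- 30 nt)."""
    t = target_seq
    L = len(t)
    length = site.end - site.start
    s0 = site.start - 1
    if circular:
        idx = [(s0 - FLANK + k) % L for k in range(min(L, length + 2 * FLANK))]
        return "".join(t[i] for i in idx)
    lo = max(0, s0 - FLANK)
    hi = min(L, s0 + length + FLANK)
    return t[lo:hi]


def predict_targets(
    mirnas: Mapping[str, str],
    targets: Mapping[str, Mapping[str, tuple[str, bool]]],
    context_cutoff: float = 50.0,
    energy_cutoff: float = -10.0,
) -> list[TargetPair]:
    """Intersection-filtered target pairs over all (miRNA, target) combinations.

    ``targets`` maps target class -> {target_id: (sequence, circular_flag)}.
    Only pairs with at least one canonical seed site are reported; a pair
    passes when best context score >= context_cutoff and best duplex energy
    < energy_cutoff.
    """
    pairs: list[TargetPair] = []
    for cls in sorted(targets):
        for tid in sorted(targets[cls]):
            seq, circular = targets[cls][tid]
            seq = normalize_rna(seq)
            topology = "circular" if circular else "linear"
            for mid in sorted(mirnas):
                mseq = normalize_rna(mirnas[mid])
                sites = find_seed_sites(mseq, seq, topology, mirna_id=mid, target_id=tid)
                if not sites:
                    continue
                for s in sites:
                    score_site(s, seq, circular)
                best_site = max(
                    sites, key=lambda s: (s.context_score, -s.start)
                )
                best_duplex: DuplexResult | None = None
                for s in sites:
                    dup = duplex_align(mseq, _window(seq, s, circular), mid, tid)
                    if best_duplex is None or dup.energy < best_duplex.energy:
                        best_duplex = dup
                passes = (
                    best_site.context_score >= context_cutoff
                    and best_duplex.energy < energy_cutoff
                )
                pairs.append(
                    TargetPair(
                        mirna_id=mid,
                        target_id=tid,
                        target_class=cls,
                        best_site=best_site,
                        best_duplex=best_duplex,
                        passes_intersection=passes,
                    )
                )
    return pairs


def pairs_to_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    rows = [
        (
            p.mirna_id,
            p.target_id,
            p.target_class,
            p.best_site.site_type,
            p.best_site.start,
            p.best_site.end,
            p.best_site.context_score,
            p.best_duplex.score,
            p.best_duplex.energy,
            p.passes_intersection,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=TARGET_PAIR_COLUMNS)
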