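"""Hypergeometric over-representation testing against GMT term collections.

Local stand-in for web-service enrichment: the DE gene set (|log2FC| > 1,
p < 0.05 by default) is tested per term with the hypergeometric upper tail,
optionally EASE-style (k - 1).  BH-adjusted q-values are reported; the
significance flag uses the raw p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

CATEGORIES = ("BP", "MF", "CC", "pathway")

ENRICH_COLUMNS = [
    "term_id",
    "name",
    "category",
    "k",
    "K",
    "n",
    "N",
    "p",
    "q",
    "fold_enrichment",
    "significant",
]


@dataclass
class Term:
    term_id: str
    name: str
    category: str
    members: frozenset[str]


@dataclass
class TermCollection:
    terms: dict[str, Term] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*(t.members for t in self.terms.values())) if self.terms else set()
        for t in self.terms.values():
            if not t.members:
                raise ValueError(f"empty term: {t.term_id}")
            stray = t.members - self.universe
            if stray:
                raise ValueError(
                    f"term {t.term_id} has members outside the universe: {sorted(stray)[:5]}"
                )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError("require 0 <= K, n <= N")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def read_gmt(path: str | Path, default_category: str = "pathway") -> TermCollection:
    """Parse a GMT file (term <TAB> description <TAB> members...).

    A description of the form ``CATEGORY|name`` with CATEGORY in
    {BP, MF, CC, pathway} sets the term category; anything else is kept as
    the name with the default category.
    """
    terms: dict[str, Term] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description, >=1 member")
        term_id, desc = parts[0], parts[1]
        members = frozenset(g for g in parts[2:] if g)
        category, name = default_category, desc
        if "|" in desc:
            cat, rest = desc.split("|", 1)
            if cat in CATEGORIES:
                category, name = cat, rest
        if term_id in terms:
            raise ValueError(f"{path}:{ln}: duplicated term id {term_id}")
        terms[term_id] = Term(term_id, name, category, members)
    return TermCollection(terms=terms)


def write_gmt(collection: TermCollection, path: str | Path) -> None:
    lines = []
    for tid in sorted(collection.terms):
        t = collection.terms[tid]
        desc = f"{t.category}|{t.name}"
        lines.append("\t".join([tid, desc, *sorted(t.members)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def select_de_set(
    de_records: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> set[str]:
    """Features with |log2fc| > threshold and p < alpha."""
    mask = (de_records["log2fc"].abs() > lfc_threshold) & (de_records["p"] < alpha)
    return set(de_records.loc[mask, "feature_id"])


def enrich_terms(
    de_records: pd.DataFrame,
    collection: TermCollection,
    universe: Iterable[str] | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    term_alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation results, sorted by ascending p.

    The universe defaults to the measured features (the DE table), not the
    term collection; terms are restricted to the universe.  ``ease=True``
    tests k - 1 (EASE-style conservative score).
    """
    uni = set(universe) if universe is not None else set(de_records["feature_id"])
    if not uni:
        raise ValueError("empty universe")
    de_set = select_de_set(de_records, lfc_threshold, alpha) & uni
    N = len(uni)
    n = len(de_set)
    rows = []
    for tid in sorted(collection.terms):
        t = collection.terms[tid]
        members = t.members & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_set)
        if k < 1:
            continue
        k_test = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_test, K, n, N) if k_test > 0 else 1.0
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((tid, t.name, t.category, k, K, n, N, p, fold))
    frame = pd.DataFrame(
        rows, columns=["term_id", "name", "category", "k", "K", "n", "N", "p", "fold_enrichment"]
    )
    if frame.empty:
        frame["q"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
        return frame[ENRICH_COLUMNS]
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame["significant"] = frame["p"] < term_alpha
    frame = frame.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return frame[ENRICH_COLUMNS]


def category_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Significant-term counts per category (BP/MF/CC/pathway bar summary)."""
    sig = results[results["significant"]]
    counts = sig.groupby("category").size().rename("n_terms").reset_index()
    return counts.sort_values("category").reset_index(drop=True)
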