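"""Per-class differential expression from pooled read counts.

For every feature a 2x2 contingency table (group-pooled feature counts
against group-pooled mapped-library totals) is tested with Fisher's exact
test, two-sided under the minimum-likelihood rule.  Fold changes are
computed on group means of normalized abundance: counts-per-million for
mRNA/lncRNA/miRNA, spliced-reads-per-billion-mapped (SRPBM) for circRNA.
Direction calls use a per-class alpha (miRNA is filtered more stringently
by default) together with an absolute log2-fold-change threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

DE_COLUMNS = [
    "feature_id",
    "class",
    "mean_case",
    "mean_ctrl",
    "log2fc",
    "p",
    "q",
    "direction",
]


@dataclass
class CountMatrix:
    """Non-negative integer read counts, features x samples, one RNA class."""

    counts: pd.DataFrame  # index = feature ids, columns = sample ids
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class: {self.rna_class!r}")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicated feature ids: {dupes[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicated sample ids")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("negative count entries")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class Thresholds:
    """Significance cut-offs used for direction calls.

    ``alpha_mirna`` defaults to the stricter miRNA filter; all other classes
    use ``alpha_default``.  ``pseudocount`` guards the fold-change ratio
    against zero group means.
    """

    lfc_threshold: float = 1.0
    alpha_default: float = 0.05
    alpha_mirna: float = 0.01
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.pseudocount <= 0:
            raise ValueError("lfc_threshold and pseudocount must be positive")
        if not (0 < self.alpha_default < 1) or not (0 < self.alpha_mirna < 1):
            raise ValueError("alphas must lie in (0, 1)")

    def alpha_for(self, rna_class: str) -> float:
        return self.alpha_mirna if rna_class == "miRNA" else self.alpha_default


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Two-sided by the minimum-likelihood rule: sum of hypergeometric masses of
    all tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    cells = (a, b, c, d)
    if any(int(x) != x for x in cells):
        raise ValueError("table cells must be integers")
    if min(cells) < 0:
        raise ValueError("table cells must be non-negative")
    if sum(cells) == 0:
        raise ValueError("degenerate table: all margins zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def build_gene_table(
    counts_case: int, total_case: int, counts_ctrl: int, total_ctrl: int
) -> np.ndarray:
    """2x2 table of pooled feature counts against pooled library totals."""
    if counts_case < 0 or counts_ctrl < 0:
        raise ValueError("pooled counts must be non-negative")
    if counts_case > total_case or counts_ctrl > total_ctrl:
        raise ValueError("feature count exceeds library total")
    return np.array(
        [
            [counts_case, total_case - counts_case],
            [counts_ctrl, total_ctrl - counts_ctrl],
        ],
        dtype=np.int64,
    )


def log2_fold_change(mean_case: float, mean_ctrl: float, pseudocount: float = 0.5) -> float:
    """log2((mean_case + pc) / (mean_ctrl + pc)); antisymmetric in the groups."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if mean_case < 0 or mean_ctrl < 0:
        raise ValueError("means must be non-negative")
    num, den = mean_case + pseudocount, mean_ctrl + pseudocount
    if den == 0 or num == 0:
        raise ValueError("zero mean requires a positive pseudocount")
    return float(np.log2(num / den))


def srpbm(junction_reads: float, mapped_total: float) -> float:
    """Back-splice junction reads per billion mapped reads."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    if junction_reads < 0:
        raise ValueError("junction_reads must be non-negative")
    return float(junction_reads) * 1e9 / float(mapped_total)


def cpm(reads: float, mapped_total: float) -> float:
    """Reads per million mapped reads."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    if reads < 0:
        raise ValueError("reads must be non-negative")
    return float(reads) * 1e6 / float(mapped_total)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative 2^-ddCt relative expression from qPCR cycle thresholds."""
    for ct in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def circ_source_summary(origins: Mapping[str, str]) -> dict[str, float]:
    """Proportion of circRNAs per genomic origin (exon/intron/intergenic)."""
    allowed = {"exon", "intron", "intergenic"}
    if not origins:
        raise ValueError("no circRNA annotations supplied")
    counts: dict[str, int] = {}
    for circ_id, origin in origins.items():
        if origin not in allowed:
            raise ValueError(f"unlabeled or unknown origin for {circ_id}: {origin!r}")
        counts[origin] = counts.get(origin, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}


def _split_groups(sample_map: Mapping[str, str], sample_ids: list[str]) -> tuple[list[str], list[str]]:
    missing = [s for s in sample_ids if s not in sample_map]
    if missing:
        raise ValueError(f"samples absent from sample map: {missing[:5]}")
    case = [s for s in sample_ids if sample_map[s] == "case"]
    ctrl = [s for s in sample_ids if sample_map[s] == "control"]
    if not case or not ctrl:
        raise ValueError("both groups must contain at least one sample")
    return case, ctrl


def call_differential(
    matrix: CountMatrix,
    sample_map: Mapping[str, str],
    mapped_totals: Mapping[str, float],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-feature DE table with direction calls for one RNA class.

    Fisher p-values come from group-pooled counts versus group-pooled mapped
    totals.  BH-adjusted q is reported alongside, but direction calls use the
    raw p against the class alpha.
    """
    thresholds = thresholds or Thresholds()
    case, ctrl = _split_groups(sample_map, matrix.sample_ids)
    missing_totals = [s for s in matrix.sample_ids if s not in mapped_totals]
    if missing_totals:
        raise ValueError(f"samples absent from mapped totals: {missing_totals[:5]}")

    counts = matrix.counts
    totals = pd.Series({s: float(mapped_totals[s]) for s in matrix.sample_ids})
    if (totals <= 0).any():
        raise ValueError("mapped totals must be positive")

    scale = 1e9 if matrix.rna_class == "circRNA" else 1e6
    norm = counts.div(totals, axis=1) * scale
    mean_case = norm[case].mean(axis=1)
    mean_ctrl = norm[ctrl].mean(axis=1)

    pooled_case = counts[case].sum(axis=1).astype(np.int64)
    pooled_ctrl = counts[ctrl].sum(axis=1).astype(np.int64)
    total_case = int(totals[case].sum())
    total_ctrl = int(totals[ctrl].sum())

    alpha = thresholds.alpha_for(matrix.rna_class)
    records = []
    for fid in counts.index:
        table = build_gene_table(
            int(pooled_case[fid]), total_case, int(pooled_ctrl[fid]), total_ctrl
        )
        p = fisher_exact_2x2(*table.ravel())
        lfc = log2_fold_change(
            float(mean_case[fid]), float(mean_ctrl[fid]), thresholds.pseudocount
        )
        records.append((fid, matrix.rna_class, mean_case[fid], mean_ctrl[fid], lfc, p))

    table = pd.DataFrame(
        records, columns=["feature_id", "class", "mean_case", "mean_ctrl", "log2fc", "p"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    up = (table["log2fc"] > thresholds.lfc_threshold) & (table["p"] < alpha)
    down = (table["log2fc"] < -thresholds.lfc_threshold) & (table["p"] < alpha)
    table["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return table[DE_COLUMNS]


def call_differential_all(
    matrices: Mapping[str, CountMatrix],
    sample_map: Mapping[str, str],
    mapped_totals: Mapping[str, float],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Concatenated DE tables over several RNA classes."""
    frames = [
        call_differential(matrices[cls], sample_map, mapped_totals, thresholds)
        for cls in sorted(matrices)
    ]
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
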