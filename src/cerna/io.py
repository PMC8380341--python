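"""Shared file-format layer: FASTA with key=value headers, provenance TSVs,
count matrices and sample maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .diffexpr import CountMatrix
from .targetpred import normalize_rna


@dataclass
class SeqEntry:
    """One FASTA record with parsed header metadata."""

    id: str
    seq: str  # RNA alphabet, U not T
    rna_class: str | None = None
    circular: bool = False
    attrs: dict[str, str] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[SeqEntry]:
    """Read FASTA; header fields after the id are parsed as key=value pairs.

    Recognized keys: ``class`` (RNA class) and ``topology`` (circular flag);
    unknown keys are preserved in ``attrs``.  T is mapped to U.
    """
    entries: list[SeqEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        attrs: dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, val = token.split("=", 1)
                attrs[key] = val
        try:
            seq = normalize_rna(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id}: {exc}") from exc
        entries.append(
            SeqEntry(
                id=rec.id,
                seq=seq,
                rna_class=attrs.pop("class", None),
                circular=attrs.pop("topology", "linear") == "circular",
                attrs=attrs,
            )
        )
    return entries


def write_fasta(entries: Iterable[SeqEntry], path: str | Path, width: int = 70) -> int:
    """Write FASTA with class/topology header fields; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for e in entries:
            fields = []
            if e.rna_class:
                fields.append(f"class={e.rna_class}")
            fields.append(f"topology={'circular' if e.circular else 'linear'}")
            fields.extend(f"{k}={v}" for k, v in sorted(e.attrs.items()))
            fh.write(f">{e.id} {' '.join(fields)}\n")
            for i in range(0, len(e.seq), width):
                fh.write(e.seq[i : i + width] + "\n")
            n += 1
    return n


def write_table(frame: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    """TSV with `#`-prefixed provenance comment lines, then header + rows."""
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """TSV with columns sample_id, group (case|control)."""
    frame = read_table(path, dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: sample map needs columns {sorted(required)}")
    bad = set(frame["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: unknown groups {sorted(bad)}")
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return dict(zip(frame["sample_id"], frame["group"]))


def read_mapped_totals(path: str | Path) -> dict[str, float]:
    """TSV with columns sample_id, mapped_total."""
    frame = read_table(path)
    if not {"sample_id", "mapped_total"}.issubset(frame.columns):
        raise ValueError(f"{path}: totals need columns sample_id, mapped_total")
    return dict(zip(frame["sample_id"].astype(str), frame["mapped_total"].astype(float)))


def read_counts(
    path: str | Path,
    rna_class: str,
    sample_map: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Read a feature-by-sample count TSV (first column = feature id).

    Cells must be integers; when a sample map is given every sample column
    must appear in it.
    """
    frame = read_table(path)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: empty count table")
    feature_col = frame.columns[0]
    if frame[feature_col].duplicated().any():
        dupes = frame.loc[frame[feature_col].duplicated(), feature_col].tolist()
        raise ValueError(f"{path}: duplicated feature ids {dupes[:5]}")
    frame = frame.set_index(feature_col)
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            raise ValueError(f"{path}: non-integer counts in sample {col}")
        frame[col] = vals.astype("int64")
    if sample_map is not None:
        missing = [s for s in frame.columns if s not in sample_map]
        if missing:
            raise ValueError(f"{path}: samples missing from sample map: {missing}")
    return CountMatrix(counts=frame, rna_class=rna_class)


def write_counts(matrix: CountMatrix, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    frame = matrix.counts.reset_index()
    frame = frame.rename(columns={frame.columns[0]: "feature_id"})
    write_table(frame, path, params)
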