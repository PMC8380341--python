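"""Synthetic dataset generator with planted DE effects and ceRNA triads.

Counts are negative-binomial draws around log-normal baseline abundances;
a configurable fraction of features per class gets a planted fold change,
and a configurable number of sponge-miRNA-mRNA triads get coordinated
anticorrelated effects plus real 8mer seed sites inserted into the sponge
and the mRNA 3'UTR sequences.  Everything is deterministic under the
config seed, and the planted truth is returned for recovery testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix, RNA_CLASSES
from .io import SeqEntry, write_fasta, write_counts, write_table
from .targetpred import planted_site_8mer

NUCLEOTIDES = np.array(list("ACGU"))


@dataclass
class SimConfig:
    n_case: int = 40
    n_control: int = 40
    n_features: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 300, "lncRNA": 100, "circRNA": 60, "miRNA": 60}
    )
    nb_dispersion: float = 0.1
    baseline_logmean_mu: float = 5.0
    baseline_logmean_sigma: float = 1.0
    de_fraction: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.1, "lncRNA": 0.1, "circRNA": 0.1, "miRNA": 0.1}
    )
    de_log2fc: float = 2.0
    n_planted_triads: int = 10
    utr_length: int = 300
    lnc_length: int = 400
    circ_length: int = 250
    mirna_length: int = 22
    background_reads: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if set(self.n_features) != set(RNA_CLASSES):
            raise ValueError(f"n_features must cover exactly {RNA_CLASSES}")
        if any(v < 0 for v in self.n_features.values()):
            raise ValueError("feature counts must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for cls, frac in self.de_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"de_fraction[{cls}] outside [0, 1]")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be positive")
        if self.n_planted_triads < 0:
            raise ValueError("n_planted_triads must be >= 0")
        for name in ("utr_length", "lnc_length", "circ_length"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} too short to hold an 8mer site")
        if self.mirna_length < 19:
            raise ValueError("mirna_length must be >= 19")
        k = self.n_planted_triads
        if k > self.n_features["miRNA"] or k > self.n_features["mRNA"]:
            raise ValueError("not enough miRNAs/mRNAs for the planted triads")
        if math.ceil(k / 2) > self.n_features["lncRNA"] or k // 2 > self.n_features["circRNA"]:
            raise ValueError("not enough sponges for the planted triads")

    def feature_ids(self, cls: str) -> list[str]:
        return [f"{cls}_{i:04d}" for i in range(self.n_features[cls])]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        case = [f"case_{i:03d}" for i in range(self.n_case)]
        ctrl = [f"ctrl_{i:03d}" for i in range(self.n_control)]
        return case, ctrl


@dataclass(frozen=True)
class PlantedTriad:
    sponge_id: str
    sponge_class: str
    mirna_id: str
    mrna_id: str
    pattern: str  # up-down-up | down-up-down


@dataclass
class TruthSet:
    de_effects: dict[str, float] = field(default_factory=dict)
    triads: list[PlantedTriad] = field(default_factory=list)
    site_plants: dict[tuple[str, str], tuple[int, str]] = field(default_factory=dict)

    def validate(self, check_sites: bool = True) -> None:
        for t in self.triads:
            s = self.de_effects.get(t.sponge_id, 0.0)
            m = self.de_effects.get(t.mirna_id, 0.0)
            g = self.de_effects.get(t.mrna_id, 0.0)
            if not (s * g > 0 and s * m < 0):
                raise AssertionError(f"triad {t} effects not anticorrelated: {s}, {m}, {g}")
            if not check_sites:
                continue
            for tid in (t.sponge_id, t.mrna_id):
                if (t.mirna_id, tid) not in self.site_plants:
                    raise AssertionError(f"missing site plant for ({t.mirna_id}, {tid})")


@dataclass
class Dataset:
    config: SimConfig
    sequences: dict[str, list[SeqEntry]]
    counts: dict[str, CountMatrix]
    sample_map: dict[str, str]
    mapped_totals: dict[str, float]
    truth: TruthSet


def planted_triads(cfg: SimConfig) -> list[PlantedTriad]:
    """Triad membership is a deterministic function of the config: triad k
    takes the k-th miRNA and mRNA, sponges alternate lncRNA/circRNA, and
    the direction pattern alternates."""
    triads = []
    for k in range(cfg.n_planted_triads):
        if k % 2 == 0:
            sponge_cls, idx = "lncRNA", k // 2
        else:
            sponge_cls, idx = "circRNA", k // 2
        triads.append(
            PlantedTriad(
                sponge_id=f"{sponge_cls}_{idx:04d}",
                sponge_class=sponge_cls,
                mirna_id=f"miRNA_{k:04d}",
                mrna_id=f"mRNA_{k:04d}",
                pattern="up-down-up" if k % 2 == 0 else "down-up-down",
            )
        )
    return triads


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def _plant_site(
    rng: np.random.Generator, seq: str, site: str, au_flank: int = 15
) -> tuple[str, int]:
    """Insert (overwrite) the site at a random position, surrounded by
    AU-rich flanks; returns (new sequence, 1-based site start)."""
    if len(site) > len(seq):
        raise ValueError("planted site longer than target sequence")
    lo = min(au_flank, len(seq) - len(site))
    hi = len(seq) - len(site) - lo
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    chars = list(seq)
    for k in range(au_flank):
        left = start - 1 - k
        right = start + len(site) + k
        if left >= 0:
            chars[left] = "AU"[int(rng.integers(2))]
        if right < len(chars):
            chars[right] = "AU"[int(rng.integers(2))]
    chars[start : start + len(site)] = list(site)
    return "".join(chars), start + 1


def generate_sequences(cfg: SimConfig) -> tuple[dict[str, list[SeqEntry]], TruthSet]:
    """Random-composition RNA sequences per class, with the exact 8mer site
    of each planted triad's miRNA inserted into both the sponge and the
    mRNA 3'UTR at recorded 1-based positions."""
    rng = np.random.default_rng([cfg.seed, 0])
    lengths = {
        "mRNA": cfg.utr_length,
        "lncRNA": cfg.lnc_length,
        "circRNA": cfg.circ_length,
        "miRNA": cfg.mirna_length,
    }
    sequences: dict[str, list[SeqEntry]] = {}
    for cls in RNA_CLASSES:
        sequences[cls] = [
            SeqEntry(
                id=fid,
                seq=_random_seq(rng, lengths[cls]),
                rna_class=cls,
                circular=(cls == "circRNA"),
            )
            for fid in cfg.feature_ids(cls)
        ]
    truth = TruthSet(triads=planted_triads(cfg))
    by_id = {e.id: e for entries in sequences.values() for e in entries}
    for t in truth.triads:
        site = planted_site_8mer(by_id[t.mirna_id].seq)
        for target_id in (t.sponge_id, t.mrna_id):
            entry = by_id[target_id]
            entry.seq, start = _plant_site(rng, entry.seq, site)
            truth.site_plants[(t.mirna_id, target_id)] = (start, "8mer")
    return sequences, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def generate_counts(
    cfg: SimConfig,
) -> tuple[dict[str, CountMatrix], dict[str, str], dict[str, float], TruthSet]:
    """Count matrices per class plus sample map, mapped totals and truth.

    Planted DE features have the case-group mean multiplied by
    2^(+/- de_log2fc); planted triad members get coordinated signs.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    case_ids, ctrl_ids = cfg.sample_ids()
    sample_map = {s: "case" for s in case_ids} | {s: "control" for s in ctrl_ids}

    truth = TruthSet(triads=planted_triads(cfg))
    for t in truth.triads:
        sign = 1.0 if t.pattern == "up-down-up" else -1.0
        truth.de_effects[t.sponge_id] = sign * cfg.de_log2fc
        truth.de_effects[t.mrna_id] = sign * cfg.de_log2fc
        truth.de_effects[t.mirna_id] = -sign * cfg.de_log2fc

    counts: dict[str, CountMatrix] = {}
    for cls in RNA_CLASSES:
        fids = cfg.feature_ids(cls)
        n = len(fids)
        baselines = np.exp(
            rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sigma, size=n)
        )
        free = [f for f in fids if f not in truth.de_effects]
        n_extra = int(round(cfg.de_fraction[cls] * n))
        n_extra = min(n_extra, len(free))
        if n_extra > 0:
            chosen = rng.choice(len(free), size=n_extra, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_extra)
            for idx, s in zip(np.sort(chosen), signs):
                truth.de_effects[free[int(idx)]] = float(s) * cfg.de_log2fc
        mat = np.zeros((n, cfg.n_case + cfg.n_control), dtype=np.int64)
        for i, fid in enumerate(fids):
            base = baselines[i]
            effect = truth.de_effects.get(fid, 0.0)
            case_mean = base * (2.0 ** effect)
            mat[i, : cfg.n_case] = _nb_draw(rng, case_mean, cfg.nb_dispersion, cfg.n_case)
            mat[i, cfg.n_case :] = _nb_draw(rng, base, cfg.nb_dispersion, cfg.n_control)
        frame = pd.DataFrame(mat, index=fids, columns=case_ids + ctrl_ids)
        counts[cls] = CountMatrix(counts=frame, rna_class=cls)

    all_samples = case_ids + ctrl_ids
    totals = {
        s: float(sum(counts[cls].counts[s].sum() for cls in RNA_CLASSES) + cfg.background_reads)
        for s in all_samples
    }
    truth.validate(check_sites=False)
    return counts, sample_map, totals, truth


def generate_dataset(cfg: SimConfig) -> Dataset:
    sequences, seq_truth = generate_sequences(cfg)
    counts, sample_map, totals, truth = generate_counts(cfg)
    truth.site_plants = seq_truth.site_plants
    truth.validate()
    return Dataset(
        config=cfg,
        sequences=sequences,
        counts=counts,
        sample_map=sample_map,
        mapped_totals=totals,
        truth=truth,
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, int]:
    """Write FASTA/TSV/JSON artifacts; returns {file name: row count}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    params = {"seed": cfg.seed}
    manifest: dict[str, int] = {}

    for cls in RNA_CLASSES:
        name = f"{cls}.fasta"
        manifest[name] = write_fasta(dataset.sequences[cls], out / name)
        cname = f"{cls}_counts.tsv"
        write_counts(dataset.counts[cls], out / cname, params | {"class": cls})
        manifest[cname] = len(dataset.counts[cls].feature_ids)

    sm = pd.DataFrame(
        sorted(dataset.sample_map.items()), columns=["sample_id", "group"]
    )
    write_table(sm, out / "sample_map.tsv", params)
    manifest["sample_map.tsv"] = len(sm)

    totals = pd.DataFrame(
        sorted(dataset.mapped_totals.items()), columns=["sample_id", "mapped_total"]
    )
    write_table(totals, out / "mapped_totals.tsv", params)
    manifest["mapped_totals.tsv"] = len(totals)

    effects = pd.DataFrame(
        sorted(dataset.truth.de_effects.items()), columns=["feature_id", "log2fc"]
    )
    write_table(effects, out / "truth_de.tsv", params)
    manifest["truth_de.tsv"] = len(effects)

    triads = pd.DataFrame(
        [asdict(t) for t in dataset.truth.triads],
        columns=["sponge_id", "sponge_class", "mirna_id", "mrna_id", "pattern"],
    )
    write_table(triads, out / "truth_triads.tsv", params)
    manifest["truth_triads.tsv"] = len(triads)

    sites = pd.DataFrame(
        [
            (mid, tid, start, stype)
            for (mid, tid), (start, stype) in sorted(dataset.truth.site_plants.items())
        ],
        columns=["mirna_id", "target_id", "start", "site_type"],
    )
    write_table(sites, out / "truth_sites.tsv", params)
    manifest["truth_sites.tsv"] = len(sites)

    truth_json = {
        "de_effects": dict(sorted(dataset.truth.de_effects.items())),
        "triads": [asdict(t) for t in dataset.truth.triads],
        "site_plants": [
            {"mirna_id": mid, "target_id": tid, "start": start, "site_type": stype}
            for (mid, tid), (start, stype) in sorted(dataset.truth.site_plants.items())
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True) + "\n")
    manifest["truth.json"] = len(truth_json["de_effects"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def load_truth(path: str | Path) -> TruthSet:
    """Read back truth.json written by write_dataset."""
    data = json.loads(Path(path).read_text())
    return TruthSet(
        de_effects=data["de_effects"],
        triads=[PlantedTriad(**t) for t in data["triads"]],
        site_plants={
            (s["mirna_id"], s["target_id"]): (s["start"], s["site_type"])
            for s in data["site_plants"]
        },
    )
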