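"""Synthetic cohort generator with a ground-truth table.

Emulates the study design every downstream stage assumes: a qPCR Ct matrix
(miRNA assays x samples) for an IBC vs non-IBC cohort, a log-scale mRNA
matrix for the subset of samples with array profiles, clinical annotations,
a TargetScan-style prediction database seeded with the planted targets plus
decoys, GMT gene-set collections, and a survival table with
proportional-hazards structure.  Defaults mirror the emulated study: 20 IBC
+ 50 non-IBC samples, 384 miRNA assays, a 44-sample mRNA subset, with a
scaled-down gene universe (2000 genes) that keeps every statistical
property intact at desk scale.

Planted effects (differential miRNAs, signed miRNA-target correlations,
processing-gene shifts, hazard scores) are recorded in a TruthTable so
recovery can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .de import PROCESSING_GENES
from .targets import TargetDB


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_ibc: int = 20
    n_nonibc: int = 50
    n_mirna: int = 384
    n_gene: int = 2000
    n_mrna_samples: int = 44
    de_mirna_frac: float = 0.04       # ~15 of 384, near the 13 reported DE miRNAs
    de_shift_ct: float = 2.0          # Ct units (~4-fold)
    target_rho: float = 0.7           # planted Spearman magnitude
    frac_pos_targets: float = 0.6     # excess of positive miRNA-target pairs
    noise_sd_ct: float = 1.0
    undetected_frac: float = 0.05
    hazard_log_hr: float = 0.5        # per-unit log hazard ratio of the planted score
    processing_shift: float = 1.5     # AGO2 up / DICER1 down shift in IBC (log units)
    n_targets_per_mirna: int = 30
    weak_mirna_frac: float = 0.1      # assays with baseline Ct above the detection cutoff
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ibc", "n_nonibc", "n_mirna", "n_gene", "n_mrna_samples"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("de_mirna_frac", "frac_pos_targets", "undetected_frac", "weak_mirna_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.target_rho < 1:
            raise ValueError("target_rho must be in (0, 1)")
        if self.n_mrna_samples > self.n_ibc + self.n_nonibc:
            raise ValueError("n_mrna_samples exceeds the cohort size")
        n_de = round(self.de_mirna_frac * self.n_mirna)
        if self.n_gene < len(PROCESSING_GENES) + n_de * self.n_targets_per_mirna:
            raise ValueError("n_gene too small for the planted targets")


@dataclass
class TruthTable:
    """Planted ground truth of one synthetic cohort."""

    de_mirnas: dict[str, int]                      # miRNA -> +1 (up in IBC)
    planted_pairs: list[tuple[str, str, int, float]]  # (miRNA, gene, sign, rho)
    predicted_targets: dict[str, list[str]]
    planted_hazard_scores: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        mio.write_json(
            {
                "de_mirnas": self.de_mirnas,
                "planted_pairs": [list(p) for p in self.planted_pairs],
                "predicted_targets": {m: sorted(g) for m, g in self.predicted_targets.items()},
                "planted_hazard_scores": self.planted_hazard_scores,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = mio.read_json(path)
        return cls(
            de_mirnas={k: int(v) for k, v in d["de_mirnas"].items()},
            planted_pairs=[(p[0], p[1], int(p[2]), float(p[3])) for p in d["planted_pairs"]],
            predicted_targets={m: list(g) for m, g in d["predicted_targets"].items()},
            planted_hazard_scores={k: float(v) for k, v in d["planted_hazard_scores"].items()},
        )


@dataclass
class Cohort:
    config: CohortConfig
    ct: pd.DataFrame                 # miRNA x sample, NaN = undetected
    mrna: pd.DataFrame               # gene x mRNA-subset sample, log-like scale
    samples: pd.DataFrame            # clinical annotation, indexed by sample id
    target_db: TargetDB
    gene_sets: dict[str, set[str]]
    survival: pd.DataFrame
    truth: TruthTable


def _spearman_to_pearson(rho_s: float) -> float:
    # bivariate-normal link: rho_S = (6/pi) asin(rho_P / 2)
    return 2 * np.sin(np.pi * rho_s / 6)


def _annotations(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"IBC_{i + 1:02d}" for i in range(cfg.n_ibc)] + [
        f"NBC_{i + 1:02d}" for i in range(cfg.n_nonibc)
    ]
    ibc = np.array([True] * cfg.n_ibc + [False] * cfg.n_nonibc)
    n = len(ids)

    def pick(options, p_ibc, p_non):
        return np.where(
            ibc,
            rng.choice(options, size=n, p=p_ibc),
            rng.choice(options, size=n, p=p_non),
        )

    # marginals roughly follow the emulated cohort's clinical table
    return pd.DataFrame(
        {
            "subtype": np.where(ibc, "IBC", "non-IBC"),
            "t_status": pick(["low", "high"], [0.05, 0.95], [0.6, 0.4]),
            "n_status": pick(["pos", "neg"], [0.9, 0.1], [0.5, 0.5]),
            "m_status": pick(["M0", "M+"], [0.5, 0.5], [0.94, 0.06]),
            "stage": pick(["I", "II", "III", "IV"], [0.0, 0.0, 0.5, 0.5], [0.42, 0.30, 0.22, 0.06]),
            "grade": pick(["well", "moderate", "poor"], [0.0, 0.45, 0.55], [0.16, 0.46, 0.38]),
            "er": pick(["pos", "neg"], [0.8, 0.2], [0.7, 0.3]),
            "her2": pick(["pos", "neg"], [0.4, 0.6], [0.18, 0.82]),
            "age": np.round(rng.normal(60, 10, size=n)).astype(int),
        },
        index=pd.Index(ids, name="sample_id"),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one synthetic cohort; bit-identical for a fixed config.seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = _annotations(cfg, rng)
    ids = list(samples.index)
    ibc = (samples["subtype"] == "IBC").to_numpy()
    n = len(ids)

    mirnas = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirna)]
    n_weak = round(cfg.weak_mirna_frac * cfg.n_mirna)
    weak = set(rng.choice(cfg.n_mirna, size=n_weak, replace=False).tolist())
    baseline = np.where(
        np.isin(np.arange(cfg.n_mirna), list(weak)),
        rng.uniform(35.5, 39.0, cfg.n_mirna),
        rng.uniform(22.0, 32.0, cfg.n_mirna),
    )
    informative_idx = [i for i in range(cfg.n_mirna) if i not in weak]
    n_de = round(cfg.de_mirna_frac * cfg.n_mirna)
    de_idx = rng.choice(informative_idx, size=n_de, replace=False)
    shift = np.zeros((cfg.n_mirna, n))
    shift[np.asarray(de_idx)[:, None], np.where(ibc)[0][None, :]] = -cfg.de_shift_ct

    noise = rng.normal(0, cfg.noise_sd_ct, size=(cfg.n_mirna, n))
    ct_latent = baseline[:, None] + shift + noise
    ct_latent = np.clip(ct_latent, 1.0, 45.0)
    ct = ct_latent.copy()
    undet = rng.random(size=ct.shape) < cfg.undetected_frac
    ct[undet] = np.nan
    ct_df = pd.DataFrame(ct, index=mirnas, columns=ids)

    # mRNA subset: all IBC first, then non-IBC to fill
    mrna_ids = [s for s in ids if s.startswith("IBC")][: cfg.n_mrna_samples]
    mrna_ids += [s for s in ids if s.startswith("NBC")][: cfg.n_mrna_samples - len(mrna_ids)]
    mrna_cols = {s: ids.index(s) for s in mrna_ids}
    ibc_sub = ibc[list(mrna_cols.values())]

    genes = list(PROCESSING_GENES) + [
        f"GENE{i:05d}" for i in range(cfg.n_gene - len(PROCESSING_GENES))
    ]
    mu = rng.uniform(5, 10, size=len(genes))
    mrna = mu[:, None] + rng.normal(0, 1.0, size=(len(genes), len(mrna_ids)))
    # processing-gene plant: AGO2 up, DICER1 down in IBC
    mrna[genes.index("AGO2"), ibc_sub] += cfg.processing_shift
    mrna[genes.index("DICER1"), ibc_sub] -= cfg.processing_shift

    # planted miRNA-target correlations on the mRNA subset
    r_p = _spearman_to_pearson(cfg.target_rho)
    free_genes = list(range(len(PROCESSING_GENES), len(genes)))
    rng.shuffle(free_genes)
    planted_pairs: list[tuple[str, str, int, float]] = []
    cursor = 0
    for mi in de_idx:
        z = -ct_latent[mi, list(mrna_cols.values())]
        z = (z - z.mean()) / z.std()
        n_pos = round(cfg.frac_pos_targets * cfg.n_targets_per_mirna)
        for j in range(cfg.n_targets_per_mirna):
            gi = free_genes[cursor]
            cursor += 1
            sign = 1 if j < n_pos else -1
            eps = rng.normal(0, 1.0, size=len(mrna_ids))
            mrna[gi] = mu[gi] + sign * (r_p * z + np.sqrt(1 - r_p**2) * eps)
            planted_pairs.append((mirnas[mi], genes[gi], sign, cfg.target_rho))
    mrna_df = pd.DataFrame(mrna, index=genes, columns=mrna_ids)

    # prediction database: planted targets + per-miRNA decoys + decoy families
    db: dict[str, set[str]] = {}
    target_lookup: dict[str, set[str]] = {}
    for m, g, _, _ in planted_pairs:
        target_lookup.setdefault(m, set()).add(g)
    pool = [genes[i] for i in free_genes[cursor:]]
    for m, tset in target_lookup.items():
        decoys = rng.choice(pool, size=min(len(tset), len(pool)), replace=False)
        db[m] = tset | set(decoys.tolist())
    non_de_informative = [i for i in informative_idx if i not in set(de_idx.tolist())]
    decoy_fams = rng.choice(non_de_informative, size=min(n_de, len(non_de_informative)), replace=False)
    for mi in decoy_fams:
        db[mirnas[mi]] = set(
            rng.choice(pool, size=min(2 * cfg.n_targets_per_mirna, len(pool)), replace=False).tolist()
        )
    target_db = TargetDB(db, source_label="synthetic")

    # gene sets: one term per planted miRNA (half its targets + padding) + random terms
    gene_sets: dict[str, set[str]] = {}
    for k, (m, tset) in enumerate(sorted(target_lookup.items())):
        half = sorted(tset)[: len(tset) // 2]
        pad = rng.choice(pool, size=len(half), replace=False)
        gene_sets[f"SET_PLANTED_{k:02d}"] = set(half) | set(pad.tolist())
    for k in range(20):
        gene_sets[f"SET_RANDOM_{k:02d}"] = set(
            rng.choice(genes, size=40, replace=False).tolist()
        )

    # survival with proportional-hazards structure on a planted per-sample score
    score = rng.standard_normal(n)
    rate = 0.02 * np.exp(cfg.hazard_log_hr * score)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(24, 120, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    survival = pd.DataFrame(
        {
            "sample_id": ids,
            "dataset_id": "cohort",
            "endpoint": "DMFS",
            "time": np.round(time, 3),
            "event": event,
        }
    )

    truth = TruthTable(
        de_mirnas={mirnas[i]: 1 for i in sorted(de_idx.tolist())},
        planted_pairs=planted_pairs,
        predicted_targets={m: sorted(g) for m, g in db.items()},
        planted_hazard_scores=dict(zip(ids, np.round(score, 6).tolist())),
    )
    return Cohort(
        config=cfg, ct=ct_df, mrna=mrna_df, samples=samples,
        target_db=target_db, gene_sets=gene_sets, survival=survival, truth=truth,
    )


def generate_survival_cohort(
    n: int,
    hazard_log_hr: float = 0.5,
    n_datasets: int = 1,
    endpoint: str = "DMFS",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Stand-alone survival cohort: exponential times with a planted log-HR.

    Returns the survival table and the planted standardized score per sample
    (the linear predictor, per-unit log hazard = ``hazard_log_hr``).
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:05d}" for i in range(n)]
    score = rng.standard_normal(n)
    rate = 0.02 * np.exp(hazard_log_hr * score)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(24, 120, size=n)
    surv = pd.DataFrame(
        {
            "sample_id": ids,
            "dataset_id": [f"DS{(i % n_datasets) + 1}" for i in range(n)],
            "endpoint": endpoint,
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
        }
    )
    return surv, pd.Series(score, index=ids, name="score")


def write_fixture_tables(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text fixture files; round-trips losslessly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_ct": d / "mirna_ct.tsv",
        "mrna_expr": d / "mrna_expr.tsv",
        "samples": d / "samples.tsv",
        "targets": d / "targets.tsv",
        "genesets": d / "genesets.gmt",
        "survival": d / "survival.tsv",
        "truth": d / "truth.json",
    }
    mio.write_matrix(cohort.ct, paths["mirna_ct"])
    mio.write_matrix(cohort.mrna, paths["mrna_expr"])
    mio.write_samples(cohort.samples, paths["samples"])
    mio.write_target_db(cohort.target_db.targets, paths["targets"])
    mio.write_gmt(cohort.gene_sets, paths["genesets"])
    mio.write_survival(cohort.survival, paths["survival"])
    cohort.truth.to_json(paths["truth"])
    return paths
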