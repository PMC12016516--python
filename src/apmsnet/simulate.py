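"""Synthetic AP-MS experiments with known ground truth.

The generator emulates the statistical structure of a tagged-bait
pull-down study in *Thermococcus kodakarensis*: a ~2,306-protein proteome,
three experimental replicates per bait/condition versus four parental
control replicates, a sparse background of resin-binding proteins,
"sticky" proteins elevated equally in every purification (which a correct
pipeline must reject), planted true partners whose experimental abundance
is scaled by a known log2 effect, and proteins whose tryptic peptides
yield no usable MS signal at all (the ferredoxin-1 phenomenon) and are
therefore invisible regardless of their true associations.

Counts are negative-binomial (mean/dispersion): real spectral counts are
overdispersed relative to Poisson, and recovery/calibration properties
must hold under that extra variance.

Seeding is hierarchical: every (entity, condition, replicate) stream is
derived from the single experiment seed, so adding baits or conditions
never perturbs previously generated runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import PARENTAL, Condition, SampleSheet, SpectralCountTable, TargetTable
from .network import BaitNetwork, ComplexGroup, read_network_tsv

# 27 nt encoding the nine-residue hemagglutinin (HA) epitope, codon-optimised,
# followed by 18 nt encoding the hexahistidine affinity tag: the 45-bp insert
# appended in-frame at each target's native locus.
HA_INSERT = "TACCCATACGACGTTCCGGACTACGCA"
HIS6_INSERT = "CATCACCATCACCATCAC"


def build_tag_insert() -> str:
    """The 45-nt HA + His6 genomic insert used to tag each bait in-frame."""
    return HA_INSERT + HIS6_INSERT


DEFAULT_CONDITIONS = (Condition(sulfur=True), Condition(sulfur=False))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic AP-MS experiment.

    proteome_size
        Number of encoded proteins (default matches the ~2,306 predicted
        proteins of the modelled organism).
    n_baits, partners_per_bait
        Tagged strains to simulate and true partners planted per bait
        (default 30, the study-scale average partner count).
    effect_log2fc
        (low, high) range of planted log2 enrichments, drawn uniformly;
        the default [2, 6] spans the significance (2) and high-confidence
        (4) decision boundaries.
    background_mean, background_fraction
        Mean spectral count (per run) of resin-background binders and the
        fraction of the proteome that binds the resin at all; per-protein
        background means are exponential around ``background_mean``, so a
        few hundred proteins are typically identified per run.
    dispersion
        Negative-binomial size parameter k (variance = mu + mu^2/k).
    detectability, undetectable_fraction
        Per-protein probability that an emitted spectrum is usable
        (binomial thinning), and the fraction of proteins with
        detectability exactly 0 — present in complexes but invisible to MS.
    sticky_fraction, sticky_boost
        Fraction of proteins with elevated resin affinity in ALL
        purifications (experimental and control equally) and their mean
        multiplier; these must not be called partners.
    partner_floor
        Baseline count added to a partner's control mean before applying
        2^effect, so partners absent from controls still appear in
        experimental runs.
    bait_effect
        log2 enrichment of the bait's own protein in its purifications.
    libsize_jitter
        If > 0, each run's mean vector is scaled by a uniform factor in
        [1 - j, 1 + j] to mimic library-size variation.
    """

    proteome_size: int = 2306
    n_baits: int = 25
    partners_per_bait: int = 30
    effect_log2fc: tuple[float, float] = (2.0, 6.0)
    background_mean: float = 10.0
    background_fraction: float = 0.25
    dispersion: float = 5.0
    detectability: float = 1.0
    undetectable_fraction: float = 0.02
    sticky_fraction: float = 0.05
    sticky_boost: float = 8.0
    partner_floor: float = 1.0
    bait_effect: float = 6.0
    n_exp_reps: int = 3
    n_ctrl_reps: int = 4
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    libsize_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proteome_size < 2:
            raise ValueError("proteome_size must be >= 2")
        if not (0 < self.n_baits <= self.proteome_size):
            raise ValueError("n_baits must be in [1, proteome_size]")
        if not (0 <= self.partners_per_bait < self.proteome_size):
            raise ValueError("partners_per_bait must be in [0, proteome_size)")
        lo, hi = self.effect_log2fc
        if not (0 <= lo <= hi):
            raise ValueError("effect_log2fc range must satisfy 0 <= low <= high")
        for name in ("background_mean", "dispersion", "sticky_boost", "bait_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_fraction", "detectability",
                     "undetectable_fraction", "sticky_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.partner_floor < 0:
            raise ValueError("partner_floor must be non-negative")
        if self.n_exp_reps < 1 or self.n_ctrl_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if not (0 <= self.libsize_jitter < 1):
            raise ValueError("libsize_jitter must lie in [0, 1)")
        if not self.conditions:
            raise ValueError("at least one condition is required")


@dataclass
class GroundTruth:
    """Planted bait-prey pairs with their true effects.

    One row per (bait, prey, condition); ``detectable`` is False for
    partners whose protein yields no MS signal and can never be recovered.
    """

    frame: pd.DataFrame

    COLUMNS = ("bait", "prey", "sulfur", "pyruvate", "effect_log2fc", "detectable")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ground truth missing columns: {missing}")
        key = self.frame[["bait", "prey", "sulfur", "pyruvate"]]
        if key.duplicated().any():
            raise ValueError("planted pair duplicated within a condition")

    def pairs(self, condition: Condition, detectable_only: bool = False) -> set[tuple[str, str]]:
        df = self.frame
        mask = (df["sulfur"] == condition.sulfur) & (df["pyruvate"] == condition.pyruvate)
        if detectable_only:
            mask &= df["detectable"]
        return set(zip(df.loc[mask, "bait"], df.loc[mask, "prey"]))


def write_ground_truth(truth: GroundTruth, path) -> None:
    df = truth.frame.copy()
    for col in ("sulfur", "pyruvate", "detectable"):
        df[col] = np.where(df[col], "true", "false")
    df.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sulfur", "pyruvate", "detectable"):
        df[col] = df[col].str.lower() == "true"
    df["effect_log2fc"] = df["effect_log2fc"].astype(float)
    return GroundTruth(df.reset_index(drop=True))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = k / (k + mu[pos])
        counts[pos] = rng.negative_binomial(k, p)
    return counts


def _cond_label(cond: Condition) -> str:
    return f"S{int(cond.sulfur)}P{int(cond.pyruvate)}"


def simulate_experiment(
    config: SimConfig,
) -> tuple[SpectralCountTable, SampleSheet, GroundTruth]:
    """Generate one complete synthetic experiment.

    Returns the counts table (proteins x runs, control runs first within
    each condition), the matching sample sheet, and the planted-partner
    ground truth.  Fully reproducible from ``config.seed``.
    """
    n = config.proteome_size
    proteins = np.array([f"TK{i + 1:04d}" for i in range(n)], dtype=object)

    attr_rng = _rng(config.seed, 0)
    base_mean = np.zeros(n)
    n_bg = int(round(config.background_fraction * n))
    bg_idx = attr_rng.choice(n, size=n_bg, replace=False)
    base_mean[bg_idx] = attr_rng.exponential(config.background_mean, size=n_bg)

    n_sticky = int(round(config.sticky_fraction * n))
    sticky_idx = attr_rng.choice(n, size=n_sticky, replace=False)
    base_mean[sticky_idx] = config.background_mean * config.sticky_boost

    detect = np.full(n, config.detectability)
    n_undet = int(round(config.undetectable_fraction * n))
    undet_idx = attr_rng.choice(n, size=n_undet, replace=False)
    detect[undet_idx] = 0.0

    bait_rng = _rng(config.seed, 4)
    eligible = np.setdiff1d(np.arange(n), undet_idx)
    bait_idx = np.sort(bait_rng.choice(eligible, size=config.n_baits, replace=False))
    baits = proteins[bait_idx]

    def sample_run(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
        if config.libsize_jitter > 0:
            mu = mu * rng.uniform(1 - config.libsize_jitter, 1 + config.libsize_jitter)
        counts = _nb_counts(rng, mu, config.dispersion)
        thin = detect < 1
        if thin.any():
            counts[thin] = rng.binomial(counts[thin], detect[thin])
        return counts

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []
    truth_rows: list[dict] = []

    for ci, cond in enumerate(config.conditions):
        label = _cond_label(cond)
        for rep in range(1, config.n_ctrl_reps + 1):
            run_id = f"TS559_{label}_r{rep}"
            columns[run_id] = sample_run(_rng(config.seed, 1, ci, rep), base_mean)
            sheet_rows.append({
                "run_id": run_id, "strain": PARENTAL, "role": "control",
                "sulfur": cond.sulfur, "pyruvate": cond.pyruvate, "replicate": rep,
            })

    for bi, b_idx in enumerate(bait_idx):
        bait = str(proteins[b_idx])
        partner_rng = _rng(config.seed, 3, int(b_idx))
        candidates = np.setdiff1d(np.arange(n), [b_idx])
        partner_idx = np.sort(
            partner_rng.choice(candidates, size=config.partners_per_bait, replace=False)
        )
        for ci, cond in enumerate(config.conditions):
            label = _cond_label(cond)
            lo, hi = config.effect_log2fc
            effects = partner_rng.uniform(lo, hi, size=config.partners_per_bait)
            mu = base_mean.copy()
            mu[partner_idx] = (base_mean[partner_idx] + config.partner_floor) * (
                2.0 ** effects
            )
            mu[b_idx] = (base_mean[b_idx] + config.partner_floor) * (
                2.0 ** config.bait_effect
            )
            for rep in range(1, config.n_exp_reps + 1):
                run_id = f"{bait}_{label}_r{rep}"
                columns[run_id] = sample_run(_rng(config.seed, 2, int(b_idx), ci, rep), mu)
                sheet_rows.append({
                    "run_id": run_id, "strain": bait, "role": "experimental",
                    "sulfur": cond.sulfur, "pyruvate": cond.pyruvate, "replicate": rep,
                })
            for p_idx, eff in zip(partner_idx, effects):
                truth_rows.append({
                    "bait": bait, "prey": str(proteins[p_idx]),
                    "sulfur": cond.sulfur, "pyruvate": cond.pyruvate,
                    "effect_log2fc": float(eff),
                    "detectable": bool(detect[p_idx] > 0),
                })

    counts = pd.DataFrame(columns, index=pd.Index(proteins, name="protein_id"))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = GroundTruth(pd.DataFrame(truth_rows, columns=list(GroundTruth.COLUMNS)))
    return SpectralCountTable(counts), sheet, truth


# ---------------------------------------------------------------------------
# packaged reference fixtures


def fixture_tables() -> tuple[TargetTable, BaitNetwork]:
    """Bundled reference tables.

    Returns the table of the 25 tagged *T. kodakarensis* redox genes (with
    complex acronyms and tag termini) and a curated +S edge fixture of the
    partners shared by the OGOR, MBS and FDH complexes, used to exercise
    multi-complex intersection queries.
    """
    data = resources.files("apmsnet.data")
    with resources.as_file(data / "target_genes.tsv") as path:
        targets = TargetTable(pd.read_csv(path, sep="\t", dtype=str))
    with resources.as_file(data / "shared_prey_edges.tsv") as path:
        net = read_network_tsv(path)
    return targets, net


def complex_groups(targets: TargetTable) -> dict[str, ComplexGroup]:
    """Complex acronym -> :class:`ComplexGroup` of its tagged bait genes."""
    return {
        name: ComplexGroup(name=name, members=tuple(members))
        for name, members in targets.complexes().items()
    }
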