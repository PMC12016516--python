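"""Per-bait, per-condition spectral-count enrichment statistics.

For each tagged-bait purification, every protein detected in at least one
experimental replicate is tested for enrichment over the parental control
purifications with a one-sided Fisher's exact test on pooled spectral
counts, followed by Benjamini-Hochberg correction across the proteins
tested for that bait/condition.  A protein is called a significant
copurification partner when its adjusted P value is below ``alpha`` (0.05)
and its log2 fold change is at least ``fc_min`` (2).

The 2x2 table pools integer counts across replicates::

                         experimental   control
    this protein              a            b
    all other proteins        c            d

Pooling keeps the test exact (Fisher requires integer counts); per-run
means are reserved for the fold change, which uses a pseudocount so that
partners absent from every control run (the common case for true partners)
get a finite, large fold change.

When the tagged bait protein itself narrowly misses the fold-change cutoff
(while remaining significant by P), the cutoff for that bait/condition is
lowered to the bait's own fold change and significance is recomputed — the
"bait rescue" that keeps a marginally inefficient purification, and
everything at least as enriched as its bait, in the data set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import Condition, SampleSheet, SpectralCountTable, select_group

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and knobs of the significance and ranking procedure.

    alpha / strict_alpha
        P-value cutoffs for significance (0.05) and for the high-confidence
        rank category (0.01); on the volcano plot these are the horizontal
        lines at -log10 P = 1.3 and 2.
    fc_min / fc_strict
        log2 fold-change cutoffs for significance (2, i.e. 4-fold) and for
        the high-confidence rank category (4, i.e. 16-fold).
    pseudocount
        Added to both per-run means before the log-ratio so zero-control
        partners are finite.
    p_mode
        ``"adjusted"`` compares BH-adjusted P to the cutoffs (default);
        ``"raw"`` uses unadjusted P.
    rescue_floor
        A bait whose own log2fc falls below this is considered a failed
        purification and is never rescued.
    replicates_required
        Experimental replicates expected for full reproducibility credit.
    normalize
        If true, per-run means are rescaled to equal library size (total
        counts) before the fold change; pooled counts for the exact test
        are never rescaled.
    detection_floor
        Minimum spectral count for a protein to count as detected in a run.
    """

    alpha: float = 0.05
    strict_alpha: float = 0.01
    fc_min: float = 2.0
    fc_strict: float = 4.0
    pseudocount: float = 0.5
    rescue_floor: float = 1.0
    p_mode: str = "adjusted"
    replicates_required: int = 3
    normalize: bool = False
    detection_floor: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.strict_alpha < self.alpha <= 1):
            raise ValueError(
                f"require 0 < strict_alpha < alpha <= 1, got "
                f"{self.strict_alpha}, {self.alpha}"
            )
        if not (0 < self.fc_min < self.fc_strict):
            raise ValueError(
                f"require 0 < fc_min < fc_strict, got {self.fc_min}, {self.fc_strict}"
            )
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.p_mode not in ("adjusted", "raw"):
            raise ValueError(f"p_mode must be 'adjusted' or 'raw', got {self.p_mode!r}")
        if self.detection_floor < 1:
            raise ValueError("detection_floor must be >= 1")

    def neg_log10_thresholds(self) -> tuple[float, float]:
        """(-log10 alpha, -log10 strict_alpha): the volcano-plot y-axis lines."""
        return (-math.log10(self.alpha), -math.log10(self.strict_alpha))

    @classmethod
    def from_file(cls, path) -> "ScoringConfig":
        """Load from a JSON or YAML mapping of field names to values."""
        text = open(path, encoding="utf-8").read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)


@dataclass(frozen=True)
class ContingencyTable:
    """Pooled 2x2 spectral-count table for one protein.

    a/b: this protein's counts summed over experimental/control runs;
    c/d: all other proteins' counts summed over the same runs.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")


@dataclass
class EnrichmentRecord:
    """Result of testing one protein in one bait/condition comparison."""

    protein_id: str
    bait_gene: str
    condition: Condition
    n_detected: int
    n_replicates: int
    mean_exp: float
    mean_ctrl: float
    log2fc: float
    p_raw: float
    p_adj: float
    significant: bool
    rank: int | None = None
    rescued: bool = False

    @property
    def is_self(self) -> bool:
        """True when the prey is the bait's own gene product."""
        return self.protein_id == self.bait_gene


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided (enrichment-in-experimental) Fisher exact P value.

    The P value is the hypergeometric upper tail P(X >= a) for drawing the
    experimental column total from the pooled population, i.e. the exact
    probability of seeing at least this protein's share of experimental
    counts if counts were allocated to columns at random.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 and b == 0 and c == 0 and d == 0:
        raise ValueError("Fisher test undefined: all four cells are zero")
    return float(_fisher_sf(np.array([a]), np.array([b]), c + a, d + b)[0])


def _fisher_sf(a: np.ndarray, b: np.ndarray, total_exp: int, total_ctrl: int) -> np.ndarray:
    """Vectorised upper-tail Fisher P for pooled per-protein counts.

    ``total_exp``/``total_ctrl`` are the column totals (a+c and b+d for every
    protein).  Population N = total_exp + total_ctrl, successes K = a + b,
    draws n = total_exp; P = P(X >= a) for X ~ Hypergeom(N, K, n).
    """
    n_pop = total_exp + total_ctrl
    p = hypergeom.sf(a - 1, n_pop, a + b, total_exp)
    # exact tail is never truly 0; clamp so downstream -log10 stays finite
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a non-empty vector")
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_exp: float, mean_ctrl: float, pseudocount: float = 0.5) -> float:
    """log2((mean_exp + pseudocount) / (mean_ctrl + pseudocount))."""
    if mean_exp < 0 or mean_ctrl < 0:
        raise ValueError("mean counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_exp + pseudocount) / (mean_ctrl + pseudocount)))


def _threshold_p(record: EnrichmentRecord, config: ScoringConfig) -> float:
    return record.p_adj if config.p_mode == "adjusted" else record.p_raw


def score_bait(
    table: SpectralCountTable,
    sheet: SampleSheet,
    bait: str,
    condition: Condition,
    config: ScoringConfig = ScoringConfig(),
) -> list[EnrichmentRecord]:
    """Test every detected protein for one bait/condition comparison.

    Returns one :class:`EnrichmentRecord` per protein with a count of at
    least ``detection_floor`` in >= 1 experimental run; BH correction is
    applied across exactly those proteins.  Records are in count-table row
    order.
    """
    exp_runs, ctrl_runs = select_group(table, sheet, bait, condition)
    x = table.counts(exp_runs)
    c = table.counts(ctrl_runs)

    a = x.sum(axis=1)
    b = c.sum(axis=1)
    tested = (x >= config.detection_floor).any(axis=1)
    if not tested.any():
        return []
    n_detected = (x >= config.detection_floor).sum(axis=1)

    total_exp = int(a.sum())
    total_ctrl = int(b.sum())
    p_raw = _fisher_sf(a[tested], b[tested], total_exp, total_ctrl)
    p_adj = bh_adjust(p_raw)

    if config.normalize:
        target = np.concatenate([x, c], axis=1).sum(axis=0).mean()
        x_scaled = x * (target / np.maximum(x.sum(axis=0), 1.0))
        c_scaled = c * (target / np.maximum(c.sum(axis=0), 1.0))
        mean_exp = x_scaled.mean(axis=1)
        mean_ctrl = c_scaled.mean(axis=1)
    else:
        mean_exp = x.mean(axis=1)
        mean_ctrl = c.mean(axis=1)

    log2fc = np.log2(
        (mean_exp + config.pseudocount) / (mean_ctrl + config.pseudocount)
    )

    records: list[EnrichmentRecord] = []
    protein_ids = np.asarray(table.protein_ids, dtype=object)
    idx = np.flatnonzero(tested)
    for k, i in enumerate(idx):
        rec = EnrichmentRecord(
            protein_id=str(protein_ids[i]),
            bait_gene=bait,
            condition=condition,
            n_detected=int(n_detected[i]),
            n_replicates=len(exp_runs),
            mean_exp=float(mean_exp[i]),
            mean_ctrl=float(mean_ctrl[i]),
            log2fc=float(log2fc[i]),
            p_raw=float(p_raw[k]),
            p_adj=float(p_adj[k]),
            significant=False,
        )
        p = _threshold_p(rec, config)
        rec.significant = bool(p < config.alpha and rec.log2fc >= config.fc_min)
        records.append(rec)
    return records


def rescue_bait(
    records: list[EnrichmentRecord],
    bait: str,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[list[EnrichmentRecord], bool]:
    """Apply the bait-rescue rule; returns (records, rescue_applied).

    If the bait's own record passes the P criterion but sits just below the
    fold-change cutoff (and above ``rescue_floor``), the cutoff for this
    comparison is lowered to the bait's log2fc and significance recomputed
    for every record.  Records that become significant only under the
    lowered cutoff are flagged ``rescued``.
    """
    own = [r for r in records if r.protein_id == bait]
    if not own:
        logger.warning(
            "bait %s not detected in its own purification; no rescue possible", bait
        )
        return records, False
    bait_rec = own[0]
    p = _threshold_p(bait_rec, config)
    if not (p < config.alpha and config.rescue_floor <= bait_rec.log2fc < config.fc_min):
        return records, False

    lowered = bait_rec.log2fc
    out: list[EnrichmentRecord] = []
    for rec in records:
        newly = (
            not rec.significant
            and _threshold_p(rec, config) < config.alpha
            and rec.log2fc >= lowered
        )
        if newly:
            rec = replace(rec, significant=True, rescued=True)
        out.append(rec)
    cond = bait_rec.condition.label()
    logger.info(
        "bait rescue for %s (%s): fold-change cutoff lowered %.3g -> %.3g, "
        "%d record(s) rescued",
        bait, cond, config.fc_min, lowered, sum(r.rescued for r in out),
    )
    return out, True
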