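"""Five-tier confidence rank for significant copurification partners.

A significant association earns rank 5 when it meets three stringency
categories simultaneously: detected in all experimental replicates,
P <= 0.01, and log2 fold change >= 4.  One point is deducted for each
category not met; the replicate category deducts one point per missing
replicate (detected in 1 of 3 replicates costs two points), which is how
ranks of 1 arise under three categories.  Ranks are floored at 1 and are
defined only for significant records.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import EnrichmentRecord, ScoringConfig


@dataclass(frozen=True)
class RankCriteria:
    """Stringency categories for the 1-5 rank.

    ``p_strict``/``fc_strict`` bound the high-confidence P and fold-change
    categories; ``replicates_required`` is the full-reproducibility count
    (the experimental replicates only — extra control replicates affect the
    test, not this category).  ``use_raw_p`` ranks on unadjusted P.
    """

    replicates_required: int = 3
    p_strict: float = 0.01
    alpha: float = 0.05
    fc_strict: float = 4.0
    fc_min: float = 2.0
    use_raw_p: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_strict < self.alpha):
            raise ValueError("require 0 < p_strict < alpha")
        if not (0 < self.fc_min < self.fc_strict):
            raise ValueError("require 0 < fc_min < fc_strict")
        if self.replicates_required < 1:
            raise ValueError("replicates_required must be >= 1")

    @classmethod
    def from_config(cls, config: ScoringConfig) -> "RankCriteria":
        return cls(
            replicates_required=config.replicates_required,
            p_strict=config.strict_alpha,
            alpha=config.alpha,
            fc_strict=config.fc_strict,
            fc_min=config.fc_min,
            use_raw_p=(config.p_mode == "raw"),
        )


def rank_score(record: EnrichmentRecord, criteria: RankCriteria = RankCriteria()) -> int:
    """Rank a significant record 1-5 by the three-category deduction rule.

    Deductions: one point per experimental replicate short of
    ``replicates_required``; one point if P exceeds ``p_strict``; one point
    if log2fc falls below ``fc_strict``.  Rank = 5 - deductions, floored at 1.
    """
    if not record.significant:
        raise ValueError(
            f"rank is defined only for significant records "
            f"({record.protein_id} in {record.bait_gene} is not significant)"
        )
    p = record.p_raw if criteria.use_raw_p else record.p_adj
    deductions = max(0, criteria.replicates_required - record.n_detected)
    if p > criteria.p_strict:
        deductions += 1
    if record.log2fc < criteria.fc_strict:
        deductions += 1
    return max(1, 5 - deductions)


def assign_ranks(
    records: list[EnrichmentRecord], criteria: RankCriteria = RankCriteria()
) -> list[EnrichmentRecord]:
    """Set ``rank`` in place on every significant record; pass through others."""
    for rec in records:
        rec.rank = rank_score(rec, criteria) if rec.significant else None
    return records


def rank_distribution(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tally ranks per condition.

    Returns a frame with one row per (sulfur, pyruvate, rank) holding the
    count of significant associations at that rank and its percentage of
    that condition's significant total.  Only ranked (significant) records
    are tallied; self-associations (the bait copurifying itself) are
    excluded from the partner tallies.
    """
    rows = []
    ranked = [r for r in records if r.rank is not None and not r.is_self]
    keys = sorted({(r.condition.sulfur, r.condition.pyruvate) for r in ranked})
    for sulfur, pyruvate in keys:
        subset = [r for r in ranked
                  if (r.condition.sulfur, r.condition.pyruvate) == (sulfur, pyruvate)]
        total = len(subset)
        for rank in (5, 4, 3, 2, 1):
            n = sum(r.rank == rank for r in subset)
            rows.append({
                "sulfur": sulfur,
                "pyruvate": pyruvate,
                "rank": rank,
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
            })
    return pd.DataFrame(rows, columns=["sulfur", "pyruvate", "rank", "count", "percent"])


def rank_summary_by_bait(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Per-bait, per-condition totals and rank tallies (partner counts)."""
    ranked = [r for r in records if r.rank is not None and not r.is_self]
    rows: dict[tuple, dict] = {}
    for r in ranked:
        key = (r.bait_gene, r.condition.sulfur, r.condition.pyruvate)
        row = rows.setdefault(key, {
            "bait": r.bait_gene, "sulfur": r.condition.sulfur,
            "pyruvate": r.condition.pyruvate, "total": 0,
            "rank5": 0, "rank4": 0, "rank3": 0, "rank2": 0, "rank1": 0,
        })
        row["total"] += 1
        row[f"rank{r.rank}"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda d: (d["bait"], not d["sulfur"], not d["pyruvate"])))
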