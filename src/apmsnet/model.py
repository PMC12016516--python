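"""Model/results interface tying scoring, rescue, ranking and networks together.

:class:`Interactome` binds a spectral-count table to its sample sheet and a
:class:`~apmsnet.enrichment.ScoringConfig`; :meth:`Interactome.fit` runs the
full per-bait, per-condition procedure (Fisher enrichment, BH correction,
bait rescue, five-tier ranking) and returns an :class:`InteractomeResults`
carrying every enrichment record, summary tables, and network constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enrichment import EnrichmentRecord, ScoringConfig, rescue_bait, score_bait
from .io import (
    Condition,
    SampleSheet,
    SpectralCountTable,
    read_count_table,
    read_sample_sheet,
)
from .network import BaitNetwork, build_network, filter_rank
from .ranking import RankCriteria, assign_ranks, rank_distribution, rank_summary_by_bait

RESULT_COLUMNS = (
    "protein_id", "bait", "sulfur", "pyruvate", "n_detected", "n_replicates",
    "mean_exp", "mean_ctrl", "log2fc", "p_raw", "p_adj", "significant",
    "rank", "rescued",
)


class Interactome:
    """AP-MS interactome scoring model.

    Parameters
    ----------
    counts
        Validated proteins x runs spectral-count table.
    sheet
        Sample sheet binding each run to strain/condition/replicate/role.
    config
        Significance and ranking thresholds; defaults reproduce the
        published procedure (adjusted P < 0.05, log2FC >= 2; strict
        categories at 0.01 and 4).
    """

    def __init__(
        self,
        counts: SpectralCountTable,
        sheet: SampleSheet,
        config: ScoringConfig = ScoringConfig(),
    ) -> None:
        unknown = [r for r in counts.run_ids if r not in set(sheet.run_ids)]
        if unknown:
            raise ValueError(f"runs {unknown} missing from sample sheet")
        self.counts = counts
        self.sheet = sheet
        self.config = config

    @classmethod
    def from_tsv(cls, counts_path, sheet_path, config: ScoringConfig = ScoringConfig()):
        """Build the model from on-disk TSV inputs."""
        sheet = read_sample_sheet(sheet_path)
        counts = read_count_table(counts_path, sheet)
        return cls(counts, sheet, config)

    def fit(
        self,
        baits: list[str] | None = None,
        conditions: list[Condition] | None = None,
    ) -> "InteractomeResults":
        """Score every bait in every condition it was purified under."""
        baits = baits if baits is not None else self.sheet.baits()
        criteria = RankCriteria.from_config(self.config)
        all_records: list[EnrichmentRecord] = []
        rescues: list[tuple[str, Condition]] = []
        for bait in baits:
            conds = conditions if conditions is not None else self.sheet.conditions_for(bait)
            for cond in conds:
                records = score_bait(self.counts, self.sheet, bait, cond, self.config)
                records, rescued = rescue_bait(records, bait, self.config)
                if rescued:
                    rescues.append((bait, cond))
                assign_ranks(records, criteria)
                all_records.extend(records)
        return InteractomeResults(
            model=self, records=all_records, rescues=rescues, baits=list(baits)
        )


@dataclass
class InteractomeResults:
    """Fitted interactome: per-protein records plus derived summaries."""

    model: Interactome
    records: list[EnrichmentRecord]
    rescues: list[tuple[str, Condition]]
    baits: list[str]

    @property
    def significant(self) -> list[EnrichmentRecord]:
        return [r for r in self.records if r.significant]

    def frame(self, significant_only: bool = False) -> pd.DataFrame:
        """Records as a DataFrame with the documented result columns."""
        rows = [
            {
                "protein_id": r.protein_id,
                "bait": r.bait_gene,
                "sulfur": r.condition.sulfur,
                "pyruvate": r.condition.pyruvate,
                "n_detected": r.n_detected,
                "n_replicates": r.n_replicates,
                "mean_exp": r.mean_exp,
                "mean_ctrl": r.mean_ctrl,
                "log2fc": r.log2fc,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "rank": r.rank if r.rank is not None else pd.NA,
                "rescued": r.rescued,
            }
            for r in (self.significant if significant_only else self.records)
        ]
        return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))

    def to_tsv(self, path, significant_only: bool = False) -> None:
        """Write the result table deterministically (sorted rows)."""
        df = self.frame(significant_only)
        df = df.sort_values(
            ["bait", "sulfur", "pyruvate", "protein_id"], ascending=[True, False, False, True]
        )
        for col in ("sulfur", "pyruvate", "significant", "rescued"):
            df[col] = df[col].map(lambda v: "true" if v else "false")
        df["rank"] = df["rank"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def rank_distribution(self) -> pd.DataFrame:
        return rank_distribution(self.records)

    def rank_summary(self) -> pd.DataFrame:
        return rank_summary_by_bait(self.records)

    def network(self, min_rank: int = 1) -> BaitNetwork:
        """The bait->prey network of significant, ranked associations."""
        net = build_network(self.records)
        return filter_rank(net, min_rank) if min_rank > 1 else net

    def partner_counts(self) -> pd.DataFrame:
        """Significant partners per bait/condition, excluding self-edges."""
        summary = self.rank_summary()
        return summary[["bait", "sulfur", "pyruvate", "total"]]

    def summary(self) -> str:
        """Human-readable fit summary with the resolved thresholds."""
        cfg = self.model.config
        n_sig = len([r for r in self.significant if not r.is_self])
        dist = self.rank_distribution()
        lines = [
            "AP-MS interactome scoring summary",
            "=" * 48,
            f"baits processed:        {len(self.baits)}",
            f"records tested:         {len(self.records)}",
            f"significant partners:   {n_sig}",
            f"bait rescues applied:   {len(self.rescues)}",
            "",
            f"thresholds: p_{cfg.p_mode} < {cfg.alpha} (strict {cfg.strict_alpha}), "
            f"log2FC >= {cfg.fc_min} (strict {cfg.fc_strict}), "
            f"pseudocount {cfg.pseudocount}",
            "",
            "rank distribution (partners, by condition):",
        ]
        if dist.empty:
            lines.append("  (no significant associations)")
        else:
            for (s, p), sub in dist.groupby(["sulfur", "pyruvate"], sort=False):
                cond = Condition(bool(s), bool(p)).label()
                parts = ", ".join(
                    f"rank {int(row['rank'])}: {int(row['count'])} ({row['percent']:.1f}%)"
                    for _, row in sub.iterrows() if row["count"] > 0
                )
                lines.append(f"  {cond}: {parts if parts else 'none'}")
        for bait, cond in self.rescues:
            lines.append(f"rescued bait: {bait} in {cond.label()}")
        return "\n".join(lines)
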