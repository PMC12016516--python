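from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import apmsnet as a
from apmsnet.enrichment import _fisher_sf
from apmsnet.io import PARENTAL
from helpers import bh_stepup_oracle, hypergeom_tail_oracle, sweep_fisher_vs_oracle


class TestFisherOneSided:
    def test_no_counts_either_side_gives_p_one(self):
        assert a.fisher_one_sided(a.ContingencyTable(0, 0, 100, 100)) == 1.0

    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((5, 0, 95, 100), 1164 / 39203),  # exact enumeration over x in [0, 5]
            ((1, 1, 1, 1), 5 / 6),            # exact enumeration over x in {0, 1, 2}
        ],
    )
    def test_matches_frozen_enumeration(self, cells, expected):
        assert a.fisher_one_sided(a.ContingencyTable(*cells)) == pytest.approx(
            expected, abs=1e-12
        )
        assert hypergeom_tail_oracle(*cells) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_table_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            a.fisher_one_sided(a.ContingencyTable(0, 0, 0, 0))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            a.ContingencyTable(-1, 0, 1, 1)

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    def test_agrees_with_enumeration_oracle(self, a_, b, c, d):
        if a_ + b + c + d == 0:
            return
        got = a.fisher_one_sided(a.ContingencyTable(a_, b, c, d))
        assert got == pytest.approx(hypergeom_tail_oracle(a_, b, c, d), abs=1e-9)
        assert 0 < got <= 1


def test_exhaustive_oracle_sweep_small_margins():
    """Every 2x2 table with all margins <= 25 agrees with exact enumeration."""
    assert sweep_fisher_vs_oracle(25, _fisher_sf) < 1e-9


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert a.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_worked_step_up(self):
        # p(i)*m/i = (.04, .04, .04, .04) after the cumulative minimum
        assert a.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_all_equal(self):
        assert a.bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            a.bh_adjust([])
        with pytest.raises(ValueError):
            a.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            a.bh_adjust([1.5])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_invariants(self, pvals):
        adj = a.bh_adjust(pvals)
        assert adj == pytest.approx(bh_stepup_oracle(pvals), rel=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=30), st.randoms())
    def test_permutation_equivariant(self, pvals, rng):
        perm = list(range(len(pvals)))
        rng.shuffle(perm)
        direct = a.bh_adjust(pvals)[perm]
        permuted = a.bh_adjust([pvals[i] for i in perm])
        assert permuted == pytest.approx(direct, rel=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_readjustment_only_moves_upward(self, pvals):
        # step-up adjustment is inflationary: re-adjusting never lowers a value,
        # and a flat (tie-broken) vector is a fixed point
        once = a.bh_adjust(pvals)
        twice = a.bh_adjust(once)
        assert (twice >= once - 1e-15).all()

    @given(st.floats(1e-6, 1.0), st.integers(1, 30))
    def test_flat_vectors_are_fixed_points(self, p, m):
        assert a.bh_adjust([p] * m) == pytest.approx([p] * m)


class TestLog2FoldChange:
    def test_symmetry_at_equal_means(self):
        assert a.log2_fold_change(7.0, 7.0) == 0.0

    def test_large_counts_approach_true_ratio(self):
        got = a.log2_fold_change(400, 100, pseudocount=0.5)
        assert got == pytest.approx(np.log2(400.5 / 100.5))
        assert got == pytest.approx(1.9946067, abs=1e-6)

    def test_zero_control_is_finite(self):
        assert a.log2_fold_change(8, 0, pseudocount=0.5) == pytest.approx(
            np.log2(17.0)
        )

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            a.log2_fold_change(-1, 2)


def _experiment(exp_counts: dict, ctrl_counts: dict, n_exp=3, n_ctrl=4):
    """Tiny hand-built experiment: dicts protein -> per-run count lists."""
    exp_runs = [f"e{i}" for i in range(1, n_exp + 1)]
    ctrl_runs = [f"c{i}" for i in range(1, n_ctrl + 1)]
    rows = [[r, "TK1978", "experimental", True, True, i + 1] for i, r in enumerate(exp_runs)]
    rows += [[r, PARENTAL, "control", True, True, i + 1] for i, r in enumerate(ctrl_runs)]
    sheet = a.SampleSheet(pd.DataFrame(
        rows, columns=["run_id", "strain", "role", "sulfur", "pyruvate", "replicate"]
    ))
    proteins = sorted(set(exp_counts) | set(ctrl_counts))
    data = {
        r: [exp_counts.get(p, [0] * n_exp)[i] for p in proteins]
        for i, r in enumerate(exp_runs)
    }
    data.update({
        r: [ctrl_counts.get(p, [0] * n_ctrl)[i] for p in proteins]
        for i, r in enumerate(ctrl_runs)
    })
    frame = pd.DataFrame(data, index=pd.Index(proteins, name="protein_id"), dtype=np.int64)
    return a.SpectralCountTable(frame), sheet


class TestScoreBait:
    def test_balanced_protein_not_significant(self):
        table, sheet = _experiment(
            {"TK0001": [50, 50, 50], "TK0002": [50, 50, 50]},
            {"TK0001": [50, 50, 50, 50], "TK0002": [50, 50, 50, 50]},
        )
        recs = a.score_bait(table, sheet, "TK1978", a.Condition(True, True))
        rec = next(r for r in recs if r.protein_id == "TK0001")
        assert not rec.significant
        assert rec.p_raw > 0.4 and abs(rec.log2fc) < 0.1

    def test_strong_partner_over_large_background(self):
        table, sheet = _experiment(
            {"TK0001": [10, 12, 9], "TK9999": [10_000] * 3},
            {"TK9999": [10_000] * 4},
        )
        recs = a.score_bait(table, sheet, "TK1978", a.Condition(True, True))
        rec = next(r for r in recs if r.protein_id == "TK0001")
        assert rec.significant
        assert rec.n_detected == 3
        assert rec.log2fc > 4
        assert rec.p_raw == pytest.approx(
            hypergeom_tail_oracle(31, 0, 30_000, 40_000), rel=1e-9
        )

    def test_undetected_protein_emits_no_record(self):
        table, sheet = _experiment(
            {"TK0001": [5, 5, 5]},
            {"TK0002": [3, 3, 3, 3]},
        )
        recs = a.score_bait(table, sheet, "TK1978", a.Condition(True, True))
        assert {r.protein_id for r in recs} == {"TK0001"}

    def test_relabeling_invariance(self, small_experiment):
        """Permuting count-table rows permutes records without changing stats."""
        _, counts, sheet, _ = small_experiment
        bait = sheet.baits()[0]
        cond = sheet.conditions_for(bait)[0]
        base = a.score_bait(counts, sheet, bait, cond)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(counts.frame))
        shuffled = a.SpectralCountTable(counts.frame.iloc[perm])
        permuted = a.score_bait(shuffled, sheet, bait, cond)
        by_id = {r.protein_id: r for r in permuted}
        assert len(base) == len(permuted)
        for r in base:
            s = by_id[r.protein_id]
            assert (s.p_raw, s.p_adj, s.log2fc, s.significant) == (
                r.p_raw, r.p_adj, r.log2fc, r.significant
            )


class TestRescueBait:
    def _records(self, bait_fc, bait_padj):
        def rec(pid, fc, padj, sig):
            return a.EnrichmentRecord(
                protein_id=pid, bait_gene="TK2076", condition=a.Condition(True, True),
                n_detected=3, n_replicates=3, mean_exp=40.0, mean_ctrl=10.0,
                log2fc=fc, p_raw=padj / 2, p_adj=padj, significant=sig,
            )
        return [
            rec("TK2076", bait_fc, bait_padj, sig=bait_fc >= 2 and bait_padj < 0.05),
            rec("TK0001", 1.9, 0.001, sig=False),   # within a lowered range
            rec("TK0002", 3.0, 0.001, sig=True),    # already significant
            rec("TK0003", 1.0, 0.001, sig=False),   # below any sensible range
            rec("TK0004", 3.0, 0.30, sig=False),    # fails the P criterion
        ]

    def test_narrow_miss_lowers_threshold(self):
        recs, applied = a.rescue_bait(self._records(1.8, 0.004), "TK2076")
        assert applied
        by_id = {r.protein_id: r for r in recs}
        assert by_id["TK2076"].significant and by_id["TK2076"].rescued
        assert by_id["TK0001"].significant and by_id["TK0001"].rescued
        assert by_id["TK0002"].significant and not by_id["TK0002"].rescued
        assert not by_id["TK0003"].significant  # log2fc below the bait's 1.8
        assert not by_id["TK0004"].significant  # rescue never waives the P test

    def test_passing_bait_left_unchanged(self):
        records = self._records(3.0, 0.004)
        recs, applied = a.rescue_bait(records, "TK2076")
        assert not applied and recs == records

    def test_nonsignificant_bait_p_blocks_rescue(self):
        records = self._records(1.8, 0.2)
        recs, applied = a.rescue_bait(records, "TK2076")
        assert not applied and recs == records

    def test_failed_purification_below_floor_not_rescued(self):
        records = self._records(0.5, 0.004)
        _, applied = a.rescue_bait(records, "TK2076")
        assert not applied

    def test_undetected_bait_warns_and_passes_through(self, caplog):
        records = self._records(1.8, 0.004)[1:]
        with caplog.at_level("WARNING"):
            recs, applied = a.rescue_bait(records, "TK2076")
        assert not applied and recs == records
        assert any("not detected" in m for m in caplog.messages)


def test_scoring_config_validation():
    with pytest.raises(ValueError):
        a.ScoringConfig(alpha=0.01, strict_alpha=0.05)
    with pytest.raises(ValueError):
        a.ScoringConfig(fc_min=4, fc_strict=2)
    with pytest.raises(ValueError):
        a.ScoringConfig(pseudocount=0)
    with pytest.raises(ValueError):
        a.ScoringConfig(p_mode="bonferroni")


def test_volcano_axis_thresholds():
    """-log10 of the default cutoffs are the volcano-plot guide lines."""
    lax, strict = a.ScoringConfig().neg_log10_thresholds()
    assert lax == pytest.approx(1.3, abs=0.005)
    assert strict == pytest.approx(2.0, abs=1e-12)
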