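"""Control annotation, FPR threshold calibration, hit calling, summaries."""

import numpy as np
import pandas as pd
import pytest

from secretomics import (
    CalibrationError,
    Contrast,
    annotate_controls,
    call_hits,
    fpr_curve,
    overlap_summary,
    top_k_composition,
)
from secretomics.modstats import DiffTestTable


def make_test_table(logfc, p_adj=None, proteins=None):
    logfc = np.asarray(logfc, dtype=float)
    proteins = proteins or [f"p{i}" for i in range(len(logfc))]
    p_adj = np.asarray(p_adj, dtype=float) if p_adj is not None else np.full(len(logfc), 0.01)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": 0.1,
            "t_mod": logfc * 3,
            "df_total": 8.0,
            "p": p_adj,
            "p_adj": p_adj,
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    return DiffTestTable(table, Contrast("c", "A", "B"), d0=4.0, s0_sq=0.04)


def brute_force_calibration(pc, nc, target):
    """Independent exhaustive sweep over all distinct control values."""
    pc, nc = np.asarray(pc, float), np.asarray(nc, float)
    thresholds = [-np.inf] + sorted(set(np.concatenate([pc, nc])))
    fprs = []
    for t in thresholds:
        n_pc = (pc >= t).sum()
        n_nc = (nc >= t).sum()
        fprs.append(n_nc / (n_nc + n_pc) if n_nc + n_pc else 0.0)
    calibrated = None
    for i, t in enumerate(thresholds):
        if all(f <= target for f in fprs[i:]):
            calibrated = t
            break
    return thresholds, fprs, calibrated


class TestAnnotateControls:
    def test_disjoint_lists_label_as_given(self):
        ann = annotate_controls(["a", "b", "c", "d"], ["a", "b"], ["c"])
        assert ann.labels.tolist() == ["PC", "PC", "NC", "none"]
        assert ann.n_ambiguous == 0
        assert ann.counts() == {"PC": 2, "NC": 1, "none": 1}

    def test_gene_in_both_lists_is_ambiguous(self):
        ann = annotate_controls(["a", "b"], ["a"], ["a"])
        assert ann.labels["a"] == "none"
        assert ann.n_ambiguous == 1

    def test_case_insensitive_matching(self):
        ann = annotate_controls(["Lsp1gamma"], ["LSP1GAMMA"], [])
        assert ann.labels.iloc[0] == "PC"


class TestFPRCurve:
    def test_perfectly_separated_controls(self):
        # PC logFCs (2,3,4), NC (0,1): FPR is 0 for any t in (1, 2]; the sweep
        # over distinct control values calibrates at 2.0, which selects the
        # same hit set (logFC >= t) as any threshold in that interval.
        test = make_test_table([2, 3, 4, 0, 1])
        ann = annotate_controls(test.table.index, ["p0", "p1", "p2"], ["p3", "p4"])
        curve = fpr_curve(test, ann, target_fpr=0.10)
        assert curve.calibrated_threshold == 2.0
        row = curve.curve[curve.curve["threshold"] == 2.0].iloc[0]
        assert row["fpr"] == 0.0 and row["n_pc_above"] == 3 and row["n_nc_above"] == 0
        hits_at_cal = test.logfc >= curve.calibrated_threshold
        hits_at_15 = test.logfc >= 1.5
        assert (hits_at_cal == hits_at_15).all()

    def test_matches_exhaustive_sweep_on_worked_example(self):
        pc = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        nc = [2, 4]
        test = make_test_table(pc + nc)
        ann = annotate_controls(test.table.index,
                                [f"p{i}" for i in range(9)], ["p9", "p10"])
        curve = fpr_curve(test, ann, target_fpr=0.10)
        thr, fprs, calibrated = brute_force_calibration(pc, nc, 0.10)
        np.testing.assert_allclose(curve.curve["threshold"], thr)
        np.testing.assert_allclose(curve.curve["fpr"], fprs)
        assert curve.calibrated_threshold == calibrated

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_pc, n_nc = int(rng.integers(1, 30)), int(rng.integers(1, 30))
        pc = np.round(rng.normal(1.0, 1.0, n_pc), 2)
        nc = np.round(rng.normal(0.0, 1.0, n_nc), 2)
        target = float(rng.choice([0.05, 0.10, 0.25]))
        test = make_test_table(np.concatenate([pc, nc]))
        ann = annotate_controls(test.table.index,
                                [f"p{i}" for i in range(n_pc)],
                                [f"p{i}" for i in range(n_pc, n_pc + n_nc)])
        curve = fpr_curve(test, ann, target_fpr=target)
        _, _, calibrated = brute_force_calibration(pc, nc, target)
        assert curve.calibrated_threshold == calibrated

    def test_lowest_threshold_counts_all_controls(self):
        rng = np.random.default_rng(123)
        lfc = rng.normal(0, 1, 200)
        test = make_test_table(lfc)
        ann = annotate_controls(test.table.index,
                                [f"p{i}" for i in range(100)],
                                [f"p{i}" for i in range(100, 200)])
        curve = fpr_curve(test, ann)
        first = curve.curve.iloc[0]
        assert first["threshold"] == -np.inf
        assert first["fpr"] == pytest.approx(100 / 200)

    def test_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(14)
        test = make_test_table(rng.normal(0, 1, 60))
        ann = annotate_controls(test.table.index,
                                [f"p{i}" for i in range(30)],
                                [f"p{i}" for i in range(30, 60)])
        curve = fpr_curve(test, ann)
        assert (np.diff(curve.curve["n_pc_above"]) <= 0).all()
        assert (np.diff(curve.curve["n_nc_above"]) <= 0).all()
        assert curve.curve["fpr"].between(0, 1).all()

    def test_target_monotonicity(self):
        """Lowering the FPR target never lowers the calibrated threshold."""
        rng = np.random.default_rng(15)
        test = make_test_table(np.concatenate([rng.normal(2, 1, 40),
                                               rng.normal(0, 1, 40)]))
        ann = annotate_controls(test.table.index,
                                [f"p{i}" for i in range(40)],
                                [f"p{i}" for i in range(40, 80)])
        thresholds = []
        for target in (0.30, 0.20, 0.10, 0.05):
            c = fpr_curve(test, ann, target_fpr=target)
            thresholds.append(c.calibrated_threshold)
        assert all(t is not None for t in thresholds)
        assert all(b >= a for a, b in zip(thresholds, thresholds[1:]))

    def test_missing_controls_raise(self):
        test = make_test_table([1.0, 2.0])
        ann = annotate_controls(test.table.index, ["p0"], ["absent"])
        with pytest.raises(CalibrationError):
            fpr_curve(test, ann)


class TestCallHits:
    def test_alpha_zero_gives_no_hits(self):
        test = make_test_table([3, 2, 1], p_adj=[0.001, 0.001, 0.001])
        assert call_hits(test, threshold=0.0, alpha=0.0).hit_ids == []

    def test_toy_table_two_hits_in_order(self):
        test = make_test_table(
            [3, 2, 1.5, 0.5, -2],
            p_adj=[0.01, 0.2, 0.01, 0.001, 0.0001],
        )
        hits = call_hits(test, threshold=1.0, alpha=0.05)
        assert hits.hit_ids == ["p0", "p2"]
        flags = hits.table
        assert not flags.loc["p1", "pass_p"]
        assert not flags.loc["p4", "pass_ratio"]

    def test_everything_passes_with_permissive_cuts(self):
        test = make_test_table([3, -2], p_adj=[0.5, 0.99])
        hits = call_hits(test, threshold=-np.inf, alpha=1.0)
        assert len(hits.hit_ids) == 2

    def test_ties_broken_by_protein_id(self):
        test = make_test_table([2.0, 2.0, 2.0], p_adj=[0.01] * 3,
                               proteins=["z", "a", "m"])
        assert call_hits(test, 1.0).hit_ids == ["a", "m", "z"]

    @pytest.mark.parametrize("seed", range(4))
    def test_hit_set_monotonicity(self, seed):
        """Raising the threshold or lowering alpha never adds hits (50 perturbations each)."""
        rng = np.random.default_rng(seed)
        test = make_test_table(rng.normal(0, 2, 100), p_adj=rng.random(100))
        for _ in range(50):
            t1, t2 = sorted(rng.normal(0, 2, 2))
            a1, a2 = sorted(rng.random(2))
            low = set(call_hits(test, t2, a1).hit_ids)   # stricter
            high = set(call_hits(test, t1, a2).hit_ids)  # looser
            assert low <= high


class TestSummaries:
    def test_identical_hit_sets(self):
        t = make_test_table([2, 1], p_adj=[0.01, 0.01])
        h = call_hits(t, 0.0)
        s = overlap_summary(h, h)
        assert s.jaccard == 1.0 and s.pct_of_smaller == 1.0

    def test_disjoint_hit_sets(self):
        a = call_hits(make_test_table([2], p_adj=[0.01], proteins=["x"]), 0.0)
        b = call_hits(make_test_table([2], p_adj=[0.01], proteins=["y"]), 0.0)
        s = overlap_summary(a, b)
        assert s.n_shared == 0 and s.jaccard == 0.0 and s.pct_of_smaller == 0.0

    def test_partial_overlap_arithmetic(self):
        a = call_hits(make_test_table([3, 2, 1], p_adj=[0.01] * 3,
                                      proteins=["a", "b", "c"]), 0.0)
        b = call_hits(make_test_table([4, 3, 2, 1], p_adj=[0.01] * 4,
                                      proteins=["b", "c", "d", "e"]), 0.0)
        s = overlap_summary(a, b)
        assert s.n_shared == 2
        assert s.jaccard == pytest.approx(2 / 5)
        assert s.pct_of_smaller == pytest.approx(2 / 3)

    def test_top_k_single_category(self):
        h = call_hits(make_test_table([3, 2], p_adj=[0.01, 0.01]), 0.0)
        comp = top_k_composition(h, {"p0": "immune", "p1": "immune"}, k=2)
        assert comp == {"immune": 1.0}

    def test_top_k_truncates_to_hit_count(self):
        h = call_hits(make_test_table([3, 2], p_adj=[0.01, 0.01]), 0.0)
        comp = top_k_composition(h, {"p0": "immune"}, k=100)
        assert comp == {"immune": 0.5, "other": 0.5}

    def test_top_k_counting_fractions(self):
        lfc = np.arange(10, 0, -1)
        h = call_hits(make_test_table(lfc, p_adj=[0.01] * 10), 0.0)
        cats = {f"p{i}": "inflammatory" for i in range(4)}
        comp = top_k_composition(h, cats, k=10)
        assert comp["inflammatory"] == pytest.approx(0.4)
        assert sum(comp.values()) == pytest.approx(1.0)
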