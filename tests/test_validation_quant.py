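import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircorr.expression_io import SampleMetadata
from mircorr.validation_quant import (
    ConfirmationThresholds,
    FoldChangeResult,
    ProteinLevelResult,
    QuantError,
    confirm_target,
    delta_delta_ct,
    group_fold_change,
    relative_protein_level,
)
from .conftest import make_matrix


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["replicate_id", "condition", "gene", "ct"])


def single_replicate_table(ct_target_treated, ct_ctrl_treated, ct_target_control, ct_ctrl_control):
    return ct_frame(
        [
            ("R1", "treated", "TGT", ct_target_treated),
            ("R1", "treated", "UBC", ct_ctrl_treated),
            ("R1", "control", "TGT", ct_target_control),
            ("R1", "control", "UBC", ct_ctrl_control),
        ]
    )


class TestDeltaDeltaCt:
    def test_no_change_identity(self):
        res = delta_delta_ct(
            single_replicate_table(24.0, 20.0, 24.0, 20.0), "TGT", "UBC", "treated", "control"
        )
        assert res.delta_delta_ct == 0.0
        assert res.fold == 1.0
        assert res.p is None  # single replicate: fold returned, p unavailable

    def test_hand_arithmetic_example(self):
        # dCt(treated)=25-20=5, dCt(control)=24-20=4, ddCt=1, fold=1/2
        res = delta_delta_ct(
            single_replicate_table(25.0, 20.0, 24.0, 20.0), "TGT", "UBC", "treated", "control"
        )
        assert res.delta_delta_ct == pytest.approx(1.0, abs=1e-12)
        assert res.fold == pytest.approx(0.5, abs=1e-12)

    def test_fold_product_identity(self):
        x = 2.7
        up = delta_delta_ct(
            single_replicate_table(24.0 + x, 20.0, 24.0, 20.0), "TGT", "UBC", "treated", "control"
        )
        down = delta_delta_ct(
            single_replicate_table(24.0 - x, 20.0, 24.0, 20.0), "TGT", "UBC", "treated", "control"
        )
        assert up.fold * down.fold == pytest.approx(1.0, rel=1e-12)
        assert math.log2(up.fold) == pytest.approx(-up.delta_delta_ct, abs=1e-12)

    def test_replicate_ttest_matches_scipy_on_delta_ct_sets(self):
        rows = []
        d_treated = [5.1, 4.8, 5.3]
        d_control = [4.0, 4.2, 3.9]
        for i, d in enumerate(d_treated, 1):
            rows += [(f"R{i}", "treated", "TGT", 20.0 + d), (f"R{i}", "treated", "UBC", 20.0)]
        for i, d in enumerate(d_control, 1):
            rows += [(f"R{i}", "control", "TGT", 20.0 + d), (f"R{i}", "control", "UBC", 20.0)]
        res = delta_delta_ct(ct_frame(rows), "TGT", "UBC", "treated", "control")
        expected = stats.ttest_ind(d_treated, d_control, equal_var=False).pvalue
        assert res.p == pytest.approx(float(expected), rel=1e-9)
        assert res.n_replicates == 3

    def test_missing_cell_named(self):
        table = ct_frame(
            [
                ("R1", "treated", "TGT", 25.0),
                ("R1", "control", "TGT", 24.0),
                ("R1", "control", "UBC", 20.0),
            ]
        )
        with pytest.raises(QuantError, match="UBC.*treated"):
            delta_delta_ct(table, "TGT", "UBC", "treated", "control")

    def test_detection_limit_flags_censored(self):
        res = delta_delta_ct(
            single_replicate_table(40.0, 20.0, 24.0, 20.0), "TGT", "UBC", "treated", "control"
        )
        assert res.censored

    def test_ct_out_of_range_rejected(self):
        with pytest.raises(QuantError, match="outside"):
            delta_delta_ct(
                single_replicate_table(41.0, 20.0, 24.0, 20.0),
                "TGT", "UBC", "treated", "control",
            )


def band_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein", "condition", "raw_intensity", "loading_control_intensity"]
    )


class TestRelativeProteinLevel:
    def test_reference_is_unity(self):
        out = relative_protein_level(
            band_frame([("DLC1", "miR-scr", 80.0, 80.0)]), "miR-scr"
        )
        assert out[0].relative_level == pytest.approx(1.0)
        assert out[0].percent_change == pytest.approx(0.0)

    def test_hand_computed_ratio(self):
        out = relative_protein_level(
            band_frame(
                [
                    ("DLC1", "miR-200a", 50.0, 100.0),
                    ("DLC1", "miR-scr", 80.0, 80.0),
                ]
            ),
            "miR-scr",
        )
        by_cond = {r.condition: r for r in out}
        assert by_cond["miR-200a"].relative_level == pytest.approx(0.5)  # (50/100)/(80/80)
        assert by_cond["miR-200a"].percent_change == pytest.approx(50.0)

    def test_forty_percent_downregulation_case(self):
        # relative level 0.6 reads as a 40% drop, the miR-200a magnitude
        out = relative_protein_level(
            band_frame(
                [
                    ("HFE", "miR-200a", 60.0, 100.0),
                    ("HFE", "miR-scr", 100.0, 100.0),
                ]
            ),
            "miR-scr",
        )
        by_cond = {r.condition: r for r in out}
        assert by_cond["miR-200a"].percent_change == pytest.approx(40.0)

    def test_scale_invariance_per_lane(self):
        base = band_frame(
            [
                ("DLC1", "miR-200a", 50.0, 100.0),
                ("DLC1", "miR-scr", 80.0, 80.0),
            ]
        )
        scaled = band_frame(
            [
                ("DLC1", "miR-200a", 50.0 * 7.3, 100.0 * 7.3),
                ("DLC1", "miR-scr", 80.0 * 0.2, 80.0 * 0.2),
            ]
        )
        a = relative_protein_level(base, "miR-scr")
        b = relative_protein_level(scaled, "miR-scr")
        for ra, rb in zip(a, b):
            assert ra.relative_level == pytest.approx(rb.relative_level, rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(QuantError, match="positive"):
            relative_protein_level(
                band_frame([("DLC1", "miR-scr", 0.0, 80.0)]), "miR-scr"
            )

    def test_missing_reference_condition(self):
        with pytest.raises(QuantError, match="reference"):
            relative_protein_level(
                band_frame([("DLC1", "miR-200a", 50.0, 100.0)]), "miR-scr"
            )


def protein(percent_change, condition="miR-200c"):
    return ProteinLevelResult(
        protein="DLC1", condition=condition,
        relative_level=1 - percent_change / 100, percent_change=percent_change,
    )


def mrna(fold, p):
    return FoldChangeResult(
        gene="DLC1", condition="miR-200c", delta_ct_treated=0.0,
        delta_ct_control=0.0, delta_delta_ct=-math.log2(fold), fold=fold,
        p=p, n_replicates=3,
    )


class TestConfirmTarget:
    def test_protein_only_call_at_twenty_percent(self):
        # protein down 20%, mRNA not significant: still confirmed
        call = confirm_target(mrna(0.9, 0.4), protein(20.0))
        assert call.confirmed
        assert call.protein_down_meets_threshold
        assert not call.mrna_down_significant

    def test_no_change_not_confirmed(self):
        call = confirm_target(mrna(1.0, 0.9), protein(0.0))
        assert not call.confirmed

    def test_strict_fifteen_percent_boundary(self):
        assert not confirm_target(mrna(0.95, 0.2), protein(14.9)).confirmed
        assert confirm_target(None, protein(15.0)).confirmed

    def test_mrna_arm_requires_both_downregulation_and_significance(self):
        assert confirm_target(mrna(0.5, 0.01), None).confirmed
        assert not confirm_target(mrna(0.5, 0.2), None).confirmed
        assert not confirm_target(mrna(1.4, 0.01), None).confirmed  # up, not down

    def test_both_absent_is_an_error(self):
        with pytest.raises(QuantError):
            confirm_target(None, None)

    def test_monotone_in_evidence_strength(self):
        th = ConfirmationThresholds()
        confirmed_before = False
        for pct, p in [(5, 0.5), (10, 0.2), (16, 0.04), (30, 0.001)]:
            call = confirm_target(mrna(0.8, p), protein(float(pct)), th)
            assert call.confirmed or not confirmed_before
            confirmed_before = confirmed_before or call.confirmed


class TestGroupFoldChange:
    @staticmethod
    def _cohort(tumor_vals, normal_vals, scale="linear"):
        samples = [f"T{i}" for i in range(len(tumor_vals))] + [
            f"N{i}" for i in range(len(normal_vals))
        ]
        matrix = make_matrix([list(tumor_vals) + list(normal_vals)], ["miR-X"], samples,
                             scale=scale)
        meta = SampleMetadata(
            groups={s: ("tumor" if s.startswith("T") else "normal") for s in samples}
        )
        return matrix, meta

    def test_identical_groups(self):
        matrix, meta = self._cohort([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        fold, p = group_fold_change(matrix, meta, "miR-X")
        assert fold == pytest.approx(1.0)
        assert p > 0.9

    def test_hand_computed_fold_and_t(self):
        matrix, meta = self._cohort([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        fold, p = group_fold_change(matrix, meta, "miR-X", equal_var=True)
        assert fold == pytest.approx(2.5, abs=1e-12)
        # textbook pooled two-sample t: t = 3 / sqrt(2/3), df = 4
        t = 3.0 / math.sqrt(2.0 / 3.0)
        expected = 2 * stats.t.sf(t, df=4)
        assert p == pytest.approx(float(expected), rel=1e-9)

    def test_log2_matrix_back_transforms_for_fold(self):
        matrix, meta = self._cohort([3.0, 3.0, 3.0], [1.0, 1.0, 1.0], scale="log2")
        fold, _ = group_fold_change(matrix, meta, "miR-X")
        assert fold == pytest.approx(4.0)  # 2^3 / 2^1

    def test_small_group_rejected(self):
        matrix, meta = self._cohort([4.0, 5.0], [1.0])
        with pytest.raises(QuantError, match=">=2"):
            group_fold_change(matrix, meta, "miR-X")

    def test_invariant_under_within_group_reordering(self):
        rng = np.random.default_rng(3)
        tumor = list(rng.normal(5, 1, 8))
        normal = list(rng.normal(4, 1, 6))
        m1, meta = self._cohort(tumor, normal)
        m2, _ = self._cohort(tumor[::-1], normal[::-1])
        assert group_fold_change(m1, meta, "miR-X") == pytest.approx(
            group_fold_change(m2, meta, "miR-X")
        )
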