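"""Stouffer combination, homogeneity filtering, Venn classification and
cooperative-gene detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coopsyn import de_meta
from coopsyn.de_meta import (
    classify_genes,
    cooperative_genes,
    homogeneity,
    meta_analyze,
    signed_z,
    stouffer_combine,
)
from coopsyn.errors import ValidationError
from coopsyn.evaluation import classification_metrics, cooperative_recall

finite_z = st.floats(-8, 8, allow_nan=False)


class TestSignedZ:
    def test_inverse_normal_bridge(self):
        assert signed_z(1.0, 0.05) == pytest.approx(1.95996, abs=1e-5)
        assert signed_z(-1.0, 0.05) == pytest.approx(-1.95996, abs=1e-5)

    def test_p_of_one_maps_to_zero(self):
        assert signed_z(2.3, 1.0) == 0.0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValidationError):
            signed_z(1.0, p)

    def test_round_trips_the_de_test(self):
        """Rebuilding z from (log2fc sign, two-sided p) recovers the original statistic."""
        z = -2.7
        p = 2 * stats.norm.sf(abs(z))
        assert signed_z(-1.0, p) == pytest.approx(z, abs=1e-12)


class TestStouffer:
    def test_two_line_example(self):
        z_meta, _ = stouffer_combine([1.645, 1.645])
        assert z_meta == pytest.approx(2 * 1.645 / math.sqrt(2), abs=1e-12)

    def test_antisymmetric_pair_cancels(self):
        z_meta, p_meta = stouffer_combine([2.4, -2.4])
        assert z_meta == 0.0
        assert p_meta == 1.0

    def test_single_study_identity(self):
        assert stouffer_combine([2.0])[0] == pytest.approx(2.0, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            stouffer_combine([])

    @settings(derandomize=True, max_examples=100)
    @given(zs=st.lists(finite_z, min_size=1, max_size=6))
    def test_matches_closed_form_and_symmetries(self, zs):
        z_meta, p_meta = stouffer_combine(zs)
        assert z_meta == pytest.approx(sum(zs) / math.sqrt(len(zs)), abs=1e-12)
        assert stouffer_combine([-z for z in zs])[0] == pytest.approx(-z_meta, abs=1e-12)
        assert stouffer_combine(list(reversed(zs)))[0] == pytest.approx(z_meta, abs=1e-12)
        assert 0 < p_meta <= 1


class TestHomogeneity:
    @pytest.mark.parametrize(
        "signs,rule,frac,expected",
        [
            ((1, 1, 1, 1, 1, 1), "all", 0.5, True),
            ((1, 1, 1, -1, 1, 1), "all", 0.5, False),
            ((1, 1, 1, -1, 1, 1), "majority", 5 / 6, True),
            ((1, 1, -1, -1, 1, 1), "majority", 5 / 6, False),
            ((1, 0, 1, 0, 1, 1), "all", 0.5, True),  # zeros never break agreement
            ((0, 0, 0), "all", 0.5, True),
        ],
    )
    def test_agreement_rules(self, signs, rule, frac, expected):
        assert homogeneity(signs, rule=rule, min_agree_frac=frac) is expected

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            homogeneity([1, 1], rule="plurality")


def _records(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_line", "treatment", "log2fc", "p_value"])


def _meta_row(gene, treatment, p, homogeneous=True):
    return {
        "gene": gene, "treatment": treatment, "z_meta": 3.0, "p_meta": p,
        "direction": "up", "homogeneous": homogeneous, "n_lines": 6,
    }


class TestClassifyGenes:
    def _meta(self, p_by_treatment, homogeneous=True):
        rows = []
        for gene, ps in p_by_treatment.items():
            for treatment, p in zip(de_meta.TREATMENTS, ps):
                rows.append(_meta_row(gene, treatment, p, homogeneous))
        return pd.DataFrame(rows)

    def test_label_rules(self):
        meta = self._meta(
            {
                "g_common": (1e-9, 1e-9, 1e-9),
                "g_opc": (1e-9, 0.9, 0.9),
                "g_cur": (0.9, 1e-9, 0.9),
                "g_combo": (0.9, 0.9, 1e-9),
                "g_none": (0.9, 0.9, 0.9),
            }
        )
        labels = classify_genes(meta, adjust=None).set_index("gene")["label"]
        assert labels["g_common"] == "common"
        assert labels["g_opc"] == "opc_only"
        assert labels["g_cur"] == "curcumin_only"
        assert labels["g_combo"] == "combination_only"
        assert labels["g_none"] == "unclassified"

    def test_inhomogeneous_gene_not_regulated(self):
        meta = self._meta({"g": (1e-9, 1e-9, 1e-9)}, homogeneous=False)
        assert classify_genes(meta, adjust=None)["label"].iloc[0] == "unclassified"

    def test_mismatched_universes_rejected(self):
        meta = self._meta({"g": (0.5, 0.5, 0.5)})
        with pytest.raises(ValidationError):
            classify_genes(pd.concat([meta, pd.DataFrame([_meta_row("h", "OPC", 0.5)])]))

    def test_labels_partition_the_universe(self, gene_labels, de_records):
        assert gene_labels["gene"].is_unique
        assert set(gene_labels["gene"]) == set(de_records["gene"])
        assert gene_labels["label"].isin(de_meta.VENN_LABELS).all()

    def test_planted_class_recovery(self, gene_labels, de_truth):
        """Sensitivity >= 0.85 and FDR <= 0.10 for every Venn class on the
        default planted fixture."""
        metrics = classification_metrics(gene_labels, de_truth)
        regulated = metrics[metrics["label"] != "unclassified"]
        assert (regulated["sensitivity"] >= 0.85).all()
        assert (regulated["fdr"] <= 0.10).all()


class TestCooperativeGenes:
    def _toy(self, n_exceed):
        rows = []
        for i in range(6):
            line = f"L{i}"
            combo_fc = 3.0 if i < n_exceed else 0.5
            rows += [
                ("g", line, "OPC", 1.0, 0.5),
                ("g", line, "curcumin", 1.0, 0.5),
                ("g", line, "combination", combo_fc, 0.001),
            ]
        return _records(rows)

    def test_gene_exceeding_in_enough_lines_included(self):
        assert cooperative_genes(self._toy(4), min_lines=3) == ["g"]

    def test_gene_below_line_threshold_excluded(self):
        assert cooperative_genes(self._toy(2), min_lines=3) == []

    def test_min_lines_above_panel_size_rejected(self):
        with pytest.raises(ValidationError):
            cooperative_genes(self._toy(4), min_lines=7)

    def test_row_order_invariance(self, de_records):
        shuffled = de_records.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert cooperative_genes(shuffled) == cooperative_genes(de_records)

    def test_planted_cooperative_recall(self, cooperative_gene_list, de_truth):
        assert cooperative_recall(cooperative_gene_list, de_truth) >= 0.85


class TestMetaAnalyze:
    def test_null_calibration(self, null_experiment):
        """Under the null generator the p_meta < 0.05 rate stays in the 99%
        binomial interval around 0.05."""
        records, _ = null_experiment
        meta = meta_analyze(records)
        one = meta[meta["treatment"] == "OPC"]
        frac = (one["p_meta"] < 0.05).mean()
        half_width = 2.5758 * math.sqrt(0.05 * 0.95 / len(one))
        assert abs(frac - 0.05) < half_width

    def test_direction_consistent_with_z(self, meta_table):
        up = meta_table[meta_table["direction"] == "up"]
        down = meta_table[meta_table["direction"] == "down"]
        assert (up["z_meta"] > 0).all()
        assert (down["z_meta"] < 0).all()

    def test_precomputed_statistic_column_ingested(self):
        rec = _records([("g", "L1", t, 1.0, 0.5) for t in de_meta.TREATMENTS])
        rec["stat"] = 2.0
        meta = meta_analyze(rec, z_column="stat")
        assert np.allclose(meta["z_meta"], 2.0)
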