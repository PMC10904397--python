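"""Constraint record classification, Poisson o/e bounds, and table I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from constraintscope.constraint_core import (
    ConstraintLevel,
    GeneConstraintRecord,
    classify_constraint,
    classify_frame,
    classify_oe,
    oe_confidence_bounds,
    read_annotation_table,
    read_constraint_table,
    load_pcps_panel,
    write_classified_table,
)

C = ConstraintLevel


class TestClassification:
    @pytest.mark.parametrize(
        "loe, loelf, loeuf, expected",
        [
            # upper bound under 0.35: constrained regardless of the rest
            (0.20, 0.10, 0.318, C.CONSTRAINED),
            (0.15, 0.08, 0.232, C.CONSTRAINED),
            (0.21, 0.12, 0.325, C.CONSTRAINED),
            # point ratio under threshold but wide CI
            (0.30, 0.20, 0.40, C.LIKELY_CONSTRAINED),
            # lower bound above threshold: confidently unconstrained
            (0.60, 0.40, 0.90, C.NOT_CONSTRAINED),
            # straddling interval, point ratio above threshold
            (0.50, 0.20, 0.90, C.LIKELY_NOT_CONSTRAINED),
            # exact threshold goes to the less-constrained side
            (0.34, 0.20, 0.35, C.LIKELY_CONSTRAINED),
            (0.35, 0.35, 0.35, C.LIKELY_NOT_CONSTRAINED),
        ],
    )
    def test_level_assignment(self, loe, loelf, loeuf, expected):
        assert classify_oe(loe, loelf, loeuf) == expected

    def test_boundary_is_never_constrained(self):
        """A LOEUF of exactly 0.35 cannot be called constrained."""
        for loe in (0.1, 0.2, 0.349):
            assert classify_oe(loe, 0.05, 0.35) != C.CONSTRAINED

    def test_nan_yields_undefined_not_exception(self):
        assert classify_oe(float("nan"), 0.1, 0.5) == C.UNDEFINED
        rec = GeneConstraintRecord(gene_symbol="RMRP", lof_metrics_defined=False)
        assert classify_constraint(rec) == C.UNDEFINED

    def test_missense_classification_uses_same_threshold(self):
        rec = GeneConstraintRecord(
            gene_symbol="X", loe=0.9, loelf=0.7, loeuf=1.1,
            moe=0.2, moelf=0.1, moeuf=0.3,
        )
        assert classify_constraint(rec, kind="lof") == C.NOT_CONSTRAINED
        assert classify_constraint(rec, kind="mis") == C.CONSTRAINED

    @given(
        loelf=st.floats(0, 2, allow_nan=False),
        d1=st.floats(0, 1, allow_nan=False),
        d2=st.floats(0, 1, allow_nan=False),
        shrink=st.floats(0.0, 1.0),
        threshold=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_metrics(self, loelf, d1, d2, shrink, threshold):
        """Uniformly shrinking (loelf, loe, loeuf) never weakens the call."""
        loe, loeuf = loelf + d1, loelf + d1 + d2
        before = classify_oe(loe, loelf, loeuf, threshold)
        after = classify_oe(loe * shrink, loelf * shrink, loeuf * shrink, threshold)
        assert after.rank <= before.rank

    @given(
        loelf=st.floats(0, 2, allow_nan=False),
        d1=st.floats(0, 1, allow_nan=False),
        d2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_levels_exhaustive_and_exclusive(self, loelf, d1, d2):
        level = classify_oe(loelf + d1, loelf, loelf + d1 + d2)
        assert level in (C.CONSTRAINED, C.LIKELY_CONSTRAINED, C.LIKELY_NOT_CONSTRAINED, C.NOT_CONSTRAINED)

    def test_frame_classification_matches_scalar(self):
        rng = np.random.default_rng(5)
        lo = rng.uniform(0, 1, 200)
        oe = lo + rng.uniform(0, 0.5, 200)
        up = oe + rng.uniform(0, 0.5, 200)
        frame = pd.DataFrame({"loe": oe, "loelf": lo, "loeuf": up})
        vec = classify_frame(frame)
        for i in range(200):
            assert vec.iloc[i] == classify_oe(oe[i], lo[i], up[i])


class TestOEBounds:
    def test_zero_count_closed_form(self):
        lower, upper = oe_confidence_bounds(0, 10.0)
        assert lower == 0.0
        assert upper == pytest.approx(-math.log(0.05) / 10.0, rel=1e-12)

    def test_interval_straddles_point_ratio(self):
        lower, upper = oe_confidence_bounds(10, 10.0)
        assert lower < 1.0 < upper

    @given(obs=st.integers(0, 500), exp=st.floats(0.1, 100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bounds_bracket_ratio(self, obs, exp):
        lower, upper = oe_confidence_bounds(obs, exp)
        assert 0.0 <= lower <= obs / exp <= upper

    def test_invalid_expectation_raises(self):
        with pytest.raises(ValueError):
            oe_confidence_bounds(3, 0.0)
        with pytest.raises(ValueError):
            oe_confidence_bounds(3, -1.0)

    def test_simulated_coverage(self):
        """Realised 90% coverage at the worked-example scale (exp=100, depletion 0.5).

        Exact Poisson intervals are conservative; at an expected count of 50
        the exact coverage is 91.0%, within 1.5 points of nominal.
        """
        rng = np.random.default_rng(42)
        depletion, exp = 0.5, 100.0
        obs = rng.poisson(depletion * exp, size=10_000)
        lower, upper = oe_confidence_bounds(obs, np.full(obs.shape, exp))
        coverage = np.mean((lower <= depletion) & (depletion <= upper))
        assert abs(coverage - 0.90) < 0.015


class TestTableIO:
    def _write(self, tmp_path, text, name="metrics.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_round_trip(self, tmp_path):
        src = self._write(
            tmp_path,
            "gene_symbol\ttranscript_id\tcanonical\tcds_length\tobs_lof\texp_lof\tloe\tloelf\tloeuf\n"
            "A\tT1.1\ttrue\t1000\t5\t10.0\t0.5\t0.2\t0.9\n"
            "B\tT2.1\ttrue\t2000\t0\t20.0\t0.0\t0.0\t0.15\n"
            "C\tT3.1\ttrue\t500\t7\t7.0\t1.0\t0.5\t1.8\n",
        )
        table = read_constraint_table(src)
        assert len(table) == 3
        out = tmp_path / "classified.tsv"
        written = write_classified_table(table, out)
        back = pd.read_csv(out, sep="\t")
        assert list(back["gene_symbol"]) == ["A", "B", "C"]
        assert list(written["constraint_level"]) == ["likely_not_constrained", "constrained", "not_constrained"]
        pd.testing.assert_frame_equal(
            table[["obs_lof", "exp_lof", "loe"]], back[["obs_lof", "exp_lof", "loe"]]
        )

    def test_non_canonical_rows_dropped(self, tmp_path):
        src = self._write(
            tmp_path,
            "gene_symbol\tcanonical\tcds_length\tobs_lof\texp_lof\n"
            "A\ttrue\t1000\t5\t10.0\n"
            "A\tfalse\t900\t4\t9.0\n",
        )
        table = read_constraint_table(src)
        assert len(table) == 1
        assert table.loc[0, "obs_lof"] == 5

    def test_ratio_recomputed_when_absent(self, tmp_path):
        src = self._write(
            tmp_path,
            "gene_symbol\tcds_length\tobs_lof\texp_lof\nA\t1000\t5\t10.0\n",
        )
        table = read_constraint_table(src)
        assert table.loc[0, "loe"] == pytest.approx(0.5)
        lo, up = oe_confidence_bounds(5, 10.0)
        assert table.loc[0, "loelf"] == pytest.approx(lo)
        assert table.loc[0, "loeuf"] == pytest.approx(up)

    def test_missing_columns_named_in_error(self, tmp_path):
        src = self._write(tmp_path, "gene_symbol,cds_length\nA,1000\n", name="bad.csv")
        with pytest.raises(ValueError, match="obs_lof"):
            read_constraint_table(src)

    def test_unparseable_cell_leaves_metrics_undefined(self, tmp_path):
        src = self._write(
            tmp_path,
            "gene_symbol\tcds_length\tobs_lof\texp_lof\tloe\tloelf\tloeuf\n"
            "A\t1000\t5\t10.0\toops\t0.2\t0.9\n",
        )
        table = read_constraint_table(src)
        assert not table.loc[0, "lof_metrics_defined"]
        assert classify_frame(table).iloc[0] == C.UNDEFINED

    def test_gnomad_dialect_column_mapping(self, tmp_path):
        src = self._write(
            tmp_path,
            "gene\ttranscript\tcanonical\tcds_length\tobs_lof\texp_lof\toe_lof\toe_lof_lower\toe_lof_upper\n"
            "TP53\tENST0001.1\tTRUE\t1182\t3\t30.0\t0.1\t0.04\t0.25\n",
        )
        table = read_constraint_table(src, dialect="gnomad")
        assert table.loc[0, "gene_symbol"] == "TP53"
        assert table.loc[0, "loeuf"] == pytest.approx(0.25)


class TestAnnotations:
    def test_packaged_panel_partition(self, pcps_panel):
        """The packaged 85-gene panel respects the published MOI partition."""
        counts = pcps_panel["moi"].value_counts()
        assert counts["AD"] == 59 and counts["AR"] == 23 and counts["XLR"] == 3
        gof = pcps_panel[(pcps_panel["moi"] == "AD") & (pcps_panel["mechanism"] == "GoF")]
        assert len(gof) == 9
        assert pcps_panel["cancer_only"].sum() == 17

    def test_invalid_moi_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text(
            "gene,category,moi,mechanism,cancer_only,penetrance_class,de_novo_class\n"
            "A,pCPS_cat1,XX,LoF,True,high,low\n"
        )
        with pytest.raises(ValueError, match="moi"):
            read_annotation_table(path)
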