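"""Stress-tolerance indices: scalar formulas, yield summaries, ranking,
selection and report rounding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metstress import (
    build_yield_summary, compute_index_table, gmp, mp, msti,
    rank_and_select, sti, ssi, tol, top_k_summary,
)
from metstress.stress_indices import IndexTable, YieldSummary, \
    render_index_report
from metstress.exceptions import (
    NoStressError, UndefinedRatioError, ValidationError,
)

from conftest import two_env_dataset


class TestScalarFormulas:
    def test_sti_hand_values(self):
        assert sti(123.0, 123.0, 123.0) == pytest.approx(1.0)
        assert sti(1000.0, 500.0, 1000.0) == pytest.approx(0.5)
        assert sti(0.0, 400.0, 800.0) == 0.0
        with pytest.raises(UndefinedRatioError):
            sti(10.0, 5.0, 0.0)

    def test_ssi_hand_values(self):
        assert ssi(700.0, 700.0, 1000.0, 800.0) == pytest.approx(0.0)
        assert ssi(1000.0, 800.0, 1000.0, 800.0) == pytest.approx(1.0)
        # population values at the published Banda scale
        assert ssi(1000.0, 600.0, 790.0, 634.0) == pytest.approx(
            0.4 / (1 - 634 / 790), rel=1e-12
        )
        assert ssi(1000.0, 600.0, 790.0, 634.0) == pytest.approx(2.026,
                                                                 abs=5e-4)
        with pytest.raises(NoStressError):
            ssi(1000.0, 900.0, 800.0, 800.0)
        with pytest.raises(UndefinedRatioError):
            ssi(0.0, 0.0, 800.0, 700.0)

    def test_mp_tol_identity(self):
        assert mp(42.0, 42.0) == 42.0
        assert mp(1000.0, 500.0) == 750.0
        assert tol(42.0, 42.0) == 0.0
        assert tol(1000.0, 500.0) == 500.0
        assert tol(500.0, 1000.0) == -500.0  # stress gain keeps its sign
        assert mp(813.0, 222.0) - tol(813.0, 222.0) / 2 == pytest.approx(
            222.0
        )

    def test_msti_hand_values(self):
        assert msti(900.0, 500.0, 1100.0, 500.0) == pytest.approx(
            sti(900.0, 500.0, 1100.0)
        )
        assert msti(1000.0, 500.0, 1000.0, 500.0) == pytest.approx(0.5)
        assert msti(1000.0, 1000.0, 1000.0, 500.0) == pytest.approx(4.0)
        with pytest.raises(UndefinedRatioError):
            msti(1000.0, 500.0, 1000.0, 0.0)

    def test_gmp_hand_values_and_am_gm(self):
        assert gmp(7.0, 7.0) == pytest.approx(7.0)
        assert gmp(100.0, 400.0) == pytest.approx(200.0)

    @given(yp=st.floats(0.0, 1e4), ys=st.floats(0.0, 1e4))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_gmp_never_exceeds_mp(self, yp, ys):
        assert gmp(yp, ys) <= mp(yp, ys) + 1e-9

    @given(yp=st.floats(1.0, 1e4), ys=st.floats(1.0, 1e4),
           yp_bar=st.floats(1.0, 1e4), ys_bar=st.floats(1.0, 1e4),
           c=st.floats(0.01, 100.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_scale_invariance(self, yp, ys, yp_bar, ys_bar, c):
        if 1 - ys_bar / yp_bar <= 1e-6:
            ys_bar = 0.5 * yp_bar
        assert sti(c * yp, c * ys, c * yp_bar) == pytest.approx(
            sti(yp, ys, yp_bar), rel=1e-9
        )
        assert ssi(c * yp, c * ys, c * yp_bar, c * ys_bar) == pytest.approx(
            ssi(yp, ys, yp_bar, ys_bar), rel=1e-9
        )
        assert msti(c * yp, c * ys, c * yp_bar, c * ys_bar) == pytest.approx(
            msti(yp, ys, yp_bar, ys_bar), rel=1e-9
        )
        assert mp(c * yp, c * ys) == pytest.approx(c * mp(yp, ys), rel=1e-9)
        assert tol(c * yp, c * ys) == pytest.approx(c * tol(yp, ys),
                                                    rel=1e-9)
        assert gmp(c * yp, c * ys) == pytest.approx(c * gmp(yp, ys),
                                                    rel=1e-9)


class TestYieldSummary:
    def test_two_genotype_hand_example(self):
        ds = two_env_dataset({
            "OE": {"A": [800.0], "B": [1200.0]},
            "HSE": {"A": [400.0], "B": [600.0]},
        })
        summary = build_yield_summary(ds, "L1", "HSE")
        assert summary.yp_bar == pytest.approx(1000.0)
        assert summary.ys_bar == pytest.approx(500.0)
        assert summary.si == pytest.approx(0.5)

    def test_no_stress_contrast_rejected(self):
        ds = two_env_dataset({
            "OE": {"A": [800.0], "B": [1200.0]},
            "HSE": {"A": [800.0], "B": [1200.0]},
        })
        with pytest.raises(NoStressError):
            build_yield_summary(ds, "L1", "HSE")

    def test_genotype_missing_one_arm_excluded_with_warning(self):
        ds = two_env_dataset({
            "OE": {"A": [800.0], "B": [1200.0], "C": [np.nan]},
            "HSE": {"A": [400.0], "B": [600.0], "C": [500.0]},
        })
        with pytest.warns(UserWarning, match="1 genotype"):
            summary = build_yield_summary(ds, "L1", "HSE")
        assert set(summary.yields["genotype"]) == {"A", "B"}

    def test_simulated_si_tracks_configured_multiplier(self):
        # HSE multiplier 0.80 -> expected stress intensity 0.20
        from metstress import simulate_met
        si = []
        for seed in range(10):
            ds, _ = simulate_met(seed=seed)
            si.append(build_yield_summary(ds, "Banda", "HSE").si)
        si = np.asarray(si)
        mc_sd = si.std(ddof=1)
        assert abs(si.mean() - 0.20) < 3 * mc_sd


def reference_table(summary: YieldSummary) -> pd.DataFrame:
    """Independent scalar-formula recomputation, one genotype at a time."""
    rows = []
    for _, rec in summary.yields.iterrows():
        yp, ys = float(rec["Yp"]), float(rec["Ys"])
        rows.append({
            "genotype": rec["genotype"],
            "STI": sti(yp, ys, summary.yp_bar),
            "SSI": ssi(yp, ys, summary.yp_bar, summary.ys_bar),
            "MP": mp(yp, ys),
            "TOL": tol(yp, ys),
            "MSTI": msti(yp, ys, summary.yp_bar, summary.ys_bar),
            "GMP": gmp(yp, ys),
        })
    return pd.DataFrame(rows)


class TestIndexTable:
    def test_oracle_equivalence(self, study_dataset):
        summary = build_yield_summary(study_dataset, "Banda", "HDSE")
        table = compute_index_table(summary).records
        oracle = reference_table(summary)
        for col in ("STI", "SSI", "MP", "TOL", "MSTI", "GMP"):
            np.testing.assert_allclose(table[col], oracle[col], rtol=1e-12)

    def test_internal_identities_hold_exactly(self, study_dataset):
        summary = build_yield_summary(study_dataset, "Jhansi", "HSE")
        recs = compute_index_table(summary).records
        assert (recs["TOL"] == recs["Yp"] - recs["Ys"]).all()
        assert (recs["MP"] == (recs["Yp"] + recs["Ys"]) / 2).all()
        np.testing.assert_allclose(recs["GMP"] ** 2,
                                   recs["Yp"] * recs["Ys"], rtol=1e-9)

    def test_zero_yp_gives_missing_ssi_only(self):
        summary = YieldSummary(
            location="L1", stress_env="HSE",
            yields=pd.DataFrame({"genotype": ["A", "B"],
                                 "Yp": [0.0, 1000.0],
                                 "Ys": [100.0, 600.0]}),
            yp_bar=500.0, ys_bar=350.0,
        )
        recs = compute_index_table(summary).records.set_index("genotype")
        assert np.isnan(recs.loc["A", "SSI"])
        assert recs.loc["A", "STI"] == pytest.approx(0.0)
        assert recs.loc["A", "MP"] == pytest.approx(50.0)

    def test_scaling_yields_scales_dimensional_indices_only(self):
        base = YieldSummary(
            location="L1", stress_env="HSE",
            yields=pd.DataFrame({"genotype": ["A", "B"],
                                 "Yp": [900.0, 1100.0],
                                 "Ys": [500.0, 700.0]}),
            yp_bar=1000.0, ys_bar=600.0,
        )
        doubled = YieldSummary(
            location="L1", stress_env="HSE",
            yields=base.yields.assign(Yp=base.yields.Yp * 2,
                                      Ys=base.yields.Ys * 2),
            yp_bar=2000.0, ys_bar=1200.0,
        )
        a = compute_index_table(base).records
        b = compute_index_table(doubled).records
        for col in ("STI", "SSI", "MSTI"):
            np.testing.assert_allclose(b[col], a[col], rtol=1e-12)
        for col in ("MP", "TOL", "GMP"):
            np.testing.assert_allclose(b[col], 2 * a[col], rtol=1e-12)


def table_from_sti(sti_by_genotype: dict[str, float]) -> IndexTable:
    n = len(sti_by_genotype)
    recs = pd.DataFrame({
        "genotype": list(sti_by_genotype),
        "Yp": [1000.0] * n,
        "Ys": [500.0] * n,
        "STI": list(sti_by_genotype.values()),
        "SSI": [1.0] * n,
        "MP": [750.0] * n, "TOL": [500.0] * n,
        "MSTI": [1.0] * n, "GMP": [707.1] * n,
    })
    summary = YieldSummary("L1", "HSE", recs[["genotype", "Yp", "Ys"]],
                           1000.0, 500.0)
    return IndexTable(summary=summary, records=recs)


class TestRankAndSelect:
    def test_published_sti_ordering(self):
        # the five highest printed heat-stress STI values, plus lower rest
        table = table_from_sti({
            "Local-17": 2.16, "PDW 274": 1.88, "HI-8802": 1.83,
            "HI-8713": 1.54, "Local-5": 1.32, "DBW 187": 1.10,
            "Raj 4120": 0.90, "PDW 233": 0.40,
        })
        out = rank_and_select(table, k=5)
        top = out.records[out.records["tolerant"]].sort_values("rank")
        assert list(top["genotype"]) == ["Local-17", "PDW 274", "HI-8802",
                                         "HI-8713", "Local-5"]

    def test_all_equal_sti_falls_back_to_tie_break_chain(self):
        table = table_from_sti({"B": 1.0, "A": 1.0, "C": 1.0})
        table.records.loc[table.records["genotype"] == "C", "Ys"] = 600.0
        out = rank_and_select(table, k=1)
        top = out.records[out.records["tolerant"]]
        assert list(top["genotype"]) == ["C"]  # higher Ys wins
        # drop the Ys edge: lexicographic genotype id decides
        table2 = table_from_sti({"B": 1.0, "A": 1.0, "C": 1.0})
        out2 = rank_and_select(table2, k=1)
        assert list(out2.records[out2.records["tolerant"]]["genotype"]) \
            == ["A"]

    def test_k_equals_n_labels_everything(self):
        table = table_from_sti({"A": 1.0, "B": 2.0, "C": 3.0})
        out = rank_and_select(table, k=3)
        assert out.records["tolerant"].all()

    def test_invalid_k_rejected(self):
        table = table_from_sti({"A": 1.0, "B": 2.0})
        with pytest.raises(ValidationError):
            rank_and_select(table, k=0)
        with pytest.raises(ValidationError):
            rank_and_select(table, k=3)

    def test_ranks_are_a_permutation(self, study_dataset):
        summary = build_yield_summary(study_dataset, "Banda", "HSE")
        out = rank_and_select(compute_index_table(summary), k=5)
        assert sorted(out.records["rank"]) == list(range(1, 35))

    def test_sti_and_gmp_order_agree(self, study_dataset):
        # STI is a monotone transform of Yp*Ys = GMP^2
        summary = build_yield_summary(study_dataset, "Banda", "HSE")
        recs = compute_index_table(summary).records
        assert (recs["STI"].rank(method="first")
                == recs["GMP"].rank(method="first")).all()


class TestTopKSummary:
    def test_published_mean_row_arithmetic(self):
        frame = pd.DataFrame({
            "STI": [2.16, 1.88, 1.83, 1.54, 1.32],
            "MSTI": [6.5, 5.2, 5.2, 3.6, 2.7],
        })
        out = top_k_summary(frame)
        assert out["STI"] == pytest.approx(1.75)
        assert out["MSTI"] == pytest.approx(4.6)

    def test_k_equals_one_returns_the_record(self):
        frame = pd.DataFrame({"STI": [2.16, 1.88], "MP": [1801.0, 1665.0]})
        out = top_k_summary(frame, k=1)
        assert out["STI"] == pytest.approx(2.16)
        assert out["MP"] == pytest.approx(1801.0)

    def test_report_appends_mean_row(self, study_dataset):
        summary = build_yield_summary(study_dataset, "Banda", "HSE")
        out = rank_and_select(compute_index_table(summary), k=5)
        report = render_index_report(out)
        assert len(report) == 6
        assert report.iloc[-1]["Cultivar"] == "Mean"
        assert report.iloc[-1]["STI"] == pytest.approx(
            top_k_summary(out)["STI"]
        )
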