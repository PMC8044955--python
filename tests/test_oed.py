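"""Orthogonal-design construction, balance checking, and effect analysis."""

import numpy as np
import pandas as pd
import pytest

from fogcast.oed import (
    DesignTable,
    FactorSpec,
    ResponseTable,
    build_l16_4_3,
    default_factors,
    effects_analysis,
    full_factorial,
    select_best,
    verify_orthogonality,
)

# Golden 16-run array for the studied level sets (window, step, preFOG duration).
GOLDEN_L16 = [
    ("T01", 128, 5, 150), ("T02", 128, 10, 250), ("T03", 128, 20, 500),
    ("T04", 128, 30, 600), ("T05", 256, 5, 250), ("T06", 256, 10, 150),
    ("T07", 256, 20, 600), ("T08", 256, 30, 500), ("T09", 400, 5, 500),
    ("T10", 400, 10, 600), ("T11", 400, 20, 150), ("T12", 400, 30, 250),
    ("T13", 500, 5, 600), ("T14", 500, 10, 500), ("T15", 500, 20, 250),
    ("T16", 500, 30, 150),
]


class TestDesignConstruction:
    def test_matches_golden_array_row_for_row(self):
        d = build_l16_4_3(default_factors())
        got = list(d.runs.itertuples(index=False, name=None))
        assert got == GOLDEN_L16
        assert len(d) == 16

    def test_t15_is_500_20_250(self):
        d = build_l16_4_3(default_factors())
        row = d.runs.set_index("run_id").loc["T15"]
        assert tuple(row) == (500, 20, 250)

    def test_wrong_factor_count_rejected(self):
        with pytest.raises(ValueError):
            build_l16_4_3(default_factors()[:2])

    def test_level_validation(self):
        with pytest.raises(ValueError):
            FactorSpec("step", (5, 5, 10, 20))
        with pytest.raises(ValueError):
            FactorSpec("step", (30, 20, 10, 5))

    def test_full_factorial_sizes(self):
        assert len(full_factorial(default_factors())) == 64
        assert len(full_factorial([FactorSpec("step", (5, 10, 20, 30))])) == 4


class TestOrthogonality:
    def test_l16_balance(self):
        d = build_l16_4_3(default_factors())
        report = verify_orthogonality(d)
        assert report.passed
        assert all(report.level_balance.values())
        assert all(f == 1 for f in report.pair_frequency.values())

    def test_full_factorial_uniform_pairs(self):
        report = verify_orthogonality(full_factorial(default_factors()))
        assert report.passed
        assert all(f == 4 for f in report.pair_frequency.values())

    def test_single_cell_perturbation_detected(self):
        d = build_l16_4_3(default_factors())
        runs = d.runs.copy()
        runs.loc[4, "step"] = 30  # T05 step 5 -> 30
        report = verify_orthogonality(DesignTable(runs, "perturbed"))
        assert not report.passed
        offending = [p for p, ok in report.pair_balance.items() if not ok]
        assert all("step" in p for p in offending)
        assert offending  # the step pairings break


def _response_for(d: DesignTable, y: np.ndarray) -> ResponseTable:
    rows = d.runs.copy()
    rows["replicate"] = 0
    rows["f1"] = y
    rows["kappa"] = y
    return ResponseTable(rows)


def planted_table_response(d, rng=None, sigma=0.0):
    """Additive per-level effects with optimum at (256, 10, 150)."""
    w_eff = {128: 0.00, 256: 0.08, 400: 0.03, 500: 0.05}
    s_eff = {5: 0.01, 10: 0.04, 20: 0.00, 30: 0.02}
    p_eff = {150: 0.06, 250: 0.02, 500: 0.04, 600: 0.00}
    y = np.array(
        [
            0.5 + w_eff[w] + s_eff[s] + p_eff[p]
            for w, s, p in d.runs[["window_size", "step", "prefog_duration"]]
            .itertuples(index=False, name=None)
        ]
    )
    if rng is not None and sigma > 0:
        y = y + rng.standard_normal(len(y)) * sigma
    return y


class TestEffectsAnalysis:
    def test_constant_response_gives_logworth_zero(self):
        d = build_l16_4_3(default_factors())
        r = _response_for(d, np.full(16, 0.7))
        e = effects_analysis(d, r, "f1", interactions=["window_size:prefog_duration"])
        assert np.all(e.terms["p_value"] == 1.0)
        assert np.all(e.terms["logworth"] == 0.0)

    def test_logworth_is_neg_log10_p(self):
        d = build_l16_4_3(default_factors())
        rng = np.random.default_rng(0)
        y = planted_table_response(d, rng, sigma=0.01)
        e = effects_analysis(d, _response_for(d, y), "f1")
        np.testing.assert_allclose(
            e.terms["logworth"], -np.log10(e.terms["p_value"]), rtol=1e-12
        )
        # monotone: smaller p <=> larger logworth
        order_p = e.terms.sort_values("p_value")["term"].tolist()
        order_lw = e.terms.sort_values("logworth", ascending=False)["term"].tolist()
        assert order_p == order_lw

    def test_level_means_match_direct_average(self):
        d = build_l16_4_3(default_factors())
        y = planted_table_response(d)
        e = effects_analysis(d, _response_for(d, y))
        for f in ("window_size", "step", "prefog_duration"):
            rows = d.runs.copy()
            rows["y"] = y
            want = rows.groupby(f)["y"].mean()
            pd.testing.assert_series_equal(
                e.level_means[f], want, check_names=False
            )

    def test_noiseless_additive_full_factorial_recovered_exactly(self):
        d = full_factorial(default_factors())
        y = planted_table_response(d)
        e = effects_analysis(d, _response_for(d, y))
        # each factor's level-mean spread equals the planted effect spread
        w_means = e.level_means["window_size"]
        assert w_means.loc[256] - w_means.loc[128] == pytest.approx(0.08, abs=1e-9)
        p_means = e.level_means["prefog_duration"]
        assert p_means.loc[150] - p_means.loc[600] == pytest.approx(0.06, abs=1e-9)

    def test_three_factor_interaction_rejected(self):
        d = build_l16_4_3(default_factors())
        r = _response_for(d, np.linspace(0, 1, 16))
        with pytest.raises(ValueError, match="higher-order"):
            effects_analysis(d, r, interactions=["window_size:step:prefog_duration"])

    def test_interaction_term_reported(self):
        d = build_l16_4_3(default_factors())
        rng = np.random.default_rng(1)
        y = planted_table_response(d, rng, sigma=0.01)
        e = effects_analysis(d, _response_for(d, y),
                             interactions=["window_size:prefog_duration"])
        assert "window_size*prefog_duration" in set(e.terms["term"])

    def test_missing_runs_excluded_with_warning(self, caplog):
        d = build_l16_4_3(default_factors())
        y = planted_table_response(d).astype(float)
        y[3] = np.nan
        with caplog.at_level("WARNING"):
            e = effects_analysis(d, _response_for(d, y))
        assert "excluded" in caplog.text
        assert len(e.level_means["step"]) == 4

    def test_categorical_coding_with_replicates(self):
        d = build_l16_4_3(default_factors())
        rng = np.random.default_rng(3)
        rows = []
        for rep in range(3):
            r = d.runs.copy()
            r["replicate"] = rep
            r["f1"] = planted_table_response(d, rng, sigma=0.01)
            r["kappa"] = r["f1"]
            rows.append(r)
        resp = ResponseTable(pd.concat(rows, ignore_index=True))
        e = effects_analysis(d, resp, coding="auto")
        assert e.coding == "categorical"
        terms = set(e.terms["term"])
        assert {"window_size", "step", "prefog_duration"} <= terms


@pytest.fixture(scope="module")
def tiny_cohort():
    from fogcast.synth import GaitSimParams, simulate_cohort

    return simulate_cohort(
        GaitSimParams(prefog_drift=0.6, seed=31), 2, 16.0, [(8.0, 3.0)]
    )


@pytest.fixture(scope="module")
def tiny_design():
    return DesignTable(
        pd.DataFrame(
            {
                "run_id": ["A", "B"],
                "window_size": [100, 128],
                "step": [50, 64],
                "prefog_duration": [200, 300],
            }
        ),
        "tiny",
    )


class TestRunDesign:
    def test_one_row_per_run(self, tiny_design, tiny_cohort):
        from fogcast.model import RFParams
        from fogcast.oed import run_design

        resp = run_design(tiny_design, tiny_cohort, RFParams(n_estimators=20, seed=0))
        assert len(resp.rows) == 2
        assert resp.rows["f1"].notna().all()

    def test_replicate_seeds_give_one_row_each(self, tiny_design, tiny_cohort):
        from fogcast.model import RFParams
        from fogcast.oed import run_design

        resp = run_design(
            tiny_design, tiny_cohort, RFParams(n_estimators=20, seed=0),
            seeds=[1, 2],
        )
        assert len(resp.rows) == 4
        assert (resp.rows["run_id"].value_counts() == 2).all()

    def test_single_patient_rejected(self, tiny_design, tiny_cohort):
        from fogcast.model import RFParams
        from fogcast.oed import run_design

        with pytest.raises(ValueError):
            run_design(tiny_design, tiny_cohort[:1], RFParams())


class TestSelectBest:
    def test_recovers_planted_optimum(self):
        d = build_l16_4_3(default_factors())
        e = effects_analysis(d, _response_for(d, planted_table_response(d)))
        best = select_best(e)
        assert best.as_tuple() == (256, 10, 150)

    def test_flat_response_tie_break(self):
        d = build_l16_4_3(default_factors())
        e = effects_analysis(d, _response_for(d, np.full(16, 0.5)))
        best = select_best(e)
        assert best.as_tuple() == (128, 30, 150)

    def test_peak_at_paper_tuple_returns_it(self):
        d = build_l16_4_3(default_factors())
        w_eff = {128: 0.0, 256: 0.02, 400: 0.05, 500: 0.09}
        s_eff = {5: 0.0, 10: 0.01, 20: 0.04, 30: 0.02}
        p_eff = {150: 0.03, 250: 0.07, 500: 0.02, 600: 0.0}
        y = np.array(
            [
                w_eff[w] + s_eff[s] + p_eff[p]
                for w, s, p in d.runs[
                    ["window_size", "step", "prefog_duration"]
                ].itertuples(index=False, name=None)
            ]
        )
        best = select_best(effects_analysis(d, _response_for(d, y)))
        assert best.as_tuple() == (500, 20, 250)

    def test_missing_level_means_rejected(self):
        d = build_l16_4_3(default_factors())
        e = effects_analysis(d, _response_for(d, planted_table_response(d)))
        e.level_means["step"] = e.level_means["step"].iloc[:2]
        with pytest.raises(ValueError, match="step"):
            select_best(e)
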