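"""Cell cycle indicator, regression links, AIC selection, Hill and growth
fits, and the end-to-end proliferation prediction chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eposignal.network import Perturbation
from eposignal.phenotype import (
    CellCycleMeasurement,
    ProliferationPipeline,
    cell_cycle_indicator,
    fit_doubling_time,
    fit_hill,
    fit_signaling_to_cci,
    predict_proliferation,
    select_proliferation_model,
)


class TestCellCycleIndicator:
    @pytest.mark.parametrize("triple, expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((2.0, 0.5, 0.25), 16.0),
        ((13 / 4, 0.5, 0.5), 13.0),
    ])
    def test_worked_examples(self, triple, expected):
        assert cell_cycle_indicator(triple) == pytest.approx(expected)

    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10),
           st.floats(0.1, 10))
    def test_multiplicative_in_activator(self, d2, g2, p27, a):
        base = cell_cycle_indicator((d2, g2, p27))
        scaled = cell_cycle_indicator((a * d2, g2, p27))
        assert scaled == pytest.approx(a * base, rel=1e-9)

    def test_non_positive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            CellCycleMeasurement(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            cell_cycle_indicator((1.0, -2.0, 1.0))


def _stage1_frame(rng=None, b=(0.002, 0.004), n_per_ct=8):
    """Synthetic stage-1 design with a known log-linear rule."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for ct in ("A", "B"):
        I_akt = rng.uniform(100, 2000, n_per_ct)
        I_erk = rng.uniform(100, 2000, n_per_ct)
        log_cci = 0.1 + b[0] * I_akt + b[1] * I_erk
        rows.append(pd.DataFrame(dict(context=ct, I_pAKT=I_akt,
                                      I_ppERK=I_erk, cci=np.exp(log_cci))))
    return pd.concat(rows, ignore_index=True)


class TestStage1Link:
    def test_noiseless_recovery(self):
        df = _stage1_frame()
        links = fit_signaling_to_cci(df)
        for lm in links.values():
            assert lm.r_squared == pytest.approx(1.0, abs=1e-9)
            assert lm.coefficients["I_pAKT"] == pytest.approx(0.002, rel=1e-6)
            assert lm.coefficients["I_ppERK"] == pytest.approx(0.004, rel=1e-6)

    def test_permuted_response_has_no_signal(self):
        rng = np.random.default_rng(42)
        df = _stage1_frame(rng, n_per_ct=12)
        df = df[df["context"] == "A"].copy()
        df["cci"] = rng.permutation(df["cci"].to_numpy())
        lm = fit_signaling_to_cci(df)["A"]
        assert lm.r_squared < 0.2

    def test_positive_slopes_on_generator_truth(self, truth):
        """Inhibitor-dose design from the kinetic truth: both integrated
        responses link positively to the cell cycle indicator."""
        from eposignal.synth import DesignSpec, generate_cci_dataset
        design = DesignSpec()
        cci = generate_cci_dataset(truth, design, seed=5)
        rows = []
        for r in cci.itertuples():
            from eposignal.calibration import parse_perturbation_id
            ints = truth.integrals(r.context, r.epo_Uml,
                                   parse_perturbation_id(r.perturbation_id))
            rows.append(dict(context=r.context,
                             cci=cell_cycle_indicator(
                                 (r.fc_ccnd2, r.fc_ccng2, r.fc_cdkn1b)),
                             **ints))
        links = fit_signaling_to_cci(pd.DataFrame(rows))
        for ct, lm in links.items():
            assert lm.coefficients["I_pAKT"] > 0, ct
            assert lm.coefficients["I_ppERK"] > 0, ct

    def test_too_few_conditions_rejected(self):
        df = _stage1_frame(n_per_ct=2)
        with pytest.raises(ValueError, match=">= 3"):
            fit_signaling_to_cci(df)


from tests_toys import selection_replicates as _selection_replicates


class TestProliferationModelSelection:
    def test_ps6_generating_model_recovered(self):
        assert _selection_replicates("pS6-only") >= 0.9

    def test_cci_generating_model_recovered(self):
        assert _selection_replicates("CCI-only") >= 0.9

    def test_identical_candidates_tie_break_deterministic(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(dict(I_pS6=rng.uniform(1, 10, 8),
                               cci=rng.uniform(1, 10, 8)))
        df["proliferation"] = 0.1 * df["I_pS6"] + rng.normal(0, 0.1, 8)
        cands = {"dup-b": ["I_pS6"], "dup-a": ["I_pS6"]}
        best, table = select_proliferation_model(df, candidates=cands)
        aics = table["aic"].to_numpy()
        assert aics[0] == pytest.approx(aics[1])
        # equal AIC and parameter count: alphabetical candidate wins
        best2, _ = select_proliferation_model(df, candidates=cands)
        assert best.predictors == best2.predictors

    def test_underdetermined_candidate_excluded(self):
        df = pd.DataFrame(dict(I_pS6=[1.0, 2.0, 3.0], cci=[1.0, 2.0, 1.5],
                               proliferation=[0.1, 0.2, 0.3]))
        best, table = select_proliferation_model(df)
        excluded = table[table["excluded"] != ""]
        assert "pS6+CCI" in excluded["candidate"].tolist()


class TestHillFit:
    def test_noiseless_round_trip(self):
        x = np.array([0.0, 0.05, 0.1, 0.26, 0.5, 1.0, 5.0, 50.0])
        true = dict(y0=0.0, a=1.0, b=2.0, c=0.26)
        y = true["a"] * x**2 / (0.26**2 + x**2)
        fit = fit_hill(x, y)
        assert fit.c == pytest.approx(0.26, abs=1e-6)
        assert not fit.degenerate

    def test_flat_response_degenerate(self):
        x = np.linspace(0, 10, 8)
        fit = fit_hill(x, np.full(8, 3.0))
        assert fit.degenerate
        assert fit.a == pytest.approx(0.0, abs=1e-9)

    def test_half_max_identity_on_fitted_curve(self):
        x = np.array([0.0, 0.05, 0.2, 0.5, 1.0, 2.0, 10.0, 40.0])
        y = 0.2 + 0.8 * x / (0.5 + x)
        fit = fit_hill(x, y)
        assert fit.predict(fit.c) == pytest.approx(fit.y0 + fit.a / 2,
                                                   rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(np.array([0, 1, 2, 3.0]), np.array([0, 1, 2, 3.0]))


class TestDoublingTime:
    def test_exact_exponential_growth(self):
        t = np.array([0.0, 6.0, 13.1, 20.0, 26.2])
        counts = 1e5 * 2 ** (t / 13.1)
        fit = fit_doubling_time(t, counts)
        assert fit.doubling_time_h == pytest.approx(13.1, rel=1e-9)

    def test_constant_counts_no_growth(self):
        fit = fit_doubling_time(np.array([0.0, 10.0, 20.0]),
                                np.array([5.0, 5.0, 5.0]))
        assert np.isinf(fit.doubling_time_h) and fit.no_growth

    def test_halving_counts_flagged_negative(self):
        t = np.array([0.0, 10.0, 20.0])
        fit = fit_doubling_time(t, 100.0 * 0.5 ** (t / 10))
        assert fit.negative_growth and np.isinf(fit.doubling_time_h)


@pytest.fixture(scope="module")
def pipeline(truth):
    """Links fitted on noise-free synthetic data from the truth itself."""
    from eposignal.calibration import parse_perturbation_id
    from eposignal.synth import (DesignSpec, generate_cci_dataset,
                                 generate_proliferation_dataset)
    design = DesignSpec()
    cci = generate_cci_dataset(truth, design, noise=False)
    prolif = generate_proliferation_dataset(truth, design, noise=False)
    rows = []
    for r in cci.itertuples():
        ints = truth.integrals(r.context, r.epo_Uml,
                               parse_perturbation_id(r.perturbation_id))
        rows.append(dict(context=r.context, epo_Uml=r.epo_Uml,
                         perturbation_id=r.perturbation_id,
                         cci=r.cci_true, **ints))
    feat = pd.DataFrame(rows)
    stage1 = fit_signaling_to_cci(feat)
    merged = feat.merge(prolif, on=["context", "epo_Uml", "perturbation_id"])
    stage2 = {ct: select_proliferation_model(sub, cell_type=ct)[0]
              for ct, sub in merged.groupby("context")}
    return ProliferationPipeline(
        instances={ct: truth.instance(ct) for ct in truth.contexts},
        stage1=stage1, stage2=stage2)


class TestPredictionChain:
    def test_unperturbed_condition_is_unity(self, pipeline):
        assert predict_proliferation(pipeline, "mCFU-E", 5.0) == pytest.approx(1.0)

    def test_monotone_in_inhibitor_dose(self, pipeline):
        doses = [0.0, 0.05, 0.5, 5.0]
        preds = [predict_proliferation(
            pipeline, "BaF3-EpoR", 5.0,
            [Perturbation("inhibitor", "U0126", d)] if d else [])
            for d in doses]
        assert all(a >= b - 1e-9 for a, b in zip(preds, preds[1:]))

    def test_combined_below_either_single(self, pipeline):
        both = predict_proliferation(
            pipeline, "BaF3-EpoR", 5.0,
            [Perturbation("inhibitor", "AKTVIII", 5.0),
             Perturbation("inhibitor", "U0126", 5.0)])
        akt = predict_proliferation(
            pipeline, "BaF3-EpoR", 5.0,
            [Perturbation("inhibitor", "AKTVIII", 5.0)])
        mek = predict_proliferation(
            pipeline, "BaF3-EpoR", 5.0,
            [Perturbation("inhibitor", "U0126", 5.0)])
        assert both < min(akt, mek)

    def test_missing_link_stage_is_configuration_error(self, pipeline):
        broken = ProliferationPipeline(instances=pipeline.instances,
                                       stage1=pipeline.stage1, stage2={})
        with pytest.raises(ValueError, match="link stages"):
            predict_proliferation(broken, "mCFU-E", 5.0)

    def test_self_consistency_r_squared(self, truth, pipeline):
        """Predicting the noise-free generating data reproduces it almost
        exactly (self-consistency ceiling)."""
        from eposignal.calibration import parse_perturbation_id
        from eposignal.synth import DesignSpec, generate_proliferation_dataset
        design = DesignSpec()
        prolif = generate_proliferation_dataset(truth, design, noise=False)
        for ct, sub in prolif.groupby("context"):
            obs = sub["proliferation"].to_numpy()
            pred = np.array([
                predict_proliferation(pipeline, ct, r.epo_Uml,
                                      parse_perturbation_id(r.perturbation_id))
                for r in sub.itertuples()])
            ss_res = np.sum((obs - pred) ** 2)
            ss_tot = np.sum((obs - obs.mean()) ** 2)
            assert 1 - ss_res / ss_tot >= 0.95
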