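"""Training-site sampling, frequency tables, GLM background fits, and LASSO
stability selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from mutrec.background import (
    BackgroundMutationModel,
    LassoStabilitySelector,
    build_frequency_table,
    fit_background,
    fit_cbs_background,
    sample_training_sites,
)
from mutrec.variants import CohortMetadata, MutationRecord


def snv(sample, chrom, pos):
    return MutationRecord(sample, chrom, pos, "A", "C")


class TestTrainingSites:
    def test_balanced_sampling_and_labels(self, tiny_masked):
        muts = [snv("s1", "chr1", p) for p in range(0, 300, 3)]
        df = sample_training_sites(muts, tiny_masked, seed=0)
        assert len(df) == 200 and df.label.sum() == 100

    def test_ratio_scales_negatives(self, tiny_masked):
        muts = [snv("s1", "chr1", p) for p in range(100)]
        df = sample_training_sites(muts, tiny_masked, ratio=2.0, seed=0)
        assert len(df) == 300

    def test_deterministic_under_seed(self, tiny_masked):
        muts = [snv("s1", "chr1", p) for p in range(50)]
        a = sample_training_sites(muts, tiny_masked, seed=5)
        b = sample_training_sites(muts, tiny_masked, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_negatives_never_collide_with_mutated(self, tiny_masked):
        muts = [snv("s1", "chr1", p) for p in range(0, 1000, 2)]
        df = sample_training_sites(muts, tiny_masked, seed=1)
        neg = df[df.label == 0]
        mutated = {(m.chrom, m.pos) for m in muts}
        assert not any((r.chrom, r.pos) in mutated for r in neg.itertuples())

    def test_too_many_negatives_requested(self, tiny_masked):
        muts = [snv("s1", "chr1", p) for p in range(1000)]
        with pytest.raises(ValueError, match="negative sites"):
            sample_training_sites(muts, tiny_masked, ratio=2.0, seed=0)


class TestFrequencyTable:
    def combos(self):
        return pd.DataFrame({"a": ["0", "0", "1", "1"], "b": ["0", "1", "0", "1"],
                             "n_sites": [10, 20, 30, 40]})

    def test_row_count_bounded_by_combos_times_patients(self):
        mutated = pd.DataFrame({"a": ["0"], "b": ["1"], "patient": ["p1"]})
        freq = build_frequency_table(self.combos(), mutated, ["p1"])
        assert len(freq) <= 4

    def test_mutation_conservation(self):
        mutated = pd.DataFrame(
            {"a": ["0", "0", "1"], "b": ["1", "1", "0"], "patient": ["p1", "p1", "p2"]}
        )
        freq = build_frequency_table(self.combos(), mutated, ["p1", "p2"])
        assert freq.n_mutated.sum() == 3

    def test_per_patient_duplication(self):
        mutated = pd.DataFrame({"a": ["0"], "b": ["0"], "patient": ["p1"]})
        freq = build_frequency_table(self.combos(), mutated, ["p1", "p2"])
        tot = freq.groupby("patient").n_total.sum()
        assert tot["p1"] == tot["p2"] == 100

    def test_continuous_covariate_rejected(self):
        bad = pd.DataFrame({"a": [0.5, 1.5], "n_sites": [5, 5]})
        with pytest.raises(TypeError, match="continuous"):
            build_frequency_table(bad, pd.DataFrame({"a": [], "patient": []}), ["p1"])


def simulate_sites(rng, n, beta0, beta, patients=("p1", "p2")):
    X = pd.DataFrame(
        {
            "x": rng.integers(0, 2, n).astype(str),
            "patient": rng.choice(patients, n),
        }
    )
    pat_eff = {p: i * 0.5 for i, p in enumerate(patients)}
    lin = beta0 + beta * (X.x == "1") + X.patient.map(pat_eff)
    y = (rng.random(n) < expit(lin)).astype(int)
    return X, y


class TestBackgroundModel:
    def test_frequency_fit_equals_per_site_fit(self):
        """Aggregated binomial fit and per-site Bernoulli fit share the MLE."""
        rng = np.random.default_rng(0)
        X, y = simulate_sites(rng, 4000, -3.0, 1.2)
        per_site = BackgroundMutationModel().fit(X, y)
        df = X.copy()
        df["y"] = y
        agg = (
            df.groupby(["x", "patient"], observed=True)
            .agg(n_total=("y", "size"), n_mutated=("y", "sum"))
            .reset_index()
        )
        freq_fit = BackgroundMutationModel().fit_frequency_table(agg)
        pd.testing.assert_series_equal(per_site.coef_, freq_fit.coef_, atol=1e-6, rtol=0)

    def test_planted_coefficient_recovery(self):
        rng = np.random.default_rng(1)
        X, y = simulate_sites(rng, 100_000, -9.0 + 4.0, 1.5)  # keep events frequent enough
        m = BackgroundMutationModel().fit(X, y)
        est, se = m.coef_["x[1]"], m.bse_["x[1]"]
        assert abs(est - 1.5) < 2 * se

    def test_intercept_only_model_reproduces_global_rate(self):
        freq = pd.DataFrame(
            {"u": ["0", "0"], "patient": ["p1", "p2"], "n_mutated": [3, 7], "n_total": [1000, 1000]}
        )
        m = fit_background(freq, patient_effects=False)
        q = m.predict_q("p1", {"u": "0"})
        assert q == pytest.approx(10 / 2000, rel=1e-6)

    def test_calibration_identity(self):
        """Mean fitted q over training data equals the observed mutation rate."""
        rng = np.random.default_rng(2)
        X, y = simulate_sites(rng, 5000, -2.0, 0.8)
        m = BackgroundMutationModel().fit(X, y)
        qhat = m.predict_proba(X)[:, 1]
        assert qhat.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_predict_q_examples(self):
        m = BackgroundMutationModel(patient_effects=False)
        m.covariate_cols_ = ["x"]
        m.levels_ = {"x": ["0", "1"]}
        m.coef_ = pd.Series({"const": -13.8155, "x[1]": 0.0})
        m.bse_ = pd.Series({"const": 0.1, "x[1]": 0.1})
        m.zero_patients_ = []
        q0 = m.predict_q("p", {"x": "0"})
        assert q0 == pytest.approx(1e-6, rel=1e-3)
        # a zero-coefficient covariate leaves q unchanged
        assert m.predict_q("p", {"x": "1"}) == pytest.approx(q0)
        # +ln 2 on the logit scale doubles q in the small-q regime
        m2_coef = m.coef_.copy()
        m2_coef["const"] += np.log(2)
        m.coef_ = m2_coef
        assert m.predict_q("p", {"x": "0"}) == pytest.approx(2 * q0, rel=1e-4)

    def test_zero_mutation_patient_gets_floor_intercept(self):
        freq = pd.DataFrame(
            {
                "u": ["0"] * 3,
                "patient": ["p1", "p2", "p3"],
                "n_mutated": [5, 8, 0],
                "n_total": [10_000] * 3,
            }
        )
        m = fit_background(freq)
        pat_cols = [c for c in m.coef_.index if c.startswith("patient[")]
        assert m.coef_["patient[p3]"] == min(0.0, *[m.coef_[c] for c in pat_cols])
        assert np.isfinite(m.predict_q("p3", {"u": "0"}))

    def test_unseen_level_policy(self):
        freq = pd.DataFrame(
            {"x": ["0", "1"], "patient": ["p1", "p1"], "n_mutated": [1, 2], "n_total": [100, 100]}
        )
        m = fit_background(freq)
        with pytest.raises(ValueError, match="unseen"):
            m.predict_q("p1", {"x": "7"})
        m.unseen_level = "reference"
        with pytest.warns(UserWarning, match="reference"):
            q = m.predict_q("p1", {"x": "7"})
        assert q == pytest.approx(m.predict_q("p1", {"x": "0"}))

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(3)
        X, y = simulate_sites(rng, 2000, -2.5, 1.0)
        m = BackgroundMutationModel().fit(X, y)
        m2 = BackgroundMutationModel.from_dict(m.to_dict())
        row = {"x": "1", "patient": "p2"}
        assert m2.predict_q("p2", row) == pytest.approx(m.predict_q("p2", row), rel=1e-12)

    def test_sklearn_params_interface(self):
        m = BackgroundMutationModel(model_class="indel")
        assert m.get_params()["model_class"] == "indel"
        m.set_params(patient_effects=False)
        assert m.patient_effects is False


class TestCbsModel:
    def make_freq(self, boundary_beta=0.7, n_pat=12, seed=0):
        rng = np.random.default_rng(seed)
        patients = [f"p{i}" for i in range(n_pat)]
        meta = CohortMetadata(
            subtype={p: ("CIN" if i % 2 else "GS") for i, p in enumerate(patients)},
            mutsig1={p: float(rng.beta(2, 5)) for p in patients},
            mutsig17={p: float(rng.beta(2, 8)) for p in patients},
        )
        rows = []
        for p in patients:
            for b in ("0", "1"):
                n_tot = 40_000
                lin = -7.0 + boundary_beta * (b == "1") + 0.4 * (meta.subtype[p] == "CIN")
                rows.append(
                    {"boundary": b, "patient": p, "n_total": n_tot,
                     "n_mutated": rng.binomial(n_tot, expit(lin))}
                )
        return pd.DataFrame(rows), meta

    def test_boundary_effect_recovered(self):
        freq, meta = self.make_freq(boundary_beta=np.log(2))
        m = fit_cbs_background(freq, meta)
        assert abs(m.coef_["boundary[1]"] - np.log(2)) < 2 * m.bse_["boundary[1]"]

    def test_gs_is_subtype_reference(self):
        freq, meta = self.make_freq()
        m = fit_cbs_background(freq, meta)
        assert m.levels_["subtype"][0] == "GS"
        assert "subtype[CIN]" in m.coef_.index

    def test_single_subtype_drops_covariate(self):
        freq, meta = self.make_freq()
        meta.subtype = {p: "CIN" for p in meta.subtype}
        m = fit_cbs_background(freq, meta)
        assert not any(c.startswith("subtype") for c in m.coef_.index)

    def test_constant_signature_dropped(self):
        freq, meta = self.make_freq()
        meta.mutsig1 = {p: 0.0 for p in meta.mutsig1}
        m = fit_cbs_background(freq, meta)
        assert "mutsig1" not in m.coef_.index and "mutsig17" in m.coef_.index

    def test_missing_metadata_names_sample(self):
        freq, meta = self.make_freq()
        del meta.subtype["p3"]
        with pytest.raises(ValueError, match="p3"):
            fit_cbs_background(freq, meta)


class TestLassoStability:
    def planted(self, seed=0, n=1200, strong=3, noise=6, beta=2.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, strong + noise))
        lin = -1.0 + X[:, :strong] @ np.full(strong, beta)
        y = (rng.random(n) < expit(lin)).astype(float)
        cols = [f"inf{i}" for i in range(strong)] + [f"noise{i}" for i in range(noise)]
        return pd.DataFrame(X, columns=cols), y

    def test_planted_effects_always_selected(self):
        X, y = self.planted()
        sel = LassoStabilitySelector(n_boot=20, random_state=0).fit(X, y)
        freq = pd.Series(sel.selection_frequency_, index=X.columns)
        assert (freq[[c for c in X if c.startswith("inf")]] == 1.0).all()
        assert sel.selected_features_ == [c for c in X if c.startswith("inf")]

    def test_noise_not_stability_selected(self):
        X, y = self.planted(seed=3)
        sel = LassoStabilitySelector(n_boot=20, random_state=1).fit(X, y)
        freq = pd.Series(sel.selection_frequency_, index=X.columns)
        assert (freq[[c for c in X if c.startswith("noise")]] <= 0.95).all()

    def test_zero_cut_returns_all_ever_selected(self):
        X, y = self.planted(seed=4)
        sel = LassoStabilitySelector(n_boot=10, stability_cut=0.0, random_state=2).fit(X, y)
        ever = sel.selection_frequency_ > 0
        assert list(np.asarray(X.columns)[ever]) == sel.selected_features_

    def test_determinism_and_transform(self):
        X, y = self.planted(seed=5)
        a = LassoStabilitySelector(n_boot=8, random_state=7).fit(X, y)
        b = LassoStabilitySelector(n_boot=8, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.selection_frequency_, b.selection_frequency_)
        assert list(a.transform(X).columns) == a.selected_features_

    def test_degenerate_inputs_rejected(self):
        X, y = self.planted()
        with pytest.raises(ValueError, match="2 features"):
            LassoStabilitySelector().fit(X.iloc[:, :1], y)
        with pytest.raises(ValueError, match="classes"):
            LassoStabilitySelector().fit(X, np.zeros(len(X)))
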