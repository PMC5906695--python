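"""Background mutation models.

Two-stage construction mirroring the discovery pipeline:

1. feature selection — L1-penalized logistic regression on all mutated sites
   plus an equal number of sampled non-mutated sites, with the penalty chosen
   by 10-fold cross-validation at the one-standard-error point, repeated over
   100 half-sample bootstraps; features selected in more than 95% of
   bootstraps are kept (:class:`LassoStabilitySelector`);
2. rate estimation — a logistic GLM on the frequency table of mutated /
   non-mutated site counts per covariate combination and patient, giving a
   per-base, per-patient mutation probability q (:class:`BackgroundMutationModel`).

Both are scikit-learn style estimators (``fit``, fitted ``_`` attributes,
``get_params``/``set_params``) and compose with sklearn tooling.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

import statsmodels.api as sm

from .genome import MaskedGenome

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# training-site sampling
# ---------------------------------------------------------------------------


def _offsets_to_coords(analyzable, offsets: np.ndarray) -> list[tuple[str, int]]:
    """Map offsets into the concatenated analyzable space to (chrom, pos)."""
    spans = list(analyzable)
    lengths = np.array([e - s for _, s, e in spans], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    idx = np.searchsorted(cum, offsets, side="right") - 1
    return [
        (spans[i][0], int(spans[i][1] + off - cum[i])) for i, off in zip(idx, offsets)
    ]


def sample_training_sites(
    muts: Sequence,
    masked: MaskedGenome,
    ratio: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """All mutated sites (label 1) plus ratio-times-as-many sampled non-mutated
    analyzable sites (label 0), uniform without replacement; deterministic
    under ``seed``. Returns a DataFrame (chrom, pos, label).
    """
    muts = list(muts)
    if not muts:
        raise ValueError("at least one mutated site is required")
    rng = np.random.default_rng(seed)
    mutated = {(m.chrom, m.pos) for m in muts}
    n_neg = int(round(ratio * len(muts)))
    total = masked.n_test_bases
    if n_neg > total - len(mutated):
        raise ValueError(
            f"requested {n_neg} negative sites but only {total - len(mutated)} available"
        )
    rows = [(m.chrom, m.pos, 1) for m in muts]
    seen: set[tuple[str, int]] = set()
    while len(seen) < n_neg:
        need = n_neg - len(seen)
        offs = rng.integers(0, total, size=2 * need + 16)
        for chrom, pos in _offsets_to_coords(masked.analyzable, offs):
            if (chrom, pos) not in mutated and (chrom, pos) not in seen:
                seen.add((chrom, pos))
                rows.append((chrom, pos, 0))
                if len(seen) == n_neg:
                    break
    return pd.DataFrame(rows, columns=["chrom", "pos", "label"])


# ---------------------------------------------------------------------------
# LASSO bootstrap stability selection
# ---------------------------------------------------------------------------


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int, ratio: float = 1e-3) -> np.ndarray:
    n = len(y)
    p0 = y.mean()
    lam_max = np.abs(X.T @ (y - p0)).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


class LassoStabilitySelector(BaseEstimator):
    """Bootstrap stability selection with L1-penalized logistic regression.

    For each of ``n_boot`` half-sample bootstraps, the penalty is chosen by
    ``cv_folds``-fold cross-validation at the one-standard-error point on
    binomial deviance, and the features with nonzero coefficients at that
    penalty are recorded. Features selected in more than ``stability_cut``
    of the bootstraps are retained.

    Attributes (after fit): ``selection_frequency_`` (per-feature fraction of
    bootstraps), ``support_`` (boolean mask), ``selected_features_``.
    """

    def __init__(
        self,
        n_boot: int = 100,
        boot_frac: float = 0.5,
        stability_cut: float = 0.95,
        cv_folds: int = 10,
        n_lambdas: int = 15,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.boot_frac = boot_frac
        self.stability_cut = stability_cut
        self.cv_folds = cv_folds
        self.n_lambdas = n_lambdas
        self.random_state = random_state

    def _fit_l1(self, X, y, lam):
        # glmnet objective (1/N) sum loss + lam * ||b||_1  <=>  liblinear C = 1/(N*lam)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear", max_iter=200, tol=1e-6
        )
        clf.fit(X, y)
        return clf

    def _one_se_lambda(self, X, y, lambdas, rng) -> float:
        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        dev = np.zeros((self.cv_folds, len(lambdas)))
        for f, (tr, va) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("degenerate CV fold with a single class")
            for j, lam in enumerate(lambdas):
                clf = self._fit_l1(X[tr], y[tr], lam)
                dev[f, j] = _binomial_deviance(y[va], clf.predict_proba(X[va])[:, 1])
        mean = dev.mean(axis=0)
        se = dev.std(axis=0, ddof=1) / np.sqrt(self.cv_folds)
        j_min = int(np.argmin(mean))
        cut = mean[j_min] + se[j_min]
        # lambdas are descending: the largest lambda within one SE of the minimum
        j_1se = int(np.nonzero(mean <= cut)[0][0])
        return float(lambdas[j_1se])

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.array([f"x{i}" for i in range(X.shape[1])], dtype=object)
        y = np.asarray(y, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("stability selection needs at least 2 features")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        m = max(2, int(round(self.boot_frac * n)))
        counts = np.zeros(X.shape[1])
        for b in range(self.n_boot):
            boot_rng = np.random.default_rng(
                None if self.random_state is None else self.random_state + b + 1
            )
            idx = boot_rng.choice(n, size=m, replace=False)
            Xb, yb = X[idx], y[idx]
            if len(np.unique(yb)) < 2:  # resample a degenerate half-sample
                idx = boot_rng.choice(n, size=m, replace=False)
                Xb, yb = X[idx], y[idx]
            scaler = StandardScaler()
            Xs = scaler.fit_transform(Xb)
            lambdas = _lambda_grid(Xs, yb, self.n_lambdas)
            lam = self._one_se_lambda(Xs, yb, lambdas, boot_rng)
            clf = self._fit_l1(Xs, yb, lam)
            counts += np.abs(clf.coef_[0]) > 1e-10
        self.selection_frequency_ = counts / self.n_boot
        self.support_ = self.selection_frequency_ > self.stability_cut
        self.selected_features_ = list(self.feature_names_in_[self.support_])
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


def lasso_stability_select(features, labels, cfg: "LassoStabilitySelector | None" = None, **kw):
    """Functional wrapper: returns (selected feature names, per-feature frequency)."""
    sel = cfg if cfg is not None else LassoStabilitySelector(**kw)
    sel.fit(features, labels)
    freq = pd.Series(sel.selection_frequency_, index=sel.feature_names_in_)
    return sel.selected_features_, freq


# ---------------------------------------------------------------------------
# frequency table
# ---------------------------------------------------------------------------


def build_frequency_table(
    site_combos: pd.DataFrame,
    mutated: pd.DataFrame,
    patients: Sequence[str],
    covariate_cols: Sequence[str] | None = None,
    weight_col: str = "n_sites",
) -> pd.DataFrame:
    """Aggregate sites into (covariate combination, patient) binomial counts.

    ``site_combos``: one row per site (or pre-aggregated with a ``n_sites``
    column) with categorical covariate columns. ``mutated``: one row per
    (mutated site, patient) with the same covariate columns plus ``patient``.
    Every patient is assumed able to mutate every site, so ``n_total`` for a
    combination is its site count for each patient. Combinations with zero
    occupancy are omitted.
    """
    if covariate_cols is None:
        covariate_cols = [c for c in site_combos.columns if c != weight_col]
    for c in covariate_cols:
        if pd.api.types.is_float_dtype(site_combos[c]):
            raise TypeError(f"covariate {c!r} is continuous; discretize/binarize it first")
    combos = site_combos.copy()
    if weight_col not in combos:
        combos[weight_col] = 1
    totals = combos.groupby(list(covariate_cols), observed=True)[weight_col].sum().rename("n_total")
    mut_counts = (
        mutated.groupby(list(covariate_cols) + ["patient"], observed=True)
        .size()
        .rename("n_mutated")
    )
    rows = []
    for patient in patients:
        df = totals.reset_index()
        df["patient"] = patient
        rows.append(df)
    freq = pd.concat(rows, ignore_index=True)
    freq = freq.merge(mut_counts.reset_index(), on=list(covariate_cols) + ["patient"], how="left")
    freq["n_mutated"] = freq["n_mutated"].fillna(0).astype(int)
    if (freq["n_mutated"] > freq["n_total"]).any():
        raise ValueError("more mutated than total sites in a cell; inconsistent inputs")
    return freq


# ---------------------------------------------------------------------------
# logistic background model
# ---------------------------------------------------------------------------


class BackgroundMutationModel(BaseEstimator):
    """Per-patient logistic background mutation model.

    Fits ``logit(q) = b0 + b_patient + sum(b_level * x)`` by maximum
    likelihood on aggregated binomial counts (statsmodels GLM). Categorical
    covariates are dummy-coded against their first (sorted) level; patients
    are fixed-effect intercept offsets against the first patient. Continuous
    per-patient covariates (e.g. signature fractions) are passed through.

    Parameters
    ----------
    model_class : {"snv", "indel", "cbs"}
    patient_effects : include per-patient intercepts (the genome-wide models
        always do; the CBS model may drop them when patient-level covariates
        such as subtype and signature fractions are present, which patient
        fixed effects would make unidentifiable).
    unseen_level : {"error", "reference"} — behavior for covariate levels not
        seen during fitting.
    """

    def __init__(
        self,
        model_class: str = "snv",
        patient_effects: bool = True,
        continuous_cols: tuple = (),
        unseen_level: str = "error",
        ridge_fallback: float = 1e-6,
    ):
        self.model_class = model_class
        self.patient_effects = patient_effects
        self.continuous_cols = continuous_cols
        self.unseen_level = unseen_level
        self.ridge_fallback = ridge_fallback

    # -- design construction -------------------------------------------------
    def _design(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = {"const": np.ones(len(df))}
        for c in self.covariate_cols_:
            levels = self.levels_[c]
            vals = df[c].astype(str).to_numpy() if c != "patient" else df[c].to_numpy()
            unseen = ~np.isin(vals, levels)
            if unseen.any():
                if self.unseen_level == "error":
                    raise ValueError(f"unseen level(s) {set(vals[unseen])} for covariate {c!r}")
                warnings.warn(f"unseen levels for {c!r} mapped to reference level")
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (vals == lev).astype(float)
        for c in self.continuous_cols:
            cols[c] = df[c].astype(float).to_numpy()
        return pd.DataFrame(cols, index=df.index)

    # -- fitting ---------------------------------------------------------------
    def fit_frequency_table(self, freq: pd.DataFrame, covariate_cols: Sequence[str] | None = None):
        freq = freq.copy()
        if covariate_cols is None:
            covariate_cols = [
                c
                for c in freq.columns
                if c not in ("patient", "n_mutated", "n_total", *self.continuous_cols)
            ]
        covariate_cols = list(covariate_cols)
        if self.patient_effects:
            # guard: patients with zero mutated sites have a -inf MLE intercept
            per_patient = freq.groupby("patient")["n_mutated"].sum()
            self.zero_patients_ = sorted(per_patient.index[per_patient == 0])
            if self.zero_patients_:
                log.warning(
                    "%d patients with zero mutations get the cohort-minimum intercept",
                    len(self.zero_patients_),
                )
            fit_df = freq[~freq["patient"].isin(self.zero_patients_)]
            covariate_cols = covariate_cols + ["patient"]
        else:
            self.zero_patients_ = []
            fit_df = freq
        nuniq = {c: fit_df[c].nunique() for c in covariate_cols}
        covariate_cols = [c for c in covariate_cols if nuniq[c] > 1]
        for c in [c for c, n in nuniq.items() if n <= 1]:
            log.info("covariate %r is constant; dropped from the model", c)
        self.covariate_cols_ = covariate_cols
        self.levels_ = {}
        for c in covariate_cols:
            if isinstance(fit_df[c].dtype, pd.CategoricalDtype):
                observed = set(fit_df[c].astype(str))
                self.levels_[c] = [str(l) for l in fit_df[c].cat.categories if str(l) in observed]
            elif c == "patient":
                self.levels_[c] = sorted(fit_df[c].unique())
            else:
                self.levels_[c] = sorted(fit_df[c].astype(str).unique())
        X = self._design(fit_df)
        endog = np.column_stack(
            [fit_df["n_mutated"].to_numpy(), (fit_df["n_total"] - fit_df["n_mutated"]).to_numpy()]
        )
        glm = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                # rare-event rates legitimately push fitted probabilities
                # toward 0; separation is caught by the magnitude check below
                from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

                warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = glm.fit()
            ok = np.all(np.isfinite(res.params)) and np.all(np.abs(res.params) < 30)
        except Exception:  # pragma: no cover - separation is data dependent
            res, ok = None, False
        if not ok:
            warnings.warn("possible separation; refitting with a small ridge penalty")
            res = glm.fit_regularized(alpha=self.ridge_fallback, L1_wt=0.0)
        self.result_ = res
        self.coef_ = pd.Series(np.asarray(res.params), index=X.columns)
        try:
            self.bse_ = pd.Series(np.asarray(res.bse), index=X.columns)
        except Exception:
            self.bse_ = pd.Series(np.nan, index=X.columns)
        if self.patient_effects and self.zero_patients_:
            pat_cols = [c for c in self.coef_.index if c.startswith("patient[")]
            floor = min([0.0] + [self.coef_[c] for c in pat_cols])
            for p in self.zero_patients_:
                self.coef_[f"patient[{p}]"] = floor
                self.bse_[f"patient[{p}]"] = np.nan
                # appended after the fitted levels so the reference patient is unchanged
                self.levels_["patient"].append(p)
        self.freq_columns_ = list(freq.columns)
        return self

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        """Per-site fit: X holds categorical covariates (plus 'patient' when
        patient_effects) and continuous columns; y is the 0/1 mutation label.
        Aggregates to a frequency table first, so this is likelihood-identical
        to :meth:`fit_frequency_table` on the same data."""
        df = X.copy()
        df["_y"] = np.asarray(y)
        df["_w"] = 1 if sample_weight is None else np.asarray(sample_weight)
        group_cols = [c for c in X.columns]
        agg = df.groupby(group_cols, observed=True).agg(
            n_total=("_w", "sum"), n_mutated=("_y", "sum")
        ).reset_index()
        if "patient" not in agg.columns:
            agg["patient"] = "_all"
            was_pe = self.patient_effects
            self.patient_effects = False
            try:
                return self.fit_frequency_table(agg)
            finally:
                self.patient_effects = was_pe
        return self.fit_frequency_table(agg)

    # -- prediction ------------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        D = self._design(X)
        D = D.reindex(columns=self.coef_.index, fill_value=0.0)
        return D.to_numpy() @ self.coef_.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        q = expit(self.decision_function(X))
        return np.column_stack([1 - q, q])

    def predict_q(self, patient: str, features: Mapping) -> float:
        row = {**features}
        if self.patient_effects or "patient" in getattr(self, "covariate_cols_", []):
            row["patient"] = patient
        q = float(self.predict_proba(pd.DataFrame([row]))[0, 1])
        if not (0 < q < 1):
            raise ValueError("model pathology: predicted q outside (0, 1)")
        return q

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        lo = self.coef_ - z * self.bse_
        hi = self.coef_ + z * self.bse_
        return pd.DataFrame({"lower": lo, "upper": hi})

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "model_class": self.model_class,
            "patient_effects": self.patient_effects,
            "continuous_cols": list(self.continuous_cols),
            "covariate_cols": self.covariate_cols_,
            "levels": {k: list(v) for k, v in self.levels_.items()},
            "coef": {k: float(v) for k, v in self.coef_.items()},
            "bse": {k: (None if not np.isfinite(v) else float(v)) for k, v in self.bse_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundMutationModel":
        obj = cls(
            model_class=d["model_class"],
            patient_effects=d["patient_effects"],
            continuous_cols=tuple(d["continuous_cols"]),
        )
        obj.covariate_cols_ = list(d["covariate_cols"])
        obj.levels_ = {k: list(v) for k, v in d["levels"].items()}
        obj.coef_ = pd.Series(d["coef"])
        obj.bse_ = pd.Series({k: (np.nan if v is None else v) for k, v in d["bse"].items()})
        obj.zero_patients_ = []
        return obj


def fit_background(freq: pd.DataFrame, model_class: str = "snv", **kw) -> BackgroundMutationModel:
    """Fit a genome-wide background model from a frequency table."""
    return BackgroundMutationModel(model_class=model_class, **kw).fit_frequency_table(freq)


def predict_q(model: BackgroundMutationModel, patient: str, features: Mapping) -> float:
    return model.predict_q(patient, features)


def fit_cbs_background(
    freq: pd.DataFrame,
    metadata,
    patient_effects: bool = False,
) -> BackgroundMutationModel:
    """Fit the CBS-specific background model on CBS +/- 5 bp frequency counts.

    ``freq`` rows carry the categorical covariates (boundary, rep/local-rate
    levels, selected sequence features) per patient; subtype and the
    signature-1/17 fractions are joined from ``metadata`` (missing samples are
    an error). Subtype is coded against the GS reference level; the signature
    fractions enter as continuous per-patient covariates.
    """
    freq = freq.copy()
    missing = [p for p in freq["patient"].unique() if p not in metadata.subtype]
    if missing:
        raise ValueError(f"metadata missing for sample(s): {missing}")
    freq["subtype"] = freq["patient"].map(metadata.subtype)
    for col, d in (("mutsig1", metadata.mutsig1), ("mutsig17", metadata.mutsig17)):
        vals = freq["patient"].map(d)
        if vals.isna().any():
            raise ValueError(f"metadata missing {col} for sample(s)")
        freq[col] = vals.astype(float)
    continuous = []
    for col in ("mutsig1", "mutsig17"):
        if freq[col].nunique() > 1:
            continuous.append(col)
        else:
            log.info("%s is constant; dropped from the CBS model", col)
    # GS as the subtype reference level (sorted order puts it first via rename)
    order = ["GS", "CIN", "EBV", "MSI", "NA"]
    freq["subtype"] = pd.Categorical(freq["subtype"], categories=order).remove_unused_categories()
    model = BackgroundMutationModel(
        model_class="cbs",
        patient_effects=patient_effects,
        continuous_cols=tuple(continuous),
    )
    cov_cols = [
        c
        for c in freq.columns
        if c not in ("patient", "n_mutated", "n_total", "mutsig1", "mutsig17")
    ]
    model.fit_frequency_table(freq, covariate_cols=cov_cols)
    return model
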