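"""Mixed-model prediction of clinician-rated depression severity.

Follow-up clinician totals are modeled with linear mixed models (random
intercept per subject, maximum likelihood) whose fixed effects combine a
covariate tier (none / demographics / baseline score + demographics) with a
phone-based predictor set:

=====  =============================================
A      self-report (PHQ-8) total
B      first principal component of the 32 passive statistics
C      PHQ-8 + first principal component
D      no phone-based predictors
E      first and second principal components
F      weekend distance traveled (single raw passive feature)
=====  =============================================

Prediction accuracy is measured by leave-one-subject-out cross-validation:
the held-out subject's visits are predicted from the fixed effects only
(their unseen random intercept is zero), the per-subject root-mean-squared
errors are averaged across subjects, and — when passive predictors are used
— feature standardization and PCA are refit inside each training fold so no
information from the held-out subject leaks into the loadings.  Rows with a
missing predictor are excluded at fit time and skipped (and counted) at
prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .aggregate import WEEKLY_FEATURE_COLUMNS

TIERS = ("none", "demo", "full")

_PHONE_PREDICTORS = {
    "A": ("phq8",),
    "B": ("pc1",),
    "C": ("phq8", "pc1"),
    "D": (),
    "E": ("pc1", "pc2"),
    "F": ("distance_m_weekend",),
}

#: Sign-anchoring feature: components are flipped so this loading is >= 0.
PCA_SIGN_FEATURE = "distance_m_weekend"


@dataclass(frozen=True)
class ModelSpec:
    """A model row (phone predictors) and covariate tier (column)."""

    label: str  # "A".."F"
    tier: str = "full"  # "none" | "demo" | "full"

    def __post_init__(self):
        if self.label not in _PHONE_PREDICTORS:
            raise ValueError(f"unknown model label {self.label!r}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown covariate tier {self.tier!r}")

    @property
    def phone_predictors(self) -> tuple[str, ...]:
        return _PHONE_PREDICTORS[self.label]

    @property
    def needs_pca(self) -> bool:
        return any(p.startswith("pc") for p in self.phone_predictors)

    @property
    def name(self) -> str:
        suffix = {"full": "", "demo": "'", "none": "''"}[self.tier]
        return f"Model {self.label}{suffix}"


# ---------------------------------------------------------------------------
# standardization + PCA of the passive features
# ---------------------------------------------------------------------------


@dataclass
class PassivePCA:
    """Training-fold standardizer and PCA loadings for the passive features."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Project rows onto the components; rows with missing features → NaN."""
        X = rows[self.features].to_numpy(float)
        complete = ~np.isnan(X).any(axis=1)
        Z = (X - self.mean) / self.sd
        scores = np.full((len(rows), len(self.loadings)), np.nan)
        if complete.any():
            scores[complete] = Z[complete] @ self.loadings.T
        return pd.DataFrame(
            scores, index=rows.index,
            columns=[f"pc{i+1}" for i in range(len(self.loadings))],
        )


def standardize_and_pca(
    train_rows: pd.DataFrame, features: list[str] | None = None
) -> PassivePCA:
    """Z-score the passive features on complete training rows and run PCA.

    Features constant in training are dropped with a warning.  Each
    component's sign is fixed so its weekend-distance loading (or, if that
    feature was dropped, its largest-magnitude loading) is nonnegative.
    """
    features = list(features or WEEKLY_FEATURE_COLUMNS)
    X = train_rows[features].to_numpy(float)
    X = X[~np.isnan(X).any(axis=1)]
    if len(X) < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    sd = X.std(axis=0, ddof=0)
    dropped = [f for f, s in zip(features, sd) if s == 0]
    if dropped:
        warnings.warn(f"constant features dropped from PCA: {dropped}")
    keep = [f for f in features if f not in dropped]
    idx = [features.index(f) for f in keep]
    Xk = X[:, idx]
    mean = Xk.mean(axis=0)
    sd = Xk.std(axis=0, ddof=0)
    Z = (Xk - mean) / sd
    # PCA via SVD of the centered standardized matrix
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    var = svals**2
    ratio = var / var.sum()
    if PCA_SIGN_FEATURE in keep:
        anchor = keep.index(PCA_SIGN_FEATURE)
        flip = np.sign(Vt[:, anchor])
    else:
        flip = np.sign(Vt[np.arange(len(Vt)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    return PassivePCA(
        features=keep, mean=mean, sd=sd, loadings=Vt,
        explained_variance_ratio=ratio, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

DIAGNOSIS_REFERENCE = "HC"


def design_matrix(
    rows: pd.DataFrame, spec: ModelSpec, pca: PassivePCA | None,
    diagnoses: list[str] | None = None,
) -> pd.DataFrame:
    """Named fixed-effects design for a model spec (intercept included).

    Diagnostic category is dummy-coded against the healthy-control
    reference; sex enters as an indicator for male.  ``diagnoses`` fixes the
    category levels (pass the full-table levels so training and held-out
    designs share columns).  PCA score columns are added from ``pca`` when
    the spec uses components.  Rows with any missing predictor keep NaN and
    are filtered by the caller.
    """
    out = pd.DataFrame(index=rows.index)
    out["intercept"] = 1.0
    if spec.tier == "full":
        out["baseline_madrs"] = rows["baseline_madrs"].astype(float)
    if spec.tier in ("full", "demo"):
        out["age"] = rows["age"].astype(float)
        out["sex_M"] = (rows["sex"] == "M").astype(float)
        cats = diagnoses if diagnoses is not None else rows["diagnosis"].unique()
        cats = sorted(c for c in cats if c != DIAGNOSIS_REFERENCE)
        for c in cats:
            out[f"diag_{c}"] = (rows["diagnosis"] == c).astype(float)
    scores = pca.transform(rows) if (spec.needs_pca and pca is not None) else None
    for p in spec.phone_predictors:
        if p.startswith("pc"):
            if scores is None:
                raise ValueError(f"{spec.name} needs PCA scores but none were provided")
            out[p] = scores[p]
        else:
            out[p] = rows[p].astype(float)
    return out


# ---------------------------------------------------------------------------
# mixed-model fit and fixed-effects prediction
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A fitted random-intercept linear mixed model."""

    spec: ModelSpec
    columns: list[str]
    params: pd.Series  # fixed-effect coefficients
    bse: pd.Series  # their standard errors
    group_var: float  # random-intercept variance
    resid_var: float  # residual variance
    n_rows: int
    converged: bool
    pca: PassivePCA | None = None


def fit_lmm(
    y: np.ndarray, X: pd.DataFrame, groups: np.ndarray, spec: ModelSpec | None = None,
    pca: PassivePCA | None = None,
) -> FittedModel:
    """Maximum-likelihood random-intercept fit.

    ML rather than REML so fits with different fixed-effect sets remain
    comparable across cross-validation folds; predictions use the fixed
    effects only, so the estimation criterion does not enter prediction
    beyond the coefficients themselves.
    """
    if len(np.unique(groups)) < 2:
        raise ValueError(
            f"mixed model needs >= 2 subjects, got {len(np.unique(groups))} "
            f"({len(y)} rows after exclusions)"
        )
    y = np.asarray(y, float)
    Xmat = X.to_numpy(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(y, Xmat, groups=np.asarray(groups))
            result = model.fit(reml=False)
            params = pd.Series(result.fe_params, index=list(X.columns))
            bse = pd.Series(np.asarray(result.bse_fe), index=list(X.columns))
            group_var = float(np.asarray(result.cov_re)[0, 0])
            resid_var = float(result.scale)
            converged = bool(result.converged)
        if not np.all(np.isfinite(params.to_numpy())):
            raise np.linalg.LinAlgError("non-finite coefficients")
    except np.linalg.LinAlgError:
        # degenerate likelihood (e.g. zero residual variance): the ML fixed
        # effects collapse to ordinary least squares with no random effects
        beta, *_ = np.linalg.lstsq(Xmat, y, rcond=None)
        resid = y - Xmat @ beta
        dof = max(len(y) - Xmat.shape[1], 1)
        resid_var = float(resid @ resid) / dof
        cov = resid_var * np.linalg.pinv(Xmat.T @ Xmat)
        params = pd.Series(beta, index=list(X.columns))
        bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=list(X.columns))
        group_var, converged = 0.0, True
    if not np.all(np.isfinite(params.to_numpy())):
        raise ValueError("mixed-model fit produced non-finite coefficients")
    return FittedModel(
        spec=spec or ModelSpec("D", "none"),
        columns=list(X.columns),
        params=params,
        bse=bse,
        group_var=group_var,
        resid_var=resid_var,
        n_rows=len(y),
        converged=converged,
        pca=pca,
    )


def predict_fixed(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Fixed-effects prediction: x·beta with the random intercept at zero."""
    return X[model.columns].to_numpy(float) @ model.params.to_numpy()


def _complete_rows(X: pd.DataFrame) -> np.ndarray:
    return ~X.isna().any(axis=1).to_numpy()


def fit_model_spec(
    table: pd.DataFrame, spec: ModelSpec, pca: PassivePCA | None = None
) -> FittedModel:
    """Fit a spec on an analysis table (complete-case on its predictors)."""
    if spec.needs_pca and pca is None:
        pca = standardize_and_pca(table)
    X = design_matrix(table, spec, pca, diagnoses=list(table["diagnosis"].unique()))
    ok = _complete_rows(X) & table["madrs"].notna().to_numpy()
    return fit_lmm(
        table.loc[ok, "madrs"].to_numpy(float), X[ok],
        table.loc[ok, "subject"].to_numpy(), spec=spec, pca=pca,
    )


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-subject and average prediction error from LOSO-CV."""

    spec: ModelSpec
    per_subject_rmse: pd.Series
    average_rmse: float
    predictions: pd.DataFrame  # subject, visit_index, madrs, predicted
    n_excluded_rows: int  # held-out rows skipped for missing predictors
    subjects_without_scores: list[str]
    fold_models: dict = field(default_factory=dict)  # held subject -> FittedModel


def loso_cv(
    table: pd.DataFrame, spec: ModelSpec, pca_refit_per_fold: bool = True,
    keep_models: bool = False,
) -> CVResult:
    """Leave-one-subject-out cross-validation of one model spec.

    Each subject in turn is held out; the model (and, when passive
    predictors are used and ``pca_refit_per_fold`` is true, the feature
    standardizer and PCA loadings) is fit on the remaining subjects, and the
    held-out visits are predicted from fixed effects alone.  The reported
    average is the mean of per-subject RMSEs over subjects with at least one
    scorable visit — not a pooled RMSE.
    """
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out CV needs at least 3 subjects")
    diagnoses = list(table["diagnosis"].unique())
    global_pca = None
    if spec.needs_pca and not pca_refit_per_fold:
        global_pca = standardize_and_pca(table)

    rmses: dict[str, float] = {}
    missing: list[str] = []
    pred_rows = []
    fold_models: dict = {}
    n_excluded = 0
    for held in subjects:
        train = table[table["subject"] != held]
        test = table[table["subject"] == held]
        pca = None
        if spec.needs_pca:
            pca = global_pca if global_pca is not None else standardize_and_pca(train)
        Xtr = design_matrix(train, spec, pca, diagnoses=diagnoses)
        ok = _complete_rows(Xtr) & train["madrs"].notna().to_numpy()
        model = fit_lmm(
            train.loc[ok, "madrs"].to_numpy(float), Xtr[ok],
            train.loc[ok, "subject"].to_numpy(), spec=spec, pca=pca,
        )
        if keep_models:
            fold_models[held] = model
        Xte = design_matrix(test, spec, pca, diagnoses=diagnoses)
        ok_te = _complete_rows(Xte) & test["madrs"].notna().to_numpy()
        n_excluded += int((~ok_te).sum())
        if not ok_te.any():
            missing.append(held)
            continue
        preds = predict_fixed(model, Xte[ok_te])
        actual = test.loc[ok_te, "madrs"].to_numpy(float)
        rmses[held] = float(np.sqrt(np.mean((preds - actual) ** 2)))
        for vi, a, p in zip(test.loc[ok_te, "visit_index"], actual, preds):
            pred_rows.append(dict(subject=held, visit_index=vi, madrs=a, predicted=p))

    per_subject = pd.Series(rmses, name="rmse")
    return CVResult(
        spec=spec,
        per_subject_rmse=per_subject,
        average_rmse=float(per_subject.mean()) if len(per_subject) else np.nan,
        predictions=pd.DataFrame(pred_rows, columns=["subject", "visit_index", "madrs", "predicted"]),
        n_excluded_rows=n_excluded,
        subjects_without_scores=missing,
        fold_models=fold_models,
    )


def run_model_zoo(
    table: pd.DataFrame,
    labels: str = "ABCDEF",
    tiers: tuple[str, ...] = TIERS,
    pca_refit_per_fold: bool = True,
) -> pd.DataFrame:
    """LOSO average RMSE for every model row x covariate tier (18 cells).

    Returns a frame indexed by model label with one column per tier; cells
    whose predictors are entirely missing come back NaN.
    """
    grid = {}
    for tier in tiers:
        col = {}
        for label in labels:
            spec = ModelSpec(label, tier)
            try:
                col[label] = loso_cv(table, spec, pca_refit_per_fold=pca_refit_per_fold).average_rmse
            except ValueError:
                col[label] = np.nan
        grid[tier] = col
    out = pd.DataFrame(grid)
    out.index.name = "model"
    return out[list(tiers)]
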