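"""Parametric empirical-Bayes batch harmonization (ComBat).

Removes additive (location) and multiplicative (scale) site effects from a
features matrix while preserving the effects of protected covariates. The
model per feature g and batch i is

    x_ijg = alpha_g + W_j beta_g + gamma_ig + delta_ig * eps_ijg

with eps ~ N(0, sigma_g^2). Batch locations gamma share a normal prior across
features within a batch, scales delta^2 an inverse-gamma prior; both priors
are estimated by method of moments across features and the per-batch
(gamma*, delta*^2) are the conditional posterior modes obtained by fixed-point
iteration. Adjusted data are

    x_adj = sigma_g * (z_ijg - gamma*_ig) / delta*_ig + alpha_g + W_j beta_g.

Only imaging blocks are harmonized in the pipeline; language and clinical
blocks pass through untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ConstantFeature, FeatureMismatch, SingularDesign,
                     TooFewPerBatch, UnseenBatch)
from .matrix import FeatureMatrix

MIN_PER_BATCH = 3
EB_TOL = 1e-6
EB_MAX_ITER = 200


@dataclass
class CombatModel:
    """Fitted harmonization parameters (everything needed to transform)."""
    feature_names: list[str]
    batch_levels: list[str]
    covariate_names: list[str]
    alpha: np.ndarray               # (p,) intercept (grand mean)
    beta: np.ndarray                # (n_cov, p) covariate coefficients
    sigma2: np.ndarray              # (p,) pooled residual variance
    gamma_star: np.ndarray          # (n_batch, p) shrunken locations
    delta2_star: np.ndarray         # (n_batch, p) shrunken squared scales
    gamma_hat: np.ndarray = field(repr=False, default=None)
    delta2_hat: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "batch_levels": self.batch_levels,
            "covariate_names": self.covariate_names,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
        }


def _design(batch: pd.Series, levels: list[str], covariates: pd.DataFrame | None):
    """Full-rank design: batch one-hots followed by covariate columns."""
    B = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    if covariates is not None and covariates.shape[1] > 0:
        W = np.column_stack([B, covariates.to_numpy(float)])
    else:
        W = B
    return B, W


def combat_fit(m: FeatureMatrix, batch: pd.Series,
               covariates: pd.DataFrame | None = None) -> CombatModel:
    """Estimate the ComBat model on a raw feature matrix.

    ``batch`` maps subject id → site label, aligned to ``m``'s subjects;
    ``covariates`` (optional) are numeric design columns whose effects are
    preserved through harmonization.

    Raises
    ------
    TooFewPerBatch, ConstantFeature, SingularDesign
    """
    X = m.values                                  # n × p
    n, p = X.shape
    batch = batch.reindex(m.subjects)
    if batch.isna().any():
        raise UnseenBatch("batch labels missing for some subjects")
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    small = [lv for lv in levels if counts[lv] < MIN_PER_BATCH]
    if len(levels) >= 2 and small:
        raise TooFewPerBatch(f"batches below {MIN_PER_BATCH} subjects: {small}")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        name = m.feature_names[int(np.argmax(sds == 0))]
        raise ConstantFeature(f"feature {name!r} is constant in the pooled sample")
    if covariates is not None:
        covariates = covariates.reindex(m.subjects)
    B, W = _design(batch, levels, covariates)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise SingularDesign("design (batch indicators + covariates) is rank deficient")

    # least squares; grand mean alpha = sample-size-weighted batch intercepts
    coef, *_ = np.linalg.lstsq(W, X, rcond=None)
    n_batch = len(levels)
    batch_int = coef[:n_batch]                    # per-batch intercepts
    weights = counts.reindex(levels).to_numpy(float) / n
    alpha = weights @ batch_int
    beta = coef[n_batch:]
    cov_names = list(covariates.columns) if covariates is not None else []

    fitted = W @ coef
    resid = X - fitted
    sigma2 = (resid ** 2).sum(axis=0) / n         # pooled variance, n denominator

    stand_mean = alpha[None, :] + (W[:, n_batch:] @ beta if beta.size else 0.0)
    Z = (X - stand_mean) / np.sqrt(sigma2)

    gamma_hat = np.empty((n_batch, p))
    delta2_hat = np.empty((n_batch, p))
    for i, lv in enumerate(levels):
        zi = Z[(batch == lv).to_numpy()]
        gamma_hat[i] = zi.mean(axis=0)
        delta2_hat[i] = zi.var(axis=0, ddof=1) if len(zi) > 1 else np.ones(p)

    if n_batch == 1:
        # nothing to shrink toward a between-batch contrast
        gamma_star = np.zeros((1, p))
        delta2_star = np.ones((1, p))
        return CombatModel(m.feature_names, levels, cov_names, alpha, beta,
                           sigma2, gamma_star, delta2_star, gamma_hat, delta2_hat)

    # empirical-Bayes hyperparameters by method of moments across features
    gamma_bar = gamma_hat.mean(axis=1)            # (n_batch,)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta2_hat.mean(axis=1)
    d_var = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean ** 2) / d_var
    b_prior = (d_mean * d_var + d_mean ** 3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i, lv in enumerate(levels):
        mask = (batch == lv).to_numpy()
        zi = Z[mask]
        ni = len(zi)
        g = gamma_hat[i].copy()
        d2 = delta2_hat[i].copy()
        for _ in range(EB_MAX_ITER):
            g_new = (ni * tau2[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (ni * tau2[i] + d2)
            ss = ((zi - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (b_prior[i] + 0.5 * ss) / (ni / 2 + a_prior[i] - 1)
            change = max(np.abs(g_new - g).max(), np.abs(d2_new - d2).max())
            g, d2 = g_new, d2_new
            if change < EB_TOL:
                break
        gamma_star[i] = g
        delta2_star[i] = d2

    return CombatModel(m.feature_names, levels, cov_names, alpha, beta,
                       sigma2, gamma_star, delta2_star, gamma_hat, delta2_hat)


def combat_transform(m: FeatureMatrix, model: CombatModel, batch: pd.Series,
                     covariates: pd.DataFrame | None = None) -> FeatureMatrix:
    """Apply a fitted ComBat model; output carries the ``harmonized`` state.

    Raises
    ------
    UnseenBatch
        A subject's batch label was not present at fit time.
    FeatureMismatch
        Feature names differ from the fit.
    """
    if m.feature_names != model.feature_names:
        raise FeatureMismatch("feature names differ from the fitted model")
    batch = batch.reindex(m.subjects)
    unseen = sorted(set(batch.dropna().unique()) - set(model.batch_levels))
    if unseen or batch.isna().any():
        raise UnseenBatch(f"batch labels not seen at fit: {unseen or 'missing labels'}")
    if model.covariate_names:
        if covariates is None or list(covariates.columns) != model.covariate_names:
            raise FeatureMismatch("covariates must match the fitted model")
        covariates = covariates.reindex(m.subjects)
        cov_term = covariates.to_numpy(float) @ model.beta
    else:
        cov_term = 0.0

    X = m.values
    stand_mean = model.alpha[None, :] + cov_term
    Z = (X - stand_mean) / np.sqrt(model.sigma2)
    idx = np.array([model.batch_levels.index(b) for b in batch])
    Z_adj = (Z - model.gamma_star[idx]) / np.sqrt(model.delta2_star[idx])
    X_adj = Z_adj * np.sqrt(model.sigma2) + stand_mean
    df = pd.DataFrame(X_adj, index=m.data.index, columns=m.data.columns)
    return m.with_data(df, state="harmonized")


def harmonize(m: FeatureMatrix, batch: pd.Series,
              covariates: pd.DataFrame | None = None) -> tuple[FeatureMatrix, CombatModel]:
    """Fit-and-transform convenience wrapper."""
    model = combat_fit(m, batch, covariates)
    return combat_transform(m, model, batch, covariates), model
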