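"""Parametric empirical-Bayes batch correction (ComBat) across visits.

Proteomic visits assayed years apart form batches with additive and
multiplicative technical shifts. The correction standardizes each
protein given a covariate model (chronological age is preserved),
estimates per-batch location/scale parameters, shrinks them across
proteins with parametric empirical-Bayes priors (normal for locations,
inverse-gamma for scales), removes the shrunken effects and
back-transforms. A final per-protein re-centering restores each
protein's original grand mean exactly (the EB shrinkage otherwise
perturbs it by a small constant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import LongitudinalDataset

__all__ = ["BatchSpec", "CombatCorrector", "combat_adjust",
           "dataset_to_matrix", "matrix_to_dataset"]


@dataclass
class BatchSpec:
    """Batch label per sample plus covariates to preserve."""

    batch: pd.Series  # sample -> batch label
    covariates: pd.DataFrame | None = None  # sample x covariate (e.g. age)
    parametric: bool = True

    def __post_init__(self) -> None:
        counts = self.batch.value_counts()
        if (counts < 1).any():
            raise ValueError("every batch needs at least one sample")
        if not self.parametric:
            raise NotImplementedError("only the parametric variant is provided")


def _eb_iterate(gamma_hat, delta_hat, g_bar, t2, a_prior, b_prior, n_b,
                z_batch, tol=1e-4, max_iter=200):
    """Iterative empirical-Bayes posterior means (location and scale)."""
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * t2 * gamma_hat + delta_star * g_bar) / (
            n_b * t2 + delta_star
        )
        sum2 = ((z_batch - gamma_new[None, :]) ** 2).sum(axis=0)
        delta_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
            np.max(np.abs(delta_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)),
        )
        gamma_star, delta_star = gamma_new, delta_new
        if change < tol:
            break
    return gamma_star, delta_star


class CombatCorrector(BaseEstimator):
    """Fit-and-apply parametric ComBat on a proteins x samples matrix."""

    def __init__(self, parametric: bool = True):
        self.parametric = parametric

    def fit_transform(self, matrix: pd.DataFrame, batch: pd.Series,
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Remove batch location/scale effects, preserving covariates.

        Parameters
        ----------
        matrix : DataFrame, proteins x samples (no missing cells)
        batch : Series, sample -> batch label
        covariates : DataFrame, sample x covariates preserved in the
            standardization model (e.g. chronological age)
        """
        if matrix.isna().any().any():
            raise ValueError("matrix contains missing cells")
        samples = list(matrix.columns)
        batch = batch.loc[samples]
        levels = list(pd.unique(batch))
        counts = batch.value_counts()
        if len(levels) < 2:
            warnings.warn("single batch: nothing to adjust", RuntimeWarning)
            return matrix.copy()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"batches with a single sample: {small}")

        Y = matrix.to_numpy(float)  # G x N
        n_genes, n_samples = Y.shape
        onehot = pd.get_dummies(batch, dtype=float)[levels].to_numpy()  # N x B
        n_b = onehot.sum(axis=0)
        parts = [onehot]
        if covariates is not None:
            cov = covariates.loc[samples].to_numpy(float)
            cov = cov - cov.mean(axis=0, keepdims=True)
            parts.append(cov)
        X = np.column_stack(parts)  # N x (B + q)
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (B+q) x G
        n_batches = len(levels)
        grand_mean = (n_b / n_samples) @ beta[:n_batches]  # per gene
        cov_effect = (X[:, n_batches:] @ beta[n_batches:]).T if X.shape[1] > n_batches \
            else np.zeros_like(Y)
        resid = Y - (X @ beta).T
        sigma2 = (resid ** 2).mean(axis=1)  # pooled per-gene variance (MLE)
        sigma = np.sqrt(np.maximum(sigma2, 1e-12))

        Z = (Y - grand_mean[:, None] - cov_effect) / sigma[:, None]

        adjusted = Z.copy()
        for b, level in enumerate(levels):
            mask = (batch == level).to_numpy()
            zb = Z[:, mask]  # G x n_b
            gamma_hat = zb.mean(axis=1)
            delta_hat = zb.var(axis=1, ddof=1)
            g_bar = gamma_hat.mean()
            t2 = gamma_hat.var(ddof=1)
            v = delta_hat.mean()
            s2 = delta_hat.var(ddof=1)
            a_prior = (2.0 * s2 + v ** 2) / s2
            b_prior = (v * s2 + v ** 3) / s2
            gamma_star, delta_star = _eb_iterate(
                gamma_hat, delta_hat, g_bar, t2, a_prior, b_prior,
                float(mask.sum()), zb.T,
            )
            adjusted[:, mask] = (zb - gamma_star[:, None]) / np.sqrt(
                delta_star
            )[:, None]

        out = adjusted * sigma[:, None] + grand_mean[:, None] + cov_effect
        # restore each protein's grand mean exactly
        out += (Y.mean(axis=1) - out.mean(axis=1))[:, None]
        result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
        self.batch_levels_ = levels
        return result


def combat_adjust(matrix: pd.DataFrame, spec: BatchSpec) -> pd.DataFrame:
    """Functional wrapper over :class:`CombatCorrector`."""
    corrector = CombatCorrector(parametric=spec.parametric)
    return corrector.fit_transform(matrix, spec.batch, spec.covariates)


# -----------------------------------------------------------------------------
# longitudinal dataset <-> matrix plumbing (batch = visit)


def dataset_to_matrix(dataset: LongitudinalDataset):
    """Pivot to a proteins x (subject, visit) matrix plus batch/age specs.

    Returns ``(matrix, batch, covariates)`` where samples are
    (subject, visit) pairs, the batch label is the visit index and the
    covariate table carries the age at sampling.
    """
    obs = dataset.observations
    wide = obs.pivot_table(index="protein_id",
                           columns=["subject_id", "visit"], values="value")
    if wide.isna().any().any():
        raise ValueError("dataset is not complete across proteins and visits")
    sample_index = wide.columns
    meta = obs.drop_duplicates(["subject_id", "visit"]).set_index(
        ["subject_id", "visit"]
    )
    batch = pd.Series([v for (_, v) in sample_index], index=sample_index,
                      name="batch")
    ages = pd.DataFrame({"age": meta.loc[sample_index, "age"].to_numpy()},
                        index=sample_index)
    return wide, batch, ages


def matrix_to_dataset(matrix: pd.DataFrame,
                      template: LongitudinalDataset) -> LongitudinalDataset:
    """Rebuild a long dataset from an adjusted matrix, keeping ages."""
    long = matrix.stack([0, 1], future_stack=True).rename("value").reset_index()
    long.columns = ["protein_id", "subject_id", "visit", "value"]
    ages = template.observations.drop_duplicates(
        ["subject_id", "visit"])[["subject_id", "visit", "age"]]
    merged = long.merge(ages, on=["subject_id", "visit"], how="left")
    return LongitudinalDataset(merged[["subject_id", "visit", "age",
                                       "protein_id", "value"]])
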