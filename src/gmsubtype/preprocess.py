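"""Covariate adjustment of ROI volumes.

Two operations feed the rest of the pipeline:

* :func:`residualize` — per-ROI ordinary least squares of volume on
  nuisance covariates (center of origin as indicator-coded factor, ICV
  as continuous).  The residuals are the clustering input.
* :func:`zscore_vs_reference` — cluster-wise z-profiles of residuals
  (adjusted for ICV, center and age) against a reference cluster,
  with a below-threshold atrophy mask (default z < -0.5, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_Z_COVARIATES = ("icv", "center", "age")


class RankDeficientDesignError(ValueError):
    """The covariate design matrix is rank deficient (collinear)."""


@dataclass
class ResidualMatrix:
    """Subjects x ROIs residual volumes plus the fitted adjustment model."""

    values: pd.DataFrame           # subjects x ROIs, mm^3, centered
    covariates: tuple[str, ...]    # covariate names adjusted for
    design_columns: tuple[str, ...]
    coefficients: pd.DataFrame     # design columns x ROIs

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="subject_id",
                           float_format="%.17g")


@dataclass
class ZProfile:
    """Clusters x ROIs z-scores against a reference cluster."""

    z: pd.DataFrame                # index: cluster label, columns: ROI names
    reference: int
    threshold: float
    mask: pd.DataFrame = field(init=False)  # True where z < threshold (strict)

    def __post_init__(self) -> None:
        self.mask = self.z < self.threshold

    def to_csv(self, path) -> None:
        self.z.to_csv(path, index_label="cluster", float_format="%.17g")

    def mask_table(self) -> pd.DataFrame:
        """Long-form (cluster, ROI, below_threshold) table."""
        long = self.mask.stack().reset_index()
        long.columns = ["cluster", "roi", "below_threshold"]
        return long


def _design_matrix(cohort: pd.DataFrame,
                   covariates) -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous columns + drop-first dummies for categoricals.

    Constant covariates (single-level center, constant ICV) carry no
    information and are dropped rather than treated as an error, so an
    intercept-only fit (mean centering) falls out naturally.  Continuous
    covariates are standardized internally for numerical conditioning
    (ICV is ~10^6 mm^3); the residuals are unaffected and the reported
    coefficients are back-transformed to the original scale.
    """
    n = len(cohort)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    scales: list[tuple[float, float]] = [(0.0, 1.0)]  # (mean, sd) per column
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate column not found: {cov!r}")
        s = cohort[cov]
        if s.isna().any():
            bad = cohort.loc[s.isna(), "subject_id"].tolist() \
                if "subject_id" in cohort.columns else list(cohort.index[s.isna()])
            raise ValueError(f"covariate {cov!r} missing for subjects: {bad}")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s))
            for lev in levels[1:]:  # drop first level
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
                scales.append((0.0, 1.0))
        else:
            x = s.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue  # constant: no adjustment possible or needed
            mu, sd = x.mean(), x.std()
            cols.append((x - mu) / sd)
            names.append(cov)
            scales.append((mu, sd))
    return np.column_stack(cols), names, scales


def residualize(cohort: pd.DataFrame,
                roi_names,
                covariates=("center", "icv")) -> ResidualMatrix:
    """Residuals of each ROI volume after OLS on the given covariates.

    Fits one multiple linear regression per ROI (shared design matrix)
    with an intercept; returns centered residuals and the coefficient
    table.  Raises :class:`RankDeficientDesignError` if the covariates
    are collinear.
    """
    roi_names = list(roi_names)
    missing = [r for r in roi_names if r not in cohort.columns]
    if missing:
        raise KeyError(f"ROI columns not found in cohort: {missing}")
    X, design_names, scales = _design_matrix(cohort, covariates)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} subjects cannot identify {k} model parameters")
    if np.linalg.matrix_rank(X) < k:
        raise RankDeficientDesignError(
            f"design matrix with columns {design_names} is rank deficient")
    Y = cohort[roi_names].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("ROI volumes contain missing values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    values = pd.DataFrame(resid, index=cohort.index, columns=roi_names)
    # back-transform coefficients to the covariates' original units
    beta_orig = beta.copy()
    for j, (mu, sd) in enumerate(scales):
        if j == 0:
            continue
        beta_orig[j] = beta[j] / sd
        beta_orig[0] -= beta[j] * mu / sd
    coef = pd.DataFrame(beta_orig, index=design_names, columns=roi_names)
    return ResidualMatrix(values=values, covariates=tuple(covariates),
                          design_columns=tuple(design_names), coefficients=coef)


def zscore_vs_reference(cohort: pd.DataFrame,
                        roi_names,
                        labels,
                        reference: int,
                        covariates=DEFAULT_Z_COVARIATES,
                        threshold: float = -0.5,
                        sd_mode: str = "reference") -> ZProfile:
    """Cluster-wise ROI z-profiles against a reference cluster.

    All subjects are pooled for the covariate residualization, then for
    each cluster and ROI::

        z = (cluster mean residual - reference mean residual) / SD

    where SD is the reference cluster's residual SD (``sd_mode =
    "reference"``, the default, treating the reference as the normative
    group) or the whole-sample residual SD (``sd_mode = "pooled"``).
    The mask flags z strictly below ``threshold``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels length does not match cohort")
    if sd_mode not in ("reference", "pooled"):
        raise ValueError(f"unknown sd_mode: {sd_mode!r}")
    ref_rows = labels == reference
    if ref_rows.sum() < 3:
        raise ValueError(f"reference cluster {reference} has fewer than 3 members")
    rm = residualize(cohort, roi_names, covariates)
    resid = rm.values.to_numpy()
    ref_mean = resid[ref_rows].mean(axis=0)
    if sd_mode == "reference":
        sd = resid[ref_rows].std(axis=0, ddof=1)
    else:
        sd = resid.std(axis=0, ddof=1)
    zero_sd = np.flatnonzero(sd == 0)
    if zero_sd.size:
        raise ValueError(
            f"zero residual SD for ROIs: {[rm.roi_names[j] for j in zero_sd]}")
    clusters = np.unique(labels)
    z = np.empty((clusters.size, resid.shape[1]))
    for i, c in enumerate(clusters):
        z[i] = (resid[labels == c].mean(axis=0) - ref_mean) / sd
    zdf = pd.DataFrame(z, index=pd.Index(clusters, name="cluster"),
                       columns=rm.roi_names)
    return ZProfile(z=zdf, reference=reference, threshold=threshold)
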