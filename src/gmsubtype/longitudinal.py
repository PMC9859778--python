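"""Linear mixed models for MMSE trajectories by subtype.

MMSE at months 0/12/24/36 is modelled with fixed effects for cluster,
visit (categorical) and their interaction, a random intercept per
subject, and restricted maximum likelihood.  Estimated marginal means
(EMMs) per cluster x visit are model-based cell means with any
covariate (e.g. WMH) held at its sample mean; pairwise cluster
contrasts per visit use Wald z tests on the fixed-effect covariance.

The statsmodels-style entry point is :class:`MMSETrajectoryModel`;
:func:`fit_mmse_lmm` is the functional equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sps
import statsmodels.formula.api as smf

from .simulate import MMSE_COLUMNS, MMSE_MONTHS


class ConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


def cohort_to_visits(cohort: pd.DataFrame, labels) -> pd.DataFrame:
    """Wide cohort MMSE columns -> long visit records.

    Returns one row per observed subject-visit with columns
    ``subject_id, cluster, month, mmse`` plus ``wmh`` and ``age`` when
    present; visits with missing MMSE are dropped.
    """
    labels = np.asarray(labels)
    frames = []
    for month, col in zip(MMSE_MONTHS, MMSE_COLUMNS):
        if col not in cohort.columns:
            continue
        sub = pd.DataFrame({
            "subject_id": cohort["subject_id"].to_numpy(),
            "cluster": labels,
            "month": month,
            "mmse": cohort[col].to_numpy(dtype=float),
        })
        for extra in ("wmh", "age"):
            if extra in cohort.columns:
                sub[extra] = cohort[extra].to_numpy(dtype=float)
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    return long[long["mmse"].notna()].reset_index(drop=True)


@dataclass
class MMSETrajectoryResults:
    """Fitted trajectory model: estimates, EMMs and contrasts."""

    fixed_effects: pd.DataFrame       # estimate, se, z, p per fixed effect
    subject_intercept_var: float
    residual_var: float
    emm: pd.DataFrame                 # cluster, month, emm, se
    converged: bool
    adjust_for_wmh: bool
    n_subjects: int
    n_observations: int
    _fe_cov: pd.DataFrame = field(repr=False, default=None)
    _design_builder: object = field(repr=False, default=None)
    _covariate_means: dict = field(repr=False, default_factory=dict)

    def _cell_row(self, cluster, month) -> np.ndarray:
        new = {"cluster": [cluster], "month": [month]}
        for name, value in self._covariate_means.items():
            new[name] = [value]
        X = dmatrix(self._design_builder, new, return_type="dataframe")
        return X.to_numpy()[0]

    def contrast(self, cluster_a, cluster_b, month) -> dict:
        """EMM difference cluster_a - cluster_b at one visit (Wald z)."""
        x = self._cell_row(cluster_a, month) - self._cell_row(cluster_b, month)
        beta = self.fixed_effects["estimate"].to_numpy()
        diff = float(x @ beta)
        se = float(np.sqrt(x @ self._fe_cov.to_numpy() @ x))
        z = diff / se if se > 0 else np.nan
        return {"cluster_a": cluster_a, "cluster_b": cluster_b, "month": month,
                "diff": diff, "se": se, "z": z,
                "p_value": float(2 * sps.norm.sf(abs(z)))}

    def summary(self) -> str:
        lines = ["MMSE trajectory linear mixed model (REML)",
                 f"  subjects: {self.n_subjects}, observations: "
                 f"{self.n_observations}",
                 f"  subject intercept variance: "
                 f"{self.subject_intercept_var:.3f}",
                 f"  residual variance: {self.residual_var:.3f}",
                 f"  WMH adjusted: {self.adjust_for_wmh}", "",
                 "Fixed effects:",
                 self.fixed_effects.to_string(float_format="%.3f"), "",
                 "Estimated marginal means:",
                 self.emm.to_string(index=False, float_format="%.2f")]
        return "\n".join(lines)


def fit_mmse_lmm(visits: pd.DataFrame,
                 adjust_for_wmh: bool = False) -> MMSETrajectoryResults:
    """Fit the random-intercept LMM of MMSE on cluster x visit.

    ``visits`` is long format with columns ``subject_id, cluster,
    month, mmse`` (and ``wmh`` when ``adjust_for_wmh``).  Raises
    :class:`ConvergenceError` when the optimizer fails; a variance
    component estimated at the boundary produces a warning but the fit
    is retained.
    """
    d = visits.copy()
    required = {"subject_id", "cluster", "month", "mmse"}
    if not required <= set(d.columns):
        raise ValueError(f"visits table needs columns {sorted(required)}")
    d = d[d["mmse"].notna()]
    if d.duplicated(["subject_id", "month"]).any():
        raise ValueError("at most one record per subject and visit")
    if ((d["mmse"] < 0) | (d["mmse"] > 30)).any():
        raise ValueError("MMSE values must lie in [0, 30]")
    if d["cluster"].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    if d["month"].nunique() < 2:
        raise ValueError("need at least 2 visits with data")

    formula = "mmse ~ C(cluster) * C(month)"
    covariate_means: dict[str, float] = {}
    if adjust_for_wmh:
        if "wmh" not in d.columns or d["wmh"].isna().any():
            raise ValueError("adjust_for_wmh requires complete wmh values")
        formula += " + wmh"
        covariate_means["wmh"] = float(d["wmh"].mean())

    model = smf.mixedlm(formula, data=d, groups=d["subject_id"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"mixed-model fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(
            "mixed-model optimizer did not converge; "
            f"optimizer messages: {[str(w.message) for w in caught]}")
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    if re_var <= 1e-8 * res.scale:
        warnings.warn("subject intercept variance estimated at the boundary "
                      "(~0); fit retained")

    fe_names = list(res.fe_params.index)
    fixed = pd.DataFrame({
        "estimate": res.fe_params,
        "se": res.bse_fe,
        "z": res.fe_params / res.bse_fe,
    })
    fixed["p_value"] = 2 * sps.norm.sf(np.abs(fixed["z"]))
    fe_cov = res.cov_params().loc[fe_names, fe_names]

    result = MMSETrajectoryResults(
        fixed_effects=fixed,
        subject_intercept_var=re_var,
        residual_var=float(res.scale),
        emm=pd.DataFrame(),
        converged=bool(res.converged),
        adjust_for_wmh=adjust_for_wmh,
        n_subjects=d["subject_id"].nunique(),
        n_observations=len(d),
        _fe_cov=fe_cov,
        _design_builder=model.data.design_info,
        _covariate_means=covariate_means,
    )
    rows = []
    for c in sorted(d["cluster"].unique()):
        for m in sorted(d["month"].unique()):
            x = result._cell_row(c, m)
            emm = float(x @ res.fe_params.to_numpy())
            se = float(np.sqrt(x @ fe_cov.to_numpy() @ x))
            rows.append({"cluster": c, "month": m, "emm": emm, "se": se})
    result.emm = pd.DataFrame(rows)
    return result


def trajectory_contrasts(result: MMSETrajectoryResults) -> pd.DataFrame:
    """All pairwise cluster EMM differences per visit, plus growth flags.

    Returns one row per (cluster pair, visit) with the Wald z test, and
    per pair two monotonicity flags: whether |difference| grows
    strictly / non-decreasingly over the visits.
    """
    clusters = sorted(result.emm["cluster"].unique())
    months = sorted(result.emm["month"].unique())
    rows = []
    for a, b in combinations(clusters, 2):
        diffs = []
        for m in months:
            row = result.contrast(a, b, m)
            rows.append(row)
            diffs.append(abs(row["diff"]))
        strict = all(d2 > d1 for d1, d2 in zip(diffs, diffs[1:]))
        weak = all(d2 >= d1 for d1, d2 in zip(diffs, diffs[1:]))
        for row in rows[-len(months):]:
            row["pair_abs_diff_strictly_increasing"] = strict
            row["pair_abs_diff_nondecreasing"] = weak
    return pd.DataFrame(rows)


class MMSETrajectoryModel:
    """Model object for MMSE decline by subtype (statsmodels-style).

    Parameters
    ----------
    visits : long-format DataFrame (``subject_id, cluster, month, mmse``
        and optional covariates).
    adjust_for_wmh : include WMH burden as a fixed covariate.
    """

    def __init__(self, visits: pd.DataFrame, adjust_for_wmh: bool = False):
        self.visits = visits
        self.adjust_for_wmh = adjust_for_wmh

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, labels,
                    adjust_for_wmh: bool = False) -> "MMSETrajectoryModel":
        return cls(cohort_to_visits(cohort, labels), adjust_for_wmh)

    def fit(self) -> MMSETrajectoryResults:
        return fit_mmse_lmm(self.visits, adjust_for_wmh=self.adjust_for_wmh)


def plot_trajectories(result: MMSETrajectoryResults, path=None):
    """EMM-versus-month plot with standard-error bars, one line per cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c, sub in result.emm.groupby("cluster"):
        ax.errorbar(sub["month"], sub["emm"], yerr=sub["se"],
                    marker="o", capsize=3, label=f"cluster {c}")
    ax.set_xlabel("month")
    ax.set_ylabel("MMSE (estimated marginal mean)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
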