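"""Statsmodels-style model objects for the subtyping analysis.

:class:`SubtypeModel` holds a cohort table and an ROI schema;
``fit(seed)`` runs residualization, random-forest proximity, average
linkage and Calinski-Harabasz model selection, and returns a
:class:`SubtypeResults` carrying labels, the CH curve, ROI importance
and the supervised-discrimination summary.  Characterization
(z-profiles, ANCOVA/FDR, ratio, comparison battery), stability
assessment and the longitudinal model hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rfclust, stats as gstats
from .longitudinal import MMSETrajectoryModel, MMSETrajectoryResults
from .preprocess import ResidualMatrix, ZProfile, residualize, zscore_vs_reference
from .schema import ROISchema, default_schema


class SubtypeModel:
    """Gray-matter subtype discovery model for a subjects x ROI cohort.

    Parameters
    ----------
    cohort : DataFrame with one row per subject, the schema's ROI
        volume columns, and nuisance covariates.
    schema : ROI schema naming the volume columns; defaults to the
        canonical 96-ROI layout.
    covariates : nuisance covariates removed before clustering
        (default center of origin and intracranial volume).
    n_trees, forest_repeats : random-forest size; the proximity matrix
        averages ``forest_repeats`` forests of ``n_trees`` trees.
    k_range : candidate cluster counts for CH selection.
    """

    def __init__(self, cohort: pd.DataFrame, schema: ROISchema | None = None,
                 covariates=("center", "icv"),
                 n_trees: int = rfclust.DEFAULT_N_TREES,
                 forest_repeats: int = rfclust.DEFAULT_FOREST_REPEATS,
                 k_range=rfclust.DEFAULT_K_RANGE,
                 dissimilarity_transform: str = "sqrt",
                 top_k: int = 10):
        self.cohort = cohort
        self.schema = schema if schema is not None else default_schema()
        self.covariates = tuple(covariates)
        self.n_trees = n_trees
        self.forest_repeats = forest_repeats
        self.k_range = tuple(k_range)
        self.dissimilarity_transform = dissimilarity_transform
        self.top_k = top_k

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "SubtypeModel":
        return cls(cohort, **kwargs)

    def residualize(self) -> ResidualMatrix:
        return residualize(self.cohort, self.schema.names, self.covariates)

    def fit(self, seed: int = 0) -> "SubtypeResults":
        residuals = self.residualize()
        prox = rfclust.rf_proximity(residuals, n_trees=self.n_trees,
                                    seed=seed,
                                    forest_repeats=self.forest_repeats)
        diss = rfclust.proximity_to_dissimilarity(
            prox, transform=self.dissimilarity_transform)
        tree = rfclust.average_linkage(diss)
        solution = rfclust.select_k(tree, residuals, k_range=self.k_range)
        importance = rfclust.gini_importance(
            residuals, solution.labels, n_trees=self.n_trees, seed=seed + 1,
            top_k=self.top_k)
        discrimination = rfclust.supervised_discrimination(
            residuals.values[importance.top], solution.labels,
            n_trees=self.n_trees, seed=seed + 2)
        solution.provenance = {"seed": seed, "n_trees": self.n_trees,
                               "forest_repeats": self.forest_repeats,
                               "covariates": self.covariates,
                               "transform": self.dissimilarity_transform}
        return SubtypeResults(model=self, seed=seed, residuals=residuals,
                              proximity=prox, tree=tree, solution=solution,
                              importance=importance,
                              discrimination=discrimination)


@dataclass
class SubtypeResults:
    """Fitted subtype solution and downstream characterization methods."""

    model: SubtypeModel
    seed: int
    residuals: ResidualMatrix
    proximity: rfclust.ProximityMatrix
    tree: rfclust.LinkageTree
    solution: rfclust.ClusterSolution
    importance: rfclust.ImportanceRanking
    discrimination: rfclust.DiscriminationSummary
    _stability: rfclust.StabilityReport | None = field(default=None, repr=False)

    # -- accessors --------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.solution.labels

    @property
    def chosen_k(self) -> int:
        return self.solution.chosen_k

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    # -- characterization -------------------------------------------
    def z_profile(self, reference: int | None = None,
                  threshold: float = -0.5,
                  sd_mode: str = "reference") -> ZProfile:
        """Cluster z-profiles vs a reference cluster (default: the one
        with the largest mean cortical residual, i.e. most preserved)."""
        if reference is None:
            cortical = self.model.schema.cortical
            means = {int(c): self.residuals.values.loc[self.labels == c,
                                                       cortical].mean().mean()
                     for c in np.unique(self.labels)}
            reference = max(means, key=means.get)
        return zscore_vs_reference(self.model.cohort, self.model.schema.names,
                                   self.labels, reference=reference,
                                   threshold=threshold, sd_mode=sd_mode)

    def ancova(self, alpha: float = 0.05) -> gstats.AncovaTable:
        """Per-ROI cluster ANCOVA (age-adjusted, on center/ICV residuals)."""
        return gstats.ancova_per_roi(self.residuals.values, self.labels,
                                     self.model.cohort["age"], alpha=alpha)

    def bg_ratio(self) -> gstats.RatioResult:
        return gstats.bg_cortical_ratio(self.model.cohort, self.model.schema,
                                        labels=self.labels)

    def characterize(self) -> list[gstats.GroupComparisonResult]:
        return gstats.characterize_table(self.model.cohort, self.labels)

    def stability(self, n_repeats: int = 100,
                  n_trees: int | None = None,
                  forest_repeats: int | None = None) -> rfclust.StabilityReport:
        self._stability = rfclust.stability_assessment(
            self.residuals, self.proximity, n_repeats=n_repeats,
            base_seed=self.seed, n_trees=n_trees,
            forest_repeats=forest_repeats)
        return self._stability

    def longitudinal(self, adjust_for_wmh: bool = False) -> MMSETrajectoryResults:
        return MMSETrajectoryModel.from_cohort(
            self.model.cohort, self.labels,
            adjust_for_wmh=adjust_for_wmh).fit()

    # -- reporting --------------------------------------------------
    def summary(self) -> str:
        ch = self.solution.ch_table()
        sizes = self.cluster_sizes()
        lines = [
            "Gray-matter subtype clustering (RF proximity + average linkage)",
            f"  subjects: {self.proximity.n}, ROIs: "
            f"{len(self.residuals.roi_names)}",
            f"  forest: {self.proximity.n_trees} trees x "
            f"{self.proximity.forest_repeats} repeats, seed {self.seed}",
            f"  chosen K = {self.chosen_k} "
            f"(CH = {self.solution.ch_by_k[self.chosen_k]:.2f})",
            "  cluster sizes: "
            + ", ".join(f"C{c}={n}" for c, n in sizes.items()),
            "",
            "Calinski-Harabasz index by K:",
            ch.to_string(index=False, float_format="%.2f"),
            "",
            f"Top {self.importance.top_k} discriminating ROIs "
            f"(mean decrease in Gini):",
        ]
        top = self.importance.to_frame().sort_values("rank").head(
            self.importance.top_k)
        lines.append(top.to_string(index=False, float_format="%.4f"))
        lines.append("")
        lines.append(f"OOB accuracy of reduced supervised forest: "
                     f"{self.discrimination.oob_accuracy:.3f}")
        return "\n".join(lines)
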