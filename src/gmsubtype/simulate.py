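"""Synthetic dementia-with-Lewy-bodies cohort generator.

Generates seeded cohorts with planted gray-matter subtype structure so
that the clustering, characterization and longitudinal stages can be
exercised and validated end to end.  The defaults emulate a 165-patient
multicenter DLB cohort with three latent subtypes:

* cluster 1 — *cortical predominant*: oldest patients, diffusely
  reduced cortical volumes, worst baseline cognition and fastest
  cognitive decline;
* cluster 2 — *fronto-occipital predominant*: intermediate age and
  volumes with extra atrophy in frontal and occipital lobes;
* cluster 3 — *subcortical predominant*: youngest patients, preserved
  cortex, hence proportionally low basal-ganglia/cortical volume ratio,
  highest frequency of cognitive fluctuations and stable cognition.

ROI volumes follow a log-normal multiplicative model: a per-ROI
baseline volume is scaled by head size (ICV), a center-of-origin
offset, an age effect on cortical regions, the planted subtype effect,
and residual noise.  Subtype effects are expressed in units of the
residual log-volume noise SD, i.e. in within-cluster SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import ROISchema, default_schema

MMSE_MONTHS = (0, 12, 24, 36)
MMSE_COLUMNS = tuple(f"mmse_{m:02d}" for m in MMSE_MONTHS)
CLINICAL_BINARIES = ("vh", "cf", "parkinsonism", "rbd", "apoe4", "ad_copath")

#: mean single-hemisphere baseline volumes, mm^3 (cortical ~452 cm^3
#: bilateral total; basal ganglia sized for a ~0.031 BG/cortical ratio)
_BASELINE_MM3: dict[str, float] = {
    "Precentral": 9500, "Frontal_Sup": 10500, "Frontal_Sup_Orb": 2600,
    "Frontal_Mid": 13500, "Frontal_Mid_Orb": 2400, "Frontal_Inf_Oper": 3100,
    "Frontal_Inf_Tri": 5600, "Frontal_Inf_Orb": 4600, "Rolandic_Oper": 3000,
    "Supp_Motor_Area": 6200, "Olfactory": 900, "Frontal_Sup_Medial": 8600,
    "Frontal_Med_Orb": 2200, "Rectus": 2300, "Frontal_Pole": 3500,
    "Insula": 5200, "Cingulum_Ant": 4000, "Cingulum_Mid": 5700,
    "Cingulum_Post": 1400, "Parahippocampal": 3100, "Calcarine": 6300,
    "Cuneus": 4300, "Lingual": 6400, "Occipital_Sup": 3900,
    "Occipital_Mid": 9200, "Occipital_Inf": 2700, "Occipital_Pole": 3200,
    "Fusiform": 6900, "Postcentral": 10900, "Parietal_Sup": 5900,
    "Parietal_Inf": 6800, "SupraMarginal": 5400, "Angular": 5100,
    "Precuneus": 9900, "Paracentral_Lobule": 3800, "Heschl": 1300,
    "Temporal_Sup": 6900, "Temporal_Pole_Sup": 3600, "Temporal_Mid": 13500,
    "Temporal_Pole_Mid": 2300, "Temporal_Inf": 9800,
    # subcortical
    "Hippocampus": 3500, "Amygdala": 1400, "Caudate": 2800,
    "Putamen": 3300, "Pallidum": 906, "Thalamus": 6500,
    # brainstem (unpaired)
    "Midbrain": 6500, "Pons": 14000,
}


class SpecValidationError(ValueError):
    """Raised when a SimulationSpec field fails validation."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{fieldname}: {msg}")


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort.

    Cluster-indexed sequences are ordered cluster 1, 2, 3 (or however
    many clusters ``n_per_cluster`` defines).  Atrophy effects are mean
    shifts of log ROI volume in units of ``noise_sd`` (within-cluster
    SDs); negative values mean smaller volumes.
    """

    n_per_cluster: Sequence[int] = (49, 76, 40)

    # planted atrophy: per-cluster shifts by ROI class, lobe, and single
    # ROI, in units of noise_sd.  Defaults put cluster 1 ~-0.18 log
    # (-18%/exp) uniformly across cortex and concentrate cluster 2's
    # deficit in frontal+occipital lobes, so that the cluster-mean
    # BG/cortical ratios land near 0.037 / 0.034 / 0.030.
    atrophy_effects: Sequence[Mapping[str, float]] = (
        {"cortical": -4.0, "subcortical": 0.0, "brainstem": 0.0},
        {"cortical": -0.35, "subcortical": 0.0, "brainstem": 0.0},
        {"cortical": 0.0, "subcortical": 0.0, "brainstem": 0.0},
    )
    lobe_effects: Sequence[Mapping[str, float]] = (
        {},
        {"frontal": -3.85, "occipital": -3.85},
        {},
    )
    roi_effects: Sequence[Mapping[str, float]] = (
        {"Olfactory_R": -2.0},
        {"Cingulum_Mid_L": -3.3},
        {},
    )

    # centers: names, multiplicative (log) volume offsets, per-cluster mix
    center_names: Sequence[str] = ("Mayo", "Prague", "Strasbourg", "Amsterdam")
    center_log_offsets: Sequence[float] = (0.0, 0.03, -0.03, 0.015)
    center_mix: Sequence[Sequence[float]] = (
        (28, 14, 4, 3),
        (26, 12, 15, 23),
        (14, 3, 15, 8),
    )

    icv_mean: float = 1_450_000.0  # mm^3
    icv_sd: float = 130_000.0

    age_means: Sequence[float] = (73.43, 69.05, 63.68)
    age_sds: Sequence[float] = (8.02, 7.52, 8.23)
    age_ref: float = 70.0
    age_log_slope_cortical: float = -0.001  # log-volume per year of age

    sex_male_freq: Sequence[float] = (0.714, 0.789, 0.600)
    education_means: Sequence[float] = (15.02, 13.24, 12.60)
    education_sds: Sequence[float] = (3.61, 3.90, 3.80)

    # per-cluster Bernoulli frequencies, from available-case counts
    clinical_frequencies: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "vh": (0.660, 0.520, 0.475),
            "cf": (0.711, 0.851, 0.947),
            "parkinsonism": (0.915, 0.895, 0.775),
            "rbd": (0.778, 0.814, 0.714),
            "apoe4": (0.367, 0.528, 0.342),
            "ad_copath": (0.069, 0.150, 0.061),
        }
    )

    wmh_means: Sequence[float] = (21.37, 14.55, 12.43)  # cm^3
    wmh_sds: Sequence[float] = (15.41, 13.13, 7.96)

    mmse_baseline_means: Sequence[float] = (21.57, 22.93, 24.50)
    mmse_baseline_sds: Sequence[float] = (5.49, 5.27, 4.38)
    mmse_annual_slopes: Sequence[float] = (-2.5, -1.5, -0.5)
    mmse_visit_noise_sd: float = 1.5
    visit_retention: Sequence[float] = (0.994, 0.588, 0.461, 0.182)

    noise_sd: float = 0.045  # residual log-volume noise
    roi_correlation: float = 0.0  # exchangeable within-subject noise correlation
    seed: int = 0

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        k = len(self.n_per_cluster)
        _check(k >= 1, "n_per_cluster", "needs at least one cluster")
        _check(all(int(n) == n and n >= 2 for n in self.n_per_cluster),
               "n_per_cluster", "all counts must be integers >= 2")
        for name in ("atrophy_effects", "lobe_effects", "roi_effects",
                     "center_mix", "age_means", "age_sds", "sex_male_freq",
                     "education_means", "education_sds", "wmh_means",
                     "wmh_sds", "mmse_baseline_means", "mmse_baseline_sds",
                     "mmse_annual_slopes"):
            _check(len(getattr(self, name)) == k, name,
                   f"needs one entry per cluster ({k})")
        _check(len(self.center_names) == len(self.center_log_offsets),
               "center_log_offsets", "must match center_names length")
        for row in self.center_mix:
            _check(len(row) == len(self.center_names), "center_mix",
                   "each row must match center_names length")
            _check(all(w >= 0 for w in row) and sum(row) > 0, "center_mix",
                   "weights must be non-negative with positive sum")
        for name in ("age_sds", "education_sds", "wmh_sds",
                     "mmse_baseline_sds"):
            _check(all(s > 0 for s in getattr(self, name)), name, "SDs must be > 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.mmse_visit_noise_sd >= 0, "mmse_visit_noise_sd", "must be >= 0")
        _check(0.0 <= self.roi_correlation < 1.0, "roi_correlation",
               "must be in [0, 1)")
        _check(self.icv_mean > 0 and self.icv_sd >= 0, "icv_distribution",
               "mean must be > 0 and SD >= 0")
        for feat, freqs in self.clinical_frequencies.items():
            _check(len(freqs) == k, f"clinical_frequencies[{feat}]",
                   f"needs one entry per cluster ({k})")
            _check(all(0.0 <= f <= 1.0 for f in freqs),
                   f"clinical_frequencies[{feat}]", "frequencies must be in [0, 1]")
        _check(all(0.0 <= f <= 1.0 for f in self.sex_male_freq),
               "sex_male_freq", "frequencies must be in [0, 1]")
        _check(len(self.visit_retention) == len(MMSE_MONTHS), "visit_retention",
               f"needs {len(MMSE_MONTHS)} per-visit probabilities")
        _check(all(0.0 <= p <= 1.0 for p in self.visit_retention),
               "visit_retention", "probabilities must be in [0, 1]")
        _check(all(s > 0 for s in (self.mmse_baseline_sds)), "mmse_baseline_sds",
               "SDs must be > 0")
        for c, sd in enumerate(self.mmse_baseline_sds):
            _check(sd > self.mmse_visit_noise_sd,
                   "mmse_baseline_sds",
                   f"cluster {c + 1} baseline SD must exceed the visit noise SD")

    @property
    def n_clusters(self) -> int:
        return len(self.n_per_cluster)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_cluster))

    def to_dict(self) -> dict:
        return asdict(self)


def planted_design(spec: SimulationSpec) -> np.ndarray:
    """Ground-truth cluster labels (1-based) in generation order."""
    spec.validate()
    return np.repeat(np.arange(1, spec.n_clusters + 1),
                     np.asarray(spec.n_per_cluster, dtype=int))


def _clipped_normal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Mean of clip(N(mu, sigma^2), lo, hi)."""
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return (lo * stats.norm.cdf(a)
            + hi * stats.norm.sf(b)
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            - sigma * (stats.norm.pdf(b) - stats.norm.pdf(a)))


def _compensated_mmse_mean(target: float, sigma: float) -> float:
    """Latent mean whose [0, 30]-clipped normal has the target mean.

    MMSE is bounded at 30, so an uncompensated normal draw would be
    biased low after clipping; this keeps the observed baseline mean on
    target.
    """
    f = lambda mu: _clipped_normal_mean(mu, sigma, 0.0, 30.0) - target
    return optimize.brentq(f, target - 1.0, target + 3.0 * sigma, xtol=1e-10)


def _log_shift_matrix(spec: SimulationSpec, schema: ROISchema) -> np.ndarray:
    """Per-cluster x per-ROI planted log-volume shifts (clusters x 96)."""
    shifts = np.zeros((spec.n_clusters, len(schema)))
    for c in range(spec.n_clusters):
        class_eff = spec.atrophy_effects[c]
        lobe_eff = spec.lobe_effects[c]
        roi_eff = spec.roi_effects[c]
        for j, roi in enumerate(schema):
            e = class_eff.get(roi.roi_class, 0.0)
            e += lobe_eff.get(roi.lobe, 0.0)
            e += roi_eff.get(roi.name, 0.0)
            shifts[c, j] = e * spec.noise_sd
    return shifts


def simulate_cohort(spec: SimulationSpec | None = None,
                    schema: ROISchema | None = None) -> pd.DataFrame:
    """Generate a cohort table with planted subtype structure.

    Returns a DataFrame with one row per subject: demographics,
    covariates, the 96 ROI volumes (mm^3), binary clinical features,
    longitudinal MMSE columns (``mmse_00`` .. ``mmse_36``, NaN where a
    visit was missed) and the planted label in ``true_cluster``.
    Deterministic given ``spec.seed``.
    """
    spec = spec if spec is not None else SimulationSpec()
    schema = schema if schema is not None else default_schema()
    spec.validate()
    for roi in schema:
        base = roi.name[:-2] if roi.name.endswith(("_L", "_R")) else roi.name
        if base not in _BASELINE_MM3:
            raise SpecValidationError(f"schema: no baseline volume for ROI {roi.name}")

    rng = np.random.default_rng(spec.seed)
    labels = planted_design(spec)
    n = spec.n_total
    p = len(schema)

    base_names = [r.name[:-2] if r.name.endswith(("_L", "_R")) else r.name
                  for r in schema]
    log_base = np.log([_BASELINE_MM3[b] for b in base_names])
    cortical_mask = np.array([r.roi_class == "cortical" for r in schema])
    shifts = _log_shift_matrix(spec, schema)

    rows: dict[str, np.ndarray] = {}
    cluster_idx = labels - 1

    age = np.empty(n)
    sex = np.empty(n, dtype=int)
    education = np.empty(n)
    center_code = np.empty(n, dtype=int)
    wmh = np.empty(n)
    clin = {feat: np.empty(n, dtype=int) for feat in CLINICAL_BINARIES}
    mmse = np.full((n, len(MMSE_MONTHS)), np.nan)

    months = np.asarray(MMSE_MONTHS, dtype=float)
    for c in range(spec.n_clusters):
        idx = np.flatnonzero(cluster_idx == c)
        m = idx.size
        age[idx] = rng.normal(spec.age_means[c], spec.age_sds[c], m)
        sex[idx] = rng.random(m) < spec.sex_male_freq[c]
        education[idx] = np.clip(
            rng.normal(spec.education_means[c], spec.education_sds[c], m), 0, None)
        # centers allocated in fixed proportions (largest-remainder), then
        # shuffled across the cluster's subjects: the center-by-cluster
        # table is deterministic, as in a real multicenter sample
        mix = np.asarray(spec.center_mix[c], dtype=float)
        quota = mix / mix.sum() * m
        counts = np.floor(quota).astype(int)
        remainder = np.argsort(-(quota - counts), kind="stable")
        counts[remainder[: m - counts.sum()]] += 1
        codes = np.repeat(np.arange(len(mix)), counts)
        center_code[idx] = rng.permutation(codes)
        mu_w, sd_w = spec.wmh_means[c], spec.wmh_sds[c]
        shape = (mu_w / sd_w) ** 2
        wmh[idx] = rng.gamma(shape, scale=sd_w ** 2 / mu_w, size=m)
        for feat in CLINICAL_BINARIES:
            clin[feat][idx] = rng.random(m) < spec.clinical_frequencies[feat][c]

        # MMSE: subject-level latent baseline + linear decline + visit noise
        sd_total = spec.mmse_baseline_sds[c]
        sd_subj = math.sqrt(sd_total ** 2 - spec.mmse_visit_noise_sd ** 2)
        mu_lat = _compensated_mmse_mean(spec.mmse_baseline_means[c], sd_total)
        b = rng.normal(mu_lat, sd_subj, m)
        traj = (b[:, None]
                + spec.mmse_annual_slopes[c] * months[None, :] / 12.0
                + rng.normal(0.0, spec.mmse_visit_noise_sd, (m, len(months))))
        mmse[idx] = np.clip(traj, 0.0, 30.0)

    # visit dropout, missing completely at random per visit
    for v, keep_p in enumerate(spec.visit_retention):
        dropped = rng.random(n) >= keep_p
        mmse[dropped, v] = np.nan

    icv = rng.normal(spec.icv_mean, spec.icv_sd, n)
    icv = np.clip(icv, 0.5 * spec.icv_mean, None)

    # ROI volumes, log-normal multiplicative model
    if spec.roi_correlation > 0:
        rho = spec.roi_correlation
        shared = rng.normal(0.0, 1.0, (n, 1))
        eps = (math.sqrt(rho) * shared
               + math.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, (n, p)))
    else:
        eps = rng.normal(0.0, 1.0, (n, p))
    log_v = (log_base[None, :]
             + np.log(icv / spec.icv_mean)[:, None]
             + np.asarray(spec.center_log_offsets)[center_code][:, None]
             + (spec.age_log_slope_cortical
                * (age - spec.age_ref))[:, None] * cortical_mask[None, :]
             + shifts[cluster_idx]
             + spec.noise_sd * eps)
    volumes = np.exp(log_v)

    rows["subject_id"] = np.array([f"S{i + 1:04d}" for i in range(n)])
    rows["center"] = np.asarray(spec.center_names)[center_code]
    rows["age"] = age
    rows["sex"] = sex
    rows["education"] = education
    rows["icv"] = icv
    for feat in CLINICAL_BINARIES:
        rows[feat] = clin[feat]
    rows["wmh"] = wmh
    for v, col in enumerate(MMSE_COLUMNS):
        rows[col] = mmse[:, v]
    rows["true_cluster"] = labels

    df = pd.DataFrame(rows)
    df = pd.concat([df, pd.DataFrame(volumes, columns=schema.names)], axis=1)
    return df
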