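"""Synthetic cohort generation for structural-covariance-network analyses.

Generates voxel-level gray-matter-volume (GMV) data for parcellated
subjects under a latent-factor model with known ground truth, so that every
downstream stage -- regional GMV extraction, individual SCN construction,
graph metrics, classification, attribution, and clinical score prediction
-- can be tested without access to real imaging data.

The generative model for the mean voxel value of subject ``s`` in parcel
``r`` is

    mu[s, r] = baseline[r] + lam[r] . z[s] + eps[s, r]
               + site_offset[site(s), r] / n_vox[r]
               + age/sex terms + global_shift / n_vox[r]

where ``z[s]`` are shared latent factors inducing inter-parcel covariance,
``lam`` is the d x q loading matrix and ``eps`` is a subject-parcel
residual.  Patients additionally receive

* a mean reduction of ``mean_effect`` standard deviations of regional GMV
  on the affected parcels, scaled by a per-patient latent severity, and
* a rotation of the affected parcels' loading vectors by ``cov_effect``
  radians, which alters inter-parcel covariance while preserving each
  parcel's marginal mean and variance (covariance and mean alterations are
  therefore separable).

Voxel values are Gaussian around ``mu[s, r]`` and clipped at zero.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtlasSpec",
    "CohortConfig",
    "ParcellatedSubject",
    "generate_cohort",
    "generate_reference",
    "generate_clinical",
    "generate_edge_features",
    "implied_regional_covariance",
    "write_cohort",
    "read_cohort",
    "write_config",
]

_NETWORK_NAMES = (
    "Visual",
    "SomatoMotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Control",
    "DefaultMode",
)


@dataclass(frozen=True)
class AtlasSpec:
    """Parcellation descriptor: parcel ids 1..d, names, voxel counts and a
    pseudo functional-network assignment (1..7, used for reporting only)."""

    parcel_ids: np.ndarray
    parcel_names: tuple
    voxel_counts: np.ndarray
    network_assignment: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.parcel_ids, dtype=int)
        counts = np.asarray(self.voxel_counts, dtype=int)
        nets = np.asarray(self.network_assignment, dtype=int)
        object.__setattr__(self, "parcel_ids", ids)
        object.__setattr__(self, "voxel_counts", counts)
        object.__setattr__(self, "network_assignment", nets)
        d = len(ids)
        if not np.array_equal(ids, np.arange(1, d + 1)):
            raise ValueError("parcel_ids must be the consecutive integers 1..d")
        if len(self.parcel_names) != d or len(counts) != d or len(nets) != d:
            raise ValueError("parcel_names, voxel_counts and network_assignment "
                             "must all have length d")
        if np.any(counts < 2):
            raise ValueError("every parcel needs at least 2 voxels")

    @property
    def d(self) -> int:
        return len(self.parcel_ids)

    @classmethod
    def create(cls, d: int = 100, voxel_range: tuple = (50, 400),
               seed: int = 0) -> "AtlasSpec":
        """Build a synthetic atlas with ``d`` parcels and uniformly drawn
        voxel counts.  ``d`` defaults to the coarse 100-parcel scheme; 200
        gives the fine scheme; other values are allowed for small fixtures."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(voxel_range[0], voxel_range[1] + 1, size=d)
        nets = rng.integers(1, 8, size=d)
        names = tuple(
            f"{_NETWORK_NAMES[nets[i] - 1]}_{i + 1}" for i in range(d)
        )
        return cls(np.arange(1, d + 1), names, counts, nets)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generative model.

    ``mean_effect`` is the patient regional-GMV reduction in SD units of
    regional GMV (per affected parcel).  ``cov_effect`` is the loading
    rotation angle in radians applied to affected parcels in patients.
    ``site_offsets`` are on the regional-GMV scale: scalar per site
    (broadcast over parcels) or an (n_sites, d) array.
    """

    n_controls: int
    n_patients: int
    n_sites: int = 1
    site_offsets: object = None
    latent_dim: int = 5
    mean_effect: float = 0.0
    cov_effect: float = 0.0
    affected_parcels: object = None
    noise_sd: float = 0.05
    voxel_sd: float = 0.1
    baseline_range: tuple = (0.45, 0.65)
    loading_scale: float = 0.03
    age_effect: float = -0.0008
    sex_effect: float = 0.008
    severity_sd: float = 0.3
    clinical_coupling: float = 0.4
    global_shift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_controls + self.n_patients == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mean_effect < 0 or self.cov_effect < 0:
            raise ValueError("effect sizes must be >= 0")


@dataclass
class ParcellatedSubject:
    """Per-subject voxel-wise GMV grouped by parcel, plus covariates.

    ``voxels`` maps parcel id -> 1-D array of voxel GMV values (>= 0).
    ``severity`` is the latent disease-severity used by the generator
    (ground truth; 0 for controls, absent for real data).
    """

    subject_id: str
    voxels: dict
    age: float
    sex: int
    site: int
    label: str  # "HC" or "PAT"
    severity: float = 0.0

    def validate_against(self, atlas: AtlasSpec) -> None:
        for pid, n in zip(atlas.parcel_ids, atlas.voxel_counts):
            if pid not in self.voxels:
                raise ValueError(
                    f"subject {self.subject_id} is missing parcel {pid}")
            if len(self.voxels[pid]) != n:
                raise ValueError(
                    f"subject {self.subject_id}, parcel {pid}: expected "
                    f"{n} voxels, got {len(self.voxels[pid])}")


# ---------------------------------------------------------------------------
# population-level parameters (deterministic in atlas + config.seed)

def _resolve_affected(atlas: AtlasSpec, config: CohortConfig,
                      rng: np.random.Generator) -> np.ndarray:
    if config.affected_parcels is not None:
        idx = np.asarray(config.affected_parcels, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= atlas.d):
            raise ValueError("affected_parcels out of range for this atlas")
        return idx
    if config.mean_effect > 0 or config.cov_effect > 0:
        k = max(1, int(round(0.1 * atlas.d)))
        return np.sort(rng.choice(atlas.d, size=k, replace=False))
    return np.array([], dtype=int)


def _population(atlas: AtlasSpec, config: CohortConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    d, q = atlas.d, config.latent_dim
    baseline = rng.uniform(*config.baseline_range, size=d)
    lam = rng.normal(0.0, config.loading_scale, size=(d, q))
    rot_raw = rng.normal(size=(d, q))
    affected = _resolve_affected(atlas, config, rng)

    # patient loadings: rotate affected rows within the latent space by
    # cov_effect radians, preserving the row norm (marginal variance)
    lam_pat = lam.copy()
    theta = config.cov_effect
    if theta > 0 and affected.size:
        for r in affected:
            v = rot_raw[r] - (rot_raw[r] @ lam[r]) * lam[r] / (lam[r] @ lam[r])
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            v /= nv
            norm_r = np.linalg.norm(lam[r])
            lam_pat[r] = math.cos(theta) * lam[r] + math.sin(theta) * norm_r * v

    nvox = atlas.voxel_counts.astype(float)
    # between-subject SD of regional GMV (voxel-sum scale), used to express
    # mean_effect in SD units
    reg_var = (nvox ** 2) * ((lam ** 2).sum(axis=1) + config.noise_sd ** 2) \
        + nvox * config.voxel_sd ** 2
    reg_sd = np.sqrt(reg_var)

    offs = config.site_offsets
    if offs is None:
        site_offsets = np.zeros((config.n_sites, d))
    else:
        offs = np.asarray(offs, dtype=float)
        if offs.ndim == 1:
            site_offsets = np.repeat(offs[:, None], d, axis=1)
        else:
            site_offsets = offs
        if site_offsets.shape != (config.n_sites, d):
            raise ValueError("site_offsets must be (n_sites,) or (n_sites, d)")

    return dict(baseline=baseline, lam=lam, lam_pat=lam_pat,
                affected=affected, reg_sd=reg_sd, site_offsets=site_offsets)


def implied_regional_covariance(atlas: AtlasSpec,
                                config: CohortConfig) -> np.ndarray:
    """Model-implied covariance of regional GMV (voxel sums) for controls.

    Cov = N (Lam Lam' + noise_sd^2 I + age/sex terms) N + diag(n voxel_sd^2)
    with N = diag(voxel counts).  Age variance uses the unclipped prior
    (SD 10 years); the clipping applied at generation is negligible for the
    default range.
    """
    pop = _population(atlas, config)
    nvox = atlas.voxel_counts.astype(float)
    lam = pop["lam"]
    d = atlas.d
    ones = np.ones((d, d))
    cov_mu = lam @ lam.T + np.eye(d) * config.noise_sd ** 2
    cov_mu = cov_mu + ones * (100.0 * config.age_effect ** 2
                              + 0.25 * config.sex_effect ** 2)
    cov = np.outer(nvox, nvox) * cov_mu + np.diag(nvox * config.voxel_sd ** 2)
    return cov


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(atlas: AtlasSpec, config: CohortConfig, *,
                    subject_seed: int | None = None) -> list:
    """Generate a labelled cohort of :class:`ParcellatedSubject`.

    Population parameters (baselines, loadings, site patterns) are
    deterministic in ``config.seed``; subject-level draws use
    ``subject_seed`` (default ``config.seed + 1``), so two cohorts from the
    same population can be generated by varying ``subject_seed`` only.
    """
    pop = _population(atlas, config)
    rng = np.random.default_rng(
        config.seed + 1 if subject_seed is None else subject_seed)
    d = atlas.d
    n = config.n_controls + config.n_patients
    labels = np.array(["HC"] * config.n_controls + ["PAT"] * config.n_patients)

    age = np.clip(rng.normal(35.0, 10.0, size=n), 18.0, 70.0)
    sex = rng.integers(0, 2, size=n)
    site = rng.integers(0, config.n_sites, size=n)
    z = rng.normal(size=(n, config.latent_dim))
    eps = rng.normal(0.0, config.noise_sd, size=(n, d))
    severity = np.zeros(n)
    pat = labels == "PAT"
    severity[pat] = np.clip(
        rng.normal(1.0, config.severity_sd, size=pat.sum()), 0.1, None)

    nvox = atlas.voxel_counts.astype(float)
    mu = np.empty((n, d))
    is_pat = pat
    mu[~is_pat] = z[~is_pat] @ pop["lam"].T
    mu[is_pat] = z[is_pat] @ pop["lam_pat"].T
    mu += pop["baseline"][None, :] + eps
    mu += pop["site_offsets"][site] / nvox[None, :]
    mu += config.age_effect * (age - 35.0)[:, None]
    mu += config.sex_effect * sex[:, None]
    mu += config.global_shift / nvox[None, :]
    if config.mean_effect > 0 and pop["affected"].size:
        shift = config.mean_effect * pop["reg_sd"][pop["affected"]] \
            / nvox[pop["affected"]]
        mu[np.ix_(is_pat, pop["affected"])] -= severity[is_pat, None] * shift

    # voxel draws, parcel by parcel (vectorized over subjects)
    voxels_by_parcel = []
    for r in range(d):
        vals = rng.normal(mu[:, r][:, None], config.voxel_sd,
                          size=(n, atlas.voxel_counts[r]))
        voxels_by_parcel.append(np.clip(vals, 0.0, None))

    subjects = []
    for s in range(n):
        vox = {int(atlas.parcel_ids[r]): voxels_by_parcel[r][s]
               for r in range(d)}
        subjects.append(ParcellatedSubject(
            subject_id=f"sub-{s:04d}", voxels=vox, age=float(age[s]),
            sex=int(sex[s]), site=int(site[s]), label=str(labels[s]),
            severity=float(severity[s])))
    return subjects


def generate_reference(atlas: AtlasSpec, config: CohortConfig, *,
                       subject_seed: int | None = None) -> list:
    """Healthy-only multi-site reference cohort (patients forced to zero)."""
    if config.n_sites < 1:
        raise ValueError("reference generation needs n_sites >= 1")
    cfg = dataclasses.replace(config,
                              n_controls=config.n_controls + config.n_patients,
                              n_patients=0)
    return generate_cohort(atlas, cfg, subject_seed=subject_seed)


# ---------------------------------------------------------------------------
# clinical table

# couplings of clinical features to the latent severity; BMI and the
# affect-related SANS items are given the largest loadings
_SEVERITY_LOADINGS = {
    "bmi": 1.0,
    "sans_unchanging_facial_expression": 0.85,
    "sans_inappropriate_affect": 0.80,
    "sans_paucity_expressive_gestures": 0.78,
    "sans_affective_flattening_sum": 0.82,
    "sans_alogia_sum": 0.70,
    "panss_p4_excitement": 0.60,
    "panss_g4_tension": 0.60,
    "antipsychotic_use": 0.50,
    "antipsychotic_dose": 0.50,
    "hospitalizations": 0.35,
    "illness_duration": 0.30,
}

_PANSS_ITEMS = ([f"panss_p{i}" for i in (1, 2, 3, 5, 6, 7)]
                + ["panss_p4_excitement"]
                + [f"panss_n{i}" for i in range(1, 8)]
                + [f"panss_g{i}" for i in (1, 2, 3)] + ["panss_g4_tension"]
                + [f"panss_g{i}" for i in range(5, 17)])
_SANS_ITEMS = (["sans_unchanging_facial_expression",
                "sans_inappropriate_affect",
                "sans_paucity_expressive_gestures",
                "sans_affective_flattening_sum", "sans_alogia_sum"]
               + [f"sans_item{i}" for i in range(1, 16)])


def clinical_feature_names() -> list:
    demo = ["age", "sex", "handedness", "bmi", "education_years",
            "illness_duration", "age_onset", "hospitalizations",
            "antipsychotic_use", "antipsychotic_dose", "dup_months"]
    subst = ["smoking", "alcohol", "other_drugs"]
    return demo + _PANSS_ITEMS + _SANS_ITEMS + subst


def generate_clinical(patients: Sequence[ParcellatedSubject],
                      config: CohortConfig) -> pd.DataFrame:
    """Clinical/demographic table for the patient subsample.

    Each severity-coupled feature j is a noisy linear read-out of the
    (standardized) latent severity u with correlation
    rho_j = clinical_coupling * loading_j; uncoupled features are pure
    noise.  With coupling 0 no clinical feature carries information about
    the brain effect, so decision-score regression has no signal by
    construction.
    """
    patients = [s for s in patients if s.label == "PAT"] or list(patients)
    if len(patients) == 0:
        raise ValueError("generate_clinical needs at least one patient")
    rng = np.random.default_rng(config.seed + 7919)
    n = len(patients)
    u = np.array([s.severity for s in patients])
    u_std = (u - u.mean()) / (u.std() if u.std() > 0 else 1.0)

    def readout(name, scale=1.0):
        rho = np.clip(config.clinical_coupling
                      * _SEVERITY_LOADINGS.get(name, 0.0), 0.0, 0.95)
        return rho * u_std + math.sqrt(max(1.0 - rho ** 2, 0.0)) \
            * rng.normal(size=n)

    cols = {}
    cols["age"] = np.array([s.age for s in patients])
    cols["sex"] = np.array([s.sex for s in patients], dtype=float)
    cols["handedness"] = (rng.random(n) < 0.12).astype(float)
    cols["bmi"] = np.clip(25.0 + 4.0 * readout("bmi"), 15.0, None)
    cols["education_years"] = np.clip(
        np.round(12.0 + 2.0 * rng.normal(size=n)), 7, 20)
    cols["illness_duration"] = np.clip(
        4.5 + 5.0 * readout("illness_duration"), 0.0, None)
    cols["age_onset"] = np.clip(cols["age"] - cols["illness_duration"], 14.0,
                                None)
    cols["hospitalizations"] = np.clip(
        np.round(2.0 + 2.0 * readout("hospitalizations")), 0, None)
    cols["antipsychotic_use"] = (
        rng.random(n) < 1.0 / (1.0 + np.exp(-(0.8 + readout(
            "antipsychotic_use"))))).astype(float)
    cols["antipsychotic_dose"] = cols["antipsychotic_use"] * np.clip(
        340.0 + 250.0 * readout("antipsychotic_dose"), 0.0, None)
    cols["dup_months"] = np.clip(6.0 + 6.0 * rng.normal(size=n), 0.0, None)
    for name in _PANSS_ITEMS:
        cols[name] = np.clip(np.round(2.5 + 1.5 * readout(name)), 1, 7)
    for name in _SANS_ITEMS:
        cols[name] = np.clip(np.round(2.0 + 1.2 * readout(name)), 0, 5)
    for name in ("smoking", "alcohol", "other_drugs"):
        cols[name] = (rng.random(n) < 0.4).astype(float)

    table = pd.DataFrame(cols, index=[s.subject_id for s in patients])
    table.index.name = "subject_id"
    return table[clinical_feature_names()]


# ---------------------------------------------------------------------------
# direct feature-level generator (attribution experiments)

def generate_edge_features(n_per_group: int, d: int, planted_edges,
                           effect: float, seed: int = 0):
    """Edge-feature matrix with signal planted on chosen edges.

    Returns (X, y, planted_idx): X has one column per upper-triangle edge of
    a d-node network (standard-normal noise); the planted columns receive a
    mean shift of ``effect`` SD in patients (y = 1).  Used to probe
    attribution recovery with a known ground truth at the feature level.
    """
    n_edges = d * (d - 1) // 2
    planted_idx = np.asarray(planted_edges, dtype=int)
    if planted_idx.size and (planted_idx.min() < 0
                             or planted_idx.max() >= n_edges):
        raise ValueError("planted edge index out of range")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = np.array([0] * n_per_group + [1] * n_per_group)
    X = rng.normal(size=(n, n_edges))
    X[np.ix_(y == 1, planted_idx)] += effect
    return X, y, planted_idx


# ---------------------------------------------------------------------------
# text I/O

def write_cohort(subjects: Sequence[ParcellatedSubject], path) -> None:
    """Write a cohort to ``path``: one TSV per subject
    (parcel_id, voxel_index, value) plus a covariates TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in subjects:
        rows = []
        for pid in sorted(s.voxels):
            for i, v in enumerate(s.voxels[pid]):
                rows.append((pid, i, v))
        df = pd.DataFrame(rows, columns=["parcel_id", "voxel_index", "value"])
        df.to_csv(path / f"{s.subject_id}.tsv", sep="\t", index=False)
        meta.append((s.subject_id, s.age, s.sex, s.site, s.label, s.severity))
    pd.DataFrame(meta, columns=["subject_id", "age", "sex", "site", "label",
                                "severity"]).to_csv(
        path / "covariates.tsv", sep="\t", index=False)


def read_cohort(path) -> list:
    path = Path(path)
    meta = pd.read_csv(path / "covariates.tsv", sep="\t")
    subjects = []
    for _, row in meta.iterrows():
        df = pd.read_csv(path / f"{row.subject_id}.tsv", sep="\t")
        vox = {int(pid): grp.sort_values("voxel_index")["value"].to_numpy()
               for pid, grp in df.groupby("parcel_id")}
        subjects.append(ParcellatedSubject(
            subject_id=str(row.subject_id), voxels=vox, age=float(row.age),
            sex=int(row.sex), site=int(row.site), label=str(row.label),
            severity=float(row.severity)))
    return subjects


def write_config(config: CohortConfig, path) -> None:
    """Echo the configuration as key=value lines (log-friendly)."""
    lines = [f"{f.name}={getattr(config, f.name)!r}"
             for f in dataclasses.fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")
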