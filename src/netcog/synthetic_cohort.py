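"""Reproducible synthetic two-group cohorts of ROI time series and scores.

No public accession exists for the clinical cohort this framework targets
(resting-state fMRI of end-stage renal disease patients and matched
controls), so this module generates cohorts with the statistical structure
the prediction pipeline assumes:

* Each subject is an ROI x timepoint BOLD-like signal block from a latent
  community model: ROIs are partitioned into modules that share a Gaussian
  factor, plus independent unit-variance noise. The factor loading is lower
  for patients, so patients' binarized networks have lower within-module
  connectivity and hence lower local-efficiency AUC — the group difference
  the clinical study reports.
* Each subject's cognition score (0-30 scale, emulating the Montreal
  Cognitive Assessment) is a noisy linear function of that subject's own
  local-efficiency AUC, embedding exactly the signal the predictor exploits.

Generation is fully deterministic given the config seed; each subject draws
from its own counter-derived stream so per-subject generation is
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import (
    TimeSeriesMatrix,
    correlation_matrix,
    fisher_z,
    read_timeseries,
    sparsity_grid,
    write_matrix,
)
from .graphmetrics import metric_curves

__all__ = [
    "GROUPS",
    "CohortConfig",
    "Subject",
    "Cohort",
    "generate_subject_timeseries",
    "assign_score",
    "subject_elocal_auc",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "save_config",
    "load_config",
]

GROUPS = ("patient", "control")

#: score scale bounds (MoCA-like 0-30 cognition score)
SCORE_MIN, SCORE_MAX = 0.0, 30.0


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    The defaults emulate the clinical study design: 50 patients vs 40
    controls, 90 regions of interest (an AAL-style parcellation), and 230
    retained volumes (a typical 240-volume run minus the 10 discarded
    start-up volumes; the true run length is unreported, so 240 is an
    assumption). ``patient_effect`` is subtracted from the control factor
    loading for patients. The score link (intercept + slope * Elocal AUC)
    is calibrated so the default cohort lands near the reported group means
    (patients ~21.5, controls ~27.4 points).
    """

    n_patients: int = 50
    n_controls: int = 40
    n_rois: int = 90
    n_timepoints: int = 230
    module_size: int = 10
    connectivity_strength_control: float = 0.6
    patient_effect: float = 0.3
    score_intercept: float = -5.1
    score_slope: float = 150.0
    score_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if not 0.0 < self.connectivity_strength_control < 1.0:
            raise ValueError("connectivity_strength_control must lie in (0, 1)")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")


@dataclass
class Subject:
    subject_id: str
    group: str
    timeseries: TimeSeriesMatrix
    score: float


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        shapes = {s.timeseries.values.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError("all subjects must share one time-series shape")

    def group_subjects(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    @property
    def patients(self) -> list[Subject]:
        return self.group_subjects("patient")

    @property
    def controls(self) -> list[Subject]:
        return self.group_subjects("control")

    def scores(self, group: str | None = None) -> np.ndarray:
        subs = self.subjects if group is None else self.group_subjects(group)
        return np.array([s.score for s in subs])


def _module_partition(n_rois: int, module_size: int) -> list[np.ndarray]:
    """Consecutive ROI blocks of ~module_size (last block absorbs remainder)."""
    n_modules = max(n_rois // module_size, 1)
    bounds = np.linspace(0, n_rois, n_modules + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def generate_subject_timeseries(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> TimeSeriesMatrix:
    """Draw one subject's ROI x timepoint matrix from the latent-module model.

    Rows in the same module share a standard-normal latent signal with
    loading ``connectivity_strength_control`` (patients: loading reduced by
    ``patient_effect``, floored at 0); independent unit-variance noise is
    added to every row.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    loading = config.connectivity_strength_control
    if group == "patient":
        loading = max(loading - config.patient_effect, 0.0)
    x = rng.standard_normal((config.n_rois, config.n_timepoints))
    for module in _module_partition(config.n_rois, config.module_size):
        latent = rng.standard_normal(config.n_timepoints)
        x[module] += loading * latent
    return TimeSeriesMatrix(values=x)


def assign_score(
    elocal_auc: float, config: CohortConfig, rng: np.random.Generator
) -> float:
    """Noisy linear score link, clipped to the 0-30 scale."""
    if not np.isfinite(elocal_auc):
        raise ValueError("elocal_auc must be finite")
    raw = (config.score_intercept + config.score_slope * elocal_auc
           + rng.normal(0.0, config.score_noise_sd))
    return float(np.clip(raw, SCORE_MIN, SCORE_MAX))


def subject_elocal_auc(ts: TimeSeriesMatrix, grid: np.ndarray | None = None) -> float:
    """Local-efficiency AUC of one subject over the sparsity grid."""
    if grid is None:
        grid = sparsity_grid()
    zm = fisher_z(correlation_matrix(ts))
    return metric_curves(zm, grid, metrics=("elocal",)).aucs["elocal"]


def generate_cohort(
    config: CohortConfig, grid: np.ndarray | None = None
) -> Cohort:
    """Generate the full cohort: time series plus Elocal-AUC-linked scores.

    Patients come first (``patient_01``..), then controls. Subject ``i``
    draws from the ``i``-th child of the config seed's seed-sequence, so the
    cohort is identical for identical configs.
    """
    if config.n_patients < 1 or config.n_controls < 1:
        raise ValueError("n_patients and n_controls must both be >= 1")
    if grid is None:
        grid = sparsity_grid()
    groups = (["patient"] * config.n_patients + ["control"] * config.n_controls)
    counts = {"patient": 0, "control": 0}
    children = np.random.SeedSequence(config.seed).spawn(len(groups))
    subjects = []
    for group, child in zip(groups, children):
        counts[group] += 1
        rng = np.random.default_rng(child)
        ts = generate_subject_timeseries(group, config, rng)
        score = assign_score(subject_elocal_auc(ts, grid), config, rng)
        subjects.append(Subject(
            subject_id=f"{group}_{counts[group]:02d}",
            group=group, timeseries=ts, score=score,
        ))
    return Cohort(subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, directory) -> Path:
    """Write per-subject CSV matrices plus a manifest CSV (and config YAML)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        rel = f"{s.subject_id}.csv"
        write_matrix(s.timeseries.values, directory / rel)
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "score": s.score, "path": rel})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if cohort.config is not None:
        save_config(cohort.config, directory / "config.yaml")
    return manifest


def read_cohort(directory) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    config_path = directory / "config.yaml"
    config = load_config(config_path) if config_path.exists() else None
    subjects = [
        Subject(subject_id=row.subject_id, group=row.group,
                timeseries=read_timeseries(directory / row.path),
                score=float(row.score))
        for row in manifest.itertuples()
    ]
    return Cohort(subjects=subjects, config=config)


def save_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config(path, **overrides) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return CohortConfig(**data)


def with_overrides(config: CohortConfig, **overrides) -> CohortConfig:
    """Copy a config with some fields replaced."""
    return replace(config, **overrides)
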