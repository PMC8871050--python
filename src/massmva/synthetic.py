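"""Synthetic multimodal cohort generator.

Emulates the statistical structure of a two-group case-control imaging
study: for each subject we draw demographic covariates (age, sex, total
intracranial volume) and, for each atlas region, a vector of regional mean
features across imaging modalities.  Features are multivariate Gaussian
with a configurable modality-by-modality noise covariance, additive
confound contributions, and an optional planted group mean-shift along a
unit direction in modality space — the signal the downstream multivariate
test is supposed to detect.

The defaults mirror a study of 19 + 25 patients, 119 atlas regions and
three modalities (task fMRI contrast, resting-state residual variance,
gray-matter density).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_MODALITIES",
    "SyntheticCohortSpec",
    "simulate_cohort",
    "feature_column",
    "split_feature_column",
    "write_cohort",
    "read_cohort",
    "write_spec",
    "read_spec",
]

#: canonical modality order; CV1..CV3 of the results table follow it
DEFAULT_MODALITIES: tuple[str, ...] = ("task_fmri", "rest_fmri", "structural")

_FEATURE_SEP = "__"

# population scalings used to standardize confounds inside the generator,
# so confound_coeffs are expressed per 1 SD of the confound
_AGE_MEAN, _AGE_SD = 41.5, (65.0 - 18.0) / np.sqrt(12.0)
_TIV_MEAN, _TIV_SD = 1450.0, 120.0


def _default_noise_covariance(p: int) -> np.ndarray:
    """Exchangeable correlation 0.3, unit variances."""
    cov = np.full((p, p), 0.3)
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic two-group cohort.

    Parameters
    ----------
    n_group1, n_group2
        Subjects per diagnostic group (>= 2 each).
    n_regions, n_modalities
        Size of the regional feature grid.
    effect_size
        Magnitude of the group-2 mean shift, in units of the per-modality
        noise SD (sqrt of the diagonal of ``noise_covariance``).
    effect_direction
        Unit vector (length ``n_modalities``) along which the shift is
        applied.  Defaults to the equal-weight unit vector.
    affected_regions
        Region indices (0-based) that carry the planted effect.
    confound_coeffs
        ``(3, n_modalities)`` coefficients of the standardized age, sex and
        TIV confounds on each modality, in feature units.
    noise_covariance
        Symmetric positive-definite ``(n_modalities, n_modalities)`` matrix.
    group_confound_shift
        Optional mean shift (in confound SD units) of age and TIV in group
        2, to exercise confound adjustment; 0 keeps confounds independent
        of diagnosis, matching a cohort whose groups do not differ
        demographically.
    seed
        Seed for all randomness; identical spec + seed gives identical
        output.
    """

    n_group1: int = 19
    n_group2: int = 25
    n_regions: int = 119
    n_modalities: int = 3
    effect_size: float = 0.0
    effect_direction: np.ndarray | None = None
    affected_regions: frozenset[int] = field(default_factory=frozenset)
    confound_coeffs: np.ndarray | None = None
    noise_covariance: np.ndarray | None = None
    group_labels: tuple[str, str] = ("schizophrenia", "depression")
    modalities: tuple[str, ...] | None = None
    group_confound_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = int(self.n_modalities)
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_regions < 1 or p < 1:
            raise ValueError("n_regions and n_modalities must be >= 1")
        if self.modalities is None:
            self.modalities = tuple(
                DEFAULT_MODALITIES[i] if i < len(DEFAULT_MODALITIES) else f"modality_{i}"
                for i in range(p)
            )
        if len(self.modalities) != p:
            raise ValueError("modalities length must equal n_modalities")
        if self.effect_direction is None:
            self.effect_direction = np.full(p, 1.0 / np.sqrt(p))
        self.effect_direction = np.asarray(self.effect_direction, dtype=float)
        if self.effect_direction.shape != (p,):
            raise ValueError("effect_direction must have length n_modalities")
        if self.effect_size > 0:
            norm = float(np.linalg.norm(self.effect_direction))
            if abs(norm - 1.0) > 1e-12:
                raise ValueError(
                    f"effect_direction must be unit norm (got {norm!r})"
                )
        if self.confound_coeffs is None:
            # modest realistic confound loadings: age/TIV stronger than sex
            self.confound_coeffs = np.tile([[0.3], [0.2], [0.3]], (1, p))
        self.confound_coeffs = np.asarray(self.confound_coeffs, dtype=float)
        if self.confound_coeffs.shape != (3, p):
            raise ValueError("confound_coeffs must have shape (3, n_modalities)")
        if self.noise_covariance is None:
            self.noise_covariance = _default_noise_covariance(p)
        self.noise_covariance = np.asarray(self.noise_covariance, dtype=float)
        cov = self.noise_covariance
        if cov.shape != (p, p) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError(f"noise_covariance must be symmetric {p}x{p}, got\n{cov}")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(
                f"noise_covariance is not positive definite:\n{cov}"
            )
        self.affected_regions = frozenset(int(i) for i in self.affected_regions)
        bad = [i for i in self.affected_regions if not 0 <= i < self.n_regions]
        if bad:
            raise ValueError(f"affected_regions out of range: {bad}")

    def region_names(self) -> list[str]:
        width = max(3, len(str(self.n_regions)))
        return [f"region_{i + 1:0{width}d}" for i in range(self.n_regions)]


def feature_column(region: str, modality: str) -> str:
    return f"{region}{_FEATURE_SEP}{modality}"


def split_feature_column(column: str) -> tuple[str, str]:
    region, sep, modality = column.rpartition(_FEATURE_SEP)
    if not sep or not region:
        raise ValueError(f"not a feature column: {column!r}")
    return region, modality


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a cohort table from ``spec``.

    Returns a DataFrame with one row per subject and columns
    ``subject_id, diagnosis, age, sex, tiv`` followed by one
    ``<region>__<modality>`` column per feature.  Deterministic for a
    fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group1 + spec.n_group2
    p = spec.n_modalities
    group = np.repeat([0, 1], [spec.n_group1, spec.n_group2])

    age = rng.uniform(18.0, 65.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)  # 0 female, 1 male
    # TIV in mL; males run ~100 mL larger on average
    tiv = rng.normal(_TIV_MEAN - 50.0, 110.0, size=n) + 100.0 * sex
    if spec.group_confound_shift:
        age = age + spec.group_confound_shift * _AGE_SD * group
        tiv = tiv + spec.group_confound_shift * _TIV_SD * group

    z = np.column_stack(
        [
            (age - _AGE_MEAN) / _AGE_SD,
            (sex - 0.5) / 0.5,
            (tiv - _TIV_MEAN) / _TIV_SD,
        ]
    )
    confound_part = z @ spec.confound_coeffs  # (n, p)

    noise_sd = np.sqrt(np.diag(spec.noise_covariance))
    shift = spec.effect_size * spec.effect_direction * noise_sd
    chol = np.linalg.cholesky(spec.noise_covariance)

    columns: dict[str, np.ndarray] = {}
    region_names = spec.region_names()
    for r, rname in enumerate(region_names):
        noise = rng.standard_normal((n, p)) @ chol.T
        y = confound_part + noise
        if r in spec.affected_regions and spec.effect_size != 0.0:
            y = y + np.outer(group, shift)
        for m, mname in enumerate(spec.modalities):
            columns[feature_column(rname, mname)] = y[:, m]

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "diagnosis": np.where(group == 0, spec.group_labels[0], spec.group_labels[1]),
            "age": age,
            "sex": sex,
            "tiv": tiv,
            **columns,
        }
    )
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    return table


def _spec_to_dict(spec: SyntheticCohortSpec) -> dict:
    out = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, frozenset):
            v = sorted(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def write_spec(spec: SyntheticCohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path) -> SyntheticCohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["affected_regions"] = frozenset(raw.get("affected_regions", ()))
    for key in ("effect_direction", "confound_coeffs", "noise_covariance"):
        if raw.get(key) is not None:
            raw[key] = np.asarray(raw[key], dtype=float)
    for key in ("group_labels", "modalities"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return SyntheticCohortSpec(**raw)
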