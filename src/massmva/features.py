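"""Regional feature extraction and assembly.

Turns per-subject 3D modality volumes plus an integer-labeled atlas into
per-region mean features, and assembles/standardizes the per-region
subjects x modalities matrices (``Y_reg``) consumed by the multivariate
model.  Missing voxels (NaN) are excluded from means rather than
zero-filled, because zero is a meaningful value in contrast maps.

Volumes must already live on a common grid (e.g. MNI space); mismatched
shapes or affines are a hard error, never silently resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import feature_column, split_feature_column

__all__ = [
    "AtlasLabelVolume",
    "ModalityVolume",
    "RegionFeatureMatrix",
    "region_means",
    "assemble_feature_tensor",
    "tensor_from_cohort",
    "tensor_to_frame",
    "standardize_features",
    "load_atlas",
    "load_modality_volume",
    "save_volume",
    "read_region_lookup",
]


@dataclass
class AtlasLabelVolume:
    """Integer-labeled parcellation volume; label 0 is background."""

    voxels: np.ndarray
    label_map: dict[int, str]
    voxel_dimensions: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    missing_labels: list[int] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("atlas voxels must be integer labels")
        if 0 in self.label_map:
            raise ValueError("label 0 is background and cannot be a region")
        present = set(np.unique(self.voxels).tolist())
        self.missing_labels = sorted(k for k in self.label_map if k not in present)
        if self.missing_labels:
            warnings.warn(
                f"atlas labels absent from the volume: {self.missing_labels}",
                stacklevel=2,
            )

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.label_map)


@dataclass
class ModalityVolume:
    """A scalar 3D map for one modality; NaN marks missing voxels."""

    voxels: np.ndarray
    modality_tag: str = "structural"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)


@dataclass
class RegionFeatureMatrix:
    """Per-region data matrix: one row per subject, one column per modality."""

    region_id: int
    region_name: str
    values: np.ndarray
    subject_order: list[str]
    modality_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x modalities)")
        n, p = self.values.shape
        if n != len(self.subject_order) or p != len(self.modality_order):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.subject_order)} subjects x {len(self.modality_order)} modalities"
            )
        if np.isnan(self.values).any():
            bad = np.argwhere(np.isnan(self.values))
            gaps = [
                (self.subject_order[i], self.modality_order[j]) for i, j in bad[:10]
            ]
            raise ValueError(
                f"region {self.region_name!r} has missing values, e.g. {gaps}"
            )


def _check_same_grid(values: ModalityVolume | np.ndarray, atlas: AtlasLabelVolume):
    vox = values.voxels if isinstance(values, ModalityVolume) else np.asarray(values, float)
    if vox.shape != atlas.voxels.shape:
        raise ValueError(
            f"volume shape {vox.shape} does not match atlas shape {atlas.voxels.shape}"
        )
    aff = getattr(values, "affine", None)
    if aff is not None and atlas.affine is not None and not np.allclose(aff, atlas.affine, atol=1e-6):
        raise ValueError("volume and atlas affines differ; resample upstream")
    return vox


def region_means(
    values: ModalityVolume | np.ndarray,
    atlas: AtlasLabelVolume,
    region_ids: list[int] | None = None,
) -> dict[int, float]:
    """Mean voxel value per atlas region, excluding NaN voxels.

    A region whose voxels are all missing (or absent from the atlas) maps
    to NaN with a warning, never to a silent 0.
    """
    vox = _check_same_grid(values, atlas)
    if region_ids is None:
        region_ids = atlas.region_ids
    if not len(region_ids):
        raise ValueError("region_ids is empty")
    labels = atlas.voxels
    out: dict[int, float] = {}
    empty: list[int] = []
    for rid in region_ids:
        sel = vox[labels == rid]
        sel = sel[~np.isnan(sel)]
        if sel.size == 0:
            out[int(rid)] = float("nan")
            empty.append(int(rid))
        else:
            out[int(rid)] = float(sel.mean())
    if empty:
        warnings.warn(f"regions with no valid voxels: {empty}", stacklevel=2)
    return out


def assemble_feature_tensor(
    per_subject_means: dict[str, dict[int, dict[str, float]]],
    cohort: pd.DataFrame,
    modality_order: list[str],
    region_names: dict[int, str] | None = None,
) -> list[RegionFeatureMatrix]:
    """Stack per-subject regional means into one ``Y_reg`` per region.

    ``per_subject_means`` maps subject_id -> region_id -> modality -> value.
    Rows follow the cohort's subject order and columns follow
    ``modality_order``, regardless of input arrival order.  Any missing
    (subject, region, modality) entry aborts assembly with the full gap
    list.
    """
    subjects = list(cohort["subject_id"])
    missing_subjects = [s for s in subjects if s not in per_subject_means]
    if missing_subjects:
        raise ValueError(f"no regional means for subjects: {missing_subjects}")
    region_ids = sorted({r for s in subjects for r in per_subject_means[s]})
    if not region_ids:
        raise ValueError("per_subject_means contains no regions")

    gaps = []
    tensor = []
    for rid in region_ids:
        mat = np.full((len(subjects), len(modality_order)), np.nan)
        for i, sid in enumerate(subjects):
            per_region = per_subject_means[sid].get(rid, {})
            for j, mod in enumerate(modality_order):
                if mod in per_region:
                    mat[i, j] = per_region[mod]
                else:
                    gaps.append((sid, rid, mod))
        if not gaps:
            name = region_names.get(rid, str(rid)) if region_names else str(rid)
            tensor.append(
                RegionFeatureMatrix(rid, name, mat, list(subjects), list(modality_order))
            )
    if gaps:
        raise ValueError(f"missing (subject, region, modality) entries: {gaps[:20]}")
    return tensor


def tensor_from_cohort(
    cohort: pd.DataFrame, modality_order: list[str] | None = None
) -> list[RegionFeatureMatrix]:
    """Parse ``<region>__<modality>`` feature columns into Y_reg matrices."""
    parsed: dict[str, dict[str, str]] = {}
    for col in cohort.columns:
        if "__" not in col:
            continue
        region, modality = split_feature_column(col)
        parsed.setdefault(region, {})[modality] = col
    if not parsed:
        raise ValueError("cohort table has no <region>__<modality> feature columns")
    regions = sorted(parsed)
    if modality_order is None:
        first = parsed[regions[0]]
        # preserve column order of the file for the first region
        modality_order = [split_feature_column(c)[1] for c in cohort.columns
                          if "__" in c and split_feature_column(c)[0] == regions[0]]
    subjects = list(cohort["subject_id"].astype(str))
    tensor = []
    for idx, region in enumerate(regions):
        cols = []
        for mod in modality_order:
            if mod not in parsed[region]:
                raise ValueError(f"region {region!r} lacks modality {mod!r}")
            cols.append(parsed[region][mod])
        mat = cohort[cols].to_numpy(dtype=float)
        tensor.append(
            RegionFeatureMatrix(idx + 1, region, mat, subjects, list(modality_order))
        )
    return tensor


def tensor_to_frame(
    tensor: list[RegionFeatureMatrix], cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Inverse of :func:`tensor_from_cohort`; optionally prepends cohort columns."""
    if not tensor:
        raise ValueError("empty tensor")
    subjects = tensor[0].subject_order
    data: dict[str, np.ndarray] = {}
    for Y in tensor:
        if Y.subject_order != subjects:
            raise ValueError("inconsistent subject order across regions")
        for j, mod in enumerate(Y.modality_order):
            data[feature_column(Y.region_name, mod)] = Y.values[:, j]
    frame = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    frame = frame.reset_index()
    if cohort is not None:
        meta = cohort[[c for c in cohort.columns if "__" not in c]]
        frame = meta.merge(frame, on="subject_id")
    return frame


def standardize_features(Y: RegionFeatureMatrix) -> RegionFeatureMatrix:
    """Z-score each modality column (mean 0, sample SD 1, ddof=1)."""
    sd = Y.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        mods = [Y.modality_order[j] for j in zero]
        raise ValueError(
            f"zero-variance column(s) {mods} in region {Y.region_name!r}"
        )
    z = (Y.values - Y.values.mean(axis=0)) / sd
    return RegionFeatureMatrix(
        Y.region_id, Y.region_name, z, list(Y.subject_order), list(Y.modality_order)
    )


# ---------------------------------------------------------------- NIfTI I/O

def load_atlas(path, lookup: dict[int, str] | None = None) -> AtlasLabelVolume:
    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj)
    voxels = np.rint(voxels).astype(np.int32)
    if lookup is None:
        ids = [int(v) for v in np.unique(voxels) if v != 0]
        lookup = {i: str(i) for i in ids}
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AtlasLabelVolume(voxels, lookup, zooms, affine=img.affine)


def load_modality_volume(path, modality_tag: str) -> ModalityVolume:
    img = nib.load(str(path))
    return ModalityVolume(
        np.asanyarray(img.dataobj).astype(float), modality_tag, affine=img.affine
    )


def save_volume(voxels: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(voxels, dtype=np.float32),
                             affine if affine is not None else np.eye(4)), str(path))


def read_region_lookup(path) -> dict[int, str]:
    """Two-column whitespace/tab text file: integer id, region name."""
    lookup: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, _, name = line.partition("\t")
            if not name:
                rid, _, name = line.partition(" ")
            lookup[int(rid)] = name.strip()
    return lookup
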