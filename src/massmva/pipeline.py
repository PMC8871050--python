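"""Mass application of the regional multivariate test.

Runs :func:`massmva.mglm.region_test` over every atlas region, corrects
the resulting p-values for multiple comparisons across regions
(Benjamini-Hochberg FDR by default, Bonferroni selectable), ranks regions
by significance, and exports the results table and region-filled statistic
volumes.  Regions that cannot be tested (zero-variance column, singular
error SSCP) are excluded and logged, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import (
    AtlasLabelVolume,
    ModalityVolume,
    RegionFeatureMatrix,
    standardize_features,
)
from .mglm import HypothesisContrast, DesignMatrix, build_design, region_test

__all__ = [
    "MassResultTable",
    "run_mass_analysis",
    "correct_pvalues",
    "export_results_table",
    "read_results_table",
    "stat_map_from_atlas",
    "write_manifest",
]

logger = logging.getLogger("massmva")

_CORRECTIONS = {"none", "bonferroni", "benjamini_hochberg"}


@dataclass
class MassResultTable:
    """Region test results sorted by ascending p-value."""

    results: list
    correction_method: str = "benjamini_hochberg"
    alpha: float = 0.05
    modality_order: list[str] = field(default_factory=list)
    excluded: list[tuple[object, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.results = sorted(self.results, key=lambda r: (r.p_value, r.region_id))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            row = {
                "rank": rank,
                "region_id": r.region_id,
                "region_name": r.region_name,
                "p_value": r.p_value,
                "p_corrected": r.p_corrected,
                "chi_square": r.chi_square,
                "df": r.df,
                "wilks_lambda": r.wilks_lambda,
                "f_stat": r.f_stat,
            }
            for j, w in enumerate(r.canonical_vector, start=1):
                row[f"CV{j}"] = w
            rows.append(row)
        return pd.DataFrame(rows)


def correct_pvalues(p_values, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-comparison adjustment across regions.

    ``bonferroni``: min(1, m*p).  ``benjamini_hochberg``: step-up adjusted
    values.  ``none`` passes through.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}; choose from {sorted(_CORRECTIONS)}")
    if method == "none" or p.size == 0:
        return p.copy()
    sm_method = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def run_mass_analysis(
    tensor: list[RegionFeatureMatrix],
    cohort: pd.DataFrame,
    group_column: str = "diagnosis",
    confounds: tuple[str, ...] = ("age", "sex", "tiv"),
    group_order: tuple[str, str] | None = None,
    standardize: bool = True,
    correction: str = "benjamini_hochberg",
    alpha: float = 0.05,
    design: DesignMatrix | None = None,
    contrast: HypothesisContrast | None = None,
) -> MassResultTable:
    """One multivariate test per region, with multiplicity correction."""
    if not tensor:
        raise ValueError("empty feature tensor")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    subjects = list(cohort["subject_id"].astype(str))
    if design is None or contrast is None:
        design, contrast = build_design(
            cohort, group_column=group_column, confounds=confounds, group_order=group_order
        )

    results = []
    excluded: list[tuple[object, str]] = []
    for Y in sorted(tensor, key=lambda y: y.region_id):
        if list(Y.subject_order) != subjects:
            raise ValueError(
                f"region {Y.region_name!r} subject order differs from the cohort table"
            )
        try:
            Z = standardize_features(Y) if standardize else Y
            results.append(region_test(Z, design, contrast))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("excluding region %s: %s", Y.region_name, exc)
            excluded.append((Y.region_id, str(exc)))
    if not results:
        raise ValueError("all regions were excluded; nothing to report")

    adjusted = correct_pvalues([r.p_value for r in results], correction)
    for r, padj in zip(results, adjusted):
        r.p_corrected = float(padj)
    return MassResultTable(
        results=results,
        correction_method=correction,
        alpha=alpha,
        modality_order=list(tensor[0].modality_order),
        excluded=excluded,
    )


def export_results_table(table: MassResultTable, path) -> None:
    """CSV export, full float precision, with the CV -> modality mapping in the header."""
    frame = table.to_frame()
    if frame.empty:
        raise ValueError("result table is empty")
    with open(path, "w") as fh:
        mapping = ", ".join(
            f"CV{j + 1}={m}" for j, m in enumerate(table.modality_order)
        )
        fh.write(f"# canonical vector columns: {mapping}\n")
        fh.write(
            f"# correction={table.correction_method} alpha={table.alpha}\n"
        )
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def stat_map_from_atlas(
    table: MassResultTable, atlas: AtlasLabelVolume, fieldname: str = "chi_square"
) -> ModalityVolume:
    """Paint each region's scalar statistic into the atlas volume.

    ``fieldname`` is one of ``chi_square``, ``p_value``, ``p_corrected``,
    ``wilks_lambda``, ``f_stat``, or ``cv_component_k`` (1-based k).
    Background and unlisted voxels are NaN.
    """
    present = set(np.unique(atlas.voxels).tolist())
    absent = [r.region_id for r in table.results if r.region_id not in present]
    if absent:
        raise ValueError(f"regions absent from the atlas: {absent}")
    out = np.full(atlas.voxels.shape, np.nan)
    for r in table.results:
        if fieldname.startswith("cv_component_"):
            k = int(fieldname.rsplit("_", 1)[1])
            value = float(r.canonical_vector[k - 1])
        else:
            value = float(getattr(r, fieldname))
        out[atlas.voxels == r.region_id] = value
    return ModalityVolume(out, modality_tag=fieldname, affine=atlas.affine)


def write_manifest(path, config: dict, table: MassResultTable | None = None) -> None:
    """JSON run manifest: config echo, exclusions, library versions."""
    import nibabel
    import scipy
    import statsmodels

    manifest = {
        "config": config,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    if table is not None:
        manifest["n_regions_tested"] = len(table.results)
        manifest["excluded_regions"] = [
            {"region_id": rid, "reason": reason} for rid, reason in table.excluded
        ]
        manifest["correction_method"] = table.correction_method
        manifest["alpha"] = table.alpha
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
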