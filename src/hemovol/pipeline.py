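"""Orchestration: the phantom benchmark and cohort-style method comparison.

Two entry points mirror the two experiments a volumetry study runs:

* :func:`run_phantom_benchmark` — generate the calibrated six-shape phantom
  suite, run all four estimators plus the roundness index on each, and emit
  a table of volumes and relative errors against the known exact volumes.
* :func:`run_cohort_comparison` — given any set of per-region masks (real or
  synthetic), compute per-region volumes, roundness and relative errors
  against planimetry, then the agreement statistics per hemorrhage type:
  Bland-Altman, one-sided Wilcoxon, Spearman of roundness against relative
  error, and (when decision metadata is available) Cohen's kappa between
  volume-based surgical decisions.

Regions with planimetry volume below 0.5 cm^3 are excluded before any
statistic, matching standard practice for tiny annotation fragments.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantoms import PhantomSpec, calibrate_to_volume, default_suite, generate_phantom
from .shape import roundness_index
from .stats import (
    PairedVolumes,
    bland_altman,
    cohens_kappa,
    relative_error,
    spearman_rho,
    surgical_decision,
    wilcoxon_one_sided,
)
from .volumetry import (
    METHODS,
    abc_over_2,
    pca_axes_2d,
    pca_axes_3d,
    planimetry_volume,
    truncated_pyramid_volume,
)
from .voxelgrid import VoxelGrid, read_mask

__all__ = [
    "BenchmarkConfig",
    "run_phantom_benchmark",
    "run_cohort_comparison",
    "measure_region",
    "MIN_REGION_CM3",
]

logger = logging.getLogger("hemovol")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)

MIN_REGION_CM3 = 0.5
COMPARATORS = ("truncated_pyramid", "abc2_pca2d", "abc2_pca3d")


def measure_region(grid: VoxelGrid) -> dict:
    """All four volume estimates (cm^3) plus roundness for one region."""
    vols = {
        "planimetry": planimetry_volume(grid).volume_cm3,
        "truncated_pyramid": truncated_pyramid_volume(grid).volume_cm3,
        "abc2_pca2d": abc_over_2(pca_axes_2d(grid)).volume_cm3,
        "abc2_pca3d": abc_over_2(pca_axes_3d(grid)).volume_cm3,
    }
    vols["roundness"] = roundness_index(grid).R
    return vols


@dataclass(frozen=True)
class BenchmarkConfig:
    """Declarative configuration of the phantom benchmark."""

    shapes: tuple[str, ...] = ()
    targets: tuple[float, ...] = ()
    pixel_size: float = 0.45
    slice_thickness: float = 1.5
    seed: int = 0
    refinement: int = 8

    def suite(self) -> list[tuple[PhantomSpec, float]]:
        if not self.shapes:
            return [
                (PhantomSpec(s.shape, seed=self.seed), t) for s, t in default_suite()
            ]
        if len(self.shapes) != len(self.targets):
            raise ValueError("shapes and targets must have equal length")
        return [
            (PhantomSpec(shape, seed=self.seed), target)
            for shape, target in zip(self.shapes, self.targets)
        ]


def run_phantom_benchmark(config: BenchmarkConfig = BenchmarkConfig()) -> pd.DataFrame:
    """Calibrated phantom suite -> per-shape volumes, roundness, relative errors.

    Columns: shape, roundness, exact_cm3, one volume column per method, one
    ``relerr_<method>`` column per method. Deterministic given the config.
    """
    rows = []
    for spec, target in config.suite():
        t0 = time.perf_counter()
        calibrated = calibrate_to_volume(spec, target)
        grid = generate_phantom(calibrated, config.pixel_size, config.slice_thickness)
        m = measure_region(grid)
        row = {"shape": spec.shape, "roundness": m["roundness"], "exact_cm3": target}
        for method in METHODS:
            row[method] = m[method]
            row[f"relerr_{method}"] = relative_error(target, m[method])
        rows.append(row)
        logger.info("benchmark %s: %.1fs", spec.shape, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def _load_grids(masks) -> list[VoxelGrid]:
    grids = []
    for m in masks:
        grids.append(m if isinstance(m, VoxelGrid) else read_mask(m))
    return grids


def run_cohort_comparison(
    masks,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-region method comparison plus the agreement-statistics bundle.

    Parameters
    ----------
    masks:
        Sequence of :class:`VoxelGrid` objects or mask file paths, one per
        annotated hemorrhage region.
    metadata:
        Optional per-region frame aligned with ``masks``; recognized columns:
        ``region_id``, ``hemorrhage_type`` (EDH/IPH), ``location``
        (frontal/temporal/other), ``patient_id``, ``surgeon_decision``
        (surgery/observation). Without it, all regions form one stratum and
        the decision analysis is skipped.

    Returns
    -------
    (comparison, stats_bundle):
        ``comparison`` is the per-region table (volumes, roundness, relative
        errors vs planimetry). ``stats_bundle`` maps each stratum to
        Bland-Altman / Wilcoxon / Spearman results per comparator, plus an
        optional ``kappa`` entry.
    """
    grids = _load_grids(masks)
    n_in = len(grids)
    if metadata is not None and len(metadata) != n_in:
        raise ValueError("metadata must align with masks")

    rows = []
    for k, grid in enumerate(grids):
        m = measure_region(grid)
        row = {
            "region_id": (
                metadata["region_id"].iloc[k]
                if metadata is not None and "region_id" in metadata
                else k
            ),
            "hemorrhage_type": (
                metadata["hemorrhage_type"].iloc[k]
                if metadata is not None and "hemorrhage_type" in metadata
                else "ALL"
            ),
            "location": (
                metadata["location"].iloc[k]
                if metadata is not None and "location" in metadata
                else "other"
            ),
            **{method: m[method] for method in METHODS},
            "roundness": m["roundness"],
        }
        for comp in COMPARATORS:
            row[f"relerr_{comp}"] = relative_error(m["planimetry"], m[comp])
        rows.append(row)
    table = pd.DataFrame(rows)

    excluded = table[table["planimetry"] < MIN_REGION_CM3]
    if len(excluded):
        logger.info(
            "excluding %d region(s) below %.1f cm^3: %s",
            len(excluded),
            MIN_REGION_CM3,
            list(excluded["region_id"]),
        )
    table = table[table["planimetry"] >= MIN_REGION_CM3].reset_index(drop=True)
    if len(table) < 2:
        raise ValueError("fewer than 2 regions remain after the 0.5 cm^3 exclusion")

    bundle: dict = {}
    for htype, sub in table.groupby("hemorrhage_type"):
        stratum: dict = {}
        for comp in COMPARATORS:
            pair = PairedVolumes(
                sub["planimetry"].to_numpy(),
                sub[comp].to_numpy(),
                region_ids=tuple(sub["region_id"]),
            )
            entry: dict = {"bland_altman": bland_altman(pair)}
            try:
                w, p_greater = wilcoxon_one_sided(pair, "m2_greater")
                _, p_less = wilcoxon_one_sided(pair, "m1_greater")
                entry["wilcoxon"] = {
                    "statistic": w,
                    "p_comparator_greater": p_greater,
                    "p_planimetry_greater": p_less,
                }
            except ValueError as err:
                logger.warning("wilcoxon skipped for %s/%s: %s", htype, comp, err)
            try:
                rho, p_rho = spearman_rho(
                    sub["roundness"].to_numpy(), sub[f"relerr_{comp}"].to_numpy()
                )
                entry["spearman_roundness_vs_error"] = {"rho": rho, "p": p_rho}
            except ValueError as err:
                logger.warning("spearman skipped for %s/%s: %s", htype, comp, err)
            stratum[comp] = entry
        bundle[htype] = stratum

    if metadata is not None and "surgeon_decision" in metadata:
        bundle["kappa"] = _decision_kappa(table, metadata)
    elif metadata is not None:
        logger.warning("no surgeon_decision metadata: decision analysis skipped")

    return table, bundle


def _decision_kappa(table: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Kappa between surgeon decisions and volume-rule decisions.

    Grouped per patient on the largest region when patient ids are supplied,
    else per region.
    """
    meta = metadata.set_index("region_id") if "region_id" in metadata else metadata
    merged = table.merge(
        meta[["surgeon_decision"] + (["patient_id"] if "patient_id" in meta else [])],
        left_on="region_id",
        right_index=True,
        how="inner",
    )
    if "patient_id" in merged:
        merged = (
            merged.sort_values("planimetry", ascending=False)
            .groupby("patient_id", as_index=False)
            .first()
        )
    rule_dec = [
        surgical_decision(v, t, loc)
        for v, t, loc in zip(
            merged["planimetry"], merged["hemorrhage_type"], merged["location"]
        )
    ]
    surg_dec = list(merged["surgeon_decision"])
    cats = ["surgery", "observation"]
    counts = np.zeros((2, 2))
    for a, b in zip(surg_dec, rule_dec):
        counts[cats.index(a), cats.index(b)] += 1
    result = cohens_kappa(counts)
    return {"table": counts, "kappa": result.kappa, "n": len(merged)}
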