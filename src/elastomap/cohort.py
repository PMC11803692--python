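"""Longitudinal synthetic cohorts.

The study followed three arms of tumor-bearing or sham-injected mice with
multiparametric MRI every four weeks; only group means ± SEM are printed.
The generator treats those printed group means as ground-truth trajectories
and draws per-subject truth around them, so recovery of the printed means
(and the power of the reported tests) can be checked hermetically.

Dispersion model per (subject, region, metric):

    value(week) = mean(group, region, metric, week)
                  + sd * (sqrt(rho) * b_subject + sqrt(1 - rho) * e_week)

with b, e standard normal, giving marginal SD ``sd`` at every week and
within-subject correlation ``rho`` (default 0.5) between any two weeks —
the quantity paired t-tests are sensitive to but the printed tables cannot
constrain. ``sd`` defaults to printed SEM * sqrt(n). Tumor volume uses a
multiplicative dispersion (SD proportional to the mean) because its printed
SEM scales with the mean; values are floored at a small positive volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .phantom import (
    DEFAULT_GRID,
    DEFAULT_SPACING_MM,
    Band,
    Ellipsoid,
    PropertyPhantom,
    RegionParams,
    build_property_phantom,
    _default_regions,
)

__all__ = ["StudyDesign", "build_longitudinal_cohort", "region_params_from_metrics"]

METRICS = ("volume_mm3", "t2_ms", "adc", "fa", "gstar_kpa", "y")
GROUPS = ("treatment_control", "radiotherapy", "sham")
WEEKS = (4, 8, 12, 16)

Trajectory = Mapping[str, Mapping[str, Mapping[str, Mapping[int, float]]]]

# Printed group means. Weeks 4 and 8 precede randomization, so both tumor
# arms share the pooled tumor-bearing trajectory there. Cells the study did
# not print (week-4 core ADC/FA, sham absolute stiffness, needle tract and
# contralateral means) carry plausible healthy-brain defaults chosen once.
_CONTROL_CC = {
    "gstar_kpa": {4: 4.44, 8: 5.31, 12: 4.73},
    "y": {4: 0.337, 8: 0.354, 12: 0.321},
    "t2_ms": {4: 40.5, 8: 40.44, 12: 41.13},
    "adc": {4: 598.9, 8: 608.5, 12: 633.4},
    "fa": {4: 0.382, 8: 0.386, 12: 0.39},
}
_CONTROL_CORE = {
    "gstar_kpa": {4: 3.9, 8: 5.51, 12: 4.24},
    "y": {4: 0.322, 8: 0.375, 12: 0.346},
    "t2_ms": {4: 40.19, 8: 41.65, 12: 44.83},
    "adc": {4: 600.0, 8: 610.2, 12: 711.2},
    "fa": {4: 0.2398, 8: 0.2097, 12: 0.2479},
    "volume_mm3": {4: 1.6, 8: 3.76, 12: 16.88},
}
_RT_CC = {
    "gstar_kpa": {4: 4.44, 8: 5.31, 12: 5.65, 16: 5.65},
    "y": {4: 0.337, 8: 0.354, 12: 0.344, 16: 0.344},
    "t2_ms": {4: 40.5, 8: 40.44, 12: 40.69, 16: 40.69},
    "adc": {4: 598.9, 8: 608.5, 12: 608.7, 16: 608.7},
    "fa": {4: 0.382, 8: 0.386, 12: 0.404, 16: 0.404},
}
_RT_CORE = {
    "gstar_kpa": {4: 4.2, 8: 4.94, 12: 5.38, 16: 4.42},
    "y": {4: 0.322, 8: 0.375, 12: 0.346, 16: 0.346},
    "t2_ms": {4: 40.19, 8: 41.65, 12: 43.06, 16: 44.10},
    "adc": {4: 600.0, 8: 610.2, 12: 654.0, 16: 730.5},
    "fa": {4: 0.215, 8: 0.244, 12: 0.236, 16: 0.248},
    "volume_mm3": {4: 1.6, 8: 3.76, 12: 10.96, 16: 23.01},
}
_SHAM_QUIET = {  # needle tract and contralateral: stable healthy values
    "gstar_kpa": {4: 4.7, 8: 4.7, 12: 4.7},
    "y": {4: 0.33, 8: 0.33, 12: 0.33},
    "t2_ms": {4: 40.4, 8: 40.4, 12: 40.4},
    "adc": {4: 600.0, 8: 600.0, 12: 600.0},
    "fa": {4: 0.25, 8: 0.25, 12: 0.25},
}
_SHAM_CC = {
    # printed delta week8-week4 is -1.1 kPa; absolute level is not printed
    "gstar_kpa": {4: 5.0, 8: 3.9, 12: 3.9},
    "y": {4: 0.33, 8: 0.33, 12: 0.33},
    "t2_ms": {4: 40.4, 8: 40.4, 12: 40.4},
    "adc": {4: 600.0, 8: 595.0, 12: 595.0},
    "fa": {4: 0.38, 8: 0.3922, 12: 0.3922},
}

DEFAULT_TRAJECTORIES: Trajectory = {
    "treatment_control": {"corpus_callosum": _CONTROL_CC, "tumor_core": _CONTROL_CORE},
    "radiotherapy": {"corpus_callosum": _RT_CC, "tumor_core": _RT_CORE},
    "sham": {
        "corpus_callosum": _SHAM_CC,
        "needle_tract": _SHAM_QUIET,
        "contralateral": _SHAM_QUIET,
    },
}

# SEM*sqrt(n) from printed values: |G*| 0.22*sqrt(23), T2 0.28*sqrt(23),
# ADC 12.27*sqrt(10), FA 0.007*sqrt(23), Y 0.012*sqrt(23).
DEFAULT_BETWEEN_SUBJECT_SD = {
    "gstar_kpa": 1.06,
    "t2_ms": 1.34,
    "adc": 38.8,
    "fa": 0.034,
    "y": 0.058,
    "volume_mm3": 0.4,  # interpreted as relative SD, see module docstring
}
RELATIVE_SD_METRICS = frozenset({"volume_mm3"})
MIN_VOLUME_MM3 = 0.2


@dataclass(frozen=True)
class StudyDesign:
    """Arms, imaging weeks and ground-truth trajectories of the cohort."""

    weeks: tuple[int, ...] = (4, 8, 12, 16)
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"treatment_control": 10, "radiotherapy": 13, "sham": 9}
    )
    truth_trajectories: Trajectory = field(default_factory=lambda: DEFAULT_TRAJECTORIES)
    between_subject_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD)
    )
    within_subject_correlation: float = 0.5
    week16_subset: int = 5  # radiotherapy subjects imaged at week 16

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in self.truth_trajectories:
                raise KeyError(f"unknown group '{g}': no truth trajectory")
        for g, regions in self.truth_trajectories.items():
            for region, metrics in regions.items():
                for metric, traj in metrics.items():
                    if metric not in METRICS:
                        raise KeyError(f"unknown metric '{metric}' in {g}/{region}")
                    missing = [w for w in self.group_weeks(g) if w not in traj]
                    if missing:
                        raise ValueError(
                            f"trajectory {g}/{region}/{metric} missing weeks {missing}"
                        )
        for m in self.between_subject_sd:
            if m not in METRICS:
                raise KeyError(f"unknown metric '{m}' in between_subject_sd")

    def group_weeks(self, group: str) -> tuple[int, ...]:
        """Weeks at which a group is imaged (week 16 is radiotherapy-only)."""
        if group == "radiotherapy":
            return tuple(w for w in self.weeks)
        return tuple(w for w in self.weeks if w != 16)

    def with_groups(self, **counts: int) -> "StudyDesign":
        g = dict(self.groups)
        g.update(counts)
        return replace(self, groups=g)


def _axial_eigs(adc_1e6: float, fa: float) -> tuple[float, float, float]:
    """Axially symmetric eigenvalues (mm^2/s) with the given MD and FA.

    For lambda = MD*(1+2f, 1-f, 1-f) the FA works out to 3f/sqrt(3+6f^2),
    inverted as f = FA/sqrt(3-2FA^2).
    """
    md = adc_1e6 * 1e-6
    f = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return (md * (1 + 2 * f), md * (1 - f), md * (1 - f))


def region_params_from_metrics(metrics: Mapping[str, float],
                               fiber_axis: tuple[float, float, float] | None = None
                               ) -> RegionParams:
    """Translate a (|G*| kPa, Y, T2, ADC, FA) record into voxel parameters."""
    gstar_pa = metrics["gstar_kpa"] * 1000.0
    y = metrics["y"]
    gd = gstar_pa * np.cos(np.pi * y / 2.0)
    gl = gstar_pa * np.sin(np.pi * y / 2.0)
    return RegionParams(
        gd_pa=float(gd),
        gl_pa=float(gl),
        t2_ms=float(metrics["t2_ms"]),
        d_eigs=_axial_eigs(metrics["adc"], metrics["fa"]),
        fiber_axis=fiber_axis,
    )


def _subject_phantom(truth: Mapping[str, Mapping[str, float]],
                     grid_shape: tuple[int, int, int],
                     spacing_mm: tuple[float, float, float]) -> PropertyPhantom:
    """Voxel phantom whose regional parameters equal one subject-week truth."""
    shapes = _default_regions()
    regions: dict[str, RegionParams] = {
        "brain": RegionParams(gd_pa=4700.0, gl_pa=2600.0, t2_ms=40.0,
                              d_eigs=_axial_eigs(600.0, 0.25)),
    }
    for region, metrics in truth.items():
        axis = (1.0, 0.0, 0.0) if region == "corpus_callosum" else None
        regions[region] = region_params_from_metrics(metrics, fiber_axis=axis)
        if region == "tumor_core" and "volume_mm3" in metrics:
            prev = shapes["tumor_core"]
            shapes["tumor_core"] = Ellipsoid.from_volume(
                prev.center_mm, max(metrics["volume_mm3"], MIN_VOLUME_MM3)
            )
    shapes = {k: v for k, v in shapes.items() if k in regions}
    return build_property_phantom(
        regions=regions, shapes=shapes, grid_shape=grid_shape, spacing_mm=spacing_mm
    )


def build_longitudinal_cohort(
    design: StudyDesign | None = None,
    seed: int = 0,
    phantoms: bool = False,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> tuple[pd.DataFrame, dict[tuple[str, int], PropertyPhantom]]:
    """Draw per-subject ground truth around the design's group means.

    Returns a tidy table with columns (subject, group, week, region, metric,
    value) and, when ``phantoms`` is true, a PropertyPhantom per
    (subject, week) whose regional parameters equal that subject's truth.
    Identical seeds give bitwise-identical tables.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    rho = design.within_subject_correlation
    if not 0.0 <= rho <= 1.0:
        raise ValueError("within_subject_correlation must lie in [0, 1]")

    rows: list[dict] = []
    phantom_map: dict[tuple[str, int], PropertyPhantom] = {}
    for group in design.groups:
        n = design.groups[group]
        if n < 2:
            raise ValueError(f"group '{group}' needs >= 2 subjects, got {n}")
        weeks = design.group_weeks(group)
        regions = design.truth_trajectories[group]
        for i in range(n):
            subject = f"{group}_{i:02d}"
            subj_weeks = weeks
            if group == "radiotherapy" and i >= design.week16_subset:
                subj_weeks = tuple(w for w in weeks if w != 16)
            truth_by_week: dict[int, dict[str, dict[str, float]]] = {
                w: {} for w in subj_weeks
            }
            for region, metrics in regions.items():
                for metric, traj in metrics.items():
                    sd = design.between_subject_sd.get(metric, 0.0)
                    b = rng.normal()
                    for w in subj_weeks:
                        e = rng.normal()
                        z = np.sqrt(rho) * b + np.sqrt(1.0 - rho) * e
                        mean = traj[w]
                        if metric in RELATIVE_SD_METRICS:
                            value = mean * (1.0 + sd * z)
                            value = max(value, MIN_VOLUME_MM3)
                        else:
                            value = mean + sd * z
                        rows.append(
                            dict(subject=subject, group=group, week=w,
                                 region=region, metric=metric, value=value)
                        )
                        truth_by_week[w].setdefault(region, {})[metric] = value
            if phantoms:
                for w in subj_weeks:
                    phantom_map[(subject, w)] = _subject_phantom(
                        truth_by_week[w], grid_shape, spacing_mm
                    )
    table = pd.DataFrame(rows)
    return table, phantom_map
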