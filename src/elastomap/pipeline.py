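"""End-to-end seeded pipeline: cohort -> raw signals -> maps -> statistics.

For every subject and imaging week the pipeline

1. builds the subject's truth phantom from the cohort draw,
2. forward-simulates the 900 Hz shear-wave field (finite-difference
   Helmholtz solve), encodes it as four wrapped wave phases per encoding
   direction, and reconstructs the elastogram,
3. synthesizes the 30-echo T2 train and fits the T2 map with the 4-SD
   noise filter,
4. synthesizes the 30-direction DWI set and fits ADC/FA,
5. reduces every map to region means (tumor core, corpus callosum, needle
   tract, contralateral as present), assembling the measured longitudinal
   table next to the truth table,
6. runs the study's paired and unpaired comparisons and writes a report.

Outputs are deterministic given the seed; the report carries no
timestamps, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .cohort import StudyDesign, build_longitudinal_cohort
from .config import PipelineConfig, stage_rng
from .dti import fit_diffusion_tensor
from .phantom import REGION_IDS, synthesize_dwi, synthesize_echo_train
from .recon import reconstruct_elastogram
from .relaxometry import fit_t2_map
from .roi_stats import (
    ComparisonResult,
    group_comparison_test,
    paired_timepoint_test,
    summarize_regions,
)
from .wavesim import (
    add_compressional_component,
    encode_wave_phases,
    solve_heterogeneous_helmholtz,
)

__all__ = ["run_pipeline", "measure_subject"]

logger = logging.getLogger(__name__)


def measure_subject(
    phantom, config: PipelineConfig, wave_rng, echo_rng, dwi_rng
) -> dict[str, np.ndarray]:
    """All quantitative maps plus validity masks for one subject-week."""
    t0 = time.perf_counter()
    field = solve_heterogeneous_helmholtz(
        phantom, source_face="x0", polarization=(0.0, 0.0, 1.0),
        frequency=config.frequency_hz,
    )
    if config.compressional_amplitude_frac > 0:
        amp = config.compressional_amplitude_frac * np.abs(field.displacement).max()
        field = add_compressional_component(field, amp)
    scale = config.target_phase_rad / np.abs(field.displacement).max()
    acq = encode_wave_phases(
        field, scale=scale, noise_sd_rad=config.phase_noise_sd_rad,
        wrap=True, seed=wave_rng,
    )
    elast = reconstruct_elastogram(
        acq, density=config.density_kg_m3,
        smooth_sigma_vox=config.smooth_sigma_vox, combine=config.combine,
    )
    logger.info("MRE simulate+reconstruct: %.1f s; %d voxels clipped",
                time.perf_counter() - t0, int(elast.clipped.sum()))

    train = synthesize_echo_train(
        phantom, s0=config.echo_s0, noise_sd=config.echo_noise_sd, seed=echo_rng
    )
    t2map = fit_t2_map(
        train, noise_sd=config.echo_noise_sd,
        threshold_multiplier=config.t2_threshold_multiplier,
        filter_mode=config.t2_filter_mode,
    )
    logger.info("T2 fit: %d voxels invalidated", t2map.n_invalidated)

    dwi = synthesize_dwi(
        phantom, bvalue=config.bvalue, s0=config.dwi_s0,
        noise_sd=config.dwi_noise_sd, seed=dwi_rng,
    )
    tens = fit_diffusion_tensor(dwi)

    return dict(
        gstar_kpa=elast.g_magnitude / 1000.0,
        y=elast.y,
        t2_ms=t2map.t2,
        adc=tens.adc * 1e6,  # report in 1e-6 mm^2/s as the field prints it
        fa=tens.fa,
        _validity=dict(
            gstar_kpa=elast.validity, y=elast.validity,
            t2_ms=t2map.validity, adc=tens.validity, fa=tens.validity,
        ),
    )


def _default_comparisons(measured: pd.DataFrame, config: PipelineConfig
                         ) -> list[ComparisonResult]:
    """The study's headline comparisons, run on whatever arms are present."""
    out: list[ComparisonResult] = []

    def _try(fn, *args, **kwargs):
        try:
            out.append(fn(*args, **kwargs))
        except (ValueError, KeyError) as exc:
            logger.info("comparison skipped: %s", exc)

    for metric in ("gstar_kpa", "y", "t2_ms", "adc", "fa"):
        _try(paired_timepoint_test, measured, "treatment_control",
             "corpus_callosum", metric, 4, 8)
        _try(paired_timepoint_test, measured, "treatment_control",
             "tumor_core", metric, 4, 8)
        _try(paired_timepoint_test, measured, "treatment_control",
             "tumor_core", metric, 8, 12)
    _try(paired_timepoint_test, measured, "treatment_control",
         "tumor_core", "volume_mm3", 8, 12)
    for metric in ("gstar_kpa", "adc", "fa"):
        _try(group_comparison_test, measured, "treatment_control", "sham",
             "corpus_callosum", metric, delta_weeks=(4, 8), welch=config.welch)
    for metric in ("gstar_kpa", "t2_ms", "adc", "volume_mm3"):
        _try(group_comparison_test, measured, "radiotherapy",
             "treatment_control", "tumor_core", metric, week=12,
             welch=config.welch)
    return out


def _comparisons_frame(results: list[ComparisonResult], alpha: float) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(dict(
            label=r.label, kind=r.kind, region=r.region, metric=r.metric,
            estimate=r.estimate,
            mean_1=r.arm_means[0], sem_1=r.arm_sems[0], n_1=r.arm_ns[0],
            mean_2=r.arm_means[1], sem_2=r.arm_sems[1], n_2=r.arm_ns[1],
            t=r.t, df=r.df, p=r.p, significant=r.p <= alpha,
        ))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("elastomap")
    root.addHandler(handler)
    try:
        stage = "cohort"
        t0 = time.perf_counter()
        design = StudyDesign().with_groups(**config.group_sizes)
        cohort_seed = int(config.stage_seed("cohort").generate_state(1)[0] % 2**31)
        truth, phantoms = build_longitudinal_cohort(
            design, seed=cohort_seed, phantoms=True,
            grid_shape=config.grid_shape, spacing_mm=config.spacing_mm,
        )
        eio.save_table(out / "truth.csv", truth)
        logger.info("stage cohort: %d subject-weeks in %.1f s",
                    len(phantoms), time.perf_counter() - t0)

        stage = "measurement"
        measured_parts: list[pd.DataFrame] = []
        for key, (subject, week) in enumerate(sorted(phantoms)):
            phantom = phantoms[(subject, week)]
            maps = measure_subject(
                phantom, config,
                wave_rng=stage_rng(config, "wave", key),
                echo_rng=stage_rng(config, "echo", key),
                dwi_rng=stage_rng(config, "dwi", key),
            )
            validity = maps.pop("_validity")
            group = subject.rsplit("_", 1)[0]
            present = {
                name: rid for name, rid in REGION_IDS.items()
                if name not in ("background", "brain")
                and (phantom.labels == rid).any()
            }
            rows = summarize_regions(
                maps, phantom.labels, present, subject, week, group,
                voxel_volume_mm3=phantom.voxel_volume_mm3
                if "tumor_core" in present else None,
                validity=validity,
            )
            # volume is only reported for the tumor core
            rows = rows[(rows.metric != "volume_mm3") | (rows.region == "tumor_core")]
            measured_parts.append(rows)
        measured = pd.concat(measured_parts, ignore_index=True)
        eio.save_table(out / "measured.csv", measured)

        stage = "statistics"
        results = _default_comparisons(measured, config)
        frame = _comparisons_frame(results, config.alpha)
        eio.save_table(out / "comparisons.csv", frame)
        _write_report(out / "report.txt", config, measured, frame)
        return out
    except Exception:
        logger.exception("pipeline aborted in stage '%s'", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_report(path: Path, config: PipelineConfig, measured: pd.DataFrame,
                  comparisons: pd.DataFrame) -> None:
    lines = ["elastomap pipeline report", "=" * 25, ""]
    lines.append(f"seed: {config.seed}")
    lines.append(f"grid: {tuple(config.grid_shape)} at {tuple(config.spacing_mm)} mm")
    lines.append(f"subjects: {dict(config.group_sizes)}")
    lines.append("")
    lines.append("group means +/- SEM (measured)")
    lines.append("-" * 30)
    summ = (measured.groupby(["group", "region", "metric", "week"])["value"]
            .agg(["mean", "sem", "count"]).reset_index())
    for _, r in summ.iterrows():
        lines.append(
            f"{r['group']:18s} {r['region']:16s} {r['metric']:12s} "
            f"wk{int(r['week']):<3d} {r['mean']:10.4g} +/- {r['sem']:8.3g} "
            f"(n={int(r['count'])})"
        )
    lines.append("")
    lines.append(f"comparisons (alpha = {config.alpha})")
    lines.append("-" * 30)
    for _, r in comparisons.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"{r['label']:60s} diff {r['estimate']:+9.4g}  t={r['t']:7.3f} "
            f"df={r['df']:5.1f} p={r['p']:.4g}{star}"
        )
    path.write_text("\n".join(lines) + "\n")
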