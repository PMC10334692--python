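"""End-to-end orchestration: inputs -> surfaces -> remission -> lifetime -> cohort.

A :class:`RunConfig` collects every setting of a run; its defaults are the
reference analysis: cohorts of N = 100,000 starting at age 30 in calendar
year 1990 with 30 years of follow-up and Euler step 0.01; 5,000 lifetime-
prevalence resamples; 1,000 GBD-table resamples for the remission bands;
remission curves reported for 2019 on ages 17.5-72.5.

:func:`run_pipeline` processes every (sex, location) combination
independently and writes, per combination, the remission-curve table, the
baseline functions (q0, p0, i0) on an age grid, and the cohort prevalence
trajectory, plus one metadata JSON sufficient to re-execute the run
bit-identically.  Stage failures abort with the failing stage named.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import GbdTable, read_gbd_csv, read_lifetime_table
from .lifetime import BaselineFunctions, fit_resampled_baseline
from .multistate import (TransitionRates, initialize_cohort, prevalence_curves,
                         run_cohort)
from .remission import (estimate_remission, remission_from_pde,
                        resample_remission)
from .surfaces import SurfaceSpec, fit_surface
from .synthetic import (default_ground_truth, emit_gbd_tables,
                        emit_lifetime_table, solve_truth)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (defaults = reference analysis)."""

    # inputs: file paths, or synthetic generation when both are None
    gbd_csv: str | None = None
    lifetime_csv: str | None = None
    synth_noise: float = 0.05
    synth_ci_halfwidth: float = 0.03

    sexes: tuple[str, ...] = ("male", "female")
    locations: tuple[str, ...] = ("Germany",)

    # surface model
    age_degree: int = 13
    year_degree: int = 1
    interaction: bool = True
    weight_by_ui: bool = False
    age_range: tuple[float, float] | None = (12.5, 82.5)
    include_dp_dt: bool = True

    # remission reporting
    remission_year: int = 2019
    remission_age_start: float = 17.5
    remission_age_stop: float = 72.5
    remission_age_step: float = 5.0
    n_resamples: int = 1000

    # lifetime stage
    n_lifetime_samples: int = 5000

    # cohort
    cohort_size: float = 100_000.0
    start_age: float = 30.0
    start_year: float = 1990.0
    follow_up: float = 30.0
    step: float = 0.01

    seed: int = 0
    outdir: str = "results/run"

    @property
    def surface_spec(self) -> SurfaceSpec:
        return SurfaceSpec(
            age_degree=self.age_degree, year_degree=self.year_degree,
            interaction=self.interaction, weight_by_ui=self.weight_by_ui,
            age_range=tuple(self.age_range) if self.age_range else None,
        )

    @property
    def remission_ages(self) -> np.ndarray:
        return np.arange(self.remission_age_start,
                         self.remission_age_stop + 1e-9,
                         self.remission_age_step)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("sexes", "locations"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        if cfg.age_range is not None:
            cfg.age_range = tuple(cfg.age_range)
        return cfg


def _stage_seed(base: int, *key: str) -> int:
    """Stable per-stage sub-seed below 2**31 (process-independent)."""
    import zlib
    parts = [zlib.crc32(k.encode()) % (2**31) for k in key]
    ss = np.random.SeedSequence([base] + parts)
    return int(ss.generate_state(1)[0] % (2**31))


def _load_inputs(config: RunConfig):
    if (config.gbd_csv is None) != (config.lifetime_csv is None):
        raise PipelineError(
            "stage gbd_io: provide both gbd_csv and lifetime_csv, or neither "
            "(synthetic inputs)")
    if config.gbd_csv is None:
        truth = default_ground_truth(noise=config.synth_noise,
                                     seed=config.seed)
        solution = solve_truth(truth)
        table = emit_gbd_tables(solution, config.synth_noise, config.seed,
                                location=config.locations[0])
        points = emit_lifetime_table(solution, config.synth_ci_halfwidth)
        return table, points, {"input": "synthetic",
                               "noise": config.synth_noise}
    try:
        table = read_gbd_csv(config.gbd_csv)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage gbd_io: reading {config.gbd_csv}: {exc}"
                            ) from exc
    try:
        points = read_lifetime_table(config.lifetime_csv)
    except (OSError, ValueError) as exc:
        raise PipelineError(
            f"stage gbd_io: reading {config.lifetime_csv}: {exc}") from exc
    return table, points, {"input": "files", "gbd_csv": str(config.gbd_csv),
                           "lifetime_csv": str(config.lifetime_csv)}


def _cohort_for(config: RunConfig, sex: str, prev, inc,
                baseline: BaselineFunctions) -> pd.DataFrame:
    start_age, start_year = config.start_age, config.start_year

    def year_at(age: float) -> float:
        # age and calendar year advance in lockstep along the cohort
        return start_year + (age - start_age)

    def r_fn(age: float) -> float:
        y = year_at(age)
        p = float(prev.predict(age, y))
        i = max(float(inc.predict(age, y)), 0.0)
        dp_dt = float(prev.d_year(age, y)) if config.include_dp_dt else 0.0
        r = remission_from_pde(p, i, float(prev.d_age(age, y)), dp_dt)
        return max(r, 0.0)  # simulation needs a proper hazard

    rates = TransitionRates.with_gbd_reactivation(
        i0=lambda a: max(float(baseline.i0(a, sex)), 0.0),
        r=r_fn,
        i_gbd=lambda a: max(float(inc.predict(a, year_at(a))), 0.0),
    )
    init, flagged = initialize_cohort(baseline, prev, start_age, start_year,
                                      config.cohort_size, sex)
    traj = run_cohort(init, rates, config.follow_up, config.step,
                      start_year=start_year,
                      meta={"sex": sex, "location": prev.location,
                            "init_renormalized": flagged})
    frame = traj.to_frame()
    frame.insert(0, "location", prev.location)
    frame.insert(0, "sex", sex)
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for every (sex, location); write artifacts.

    Returns a dict with the output frames and paths.  Output CSVs:
    remission_curves.csv, baseline_functions.csv, trajectories.csv, and
    metadata.json in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, points, input_meta = _load_inputs(config)

    try:
        baselines = {
            # lifetime prevalence is modelled jointly over sexes; one
            # baseline per run, evaluated per sex downstream
            "all": fit_resampled_baseline(
                points, config.n_lifetime_samples,
                seed=_stage_seed(config.seed, "lifetime"))
        }
    except Exception as exc:
        raise PipelineError(f"stage lifetime: {exc}") from exc
    baseline = baselines["all"]

    remission_frames, trajectory_frames, baseline_rows = [], [], []
    surfaces_by_key = {}
    for location in config.locations:
        for sex in config.sexes:
            try:
                prev = fit_surface(table.slice("prevalence", sex, location),
                                   config.surface_spec)
                inc = fit_surface(table.slice("incidence", sex, location),
                                  config.surface_spec)
            except Exception as exc:
                raise PipelineError(
                    f"stage surfaces ({sex}, {location}): {exc}") from exc
            surfaces_by_key[(sex, location)] = (prev, inc)

            try:
                est = resample_remission(
                    table, config.surface_spec, config.remission_ages,
                    config.remission_year, n_resamples=config.n_resamples,
                    seed=_stage_seed(config.seed, "remission", sex, location),
                    sex=sex, location=location,
                    include_dp_dt=config.include_dp_dt)
            except Exception as exc:
                raise PipelineError(
                    f"stage remission ({sex}, {location}): {exc}") from exc
            remission_frames.append(est.to_frame())

            try:
                trajectory_frames.append(
                    _cohort_for(config, sex, prev, inc, baseline))
            except Exception as exc:
                raise PipelineError(
                    f"stage multistate ({sex}, {location}): {exc}") from exc

    ages = np.arange(15.0, 81.0, 1.0)
    for sex in config.sexes:
        baseline_rows.append(pd.DataFrame({
            "sex": sex, "age": ages,
            "q0": baseline.q0(ages, sex),
            "p0": baseline.p0(ages, sex),
            "i0": baseline.i0(ages, sex),
        }))

    remission_df = pd.concat(remission_frames, ignore_index=True)
    baseline_df = pd.concat(baseline_rows, ignore_index=True)
    trajectory_df = pd.concat(trajectory_frames, ignore_index=True)

    paths = {
        "remission": outdir / "remission_curves.csv",
        "baseline": outdir / "baseline_functions.csv",
        "trajectories": outdir / "trajectories.csv",
        "metadata": outdir / "metadata.json",
    }
    remission_df.to_csv(paths["remission"], index=False)
    baseline_df.to_csv(paths["baseline"], index=False)
    # thin the 0.01-step trajectory to yearly rows for the output table
    step_per_year = int(round(1.0 / config.step))
    trajectory_df.iloc[::step_per_year].to_csv(paths["trajectories"],
                                               index=False)
    metadata = {
        "package_version": __version__,
        "config": asdict(config),
        "input": input_meta,
        "lifetime": {
            "n_valid": baseline.n_valid,
            "n_total": baseline.n_total,
            "pooled_coefs": asdict(baseline.coefs),
            "sex_coding": {"male": 0, "female": 1},
        },
    }
    with open(paths["metadata"], "w") as fh:
        json.dump(metadata, fh, indent=2, default=str)

    return {
        "remission": remission_df,
        "baseline": baseline_df,
        "baseline_functions": baseline,
        "trajectories": trajectory_df,
        "surfaces": surfaces_by_key,
        "paths": paths,
        "metadata": metadata,
    }
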