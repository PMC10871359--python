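"""Pipeline orchestration: config validation, stage chaining, run manifest.

The pipeline chains the analysis stages in acquisition order --
extract (skipped when traces are supplied directly) -> select -> histogram ->
fit -- from a single validated configuration with one master seed, and writes
every artifact plus a JSON run manifest (config echo, per-stage counts, file
digests) so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import smfretq
from smfretq.extraction import detect_spots, extract_traces, pair_channels, read_movie
from smfretq.histograms import (
    ConditionHistogram,
    average_histograms,
    combine_movies_if_sparse,
    compute_fret,
    histogram_quartiles,
    movie_histogram,
)
from smfretq.kinetics import KineticModel
from smfretq.occupancy import TrimodalFit, TrimodalModel, fit_trimodal
from smfretq.photophysics import PhotophysicsParams, simulate_condition
from smfretq.registration import ChannelTransform
from smfretq.selection import SelectionCriteria, SelectionReport, apply_selection
from smfretq.traces import FluorTrace, read_traces, write_traces

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_config",
    "run_simulate",
    "run_all",
    "report_conditions",
]

logger = logging.getLogger(__name__)


def _from_dict(cls, d: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class ExtractionConfig:
    n_avg_frames: int = 10
    threshold_sd: float = 5.0
    min_separation_px: float = 6.0
    aperture_radius_px: float = 3.0
    annulus_radii_px: tuple[float, float] = (5.0, 8.0)
    transform_matrix: tuple = ((1.0, 0.0), (0.0, 1.0))
    transform_offset: tuple = (0.0, 0.0)

    def transform(self) -> ChannelTransform:
        return ChannelTransform(
            matrix=np.asarray(self.transform_matrix, dtype=float),
            offset=np.asarray(self.transform_offset, dtype=float),
        )


@dataclass(frozen=True)
class HistogramConfig:
    bin_width: float = 0.02
    fret_min: float = -0.1
    fret_max: float = 1.0
    n_display_frames: int = 50
    min_traces: int = 20
    max_combine: int = 3


@dataclass(frozen=True)
class FitConfig:
    fixed_means: tuple[float, float, float] = (0.3, 0.5, 0.7)
    initial_amplitude: float = 0.05
    initial_sigma: float = 0.01

    def model(self) -> TrimodalModel:
        return TrimodalModel(
            fixed_means=tuple(self.fixed_means),
            amplitudes=(self.initial_amplitude,) * 3,
            sigma=self.initial_sigma,
        )


@dataclass(frozen=True)
class SimulationConfig:
    state_names: tuple[str, ...] = ("splayed", "compact", "super-compact")
    state_fret: tuple[float, ...] = (0.35, 0.50, 0.70)
    rate_matrix: tuple = ((0.0, 0.6, 0.0), (0.6, 0.0, 0.4), (0.0, 0.8, 0.0))
    initial_probs: tuple | None = None
    n_movies: int = 4
    traces_per_movie: int = 50
    n_frames: int = 600
    total_intensity: float = 1000.0
    donor_bleach_tau: float = 40.0
    acceptor_bleach_tau: float = 25.0
    acceptor_blink_on_rate: float = 0.0
    acceptor_blink_off_rate: float = 0.0
    background_mean: float = 200.0
    read_noise_sd: float = 20.0
    donor_leak_fraction: float = 0.0

    def kinetic_model(self) -> KineticModel:
        return KineticModel(
            state_names=tuple(self.state_names),
            state_fret=tuple(self.state_fret),
            rate_matrix=np.asarray(self.rate_matrix, dtype=float),
            initial_probs=None if self.initial_probs is None else np.asarray(self.initial_probs),
        )

    def photophysics(self, frame_interval: float) -> PhotophysicsParams:
        return PhotophysicsParams(
            total_intensity=self.total_intensity,
            frame_interval=frame_interval,
            donor_bleach_tau=self.donor_bleach_tau,
            acceptor_bleach_tau=self.acceptor_bleach_tau,
            acceptor_blink_on_rate=self.acceptor_blink_on_rate,
            acceptor_blink_off_rate=self.acceptor_blink_off_rate,
            background_mean=self.background_mean,
            read_noise_sd=self.read_noise_sd,
            donor_leak_fraction=self.donor_leak_fraction,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    output_dir: str = "smfretq_out"
    seed: int = 0
    frame_interval: float = 0.1
    condition: str = "condition"
    trace_files: tuple[str, ...] = ()       # pre-extracted traces, one file per movie
    movie_files: tuple = ()                 # (donor_tiff, acceptor_tiff) pairs
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        errors: list[str] = []
        parsed: dict[str, Any] = {}
        sections = {
            "extraction": ExtractionConfig,
            "selection": SelectionCriteria,
            "histogram": HistogramConfig,
            "fit": FitConfig,
            "simulation": SimulationConfig,
        }
        for key, section_cls in sections.items():
            if key in d:
                try:
                    val = d.pop(key)
                    parsed[key] = _from_dict(section_cls, val, key) if val is not None else None
                except (ValueError, TypeError) as exc:
                    errors.append(str(exc))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            errors.append(f"top level: unknown keys {sorted(unknown)}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        for key in ("trace_files", "movie_files"):
            if key in d:
                d[key] = tuple(tuple(p) if isinstance(p, (list, tuple)) else p for p in d[key])
        return cls(**{k: v for k, v in d.items() if k in names}, **parsed)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Everything a completed run produced, in memory."""

    per_movie_traces: list[list[FluorTrace]]
    accepted_per_movie: list[list[FluorTrace]]
    reports: list[SelectionReport]
    groups: list[list[int]] | None
    condition_histogram: ConditionHistogram | None
    fit: TrimodalFit | None
    manifest: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=lambda o: list(o)))


def run_simulate(config: PipelineConfig, write: bool = True) -> list[list[FluorTrace]]:
    """Simulation stage: synthesize per-movie trace sets from the config."""
    if config.simulation is None:
        raise ValueError("configuration has no 'simulation' section")
    sim = config.simulation
    cond = simulate_condition(
        sim.kinetic_model(),
        sim.photophysics(config.frame_interval),
        n_movies=sim.n_movies,
        traces_per_movie=sim.traces_per_movie,
        seed=config.seed,
        n_frames=sim.n_frames,
    )
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for mi, movie in enumerate(cond.movies):
            write_traces(movie, out / f"{config.condition}_movie{mi:02d}_traces.tsv")
        truth = {
            "pooled_occupancy": cond.pooled_occupancy.tolist(),
            "state_fret": list(sim.state_fret),
        }
        (out / f"{config.condition}_ground_truth.json").write_text(json.dumps(truth, indent=2))
    return cond.movies


def _load_input_traces(config: PipelineConfig, manifest: dict) -> list[list[FluorTrace]]:
    if config.simulation is not None:
        movies = run_simulate(config, write=False)
        manifest["input"] = "simulation"
    elif config.trace_files:
        movies = [read_traces(p) for p in config.trace_files]
        manifest["input"] = list(config.trace_files)
    elif config.movie_files:
        movies = []
        ext = config.extraction
        for mi, (donor_path, acceptor_path) in enumerate(config.movie_files):
            stack_d = read_movie(donor_path)
            stack_a = read_movie(acceptor_path)
            spots = detect_spots(
                stack_d,
                n_avg_frames=ext.n_avg_frames,
                threshold_sd=ext.threshold_sd,
                min_separation_px=ext.min_separation_px,
            )
            spots = pair_channels(spots, ext.transform())
            movies.append(
                extract_traces(
                    stack_d,
                    stack_a,
                    spots,
                    aperture_radius_px=ext.aperture_radius_px,
                    annulus_radii_px=tuple(ext.annulus_radii_px),
                    frame_interval=config.frame_interval,
                    movie_id=f"movie{mi:02d}",
                )
            )
            manifest.setdefault("spots_per_movie", []).append(len(spots))
        manifest["input"] = [list(pair) for pair in config.movie_files]
    else:
        raise ValueError("configuration supplies no input: need simulation, trace_files or movie_files")
    manifest["n_movies"] = len(movies)
    manifest["traces_per_movie"] = [len(m) for m in movies]
    return movies


def run_select(config: PipelineConfig) -> PipelineResult | None:
    """Run the pipeline through trace selection only."""
    return _run(config, stage="select")


def run_histogram(config: PipelineConfig) -> PipelineResult | None:
    """Run the pipeline through histogramming only."""
    return _run(config, stage="histogram")


def run_fit(config: PipelineConfig) -> PipelineResult:
    """Run the pipeline through the trimodal occupancy fit."""
    return _run(config, stage="fit")


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts plus the manifest."""
    return _run(config, stage="all")


def _run(config: PipelineConfig, stage: str = "all") -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": f"smfretq {smfretq.__version__}",
        "stage": stage,
        "config": _config_echo(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    movies = _load_input_traces(config, manifest)

    # --- selection ---
    accepted_per_movie: list[list[FluorTrace]] = []
    all_reports: list[SelectionReport] = []
    report_by_id: dict[str, SelectionReport] = {}
    for movie in movies:
        if movie:
            acc, reps = apply_selection(movie, config.selection)
        else:
            acc, reps = [], []
        accepted_per_movie.append(acc)
        all_reports.extend(reps)
        report_by_id.update({r.trace_id: r for r in reps})
    n_accepted = sum(len(m) for m in accepted_per_movie)
    manifest["accepted_per_movie"] = [len(m) for m in accepted_per_movie]
    if n_accepted == 0:
        reasons = [r for rep in all_reports for r in rep.rejection_reasons]
        dominant = max(set(reasons), key=reasons.count) if reasons else "no traces"
        raise RuntimeError(
            f"no traces passed selection (dominant rejection reason: {dominant!r})"
        )
    _write_selection_report(all_reports, out / f"{config.condition}_selection.tsv")
    summary = {
        "n_traces": len(all_reports),
        "n_accepted": n_accepted,
        "rejection_counts": _reason_counts(all_reports),
    }
    (out / f"{config.condition}_selection_summary.json").write_text(json.dumps(summary, indent=2))
    if stage == "select":
        return _finish(config, manifest, out, movies, accepted_per_movie, all_reports,
                       None, None, None)

    # --- histograms ---
    hcfg = config.histogram
    groups = combine_movies_if_sparse(accepted_per_movie, hcfg.min_traces, hcfg.max_combine)
    manifest["movie_groups"] = groups
    movie_hists = []
    for gi, group in enumerate(groups):
        series = []
        for mi in group:
            for trace in accepted_per_movie[mi]:
                lifetime = report_by_id[trace.trace_id].fret_lifetime_frames
                series.append(compute_fret(trace, lifetime))
        if not series:
            continue
        movie_hists.append(
            movie_histogram(
                series,
                n_display_frames=hcfg.n_display_frames,
                bin_width=hcfg.bin_width,
                fret_range=(hcfg.fret_min, hcfg.fret_max),
                movie_id=f"group{gi:02d}",
            )
        )
    cond_hist = average_histograms(movie_hists)
    _write_histograms(cond_hist, out, config.condition)
    if stage == "histogram":
        return _finish(config, manifest, out, movies, accepted_per_movie, all_reports,
                       groups, cond_hist, None)

    # --- trimodal fit ---
    fit = fit_trimodal(cond_hist, config.fit.model())
    fit_payload = {
        "fixed_means": list(fit.model.fixed_means),
        "amplitudes": list(fit.model.amplitudes),
        "sigma": fit.model.sigma,
        "areas": list(fit.areas),
        "occupancy_percent": list(fit.occupancy_percent),
        "amplitude_percent": list(fit.amplitude_percent),
        "residual_ss": fit.residual_ss,
        "converged": fit.converged,
        "quartiles": list(cond_hist.quartiles),
        "n_accepted": n_accepted,
    }
    (out / f"{config.condition}_fit.json").write_text(json.dumps(fit_payload, indent=2))
    return _finish(config, manifest, out, movies, accepted_per_movie, all_reports,
                   groups, cond_hist, fit)


def _finish(
    config: PipelineConfig,
    manifest: dict,
    out: Path,
    movies,
    accepted_per_movie,
    all_reports,
    groups,
    cond_hist,
    fit,
) -> PipelineResult:
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["outputs"] = {
        p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        per_movie_traces=movies,
        accepted_per_movie=accepted_per_movie,
        reports=all_reports,
        groups=groups,
        condition_histogram=cond_hist,
        fit=fit,
        manifest=manifest,
    )


def _reason_counts(reports: list[SelectionReport]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rep in reports:
        for reason in rep.rejection_reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return counts


def _write_selection_report(reports: list[SelectionReport], path: Path) -> None:
    df = pd.DataFrame(
        {
            "trace_id": [r.trace_id for r in reports],
            "donor_steps": [r.donor_step_count for r in reports],
            "acceptor_steps": [r.acceptor_step_count for r in reports],
            "fret_lifetime": [r.fret_lifetime_frames for r in reports],
            "total_cv": [r.total_intensity_cv for r in reports],
            "anticorrelation_r": [r.anticorrelation_r for r in reports],
            "accepted": [int(r.accepted) for r in reports],
            "rejection_reasons": [";".join(r.rejection_reasons) for r in reports],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _write_histograms(cond: ConditionHistogram, out: Path, condition: str) -> None:
    df = pd.DataFrame(
        {
            "bin_center": cond.bin_centers,
            "mean_fraction": cond.mean_fractions,
            "sem": cond.sem_fractions,
        }
    )
    df.to_csv(out / f"{condition}_histogram.tsv", sep="\t", index=False)
    per_movie = pd.DataFrame({"bin_center": cond.bin_centers})
    for h in cond.movie_histograms:
        per_movie[h.movie_id] = h.fractions
    per_movie.to_csv(out / f"{condition}_histogram_per_movie.tsv", sep="\t", index=False)
    quart = {
        "condition": list(cond.quartiles),
        "per_movie": [list(q) for q in cond.movie_quartiles],
    }
    (out / f"{condition}_quartiles.json").write_text(json.dumps(quart, indent=2))


def report_conditions(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Cross-condition comparison table from completed run directories."""
    rows = []
    for d in run_dirs:
        d = Path(d)
        fits = sorted(d.glob("*_fit.json"))
        if not fits:
            raise ValueError(f"{d}: no completed condition (missing *_fit.json)")
        for f in fits:
            payload = json.loads(f.read_text())
            condition = f.name.removesuffix("_fit.json")
            rows.append(
                {
                    "condition": condition,
                    "n_traces": payload["n_accepted"],
                    "q25": payload["quartiles"][0],
                    "q50": payload["quartiles"][1],
                    "q75": payload["quartiles"][2],
                    "occ_low_pct": payload["occupancy_percent"][0],
                    "occ_mid_pct": payload["occupancy_percent"][1],
                    "occ_high_pct": payload["occupancy_percent"][2],
                    "sigma": payload["sigma"],
                }
            )
    return pd.DataFrame(rows)
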