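"""Config-driven end-to-end pipeline: simulate/load -> baseline-correct ->
intensity map -> ROI report (-> calibration/LOD).

A single YAML file holds every tunable of a run; CLI flags may override
individual values. Unknown keys are rejected so typos cannot silently fall
back to defaults. Every text output carries a header comment with a short
hash of the resolved configuration, and all randomness derives from the
configured seed, so a rerun with the same config file is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .baseline import BaselineParams, correct_map
from .errors import ConfigError, InputError, SerrsmapError
from .quantify import band_intensity, fit_calibration, intensity_map, limit_of_detection
from .roi_stats import Thresholds, heterogeneity_report
from .spectra_io import (
    BandDefinition,
    ROI,
    SpectralMap,
    read_map_long,
    read_map_matrix,
    read_rois,
    read_spectrum,
    write_map_long,
)
from .synth import GeneratorConfig, default_phantom_layout, simulate_phantom
from .baseline import subtract_baseline

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_map_auto"]

log = logging.getLogger("serrsmap")


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    seed: int = 0
    baseline: BaselineParams = field(default_factory=BaselineParams)
    clip_negative: bool = True
    band: BandDefinition = field(default_factory=lambda: BandDefinition(950.0, 960.0))
    thresholds: Thresholds = field(default_factory=Thresholds)
    k_sigma: float = 3.0
    input_map: str | None = None  # None -> simulate the default phantom
    rois: str | None = None  # ROI csv; None -> default phantom layout
    series: str | None = None  # optional dilution-series csv for LOD
    output_dir: str = "serrsmap_out"
    write_png: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        if "baseline" in data:
            kwargs["baseline"] = _from_mapping(BaselineParams, data.pop("baseline"),
                                               "baseline")
        if "band" in data:
            b = data.pop("band")
            kwargs["band"] = (BandDefinition.parse(b) if isinstance(b, str)
                              else _from_mapping(BandDefinition, b, "band"))
        if "thresholds" in data:
            kwargs["thresholds"] = _from_mapping(Thresholds, data.pop("thresholds"),
                                                 "thresholds")
        if "generator" in data:
            gen = dict(data.pop("generator"))
            for key in ("np_lines", "substrate_lines"):
                if key in gen:
                    gen[key] = tuple(tuple(line) for line in gen[key])
            if "pixel_pitch" in gen:
                gen["pixel_pitch"] = tuple(gen["pixel_pitch"])
            if "signature_band" in gen:
                gen["signature_band"] = tuple(gen["signature_band"])
            kwargs["generator"] = _from_mapping(GeneratorConfig, gen, "generator")
        if "lod" in data:
            lod = data.pop("lod")
            extra = set(lod) - {"k_sigma"}
            if extra:
                raise ConfigError(f"lod: unknown keys {sorted(extra)}")
            kwargs["k_sigma"] = float(lod.get("k_sigma", 3.0))
        if "io" in data:
            io = data.pop("io")
            allowed = {"input_map", "rois", "series", "output_dir", "write_png"}
            extra = set(io) - allowed
            if extra:
                raise ConfigError(f"io: unknown keys {sorted(extra)}")
            kwargs.update(io)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"pipeline config: unknown keys {sorted(unknown)}")
        kwargs.update(data)
        if "seed" in kwargs:
            kwargs["seed"] = int(kwargs["seed"])
            kwargs.setdefault("generator", GeneratorConfig())
            kwargs["generator"] = dataclasses.replace(kwargs["generator"],
                                                      seed=kwargs["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_map_auto(path: str | Path) -> SpectralMap:
    """Load a map file, auto-detecting long vs matrix dialect from the header."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                break
        else:
            raise InputError(f"{path}: empty file")
    cols = [t.strip().lower() for t in line.replace("\t", ",").split(",")]
    if cols[:4] == ["x", "y", "shift", "intensity"]:
        return read_map_long(path)
    return read_map_matrix(path)


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    output_dir: Path
    corrected_map_path: Path
    intensity_csv: Path
    roi_report_csv: Path
    comparisons_csv: Path
    summary_txt: Path
    truth_csv: Path | None
    lod_pm: float | None
    report: object  # HeterogeneityReport


def _read_series_csv(path: str | Path, config: PipelineConfig):
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if "concentration_pM" not in df.columns:
        raise InputError(f"{path}: series needs a concentration_pM column")
    series = []
    if "spectrum_path" in df.columns:
        base = Path(path).parent
        for conc, group in df.groupby("concentration_pM"):
            vals = []
            for p in group["spectrum_path"]:
                s = read_spectrum(base / p)
                corrected = subtract_baseline(s, config.baseline,
                                              clip_negative=config.clip_negative)
                vals.append(band_intensity(corrected, config.band))
            series.append((float(conc), vals))
    elif "intensity" in df.columns:
        for conc, group in df.groupby("concentration_pM"):
            series.append((float(conc), group["intensity"].to_list()))
    else:
        raise InputError(f"{path}: series needs spectrum_path or intensity column")
    return series


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    Stages: (validate) -> simulate or load -> baseline-correct -> band
    intensity map -> ROI heterogeneity report -> optional calibration/LOD.
    Any stage error aborts the run with the stage name attached and removes
    files already written to the output directory.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"serrsmap config={chash} seed={config.seed}"
    written: list[Path] = []

    fh = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    def _emit(path: Path) -> Path:
        written.append(path)
        return path

    stage = "validate"
    try:
        import scipy

        log.info("serrsmap run, config hash %s, seed %d", chash, config.seed)
        log.info("numpy %s, scipy %s", np.__version__, scipy.__version__)

        # band must overlap the axis before anything is computed
        if config.input_map is None:
            axis = config.generator.axis()
        else:
            stage = "load"
            spectral_map = load_map_auto(config.input_map)
            if spectral_map.shared_axis is None:
                raise InputError("pipeline requires a map with a shared shift axis")
            axis = spectral_map.shared_axis
        stage = "validate"
        if not ((axis >= config.band.lo) & (axis <= config.band.hi)).any():
            raise ConfigError(
                f"band {config.band.lo:g}-{config.band.hi:g} cm^-1 outside the "
                f"spectral axis [{axis[0]:g}, {axis[-1]:g}]"
            )

        truth_csv = None
        if config.input_map is None:
            stage = "simulate"
            regions, default_rois, extent = default_phantom_layout(config.generator)
            spectral_map, truth = simulate_phantom(regions, config.generator, extent)
            truth_csv = _emit(out / "truth.csv")
            truth.write_csv(truth_csv)
            write_map_long(spectral_map, _emit(out / "simulated.map"), header=header)
            log.info("simulated phantom: %d points", spectral_map.n_points)
        else:
            default_rois = None
            log.info("loaded map %s: %d points", config.input_map, spectral_map.n_points)

        stage = "baseline"
        corrected = correct_map(spectral_map, config.baseline,
                                clip_negative=config.clip_negative)
        corrected_path = _emit(out / "corrected.map")
        write_map_long(corrected, corrected_path, header=header)
        log.info("baseline-corrected %d spectra (lam=%g, d=%d)",
                 corrected.n_points, config.baseline.lam, config.baseline.diff_order)

        stage = "intensity map"
        imap = intensity_map(corrected, config.band,
                             provenance={"config": chash,
                                         "baseline": dataclasses.asdict(config.baseline)})
        intensity_csv = _emit(out / "intensity.csv")
        imap.write_csv(intensity_csv, header=header)
        if config.write_png:
            _render_png(imap, _emit(out / "intensity.png"))

        stage = "roi report"
        if config.rois is not None:
            rois = read_rois(config.rois)
        elif default_rois is not None:
            rois = default_rois
        else:
            raise InputError("an input map needs an ROI file (io.rois)")
        report = heterogeneity_report(corrected, rois, config.band, config.thresholds)
        roi_csv = _emit(out / "roi_report.csv")
        cmp_csv = _emit(out / "comparisons.csv")
        with open(roi_csv, "w", encoding="utf-8") as f:
            f.write(f"# {header}\n")
            report.roi_table().to_csv(f, index=False, float_format="%.9g")
        with open(cmp_csv, "w", encoding="utf-8") as f:
            f.write(f"# {header}\n")
            report.comparison_table().to_csv(f, index=False, float_format="%.9g")
        log.info("ROI report: %d ROIs, %d comparisons", len(report.summaries),
                 len(report.comparisons))

        lod_pm = None
        if config.series is not None:
            stage = "calibration"
            series = _read_series_csv(config.series, config)
            fit = fit_calibration(series, k_sigma=config.k_sigma)
            lod_pm = limit_of_detection(series, k_sigma=config.k_sigma, fit=fit)
            log.info("calibration: i_max=%.3g k_half=%.3g floor=%.3g LOD=%.3g pM",
                     fit.i_max, fit.k_half, fit.floor, lod_pm)

        stage = "summary"
        summary = _emit(out / "summary.txt")
        with open(summary, "w", encoding="utf-8") as f:
            f.write(f"# {header}\n")
            f.write(report.to_text())
            if lod_pm is not None:
                f.write(f"\nlimit of detection: {lod_pm:.4g} pM (k_sigma={config.k_sigma:g})\n")

        return PipelineResult(
            output_dir=out,
            corrected_map_path=corrected_path,
            intensity_csv=intensity_csv,
            roi_report_csv=roi_csv,
            comparisons_csv=cmp_csv,
            summary_txt=summary,
            truth_csv=truth_csv,
            lod_pm=lod_pm,
            report=report,
        )
    except SerrsmapError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"pipeline stage '{stage}': {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()


def _render_png(imap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ux, uy, grid = imap.to_grid()
    fig, ax = plt.subplots(figsize=(7, 3))
    pcm = ax.pcolormesh(ux, uy, grid, shading="nearest", cmap="inferno")
    fig.colorbar(pcm, ax=ax, label=f"{imap.band.lo:g}-{imap.band.hi:g} cm$^{{-1}}$ (cts/s)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
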