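"""End-to-end orchestration: stack -> masks -> PIV -> strain -> statistics.

A :class:`RunConfig` (TOML-loadable) drives the full analysis of one
recording: nucleus segmentation, displacement fields against the t=0
reference, strain maps at peak deformation, compartment labelling,
compartment/shell statistics and a Kelvin-Voigt fit of the mean
displacement dynamics.  All artifacts are written to the output directory
together with a machine-readable manifest (config hash, seed, versions),
so identical inputs reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compartments import label_compartments
from .core import (DEFAULT_FRAME_RATE_HZ, DEFAULT_PIXEL_SIZE_UM,
                   DEFAULT_T_OFF_S, DEFAULT_T_ON_S, ImageStack, TimeSeries)
from .errors import StageError
from .kinetics import fit_kelvin_voigt
from .piv import PIVConfig, displacement_sequence
from .strain import (displacement_magnitude_map, strain_from_displacement,
                     upsample_to_image)
from .stats_report import compartment_strain_table, shell_displacement_stats

logger = logging.getLogger("nucleostrain")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the acquisition
    protocol (4 fps, 20 s baseline / 10 s stimulus / 30 s recovery,
    0.1233 µm pixels) and the printed analysis parameters (32 px windows at
    75 % overlap with a 4 px final grid, 6 px border cutoff, 7 density
    bins, 4 px shells)."""

    stack_path: Optional[str] = None
    stain_path: Optional[str] = None
    mask_path: Optional[str] = None
    output_dir: str = "nucleostrain_out"
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 1.0 / DEFAULT_FRAME_RATE_HZ
    t_on: float = DEFAULT_T_ON_S
    t_off: float = DEFAULT_T_OFF_S
    piv: PIVConfig = field(default_factory=PIVConfig)
    border_cutoff: int = 6
    n_bins: int = 7
    shell_thickness: int = 4
    n_shells: int = 3
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        piv_raw = raw.pop("piv", {})
        if "pass_windows" in piv_raw:
            piv_raw["pass_windows"] = tuple(piv_raw["pass_windows"])
        cfg = cls(**raw)
        cfg.piv = PIVConfig(**piv_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["piv"]["pass_windows"] = list(d["piv"]["pass_windows"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    """Artifacts of one pipeline run (also written to output_dir)."""

    config: RunConfig
    nucleus_mask: np.ndarray
    fields: list
    hydro_map: np.ndarray
    shear_map: np.ndarray
    displacement_map: np.ndarray
    labels: object
    strain_table: pd.DataFrame
    shell_table: Optional[pd.DataFrame]
    kv_params: object
    displacement_series: TimeSeries
    peak_index: int
    manifest: dict


def _write_toml(path: Path, data: dict) -> None:
    """Minimal flat TOML writer for the manifest/spec echo."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return json.dumps(str(v))

    lines = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        if v is None:
            continue
        lines.append(f"{k} = {fmt(v)}")
    for name, tbl in tables.items():
        lines.append(f"\n[{name}]")
        for k, v in tbl.items():
            if v is None:
                continue
            lines.append(f"{k} = {fmt(v)}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig, stack: Optional[ImageStack] = None,
                 stain: Optional[np.ndarray] = None) -> RunResult:
    """Execute the full analysis; see module docstring.

    ``stack``/``stain`` may be passed in-memory (e.g. a rendered phantom);
    otherwise they are read from the configured TIFF paths.  Each stage
    failure raises a stage-tagged error; artifacts written before the
    failure are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    try:
        # ------------------------------------------------------------ load
        if stack is None:
            if config.stack_path is None:
                raise StageError("load", "no stack given or configured")
            stack = ImageStack.from_tiff(config.stack_path,
                                         pixel_size=config.pixel_size,
                                         frame_interval=config.frame_interval)
        if stain is None and config.stain_path is not None:
            import tifffile

            stain_img = tifffile.imread(config.stain_path)
            stain = stain_img[0] if stain_img.ndim == 3 else stain_img
        logger.info("loaded stack: %d frames of %s", stack.n_frames,
                    stack.shape)

        # ------------------------------------------------------- segment
        try:
            if config.mask_path is not None:
                import tifffile

                nucleus = tifffile.imread(config.mask_path).astype(bool)
            else:
                from .compartments import segment_nucleus

                nucleus = segment_nucleus(stack.frames[0])
        except Exception as exc:
            raise StageError("segmentation", str(exc)) from exc

        # ----------------------------------------------------------- PIV
        try:
            fields = displacement_sequence(stack, config=config.piv,
                                           mask=nucleus)
        except Exception as exc:
            raise StageError("piv", str(exc)) from exc
        logger.info("PIV: %d fields, final grid spacing %.1f px",
                    len(fields), fields[0].spacing)

        # -------------------------------------------------------- strain
        times = stack.timestamps[1:]
        peak_index = int(np.argmin(np.abs(times - config.t_off)))
        peak_field = fields[peak_index]
        try:
            sf = strain_from_displacement(peak_field)
            hydro_map = upsample_to_image(sf, stack.shape, "hydro",
                                          mask=nucleus)
            shear_map = upsample_to_image(sf, stack.shape, "shear",
                                          mask=nucleus)
            disp_map = displacement_magnitude_map(peak_field, stack.shape,
                                                  mask=nucleus)
        except Exception as exc:
            raise StageError("strain", str(exc)) from exc

        # -------------------------------------------------- compartments
        try:
            labels = label_compartments(
                stack.frames[0], stain_frame=stain, nucleus=nucleus,
                border_cutoff=config.border_cutoff, n_bins=config.n_bins,
                shell_thickness=config.shell_thickness,
                n_shells=config.n_shells, pixel_size=config.pixel_size)
        except Exception as exc:
            raise StageError("compartments", str(exc)) from exc

        # --------------------------------------------------------- stats
        strain_table = compartment_strain_table(hydro_map, shear_map,
                                                disp_map, labels)
        strain_table.to_csv(out / "compartment_strain.csv", index=False)
        if stain is not None and labels.nucleolus_mask.any():
            shell_table = shell_displacement_stats(disp_map, labels)
            shell_table.to_csv(out / "shell_displacement.csv", index=False)
        else:
            shell_table = None
            logger.info("no stain channel / nucleolus: shell statistics "
                        "skipped")

        # ------------------------------------------------------ kinetics
        interior = labels.interior_mask
        series_vals = [0.0]
        for f in fields:
            mag = f.magnitude_um()
            sel = np.isfinite(mag)
            series_vals.append(float(mag[sel].mean()) if sel.any() else 0.0)
        series = TimeSeries(t=stack.timestamps, value=np.array(series_vals),
                            stimulus_window=(config.t_on, config.t_off),
                            label="mean displacement (um)")
        pd.DataFrame({"t_s": series.t, "value": series.value}).to_csv(
            out / "displacement_series.csv", index=False)
        try:
            kv = fit_kelvin_voigt(series)
        except Exception as exc:
            raise StageError("kinetics", str(exc)) from exc

        # -------------------------------------------------------- report
        manifest = {
            "package": "nucleostrain",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_frames": stack.n_frames,
            "config": config.to_dict(),
        }
        report = {
            "kelvin_voigt": {
                "E": kv.E, "tau_c": kv.tau_c, "tau_r": kv.tau_r,
                "eta": kv.eta, "fit_rmse": kv.fit_rmse, "flat": kv.flat,
            },
            "peak_frame_index": peak_index + 1,
            "n_fields": len(fields),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        _write_toml(out / "manifest.toml",
                    {k: v for k, v in manifest.items() if k != "config"}
                    | {"config": {}})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))

        return RunResult(config=config, nucleus_mask=nucleus, fields=fields,
                         hydro_map=hydro_map, shear_map=shear_map,
                         displacement_map=disp_map, labels=labels,
                         strain_table=strain_table, shell_table=shell_table,
                         kv_params=kv, displacement_series=series,
                         peak_index=peak_index, manifest=manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()
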