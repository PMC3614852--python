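"""End-to-end reconstruction pipeline.

Stages run in a fixed order — preparation (stack reading), registration,
segmentation/masking, volume assembly (with optional isotropic
interpolation), isosurface reconstruction, metrics — mirroring the standard
processing chain for cross-sectional photograph stacks.  Registration may be
skipped for pre-aligned input; reordering is not supported.

A run writes the mesh plus a JSON report containing the resolved
configuration, per-stage parameters and timings, registration residuals and
mesh metrics.  Identical configuration and seed produce byte-identical mesh
output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import formats, mc_core, mesh as mesh_metrics, registration, volume as volume_mod

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "preparation",
    "registration",
    "segmentation",
    "volume",
    "reconstruction",
    "metrics",
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration for :func:`run_pipeline`.

    ``mask_mode`` is one of ``"none"``, ``"dir"`` (read binary masks from
    ``mask_dir``) or ``"threshold"`` (mask = pixels within
    [``mask_low``, ``mask_high``]).
    """

    input_dir: str
    output_mesh: str
    report_path: str | None = None
    pixel_size: float | None = None
    slice_spacing: float | None = None
    isovalue: float = volume_mod.DEFAULT_ISOVALUE
    isotropic: bool = True
    interpolation: str = "auto"  # "auto": shape-based when masked, else linear
    registration_enabled: bool = False
    reference_index: int = 0
    fiducials: str = "auto"  # "auto" or a JSON file of per-slice (x, y) points
    expected_fiducials: int = 3
    fiducial_window: tuple[float, float] = registration.DEFAULT_FIDUCIAL_WINDOW
    mask_mode: str = "none"
    mask_dir: str | None = None
    mask_low: float = 128.0
    mask_high: float = 255.0
    pad: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mask_mode not in ("none", "dir", "threshold"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        if self.interpolation not in ("auto", "linear", "shape"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.mask_mode == "dir" and not self.mask_dir:
            raise ValueError("mask_mode 'dir' requires mask_dir")
        if not float("-inf") < float(self.isovalue) < float("inf"):
            raise ValueError("isovalue must be finite")

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        """Load a YAML (or JSON) config document; CLI overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        if "fiducial_window" in data:
            data["fiducial_window"] = tuple(data["fiducial_window"])
        return cls(**data)

    def resolved(self) -> dict:
        d = asdict(self)
        d["fiducial_window"] = list(self.fiducial_window)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report dict.

    Any stage error propagates as :class:`PipelineError` naming the stage;
    partial mesh/report outputs are removed on failure.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {"config": config.resolved(), "stages": {}}
    out_mesh = Path(config.output_mesh)
    report_path = Path(config.report_path or str(out_mesh) + ".report.json")

    def stage(name: str):
        t0 = time.perf_counter()

        def finish(**params):
            report["stages"][name] = {"wall_time_s": time.perf_counter() - t0, **params}

        return finish

    try:
        finish = stage("preparation")
        try:
            stack = formats.read_stack(
                config.input_dir, config.pixel_size, config.slice_spacing
            )
        except Exception as exc:
            raise PipelineError("preparation", str(exc)) from exc
        finish(
            n_slices=len(stack),
            pixel_size_mm=stack.pixel_size,
            slice_spacing_mm=stack.slice_spacing,
        )

        finish = stage("registration")
        if config.registration_enabled:
            try:
                fid_sets = None
                if config.fiducials != "auto":
                    pts = json.loads(Path(config.fiducials).read_text())
                    fid_sets = [
                        registration.FiducialSet(points=p) for p in pts["per_slice_points"]
                    ]
                stack, transforms = registration.register_stack(
                    stack,
                    reference_index=config.reference_index,
                    expected_count=config.expected_fiducials,
                    intensity_window=config.fiducial_window,
                    fiducials=fid_sets,
                )
            except Exception as exc:
                raise PipelineError("registration", str(exc)) from exc
            finish(
                enabled=True,
                reference_index=config.reference_index,
                residual_rms_px=[t.residual_rms for t in transforms],
            )
        else:
            finish(enabled=False)

        finish = stage("segmentation")
        try:
            if config.mask_mode == "dir":
                masks = formats.read_mask_stack(config.mask_dir, companion=stack)
            elif config.mask_mode == "threshold":
                masks = volume_mod.threshold_mask(stack, config.mask_low, config.mask_high)
            else:
                masks = None
        except Exception as exc:
            raise PipelineError("segmentation", str(exc)) from exc
        finish(mode=config.mask_mode)

        finish = stage("volume")
        try:
            vol = volume_mod.stack_to_volume(stack, masks)
            method = config.interpolation
            if method == "auto":
                method = "shape" if masks is not None else "linear"
            if config.isotropic:
                vol = volume_mod.interpolate_to_isotropic(vol, method=method)
        except Exception as exc:
            raise PipelineError("volume", str(exc)) from exc
        finish(shape_zyx=list(vol.data.shape), spacing_mm=list(vol.spacing),
               interpolation=method)

        finish = stage("reconstruction")
        try:
            surface = mc_core.extract_isosurface(vol, config.isovalue, pad=config.pad)
            out_mesh.parent.mkdir(parents=True, exist_ok=True)
            formats.write_mesh(surface, out_mesh)
        except Exception as exc:
            raise PipelineError("reconstruction", str(exc)) from exc
        finish(isovalue=config.isovalue, n_vertices=surface.n_vertices,
               n_triangles=surface.n_triangles)

        finish = stage("metrics")
        try:
            metrics = mesh_metrics.mesh_report(surface)
        except Exception as exc:
            raise PipelineError("metrics", str(exc)) from exc
        report["metrics"] = metrics
        finish(**{k: v for k, v in metrics.items() if k != "watertight"})

        report_path.parent.mkdir(parents=True, exist_ok=True)
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    except PipelineError:
        for p in (out_mesh, report_path):
            if p.exists():
                p.unlink()
                logger.info("removed partial output %s", p)
        raise
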