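"""End-to-end orchestration: structure file in, complementarity report out.

Stages: parse -> split partners -> surfaces -> interface -> patch centres
-> patches -> orient (template up, target down) -> cone fit -> disk
projection -> Zernike descriptors -> real distance -> decoy null ->
report bundle.  Every numeric output is a deterministic function of the
input file, the configuration, and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .decoys import DecoyResult, decoy_distribution, plot_decoy_histogram
from .errors import NoInterfaceError, ZernpatchError
from .patches import (
    InterfaceRegion,
    extract_patch,
    find_interface,
    interface_patch_center,
    orient_patch,
)
from .projection import DiskImage, fit_cone, project_to_disk
from .structure_io import PartnerSelection, assign_radii, parse_structure, split_partners
from .surface import compute_surface
from .zernike import ZernikeDescriptor, decompose, zernike_distance

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults follow the method's standard
    operating point: 3 A interface cutoff, 8 A patches, order-20 expansion
    on a 64 x 64 grid, 100 decoys)."""

    structure_path: str
    template_chains: str
    target_chains: str
    structure_format: str = "auto"
    interface_cutoff: float = 3.0
    patch_radius: float = 8.0
    order: int = 20
    grid_size: int = 64
    cone_half_angle: float = 45.0
    probe_radius: float = 1.4
    n_sphere_points: int = 256
    n_decoys: int = 100
    seed: int = 0
    distance_mode: str = "modulus"
    swap_decoy_roles: bool = False
    exclude_interface_decoys: bool = False
    output_dir: str = "zernpatch_out"
    write_plots: bool = False

    def __post_init__(self) -> None:
        positive = {
            "interface_cutoff": self.interface_cutoff,
            "patch_radius": self.patch_radius,
            "grid_size": self.grid_size,
            "cone_half_angle": self.cone_half_angle,
            "probe_radius": self.probe_radius,
            "n_sphere_points": self.n_sphere_points,
            "n_decoys": self.n_decoys,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if not (0 <= self.order <= 40):
            raise ValueError("expansion order must be in [0, 40]")
        self.selection = PartnerSelection.from_strings(
            self.template_chains, self.target_chains
        )


@dataclass
class RunReport:
    """Numeric results plus the paths of the written report files."""

    real_distance: float
    decoy_result: DecoyResult
    interface: InterfaceRegion
    template_descriptor: ZernikeDescriptor
    target_descriptor: ZernikeDescriptor
    template_image: DiskImage
    target_image: DiskImage
    config: RunConfig
    output_files: dict[str, str]


class StageError(ZernpatchError):
    """Wraps a failure with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}': {original}")
        self.stage = stage
        self.original = original


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except ZernpatchError as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %-18s done", name)
        return result

    structure = stage("parse", parse_structure, config.structure_path,
                      config.structure_format)
    structure = stage("radii", assign_radii, structure)
    template_st, target_st = stage("split", split_partners, structure,
                                   config.selection)
    logger.info("partners: template %d atoms, target %d atoms",
                len(template_st), len(target_st))
    template_cloud = stage("surface-template", compute_surface, template_st,
                           config.probe_radius, config.n_sphere_points)
    target_cloud = stage("surface-target", compute_surface, target_st,
                         config.probe_radius, config.n_sphere_points)
    region = stage("interface", find_interface, template_cloud, target_cloud,
                   config.interface_cutoff)
    if region.is_empty:
        raise StageError(
            "interface",
            NoInterfaceError(
                f"no interface at cutoff {config.interface_cutoff} A"
            ),
        )

    t_center = stage("center-template", interface_patch_center, region, "template")
    g_center = stage("center-target", interface_patch_center, region, "target")
    t_patch = stage("patch-template", extract_patch, template_cloud, t_center,
                    config.patch_radius)
    g_patch = stage("patch-target", extract_patch, target_cloud, g_center,
                    config.patch_radius)
    t_oriented = stage("orient-template", orient_patch, t_patch, "up")
    g_oriented = stage("orient-target", orient_patch, g_patch, "down")
    t_cone = stage("cone-template", fit_cone, t_oriented, config.cone_half_angle)
    g_cone = stage("cone-target", fit_cone, g_oriented, config.cone_half_angle)
    t_image = stage("project-template", project_to_disk, t_oriented, t_cone,
                    config.grid_size)
    g_image = stage("project-target", project_to_disk, g_oriented, g_cone,
                    config.grid_size)
    t_desc = stage("decompose-template", decompose, t_image, config.order)
    g_desc = stage("decompose-target", decompose, g_image, config.order)
    real_distance = zernike_distance(t_desc, g_desc, config.distance_mode)
    logger.info("real interface distance: %.6g", real_distance)

    if config.swap_decoy_roles:
        ref_desc, decoy_cloud = g_desc, template_cloud
        decoy_sign = "up"
        excluded = region.template_points
    else:
        ref_desc, decoy_cloud = t_desc, target_cloud
        decoy_sign = "down"
        excluded = region.target_points
    decoy_result = stage(
        "decoys",
        decoy_distribution,
        ref_desc,
        decoy_cloud,
        real_distance,
        patch_radius=config.patch_radius,
        order=config.order,
        grid_size=config.grid_size,
        cone_half_angle=config.cone_half_angle,
        n_decoys=config.n_decoys,
        rng_seed=config.seed,
        sign=decoy_sign,
        distance_mode=config.distance_mode,
        exclude_indices=excluded if config.exclude_interface_decoys else None,
    )

    files: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = str(path)

    emit("coefficients_template.csv", t_desc.write_csv)
    emit("coefficients_target.csv", g_desc.write_csv)
    emit("disk_image_template.csv", t_image.write_csv)
    emit("disk_image_target.csv", g_image.write_csv)
    emit("interface_residues.csv", region.write_residues_csv)
    emit("surface_template.csv", template_cloud.write_csv)
    emit("surface_target.csv", target_cloud.write_csv)

    result = {
        "real_distance": real_distance,
        "percentile": decoy_result.percentile,
        "z_score": decoy_result.z_score,
        "decoys": decoy_result.to_dict(),
        "config": _config_echo(config),
        "version": __version__,
    }
    emit("result.json", lambda p: Path(p).write_text(json.dumps(result, indent=2)))

    if config.write_plots:
        emit("decoy_histogram.png",
             lambda p: plot_decoy_histogram(decoy_result, p))
        emit("disk_image_template.png",
             lambda p: _plot_disk_image(t_image, p))
        emit("disk_image_target.png",
             lambda p: _plot_disk_image(g_image, p))

    return RunReport(
        real_distance=real_distance,
        decoy_result=decoy_result,
        interface=region,
        template_descriptor=t_desc,
        target_descriptor=g_desc,
        template_image=t_image,
        target_image=g_image,
        config=config,
        output_files=files,
    )


def _config_echo(config: RunConfig) -> dict:
    echo = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        echo[f.name] = v if isinstance(v, (int, float, str, bool)) else str(v)
    return echo


def _plot_disk_image(image: DiskImage, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    masked = np.where(image.mask, image.values, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(masked.T, origin="lower", extent=[-1, 1, -1, 1],
                   cmap="viridis")
    fig.colorbar(im, ax=ax, label="distance to cone vertex (A)")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
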