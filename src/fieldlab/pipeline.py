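"""End-to-end pipeline: phantom → montage → solve → analyze, plus file I/O.

``run_pipeline`` executes the full forward model for one montage and
writes volumes (NIfTI), reports (CSV/JSON), a verbatim copy of the
configuration, and a log into the output directory.  Identical
configurations produce byte-identical reports: every stage is
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .analysis import (
    FocalityReport,
    ROBUST_PERCENTILE,
    compare_montages,
    focality_volume,
    roi_summary,
)
from .errors import ConfigurationError, GeometryError, UnknownNameError
from .montage import Montage, get_montage, montage_from_yaml, stamp_montage
from .phantom import (
    HeadLabelVolume,
    PhantomConfig,
    TissueTable,
    assign_conductivity,
    build_phantom,
    label_rois,
)
from .solver import (
    FieldSolution,
    assemble_system,
    compute_current_density,
    compute_efield,
    solve_potential,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "simulate_montage",
    "write_volume",
    "read_volume",
    "load_run_outputs",
]

log = logging.getLogger("fieldlab")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; every field has a default."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    montage: str = "M1-SO"  # montage name or path to a montage YAML file
    total_current_mA: float = 1.0
    rel_tol: float = 1e-8
    percentile: float = ROBUST_PERCENTILE
    focality_fraction: float = 0.5
    out_dir: str = "fieldlab_run"
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["phantom"]["layer_radii"] = list(self.phantom.layer_radii)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path} is not a run-configuration mapping")
        phantom = doc.pop("phantom", {})
        if "layer_radii" in phantom:
            phantom["layer_radii"] = tuple(phantom["layer_radii"])
        return cls(phantom=PhantomConfig(**phantom), **doc)


def resolve_montage(name_or_path: str) -> Montage:
    """A named montage, or one loaded from a YAML file if the path exists."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") or p.exists():
        if not p.exists():
            raise UnknownNameError(f"montage file {name_or_path!r} does not exist")
        return montage_from_yaml(p)
    return get_montage(name_or_path)


def simulate_montage(
    vol: HeadLabelVolume,
    montage: Montage,
    table: TissueTable | None = None,
    total_current_mA: float | None = None,
    rel_tol: float = 1e-8,
) -> FieldSolution:
    """Stamp a montage, solve the volume-conductor problem, derive E and J."""
    table = table if table is not None else TissueTable()
    stamped, anode, cathode = stamp_montage(vol, montage)
    sigma = assign_conductivity(stamped, table)
    system = assemble_system(sigma, anode, cathode, vol.voxel_size)
    current = montage.total_current_mA if total_current_mA is None else total_current_mA
    solution = solve_potential(system, total_current_mA=current, rel_tol=rel_tol)
    solution.E = compute_efield(solution.V, system.conductive, vol.voxel_size)
    solution.J = compute_current_density(solution.E, system.sigma)
    solution.diagnostics["montage"] = montage.name
    solution.diagnostics["total_current_mA"] = current
    return solution


def run_pipeline(config: RunConfig) -> Path:
    """Run the full forward model for one montage and write all outputs.

    Returns the output directory.  Raises before any computation if the
    montage name is unknown.
    """
    montage = resolve_montage(config.montage)  # fail fast on bad names
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        t0 = time.perf_counter()
        vol = build_phantom(config.phantom)
        rois = label_rois(vol, config.phantom.roi_scheme)
        log.info("phantom built: shape=%s voxel=%gmm (%.2fs)",
                 vol.labels.shape, vol.voxel_size, time.perf_counter() - t0)

        t1 = time.perf_counter()
        solution = simulate_montage(
            vol, montage, total_current_mA=config.total_current_mA, rel_tol=config.rel_tol
        )
        diag = solution.diagnostics
        log.info(
            "solved montage=%s unknowns=%d iterations=%d residual=%.3e "
            "delivered=%.6fmA (%.2fs)",
            montage.name, diag["n_unknowns"], diag["iterations"],
            diag["relative_residual"], diag["delivered_current_mA"],
            time.perf_counter() - t1,
        )

        brain = vol.mask("gray") | vol.mask("white")
        roi_df = roi_summary(solution, rois, montage.name, config.percentile)
        foc = focality_volume(
            solution,
            brain,
            fraction=config.focality_fraction,
            head_mask=vol.labels != 0,
            montage_name=montage.name,
        )

        affine = vol.affine
        write_volume(vol.labels, affine, out / "labels.nii.gz")
        write_volume(solution.sigma, affine, out / "sigma.nii.gz")
        write_volume(solution.V, affine, out / "V.nii.gz")
        write_volume(solution.E_magnitude(), affine, out / "E_magnitude.nii.gz")
        write_volume(solution.J_magnitude(), affine, out / "J_magnitude.nii.gz")
        with open(out / "label_codes.json", "w") as fh:
            json.dump({str(k): v for k, v in vol.label_codes.items()}, fh, indent=2)

        _write_csv(roi_df, out / "roi_report.csv")
        _write_csv(foc.depth_profile, out / "depth_profile.csv")
        with open(out / "focality.json", "w") as fh:
            json.dump(foc.as_dict(), fh, indent=2, sort_keys=True)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2, sort_keys=True)
        log.info("outputs written to %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_csv(df: pd.DataFrame, path) -> None:
    # fixed float formatting keeps repeated runs byte-identical
    df.to_csv(path, index=False, float_format="%.10g")


def compare_run_dirs(dirs: list[str | Path]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild the montage comparison from ``run_pipeline`` output directories."""
    roi_reports: dict[str, pd.DataFrame] = {}
    focality: dict[str, FocalityReport] = {}
    for d in dirs:
        d = Path(d)
        df = pd.read_csv(d / "roi_report.csv")
        name = str(df["montage"].iloc[0])
        roi_reports[name] = df
        with open(d / "focality.json") as fh:
            doc = json.load(fh)
        focality[name] = FocalityReport(
            montage=name,
            brain_peak=doc["brain_peak_V_per_m"],
            brain_max=doc["brain_max_V_per_m"],
            fraction=doc["fraction"],
            focal_volume_mm3=doc["focal_volume_mm3"],
            brain_volume_mm3=doc["brain_volume_mm3"],
            depth_profile=pd.read_csv(d / "depth_profile.csv"),
        )
    return compare_montages(roi_reports, focality)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a lattice as NIfTI-1: int16 for labels, float32 for fields."""
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


def read_volume(path, reference: tuple | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; optionally check alignment with a reference.

    ``reference`` is ``(shape, affine)``; a mismatch raises
    :class:`GeometryError`.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    if reference is not None:
        ref_shape, ref_affine = reference
        if tuple(data.shape) != tuple(ref_shape) or not np.allclose(
            affine, ref_affine, atol=1e-6
        ):
            raise GeometryError(
                f"volume {path} is not aligned with the reference lattice"
            )
    return data, affine


def load_run_outputs(out_dir) -> dict:
    """Convenience loader for a pipeline output directory."""
    out = Path(out_dir)
    labels, affine = read_volume(out / "labels.nii.gz")
    ref = (labels.shape, affine)
    result = {"labels": labels, "affine": affine}
    for key in ("sigma", "V", "E_magnitude", "J_magnitude"):
        result[key], _ = read_volume(out / f"{key}.nii.gz", reference=ref)
    result["roi_report"] = pd.read_csv(out / "roi_report.csv")
    with open(out / "focality.json") as fh:
        result["focality"] = json.load(fh)
    return result
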