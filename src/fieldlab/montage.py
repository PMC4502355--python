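"""Electrode montages: specification, scalp projection, and voxel stamping.

A montage is a named set of electrodes — conventional 5 x 7 cm sponge pads
or 12 mm high-definition disks — at 10-10 scalp positions, together with
the total injected current (1 mA by default).  Stamping adds a
scalp-conforming saline-sponge/gel layer topped by a metal conductor layer
to the label volume and returns the conductor voxel masks used by the
solver as Dirichlet boundary sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import GeometryError, PlacementError, UnknownNameError
from .phantom import AIR_CODE, HeadLabelVolume
from .tenten import standard_position

__all__ = [
    "ElectrodeSpec",
    "Montage",
    "MONTAGE_NAMES",
    "get_montage",
    "project_to_scalp",
    "stamp_electrode",
    "stamp_montage",
    "montage_to_yaml",
    "montage_from_yaml",
]

PAD_DIMS_MM = (50.0, 70.0)  # conventional sponge pad: width x length
DISK_DIAMETER_MM = 12.0  # high-definition disk electrode
DEFAULT_SPONGE_MM = 5.0  # sponge thickness under pads
DEFAULT_GEL_MM = 2.0  # gel thickness under HD disks
DEFAULT_CONDUCTOR_MM = 2.0


@dataclass(frozen=True)
class ElectrodeSpec:
    """One electrode of a montage.

    ``orientation`` applies to rectangular pads: "vertical" aligns the
    70 mm axis with the local meridian (toward the vertex), "horizontal"
    with the local parallel.  At the vertex itself the meridian degenerates
    and the nasion direction is used as the reference, so a "horizontal"
    pad on Cz runs ear to ear.
    """

    position: str
    polarity: str  # "anode" | "cathode"
    shape: str = "rectangle"  # "rectangle" | "disk"
    dims_mm: tuple[float, ...] = PAD_DIMS_MM
    orientation: str | None = None
    sponge_thickness_mm: float = DEFAULT_SPONGE_MM
    conductor_thickness_mm: float = DEFAULT_CONDUCTOR_MM

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disk"):
            raise UnknownNameError(f"unknown electrode shape {self.shape!r}")
        if self.polarity not in ("anode", "cathode"):
            raise UnknownNameError(f"polarity must be anode/cathode, got {self.polarity!r}")
        if self.shape == "rectangle" and self.orientation not in ("vertical", "horizontal"):
            raise UnknownNameError(
                "rectangular pads need orientation 'vertical' or 'horizontal'"
            )


def _pad(position: str, polarity: str, orientation: str) -> ElectrodeSpec:
    return ElectrodeSpec(position, polarity, "rectangle", PAD_DIMS_MM, orientation)


def _disk(position: str, polarity: str) -> ElectrodeSpec:
    return ElectrodeSpec(
        position, polarity, "disk", (DISK_DIAMETER_MM,), None,
        sponge_thickness_mm=DEFAULT_GEL_MM,
    )


@dataclass(frozen=True)
class Montage:
    """Named electrode configuration with total injected current in mA."""

    name: str
    electrodes: tuple[ElectrodeSpec, ...]
    total_current_mA: float = 1.0

    def __post_init__(self) -> None:
        pols = {e.polarity for e in self.electrodes}
        if not {"anode", "cathode"} <= pols:
            raise UnknownNameError("a montage needs at least one anode and one cathode")

    def anodes(self) -> tuple[ElectrodeSpec, ...]:
        return tuple(e for e in self.electrodes if e.polarity == "anode")

    def cathodes(self) -> tuple[ElectrodeSpec, ...]:
        return tuple(e for e in self.electrodes if e.polarity == "cathode")


def _build_named_montages() -> dict[str, Montage]:
    return {
        # conventional pads
        "M1-SO": Montage(
            "M1-SO",
            (_pad("C3", "anode", "vertical"), _pad("Fp2", "cathode", "horizontal")),
        ),
        "DLPFC": Montage(
            "DLPFC",
            (_pad("F3", "anode", "vertical"), _pad("F4", "cathode", "vertical")),
        ),
        # anode centered on the vertex with the pad length along the
        # ear-to-ear line (the "horizontal" convention at the pole)
        "Cz-Oz": Montage(
            "Cz-Oz",
            (_pad("Cz", "anode", "horizontal"), _pad("Oz", "cathode", "horizontal")),
        ),
        # high-definition ring and paired montages
        "HD-4x1": Montage(
            "HD-4x1",
            (
                _disk("C3", "anode"),
                _disk("Cz", "cathode"),
                _disk("F3", "cathode"),
                _disk("T7", "cathode"),
                _disk("P3", "cathode"),
            ),
        ),
        "HD-2x2": Montage(
            "HD-2x2",
            (
                _disk("C3", "anode"),
                _disk("C5", "anode"),
                _disk("FC3", "cathode"),
                _disk("FC5", "cathode"),
            ),
        ),
    }


MONTAGE_NAMES: tuple[str, ...] = ("M1-SO", "DLPFC", "Cz-Oz", "HD-4x1", "HD-2x2")


def get_montage(name: str) -> Montage:
    """Return one of the five standard montages by name."""
    montages = _build_named_montages()
    if name not in montages:
        raise UnknownNameError(
            f"unknown montage {name!r}; valid names: {', '.join(MONTAGE_NAMES)}"
        )
    return montages[name]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def project_to_scalp(direction: np.ndarray, vol: HeadLabelVolume) -> np.ndarray:
    """Center (mm) of the outermost skin voxel along a ray from the origin."""
    d = np.asarray(direction, float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise GeometryError("direction must be nonzero")
    d = d / norm
    skin_code = vol.code_of("skin")
    extent = max(abs(vol.origin).max(), 1.0) + vol.voxel_size * vol.labels.shape[0]
    ts = np.arange(0.0, extent, vol.voxel_size / 2.0)
    pts = ts[:, None] * d[None, :]
    idx = vol.world_to_index(pts)
    shape = np.array(vol.labels.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[ok]
    labels = vol.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    hits = np.nonzero(labels == skin_code)[0]
    if hits.size == 0:
        raise GeometryError("ray does not intersect any skin voxel")
    i = idx[hits[-1]]
    return vol.origin + vol.voxel_size * i


def _tangent_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local (meridian, parallel) unit vectors at scalp direction ``d``."""
    zhat = np.array([0.0, 0.0, 1.0])
    m = zhat - np.dot(zhat, d) * d
    if np.linalg.norm(m) < 1e-8:  # at the vertex: use the nasion as reference
        yhat = np.array([0.0, 1.0, 0.0])
        m = yhat - np.dot(yhat, d) * d
    e_meridian = m / np.linalg.norm(m)
    e_parallel = np.cross(d, e_meridian)
    e_parallel /= np.linalg.norm(e_parallel)
    return e_meridian, e_parallel


def stamp_electrode(
    vol: HeadLabelVolume, spec: ElectrodeSpec, in_place: bool = True
) -> np.ndarray:
    """Stamp one electrode assembly onto the volume.

    Adds a scalp-conforming sponge/gel shell over the footprint, topped by a
    conductor shell, writing the ``sponge_or_gel`` and ``electrode`` label
    codes (created if absent).  Returns the boolean conductor voxel mask.
    Raises :class:`PlacementError` if the footprint touches an existing
    electrode assembly and :class:`GeometryError` if the assembly does not
    fit inside the lattice.
    """
    target = vol if in_place else vol.copy()
    d = standard_position(spec.position)
    scalp_pt = project_to_scalp(d, target)
    r_scalp = float(np.linalg.norm(scalp_pt))
    r_sponge = r_scalp + spec.sponge_thickness_mm
    r_outer = r_sponge + spec.conductor_thickness_mm
    half_extent = -target.origin.min()
    if r_outer > half_extent:
        raise GeometryError(
            f"electrode assembly at {spec.position} (outer radius {r_outer:.1f} mm) "
            f"extends past the lattice half-extent {half_extent:.1f} mm"
        )

    r = target.radius_grid()
    x, y, z = target.coordinate_grids()
    with np.errstate(invalid="ignore", divide="ignore"):
        cosg = np.clip((x * d[0] + y * d[1] + z * d[2]) / r, -1.0, 1.0)
    gamma = np.arccos(cosg)

    # arc distances at each voxel's own radius: the assembly has a constant
    # cross-section with height (a prism over the scalp), not a widening cone
    if spec.shape == "disk":
        radius = spec.dims_mm[0] / 2.0
        in_footprint = gamma * r <= radius
    else:
        width, length = spec.dims_mm
        e_mer, e_par = _tangent_frame(d)
        # geodesic tangent coordinates: arc length along the local meridian
        # and parallel directions
        vx = x / np.where(r > 0, r, 1.0) - cosg * d[0]
        vy = y / np.where(r > 0, r, 1.0) - cosg * d[1]
        vz = z / np.where(r > 0, r, 1.0) - cosg * d[2]
        vnorm = np.sqrt(vx**2 + vy**2 + vz**2)
        vnorm = np.where(vnorm > 0, vnorm, 1.0)
        arc = gamma * r
        s_mer = arc * (vx * e_mer[0] + vy * e_mer[1] + vz * e_mer[2]) / vnorm
        s_par = arc * (vx * e_par[0] + vy * e_par[1] + vz * e_par[2]) / vnorm
        if spec.orientation == "vertical":
            in_footprint = (np.abs(s_mer) <= length / 2) & (np.abs(s_par) <= width / 2)
        else:
            in_footprint = (np.abs(s_par) <= length / 2) & (np.abs(s_mer) <= width / 2)

    sponge_sel = in_footprint & (r > r_scalp) & (r <= r_sponge)
    conductor_sel = in_footprint & (r > r_sponge) & (r <= r_outer)

    sponge_code = _ensure_code(target, "sponge_or_gel")
    electrode_code = _ensure_code(target, "electrode")
    occupied = (target.labels == sponge_code) | (target.labels == electrode_code)
    if np.any(occupied & (sponge_sel | conductor_sel)):
        raise PlacementError(
            f"electrode at {spec.position} overlaps an already-stamped electrode"
        )
    # only claim air voxels: head tissue is never overwritten
    sponge_sel &= target.labels == AIR_CODE
    conductor_sel &= target.labels == AIR_CODE
    if not conductor_sel.any() or not sponge_sel.any():
        raise GeometryError(f"electrode at {spec.position} produced an empty assembly")
    target.labels[sponge_sel] = sponge_code
    target.labels[conductor_sel] = electrode_code
    return conductor_sel


def _ensure_code(vol: HeadLabelVolume, name: str) -> int:
    for code, n in vol.label_codes.items():
        if n == name:
            return code
    code = max(vol.label_codes) + 1
    vol.label_codes[code] = name
    return code


def stamp_montage(
    vol: HeadLabelVolume, montage: Montage
) -> tuple[HeadLabelVolume, np.ndarray, np.ndarray]:
    """Stamp every electrode of a montage onto a copy of the volume.

    Returns ``(stamped_volume, anode_conductor_mask, cathode_conductor_mask)``.
    """
    stamped = vol.copy()
    anode_mask = np.zeros(vol.labels.shape, dtype=bool)
    cathode_mask = np.zeros(vol.labels.shape, dtype=bool)
    for spec in montage.electrodes:
        mask = stamp_electrode(stamped, spec, in_place=True)
        if spec.polarity == "anode":
            anode_mask |= mask
        else:
            cathode_mask |= mask
    return stamped, anode_mask, cathode_mask


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def montage_to_yaml(montage: Montage, path) -> None:
    doc = {
        "name": montage.name,
        "total_current_mA": montage.total_current_mA,
        "electrodes": [
            {
                "label": e.position,
                "polarity": e.polarity,
                "shape": e.shape,
                "dims_mm": list(e.dims_mm),
                "orientation": e.orientation,
                "sponge_thickness_mm": e.sponge_thickness_mm,
                "conductor_thickness_mm": e.conductor_thickness_mm,
            }
            for e in montage.electrodes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def montage_from_yaml(path) -> Montage:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    electrodes = tuple(
        ElectrodeSpec(
            position=e["label"],
            polarity=e["polarity"],
            shape=e.get("shape", "rectangle"),
            dims_mm=tuple(e.get("dims_mm", PAD_DIMS_MM)),
            orientation=e.get("orientation"),
            sponge_thickness_mm=e.get("sponge_thickness_mm", DEFAULT_SPONGE_MM),
            conductor_thickness_mm=e.get("conductor_thickness_mm", DEFAULT_CONDUCTOR_MM),
        )
        for e in doc["electrodes"]
    )
    return Montage(doc["name"], electrodes, doc.get("total_current_mA", 1.0))
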