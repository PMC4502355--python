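"""Synthetic layered-sphere head phantoms.

A volume-conductor head model is represented as a 3-D lattice of integer
tissue labels (:class:`HeadLabelVolume`).  The default phantom is a set of
concentric spherical shells — white matter, gray matter, CSF, skull, fat,
skin — surrounded by air, emulating a segmented structural MRI of a human
head.  Geometric stand-ins for the regions of interest usually analyzed in
tDCS forward modeling (motor/somatosensory/prefrontal/visual cortex plus
the deep structures insula, cingulate, thalamus, brainstem) are carved out
of the gray/white shells by :func:`label_rois`.

Coordinate convention: world origin at the sphere center, +z toward the
vertex, +y toward the nasion, +x toward the right preauricular point.
World coordinates are in mm; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, LabelingError, UnknownNameError

__all__ = [
    "DEFAULT_CONDUCTIVITIES",
    "TISSUE_ORDER",
    "TissueTable",
    "HeadLabelVolume",
    "PhantomConfig",
    "ROIVolume",
    "ROI_NAMES",
    "build_phantom",
    "build_layered_volume",
    "assign_conductivity",
    "label_rois",
]

#: Isotropic tissue conductivities (S/m) of the standard head model.
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "skin": 0.465,
    "fat": 0.025,
    "skull": 0.01,
    "CSF": 1.65,
    "gray": 0.276,
    "white": 0.126,
    "air": 1e-15,
    "sponge_or_gel": 1.4,
    "electrode": 5.99e7,
}

#: Radial order of the phantom shells, innermost first.
TISSUE_ORDER: tuple[str, ...] = ("white", "gray", "CSF", "skull", "fat", "skin")

AIR_CODE = 0


@dataclass(frozen=True)
class TissueTable:
    """Mapping from tissue name to isotropic conductivity in S/m."""

    entries: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        for name, sigma in self.entries.items():
            if not sigma > 0:
                raise ConfigurationError(
                    f"conductivity of {name!r} must be strictly positive, got {sigma}"
                )

    def __getitem__(self, name: str) -> float:
        try:
            return self.entries[name]
        except KeyError:
            raise LabelingError(f"no conductivity for tissue {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries


@dataclass
class HeadLabelVolume:
    """3-D integer tissue-label lattice with isotropic voxel size.

    Attributes
    ----------
    labels : ndarray of int16, shape (nx, ny, nz)
        One tissue/material code per voxel; ``0`` is air/background.
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    label_codes : dict
        Mapping code -> tissue name.
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray
    label_codes: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ConfigurationError("labels must be a 3-D lattice")

    # -- geometry helpers -------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """World affine (mm) in NIfTI convention (voxel index -> world)."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + self.voxel_size * np.arange(self.labels.shape[a])
            for a in range(3)
        )

    def radius_grid(self) -> np.ndarray:
        """Distance (mm) of every voxel center from the world origin."""
        x, y, z = self.axis_coords()
        return np.sqrt(
            x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = self.axis_coords()
        return np.meshgrid(x, y, z, indexing="ij", sparse=True)

    def code_of(self, tissue: str) -> int:
        for code, name in self.label_codes.items():
            if name == tissue:
                return code
        raise LabelingError(f"volume has no label code for tissue {tissue!r}")

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == self.code_of(tissue)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices of world points (mm); no bounds check."""
        return np.rint((np.asarray(points, float) - self.origin) / self.voxel_size).astype(
            int
        )

    def copy(self) -> "HeadLabelVolume":
        return HeadLabelVolume(
            self.labels.copy(), self.voxel_size, self.origin.copy(), dict(self.label_codes)
        )


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the layered-sphere phantom.

    ``layer_radii`` are outer radii (mm) in the order of :data:`TISSUE_ORDER`;
    they must be strictly increasing.  ``margin`` is the air padding around
    the scalp left for electrode assemblies.  The optional midsagittal CSF
    conduit emulates a highly conductive intracerebral vessel running from
    the vertex toward the head center.
    """

    layer_radii: tuple[float, ...] = (58.0, 72.0, 76.0, 83.0, 85.0, 92.0)
    voxel_size: float = 1.0
    medial_csf_conduit: bool = False
    conduit_radius: float = 2.0
    roi_scheme: str = "default"
    random_seed: int = 0
    margin: float = 12.0

    def __post_init__(self) -> None:
        radii = np.asarray(self.layer_radii, float)
        if len(radii) != len(TISSUE_ORDER):
            raise ConfigurationError(
                f"expected {len(TISSUE_ORDER)} layer radii, got {len(radii)}"
            )
        if not np.all(np.diff(radii) > 0) or radii[0] <= 0:
            raise ConfigurationError("layer radii must be positive and strictly increasing")
        thickness = np.diff(np.concatenate([[0.0], radii]))
        if self.voxel_size > thickness.min():
            raise ConfigurationError(
                f"voxel size {self.voxel_size} mm exceeds the thinnest layer "
                f"({thickness.min()} mm)"
            )
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel size must be positive")


def build_layered_volume(
    radii: Sequence[float],
    tissue_names: Sequence[str],
    voxel_size: float,
    margin: float = 12.0,
) -> HeadLabelVolume:
    """Voxelize concentric spherical shells into a :class:`HeadLabelVolume`.

    ``radii`` are strictly increasing outer radii (mm); ``tissue_names[i]``
    labels the shell whose outer radius is ``radii[i]``.  A voxel belongs to
    the innermost shell whose outer radius is >= its center distance from
    the origin; everything beyond the last radius is air (code 0).  The grid
    is sized so the world origin falls exactly on a voxel center, which
    makes the construction symmetric under coordinate reflections.
    """
    radii = np.asarray(radii, float)
    if not np.all(np.diff(radii) > 0):
        raise ConfigurationError("radii must be strictly increasing")
    if len(radii) != len(tissue_names):
        raise ConfigurationError("radii and tissue_names must have equal length")
    half = radii[-1] + margin
    n_half = int(np.ceil(half / voxel_size))
    n = 2 * n_half + 1
    origin = np.full(3, -n_half * voxel_size)
    codes = {AIR_CODE: "air"}
    for i, name in enumerate(tissue_names):
        codes[i + 1] = name
    vol = HeadLabelVolume(
        labels=np.zeros((n, n, n), dtype=np.int16),
        voxel_size=voxel_size,
        origin=origin,
        label_codes=codes,
    )
    r = vol.radius_grid()
    shell = np.searchsorted(radii, r)  # 0..len(radii); == len(radii) -> air
    inside = shell < len(radii)
    vol.labels[inside] = (shell[inside] + 1).astype(np.int16)
    return vol


def build_phantom(config: PhantomConfig) -> HeadLabelVolume:
    """Build the default multi-layer sphere head phantom.

    Deterministic given the configuration.  With ``medial_csf_conduit`` on,
    head voxels inside a vertical cylinder of ``conduit_radius`` running
    from the vertex down to the head center along the midsagittal plane are
    relabeled CSF, creating a preferential low-resistance conduit into
    medial regions.
    """
    vol = build_layered_volume(
        config.layer_radii, TISSUE_ORDER, config.voxel_size, config.margin
    )
    if config.medial_csf_conduit:
        x, y, z = vol.coordinate_grids()
        cyl = (x**2 + y**2 <= config.conduit_radius**2) & (z >= 0)
        head = vol.labels != AIR_CODE
        vol.labels[cyl & head] = vol.code_of("CSF")
    return vol


def assign_conductivity(vol: HeadLabelVolume, table: TissueTable | None = None) -> np.ndarray:
    """Per-voxel conductivity lattice (S/m).

    Air voxels are excluded from the conductive domain and get sigma = 0
    (the solver treats sigma == 0 as an insulated boundary, honoring the
    nominal 1e-15 S/m of air as "insulating").
    """
    table = table if table is not None else TissueTable()
    sigma = np.zeros(vol.labels.shape, dtype=np.float64)
    present = np.unique(vol.labels)
    for code in present:
        name = vol.label_codes.get(int(code))
        if name is None:
            raise LabelingError(f"label code {int(code)} has no tissue mapping")
        if name == "air":
            continue
        sigma[vol.labels == code] = table[name]
    return sigma


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------

ROI_NAMES: tuple[str, ...] = (
    "PFC",
    "M1",
    "S1",
    "occipital",
    "insula_L",
    "insula_R",
    "cingulate",
    "thalamus",
    "brainstem",
)

#: ROIs treated as deep structures in montage comparisons.
DEEP_ROIS: tuple[str, ...] = ("insula_L", "insula_R", "cingulate", "thalamus", "brainstem")
SUPERFICIAL_ROIS: tuple[str, ...] = ("PFC", "M1", "S1", "occipital")


@dataclass
class ROIVolume:
    """Integer ROI-label lattice aligned with a :class:`HeadLabelVolume`."""

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray
    roi_codes: dict[int, str]

    def mask(self, roi: str) -> np.ndarray:
        for code, name in self.roi_codes.items():
            if name == roi:
                return self.labels == code
        raise UnknownNameError(f"unknown ROI {roi!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.roi_codes[c] for c in sorted(self.roi_codes))


def _rotate_about_x(v: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([v[0], c * v[1] - s * v[2], s * v[1] + c * v[2]])


def label_rois(vol: HeadLabelVolume, scheme: str = "default") -> ROIVolume:
    """Geometric stand-in ROIs carved from the gray/white shells.

    The default scheme places: PFC as an anterior gray cap; M1 as a gray
    sector under the C3 direction with S1 immediately posterior; an
    occipital (V1/V2) posterior gray cap; left/right mid-depth gray insula
    patches; a parasagittal gray cingulate slab; a central thalamus
    ellipsoid inside white matter; and an inferior axial brainstem
    cylinder.  ROIs are assigned with a fixed precedence so labels are
    pairwise disjoint by construction.
    """
    if scheme != "default":
        raise UnknownNameError(f"unknown ROI scheme {scheme!r}")
    from .tenten import standard_position  # local import to avoid cycles

    gray = vol.mask("gray")
    white = vol.mask("white")
    brain = gray | white
    x, y, z = vol.coordinate_grids()
    r = vol.radius_grid()
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = x / r, y / r, z / r

    def cone(direction: np.ndarray, half_angle_deg: float) -> np.ndarray:
        d = direction / np.linalg.norm(direction)
        cosg = ux * d[0] + uy * d[1] + uz * d[2]
        return cosg >= np.cos(np.deg2rad(half_angle_deg))

    c3 = standard_position("C3")
    s1_dir = _rotate_about_x(c3, 24.0)  # posterior to C3

    regions: dict[str, np.ndarray] = {
        "thalamus": white
        & ((x / 10.0) ** 2 + (y / 12.0) ** 2 + (z / 8.0) ** 2 <= 1.0),
        "brainstem": brain & (x**2 + y**2 <= 8.0**2) & (z <= -25.0) & (z >= -70.0),
        "M1": gray & cone(c3, 12.0),
        "S1": gray & cone(s1_dir, 11.0),
        "insula_L": gray & (r <= 66.0) & cone(np.array([-1.0, 0.0, 0.0]), 25.0),
        "insula_R": gray & (r <= 66.0) & cone(np.array([1.0, 0.0, 0.0]), 25.0),
        "PFC": gray & cone(np.array([0.0, 1.0, 0.7]), 30.0),
        "occipital": gray & cone(np.array([0.0, -1.0, 0.7]), 30.0),
        "cingulate": gray & (np.abs(x) <= 6.0) & (z >= 10.0),
    }

    labels = np.zeros(vol.labels.shape, dtype=np.int16)
    roi_codes: dict[int, str] = {}
    for i, name in enumerate(ROI_NAMES, start=1):
        m = regions[name] & (labels == 0)
        labels[m] = i
        roi_codes[i] = name
    return ROIVolume(labels, vol.voxel_size, vol.origin.copy(), roi_codes)


def head_connected_components(vol: HeadLabelVolume) -> int:
    """Number of 6-connected components of the non-air voxel set."""
    structure = ndimage.generate_binary_structure(3, 1)
    _, n = ndimage.label(vol.labels != AIR_CODE, structure=structure)
    return int(n)
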