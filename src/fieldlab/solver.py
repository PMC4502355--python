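"""Finite-volume solver for the volume-conductor problem ∇·(σ∇V) = 0.

The quasi-static continuity equation is discretized on the labeled voxel
lattice with a 7-point finite-volume stencil: the conductance of the face
between two neighboring conductive voxels is the harmonic mean of their
conductivities times face-area over spacing.  Air voxels (σ = 0) are
excluded from the domain, which makes every outer surface a zero-flux
(insulated) boundary.  Anode conductor voxels are held at a provisional
potential of 1 V and cathode conductors at 0 V; after the solve, the
potential is rescaled linearly so the delivered current through the anode
contact equals the requested total current (valid because the problem is
linear and the metal electrodes are equipotential).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .errors import ConvergenceError, GeometryError, MaskError, TopologyError

__all__ = [
    "LinearSystem",
    "FieldSolution",
    "assemble_system",
    "solve_potential",
    "compute_efield",
    "compute_current_density",
    "surface_current",
]

_AXES = (0, 1, 2)


@dataclass
class LinearSystem:
    """Assembled sparse system over the conductive-voxel unknowns."""

    A: sparse.csr_matrix
    b: np.ndarray
    unknown_index: np.ndarray  # lattice of indices into the unknown vector, -1 elsewhere
    conductive: np.ndarray  # bool lattice: the solved domain (incl. electrodes)
    anode_mask: np.ndarray
    cathode_mask: np.ndarray
    sigma: np.ndarray
    voxel_size_mm: float
    face_conductance: tuple[np.ndarray, np.ndarray, np.ndarray] = dc_field(repr=False)

    @property
    def n_unknowns(self) -> int:
        return self.b.size


@dataclass
class FieldSolution:
    """Potential and derived fields on the voxel lattice.

    ``V`` is in volts (0 on cathode conductors), ``E`` in V/m, ``J`` in
    A/m²; all arrays are zero outside the conductive domain.
    """

    V: np.ndarray
    E: np.ndarray | None
    J: np.ndarray | None
    sigma: np.ndarray
    conductive: np.ndarray
    anode_mask: np.ndarray
    cathode_mask: np.ndarray
    voxel_size_mm: float
    diagnostics: dict

    def E_magnitude(self) -> np.ndarray:
        if self.E is None:
            raise ValueError("E has not been computed")
        return np.sqrt(np.sum(self.E**2, axis=-1))

    def J_magnitude(self) -> np.ndarray:
        if self.J is None:
            raise ValueError("J has not been computed")
        return np.sqrt(np.sum(self.J**2, axis=-1))


def _face_conductances(
    sigma: np.ndarray, conductive: np.ndarray, voxel_size_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic-mean face conductances (S) along each axis.

    ``g[axis]`` has the lattice shape shortened by one along ``axis``;
    entry i is the conductance between voxel i and voxel i+1.  For a cubic
    voxel of edge h, face area over spacing is h (in meters).
    """
    h_m = voxel_size_mm * 1e-3
    out = []
    for ax in _AXES:
        s0 = sigma[_slice(ax, slice(None, -1))]
        s1 = sigma[_slice(ax, slice(1, None))]
        both = conductive[_slice(ax, slice(None, -1))] & conductive[_slice(ax, slice(1, None))]
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = 2.0 * s0 * s1 / (s0 + s1)
        g = np.where(both, hm, 0.0) * h_m
        out.append(g)
    return tuple(out)


def _slice(axis: int, sl: slice) -> tuple:
    full = [slice(None)] * 3
    full[axis] = sl
    return tuple(full)


def assemble_system(
    sigma: np.ndarray,
    anode_mask: np.ndarray,
    cathode_mask: np.ndarray,
    voxel_size_mm: float,
) -> LinearSystem:
    """Assemble the discrete continuity equation with electrode Dirichlet sets.

    Voxels with σ <= 0 are excluded (insulated boundary).  Conductive
    voxels with no path to the electrode-bearing component are dropped from
    the domain (their potential is undefined up to a constant); if anodes
    and cathodes do not share a conductive component a
    :class:`TopologyError` is raised.
    """
    sigma = np.asarray(sigma, float)
    if not anode_mask.any() or not cathode_mask.any():
        raise MaskError("anode and cathode masks must both be nonempty")
    if np.any(anode_mask & cathode_mask):
        raise MaskError("anode and cathode masks overlap")
    conductive = sigma > 0
    if np.any((anode_mask | cathode_mask) & ~conductive):
        raise MaskError("electrode masks must lie inside the conductive domain")

    structure = ndimage.generate_binary_structure(3, 1)
    comp, _ = ndimage.label(conductive, structure=structure)
    anode_comps = np.unique(comp[anode_mask])
    cathode_comps = np.unique(comp[cathode_mask])
    common = np.intersect1d(anode_comps, cathode_comps)
    if common.size == 0:
        raise TopologyError("no conductive path connects the anode(s) to the cathode(s)")
    keep = np.isin(comp, common) & conductive
    conductive = keep

    g = _face_conductances(sigma, conductive, voxel_size_mm)

    dirichlet = anode_mask | cathode_mask
    unknown = conductive & ~dirichlet
    unknown_index = np.full(sigma.shape, -1, dtype=np.int64)
    n = int(unknown.sum())
    unknown_index[unknown] = np.arange(n)

    v_dir = np.zeros(sigma.shape)
    v_dir[anode_mask] = 1.0

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)
    for ax in _AXES:
        gi = g[ax]
        lo = _slice(ax, slice(None, -1))
        hi = _slice(ax, slice(1, None))
        iu, ju = unknown_index[lo], unknown_index[hi]
        active = gi > 0
        # face between two unknowns: symmetric off-diagonals
        both = active & (iu >= 0) & (ju >= 0)
        gi_b = gi[both]
        rows.append(iu[both]); cols.append(ju[both]); vals.append(-gi_b)
        rows.append(ju[both]); cols.append(iu[both]); vals.append(-gi_b)
        np.add.at(diag, iu[both], gi_b)
        np.add.at(diag, ju[both], gi_b)
        # face between an unknown and a Dirichlet voxel
        for a_idx, b_idx, side in ((iu, ju, hi), (ju, iu, lo)):
            m = active & (a_idx >= 0) & (b_idx < 0) & dirichlet[side]
            np.add.at(diag, a_idx[m], gi[m])
            np.add.at(b, a_idx[m], gi[m] * v_dir[side][m])

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return LinearSystem(
        A=A,
        b=b,
        unknown_index=unknown_index,
        conductive=conductive,
        anode_mask=anode_mask,
        cathode_mask=cathode_mask,
        sigma=np.where(conductive, sigma, 0.0),
        voxel_size_mm=voxel_size_mm,
        face_conductance=g,
    )


def _electrode_current_A(system: LinearSystem, V: np.ndarray, mask: np.ndarray) -> float:
    """Net current (A) flowing out of a voxel set through its boundary faces."""
    total = 0.0
    for ax in _AXES:
        gi = system.face_conductance[ax]
        lo = _slice(ax, slice(None, -1))
        hi = _slice(ax, slice(1, None))
        in_lo, in_hi = mask[lo], mask[hi]
        crossing = (in_lo != in_hi) & (gi > 0)
        dv = V[lo] - V[hi]  # positive when current flows lo -> hi
        sign = np.where(in_lo, 1.0, -1.0)
        total += float(np.sum(gi[crossing] * dv[crossing] * sign[crossing]))
    return total


def solve_potential(
    system: LinearSystem,
    total_current_mA: float = 1.0,
    rel_tol: float = 1e-8,
    maxiter: int | None = None,
) -> FieldSolution:
    """Solve for the potential and rescale to the requested total current.

    Conjugate gradients with a Jacobi preconditioner; deterministic.  The
    provisional anode potential of 1 V is rescaled so that the current
    integrated over the anode contact equals ``total_current_mA``.
    """
    if not (0 < rel_tol <= 1e-4):
        raise ValueError("rel_tol must be in (0, 1e-4]")
    A, b = system.A, system.b
    n = b.size
    if maxiter is None:
        # generous cap scaling with the per-dimension extent ~ n^(1/3)
        maxiter = max(2000, 500 * int(n ** (1 / 3)))
    inv_diag = 1.0 / A.diagonal()
    M = sparse.diags(inv_diag)
    iters = 0

    def _count(_):
        nonlocal iters
        iters += 1

    x, info = cg(A, b, rtol=rel_tol, atol=0.0, maxiter=maxiter, M=M, callback=_count)
    residual = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
    if info != 0:
        raise ConvergenceError(
            f"conjugate gradients failed to reach rel_tol={rel_tol:g} in {iters} "
            f"iterations (relative residual {residual:.3e})"
        )

    V = np.zeros(system.sigma.shape)
    V[system.unknown_index >= 0] = x[system.unknown_index[system.unknown_index >= 0]]
    V[system.anode_mask] = 1.0
    delivered_A = _electrode_current_A(system, V, system.anode_mask)
    scale = (total_current_mA * 1e-3) / delivered_A
    V *= scale
    diagnostics = {
        "iterations": iters,
        "relative_residual": residual,
        "scale_factor": scale,
        "delivered_current_mA": _electrode_current_A(system, V, system.anode_mask) * 1e3,
        "cathode_current_mA": _electrode_current_A(system, V, system.cathode_mask) * 1e3,
        "n_unknowns": n,
    }
    return FieldSolution(
        V=V,
        E=None,
        J=None,
        sigma=system.sigma,
        conductive=system.conductive,
        anode_mask=system.anode_mask,
        cathode_mask=system.cathode_mask,
        voxel_size_mm=system.voxel_size_mm,
        diagnostics=diagnostics,
    )


def compute_efield(
    V: np.ndarray, conductive: np.ndarray, voxel_size_mm: float
) -> np.ndarray:
    """E = −∇V (V/m): central differences inside the conductive domain,
    one-sided at its boundary, zero outside."""
    h_m = voxel_size_mm * 1e-3
    E = np.zeros(V.shape + (3,))
    for ax in _AXES:
        plus = np.zeros_like(V)
        minus = np.zeros_like(V)
        has_plus = np.zeros(V.shape, dtype=bool)
        has_minus = np.zeros(V.shape, dtype=bool)
        plus[_slice(ax, slice(None, -1))] = V[_slice(ax, slice(1, None))]
        has_plus[_slice(ax, slice(None, -1))] = conductive[_slice(ax, slice(1, None))]
        minus[_slice(ax, slice(1, None))] = V[_slice(ax, slice(None, -1))]
        has_minus[_slice(ax, slice(1, None))] = conductive[_slice(ax, slice(None, -1))]

        grad = np.zeros_like(V)
        central = has_plus & has_minus
        grad[central] = (plus[central] - minus[central]) / (2 * h_m)
        fwd = has_plus & ~has_minus
        grad[fwd] = (plus[fwd] - V[fwd]) / h_m
        bwd = has_minus & ~has_plus
        grad[bwd] = (V[bwd] - minus[bwd]) / h_m
        grad[~conductive] = 0.0
        E[..., ax] = -grad
    E[~conductive] = 0.0
    return E


def compute_current_density(E: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Ohmic current density J = σE (A/m²)."""
    return sigma[..., None] * E


def surface_current(
    system: LinearSystem, V: np.ndarray, region_mask: np.ndarray
) -> float:
    """Net current (mA) flowing out of a voxel region through its boundary.

    The region must separate electrodes of one polarity from the other
    (e.g. the anode contact itself, or a half-domain containing all
    anodes); a region straddling both polarities has no well-defined
    delivered current and raises :class:`GeometryError`.
    """
    if not region_mask.any():
        raise GeometryError("region mask is empty")
    has_anode = bool(np.any(region_mask & system.anode_mask))
    has_cathode = bool(np.any(region_mask & system.cathode_mask))
    if has_anode and has_cathode:
        raise GeometryError("region contains both anode and cathode voxels")
    return _electrode_current_A(system, V, region_mask) * 1e3
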