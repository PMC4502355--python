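"""Shared fixtures: phantoms and the five solved montages at 2 mm.

The heavy forward solves are session-scoped so the analysis, pipeline and
acceptance tests all reuse one set of solutions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import fieldlab as fl
from fieldlab.sphere import SphereLayers

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: validation-style head geometry (no fat shell): white, gray, CSF, skull, skin
HEAD5 = SphereLayers(
    radii_mm=(58.0, 72.0, 76.0, 83.0, 92.0),
    conductivities=(0.126, 0.276, 1.65, 0.01, 0.465),
)


@pytest.fixture(scope="session")
def phantom2() -> fl.HeadLabelVolume:
    """Default 7-layer phantom at 2 mm."""
    return fl.build_phantom(fl.PhantomConfig(voxel_size=2.0))


@pytest.fixture(scope="session")
def rois2(phantom2) -> fl.ROIVolume:
    return fl.label_rois(phantom2)


@pytest.fixture(scope="session")
def phantom1() -> fl.HeadLabelVolume:
    """Default phantom at the native 1 mm resolution (labeling only)."""
    return fl.build_phantom(fl.PhantomConfig(voxel_size=1.0))


@pytest.fixture(scope="session")
def montage_solutions(phantom2) -> dict[str, fl.FieldSolution]:
    """All five montages solved at 1 mA on the default 2 mm phantom."""
    return {
        name: fl.simulate_montage(phantom2, fl.get_montage(name))
        for name in fl.MONTAGE_NAMES
    }


@pytest.fixture(scope="session")
def brain_mask(phantom2) -> np.ndarray:
    return phantom2.mask("gray") | phantom2.mask("white")


@pytest.fixture(scope="session")
def small_sphere_solution():
    """A small 3-layer sphere with two disk electrodes at 4 mm, with its system.

    Used for conservation, reciprocity and surface-current tests where the
    assembled :class:`LinearSystem` is needed alongside the solution.
    """
    from fieldlab.montage import ElectrodeSpec
    from fieldlab.phantom import TissueTable, assign_conductivity, build_layered_volume
    from fieldlab.solver import assemble_system, solve_potential
    from fieldlab.sphere import _stamp_disk_at_direction

    layers = SphereLayers((60.0, 70.0, 80.0), (0.276, 0.01, 0.465))
    names = ["brain", "shell", "scalp"]
    vol = build_layered_volume(layers.radii_mm, names, 4.0)
    table = TissueTable(
        {"brain": 0.276, "shell": 0.01, "scalp": 0.465,
         "sponge_or_gel": 1.4, "electrode": 5.99e7}
    )
    d1 = np.array([0.0, 0.0, 1.0])
    d2 = np.array([0.0, 0.0, -1.0])
    spec = dict(shape="disk", dims_mm=(8.0,), sponge_thickness_mm=2.0)
    anode = _stamp_disk_at_direction(vol, ElectrodeSpec("Cz", "anode", **spec), d1)
    cathode = _stamp_disk_at_direction(vol, ElectrodeSpec("Cz", "cathode", **spec), d2)
    sigma = assign_conductivity(vol, table)
    system = assemble_system(sigma, anode, cathode, 4.0)
    solution = solve_potential(system, total_current_mA=1.0)
    return vol, system, solution
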