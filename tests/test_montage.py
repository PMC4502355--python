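"""10-10 positions, scalp projection, electrode stamping and montages."""

import numpy as np
import pytest

import fieldlab as fl
from fieldlab.errors import GeometryError, PlacementError, UnknownNameError
from fieldlab.montage import ElectrodeSpec, montage_from_yaml, montage_to_yaml, stamp_electrode
from fieldlab.tenten import angular_distance_deg, standard_position


class TestStandardPositions:
    def test_vertex_and_arc_fractions(self):
        assert np.allclose(standard_position("Cz"), [0, 0, 1])
        assert angular_distance_deg("Cz", "C3") == pytest.approx(36.0, abs=1e-9)
        assert angular_distance_deg("Cz", "T7") == pytest.approx(72.0, abs=1e-9)
        assert angular_distance_deg("Cz", "Oz") == pytest.approx(72.0, abs=1e-9)

    @pytest.mark.parametrize(
        "left,right",
        [("C3", "C4"), ("C5", "C6"), ("F3", "F4"), ("FC3", "FC4"),
         ("P3", "P4"), ("Fp1", "Fp2"), ("O1", "O2"), ("T7", "T8")],
    )
    def test_left_right_mirror_symmetry(self, left, right):
        a = standard_position(left)
        b = standard_position(right)
        assert np.allclose(a * [-1, 1, 1], b, atol=1e-12)

    def test_all_supported_labels_are_unit_vectors(self):
        for lab in ["Cz", "C1", "C3", "C5", "T7", "Oz", "Fpz", "Fz", "Pz",
                    "Fp2", "F3", "F4", "F7", "FC3", "FC5", "CP3", "P3", "O1"]:
            v = standard_position(lab)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_label(self):
        with pytest.raises(UnknownNameError):
            standard_position("XX9")


class TestProjectToScalp:
    def test_axis_directions_hit_skin_radius(self, phantom2):
        h = phantom2.voxel_size
        p = fl.project_to_scalp(np.array([0.0, 0.0, 1.0]), phantom2)
        assert np.allclose(p, [0, 0, 92], atol=h / 2 + 1e-9)
        p = fl.project_to_scalp(np.array([1.0, 0.0, 0.0]), phantom2)
        assert np.allclose(p, [92, 0, 0], atol=h / 2 + 1e-9)

    def test_oblique_direction_norm(self, phantom2):
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        p = fl.project_to_scalp(d, phantom2)
        assert abs(np.linalg.norm(p) - 92.0) <= phantom2.voxel_size

    def test_zero_direction(self, phantom2):
        with pytest.raises(GeometryError):
            fl.project_to_scalp(np.zeros(3), phantom2)


class TestStamping:
    def test_disk_footprint_area(self, phantom1):
        vol = phantom1.copy()
        mask = stamp_electrode(
            vol,
            ElectrodeSpec("Cz", "anode", "disk", (12.0,), None, sponge_thickness_mm=2.0),
        )
        area = mask.sum() * vol.voxel_size**3 / 2.0  # conductor layer is 2 mm thick
        assert abs(area - np.pi * 6.0**2) / (np.pi * 6.0**2) < 0.15

    def test_pad_footprint_area(self, phantom1):
        vol = phantom1.copy()
        mask = stamp_electrode(
            vol, ElectrodeSpec("C3", "anode", "rectangle", (50.0, 70.0), "vertical")
        )
        area = mask.sum() * vol.voxel_size**3 / 2.0
        assert abs(area - 3500.0) / 3500.0 < 0.10

    def test_overlapping_electrodes_rejected(self, phantom2):
        vol = phantom2.copy()
        spec = ElectrodeSpec("Cz", "anode", "disk", (12.0,), None, sponge_thickness_mm=2.0)
        stamp_electrode(vol, spec)
        with pytest.raises(PlacementError):
            stamp_electrode(vol, ElectrodeSpec("Cz", "cathode", "disk", (12.0,), None,
                                               sponge_thickness_mm=2.0))

    @pytest.mark.parametrize("voxel", [2.0, 1.0])
    def test_all_five_montages_stamp_without_overlap(self, voxel, phantom1, phantom2):
        vol = phantom1 if voxel == 1.0 else phantom2
        for name in fl.MONTAGE_NAMES:
            stamped, anode, cathode = fl.stamp_montage(vol, fl.get_montage(name))
            assert anode.any() and cathode.any()
            assert not np.any(anode & cathode)

    def test_electrode_layers_adjacent_to_sponge_and_skin(self, phantom2):
        from scipy import ndimage

        vol = phantom2.copy()
        cond = stamp_electrode(
            vol, ElectrodeSpec("Cz", "anode", "disk", (12.0,), None,
                               sponge_thickness_mm=2.0)
        )
        sponge = vol.mask("sponge_or_gel")
        skin = vol.mask("skin")
        struct = ndimage.generate_binary_structure(3, 1)
        # conductor touches sponge; sponge touches skin (6-connectivity)
        assert np.any(ndimage.binary_dilation(cond, struct) & sponge)
        assert np.any(ndimage.binary_dilation(sponge, struct) & skin)
        # electrode material is disjoint from every tissue mask
        for tissue in ("skin", "fat", "skull", "CSF", "gray", "white"):
            assert not np.any(cond & vol.mask(tissue))


class TestMontages:
    def test_m1_so_definition(self):
        m = fl.get_montage("M1-SO")
        (anode,) = m.anodes()
        (cathode,) = m.cathodes()
        assert (anode.position, anode.shape, anode.orientation) == ("C3", "rectangle", "vertical")
        assert (cathode.position, cathode.orientation) == ("Fp2", "horizontal")
        assert anode.dims_mm == (50.0, 70.0)
        assert m.total_current_mA == 1.0

    def test_dlpfc_definition(self):
        m = fl.get_montage("DLPFC")
        assert [e.position for e in m.anodes()] == ["F3"]
        assert [e.position for e in m.cathodes()] == ["F4"]
        assert all(e.orientation == "vertical" for e in m.electrodes)

    def test_cz_oz_definition(self, phantom2):
        m = fl.get_montage("Cz-Oz")
        (anode,) = m.anodes()
        (cathode,) = m.cathodes()
        assert (anode.position, cathode.position) == ("Cz", "Oz")
        # the Cz pad's 70 mm axis runs along the ear-to-ear (x) line
        vol = phantom2.copy()
        mask = stamp_electrode(vol, anode)
        idx = np.argwhere(mask)
        extent = (idx.max(axis=0) - idx.min(axis=0)) * vol.voxel_size
        assert extent[0] > extent[1]  # longer in x than in y

    def test_hd_montage_definitions(self):
        m41 = fl.get_montage("HD-4x1")
        assert [e.position for e in m41.anodes()] == ["C3"]
        assert sorted(e.position for e in m41.cathodes()) == ["Cz", "F3", "P3", "T7"]
        assert all(e.shape == "disk" and e.dims_mm == (12.0,) for e in m41.electrodes)
        m22 = fl.get_montage("HD-2x2")
        assert sorted(e.position for e in m22.anodes()) == ["C3", "C5"]
        assert sorted(e.position for e in m22.cathodes()) == ["FC3", "FC5"]

    def test_hd_4x1_ring_azimuths_90_degrees_apart(self):
        c3 = standard_position("C3")
        e1 = np.array([0.0, 0.0, 1.0])
        e1 = e1 - (e1 @ c3) * c3
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(c3, e1)
        az = []
        for lab in ("Cz", "F3", "T7", "P3"):
            u = standard_position(lab)
            v = u - (u @ c3) * c3
            az.append(np.rad2deg(np.arctan2(v @ e2, v @ e1)) % 360)
        az = np.sort(az)
        gaps = np.diff(np.concatenate([az, [az[0] + 360]]))
        assert np.all(np.abs(gaps - 90.0) < 10.0)

    def test_unknown_montage(self):
        with pytest.raises(UnknownNameError, match="M1-SO"):
            fl.get_montage("M1_SO_typo")

    def test_yaml_round_trip(self, tmp_path):
        m = fl.get_montage("HD-2x2")
        path = tmp_path / "m.yaml"
        montage_to_yaml(m, path)
        back = montage_from_yaml(path)
        assert back == m
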