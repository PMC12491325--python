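"""Loop geometry: torsion oracle, regions, contacts, PCA shape."""

import numpy as np
import pytest

from thymosig import geometry as geo


def mirror(residues):
    flip = np.array([1.0, 1.0, -1.0])
    return [{**r, "N": np.asarray(r["N"]) * flip, "CA": np.asarray(r["CA"]) * flip,
             "C": np.asarray(r["C"]) * flip} for r in residues]


class TestDihedrals:
    def test_alpha_helix_recovered_within_one_degree(self):
        res = geo.build_backbone([(-57.0, -47.0)] * 10)
        out = geo.backbone_dihedrals(res)
        for g in out[1:-1]:
            assert g.phi == pytest.approx(-57.0, abs=1.0)
            assert g.psi == pytest.approx(-47.0, abs=1.0)

    def test_arbitrary_angle_series_recovered(self):
        targets = [(75, -150), (60, 30), (-120, 140), (-57, -47), (45, -90)]
        out = geo.backbone_dihedrals(geo.build_backbone(targets))
        for g, (phi, psi) in list(zip(out, targets))[1:-1]:
            assert g.phi == pytest.approx(phi, abs=1e-6)
            assert g.psi == pytest.approx(psi, abs=1e-6)

    def test_mirror_flips_every_torsion_sign(self):
        res = geo.build_backbone([(-57.0, -47.0), (60.0, 30.0), (-120.0, 140.0),
                                  (45.0, -90.0)])
        out = geo.backbone_dihedrals(res)
        out_m = geo.backbone_dihedrals(mirror(res))
        for g, gm in zip(out, out_m):
            if g.phi is not None:
                assert gm.phi == pytest.approx(-g.phi, abs=1e-9)
            if g.psi is not None:
                assert gm.psi == pytest.approx(-g.psi, abs=1e-9)

    def test_two_residue_chain_termini_only(self):
        out = geo.backbone_dihedrals(geo.build_backbone([(0, 0), (0, 0)]))
        assert out[0].phi is None and out[-1].psi is None
        assert out[0].psi is not None and out[-1].phi is not None

    def test_chain_break_splits_series(self):
        res = geo.build_backbone([(-57, -47)] * 6)
        for atom in ("N", "CA", "C"):  # translate the tail far away
            for r in res[3:]:
                r[atom] = np.asarray(r[atom]) + 100.0
        out = geo.backbone_dihedrals(res)
        assert out[3].phi is None  # break between residues 2 and 3
        assert out[2].psi is None


class TestClassifyRegion:
    @pytest.mark.parametrize("phi,psi,expected", [
        (75.0, -150.0, True),    # inside the mirror polyproline-II region
        (-60.0, -45.0, False),   # alpha region
        (45.0, -150.0, True),    # inclusive phi_min boundary
        (None, -150.0, False),   # terminus never qualifies
    ])
    def test_default_rectangle(self, phi, psi, expected):
        assert geo.classify_region(phi, psi) is expected

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            geo.RegionSpec(phi_min=10, phi_max=-10)


class TestContactFilter:
    def test_constructed_distances(self):
        a = np.array([[0.0, 0.0, 0.0]])
        assert geo.contact_filter(a, np.array([[4.9, 0, 0]]), cutoff=5.0)
        assert not geo.contact_filter(a, np.array([[5.1, 0, 0]]), cutoff=5.0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(8, 3)) * 4, rng.normal(size=(6, 3)) * 4 + 3
        if geo.contact_filter(a, b, cutoff=5.0):
            assert geo.contact_filter(a, b, cutoff=6.0)

    def test_equals_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(size=(7, 3)) * 5, rng.normal(size=(5, 3)) * 5
            brute = min(np.linalg.norm(x - y) for x in a for y in b)
            assert geo.contact_filter(a, b, 5.0) == (brute <= 5.0)


class TestLoopShape:
    def test_coplanar_distances_preserved(self):
        t = np.linspace(0, 3, 12)
        pts = np.c_[np.cos(t), np.sin(t), np.zeros(12)]
        proj, _ = geo.loop_shape(pts)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(pts), pdist(proj), atol=1e-9)

    def test_collinear_second_component_zero(self):
        pts = np.outer(np.arange(12, dtype=float), [1.0, 2.0, 3.0])
        proj, _ = geo.loop_shape(pts)
        assert np.allclose(proj[:, 1], 0.0, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        proj, com = geo.loop_shape(pts)
        Xc = pts - pts.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        axes = v[:, ::-1][:, :2].T
        oracle = Xc @ axes.T
        for k in range(2):  # match up to the documented sign convention
            col = proj[:, k]
            assert (np.allclose(col, oracle[:, k], atol=1e-8)
                    or np.allclose(col, -oracle[:, k], atol=1e-8))
        assert np.allclose(com, proj[4:5].mean(axis=0), atol=1e-9)

    def test_too_short_loop_rejected(self):
        with pytest.raises(ValueError):
            geo.loop_shape(np.zeros((9, 3)))


def synthetic_structure(sid, lineage, rng, in_region):
    """A 12-residue synthetic loop; optionally one residue in the region."""
    phis = rng.uniform(-150, -50, size=12)
    psis = rng.uniform(100, 170, size=12)
    if in_region:
        k = rng.integers(2, 10)
        phis[k], psis[k] = rng.uniform(60, 170), rng.uniform(-170, -100)
    res = geo.build_backbone(list(zip(phis, psis)))
    return geo.StructureRecord(sid, lineage, geo.backbone_dihedrals(res))


class TestConformationContrast:
    def test_equal_fractions_null(self):
        rng = np.random.default_rng(8)
        structures = [synthetic_structure(f"s{i}", lin, rng, i % 2 == 0)
                      for i, lin in enumerate(["CD4"] * 20 + ["CD8"] * 20)]
        ratio, p, _ = geo.conformation_contrast(structures)
        assert ratio == pytest.approx(1.0)
        assert p == 1.0

    def test_duplication_invariance(self):
        rng = np.random.default_rng(9)
        structures = [synthetic_structure(f"s{i}", lin, rng, i % 3 == 0)
                      for i, lin in enumerate(["CD4"] * 15 + ["CD8"] * 15)]
        r1, _, _ = geo.conformation_contrast(structures)
        r2, _, _ = geo.conformation_contrast(structures + structures)
        assert r1 == pytest.approx(r2)

    def test_planted_cd8_enrichment_detected(self):
        """Region residues planted 3x more often in CD8 loops (80+74
        structures) are detected as ratio > 1 with Fisher p < 0.05."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            structures = [
                synthetic_structure(f"cd8_{i}", "CD8", rng, rng.random() < 0.45)
                for i in range(80)
            ] + [
                synthetic_structure(f"cd4_{i}", "CD4", rng, rng.random() < 0.15)
                for i in range(74)
            ]
            ratio, p, _ = geo.conformation_contrast(structures)
            hits += (ratio > 1) and (p < 0.05)
        assert hits >= 8

    def test_single_lineage_rejected(self):
        rng = np.random.default_rng(10)
        structures = [synthetic_structure("a", "CD8", rng, True)]
        with pytest.raises(ValueError):
            geo.conformation_contrast(structures)


def write_pdb(path, residues, chain="A"):
    """Minimal PDB writer for N/CA/C backbones (test utility)."""
    lines = []
    serial = 1
    for i, res in enumerate(residues, start=1):
        for atom in ("N", "CA", "C"):
            x, y, z = res[atom]
            lines.append(
                f"ATOM  {serial:5d} {atom.center(4)} GLY {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{atom[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestPdbRoundTrip:
    def test_backbone_written_and_reloaded_preserves_dihedrals(self, tmp_path):
        targets = [(-57.0, -47.0)] * 6
        res = geo.build_backbone(targets)
        pdb = tmp_path / "helix.pdb"
        write_pdb(pdb, res)
        loaded = geo.load_backbone_pdb(pdb, "A")
        out = geo.backbone_dihedrals(loaded)
        for g in out[1:-1]:
            assert g.phi == pytest.approx(-57.0, abs=0.05)  # PDB 1e-3 A rounding
            assert g.psi == pytest.approx(-47.0, abs=0.05)

    def test_residue_range_and_heavy_atoms(self, tmp_path):
        res = geo.build_backbone([(-57.0, -47.0)] * 6)
        pdb = tmp_path / "helix.pdb"
        write_pdb(pdb, res)
        subset = geo.load_backbone_pdb(pdb, "A", residue_range=(2, 4))
        assert [r["index"] for r in subset] == [2, 3, 4]
        coords = geo.heavy_atom_coords(pdb, "A")
        assert coords.shape == (18, 3)
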