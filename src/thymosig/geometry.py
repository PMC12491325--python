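"""CDR3 loop geometry: backbone dihedrals, Ramachandran regions, contacts.

Phi/psi torsions are computed from the standard four-atom definition
(IUPAC sign convention); residues falling in a configurable Ramachandran
rectangle — by default the mirror polyproline-II region at positive phi
and negative psi, accessible mainly to glycine — mark a structure as
"harboring the conformation", and the CD4/CD8 contrast on that flag is a
frequency ratio with a two-tailed Fisher exact test.  Loop convexity is
summarized by projecting Cα coordinates on their top two principal axes
and locating the center of mass of the peptide-contacting stretch
(excluding the first four and last five residues of the loop).

A NeRF-style builder constructs synthetic backbones at prescribed
(phi, psi), serving as a geometric ground truth for tests and planted
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import fisher_exact

# ideal backbone geometry (Engh & Huber): lengths in Å, angles in degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0
PEPTIDE_BOND_MAX = 2.5  # Å; larger C(i)–N(i+1) distances split the chain


@dataclass
class ResidueGeometry:
    chain_id: str
    residue_index: int
    residue_name: str
    phi: float | None  # degrees, (-180, 180]; None at chain start
    psi: float | None  # None at chain end
    ca_xyz: np.ndarray
    in_region: bool = False
    contacts_peptide: bool = False


@dataclass
class RegionSpec:
    """An inclusive rectangle on the Ramachandran plot, in degrees."""

    phi_min: float = 45.0
    phi_max: float = 180.0
    psi_min: float = -180.0
    psi_max: float = -90.0

    def __post_init__(self) -> None:
        if self.phi_min >= self.phi_max or self.psi_min >= self.psi_max:
            raise ValueError("region bounds must satisfy min < max")


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of four points, degrees in (-180, 180], IUPAC sign."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(
    residues: list[dict], chain_id: str = "A"
) -> list[ResidueGeometry]:
    """Phi/psi for a list of residues with 'N', 'CA', 'C' coordinate entries.

    phi(i) = torsion(C_{i-1}, N_i, CA_i, C_i) and
    psi(i) = torsion(N_i, CA_i, C_i, N_{i+1}); an angle is absent at chain
    termini and across chain breaks (C–N distance above 2.5 Å).  Residues
    missing a backbone atom get None for each affected angle.
    """
    out = []
    n = len(residues)
    for i, res in enumerate(residues):
        has = lambda r, a: r is not None and r.get(a) is not None  # noqa: E731
        phi = psi = None
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i < n - 1 else None
        bonded_prev = (
            has(prev_res, "C") and has(res, "N")
            and np.linalg.norm(np.asarray(res["N"]) - np.asarray(prev_res["C"]))
            < PEPTIDE_BOND_MAX
        )
        bonded_next = (
            has(res, "C") and has(next_res, "N")
            and np.linalg.norm(np.asarray(next_res["N"]) - np.asarray(res["C"]))
            < PEPTIDE_BOND_MAX
        )
        if bonded_prev and all(has(res, a) for a in ("N", "CA", "C")):
            phi = dihedral(prev_res["C"], res["N"], res["CA"], res["C"])
        if bonded_next and all(has(res, a) for a in ("N", "CA", "C")):
            psi = dihedral(res["N"], res["CA"], res["C"], next_res["N"])
        out.append(
            ResidueGeometry(
                chain_id=chain_id,
                residue_index=res.get("index", i),
                residue_name=res.get("name", "UNK"),
                phi=phi,
                psi=psi,
                ca_xyz=np.asarray(res["CA"], dtype=float) if has(res, "CA") else None,
            )
        )
    return out


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: place the next atom given three predecessors and internal coords."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle_deg)
    # negated so the resulting dihedral() of the four atoms equals the input
    chi = np.radians(-torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict]:
    """Synthetic N-CA-C backbone realizing the prescribed (phi, psi) series.

    Residue 1's phi and residue n's psi are undefined (termini) and the
    corresponding inputs are ignored; omega is fixed trans.  Intended as a
    geometric oracle: recomputing dihedrals from the returned coordinates
    reproduces the inputs.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    # seed the first residue in a canonical pose
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = N0 + np.array([BOND_N_CA, 0.0, 0.0])
    theta = np.radians(ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    residues = [{"index": 0, "name": "GLY", "N": N0, "CA": CA0, "C": C0}]
    prev = residues[0]
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        N = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N,
                        ANGLE_CA_C_N, psi_prev)
        CA = _place_atom(prev["CA"], prev["C"], N, BOND_N_CA,
                         ANGLE_C_N_CA, OMEGA_TRANS)
        C = _place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        prev = {"index": i, "name": "GLY", "N": N, "CA": CA, "C": C}
        residues.append(prev)
    return residues


def load_backbone_pdb(path: str | Path, chain_id: str,
                      residue_range: tuple[int, int] | None = None) -> list[dict]:
    """Extract per-residue N/CA/C coordinates from a PDB file chain."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    residues = []
    for res in model[chain_id]:
        if res.id[0] != " ":
            continue  # skip heteroatoms/waters
        idx = res.id[1]
        if residue_range and not (residue_range[0] <= idx <= residue_range[1]):
            continue
        entry = {"index": idx, "name": res.get_resname()}
        for atom in ("N", "CA", "C"):
            entry[atom] = res[atom].coord.astype(float) if atom in res else None
        residues.append(entry)
    return residues


def heavy_atom_coords(path: str | Path, chain_id: str,
                      residue_range: tuple[int, int] | None = None) -> np.ndarray:
    """All non-hydrogen atom coordinates of a PDB chain (optionally a range)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    coords = []
    for res in model[chain_id]:
        if res.id[0] != " ":
            continue
        if residue_range and not (residue_range[0] <= res.id[1] <= residue_range[1]):
            continue
        for atom in res:
            if atom.element != "H":
                coords.append(atom.coord)
    return np.asarray(coords, dtype=float)


def classify_region(phi: float | None, psi: float | None,
                    spec: RegionSpec | None = None) -> bool:
    """Inclusive rectangle membership of (phi, psi); termini never qualify."""
    if phi is None or psi is None:
        return False
    spec = spec or RegionSpec()
    return (spec.phi_min <= phi <= spec.phi_max
            and spec.psi_min <= psi <= spec.psi_max)


def contact_filter(cdr3_coords: np.ndarray, peptide_coords: np.ndarray,
                   cutoff: float = 5.0) -> bool:
    """True iff any CDR3/peptide atom pair is within ``cutoff`` Å."""
    a = np.atleast_2d(np.asarray(cdr3_coords, dtype=float))
    b = np.atleast_2d(np.asarray(peptide_coords, dtype=float))
    return bool(cdist(a, b).min() <= cutoff)


def loop_shape(ca_coords: np.ndarray, head_trim: int = 4, tail_trim: int = 5
               ) -> tuple[np.ndarray, np.ndarray]:
    """2D principal-axis projection of a CDR3 loop and its contact-region COM.

    The loop's Cα coordinates are centered and projected on the top two
    principal components (deterministic sign: each axis is flipped so its
    first loading is non-negative).  The second return value is the center
    of mass, in that plane, of the "contacting" residues — the loop minus
    its first ``head_trim`` and last ``tail_trim`` residues.
    """
    X = np.asarray(ca_coords, dtype=float)
    if len(X) <= head_trim + tail_trim:
        raise ValueError("loop shorter than head_trim + tail_trim")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axes = vt[:2]
    for k in range(2):
        if axes[k, 0] < 0:
            axes[k] = -axes[k]
    proj = Xc @ axes.T
    com = proj[head_trim : len(X) - tail_trim].mean(axis=0)
    return proj, com


@dataclass
class StructureRecord:
    structure_id: str
    lineage: str  # CD4 | CD8
    geometry: list[ResidueGeometry] = field(default_factory=list)

    def harbors(self, spec: RegionSpec | None = None) -> bool:
        return any(classify_region(g.phi, g.psi, spec) for g in self.geometry)


def conformation_contrast(
    structures: list[StructureRecord], spec: RegionSpec | None = None
) -> tuple[float, float, np.ndarray]:
    """CD8-vs-CD4 frequency ratio of region-harboring structures + Fisher p.

    A structure harbors the conformation iff at least one of its CDR3β
    residues falls in the region.  Returns (CD8 fraction / CD4 fraction,
    two-tailed Fisher p, the 2x2 table [[cd8_in, cd8_out], [cd4_in,
    cd4_out]]).
    """
    spec = spec or RegionSpec()
    table = np.zeros((2, 2), dtype=int)
    for s in structures:
        row = 0 if s.lineage == "CD8" else 1
        col = 0 if s.harbors(spec) else 1
        table[row, col] += 1
    n_cd8, n_cd4 = table[0].sum(), table[1].sum()
    if n_cd8 == 0 or n_cd4 == 0:
        raise ValueError("need structures of both lineages")
    f_cd8 = table[0, 0] / n_cd8
    f_cd4 = table[1, 0] / n_cd4
    ratio = f_cd8 / f_cd4 if f_cd4 > 0 else np.inf
    _, p = fisher_exact(table, alternative="two-sided")
    return float(ratio), float(p), table
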