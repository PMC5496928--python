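"""Kinase-domain extraction and anchored Cα superposition.

Kinase monomers are pulled out of PDB/mmCIF entries one polymer chain at a
time and superposed on two rigid anchor regions: a four-residue hinge
window starting at gatekeeper+3, and the αF helix at the core of the
C-lobe.  These regions move least between activation states, so anchoring
on them makes conformational differences elsewhere (activation loop, DFG
motif, C-helix) directly comparable across an ensemble.

Anchor presets (author residue numbering):
  ALK   hinge 1196-1199, αF 1308-1324
  MET   hinge 1158-1161, αF 1262-1278
  EGFR  hinge 766-769 or 790-793, αF 869-885 or 893-909
        (mature-protein vs precursor numbering; chosen per entry by which
        range is present)

Superposition is least squares on matched anchor Cα atoms (Kabsch, SVD with
sign correction so the rotation is always proper).  Aromatic side-chain
ring centroids across a superposed ensemble can be clustered by single
linkage to expose discrete conformational states (e.g. the DFG
phenylalanine's in/out positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

__all__ = [
    "Atom",
    "Residue",
    "KinaseMonomer",
    "AnchorSpec",
    "ANCHOR_PRESETS",
    "anchors_for",
    "RigidTransform",
    "extract_monomers",
    "superpose",
    "apply_transform",
    "ensemble_rmsd",
    "aromatic_centroids",
    "centroid_clusters",
    "write_pdb",
]

logger = logging.getLogger(__name__)

#: side-chain ring atoms per aromatic residue type
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    seqid: int  # author numbering
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class KinaseMonomer:
    """One polymer chain of a kinase entry, waters removed, altlocs resolved.

    ``ligands`` keeps the names of non-polymer heterocompounds found in the
    chain as annotations; their atoms are not part of the monomer model.
    """

    source_id: str  # entry + chain, e.g. "2XP2_A"
    residues: list[Residue]
    ligands: list[str] = field(default_factory=list)

    def residue(self, seqid: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        return None

    def ca_coords(self, seq_range: tuple[int, int] | None = None) -> np.ndarray:
        """Cα coordinates, optionally restricted to an inclusive seqid range."""
        coords = []
        for r in self.residues:
            if seq_range and not (seq_range[0] <= r.seqid <= seq_range[1]):
                continue
            ca = r.atom("CA")
            if ca is not None:
                coords.append(ca.pos)
        return np.array(coords).reshape(-1, 3)

    def all_coords(self) -> np.ndarray:
        return np.array([a.pos for r in self.residues for a in r.atoms]).reshape(-1, 3)


@dataclass(frozen=True)
class AnchorSpec:
    """Hinge (gatekeeper+3, 4 residues) and αF-helix anchor residue ranges."""

    hinge_range: tuple[int, int]
    af_helix_range: tuple[int, int]

    def __post_init__(self) -> None:
        h0, h1 = self.hinge_range
        if h1 - h0 + 1 != 4:
            raise ValueError("hinge window must span exactly 4 residues")
        f0, f1 = self.af_helix_range
        if f0 > f1:
            raise ValueError("αF-helix range reversed")
        if not (h1 < f0 or f1 < h0):
            raise ValueError("anchor ranges must not overlap")

    def ca_coords(self, m: KinaseMonomer) -> np.ndarray:
        return np.vstack([m.ca_coords(self.hinge_range), m.ca_coords(self.af_helix_range)])


ANCHOR_PRESETS: dict[str, list[AnchorSpec]] = {
    "ALK": [AnchorSpec((1196, 1199), (1308, 1324))],
    "MET": [AnchorSpec((1158, 1161), (1262, 1278))],
    "EGFR": [AnchorSpec((766, 769), (869, 885)), AnchorSpec((790, 793), (893, 909))],
}


def anchors_for(kinase: str, m: KinaseMonomer) -> AnchorSpec:
    """Pick the preset anchor spec whose ranges are present in the monomer."""
    specs = ANCHOR_PRESETS[kinase.upper()]
    for spec in specs:
        n_hinge = len(m.ca_coords(spec.hinge_range))
        if n_hinge == 4:
            return spec
    raise ValueError(f"no {kinase} anchor preset matches residues of {m.source_id}")


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Keep one position per atom name: highest occupancy, ties to altloc 'A'."""
    by_name: dict[str, Atom] = {}
    for at in res:
        cand = Atom(
            name=at.name, element=at.element.name,
            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
            occupancy=at.occ, altloc=at.altloc or "",
        )
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = cand
        elif (cand.occupancy, -ord(cand.altloc or "z")) > (prev.occupancy, -ord(prev.altloc or "z")):
            by_name[at.name] = cand
    return list(by_name.values())


def extract_monomers(path) -> list[KinaseMonomer]:
    """Extract one kinase monomer per polymer chain from a PDB/mmCIF file.

    Waters are discarded; non-polymer heterocompounds are kept as ligand
    annotations only.  Chains with no Cα atoms are skipped with a warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise IOError(f"cannot read structure file {path}: {exc}") from exc
    st.setup_entities()
    entry = st.name or path.stem
    monomers: list[KinaseMonomer] = []
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        ligands: list[str] = []
        for res in chain:
            if res.name == "HOH":
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa:
                ligands.append(res.name)
                continue
            residues.append(
                Residue(
                    seqid=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=_resolve_altlocs(res),
                )
            )
        monomer = KinaseMonomer(
            source_id=f"{entry}_{chain.name}", residues=residues, ligands=ligands
        )
        if len(monomer.ca_coords()) == 0:
            logger.warning("chain %s has no Cα atoms; skipped", chain.name)
            continue
        monomers.append(monomer)
    return monomers


def kabsch(moving: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking ``moving`` onto ``reference``.

    SVD solution with sign correction: a reflection in the optimum is
    rejected by flipping the smallest singular direction, so the returned
    rotation always has determinant +1.
    """
    if moving.shape != reference.shape or moving.shape[0] < 3:
        raise ValueError("need >= 3 matched points of equal count")
    mc = moving.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (moving - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return RigidTransform(R, t)


def superpose(
    moving: KinaseMonomer,
    reference: KinaseMonomer,
    a_m: AnchorSpec,
    a_r: AnchorSpec,
) -> tuple[RigidTransform, float]:
    """Superpose anchor Cα atoms of ``moving`` onto ``reference``.

    Anchor residues are paired positionally within each range; returns the
    optimal transform and the anchor Cα RMSD (Å) after applying it.
    """
    mov = a_m.ca_coords(moving)
    ref = a_r.ca_coords(reference)
    if len(mov) != len(ref):
        raise ValueError(
            f"anchor Cα counts differ: {len(mov)} (moving) vs {len(ref)} (reference)"
        )
    if len(mov) < 3:
        raise ValueError(f"fewer than 3 matched anchor Cα atoms ({len(mov)})")
    tr = kabsch(mov, ref)
    moved = tr.apply(mov)
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return tr, rmsd


def apply_transform(m: KinaseMonomer, tr: RigidTransform) -> KinaseMonomer:
    """Return a copy of the monomer with all atoms rigidly transformed."""
    residues = [
        Residue(
            seqid=r.seqid, icode=r.icode, name=r.name,
            atoms=[
                Atom(a.name, a.element, tr.apply(a.pos[None, :])[0], a.occupancy, a.altloc)
                for a in r.atoms
            ],
        )
        for r in m.residues
    ]
    return KinaseMonomer(source_id=m.source_id, residues=residues, ligands=list(m.ligands))


def ensemble_rmsd(
    monomers: list[KinaseMonomer],
    reference: KinaseMonomer,
    anchors,
    reference_anchor: AnchorSpec | None = None,
) -> tuple[pd.DataFrame, float, list[KinaseMonomer]]:
    """Superpose an ensemble onto a reference; report per-structure anchor RMSD.

    ``anchors`` is either one :class:`AnchorSpec` for all members or a list
    parallel to ``monomers``.  Members that fail to superpose are skipped
    with a warning.  Returns the RMSD table, its mean, and the superposed
    copies.
    """
    if len(monomers) < 2:
        raise ValueError("an ensemble needs at least 2 monomers")
    if isinstance(anchors, AnchorSpec):
        anchors = [anchors] * len(monomers)
    ref_anchor = reference_anchor or anchors[0]
    rows = []
    superposed = []
    for m, a in zip(monomers, anchors):
        try:
            tr, rmsd = superpose(m, reference, a, ref_anchor)
        except ValueError as exc:
            logger.warning("skipping %s: %s", m.source_id, exc)
            continue
        rows.append({"structure": m.source_id, "anchor_rmsd_A": rmsd})
        superposed.append(apply_transform(m, tr))
    table = pd.DataFrame(rows)
    mean = float(table["anchor_rmsd_A"].mean()) if len(table) else float("nan")
    return table, mean, superposed


def aromatic_centroids(
    monomers: list[KinaseMonomer], residue_ids: list[int]
) -> pd.DataFrame:
    """Side-chain ring centroids of named aromatic residues across an ensemble.

    Returns a table (structure, residue, x, y, z); residues missing their
    ring atoms produce no row, with a warning.
    """
    rows = []
    for m in monomers:
        for seqid in residue_ids:
            res = m.residue(seqid)
            if res is None or res.name not in RING_ATOMS:
                logger.warning("no aromatic residue %d in %s", seqid, m.source_id)
                continue
            ring = [res.atom(n) for n in RING_ATOMS[res.name]]
            if any(a is None for a in ring):
                logger.warning("incomplete ring for %s%d in %s", res.name, seqid, m.source_id)
                continue
            centroid = np.mean([a.pos for a in ring], axis=0)
            rows.append(
                {"structure": m.source_id, "residue": seqid,
                 "x": centroid[0], "y": centroid[1], "z": centroid[2]}
            )
    return pd.DataFrame(rows, columns=["structure", "residue", "x", "y", "z"])


def centroid_clusters(centroids: np.ndarray, cutoff: float = 2.0) -> np.ndarray:
    """Single-linkage clusters of centroid positions at a distance cutoff (Å).

    Two centroids share a cluster iff they are connected through steps of
    length <= cutoff.  Labels are 0-based, deterministic: clusters numbered
    by their lowest member index.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("need at least 1 centroid")
    if len(pts) == 1:
        return np.zeros(1, dtype=int)
    link = sch.linkage(pdist(pts), method="single")
    raw = sch.fcluster(link, t=cutoff, criterion="distance")
    # relabel by lowest member index
    order: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        if c not in order:
            order[c] = len(order)
        labels[i] = order[c]
    return labels


def write_pdb(m: KinaseMonomer, path) -> None:
    """Write a monomer as a single-chain PDB file."""
    st = gemmi.Structure()
    st.name = m.source_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(m.source_id.split("_")[-1][:1] or "A")
    for r in m.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.seqid, r.icode or " ")
        for a in r.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.pos)
            at.occ = a.occupancy
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
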