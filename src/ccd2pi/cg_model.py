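"""Atomic structure input and coarse-grained pseudoatom models.

A protein (one or several chains treated as a single rigid body) is reduced
to one pseudoatom per residue at the C-alpha position plus, except for Gly,
one or two side-chain pseudoatoms placed at centroids of authored atom
groups.  Charged side chains (Arg, Lys, Asp, Glu) carry a +/-1 net point
charge on their second side-chain pseudoatom.  Each pseudoatom carries an
LJ-type code indexing the bundled 8-6 parameter tables B (repulsive) and C
(attractive) and the 12-6 radius sigma.

The parameter table ships with the package (``data/cg_params.json``) and can
be replaced by any file with the same layout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "AtomicResidue",
    "AtomicProtein",
    "CoarseGrainedProtein",
    "load_cg_params",
    "load_structure",
    "coarse_grain",
    "surface_residues",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _data_file(name: str) -> dict:
    with resources.files("ccd2pi.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_cg_params(path: str | Path | None = None) -> dict:
    """Load the pseudoatom parameter table (bundled default if *path* is None)."""
    if path is None:
        params = _data_file("cg_params.json")
    else:
        with open(path) as fh:
            params = json.load(fh)
    if set(params["residues"]) != {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }:
        raise ValueError("parameter table must cover exactly the 20 standard amino acids")
    return params


@dataclass
class AtomicResidue:
    chain: str
    number: int
    icode: str
    name: str                      # three-letter residue type
    atom_names: list[str]
    coords: np.ndarray             # (n_atoms, 3) heavy-atom coordinates, A

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)


@dataclass
class AtomicProtein:
    """Ordered heavy-atom residue list for one protein (possibly multi-chain)."""

    protein_id: str
    residues: list[AtomicResidue]
    chains: list[str] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.protein_id}: duplicate residue keys")
        for r in self.residues:
            if len(r.atom_names) == 0:
                raise ValueError(f"{self.protein_id}: residue {r.key} has no heavy atoms")
        if not self.chains:
            self.chains = sorted({r.chain for r in self.residues})

    def __len__(self) -> int:
        return len(self.residues)

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])

    def atom_residue_index(self) -> np.ndarray:
        """0-based residue index of every heavy atom, aligned with :meth:`all_coords`."""
        return np.repeat(np.arange(len(self.residues)),
                         [len(r.atom_names) for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        out = np.empty((len(self.residues), 3))
        for i, r in enumerate(self.residues):
            if "CA" in r.atom_names:
                out[i] = r.coords[r.atom_names.index("CA")]
            else:
                out[i] = r.coords.mean(axis=0)
        return out


@dataclass
class CoarseGrainedProtein:
    """Pseudoatom model: flat arrays over all pseudoatoms of the protein.

    ``role`` is 0 for the C-alpha pseudoatom, 1/2 for the first/second
    side-chain pseudoatom.  ``charge``, ``lj_b``, ``lj_c`` and ``sigma`` are
    per-pseudoatom parameter vectors resolved from the type table so the
    docking engine needs no table lookups.
    """

    protein_id: str
    coords: np.ndarray             # (m, 3)
    residue_index: np.ndarray      # (m,) int, 0-based contiguous
    role: np.ndarray               # (m,) int in {0, 1, 2}
    charge: np.ndarray             # (m,) float, elementary charges
    type_code: np.ndarray          # (m,) str
    lj_b: np.ndarray
    lj_c: np.ndarray
    sigma: np.ndarray
    resnames: list[str] = field(default_factory=list)
    surface_mask: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite pseudoatom coordinates")

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if len(self.residue_index) else 0

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.role == 0]

    def com(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def total_charge(self) -> float:
        return float(self.charge.sum())

    def residue_pseudoatom_counts(self) -> np.ndarray:
        return np.bincount(self.residue_index, minlength=self.n_residues)

    def to_table(self):
        """One row per pseudoatom: residue index, role, x, y, z, q, type code."""
        import pandas as pd

        return pd.DataFrame({
            "residue_index": self.residue_index,
            "role": self.role,
            "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2],
            "q": self.charge, "type_code": self.type_code,
        })


def load_structure(path: str | Path, chains: list[str] | None = None,
                   protein_id: str | None = None) -> AtomicProtein:
    """Parse a PDB file into an :class:`AtomicProtein`.

    Model 1 only; waters and heteroatoms excluded; alternate locations
    collapsed to the highest-occupancy conformer; hydrogens dropped.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or path.stem, str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    if chains is None:
        chains = available
    missing = [c for c in chains if c not in available]
    if missing:
        raise ValueError(f"chain(s) {missing} not present in {path.name} (has {available})")

    residues: list[AtomicResidue] = []
    for cid in chains:
        for res in model[cid]:
            hetflag, resnum, icode = res.id
            if hetflag != " ":
                continue  # waters / heteroatoms
            names, coords = [], []
            for atom in res:
                if atom.is_disordered():
                    atom = atom.selected_child  # highest occupancy
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                names.append(atom.get_name())
                coords.append(atom.get_coord())
            if not names:
                warnings.warn(f"residue {cid}{resnum}{icode.strip()} has no heavy atoms; skipped")
                continue
            residues.append(AtomicResidue(cid, resnum, icode, res.get_resname(),
                                          names, np.asarray(coords, dtype=float)))
    return AtomicProtein(protein_id or path.stem, residues, chains=list(chains))


def coarse_grain(protein: AtomicProtein, params: dict | None = None) -> CoarseGrainedProtein:
    """Build the pseudoatom model of *protein* from the parameter table.

    Side-chain pseudoatoms sit at the centroid of the table's atom group;
    when all atoms of a group are missing the placement falls back to CB,
    then CA, with a warning.
    """
    params = params or load_cg_params()
    lj = params["lj_types"]
    restab = params["residues"]

    coords, ridx, role, charge, tcode = [], [], [], [], []
    resnames = []
    for i, res in enumerate(protein.residues):
        if res.name not in restab:
            raise KeyError(f"residue type {res.name!r} at {res.key} missing from parameter table")
        entry = restab[res.name]
        resnames.append(res.name)
        amap = {n: res.coords[j] for j, n in enumerate(res.atom_names)}
        ca = amap.get("CA", res.coords.mean(axis=0))
        coords.append(ca); ridx.append(i); role.append(0); charge.append(0.0); tcode.append("CA")
        for k, group in enumerate(entry["groups"]):
            pts = [amap[a] for a in group if a in amap]
            if not pts:
                fb = amap.get("CB", ca)
                which = "CB" if "CB" in amap else "CA"
                warnings.warn(f"{protein.protein_id} {res.key}: side-chain atoms "
                              f"{group} missing, falling back to {which}")
                pts = [fb]
            coords.append(np.mean(pts, axis=0))
            ridx.append(i); role.append(k + 1)
            charge.append(float(entry["charges"][k])); tcode.append(entry["types"][k])

    tcode = np.asarray(tcode)
    return CoarseGrainedProtein(
        protein_id=protein.protein_id,
        coords=np.asarray(coords, dtype=float),
        residue_index=np.asarray(ridx, dtype=int),
        role=np.asarray(role, dtype=int),
        charge=np.asarray(charge, dtype=float),
        type_code=tcode,
        lj_b=np.array([lj[t]["B"] for t in tcode]),
        lj_c=np.array([lj[t]["C"] for t in tcode]),
        sigma=np.array([lj[t]["sigma"] for t in tcode]),
        resnames=resnames,
    )


def _as_biopdb_structure(protein: AtomicProtein):
    """Build a Bio.PDB structure from an AtomicProtein (for SASA)."""
    from Bio.PDB.Atom import Atom
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Model import Model
    from Bio.PDB.Residue import Residue
    from Bio.PDB.Structure import Structure

    structure = Structure(protein.protein_id)
    model = Model(0)
    structure.add(model)
    chains: dict[str, Chain] = {}
    serial = 1
    for res in protein.residues:
        if res.chain not in chains:
            chains[res.chain] = Chain(res.chain)
            model.add(chains[res.chain])
        bres = Residue((" ", res.number, res.icode), res.name, "")
        for name, xyz in zip(res.atom_names, res.coords):
            element = "S" if name.startswith("S") else name[:1]
            atom = Atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                        name, serial, element=element)
            serial += 1
            try:
                bres.add(atom)
            except Exception:     # duplicate atom name in malformed input
                continue
        chains[res.chain].add(bres)
    return structure


def surface_residues(protein: AtomicProtein, threshold: float = 0.25) -> np.ndarray:
    """Per-residue surface mask: relative solvent accessibility >= *threshold*.

    SASA is computed with the Shrake-Rupley algorithm (Bio.PDB) and divided by
    the bundled per-type theoretical maximum accessibility.
    """
    from Bio.PDB.SASA import ShrakeRupley

    if len(protein.residues) == 0:
        raise ValueError("empty protein")
    structure = _as_biopdb_structure(protein)
    try:
        ShrakeRupley().compute(structure, level="R")
    except Exception as exc:      # pragma: no cover - defensive
        raise RuntimeError(f"SASA computation failed for {protein.protein_id}: {exc}") from exc
    max_asa = _data_file("max_asa.json")["max_asa"]
    mask = np.zeros(len(protein.residues), dtype=bool)
    model = next(structure.get_models())
    for i, res in enumerate(protein.residues):
        bres = model[res.chain][(" ", res.number, res.icode)]
        ref = max_asa.get(res.name, float(np.mean(list(max_asa.values()))))
        mask[i] = (bres.sasa / ref) >= threshold
    return mask
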