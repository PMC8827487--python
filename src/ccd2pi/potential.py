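"""Residue-pair statistical contact potential for conformation re-scoring.

A 20x20 symmetric log-odds table trained from bound complex structures:
``score(a, b) = log[(f_obs(a,b) + lambda) / (f_exp(a,b) + lambda)]`` where
``f_obs`` is the frequency of the residue-type pair among interface contacts
(a contact is a residue pair of the two partners with any heavy atom closer
than the contact distance, 5 A by default) and ``f_exp`` the product of the
marginal contact-endpoint type frequencies.  Positive scores mark pairings
enriched at native interfaces.  The summed score over the docked interface of
a conformation acts as a filter favouring native-like residue pairings;
external pre-computed scores can be ingested instead via the conformation
store.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cg_model import AtomicProtein, CoarseGrainedProtein
from .interfaces import _atoms_of

AMINO_ACIDS = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
               "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
               "TYR", "VAL")

__all__ = [
    "AMINO_ACIDS",
    "ContactPotential",
    "residue_contacts",
    "train_contact_potential",
    "pp_score",
    "score_store",
    "pp_filter_transform",
]


@dataclass
class ContactPotential:
    table: pd.DataFrame                 # 20x20, symmetric, log-odds units
    contact_distance: float = 5.0
    pseudocount: float = 1e-4
    training_set: str = ""

    def __post_init__(self):
        t = self.table
        if list(t.index) != list(AMINO_ACIDS) or list(t.columns) != list(AMINO_ACIDS):
            self.table = t.reindex(index=AMINO_ACIDS, columns=AMINO_ACIDS)
        if not np.allclose(self.table.values, self.table.values.T, atol=1e-12):
            raise ValueError("contact potential table must be symmetric")
        if not np.all(np.isfinite(self.table.values)):
            raise ValueError("contact potential table has non-finite entries")

    def score(self, a: str, b: str) -> float:
        return float(self.table.loc[a, b])

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def load(cls, path, contact_distance: float = 5.0,
             pseudocount: float = 1e-4) -> "ContactPotential":
        table = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip").astype(float)
        return cls(table, contact_distance, pseudocount)


def residue_contacts(protein_a, protein_b, d: float = 5.0) -> list[tuple[int, int]]:
    """Residue-level contact pairs (i on A, j on B) with any atoms < d A."""
    from scipy.spatial import cKDTree

    ca, ra = _atoms_of(protein_a)
    cb, rb = _atoms_of(protein_b)
    out = set()
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=d)
    for i, js in enumerate(pairs):
        for j in js:
            if np.linalg.norm(ca[i] - cb[j]) < d:
                out.add((int(ra[i]), int(rb[j])))
    return sorted(out)


def _resnames(protein) -> list[str]:
    if isinstance(protein, AtomicProtein):
        return [r.name for r in protein.residues]
    if isinstance(protein, CoarseGrainedProtein):
        return protein.resnames
    raise TypeError("need an AtomicProtein or CoarseGrainedProtein")


def train_contact_potential(complexes, contact_distance: float = 5.0,
                            pseudocount: float = 1e-4) -> ContactPotential:
    """Train the log-odds table from bound (protein_a, protein_b) pairs."""
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20))
    for a, b in complexes:
        names_a, names_b = _resnames(a), _resnames(b)
        for i, j in residue_contacts(a, b, contact_distance):
            ka, kb = idx.get(names_a[i]), idx.get(names_b[j])
            if ka is None or kb is None:
                continue
            counts[ka, kb] += 1           # count both orders: symmetric table
            counts[kb, ka] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no interface contacts found in the training complexes")
    f_obs = counts / total
    marginal = counts.sum(axis=1) / total
    f_exp = np.outer(marginal, marginal)
    table = np.log((f_obs + pseudocount) / (f_exp + pseudocount))
    df = pd.DataFrame(table, index=AMINO_ACIDS, columns=AMINO_ACIDS)
    return ContactPotential(df, contact_distance, pseudocount,
                            training_set=f"{len(list(complexes))} complexes")


def pp_score(potential: ContactPotential, receptor: CoarseGrainedProtein,
             ligand: CoarseGrainedProtein, transform) -> float:
    """Summed pair-potential score over the docked interface contacts of a pose."""
    lig_coords = transform.apply(ligand.coords)
    contacts = residue_contacts((receptor.coords, receptor.residue_index),
                                (lig_coords, ligand.residue_index),
                                potential.contact_distance)
    total = 0.0
    for i, j in contacts:
        total += potential.score(receptor.resnames[i], ligand.resnames[j])
    return total


def score_store(store, potential: ContactPotential) -> None:
    """Attach the pair-potential score to every conformation in the store."""
    for (rid, lid), confs in store.pairs.items():
        rec, lig = store.proteins[rid], store.proteins[lid]
        for c in confs:
            c.pp = pp_score(potential, rec, lig, c.transform)


def pp_filter_transform(scores, floor: float = 1e-3) -> np.ndarray:
    """Map PP scores to strictly positive multiplicative factors in (0, 1].

    Min-max affine map within the pair's conformation set with floor delta:
    ``factor = delta + (1 - delta) * (s - min) / (max - min)`` so the best PP
    maps to 1 and the worst to delta; constant scores map to all ones.  The
    positive factors keep the sign of the energy when multiplied into the
    interaction-index product.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one conformation score")
    lo, hi = s.min(), s.max()
    if hi - lo < 1e-15:
        return np.ones_like(s)
    return floor + (1.0 - floor) * (s - lo) / (hi - lo)
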