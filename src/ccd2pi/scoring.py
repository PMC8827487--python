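"""Interaction indices, sociability and the normalized interaction matrix.

For an ordered protein pair (P1, P2), every docked conformation is scored as
the product FIR x E [x PP-factor], where FIR is the fraction of the docked
interface falling inside the reference interfaces of the two sides
(``FIR = FIR_P1 * FIR_P2``), E the docking energy (negative = favourable)
and the optional pair-potential factor a positive weight from
:func:`ccd2pi.potential.pp_filter_transform`.  The interaction index II is
the minimum (best) product over the conformations, or 0 when no conformation
scores favourably.

Sociability ``S_i = 1/(2|P|) sum_j (II_ij + II_ji)`` measures how
indiscriminately a protein binds across the whole set; dividing by
``sqrt(|S_1| |S_2|)`` demotes "sticky" proteins.  The normalized interaction
index symmetrizes this ratio and divides by the fourth root of the four
per-protein extreme values, and is finally scaled per focal protein so that
the predicted best partner scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interfaces import Interface
from .potential import pp_filter_transform

__all__ = [
    "IIResult",
    "InteractionMatrix",
    "fir",
    "interaction_index",
    "compute_interaction_matrix",
    "sociability",
    "normalized_ii",
    "scale_nii",
]


def fir(docked_interface: tuple[set, set], ri_receptor: Interface,
        ri_ligand: Interface) -> float:
    """Fraction of docked-interface residues inside the reference interfaces.

    Per side: |DI ∩ RI| / |DI|; the two sides multiply.  An empty docked
    interface gives 0 by convention.
    """
    di_r, di_l = docked_interface
    if not di_r or not di_l:
        return 0.0
    fr = len(set(di_r) & set(ri_receptor.residues)) / len(di_r)
    fl = len(set(di_l) & set(ri_ligand.residues)) / len(di_l)
    return fr * fl


@dataclass
class IIResult:
    value: float
    pose_id: int | None = None
    fir: float = 0.0
    energy: float = 0.0
    pp: float | None = None


def interaction_index(store, receptor_id: str, ligand_id: str,
                      ri_receptor: Interface, ri_ligand: Interface,
                      energy: str = "maxdo", use_pp: bool = False,
                      d: float = 5.0, pp_prefilter: float | None = None,
                      pp_mode: str = "factor") -> IIResult:
    """Interaction index of *receptor_id* with respect to *ligand_id*.

    ``pp_prefilter`` optionally retains only the top fraction of conformations
    by pair-potential score before taking the minimum.  ``pp_mode`` selects
    the positive-factor transform (default) or the raw PP product.
    """
    if ri_receptor.protein_id != receptor_id or ri_ligand.protein_id != ligand_id:
        raise ValueError("reference interfaces do not match the pair")
    confs = store.pairs[(receptor_id, ligand_id)]
    if not confs:
        return IIResult(0.0, None)
    if (use_pp or pp_prefilter) and any(c.pp is None for c in confs):
        raise KeyError(f"pair potential not scored on pair ({receptor_id}, {ligand_id})")
    if pp_prefilter:
        k = max(1, int(np.ceil(pp_prefilter * len(confs))))
        confs = sorted(confs, key=lambda c: -c.pp)[:k]
    energies = np.array([c.energy(energy) for c in confs])
    firs = np.array([fir(store.docked_interface(c, d), ri_receptor, ri_ligand)
                     for c in confs])
    if use_pp:
        pps = np.array([c.pp for c in confs])
        factors = pp_filter_transform(pps) if pp_mode == "factor" else pps
    else:
        factors = np.ones(len(confs))
    products = firs * energies * factors
    best = int(np.argmin(products))
    if products[best] >= 0:
        return IIResult(0.0, None)
    c = confs[best]
    return IIResult(float(products[best]), c.pose_id, float(firs[best]),
                    float(energies[best]), c.pp)


@dataclass
class InteractionMatrix:
    """Square ordered-pair score tables plus the per-protein sociability."""

    ids: list[str]
    ii: pd.DataFrame
    fir_best: pd.DataFrame | None = None
    e_best: pd.DataFrame | None = None
    iiprime: pd.DataFrame | None = None
    nii: pd.DataFrame | None = None
    nii_scaled: pd.DataFrame | None = None
    s: pd.Series | None = None
    config: dict = field(default_factory=dict)

    def normalize(self, eps: float = 1e-9) -> "InteractionMatrix":
        """Fill II', NII, NII_scaled and S from the II table."""
        self.s = sociability(self.ii)
        self.iiprime, self.nii = normalized_ii(self.ii, self.s, eps=eps)
        self.nii_scaled = scale_nii(self.nii)
        return self

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ids:
            for l in self.ids:
                row = {"receptor": r, "ligand": l, "II": self.ii.loc[r, l]}
                for name, frame in (("FIR_best", self.fir_best), ("E_best", self.e_best),
                                    ("II_prime", self.iiprime), ("NII", self.nii),
                                    ("NII_scaled", self.nii_scaled)):
                    if frame is not None:
                        row[name] = frame.loc[r, l]
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def compute_interaction_matrix(store, ris: dict[str, Interface],
                               energy: str = "maxdo", use_pp: bool = False,
                               d: float = 5.0, pp_prefilter: float | None = None,
                               energy_overrides: dict[str, str] | None = None,
                               ) -> InteractionMatrix:
    """II over all ordered pairs of the store, using per-protein RIs.

    ``energy_overrides`` maps a receptor id to an alternative energy column
    (per-class overrides of the default energy choice).
    """
    ids = store.protein_ids()
    missing = [i for i in ids if i not in ris]
    if missing:
        raise KeyError(f"no reference interface for {missing}")
    ii = pd.DataFrame(0.0, index=ids, columns=ids)
    fir_best = pd.DataFrame(np.nan, index=ids, columns=ids)
    e_best = pd.DataFrame(np.nan, index=ids, columns=ids)
    for r in ids:
        e_choice = (energy_overrides or {}).get(r, energy)
        for l in ids:
            res = interaction_index(store, r, l, ris[r], ris[l], e_choice,
                                    use_pp, d, pp_prefilter)
            ii.loc[r, l] = res.value
            fir_best.loc[r, l] = res.fir
            e_best.loc[r, l] = res.energy
    return InteractionMatrix(ids, ii, fir_best, e_best,
                             config={"energy": energy, "use_pp": use_pp, "d": d,
                                     "pp_prefilter": pp_prefilter})


def sociability(ii: pd.DataFrame) -> pd.Series:
    """S_i = 1/(2|P|) sum_j (II_ij + II_ji), j running over all proteins."""
    if list(ii.index) != list(ii.columns):
        raise ValueError("II matrix must be square with matching labels")
    if ii.isna().any().any():
        bad = [(r, c) for r in ii.index for c in ii.columns if pd.isna(ii.loc[r, c])]
        raise ValueError(f"missing II entries: {bad[:10]}")
    n = len(ii)
    return (ii.sum(axis=1) + ii.sum(axis=0)) / (2 * n)


def normalized_ii(ii: pd.DataFrame, s: pd.Series, eps: float = 1e-9,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sociability-weighted symmetrized interaction index.

    ``II'_ij = II_ij / sqrt(|S_i| |S_j|)`` (|S| floored at *eps*), then
    ``NII_ij = min(II'_ij, II'_ji) / (m_i^row m_j^col m_i^col m_j^row)^(1/4)``
    where each m is the matrix-wide extreme (minimum, i.e. strongest under the
    negative-favourable convention) of the focal row or column of II'.  The
    fourth root is taken on magnitudes (floored at *eps*) and the numerator
    sign is carried through.
    """
    if np.allclose(s.values, 0.0):
        raise ValueError("all sociabilities are zero: degenerate experiment")
    sa = np.maximum(np.abs(s.values), eps)
    denom = np.sqrt(np.outer(sa, sa))
    iip = pd.DataFrame(ii.values / denom, index=ii.index, columns=ii.columns)

    row_min = iip.min(axis=1)   # strongest (most negative) per receptor row
    col_min = iip.min(axis=0)
    num = np.minimum(iip.values, iip.values.T)
    m = (np.maximum(np.abs(row_min.values[:, None]), eps)
         * np.maximum(np.abs(col_min.values[None, :]), eps)
         * np.maximum(np.abs(col_min.values[:, None]), eps)
         * np.maximum(np.abs(row_min.values[None, :]), eps))
    nii = num / m**0.25
    return iip, pd.DataFrame(nii, index=ii.index, columns=ii.columns)


def scale_nii(nii: pd.DataFrame) -> pd.DataFrame:
    """Per-row scaling so the predicted best partner of each protein scores 1.

    The row extreme is the strongest value under the negative-favourable sign
    convention (the row minimum); entries are divided by it and clamped to
    [0, 1].  An all-zero row stays zero with a warning.
    """
    out = pd.DataFrame(0.0, index=nii.index, columns=nii.columns)
    for r in nii.index:
        row = nii.loc[r]
        extreme = row.min()
        if extreme >= 0:
            if (row == 0).all():
                warnings.warn(f"all-zero NII row for {r}")
            out.loc[r] = 0.0
            continue
        out.loc[r] = np.clip(row / extreme, 0.0, 1.0)
    return out
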