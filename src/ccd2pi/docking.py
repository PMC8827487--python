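"""Rigid-body pose generation, coarse-grained docking energies and minimization.

Two pairwise energy functions are provided over pseudoatom models:

* an 8-6 soft Lennard-Jones with a distance-dependent dielectric
  (``E = B/r^8 - C/r^6 + q_i q_j / (15 r^2)``), the energy minimized during
  the systematic docking, and
* a 12-6 form with constant dielectric 10
  (``E = (sigma/r)^12 - (sigma/r)^6 + q_i q_j / (10 r)``) used for
  re-scoring.

The systematic exploration follows the surface-restrained protocol: start
positions cover the receptor surface quasi-uniformly; for each position the
ligand is spun about the receptor-COM -> ligand-COM axis, and minimization
keeps the ligand COM on that axis (4 degrees of freedom).  The free protocol
releases the axis constraint (6 DOF) and may restrict start positions to a
candidate surface mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .cg_model import CoarseGrainedProtein

__all__ = [
    "RigidTransform",
    "DockingConformation",
    "ConformationStore",
    "DockSettings",
    "PairContext",
    "pair_energy_maxdo",
    "pair_energy_iattract",
    "generate_start_poses",
    "minimize_pose",
    "cross_dock",
    "rescore_iattract",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion y = R x + t (applied to the ligand)."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be a proper orthonormal matrix")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply *other* first, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def as_flat(self) -> np.ndarray:
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat(cls, v: np.ndarray) -> "RigidTransform":
        v = np.asarray(v, dtype=float)
        return cls(v[:9].reshape(3, 3), v[9:12])


@dataclass
class DockingConformation:
    receptor_id: str
    ligand_id: str
    pose_id: int
    transform: RigidTransform
    e_maxdo: float
    e_iattract: float | None = None
    e_external: float | None = None
    pp: float | None = None
    docked_interface: tuple[set, set] | None = None   # (receptor residues, ligand residues)

    def energy(self, which: str) -> float:
        key = {"maxdo": self.e_maxdo, "iattract": self.e_iattract,
               "external": self.e_external}
        if which not in key:
            raise KeyError(f"unknown energy choice {which!r}")
        value = key[which]
        if value is None:
            raise KeyError(f"energy column {which!r} not present on pose "
                           f"{self.receptor_id}/{self.ligand_id}#{self.pose_id}")
        return value


class PairContext:
    """Precomputed cross pair-parameter matrices for a receptor/ligand pair.

    Caching the combined B, C, sigma and charge-product matrices makes the
    per-pose energy evaluation a handful of vectorized array operations.
    """

    def __init__(self, receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                 cutoff: float | None = 12.0):
        self.receptor = receptor
        self.ligand = ligand
        self.cutoff = cutoff
        self.B = np.sqrt(np.outer(receptor.lj_b, ligand.lj_b))
        self.C = np.sqrt(np.outer(receptor.lj_c, ligand.lj_c))
        self.S = 0.5 * (receptor.sigma[:, None] + ligand.sigma[None, :])
        self.QQ = np.outer(receptor.charge, ligand.charge)

    def _r(self, ligand_coords: np.ndarray) -> np.ndarray:
        r = cdist(self.receptor.coords, ligand_coords)
        if np.any(r == 0.0):
            raise ZeroDivisionError("zero pseudoatom-pseudoatom distance (clash singularity)")
        return r

    def maxdo(self, ligand_coords: np.ndarray) -> float:
        r = self._r(ligand_coords)
        mask = (r <= self.cutoff) if self.cutoff is not None else np.ones_like(r, bool)
        r2 = r * r
        with np.errstate(over="ignore"):
            lj = self.B / r2**4 - self.C / r2**3
            coul = self.QQ / (15.0 * r2)
        return float(np.sum((lj + coul)[mask]))

    def iattract(self, ligand_coords: np.ndarray) -> float:
        r = self._r(ligand_coords)
        mask = (r <= self.cutoff) if self.cutoff is not None else np.ones_like(r, bool)
        with np.errstate(over="ignore", invalid="ignore"):
            sr6 = (self.S / r) ** 6
            lj = np.where(self.S > 0, sr6 * sr6 - sr6, 0.0)
            coul = self.QQ / (10.0 * r)
        return float(np.sum((lj + coul)[mask]))

    def energy(self, which: str, ligand_coords: np.ndarray) -> float:
        if which == "maxdo":
            return self.maxdo(ligand_coords)
        if which == "iattract":
            return self.iattract(ligand_coords)
        raise KeyError(f"unknown energy function {which!r}")


def pair_energy_maxdo(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                      transform: RigidTransform, cutoff: float | None = 12.0) -> float:
    """8-6 LJ + distance-dependent-dielectric energy of a posed pair."""
    return PairContext(receptor, ligand, cutoff).maxdo(transform.apply(ligand.coords))


def pair_energy_iattract(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                         transform: RigidTransform, cutoff: float | None = 12.0) -> float:
    """12-6 LJ + constant-dielectric (eps = 10) energy of a posed pair."""
    return PairContext(receptor, ligand, cutoff).iattract(transform.apply(ligand.coords))


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation taking +z to *direction* (deterministic)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    c = float(z @ d)
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def generate_start_poses(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                         protocol: str = "surface-restrained",
                         n_positions: int = 24, n_rotations: int = 6,
                         seed: int = 0, clearance: float = 3.0,
                         candidate_mask: np.ndarray | None = None) -> list[RigidTransform]:
    """Quasi-uniform start poses covering the receptor surface.

    Each start position places the ligand COM on the ray from the receptor COM
    through a surface direction, offset outward so the bodies start clash-free;
    ``n_rotations`` gamma-angle spins about that COM-COM axis are generated per
    position.  In the free protocol a per-residue ``candidate_mask`` may
    restrict the positions to a surface region.
    """
    if protocol not in ("surface-restrained", "free"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if n_positions < 1 or n_rotations < 1:
        raise ValueError("n_positions and n_rotations must be >= 1")
    centered = receptor.coords - receptor.com()
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate receptor: pseudoatoms are collinear")

    rng = np.random.default_rng(seed)
    global_rot = Rotation.random(random_state=rng).as_matrix()
    directions = _fibonacci_sphere(n_positions) @ global_rot.T

    rec_com = receptor.com()
    lig_com = ligand.com()
    lig_centered = ligand.coords - lig_com
    rec_ca = receptor.ca_coords()

    poses = []
    for d in directions:
        proj = centered @ d
        surface_r = float(proj.max())
        if candidate_mask is not None:
            point = rec_com + d * surface_r
            nearest = int(np.argmin(np.linalg.norm(rec_ca - point, axis=1)))
            if not candidate_mask[nearest]:
                continue
        base = _rotation_to(-d)      # ligand z-axis faces the receptor
        # directional extent of the rotated ligand toward the receptor, so the
        # bodies start just clear of contact (spin about d leaves it unchanged)
        extent = float(((lig_centered @ base.T) @ -d).max())
        target = rec_com + d * (surface_r + extent + clearance)
        for k in range(n_rotations):
            gamma = 2 * np.pi * k / n_rotations
            spin = Rotation.from_rotvec(gamma * d).as_matrix()
            R = spin @ base
            t = target - R @ lig_com
            poses.append(RigidTransform(R, t))
    return poses


def minimize_pose(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                  start: RigidTransform, energy_fn: str = "maxdo",
                  protocol: str = "surface-restrained",
                  cutoff: float | None = 12.0, context: PairContext | None = None,
                  max_sweeps: int = 30, energy_tol: float = 1e-4,
                  trans_step: float = 1.5, rot_step: float = 0.2,
                  ) -> tuple[RigidTransform, float]:
    """Derivative-free local minimization of a rigid pose.

    Coordinate descent with shrinking steps over 4 DOF (surface-restrained:
    radial slide along the COM-COM axis + 3 rotations about the ligand COM) or
    6 DOF (free: 3 translations + 3 rotations).  Deterministic; the returned
    energy never exceeds the start energy.
    """
    ctx = context or PairContext(receptor, ligand, cutoff)
    rec_com = receptor.com()
    lig0 = start.apply(ligand.coords)
    com0 = lig0.mean(axis=0)
    axis = com0 - rec_com
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise ValueError("ligand COM coincides with receptor COM")
    axis = axis / nrm

    free = protocol == "free"
    # variables: translation DOF (1 radial or 3 cartesian) then rotvec (3)
    n_trans = 3 if free else 1
    x = np.zeros(n_trans + 3)
    steps = np.concatenate([np.full(n_trans, trans_step), np.full(3, rot_step)])

    def coords_for(v: np.ndarray) -> np.ndarray:
        delta = v[:3] if free else axis * v[0]
        Rinc = Rotation.from_rotvec(v[n_trans:n_trans + 3]).as_matrix()
        return (lig0 - com0) @ Rinc.T + com0 + delta

    def energy_of(v: np.ndarray) -> float:
        try:
            return ctx.energy(energy_fn, coords_for(v))
        except ZeroDivisionError:
            return np.inf

    best = energy_of(x)
    if not np.isfinite(best):
        warnings.warn("non-finite energy at start pose; pose discarded")
        return start, np.inf
    for _ in range(max_sweeps):
        improved_by = 0.0
        for i in range(len(x)):
            for sgn in (+1.0, -1.0):
                trial = x.copy()
                trial[i] += sgn * steps[i]
                e = energy_of(trial)
                if e < best - 1e-15:
                    improved_by += best - e
                    best, x = e, trial
                    break
        if improved_by < energy_tol:
            steps *= 0.5
            if steps.max() < 1e-3:
                break

    delta = x[:3] if free else axis * x[0]
    Rinc = Rotation.from_rotvec(x[n_trans:n_trans + 3]).as_matrix()
    R = Rinc @ start.rotation
    t = Rinc @ start.translation + (np.eye(3) - Rinc) @ com0 + delta
    final = RigidTransform(R, t)
    return final, best


@dataclass
class DockSettings:
    protocol: str = "surface-restrained"
    n_positions: int = 64
    n_rotations: int = 12
    cutoff: float | None = 12.0
    seed: int = 0
    minimize: bool = True
    max_sweeps: int = 30
    keep_top: int | None = None      # keep only the k lowest-energy poses per pair
    clearance: float = 3.0


@dataclass
class ConformationStore:
    """All docked conformations of a cross-docking run, keyed by ordered pair."""

    pairs: dict[tuple[str, str], list[DockingConformation]] = field(default_factory=dict)
    proteins: dict[str, CoarseGrainedProtein] = field(default_factory=dict)
    protocol: str = "surface-restrained"
    settings: DockSettings | None = None
    seed: int = 0

    def __getitem__(self, key: tuple[str, str]) -> list[DockingConformation]:
        return self.pairs[key]

    def protein_ids(self) -> list[str]:
        return sorted(self.proteins)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (rid, lid), confs in self.pairs.items():
            for c in confs:
                row = {"receptor": rid, "ligand": lid, "pose_id": c.pose_id,
                       "e_maxdo": c.e_maxdo, "e_iattract": c.e_iattract,
                       "e_external": c.e_external, "pp": c.pp}
                row.update({f"m{i}": v for i, v in enumerate(c.transform.as_flat())})
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        # %.17g preserves float64 exactly across the text round-trip
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path, proteins: dict[str, CoarseGrainedProtein] | None = None,
             protocol: str = "surface-restrained") -> "ConformationStore":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        store = cls(proteins=proteins or {}, protocol=protocol)
        mcols = [f"m{i}" for i in range(12)]
        for (rid, lid), grp in df.groupby(["receptor", "ligand"], sort=False):
            confs = []
            for _, row in grp.iterrows():
                confs.append(DockingConformation(
                    rid, lid, int(row.pose_id),
                    RigidTransform.from_flat(row[mcols].to_numpy(dtype=float)),
                    float(row.e_maxdo),
                    None if pd.isna(row.e_iattract) else float(row.e_iattract),
                    None if pd.isna(row.e_external) else float(row.e_external),
                    None if pd.isna(row.pp) else float(row.pp)))
            store.pairs[(rid, lid)] = confs
        return store

    def docked_interface(self, conf: DockingConformation, d: float = 5.0,
                         ) -> tuple[set[int], set[int]]:
        """Residue-level docked interface of a pose at threshold *d* (cached).

        A pre-set ``conf.docked_interface`` (planted fixture stores) takes
        precedence over recomputation from coordinates."""
        from .interfaces import detect_interface

        if conf.docked_interface is not None:
            return conf.docked_interface
        cache = getattr(conf, "_di_cache", None)
        if cache is None:
            cache = {}
            conf._di_cache = cache
        if d not in cache:
            rec = self.proteins[conf.receptor_id]
            lig = self.proteins[conf.ligand_id]
            lig_coords = conf.transform.apply(lig.coords)
            cache[d] = detect_interface((rec.coords, rec.residue_index),
                                        (lig_coords, lig.residue_index), d)
        return cache[d]

    def ingest_external_scores(self, table) -> None:
        """Attach per-conformation external scores (receptor, ligand, pose_id, score)."""
        indexed = {(r.receptor, r.ligand, r.pose_id): r.score for r in table.itertuples()}
        for key, confs in self.pairs.items():
            for c in confs:
                score = indexed.get((key[0], key[1], c.pose_id))
                if score is not None:
                    c.e_external = float(score)


def _dock_pair(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
               settings: DockSettings, pair_seed: int) -> list[DockingConformation]:
    ctx = PairContext(receptor, ligand, settings.cutoff)
    starts = generate_start_poses(receptor, ligand, settings.protocol,
                                  settings.n_positions, settings.n_rotations,
                                  seed=pair_seed, clearance=settings.clearance)
    confs = []
    for pid, start in enumerate(starts):
        if settings.minimize:
            tr, e = minimize_pose(receptor, ligand, start, "maxdo", settings.protocol,
                                  settings.cutoff, context=ctx,
                                  max_sweeps=settings.max_sweeps)
        else:
            tr = start
            try:
                e = ctx.maxdo(start.apply(ligand.coords))
            except ZeroDivisionError:
                e = np.inf
        if not np.isfinite(e):
            warnings.warn(f"pose {pid} of {receptor.protein_id}/{ligand.protein_id} "
                          "discarded (non-finite energy)")
            continue
        confs.append(DockingConformation(receptor.protein_id, ligand.protein_id, pid, tr, e))
    if settings.keep_top is not None:
        confs = sorted(confs, key=lambda c: c.e_maxdo)[: settings.keep_top]
    return confs


def cross_dock(proteins: list[CoarseGrainedProtein],
               settings: DockSettings | None = None) -> ConformationStore:
    """Complete cross-docking: every protein docked against every protein.

    Surface-restrained protocol: all N^2 ordered pairs (docking P1 against P2
    is not equivalent to docking P2 against P1).  Free protocol: N(N+1)/2
    unordered pairs, mirrored into both orderings.  Per-pair seeds derive
    deterministically from ``settings.seed``.
    """
    if not proteins:
        raise ValueError("need at least one protein")
    settings = settings or DockSettings()
    store = ConformationStore(proteins={p.protein_id: p for p in proteins},
                              protocol=settings.protocol, settings=settings,
                              seed=settings.seed)
    ids = [p.protein_id for p in proteins]
    by_id = store.proteins
    if settings.protocol == "surface-restrained":
        ordered = [(a, b) for a in ids for b in ids]
        for k, (rid, lid) in enumerate(ordered):
            pair_seed = int(np.random.SeedSequence([settings.seed, k]).generate_state(1)[0] % (2**31))
            store.pairs[(rid, lid)] = _dock_pair(by_id[rid], by_id[lid], settings, pair_seed)
    else:
        unordered = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i, len(ids))]
        for k, (rid, lid) in enumerate(unordered):
            pair_seed = int(np.random.SeedSequence([settings.seed, k]).generate_state(1)[0] % (2**31))
            confs = _dock_pair(by_id[rid], by_id[lid], settings, pair_seed)
            store.pairs[(rid, lid)] = confs
            if rid != lid:
                mirrored = [DockingConformation(lid, rid, c.pose_id,
                                                c.transform.inverse(), c.e_maxdo,
                                                c.e_iattract, c.e_external, c.pp)
                            for c in confs]
                store.pairs[(lid, rid)] = mirrored
    return store


def rescore_iattract(store: ConformationStore, reminimize: bool = True,
                     max_sweeps: int = 10) -> None:
    """Attach the 12-6 energy to every conformation, optionally after a short
    re-minimization from the 8-6-optimized pose (the transform is not replaced)."""
    cutoff = store.settings.cutoff if store.settings else 12.0
    for (rid, lid), confs in store.pairs.items():
        rec, lig = store.proteins[rid], store.proteins[lid]
        ctx = PairContext(rec, lig, cutoff)
        for c in confs:
            if reminimize:
                _, e = minimize_pose(rec, lig, c.transform, "iattract",
                                     store.protocol, cutoff, context=ctx,
                                     max_sweeps=max_sweeps)
            else:
                e = ctx.iattract(c.transform.apply(lig.coords))
            c.e_iattract = e
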