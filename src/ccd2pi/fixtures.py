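"""Seeded toy proteins, cognate complexes and pre-scored stores for testing.

The toy proteins are coarse-grained pseudo-residue constructs (test vehicles,
not physical proteins): a quasi-spherical Gly shell with one face flattened
into a disc-shaped binding patch of charged residues arranged in concentric
rings.  Partner specificity is geometric: each cognate pair carries a boss
(raised ring) on the receptor face and a matching groove on the ligand face
at a pair-specific ring radius, so only the cognate faces conform and reach
the steep Lennard-Jones contact minimum across the whole patch; mismatched
faces stand off by the boss height and lose most of the contact energy.
Uniform opposite charges on the two faces of a pair add an electrostatic
signature and make same-role encounters (face against like-charged face)
unfavourable.  Rotational symmetry of the rings makes the recognition
invariant to the spin about the face normal that the docking protocol
samples.

Everything is generated from a :class:`FixtureSpec` and a seed;
the same spec and seed reproduce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cg_model import CoarseGrainedProtein, load_cg_params
from .docking import (ConformationStore, DockingConformation, DockSettings,
                      PairContext, RigidTransform)
from .interfaces import Interface, SurfaceGraph, build_surface_graph

__all__ = [
    "FixtureSpec",
    "Benchmark",
    "make_toy_complex",
    "make_benchmark_set",
    "make_scored_store",
    "make_toy_surface",
    "designed_descriptors",
]

@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 8
    n_residues: int = 46             # approximate total per protein (body fills up)
    sphere_radius: float = 11.0      # A
    face_height: float = 6.5         # z of the flattened face plane
    patch_rings: tuple[float, ...] = (0.0, 3.0, 6.0, 8.8)   # ring radii, A
    patch_spacing: float = 4.0       # along-ring residue spacing, A
    charge_magnitude: float = 5.0    # |q| on patch residues (complementarity dial)
    bump_height: float = 2.5         # boss/groove amplitude, A
    bump_sigma: float = 1.5          # radial width of the boss/groove, A
    class_labels: tuple[str, ...] = ("c1", "c2")
    descriptor_noise: float = 0.0
    energy_noise: float = 0.0
    cognate_gap: float = 5.0         # planted-store energy advantage of cognates

# ---------------------------------------------------------------------------
# geometric toy proteins

def _patch_layout(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """(points on the face disc, ring index per point)."""
    max_r = np.sqrt(spec.sphere_radius**2 - spec.face_height**2)
    pts, rings = [], []
    for k, rho in enumerate(spec.patch_rings):
        if rho > max_r + 1e-9:
            raise ValueError(f"patch ring {rho} A exceeds the face disc ({max_r:.2f} A)")
        if rho == 0:
            pts.append((0.0, 0.0, spec.face_height))
            rings.append(k)
            continue
        m = max(3, int(np.floor(2 * np.pi * rho / spec.patch_spacing)))
        for j in range(m):
            a = 2 * np.pi * j / m
            pts.append((rho * np.cos(a), rho * np.sin(a), spec.face_height))
            rings.append(k)
    return np.asarray(pts), np.asarray(rings)

def _body_layout(spec: FixtureSpec, n_patch: int) -> np.ndarray:
    """Quasi-uniform shell points below the face plane."""
    target = max(8, spec.n_residues - n_patch)
    R, z0 = spec.sphere_radius, spec.face_height
    keep_fraction = (1 + (z0 - 1.0) / R) / 2       # sphere fraction below z0-1
    n_fib = int(np.ceil(target / keep_fraction))
    i = np.arange(n_fib) + 0.5
    phi = np.arccos(1 - 2 * i / n_fib)
    theta = np.pi * (1 + 5**0.5) * i
    pts = R * np.stack([np.sin(phi) * np.cos(theta),
                        np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    pts = pts[pts[:, 2] < z0 - 1.0]
    return pts[:target]

def _build_toy_protein(protein_id: str, bump_radius: float, bump_sign: float,
                       charge_sign: float, spec: FixtureSpec,
                       ) -> tuple[CoarseGrainedProtein, Interface]:
    """Assemble a toy protein; returns it with its designed face interface.

    ``bump_sign`` +1 raises a boss ring at ``bump_radius`` on the face,
    -1 recesses a matching groove; ``charge_sign`` sets the uniform face
    charge polarity (+1 -> Lys face, -1 -> Asp face).
    """
    params = load_cg_params()
    lj = params["lj_types"]
    patch_pts, ring_idx = _patch_layout(spec)
    body_pts = _body_layout(spec, len(patch_pts))

    coords, ridx, role, charge, tcode, resnames = [], [], [], [], [], []
    res = 0
    for p, ring in zip(patch_pts, ring_idx):
        sign = charge_sign
        name = "LYS" if sign > 0 else "ASP"
        rho = np.hypot(p[0], p[1])
        dz = bump_sign * spec.bump_height * np.exp(
            -((rho - bump_radius) ** 2) / (2 * spec.bump_sigma**2))
        p = p + np.array([0.0, 0.0, dz])
        normal = np.array([0.0, 0.0, 1.0])
        coords += [p, p + 1.2 * normal, p + 2.4 * normal]
        ridx += [res] * 3
        role += [0, 1, 2]
        charge += [0.0, 0.0, float(sign) * spec.charge_magnitude]
        tcode += ["CA", "MED" if sign > 0 else "SML", "POS" if sign > 0 else "NEG"]
        resnames.append(name)
        res += 1
    for p in body_pts:
        coords.append(p)
        ridx.append(res)
        role.append(0)
        charge.append(0.0)
        tcode.append("CA")
        resnames.append("GLY")
        res += 1

    tcode = np.asarray(tcode)
    cg = CoarseGrainedProtein(
        protein_id=protein_id,
        coords=np.asarray(coords, float),
        residue_index=np.asarray(ridx, int),
        role=np.asarray(role, int),
        charge=np.asarray(charge, float),
        type_code=tcode,
        lj_b=np.array([lj[t]["B"] for t in tcode]),
        lj_c=np.array([lj[t]["C"] for t in tcode]),
        sigma=np.array([lj[t]["sigma"] for t in tcode]),
        resnames=resnames,
        surface_mask=np.ones(res, dtype=bool),
    )
    gt = Interface(protein_id, frozenset(range(len(patch_pts))), "experimental")
    return cg, gt

_FLIP = np.diag([1.0, -1.0, -1.0])     # rotation by pi about x: face down

def _bound_transform(spec: FixtureSpec, separation: float) -> RigidTransform:
    return RigidTransform(_FLIP, np.array([0.0, 0.0, 2 * spec.face_height + separation]))

def _scan_bound_pose(receptor: CoarseGrainedProtein, ligand: CoarseGrainedProtein,
                     spec: FixtureSpec) -> tuple[RigidTransform, float]:
    """Face-to-face separation minimizing the docking energy (1-D scan)."""
    ctx = PairContext(receptor, ligand, cutoff=12.0)
    best_d, best_e = None, np.inf
    for d in np.arange(4.0, 12.01, 0.25):
        tr = _bound_transform(spec, d)
        try:
            e = ctx.maxdo(tr.apply(ligand.coords))
        except ZeroDivisionError:
            continue
        if e < best_e:
            best_d, best_e = d, e
    return _bound_transform(spec, best_d), best_e

def make_toy_complex(spec: FixtureSpec | None = None, validate: bool = True,
                     ) -> tuple[tuple[CoarseGrainedProtein, CoarseGrainedProtein],
                                RigidTransform,
                                tuple[Interface, Interface]]:
    """One cognate pair posed in contact, with its designed interfaces.

    With ``validate`` the bound pose is asserted to score below 95% of random
    contact poses (the designed recognition actually discriminates).
    """
    spec = spec or FixtureSpec()
    rho = spec.patch_rings[min(1, len(spec.patch_rings) - 1)]
    receptor, gt_r = _build_toy_protein("toyR", rho, +1.0, +1.0, spec)
    ligand, gt_l = _build_toy_protein("toyL", rho, -1.0, -1.0, spec)
    bound, e_bound = _scan_bound_pose(receptor, ligand, spec)
    if not np.isfinite(e_bound):
        raise RuntimeError("infeasible toy geometry: no finite bound energy")
    if validate:
        rng = np.random.default_rng(spec.seed)
        ctx = PairContext(receptor, ligand, cutoff=12.0)
        rand_e = []
        lig_radius = np.linalg.norm(ligand.coords - ligand.com(), axis=1).max()
        for _ in range(60):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            from scipy.spatial.transform import Rotation
            R = Rotation.random(random_state=rng).as_matrix()
            target = receptor.com() + u * (spec.sphere_radius + lig_radius * 0.55)
            t = target - R @ ligand.com()
            try:
                rand_e.append(ctx.maxdo(ligand.coords @ R.T + t))
            except ZeroDivisionError:
                rand_e.append(np.inf)
        if not e_bound < np.percentile(rand_e, 5):
            raise RuntimeError("designed bound pose does not out-score random poses")
    return (receptor, ligand), bound, (gt_r, gt_l)

@dataclass
class Benchmark:
    """A synthetic cross-docking benchmark: proteins, cognates, classes, truths."""

    proteins: list[CoarseGrainedProtein]
    cognate_pairs: list[tuple[str, str]]
    classes: dict[str, str]
    interfaces: dict[str, Interface]
    spec: FixtureSpec

    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def positive_ordered_pairs(self) -> set[tuple[str, str]]:
        out = set()
        for a, b in self.cognate_pairs:
            out.add((a, b))
            out.add((b, a))
        return out

    def write(self, outdir) -> None:
        from pathlib import Path
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in self.proteins:
            p.to_table().to_csv(outdir / f"{p.protein_id}.cg.tsv", sep="\t", index=False)
        pd.DataFrame(self.cognate_pairs, columns=["receptor", "ligand"]).to_csv(
            outdir / "cognate_pairs.tsv", sep="\t", index=False)
        pd.DataFrame([{"protein_id": k, "class": v} for k, v in self.classes.items()]
                     ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
        rows = [{"protein_id": pid, "residue": r, "provenance": itf.provenance}
                for pid, itf in self.interfaces.items() for r in sorted(itf.residues)]
        pd.DataFrame(rows).to_csv(outdir / "interfaces.tsv", sep="\t", index=False)

def make_benchmark_set(spec: FixtureSpec | None = None) -> Benchmark:
    """N toy proteins with N/2 designed cognate pairs (pattern-complementary
    faces); non-cognate faces have near-orthogonal charge patterns."""
    spec = spec or FixtureSpec()
    if spec.n_proteins % 2:
        raise ValueError("n_proteins must be even (cognate pairs)")
    n_pairs = spec.n_proteins // 2
    if n_pairs > len(spec.patch_rings):
        raise ValueError(f"at most {len(spec.patch_rings)} cognate pairs "
                         "supported (one boss/groove ring radius per pair)")
    proteins, pairs, classes, interfaces = [], [], {}, {}
    for k in range(n_pairs):
        rid, lid = f"R{k}", f"L{k}"
        rho = spec.patch_rings[k]
        rec, gt_r = _build_toy_protein(rid, rho, +1.0, +1.0, spec)
        lig, gt_l = _build_toy_protein(lid, rho, -1.0, -1.0, spec)
        proteins += [rec, lig]
        pairs.append((rid, lid))
        interfaces[rid], interfaces[lid] = gt_r, gt_l
        label = spec.class_labels[k % len(spec.class_labels)]
        classes[rid] = classes[lid] = label
    return Benchmark(proteins, pairs, classes, interfaces, spec)

# ---------------------------------------------------------------------------
# planted conformation stores (no docking)

def _dummy_protein(protein_id: str, n_residues: int, offset: float) -> CoarseGrainedProtein:
    params = load_cg_params()
    lj = params["lj_types"]
    coords = np.stack([np.arange(n_residues) * 4.0 + offset,
                       np.zeros(n_residues), np.zeros(n_residues)], axis=1)
    tcode = np.array(["CA"] * n_residues)
    return CoarseGrainedProtein(
        protein_id, coords, np.arange(n_residues), np.zeros(n_residues, int),
        np.zeros(n_residues), tcode,
        np.full(n_residues, lj["CA"]["B"]), np.full(n_residues, lj["CA"]["C"]),
        np.full(n_residues, lj["CA"]["sigma"]), ["GLY"] * n_residues,
        surface_mask=np.ones(n_residues, bool))

def make_scored_store(spec: FixtureSpec | None = None, uniform: bool = False,
                      sticky: str | None = None, n_residues: int = 12,
                      ri_size: int = 5,
                      ) -> tuple[ConformationStore, dict[str, Interface]]:
    """A conformation store with planted energies and docked interfaces.

    Bypasses docking entirely: every ordered pair gets three conformations —
    a full-overlap pose (FIR 1) whose energy carries the planted cognate
    advantage (``spec.cognate_gap``) plus Gaussian noise ``spec.energy_noise``,
    a partial-overlap pose, and a strongly favourable but off-interface pose
    (FIR 0) that the interface filter must reject.  ``uniform`` plants the
    same energy everywhere; ``sticky`` names a protein given the cognate-level
    energy with every partner.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [f"p{i}" for i in range(n)]
    cognate = {}
    for k in range(0, n - 1, 2):
        cognate[(ids[k], ids[k + 1])] = True
        cognate[(ids[k + 1], ids[k])] = True
    store = ConformationStore(
        proteins={pid: _dummy_protein(pid, n_residues, 100.0 * i)
                  for i, pid in enumerate(ids)},
        protocol="surface-restrained", seed=spec.seed)
    ri = frozenset(range(ri_size))
    ris = {pid: Interface(pid, ri, "experimental") for pid in ids}
    off = frozenset(range(ri_size + 1, min(2 * ri_size + 1, n_residues)))
    for r in ids:
        for l in ids:
            if uniform:
                e0 = -10.0
            elif sticky is not None and sticky in (r, l):
                e0 = -10.0 - spec.cognate_gap
            elif cognate.get((r, l)):
                e0 = -10.0 - spec.cognate_gap
            elif r == l:
                e0 = -6.0
            else:
                e0 = -10.0
            e0 += rng.normal(0.0, spec.energy_noise)
            confs = [
                DockingConformation(r, l, 0, RigidTransform.identity(), e0,
                                    pp=1.0, docked_interface=(set(ri), set(ri))),
                DockingConformation(r, l, 1, RigidTransform.identity(), -12.0,
                                    pp=0.2, docked_interface=(set(list(ri)[:1]) | set(off),
                                                              set(ri))),
                DockingConformation(r, l, 2, RigidTransform.identity(), -20.0,
                                    pp=0.0, docked_interface=(set(off), set(off))),
            ]
            store.pairs[(r, l)] = confs
    return store, ris

# ---------------------------------------------------------------------------
# toy surfaces and descriptor fields

def make_toy_surface(n_residues: int = 120, interface_size: int = 20,
                     spacing: float = 3.8) -> tuple[SurfaceGraph, Interface]:
    """A closed quasi-uniform spherical surface with a compact cap interface.

    A sphere has no boundary, so the decoy walk always finds fresh surface
    neighbours at any shift level.  The interface is the ``interface_size``
    residues closest to the north pole.
    """
    if interface_size >= n_residues:
        raise ValueError("interface must be smaller than the surface")
    R = spacing * np.sqrt(n_residues / (4 * np.pi))
    i = np.arange(n_residues) + 0.5
    phi = np.arccos(1 - 2 * i / n_residues)
    theta = np.pi * (1 + 5**0.5) * i
    coords = R * np.stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
    graph = build_surface_graph((coords, np.arange(n_residues)),
                                np.ones(n_residues, bool), cutoff=5.0)
    members = np.argsort(-coords[:, 2])[:interface_size]
    itf = Interface("toy_surface", frozenset(int(m) for m in members),
                    "experimental", 5.0)
    return graph, itf

def designed_descriptors(n_residues: int, surface: np.ndarray,
                         patch: frozenset[int], noise: float = 0.0,
                         seed: int = 0):
    """Descriptor table with the signal concentrated on *patch* (NIP high,
    conserved, protruding, favourable chemistry) plus optional uniform noise."""
    from .patches import DescriptorTable

    rng = np.random.default_rng(seed)
    base = np.zeros(n_residues)
    base[list(patch)] = 1.0
    def noisy(v):
        return np.clip(v + rng.uniform(-noise, noise, n_residues), 0.0, 1.0) \
            if noise > 0 else v.copy()
    return DescriptorTable(tjet=noisy(base), pc=noisy(base),
                           cv=noisy(1.0 - base), nip=noisy(base),
                           surface=np.asarray(surface, bool))
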