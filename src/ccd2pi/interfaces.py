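"""Interface detection, shifted decoy generation and interface agreement.

An interface is a set of residues of one protein.  Docked and experimental
interfaces are detected from coordinates: a residue is at the interface iff
any of its atoms (heavy atoms for atomic structures, pseudoatoms for
coarse-grained poses) lies strictly closer than ``d`` angstrom to any atom of
the partner.

Shifted decoys probe the sensitivity of partner identification to
approximations in the reference interfaces: a decoy of the same size is
produced by iteratively swapping a border interface residue for a surface
neighbour of the residue farthest from it.  Every swap removes one original
member and admits a residue that was never part of the source interface, so a
decoy with m swaps always shares exactly N - m residues with its source
(F1 = (N - m)/N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cg_model import AtomicProtein, CoarseGrainedProtein

__all__ = [
    "Interface",
    "SurfaceGraph",
    "detect_interface",
    "experimental_interface",
    "build_surface_graph",
    "shift_decoy",
    "decoy_series",
    "interface_agreement",
]


@dataclass
class Interface:
    protein_id: str
    residues: frozenset[int]
    provenance: str = "experimental"        # experimental | predicted | decoy
    distance: float | None = None
    log: list[tuple] = field(default_factory=list)   # shift_decoy iteration records

    def __post_init__(self):
        self.residues = frozenset(int(r) for r in self.residues)
        if not self.residues:
            if self.provenance == "experimental":
                raise ValueError(f"experimental interface of {self.protein_id} is empty")
            if self.provenance == "predicted":
                warnings.warn(f"empty predicted interface for {self.protein_id}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SurfaceGraph:
    """Adjacency over surface residues: edge iff any-heavy-atom distance < cutoff."""

    protein_id: str
    surface: frozenset[int]
    adjacency: dict[int, frozenset[int]]
    ca_coords: np.ndarray          # (n_residues, 3), all residues
    cutoff: float = 5.0

    def neighbors(self, residue: int) -> frozenset[int]:
        return self.adjacency.get(residue, frozenset())


def _atoms_of(obj) -> tuple[np.ndarray, np.ndarray]:
    """(coords, per-atom residue index) for atomic or coarse-grained input."""
    if isinstance(obj, AtomicProtein):
        return obj.all_coords(), obj.atom_residue_index()
    if isinstance(obj, CoarseGrainedProtein):
        return obj.coords, obj.residue_index
    coords, ridx = obj
    return np.asarray(coords, float), np.asarray(ridx, int)


def detect_interface(protein_a, protein_b, d: float = 5.0) -> tuple[set[int], set[int]]:
    """Residues of A and B whose atoms approach closer than *d* A (strict)."""
    if d <= 0:
        raise ValueError("distance threshold must be positive")
    ca, ra = _atoms_of(protein_a)
    cb, rb = _atoms_of(protein_b)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("empty protein")
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=d)
    side_a, side_b = set(), set()
    for i, js in enumerate(pairs):
        if not js:
            continue
        close = [j for j in js if np.linalg.norm(ca[i] - cb[j]) < d]  # strict <
        if close:
            side_a.add(int(ra[i]))
            side_b.update(int(rb[j]) for j in close)
    return side_a, side_b


def experimental_interface(protein_a: AtomicProtein, protein_b: AtomicProtein,
                           d: float = 5.0, allow_empty: bool = False,
                           ) -> tuple[Interface, Interface]:
    """Interfaces detected in the bound complex coordinates at d = 5 A."""
    side_a, side_b = detect_interface(protein_a, protein_b, d)
    if not side_a or not side_b:
        if allow_empty:
            warnings.warn(f"no contact between {protein_a.protein_id} and "
                          f"{protein_b.protein_id} at {d} A")
            return (Interface(protein_a.protein_id, frozenset(side_a), "decoy", d),
                    Interface(protein_b.protein_id, frozenset(side_b), "decoy", d))
        raise ValueError(f"no contact between {protein_a.protein_id} and "
                         f"{protein_b.protein_id} at {d} A")
    return (Interface(protein_a.protein_id, frozenset(side_a), "experimental", d),
            Interface(protein_b.protein_id, frozenset(side_b), "experimental", d))


def build_surface_graph(protein, surface_mask: np.ndarray, cutoff: float = 5.0) -> SurfaceGraph:
    coords, ridx = _atoms_of(protein)
    surface = frozenset(int(i) for i in np.flatnonzero(surface_mask))
    keep = np.isin(ridx, list(surface))
    coords_s, ridx_s = coords[keep], ridx[keep]
    tree = cKDTree(coords_s)
    adjacency: dict[int, set[int]] = {r: set() for r in surface}
    for i, j in tree.query_pairs(r=cutoff):
        a, b = int(ridx_s[i]), int(ridx_s[j])
        if a != b:
            adjacency[a].add(b)
            adjacency[b].add(a)

    if isinstance(protein, AtomicProtein):
        ca = protein.ca_coords()
        pid = protein.protein_id
    elif isinstance(protein, CoarseGrainedProtein):
        ca = protein.ca_coords()
        pid = protein.protein_id
    else:
        n = int(ridx.max()) + 1
        ca = np.zeros((n, 3))
        for r in range(n):
            ca[r] = coords[ridx == r].mean(axis=0)
        pid = "anonymous"
    return SurfaceGraph(pid, surface, {k: frozenset(v) for k, v in adjacency.items()},
                        np.asarray(ca, float), cutoff)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def shift_decoy(interface: Interface, graph: SurfaceGraph, fraction: float,
                seed: int = 0) -> Interface:
    """Shift ``round(fraction * N)`` residues of *interface* along the surface.

    Each iteration (i) uniformly picks a border residue ``r_s`` (an interface
    residue with a non-interface surface neighbour, surviving from the source
    interface, and not picked in the immediately preceding iteration),
    (ii) finds the interface residue farthest from ``r_s`` (C-alpha distance,
    ties to the lowest index), (iii) uniformly picks one of its surface
    neighbours ``r_n`` outside the source and current interface, and
    (iv) swaps their status.  Cardinality is preserved.  When the farthest
    residue's neighbourhood is saturated the next-farthest interface residue
    with an eligible neighbour is used instead (high shift levels crowd the
    region opposite the interface); the stuck error is raised only when no
    interface residue has an eligible neighbour left.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    source = set(interface.residues)
    n = len(source)
    m = _round_half_up(fraction * n)
    rng = np.random.default_rng(seed)
    current = set(source)
    log: list[tuple] = []
    prev_rs = None
    for it in range(m):
        border = sorted(
            r for r in current & source
            if r != prev_rs and any(nb not in current for nb in graph.neighbors(r)))
        if not border:
            raise RuntimeError(
                f"shift_decoy stuck at iteration {it}/{m}: no eligible border "
                f"residue (|current|={len(current)}, prev_rs={prev_rs})")
        r_s = int(rng.choice(border))
        others = sorted(current)
        dists = np.linalg.norm(graph.ca_coords[others] - graph.ca_coords[r_s],
                               axis=1)
        farthest = r_n = None
        for idx in np.argsort(-dists, kind="stable"):  # lowest index on ties
            cand_far = others[int(idx)]
            candidates = sorted(set(graph.neighbors(cand_far)) - current - source)
            if candidates:
                farthest = cand_far
                r_n = int(rng.choice(candidates))
                break
        if farthest is None:
            raise RuntimeError(
                f"shift_decoy stuck at iteration {it}/{m}: no interface "
                "residue has an eligible surface neighbour outside the "
                "interface")
        current.remove(r_s)
        current.add(r_n)
        log.append((it, r_s, farthest, r_n))
        prev_rs = r_s
    return Interface(interface.protein_id, frozenset(current), "decoy",
                     interface.distance, log=log)


def decoy_series(interface: Interface, graph: SurfaceGraph, seed: int = 0,
                 levels: tuple[float, ...] = tuple(np.arange(1, 11) / 10),
                 per_level: int = 10) -> list[Interface]:
    """Decoys at increasing shift levels: ``per_level`` decoys per level, in order."""
    seq = np.random.SeedSequence([seed])
    children = seq.spawn(len(levels) * per_level)
    out = []
    k = 0
    for level in levels:
        for _ in range(per_level):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            out.append(shift_decoy(interface, graph, level, seed=child_seed))
            k += 1
    return out


def interface_agreement(predicted: Interface, reference: Interface,
                        ) -> tuple[float, float, float]:
    """(F1, sensitivity, PPV) of *predicted* against *reference*."""
    if predicted.protein_id != reference.protein_id:
        raise ValueError(f"interfaces belong to different proteins: "
                         f"{predicted.protein_id} vs {reference.protein_id}")
    p, r = set(predicted.residues), set(reference.residues)
    if not p:
        warnings.warn(f"empty predicted interface for {predicted.protein_id}")
        return 0.0, 0.0, 0.0
    tp = len(p & r)
    ppv = tp / len(p)
    sens = tp / len(r) if r else 0.0
    f1 = 0.0 if (ppv + sens) == 0 else 2 * ppv * sens / (ppv + sens)
    return f1, sens, ppv
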