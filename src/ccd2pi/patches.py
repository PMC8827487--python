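"""Interface patch prediction: seed / extension / outer-layer growth.

Reference interfaces are predicted as surface patches grown in three stages
from four per-residue descriptors, all in [0, 1]:

* ``tjet`` — evolutionary conservation (supplied externally; a Shannon
  entropy fallback from an MSA is provided as plumbing),
* ``pc``   — physico-chemical interface propensity (bundled per-amino-acid
  table),
* ``cv``   — circular variance, a local-geometry measure (low = protruding);
  it always enters stage scores as ``1 - cv``,
* ``nip``  — docking-inferred binding propensity: normalized frequency of a
  residue appearing in docked interfaces across all partners.

Four strategy families combine the descriptors differently per stage.
``SC-juxt`` juxtaposes four single-philosophy schemes; the mixed families
blend the docking propensity in at every stage (``SC-mix``), only after seed
detection (``SC-monoSeed-mix``), or use it exclusively for seed detection
(``SC-dockSeed-mix``).  Stage scores are products of the selected
descriptors; at each stage, candidate residues above a percentile threshold
re-estimated among the candidates are admitted.  Each scheme is run 10 times
with different seeds and residues present in at least 2 runs form the
consensus patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .cg_model import _data_file
from .interfaces import Interface, SurfaceGraph, interface_agreement

__all__ = [
    "DescriptorTable",
    "Scheme",
    "StrategyConfig",
    "PatchPrediction",
    "STRATEGIES",
    "circular_variance",
    "circular_variance_all",
    "pc_from_resnames",
    "conservation_entropy_fallback",
    "nip_from_docking",
    "grow_patch",
    "consensus_patches",
    "select_reference_interface",
]


@dataclass
class DescriptorTable:
    """Per-residue descriptor arrays, defined on surface residues."""

    tjet: np.ndarray
    pc: np.ndarray
    cv: np.ndarray
    nip: np.ndarray
    surface: np.ndarray            # boolean mask

    def __post_init__(self):
        for name in ("tjet", "pc", "cv", "nip"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            on_surface = v[self.surface]
            if np.any((on_surface < 0) | (on_surface > 1)):
                raise ValueError(f"descriptor {name} outside [0, 1] on surface residues")

    def stage_score(self, descriptors: tuple[str, ...]) -> np.ndarray:
        """Product of the selected descriptors; ``cv`` enters as 1 - cv."""
        score = np.ones_like(self.tjet)
        for name in descriptors:
            score = score * ((1.0 - self.cv) if name == "cv" else getattr(self, name))
        return score

    def to_frame(self, protein_id: str):
        import pandas as pd

        return pd.DataFrame({
            "protein_id": protein_id, "residue": np.arange(len(self.tjet)),
            "T_JET": self.tjet, "PC": self.pc, "CV": self.cv, "NIP": self.nip,
            "surface": self.surface.astype(int),
        })


@dataclass(frozen=True)
class Scheme:
    name: str
    seed: tuple[str, ...]
    extend: tuple[str, ...]
    outer: tuple[str, ...]


@dataclass
class StrategyConfig:
    name: str
    schemes: list[Scheme]
    iterations: int = 10
    consensus_min: int = 2
    thresholds: tuple[float, float, float] = (85.0, 70.0, 60.0)  # percentiles


# The four strategy families.  SC-juxt juxtaposes the four base philosophies;
# the mixed families are three variants each of the cons/notLig/geom schemes.
STRATEGIES: dict[str, StrategyConfig] = {
    "SC-juxt": StrategyConfig("SC-juxt", [
        Scheme("SC_cons", ("tjet",), ("pc", "cv"), ("pc", "cv")),
        Scheme("SC_notLig", ("tjet", "cv"), ("pc", "cv"), ("pc", "cv")),
        Scheme("SC_geom", ("cv", "pc"), ("cv", "pc"), ("pc",)),
        Scheme("SC_NIP", ("nip",), ("nip",), ("nip",)),
    ]),
    "SC-mix": StrategyConfig("SC-mix", [
        Scheme("mix_cons", ("tjet", "nip"), ("pc", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("mix_notLig", ("tjet", "cv", "nip"), ("pc", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("mix_geom", ("cv", "pc", "nip"), ("cv", "pc", "nip"), ("pc", "nip")),
    ]),
    "SC-monoSeed-mix": StrategyConfig("SC-monoSeed-mix", [
        Scheme("mono_cons", ("tjet",), ("pc", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("mono_notLig", ("tjet", "cv"), ("pc", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("mono_geom", ("cv", "pc"), ("cv", "pc", "nip"), ("pc", "nip")),
    ]),
    "SC-dockSeed-mix": StrategyConfig("SC-dockSeed-mix", [
        Scheme("dock_cons", ("nip",), ("tjet", "pc", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("dock_notLig", ("nip",), ("tjet", "cv", "nip"), ("pc", "cv", "nip")),
        Scheme("dock_geom", ("nip",), ("pc", "cv", "nip"), ("pc", "nip")),
    ]),
}


@dataclass
class PatchPrediction:
    protein_id: str
    patches: list[frozenset[int]]
    votes: dict[int, int] = field(default_factory=dict)  # per residue, out of iterations
    selected: Interface | None = None
    mode: str | None = None


def circular_variance(ca_coords: np.ndarray, residue: int, radius: float = 12.0) -> float:
    """CV = 1 - ||sum of unit vectors to neighbours|| / n, in [0, 1].

    0 means all neighbours lie in one direction (protruding residue), 1 means
    isotropic surroundings (buried).  Residues with no neighbour within
    *radius* get CV = 0 with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = ca_coords[residue]
    delta = np.delete(ca_coords, residue, axis=0) - center
    dist = np.linalg.norm(delta, axis=1)
    near = (dist > 0) & (dist <= radius)
    if not np.any(near):
        warnings.warn(f"residue {residue} has no neighbour within {radius} A; CV = 0")
        return 0.0
    units = delta[near] / dist[near, None]
    return float(1.0 - np.linalg.norm(units.sum(axis=0)) / len(units))


def circular_variance_all(ca_coords: np.ndarray, radius: float = 12.0) -> np.ndarray:
    return np.array([circular_variance(ca_coords, i, radius)
                     for i in range(len(ca_coords))])


def pc_from_resnames(resnames: list[str]) -> np.ndarray:
    """Bundled per-amino-acid interface propensity, scaled to [0, 1]."""
    table = _data_file("pc_propensities.json")["propensity"]
    default = float(np.mean(list(table.values())))
    return np.array([table.get(r, default) for r in resnames])


def conservation_entropy_fallback(msa: list[str]) -> np.ndarray:
    """1 - normalized Shannon entropy per MSA column (plumbing fallback, not a
    substitute for a proper conservation score)."""
    if not msa or len({len(s) for s in msa}) != 1:
        raise ValueError("MSA must be non-empty with equal-length rows")
    cols = np.array([list(s) for s in msa]).T
    out = np.empty(len(cols))
    for i, col in enumerate(cols):
        letters = [c for c in col if c not in "-."]
        if not letters:
            out[i] = 0.0
            continue
        _, counts = np.unique(letters, return_counts=True)
        p = counts / counts.sum()
        out[i] = 1.0 - float(-(p * np.log(p)).sum() / np.log(20.0))
    return np.clip(out, 0.0, 1.0)


def nip_from_docking(store, protein_id: str, top_k: int = 10, d: float = 5.0,
                     surface: np.ndarray | None = None) -> np.ndarray:
    """Docking-inferred binding propensity of every residue of *protein_id*.

    For each partner (every pair in the store involving the protein, in either
    role), the residue's membership in the docked interface is counted over the
    ``top_k`` lowest-energy conformations; counts are normalized by their
    maximum so NIP is in [0, 1].
    """
    if protein_id not in store.proteins:
        raise KeyError(f"protein {protein_id!r} not present in the store")
    n = store.proteins[protein_id].n_residues
    counts = np.zeros(n)
    involved = [key for key in store.pairs if protein_id in key]
    if not involved:
        raise KeyError(f"no pair involving {protein_id!r} in the store")
    for key in involved:
        confs = sorted(store.pairs[key], key=lambda c: c.e_maxdo)[:top_k]
        side = 0 if key[0] == protein_id else 1
        for conf in confs:
            di = store.docked_interface(conf, d)[side]
            for r in di:
                counts[r] += 1
    if counts.max() > 0:
        counts = counts / counts.max()
    if surface is not None:
        counts = np.where(surface, counts, 0.0)
    return counts


def _clusters(residues: set[int], graph: SurfaceGraph) -> list[frozenset[int]]:
    """Connected components of *residues* on the surface adjacency graph."""
    remaining = set(residues)
    out = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r = frontier.pop()
            for nb in graph.neighbors(r):
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        out.append(frozenset(comp))
    return out


def grow_patch(graph: SurfaceGraph, descriptors: DescriptorTable, scheme: Scheme,
               seed: int = 0, thresholds: tuple[float, float, float] = (85.0, 70.0, 60.0),
               ) -> frozenset[int]:
    """Grow one patch through the seed -> extension -> outer-layer stages.

    Seed stage: all surface residues are candidates; those at or above the
    seed percentile of the stage score form clusters and the cluster holding
    the best-scoring residue (stochastic tie-break) becomes the seed patch.
    Growth stages admit candidate residues adjacent to the current patch whose
    stage score reaches the stage percentile, re-estimated among candidates.
    """
    surface = sorted(graph.surface)
    if not surface:
        raise ValueError("empty surface")
    rng = np.random.default_rng(seed)

    score = descriptors.stage_score(scheme.seed)
    cand_scores = score[surface]
    thr = np.percentile(cand_scores, thresholds[0])
    admitted = {r for r in surface if score[r] >= thr and score[r] > 0}
    if not admitted:
        warnings.warn(f"scheme {scheme.name}: no seed residue (all stage scores 0)")
        return frozenset()
    clusters = _clusters(admitted, graph)
    best_score = max(score[r] for r in admitted)
    top = [r for r in admitted if score[r] >= best_score - 1e-12]
    anchor = int(rng.choice(sorted(top)))
    patch = set(next(c for c in clusters if anchor in c))

    for stage, pct in (("extend", thresholds[1]), ("outer", thresholds[2])):
        score = descriptors.stage_score(getattr(scheme, stage))
        candidates = sorted({nb for r in patch for nb in graph.neighbors(r)} - patch)
        if not candidates:
            continue
        thr = np.percentile(score[candidates], pct)
        patch |= {r for r in candidates if score[r] >= thr and score[r] > 0}
    return frozenset(patch)


def consensus_patches(graph: SurfaceGraph, descriptors: DescriptorTable,
                      strategy: StrategyConfig | str, seed: int = 0) -> PatchPrediction:
    """Consensus patches over 10 seeded runs of every member scheme.

    Residues present in at least ``consensus_min`` runs of a scheme are kept
    and clustered into connected patches; patches are pooled across schemes.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    seq = np.random.SeedSequence([seed])
    children = iter(seq.spawn(len(strategy.schemes) * strategy.iterations))
    all_patches: list[frozenset[int]] = []
    votes: dict[int, int] = {}
    for scheme in strategy.schemes:
        counts: dict[int, int] = {}
        for _ in range(strategy.iterations):
            run_seed = int(next(children).generate_state(1)[0] % (2**31))
            for r in grow_patch(graph, descriptors, scheme, run_seed,
                                strategy.thresholds):
                counts[r] = counts.get(r, 0) + 1
        kept = {r for r, c in counts.items() if c >= strategy.consensus_min}
        for r in kept:
            votes[r] = max(votes.get(r, 0), counts[r])
        all_patches.extend(_clusters(kept, graph))
    # deduplicate identical patches from different schemes
    unique = sorted(set(all_patches), key=lambda p: (-len(p), sorted(p)))
    return PatchPrediction(graph.protein_id, unique, votes)


def select_reference_interface(prediction: PatchPrediction, mode: str = "blind",
                               known: Interface | None = None,
                               max_combination: int = 3) -> Interface:
    """Pick the reference interface from the consensus patches.

    Oracle mode enumerates patches and unions of up to ``max_combination``
    patches and returns the F1-maximizer against the known interface; blind
    mode returns the union of all consensus patches.
    """
    if mode not in ("blind", "oracle"):
        raise ValueError(f"unknown mode {mode!r}")
    patches = prediction.patches
    if not patches:
        warnings.warn(f"no patches for {prediction.protein_id}; empty reference interface")
        ri = Interface(prediction.protein_id, frozenset(), "predicted")
    elif mode == "blind":
        union = frozenset().union(*patches)
        ri = Interface(prediction.protein_id, union, "predicted")
    else:
        if known is None:
            raise ValueError("oracle mode requires a known interface")
        best, best_f1 = frozenset(), -1.0
        for k in range(1, min(max_combination, len(patches)) + 1):
            for combo in combinations(patches, k):
                union = frozenset().union(*combo)
                if not union:
                    continue
                f1, _, _ = interface_agreement(
                    Interface(prediction.protein_id, union, "predicted"), known)
                if f1 > best_f1:
                    best, best_f1 = union, f1
        ri = Interface(prediction.protein_id, best, "predicted")
    prediction.selected = ri
    prediction.mode = mode
    return ri
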