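"""Partner-discrimination metrics, hyper-parameter grid search and positives
extension by homology transfer.

Discrimination of cognate partners from non-interactors is summarized by the
rank-sum AUC of the scaled NII values of positive ordered pairs against
negatives.  The grid search enumerates the hyper-parameter combinations
(docked-interface distance x interface-prediction strategy x docking energy x
pair potential on/off), picks the global default by weighted-average AUC over
the functional-class subsets, retains a top pool per subset, and tests
per-class parameter overrides with a Mann-Whitney U test at p < 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "GridConfig",
    "GridCombo",
    "EvaluationResult",
    "auc_partner",
    "weighted_auc",
    "grid_search",
    "mwu_override",
    "ptopx",
    "baseline_ptopx",
    "homology_transfer",
]

STRATEGY_NAMES = ("SC-mix", "SC-monoSeed-mix", "SC-dockSeed-mix", "SC-juxt")


@dataclass(frozen=True)
class GridCombo:
    distance: float
    strategy: str | None          # None for experimental-RI grids
    energy: str
    use_pp: bool

    def label(self) -> str:
        s = self.strategy or "exp"
        return f"d{self.distance}|{s}|{self.energy}|pp={'on' if self.use_pp else 'off'}"


@dataclass
class GridConfig:
    distances: tuple[float, ...] = (4.5, 5.0, 6.0)
    strategies: tuple[str, ...] = STRATEGY_NAMES
    energies: tuple[str, ...] = ("maxdo", "iattract", "external")
    pair_potential: tuple[bool, ...] = (True, False)
    ri_source: str = "predicted"       # predicted | experimental

    def combos(self) -> list[GridCombo]:
        if self.ri_source == "experimental":
            return [GridCombo(d, None, e, p) for d, e, p in
                    product(self.distances, self.energies, self.pair_potential)]
        return [GridCombo(d, s, e, p) for d, s, e, p in
                product(self.distances, self.strategies, self.energies,
                        self.pair_potential)]

    def size(self) -> int:
        return len(self.combos())


def auc_partner(nii_scaled: pd.DataFrame, positives, scope: list[str] | None = None,
                exclude_self: bool = True) -> float:
    """Rank-sum AUC of positive ordered pairs vs negatives over NII_scaled.

    *positives* is a collection of ordered (receptor, ligand) pairs; *scope*
    restricts both rows and columns to a candidate subset (within-class
    evaluation).  Ties get mid-ranks.
    """
    ids = scope if scope is not None else list(nii_scaled.index)
    pos = {(a, b) for a, b in positives if a in ids and b in ids}
    scores, labels = [], []
    for r in ids:
        for l in ids:
            if exclude_self and r == l:
                continue
            scores.append(float(nii_scaled.loc[r, l]))
            labels.append((r, l) in pos)
    labels = np.asarray(labels)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate scope: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def weighted_auc(aucs, sizes) -> float:
    """Size-weighted average AUC over subsets: sum(N_j AUC_j) / sum(N_j)."""
    aucs = np.asarray(list(aucs), dtype=float)
    sizes = np.asarray(list(sizes), dtype=float)
    if aucs.shape != sizes.shape:
        raise ValueError("aucs and sizes must have the same length")
    if np.any(sizes <= 0):
        raise ValueError("subset sizes must be positive")
    return float((sizes * aucs).sum() / sizes.sum())


def mwu_override(default_aucs, alternative_aucs, alpha: float = 0.01,
                 ) -> tuple[bool, float]:
    """Two-sided Mann-Whitney U (tie-corrected normal approximation).

    The alternative parameter value overrides the default iff its mean AUC is
    higher and p < *alpha*.  Empty partitions never override.
    """
    default_aucs = np.asarray(list(default_aucs), dtype=float)
    alternative_aucs = np.asarray(list(alternative_aucs), dtype=float)
    if len(default_aucs) == 0 or len(alternative_aucs) == 0:
        return False, 1.0
    res = mannwhitneyu(alternative_aucs, default_aucs, alternative="two-sided",
                       method="asymptotic")
    p = float(res.pvalue)
    return bool(alternative_aucs.mean() > default_aucs.mean() and p < alpha), p


@dataclass
class EvaluationResult:
    grid: GridConfig
    auc_table: pd.DataFrame          # combos x subsets
    sizes: dict[str, int]
    weighted: pd.Series              # per combo
    default_combo: GridCombo
    retained: dict[str, list[GridCombo]]
    partitions: dict                 # (subset, parameter) -> per-value stats
    overrides: dict                  # (subset, parameter) -> (value, p)
    failed: list[GridCombo] = field(default_factory=list)


def _combo_params(combo: GridCombo) -> dict:
    params = {"distance": combo.distance, "energy": combo.energy,
              "use_pp": combo.use_pp}
    if combo.strategy is not None:
        params["strategy"] = combo.strategy
    return params


def grid_search(runner, grid: GridConfig, sizes: dict[str, int],
                retain_fraction: float = 0.2, alpha: float = 0.01,
                ) -> EvaluationResult:
    """Enumerate the grid, rank combinations and derive per-class overrides.

    *runner* maps a :class:`GridCombo` to a dict ``{subset: AUC}`` covering
    every subset in *sizes* (the whole set plus the functional classes).  The
    global default is the weighted-AUC argmax; per subset the top
    ``ceil(retain_fraction * grid size)`` combinations are retained and
    partitioned by each parameter's values (mean, max, mean +/- 2 SEM);
    parameter values beating the default within a subset are accepted only if
    a Mann-Whitney U test over the full grid gives p < *alpha*.
    """
    combos = grid.combos()
    rows, ok_combos, failed = [], [], []
    for combo in combos:
        try:
            rows.append(runner(combo))
            ok_combos.append(combo)
        except Exception as exc:
            warnings.warn(f"combination {combo.label()} failed: {exc}")
            failed.append(combo)
    if not ok_combos:
        raise RuntimeError("every grid combination failed")
    auc_table = pd.DataFrame(rows, index=[c.label() for c in ok_combos])
    subsets = list(auc_table.columns)
    weighted = pd.Series(
        [weighted_auc(auc_table.loc[c.label(), subsets],
                      [sizes[s] for s in subsets]) for c in ok_combos],
        index=[c.label() for c in ok_combos])
    default_combo = ok_combos[int(np.argmax(weighted.values))]

    n_retain = math.ceil(retain_fraction * len(ok_combos))
    retained: dict[str, list[GridCombo]] = {}
    partitions: dict = {}
    overrides: dict = {}
    by_label = {c.label(): c for c in ok_combos}
    for subset in subsets:
        order = auc_table[subset].sort_values(ascending=False)
        top = [by_label[lbl] for lbl in order.index[:n_retain]]
        retained[subset] = top
        for param in _combo_params(ok_combos[0]):
            values: dict = {}
            for combo in top:
                v = _combo_params(combo)[param]
                values.setdefault(v, []).append(float(auc_table.loc[combo.label(), subset]))
            stats = {}
            for v, aucs in values.items():
                a = np.asarray(aucs)
                sem = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
                stats[v] = {"mean": float(a.mean()), "max": float(a.max()),
                            "n": len(a), "band": (float(a.mean() - 2 * sem),
                                                  float(a.mean() + 2 * sem))}
            partitions[(subset, param)] = stats
            # per-class override test over the FULL grid
            default_v = _combo_params(default_combo)[param]
            full = {}
            for combo in ok_combos:
                v = _combo_params(combo)[param]
                full.setdefault(v, []).append(float(auc_table.loc[combo.label(), subset]))
            best_alt, best_p = None, 1.0
            for v, aucs in full.items():
                if v == default_v or v not in stats:
                    continue
                decided, p = mwu_override(full.get(default_v, []), aucs, alpha)
                if decided and p < best_p:
                    best_alt, best_p = v, p
            if best_alt is not None:
                overrides[(subset, param)] = (best_alt, best_p)
    return EvaluationResult(grid, auc_table, dict(sizes), weighted, default_combo,
                            retained, partitions, overrides, failed)


def ptopx(best_ranks: dict[str, int], x: float, n_candidates: int | dict[str, int],
          ) -> float:
    """Proportion of proteins whose best known-partner rank is within the top x%.

    ``1/N_proteins * sum_i 1[min_k R_k^i <= (x/100) N_i]`` with N_i the
    per-protein candidate count (a shared int or a per-protein dict).
    """
    if not best_ranks:
        raise ValueError("no proteins")
    hits = 0
    for pid, rank in best_ranks.items():
        n = n_candidates[pid] if isinstance(n_candidates, dict) else n_candidates
        if not 1 <= rank <= n:
            raise ValueError(f"rank {rank} of {pid} outside [1, {n}]")
        if rank <= (x / 100.0) * n:
            hits += 1
    return hits / len(best_ranks)


def baseline_ptopx(partner_counts, x: float) -> float:
    """Expected-count baseline: fraction of proteins with (x/100) N_i >= 1."""
    counts = np.asarray(list(partner_counts), dtype=float)
    if np.any(counts < 0):
        raise ValueError("partner counts must be >= 0")
    return float(np.mean((x / 100.0) * counts >= 1.0))


def homology_transfer(complexes, clusters: dict[str, str],
                      protein_chains: dict[str, list[str]],
                      min_interface: int = 5) -> set[frozenset]:
    """Extend positives by cluster propagation from known chain-chain complexes.

    *complexes* is an iterable of (chain_a, chain_b, interface_size) records;
    *clusters* maps a chain id to its homology-cluster id at the chosen
    sequence-identity level (chains without an assignment become singleton
    clusters, logged); *protein_chains* maps a protein id to its chain ids.
    A protein pair is positive iff some complex with interface strictly larger
    than *min_interface* residues links a cluster-mate of one of its chains to
    a cluster-mate of a chain of the other protein.
    """
    def cluster_of(chain: str) -> str:
        if chain not in clusters:
            warnings.warn(f"chain {chain} has no cluster assignment; singleton")
            return f"singleton:{chain}"
        return clusters[chain]

    contact_clusters = set()
    for chain_a, chain_b, size in complexes:
        if size > min_interface:
            ca, cb = cluster_of(chain_a), cluster_of(chain_b)
            contact_clusters.add(frozenset((ca, cb)))

    positives = set()
    proteins = list(protein_chains)
    for i, p1 in enumerate(proteins):
        for p2 in proteins[i:]:
            found = False
            for c1 in protein_chains[p1]:
                for c2 in protein_chains[p2]:
                    if frozenset((cluster_of(c1), cluster_of(c2))) in contact_clusters:
                        found = True
                        break
                if found:
                    break
            if found:
                positives.add(frozenset((p1, p2)))
    return positives
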