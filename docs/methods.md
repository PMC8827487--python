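# Methods

This note documents the models, parameters, numerical choices and
limitations of `ccd2pi`. Everything stated here is computed by the package's
tests or scripts; nothing is quoted from external runs.

## Coarse-grained protein model

Each residue is reduced to a pseudoatom at the Cα position plus, except for
glycine, one or two side-chain pseudoatoms placed at centroids of authored
heavy-atom groups (`src/ccd2pi/data/cg_params.json`). Charged side chains
(Arg, Lys +1; Asp, Glu −1) carry their net charge on the second side-chain
pseudoatom. Each pseudoatom has an LJ-type code with three parameters:

* `B = 3 ε r*⁸` and `C = 4 ε r*⁶`, so the 8–6 pair term `B/r⁸ − C/r⁶` has
  its minimum at `r*` with depth `ε`;
* `σ = r*/2^(1/6)`, the matching 12–6 radius.

Per-type `r*` ranges 4.6–5.6 Å and `ε` 0.10–0.30 (arbitrary coarse-grained
energy units). Pair parameters combine as geometric means for B and C and
the arithmetic mean for σ. The table is a self-contained, versioned stand-in
for a published side-chain parameterization: the partner-identification
logic is independent of the exact coarse-grained geometry, and shipping an
explicit table keeps every number reproducible from this repository alone.

Missing side-chain atoms fall back to Cβ, then Cα, with a warning (benchmark
structures have gaps). Multi-chain proteins are treated as a single rigid
body over the selected chain set. Only model 1 of multi-model files is read;
alternate locations collapse to the highest-occupancy conformer.

**Surface residues** are those with relative solvent accessibility ≥ 0.25
(configurable), from Shrake–Rupley SASA (Bio.PDB) divided by per-type
theoretical maxima (Gly-X-Gly based).

## Docking energies and protocols

Two pairwise energies over receptor/ligand pseudoatoms (charge product term
only contributes for charged–charged pairs; 12 Å cutoff by default, no
shifting; the cutoff is configurable and disabled in oracle tests):

* minimization energy: `E = B/r⁸ − C/r⁶ + qᵢqⱼ/(15 r²)` (distance-dependent
  dielectric ε = 15r);
* re-scoring energy: `E = (σ/r)¹² − (σ/r)⁶ + qᵢqⱼ/(10 r)` (constant
  dielectric ε = 10), implemented exactly as printed with no well-depth
  prefactor; re-scoring optionally re-minimizes briefly from the
  8–6-optimized pose.

Start poses cover the receptor surface quasi-uniformly (Fibonacci sphere of
directions, seeded global rotation); the ligand COM is placed on the ray
from the receptor COM, offset by the ligand's directional extent plus a
clearance (1.5–3 Å), and spun through γ rotations about the COM–COM axis.
In the **surface-restrained** protocol the minimizer has 4 degrees of
freedom (radial slide + 3 rotations) and docking P₁→P₂ is not equivalent to
P₂→P₁ (all N² ordered pairs are computed). In the **free** protocol all 6
rigid DOF are optimized and the N(N+1)/2 unordered pairs are mirrored.

The minimizer is a deterministic derivative-free coordinate descent with
shrinking steps (initial 1.5 Å / 0.2 rad, halved when a sweep improves less
than 10⁻⁴ energy units, stopping below 10⁻³): a declared simplification of
the multi-start minimization schemes used by production docking engines.
Returned energy never exceeds the start energy.

Desk-scale problem sizes: engine defaults are 64 surface positions × 12
γ-rotations per pair; the synthetic benchmark pipeline uses 16 × 3 with a
20-sweep descent, which resolves the designed recognition in about 80 s for
an 8-protein cross-dock on one CPU. Production cross-docking campaigns use
orders of magnitude more minimizations per pair; nothing in the scoring
layer depends on the pose count.

## Interfaces

A residue is at the docked interface iff any of its atoms (heavy atoms for
atomic structures, pseudoatoms for docked poses) is strictly closer than
*d* Å to the partner; *d* ∈ {4.5, 5, 6} is a grid hyper-parameter, 5 Å the
default and the fixed value for experimental interfaces extracted from bound
complexes.

**Shifted decoys** probe sensitivity to reference-interface error. Each
iteration removes a border interface residue (uniformly drawn, not the one
removed in the immediately preceding iteration) and adds a surface neighbour
(< 5 Å) of the interface residue farthest from it (Cα distances, ties to the
lowest index). Two deliberate choices:

* *No re-entry*: the removed residue is always an original member and the
  added residue is never one, so a decoy with m = round(f·N) swaps shares
  exactly N−m residues with its source and F1 = (N−m)/N deterministically —
  the property the sensitivity analysis relies on.
* *Saturation fallback*: at deep shift levels the additions crowd the region
  opposite the interface and the single farthest residue's neighbourhood can
  fill up; the generator then falls back to the next-farthest residue with
  an eligible neighbour and errors only when no interface residue has one.

The decoy series is 10 decoys at each of the shift levels 10%…100%. Note
that 100% shifts are only geometrically feasible when the non-interface
surface is at least as large as the interface.

## Patch prediction

Reference interfaces are predicted as surface patches grown in three stages
(seed → extension → outer layer) from four per-residue descriptors in
[0, 1]: conservation `T_JET` (an input column; a Shannon-entropy MSA
fallback is provided as plumbing, and a flat 0.5 is used when nothing is
supplied), physico-chemical interface propensity `PC` (bundled per-amino-acid
table, aromatic/hydrophobic high), circular variance `CV` over a 12 Å Cα
neighbourhood (enters all scores as 1−CV, favouring protruding residues),
and the docking-inferred binding propensity `NIP` (top-10 lowest-energy
poses per partner, membership counts max-normalized).

Stage scores are **products** of the stage's descriptors; candidates
(surface residues, then residues adjacent to the patch on the 5 Å surface
graph) are admitted at or above a percentile threshold re-estimated among
the candidates: seed top 15%, extension top 30%, outer layer top 40%. These
thresholds and the product form are package defaults — the strategy families
specify which descriptors enter each stage, not the functional form. The
seed patch is the connected cluster holding the best-scoring residue
(stochastic tie-break). Four families are provided: `SC-juxt` (four
single-philosophy schemes, including an NIP-only one), `SC-mix` (NIP blended
at every stage), `SC-monoSeed-mix` (NIP only after seed detection) and
`SC-dockSeed-mix` (seeds from NIP alone — the default strategy). Each scheme
runs 10 seeded iterations; residues present in ≥ 2 runs form the consensus,
clustered into connected patches. The reference interface is the union of
consensus patches (blind mode) or the F1-best union of up to 3 patches
against a known interface (oracle mode).

## Pair potential

A 20×20 symmetric interface log-odds table:
`score(a,b) = log[(f_obs + λ)/(f_exp + λ)]` with `f_obs` the ordered
contact-pair frequency among interface contacts of the training complexes,
`f_exp` the product of marginal contact-endpoint frequencies, and pseudocount
λ = 10⁻⁴. This is a standard statistical contact potential, not a
reproduction of any specific published one; externally computed
per-conformation scores can be ingested instead. A pose's PP score is the
sum of table entries over its residue-level contacts. Because multiplying a
signed energy by a signed score flips sign, PP enters the interaction-index
product through a min–max map to (0, 1] (floor 10⁻³, best score → 1) within
each pair's conformation set; a raw-product mode exists behind a flag. Note
the self-normalized log-odds is not monotone in the absolute count of a pair
— enrichment is relative to the training composition.

## Interaction matrix and normalization

`II` is the minimum of FIR × E [× PP-factor] over a pair's conformations
(optionally PP-prefiltered to a top fraction); if no product is negative the
pair gets II = 0. Sociability S averages both directions over the whole set
including self-pairs. Normalization uses magnitudes with the numerator sign
carried through (the formulas are ill-defined for mixed signs; favourable =
negative throughout), with an ε = 10⁻⁹ floor on |S| and on the four
denominator extremes. Scaling to [0, 1] is per focal protein (row-wise),
because "best partner scores 1" is a per-protein statement; values are
clamped and an all-zero row stays zero with a warning. Normalization scope
is the whole set by default, with per-class subsets supported. Self-pairs
enter S but are excluded from partner-ranking evaluation by default.

## Evaluation

AUC is the tie-corrected rank-sum statistic of positive ordered pairs versus
negatives over scaled NII. The hyper-parameter grid is distance {4.5, 5, 6}
× strategy {SC-mix, SC-monoSeed-mix, SC-dockSeed-mix, SC-juxt} × energy
{8–6, 12–6, external} × pair potential {on, off} — 72 combinations, or 18
with experimental reference interfaces (the strategy axis disappears). The
global default maximizes the subset-size-weighted mean AUC; per subset the
top ceil(20% · 72) = 15 (or ceil(30% · 18) = 6) combinations are retained and
partitioned by each parameter (mean, max, mean ± 2 SEM reported); a
non-default parameter value is adopted for a class only when a two-sided
Mann–Whitney U test over the full grid gives p < 0.01 and its mean AUC is
higher. PtopX counts proteins whose best known-partner rank is ≤ (X/100)·N
(ties in NII broken by mid-rank for AUC and by protein-id order for top-k
lists); its baseline counts proteins whose expected number of partners in a
random X% subset is ≥ 1, implemented exactly in that indicator form.
Homology transfer marks a protein pair positive when any cluster-mates of
their chains form a complex with an interface strictly larger than 5
residues; unassigned chains become logged singletons.

## Synthetic benchmark: what it emulates and what it does not

The fixture generator builds quasi-spherical pseudo-residue shells (Gly
body) with one face flattened into a disc of charged residues in concentric
rings. Cognate recognition is geometric: the receptor of pair k carries a
raised boss ring at a pair-specific radius and its partner the matching
groove, so only cognate faces conform and reach the steep Lennard-Jones
contact minimum across the whole patch, while mismatched faces stand off by
the boss height (2.5 Å) and lose most of the contact energy; uniform
opposite face charges (|q| = 5) add an electrostatic signature and disfavour
same-role encounters. Ring symmetry makes recognition invariant to the spin
about the face normal, which is the rotation the pose generator samples
densely. The benchmark docks with the free protocol because the
surface-restrained COM-line constraint cannot laterally centre two faces
from a coarse start grid.

Designed-in, generation-time-verified properties: the bound pose scores
below the 5th percentile of random contact poses; the 5 Å interface of the
bound pose recovers ≥ 80% of the designed patch; on the idealized 8-protein
set with ground-truth reference interfaces, every cognate partner is ranked
first (AUC = 1.0).

What passing these tests shows: the pipeline's filters, minimization,
normalization and evaluation are internally consistent and recover a
designed signal through the full code path. What it does not show: anything
about real proteins — the toys have no backbone, no conformational change,
no realistic surface chemistry or interface sizes, and their recognition
signal is far cleaner than physical shape/electrostatic complementarity.
Planted (docking-free) stores complement the geometric toys for
millisecond-scale unit tests: they control FIR/energy/PP per conformation
directly, carry a cognate energy advantage of 5 units, and with Gaussian
energy noise σ ∈ [0, 16] show the expected monotone AUC degradation.

## Known limitations

* The coordinate-descent minimizer finds local minima only; discrimination
  on rugged landscapes depends on start-pose density.
* The patch predictor's thresholds are fixed percentiles, not learned; on
  real proteins the blind-mode union over-predicts when several surface
  regions carry signal.
* The decoy generator requires enough non-interface surface; deep shift
  levels error out on proteins whose interface dominates their surface.
* The normalization's mixed-sign behaviour (positive II entries) is defined
  by the magnitude-with-sign convention, not by theory; a raw mode exists
  for sensitivity checks.
* PISA-style thermodynamic scoring is supported only as an external
  per-conformation score column.
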