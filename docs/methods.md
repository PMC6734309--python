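# Methods

## Problem setting

Chemical cross-linking mass spectrometry (XL-MS) identifies pairs of
residues — for lysine-reactive reagents such as DSS or BS3, lysine pairs —
close enough to be bridged by the linker, conventionally expressed as a
Cα–Cα distance of at most 33 Å. In a homo-oligomer the subunits are
sequence-identical, so peptide evidence alone cannot say whether an
identified pair (r_i, r_j) bridges residues within one subunit
(*intra*-subunit) or across two (*inter*-subunit). This package implements
the machinery needed to study that ambiguity and to use ambiguous
restraints well when rescoring rigid-body docking models of C2-symmetric
homo-dimers.

## Inter-residue distances

**EUC** is the straight-line Cα–Cα distance, ignoring the protein volume.

**SASD** (solvent-accessible-surface distance) is the shortest path
between two Cα atoms that stays in solvent. The structure is rasterized
onto a cubic grid (default spacing 1.0 Å); a voxel is protein-occupied
when its center lies within atom radius + probe radius (1.7 + 1.4 Å) of
any heavy atom; hydrogens are ignored. A residue is solvent-accessible
when some solvent voxel center lies within the access radius (4.0 Å) of
its Cα; the nearest such voxel (ties broken by lexicographic voxel index)
anchors the residue on the solvent lattice. The reported distance is

    |Cα_a − anchor_a| + shortest solvent path(anchor_a, anchor_b) + |anchor_b − Cα_b|

Shortest paths are computed on the 26-connected voxel graph with
Euclidean edge weights, solved with Dijkstra's algorithm
(`scipy.sparse.csgraph`). A literal breadth-first search on the
6-connected lattice measures Manhattan rather than Euclidean path length
and systematically overestimates diagonal paths; it is retained behind
`connectivity="6"` for comparison, but the Euclidean-weighted search is
the default for geometric fidelity. Because the solvent path between the
anchors is at least the straight line between them, SASD ≥ EUC holds by
construction (up to nothing — exactly), comfortably satisfying the
discretization bound SASD ≥ EUC − 2·spacing·√3 used in tests.

The grid defaults (spacing 1.0 Å, probe 1.4 Å, uniform heavy-atom radius
1.7 Å, access radius 4.0 Å) are declared package defaults; they are not
claimed to be voxel-for-voxel equivalent to any particular third-party
SASD implementation, whose internal connectivity and anchoring rules are
not published. All are keyword-configurable.

Buried endpoints, and anchor pairs in disconnected solvent components,
yield the non-accessible marker (`math.inf`), which by design never
satisfies a `<= threshold` comparison.

### Exact search truncation

During model scoring, every distance beyond the linker threshold scores
identically (the penalty branch), and the symmetry-difference gate only
ever compares distances within 5 Å of a matched one. Dijkstra sweeps are
therefore truncated at threshold + 5 + 1 Å, and sweeps are run only from
first-chain lysines (every non-redundant candidate has a first-chain
endpoint). Both are exact optimizations at the scoring threshold, not
approximations.

## Ambiguity enumeration and classification

For a homo-oligomer with identical lysine content per chain (guaranteed
by reference recreation, below), every unordered residue-number pair
{r_i, r_j} with at least one endpoint in the first chain yields one
candidate; self pairs (r_i = r_j) are included as inter-only candidates
with the intra alternative undefined — a residue cannot cross-link to
itself within a subunit — and an undefined intra is treated as
non-accessible. The intra alternative is computed within the first chain;
inter alternatives cover all chain combinations, reduced to the shortest,
with both oriented readings (A→B and B→A) retained for dimers because the
scoring functions need them.

Classification at threshold T (default 33 Å, inclusive comparison):
*Intra* or *Inter* when exactly one alternative is ≤ T, *Ambiguous* when
both are, *Non-accessible* when neither. The cross-method comparison
filter (pairs with a matched straight-line alternative and both
alternatives calculable) is an explicit flag on
`assignment_statistics(matched_filter=...)`, never applied silently.

## The MNXL scoring family

The base score of one distance d is the Gaussian density
N(d; μ=18.62 Å, σ²=35.94 Å²) when d ≤ 33 Å with accessible endpoints
("matched"), and a flat penalty of −0.1 otherwise ("non-accessible").
35.94 is a variance (σ ≈ 5.995 Å), matching its description, and the
unnormalized density itself is the matched score. The matched boundary is
inclusive: d = 33.0 scores the density (≈ 0.00375), d = 33 + ε the
penalty. A model's total is the sum of its inter-subunit cross-link
contributions; models are ranked by descending total with ties broken by
model id.

Each cross-link contributes through four axes evaluated in a fixed order:

1. **inclusion** — gates whether the inter readings are considered at
   all. `ALL`: always. `ONLY_BEST`: only when the better inter score is
   at least the intra score. `NON_INTRA`: only when the intra alternative
   is non-accessible.
2. **symmetry** — gates on the oriented pair. `SYMMETRY_MATCHED`: both
   readings matched. `SYMMETRY_DIFFERENCE`: at least one matched and
   |d_AB − d_BA| < 5 Å (undefined when a reading is non-accessible, which
   excludes).
3. **ambiguity** — per-reading substitution. `OBLIVIOUS`: raw scores.
   `NORMAL`: a penalized inter reading whose intra alternative is matched
   scores the neutral 0.0 instead.
4. **orientation** — aggregation. `ORIENTED`: sum of both readings;
   `STRINGENT`: the higher reading only.

Gated-out cross-links contribute exactly 0.0, so variants differ only
through their stated rules. Two boundary choices were genuinely open and
are fixed as follows:

* **ONLY_BEST ties.** The inclusion comparison is ≥, not strictly >. A
  tie can only occur between identical penalty constants (both inter
  readings and the intra alternative at −0.1); keeping ties preserves the
  nesting property NON_INTRA ⊆ ONLY_BEST ⊆ ALL of the gated-in sets,
  which a strict comparison would break exactly at that degenerate edge.
* **STRINGENT under NORMAL.** The neutral substitution happens per
  reading *before* the max, so a penalized reading with a matched intra
  competes as 0.0, not −0.1. Both behaviors are covered by the exhaustive
  rule oracle in the tests, making the choice explicit.

Intra and inter distances are recomputed on every model (not copied from
the reference): under SASD, burial and path lengths of the intra
alternative depend on where the second subunit sits, so the reference
values are not generally valid in a decoy.

## Reference recreation, decoys, and the synthetic benchmark

**Recreation.** The reference dimer's second chain is replaced by a copy
of the first chain rigidly superposed (Kabsch, common Cα atoms matched by
residue number + insertion code) onto it, so reference and models share
identical chain composition. Superposition uses Cα atoms; chains whose
shared Cα set is smaller than 3 are rejected rather than sequence-aligned.

**Model quality.** Cα-RMSD superposes the whole complex and takes the
minimum over the two chain mappings (the identical chains make labels
arbitrary). A model is near-native at RMSD ≤ 10 Å; precision is the
percentage of near-natives among the top-10 ranked models (denominator
min(10, n) for small ensembles).

**Toy dimers.** The generator builds an idealized α-helical Cα trace
(rise 1.5 Å, turn 100°, radius 2.3 Å) with radial pseudo-side-chain
atoms, centered with its axis parallel to z at x = +offset/2, and forms
chain B by the exact C2 operation (x, y, z) → (−x, −y, z). Defaults:
32 residues, 6 lysines roughly evenly spaced with seeded jitter,
interface offset 12 Å. One mid-chain lysine is enclosed in an icosahedral
cage of 12 pseudo-atoms at 3.5 Å, which provably blocks every solvent
voxel within the 4 Å access radius — guaranteeing one buried lysine. At
these defaults the simulated cross-link set mixes true-inter pairs
(including self pairs), ambiguous pairs, and intra-only pairs, which is
the regime where ambiguity handling matters; with substantially shorter
chains the set degenerates to inter-only pairs and all reasonable scoring
variants coincide.

What the toys do **not** emulate: side-chain packing and realistic
surface texture, sequence variety, flexible loops, and experimentally
realistic false-positive cross-links. Passing benchmark orderings on toys
therefore demonstrates internal consistency of the scoring rules under
controlled conditions, not field performance on crystal structures.

**Decoys.** Chain 1 is fixed; each model applies a rigid transform to
chain 2. The ensemble emulates what docking programs for symmetric
complexes actually return — surface-contact poses, symmetric ones from
symmetry-aware sampling and arbitrary ones from unconstrained sampling —
in three pools:

* *near-native* (the requested share, guaranteed rather than sampled, so
  ranking experiments have a known precision ceiling): the reference
  two-fold axis conjugated by a small rigid motion (rotation ≤ 15°,
  translation ≤ 5 Å), which yields an exactly C2-symmetric model;
  accepted only below 10 Å complex Cα-RMSD;
* *symmetric decoys* (half the remainder): a 180° rotation about a random
  axis slid until the subunits touch — an exactly symmetric but wrong
  interface;
* *random decoys* (the other half): a uniformly random rotation of chain
  2 slid into contact along a random direction.

Contact means a minimum inter-chain Cα–Cα distance between 3 and 6 Å;
clashes (< 2 Å) and wrong-pool models inside the 10 Å cutoff are
rejected. Keeping near-natives exactly symmetric matters: per-cross-link
symmetry gates compare the two oriented readings, and asymmetric
"near-natives" would lose restraints under those gates for reasons a
symmetry-constrained docking pool cannot produce. Keeping wrong decoys in
contact matters for the distance-method comparison: only contacting wrong
interfaces give straight-line distances that match through
protein-occupied space, which is precisely the failure mode surface
distances exist to avoid. Structures yielding no simulated cross-links or
fewer than ten near-native decoys are excluded from benchmarks.

**Coverage subsets** sample without replacement: coverage means distinct
cross-links observed, so with-replacement duplicates would be
meaningless. Replicate subsets of round(fraction × n) pairs are drawn
with a seeded generator.

## Problem sizes and determinism

The standard synthetic benchmark uses 10 toy dimers × 200 decoys with a
10% near-native share — large enough for stable mean-precision orderings
across scoring variants, small enough to run on a single CPU in minutes.
Every stochastic step (lysine jitter, decoy placement, coverage
subsetting, benchmark structure seeds) flows from an explicit integer
seed through `numpy.random.default_rng`; per-structure seeds are drawn
once from the top-level generator, making whole-benchmark reruns
bit-identical.

## Known limitations

* SASD values depend on grid spacing and the declared radii; they are
  internally consistent but not calibrated against any external SASD
  implementation.
* The intra alternative is computed within the first chain only; for
  heteromeric complexes or homo-oligomers with diverged subunit
  conformations the enumeration rejects the input rather than guessing.
* Scoring assumes dimers wherever oriented readings are used; higher
  oligomers are supported for enumeration/classification (shortest-inter
  reduction) but not for the oriented/symmetry scoring axes.
* The benchmark's precision ceiling is set by the guaranteed near-native
  share; saturated (100%) precisions under easy conditions are expected
  and reported as such.
* The toys' simulated inter-subunit cross-links concentrate a few
  ångströms under the 33 Å threshold (a compact helix pair offers little
  slack), unlike experimental cross-links, which cluster near the 18.6 Å
  mean of the matched-distance model. Threshold-adjacent restraints make
  surface distances cliff-sensitive: a 2–4 Å perturbation can seal a
  narrow interface channel (any gap under the probe-excluded width) and
  flip a reading from matched to penalized on a good model. On such
  structures straight-line scoring can outrank surface-distance scoring,
  and the per-cross-link symmetry gates — which drop a restraint whenever
  one oriented reading flips — amplify the effect. Benchmark comparisons
  involving the distance method or the symmetry gates should therefore be
  read per structure, not only as means over a small toy set.
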