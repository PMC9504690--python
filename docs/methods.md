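# Methods

## The model

A pharmacophore is a set of typed spherical features — aromatic (AR),
hydrophobic (H), H-bond acceptor/donor (HBA/HBD), positive/negative
ionizable (PI/NI) — each with a center (Å) and a tolerance radius.
Exclusion volumes (XV) mark forbidden space and never act as probes or
regression inputs. Activities are modelled on the pIC50/pKi scale
(−log₁₀ molar); root-mean-square errors below ~0.7 log units are what
curated experimental sets typically support.

**Model pharmacophore.** Ligands are ordered by activity; the most
active ligand's most feature-rich conformer is the initial alignment
reference. Every other ligand's best-aligned conformer (highest mapped
count, then lowest RMSD, then lowest conformer index) is transformed
into that frame and its features merged by greedy centroid clustering:
a feature joins the nearest same-type cluster within `merge_radius`
(default 1.5 Å, the H-type tolerance), else it seeds a new one; merged
positions are activity-unweighted centroids. Two refinements proved
necessary in practice and are part of the documented algorithm:

1. *Consolidation.* Greedy seeding can split one underlying site into
   two clusters when its first two members land on opposite sides;
   after the pass, closest same-type centroid pairs within
   `merge_radius` are merged until stable (deterministic: always the
   closest pair first).
2. *Second pass anchored on the merged model.* A single reference
   conformer carries only its own feature subset, so ligands sharing
   few features with it align poorly. The clusters from pass 1 form a
   pharmacophore spanning every recovered site; all ligands are
   re-aligned to it and the clustering repeated with the pass-1
   centroids as seeds. Activity lists and model-feature positions come
   from this second pass. On planted benchmarks this raises held-out
   R² from ≈0.43 to ≈0.53 and dual-method contribution concordance
   from 0.80 to 0.96.

A *relevance filter* keeps only clusters supported by at least
`ceil(min_support_fraction · n_ligands)` contributions (default
fraction 0.1): a feature seen in one ligand is noise, not consensus —
the activity list is what decides whether a feature is information.

**Featurization.** A sample's conformers are each aligned to the model
pharmacophore; the best one is greedily mapped (same type, distance ≤
the model feature's tolerance, ties by ascending distance then moving
index, injective both ways). Entry *i* of the distance vector is the
mapped Euclidean distance, or `fill_distance` = 100 Å when unmatched.
The fill must dwarf any real distance so that "larger distance" in a
tree split consistently reads as "feature farther away or absent".

**Regression.** A random forest (default 100 trees, unlimited depth,
bootstrap, mandatory seed) regresses activity on distance vectors.
Node arrays (split feature, threshold, children, node value) are
extracted after fitting; all predictions run through our own traversal
(inputs cast to float32 first, matching the library's internal cast,
with ≤-goes-left semantics), which makes serialized model bundles
(`model_features.json`, `forest.json`, `config.json`) reproduce
predictions bit-identically and exposes the node structure to the
contribution extractor.

## Rigid alignment

Alignment of two pharmacophores is a correspondence search: every
type-compatible feature-triplet pair whose three pairwise distances
agree within the summed tolerances seeds a Kabsch superposition (with
pair seeds — minimal segment rotation — or bare translations when
fewer than three common-type features exist; the identity is always a
candidate). Seeds are ranked by correspondence RMSD and the best 64
are greedily mapped; the 8 most promising preliminary mappings get a
rigid re-fit on their mapped pairs and one re-map. The score is
(mapped count, −RMSD) lexicographically; all tie-breaks are by index,
so the result is deterministic and invariant (in score) under rigid
motion of the moving pharmacophore. The bounded evaluation is a
deliberate trade: a perfectly superposable pose always produces a
zero-RMSD seed that ranks first, while the bound keeps
thousand-compound library screens at ~1–2 s.

Query matching requires *every* non-XV query feature to map (the
match criterion is not prescribed anywhere authoritative; all-features
is the strict choice and is documented) and no target feature center
strictly inside any query XV sphere. A per-type feature-count
prefilter rejects most non-matching ligands before any alignment.

## Contributions and refinement

*Activity-list method:* raw value = mean of the feature's activity
list. *Tree method:* for every internal node splitting on feature
*f*, record value(left) − value(right); raw value = the plain mean
over all such nodes in all trees (features never split on get 0). The
wording of the underlying aggregation is ambiguous in the original
description; the child-difference mean is the single-pass
deterministic reading and reproduces the one-stump case exactly. Both
raw vectors are z-scored (population SD; all-equal input gives all
zeros) — "compared against each other and scaled by variance" — and
the sign of the scaled value is the contribution direction.

`build_refined` ranks by scaled contribution, multiplied by the
(non-negative) forest importance when `weight_by_importance` — the
weighting applies to both the ranking key and the emitted feature
weights (normalized importances), so the choice is auditable in the
output. The top `num_features` (x, recommended 4–8) non-negative-key
features are emitted; fewer with a warning if the model does not
support x of them, and an error if it supports none. With
`set_exclusion_volumes`, negative features become XV spheres (radius
1.5 Å) ordered most-negative first.

The shared-pharmacophore baseline mirrors classical practice: the *n*
most active ligands are aligned onto the most active one and only
reference features present in all of them survive. The hyperparameter
search enumerates the full 2×2×2×5 = 40 refined configurations, ranks
by train F_β + F_Specificity (ties by enumeration order), and scores
exactly the top 5 on the test set; the baseline's n sweeps
2..min(8, #actives) in a separate table.

## Screening metrics

Actives are the top 20th activity percentile (exactly ⌈0.2·n⌉, ties at
the cut broken by ligand id so the count is exact). F_β uses β = 0.5
throughout. F_Specificity is implemented *as defined for this
workflow* — precision·specificity/(precision+specificity), **without**
the factor 2 of a harmonic mean — so its maximum is 0.5 and
F_Composite's maximum 0.75; a conventional harmonic variant exists
under a separate name but never enters the pipeline. Degenerate
denominators (no predicted positives, no actives) score 0 with a
logged warning, since an empty hit list is a legitimate screening
outcome. Hit lists are ranked by predicted activity, highest first,
ties by ligand id.

## Activity grids

The sample is aligned to the model once; the lattice covers its
bounding box plus a margin (dims = ⌈(extent + 2·margin)/spacing⌉ + 1
per axis; defaults 0.5 Å spacing, 3 Å margin; x varies fastest). At
each point a probe feature of the requested type (default tolerance,
weight 1) is appended to the aligned conformer — the alignment is
*not* recomputed, so the probe's effect is never conflated with a pose
change — and the full greedy mapping re-run; the value is the
prediction minus the unperturbed baseline. Points outside every
same-type model feature's tolerance cannot change the mapping and are
assigned exactly 0 without prediction. Raw grids split into positive
and negative magnitude fields (positive − negative = raw pointwise);
normalisation divides each field by its own maximum, all-zero fields
unchanged. `.kont` files are plain text — fixed-width coordinate
records (`%8d%8.3f%8.3f%8.3f`), one title line, then one `%10.4f`
value per line in point order — and round-trip within 1e-4; the
format has no public normative specification, so the dialect is
defined by the reader/writer pair here.

## Synthetic benchmark systems

`gen_reference_system` plants m = 8 typed sites uniformly in a 12 Å
box, rejection-sampled to pairwise separations > 3.6 Å (twice the
largest tolerance) so clustering is unambiguous; 4 sites are
beneficial (effect +0.8 to +1.5 logs), 2 detrimental (−0.5 to −1.2),
the rest inert, redrawn until the achievable range is ≥ 3 log units.
Ligands are random site subsets (inclusion probability 0.5, minimum 2
sites), feature centers jittered within 0.5× tolerance, with 1–3
conformers (rigid-motion copies with 0.15× extra jitter); activity =
base (5.0) + Σ included effects + N(0, σ), σ = 0.3 logs by default —
comparable to the error level a well-behaved experimental QSAR set
exhibits. The first ligand always carries the full beneficial core so
the model frame anchors there. Libraries contain actives-by-
construction (all beneficial, no detrimental sites) and decoys that
break the core, with containment flags exported for evaluation only.

Because activity is exactly linear in site indicators at σ = 0,
contribution signs, recovery rates and grid deltas have closed-form
ground truth. What the generator does **not** emulate: conformational
energetics, chemically correlated feature co-occurrence, assay
heterogeneity, activity cliffs, and feature-type frequencies of real
chemotypes — passing recovery rates here bound what curated
experimental data would give from above, they do not guarantee it.

## Problem sizes and numerical choices

Benchmarks and the acceptance script use 20 seeded systems, 30
training / 15 test ligands, 1000-compound libraries (100 true, 900
decoys) and 1 Å grid spacing on reduced lattices — sizes at which a
full run takes about a minute on one CPU while every rate is estimated
from ≥ 20 independent systems. All randomness flows from explicit
seeds (`numpy.random.default_rng`); a fitted model refuses to train
without one. Tolerances: alignment recovery asserts RMSD < 1e-6 Å,
featurization invariance 1e-6 Å, prediction invariance 1e-9,
serialization is bit-exact, `.kont` round-trips at 1e-4 (the value
format's printed precision).

## Known limitations

- Features are positions and radii only; directed features (projected
  points for donors/acceptors, ring normals for AR) are out of scope,
  so geometries distinguished only by direction are conflated.
- The alignment search is bounded (64 seed evaluations); adversarial
  inputs with many near-equivalent correspondences could in principle
  hide a marginally better pose, though the score invariants hold.
- Pharmacophore perception from structures (SMILES/SDF) and conformer
  generation are not provided; inputs are pre-computed feature sets.
- The shared-feature baseline is this package's own deterministic
  re-implementation of the classical idea, not a reproduction of any
  proprietary tool's algorithm.
- Model quality on the planted benchmark (held-out R² ≈ 0.5 at
  σ = 0.3) is limited by featurization noise from jittered, partially
  overlapping ligands — the same failure mode real datasets show when
  ligand alignment is ambiguous.
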