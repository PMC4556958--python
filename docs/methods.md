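# Methods

## Model

A pharmacophore hypothesis is a set of k typed sites (k ∈ {3, 4}) drawn from
the vocabulary {A, D, H, N, P, R} together with a symmetric k×k inter-site
distance matrix (Å) and a scalar per-pair tolerance. The distance matrix
fully determines the geometry up to chirality for k ≤ 4; matching is
distance-based, so mirror images are deliberately not distinguished. A
combinatorial pharmacophore (CP) model is an unordered set of hypotheses;
classification is the union rule (active iff any member matches), which
models an activity class produced by several distinct binding modes.

Matching a conformer against a hypothesis asks for an injective assignment
of feature points to sites with site-by-site type agreement and every
|d_ij(features) − d_ij(hypothesis)| ≤ tol. The search is a backtracking
enumeration with per-pair pruning, exact for k ≤ 4; among valid assignments
the one minimising the RMS of the k(k−1)/2 pairwise-distance deviations is
returned, ties broken by the lexicographically smallest feature-index tuple.
Because only inter-point distances enter, matching is invariant under rigid
motion by construction, and matching at tolerance t implies matching at any
t′ > t. A molecule matches if any conformer of its ensemble matches
(OR semantics), consistent with per-compound match counting over
conformer ensembles.

## Feature perception

Perception is driven by a versioned SMARTS table
(`src/combipharm/data/feature_definitions.yaml`), shipped as the single,
auditable source of truth and replaceable by the user. Conventions:

- **Ionisation at pH 7.4 is rule-based**, not a pKa calculation: carboxylic,
  sulfonic and phosphonic acids are treated as deprotonated (N sites);
  aliphatic amines, amidines and guanidines as protonated (P sites). The
  same rules drive formal-charge standardisation before conformer
  embedding.
- **Overlap policy** (no double counting): an aromatic ring yields R only —
  H patterns exclude aromatic atoms; a protonated amine yields P only —
  amines are absent from the A and D tables; charged acid groups yield N
  only. A neutral hydroxyl is both A and D, which is chemically standard.
- **Hydrophobes are clustered**: bond-connected aliphatic carbons (with only
  C/H/halogen neighbours) and carbon-bound halogens merge into one H site
  per fragment at the arithmetic centroid, so a hexyl chain is one
  hydrophobe, not six.

Feature points sit at the arithmetic centroid of their matched atoms and are
sorted by (type, atom indices), making perception deterministic and
rigid-motion equivariant.

## Conformer ensembles

ETKDG embedding (single-threaded, fixed seed → bit-stable), optional MMFF94
minimisation, heavy-atom RMSD pruning at 0.5 Å and an energy window of 10
force-field units above the minimum, with a configurable cap on ensemble
size (default 1000). The energy window and pruning threshold are package
defaults chosen to mimic "low-energy ensemble" behaviour of standard
preparation tools; only the ensemble cap is treated as externally fixed.
Input chirality is preserved; tautomers beyond the ionisation rules are not
enumerated.

## Hypothesis generation

Every k-subset of the feature points on every conformer of every calibration
active is reduced to a canonical signature: site letters sorted
alphabetically, and among letter-preserving orderings the lexicographically
smallest upper-triangle distance vector. Signatures with coincident features
(zero distances) are discarded. Within each letter multiset the generator
performs mode seeking under the Chebyshev metric on distance vectors: a
candidate center is supported by every active owning a tuple whose distances
all agree with the center's within `bin_width` (default 1.0 Å); centers
reaching the `min_actives` quota (default ⌈n_actives/2⌉) are emitted
greedily in order of support (ties: smallest summed distance to supporters,
then lexicographic), retiring tuples within `bin_width` of an emitted center
so duplicate geometries merge onto one medoid-like representative.

Mode seeking was chosen over agglomerative clustering after the latter
proved fragile: with positional noise σ the planted tuples scatter up to
~3σ√2 around the true geometry, and decoy tuples landing nearby cause
complete-linkage merges that split the planted cluster. Counting support
within a ball around each observed tuple is robust to such contamination,
deterministic, and invariant to the order of the actives.

Scores: survival = matched-active fraction; survival-inactive =
survival − λ·(matched-inactive fraction) with λ default 1.0; selectivity =
−log₁₀((n_matched + 1)/(N + 1)) over the pooled active+inactive reference
set (add-one pseudocount so that a hypothesis matching nobody in a reference
of 99 scores exactly 2.0). The commercial scores these stand in for blend
undisclosed alignment and volume terms; the definitions here are simple,
auditable and preserve the intended ranking. Filtering is two-stage:
thresholds on survival-inactive and selectivity, then the `top_k`
hypotheses with fewest inactive matches (ties: higher survival-inactive,
then id).

## Model selection

All 3- and 4-member subsets of the pool are enumerated exactly once
(Σ C(n,s); 20,475 for n = 27) in deterministic lexicographic order. Each
candidate is scored on the calibration set via the union rule; SE, SP, ACC
and BACC are stored at full precision and rounded to two decimals only in
report tables. The highest-BACC candidate is selected, with ties broken by
higher SE (recovering true inhibitors is the priority in this setting),
then fewer members, then lexicographic member ids — a total order, so
selection is invariant to candidate ordering. Selection uses calibration
data only; test metrics are reported separately. When the retained pool is
smaller than every requested size, `fit()` falls back (with a warning) to
the largest feasible member count rather than failing: a planted benchmark
with exactly two true pharmacophores legitimately yields a 2-hypothesis
pool, and single hypotheses are likewise evaluable as degenerate 1-member
models for comparison tables.

## Synthetic benchmark

`make_planted_library` emulates a labeled screen at the feature level: each
active carries one planted hypothesis geometry — the distance matrix is
embedded in 3D by classical multidimensional scaling, randomly rotated and
translated, and each site jittered by isotropic Gaussian noise (default
σ = 0.2 Å, giving pairwise-distance noise ≈ 0.28 Å, comfortably inside the
1.0 Å tolerance) — plus uniformly placed random-type decoy features
(default 5). Inactives contain only decoys and are rejection-sampled so none
matches any plant at the library tolerance. The default library is 20
actives / 200 inactives with two planted 3-site hypotheses (H–H–R at
3/4/5 Å, D–R–R at 6/7.5/5 Å) assigned round-robin, mirroring the ~1:10
active:inactive skew of transporter-inhibition screens at a size where the
full pipeline runs in well under a second. Synthetic molecular weights are
drawn uniformly from 200–700 Da per molecule for the report analyses.

What the benchmark does *not* emulate: real chemistry-space feature
densities and correlations (decoys are uniform and independent), conformer
flexibility (feature-cloud records have a single pseudo-conformer), and the
molecular-weight skew of real inhibitor sets. Passing the planted-recovery
tests therefore demonstrates correctness of the matching/selection
machinery under controlled geometry, not predictive performance on real
screens; the bundled 20-molecule SMILES library (with illustrative, not
literature, labels) exercises the chemistry path end to end.

## Numerical choices and degenerate inputs

- Distance signatures are rounded to 1e-6 Å for canonical ordering only;
  geometry is stored at full precision.
- Hypothesis validation enforces symmetry, zero diagonal, positive
  off-diagonal distances and the triangle inequality (tolerance 1e-9 Å).
- Zero-atom structures perceive to an empty feature list; embedding
  failures flag the record and leave an empty ensemble rather than raising.
- Records without perceived features are excluded from generation and are
  non-matches in the matcher, each with a warning.
- Stratified splits sort molecule ids before seeded shuffling, so the split
  depends only on (ids, labels, seed).

## Known limitations

- No excluded-volume or directional (vector) site constraints; matching is
  purely distance-based.
- Full-site matching only; partial (k−1 of k) matches are not scored.
- The SMARTS table is a compact, documented stand-in for richer perception
  chemistry; users with bespoke conventions should supply their own YAML.
- Selection cost grows as C(n,3)+C(n,4) in the pool size n; pools much
  beyond ~40 warrant pre-filtering via the score thresholds.
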