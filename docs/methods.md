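# Methods

This note records the models, parameter choices and numerical conventions
behind `helixmr`, and what the synthetic test bed does and does not show
about real data.

## Ideal helices

Helices are grown residue-by-residue from internal coordinates
(natural-extension reference frames). Only the backbone dihedrals are free
parameters — φ = −57.8°, ψ = −47.0°, ω = 180° by default — while bond
geometry is fixed at standard values: N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, C=O 1.231 Å, CA–CB 1.521 Å; angles N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°, CA–C–O 120.8°, N–CA–CB 110.5°. Torsions follow the IUPAC
sign convention (a right-handed α-helix measures φ ≈ −57°); the CB improper
N–C–CA–CB is +122.6°, giving L-residue chirality (cross-checked against an
idealised alanine template, +120.0°). The first residue sits in a canonical
frame at the origin: absolute placement is irrelevant to MR but must be
deterministic. Carbonyl oxygens are placed anti to the next amide nitrogen;
no OXT or hydrogens are emitted. The library spans lengths
5, 10, 15, 20, 25, 30, 35, 40. Measured interior dihedrals reproduce the
inputs to well below 0.1°, and the rise per residue along the fitted axis
is 1.54 Å.

`build_bent_helix` makes two-segment test constructions by rotating the
downstream half of a straight helix about a point on the fitted axis, about
a perpendicular axis, so the inter-segment axis angle is exactly the
requested bend.

## Synthetic decoy sets

The generator emulates what *ab initio* predictors hand the ensemble
machinery: same-sequence models forming one dominant structural cluster
plus wrong-topology outliers, with positional scatter growing toward loops
and termini.

* Ground truth: an up-down bundle of `n_helices` ideal helices (default 4 ×
  20 residues) on a circle of radius 10 Å with alternating axial direction,
  joined by loop residues (default 4) laid on a circular arc bowed outward
  from the bundle axis so consecutive CA–CA distances stay peptide-like
  (observed 3.55–3.80 Å).
* Core decoys (default 80): per-helix rigid-body jitter (rotation s.d.
  2° × σ, translation s.d. 0.3σ) plus i.i.d. isotropic Gaussian atom noise
  of s.d. σ = `core_noise` (default 0.5 Å), inflated by
  `terminal_noise_multiplier` (default 4) in loop residues and the four
  residues at either chain end. The jitter-plus-noise model produces the
  per-residue variance gradient that truncation exploits.
* Outliers (default 20): the truth with helices moved to a random
  derangement of the circle slots, plus `outlier_noise` (default 5 Å)
  Gaussian noise — realistic wrong-topology decoys guaranteed far outside
  any subcluster radius. With `outlier_noise = 0` no perturbation is
  requested and outliers degenerate to exact copies of the truth.

Everything is driven by one `numpy` generator seeded from the spec, so sets
are bit-reproducible. What this test bed does *not* emulate: physically
realistic force-field sampling, side-chain rotamers (decoys are
polyalanine + CB), sequence-dependent loop geometry, and decoy populations
with several competing near-native clusters. Passing tests therefore
demonstrate the correctness of the clustering/truncation machinery under a
controlled noise model, not MR success rates on real targets.

## Clustering

Decoys are clustered on the pairwise all-CA RMSD matrix (Kabsch
superposition) by greedy neighbour counting: repeatedly extract the model
with most neighbours within the cutoff, plus those neighbours. The cutoff
is auto-adjusted by bisection in [0.5, 12] Å so the largest cluster holds
between 10% and 90% of the decoys where such a cutoff exists; otherwise the
probed cutoff nearest that band is used. The upper bound is deliberately
permissive: a dominant, well-converged cluster containing 80% of the decoys
is a real signal and must not be split by the cutoff search. All ties break
toward the lower model index, so clustering is invariant to input order.
The top cluster is capped at 200 members by proximity to the centroid. No
bit-compatibility with any external clustering program is claimed.

## Truncation ensembles

Per-residue variance is the mean squared CA deviation from the
across-member mean position after superposing every member on the centroid
over all shared CAs — the simple moment estimator, chosen over
maximum-likelihood variance models for transparency and testability.
Level *k* of 20 keeps the ⌈kN/20⌉ lowest-variance residues ("evenly spaced"
is read in retained residue count, ~5% steps); ties keep the lower residue
number, so levels nest by construction. Truncated models keep original
numbering as possibly discontiguous fragments — register must survive for
the RIO comparison. Subclustering under radii 1/2/3 Å seeds on the
best-connected member (not the centroid) and caps at 30 models by proximity,
which bounds the subcluster diameter by twice the radius exactly. Within a
truncation level, a radius whose member set duplicates an already-emitted
one is dropped; side-chain modes then multiply the survivors. The
"reliable" side-chain set (kept side chains: ALA, GLY, CYS, PRO, SER, THR,
VAL — residues with at most 3 χ1 rotamers) is configurable.

On the default synthetic set, mean ensemble-to-truth CA RMSD falls from
1.71 Å at full length to 0.76 Å at the deepest tested level — variance
truncation discards the worst-modelled residues first.

## Scoring

* Kabsch: SVD form with the reflection branch removed; collinear point sets
  raise a degeneracy error (the rotation is not unique). The TM search uses
  an internal lenient variant because a seed fragment of a straight
  reference is legitimately collinear and the TM sum is still well defined
  there.
* TM-score: residue correspondence is fixed by numbering (same-sequence
  comparison; no structural alignment search). The maximisation seeds from
  contiguous fragments and iterates superposition/selection with the
  standard d0_search = clamp(d0, 4.5, 8.0) inclusion cutoff. Chains of
  ≤ 40 residues use exhaustive fragment seeding (every start, every length
  ≥ 4); longer chains use the canonical halving schedule L, L/2, …, 4.
  d0 is floored at 0.5 Å, which guards the negative cube-root region for
  L ≤ 21.
* RIO: match distance 1.5 Å between CAs (configurable); runs must be ≥ 3
  residues with crystal numbering stepping uniformly +1 or −1; symmetry
  mates are supplied as explicit extra models rather than generated from
  space-group operators, keeping crystallographic symmetry out of scope.
* Success classification: CC ≥ 25.00, ACL strictly > 10.00, rebuilt
  R_free ≤ 0.45, with exactly those boundary semantics.

## Helix geometry

Local axes come from the Sugeta–Miyazawa construction on 4-CA windows
(wider windows average the construction). Bending angles in the report are
taken between axes separated by `window` steps so the two windows share no
atoms: consecutive overlapping windows smear a discrete kink across several
residues and under-report its magnitude by roughly half, whereas the
separated form recovers constructed two-segment angles essentially exactly
(within 0.1° over 5–90°). Classification: any angle ≥ 60° → irregular
(a break, not a kink); any angle in (20°, 60°) → kinked; otherwise curved
when the largest angle exceeds 3° or the net first-to-last axis turning
exceeds 20°; else straight. The 3° threshold separates genuine low-angle
bends from the < 0.1° wobble of an ideal helix and is configurable.

## Contacts

Accepted predictions require res_i < res_j and sequence separation ≥ 5
(configurable); duplicates collapse to the maximum confidence. Top-L ties
break lexicographically. Restraints are Rosetta `AtomPair` lines with the
FADE functional form between Cβ atoms (Cα for glycine). FADE parameters
(lower −10, upper 19, fade zone 10, well depth −15.00) are a documented,
overridable default block imported from common contact-assisted-folding
practice, not values this package derives. Precision counts a pair true at
distance ≤ cutoff (8 Å default; the boundary is inclusive), with pairs
referencing missing residues counted false and logged. Interface contacts
test both (i in A, j in B) and (j in A, i in B) directions.

## Problem sizes and determinism

The reference study condition for tests is the default synthetic set
(100 decoys, 92 residues); the full factorial sweep on it emits 132
ensembles in well under a minute. TM-score oracle comparisons use
30-residue chains where exhaustive seeding is exact. All randomness flows
through seeded `numpy` generators; the acceptance script derives every
auxiliary seed from its `--seed` argument.

## Known limitations

* The clustering cutoff search assumes a unimodal relationship between
  cutoff and top-cluster fraction; pathological decoy sets could bisect to
  a suboptimal cutoff (the band endpoints are configurable).
* TM-score for mismatched residue sets normalises by the reference length
  but only pairs residues by number; models with genuinely different
  sequences need an external alignment first.
* RIO considers CA geometry only and takes the nearest crystal CA; at match
  distances approaching half the CA–CA spacing the assignment could become
  ambiguous.
* The synthetic generator's loops are geometrically plausible but not
  Ramachandran-valid; dihedral-based analyses should be restricted to
  helical segments.
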