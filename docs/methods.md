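# Methods

## Model

The predictor assumes that the propensity of a residue to contact a ligand
is reflected in how often that residue, together with its spatial
neighbours, recurs in the same local geometry inside known binding pockets.
The unit of comparison is the **motif triplet**: three residues of one
chain whose contact graph — an edge between two residues when their CA–CA
distance is strictly below `neighbor_max` — is connected.  Connectivity,
not a full clique, is required: a path A–B–C is a valid motif even when
d(A,C) exceeds the cutoff.

Two triplets match when their residues can be paired with identical
amino-acid types (no substitutions) and the paired representative atoms
superpose with RMSD strictly below `rmsd_max` under a proper rotation.
When a triplet contains repeated types, every type-consistent permutation
is tried, but a (query triplet, library triplet) pair contributes at most
one match, reported with its best-RMSD pairing.

Each match increments, for all three query residues involved, `Tot_bind`
or `Tot_other` according to whether the library triplet lies wholly in the
binding or wholly in the non-binding library.  The propensity is
`Pr = Tot_bind / (Tot_bind + Tot_other)`, defined as 0 when a residue has
no matches at all — such residues can never be predicted positive.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pocket_distance` | 3.5 Å (strict <) | heavy-atom distance defining a binding-pocket residue |
| `rmsd_max` | 0.7 Å (strict <) | superposition acceptance threshold |
| `neighbor_max` | 7.5 Å (strict <) | CA–CA contact edge for triplet connectivity |
| `min_heavy` / `max_heavy` | 10 / 60 (inclusive) | ligand heavy-atom bounds |
| `max_resolution` / `max_r_factor` | 2.0 Å / 0.20 (inclusive) | structure-quality filter |
| `min_binding_residues` | 10 | minimum pocket size per retained chain |
| `general_cutoff` | 0.143 (Pr ≥, inclusive) | positive-call threshold |
| `clustering_radius` | 10.0 Å (CA–CA, inclusive) | companion radius of the spatial filter; 0 disables |

The threshold comparison is inclusive (`Pr ≥ cutoff`) so a borderline
value such as 0.150 against 0.143 is stably positive under any rounding of
the reported three-decimal propensities.  Residue-specific mode applies
one cutoff per amino-acid type (optimised the same way as the general one,
each type scanned with the others held at the general cutoff), which
normalises for the compositional preference of residue types for binding
sites.

## Representation scheme

The superposed atoms per residue are `{N, CA, C, CB}` (`{N, CA, C}` for
glycine).  This captures backbone geometry plus the side-chain direction,
exists in essentially every well-determined residue, and keeps
identical-type pairing well defined (equal atom counts within a type).
The scheme is configurable (`RepresentationScheme`) because local
structural comparison engines differ in this choice; triplet-connectivity
distances are always CA-to-CA so that each residue contributes one well
defined point.  Residues missing a required atom are excluded from
matching and counted in the run log.

## Library construction

Pipeline order: structure-quality filter → ligand filter → pocket
definition → minimum-pocket-size filter → one representative chain per
homology cluster (most pocket residues; ties to the lexicographically
smallest chain key) → residue labelling.  Decisions worth noting:

* Structures without resolution or R-factor headers fail the quality
  filter (conservative).
* The excluded het-code list (buffers, cryoprotectants, solvents) is a
  packaged, user-editable text file; bare metal ions are recognised as
  single-heavy-atom groups of metallic elements.
* A residue is *binding* if it is in the pocket of any retained ligand of
  its own chain; pockets of different ligands may merge.  Contacts to
  ligands bound by other chains of the same entry are not transferred.
* Library triplets never span two chains, and triplets mixing binding and
  non-binding residues are dropped entirely: the method scores matches
  against exactly two libraries, and discarding mixed groups keeps
  `Tot_bind + Tot_other` well defined.  Homology clustering itself is an
  input (two-column TSV), not computed internally.

## Evaluation machinery

Metrics are computed residue-level per chain (sensitivity, specificity,
PPV, MCC; any zero-denominator metric is 0 so macro averages stay finite)
and macro-averaged with equal chain weight; the pooled view concatenates
all scored residues for a ROC curve with tie grouping and trapezoidal AUC
(verified against the Mann–Whitney U statistic in tests).  Threshold
optimisation maximises macro-MCC over a cutoff grid (default: all distinct
observed propensities plus 0 — the exact argmax; ties break to the
smallest cutoff).  The clustering-radius scan covers 1–20 Å in 1 Å steps.
Leave-one-out semantics are the caller's responsibility: each chain's
propensities must be computed with its own homology cluster excluded.

The *radius* of a binding site is defined as the maximum CA distance from
the pocket's CA centroid (a convention; no standard definition exists),
with cohort means reported with a normal-theory t confidence interval.
Apo/holo truth transfer matches residues by author numbering and falls
back to a global sequence alignment requiring 100 % identity over aligned
positions.

## The synthetic-fixture generator

`make_structure` builds chains as gently curving walks with 3.8 Å CA–CA
steps, parallel-transported local frames for N/C/O/CB placement, and a
ligand whose atoms are anchored 2.0 Å beyond the CB of each designated
pocket residue (verified at generation time: designated residues < 3.5 Å,
all others ≥ 3.6 Å, with retries on failure).  Amino-acid types within a
chain are all distinct, so every triplet has a unique composition and can
only match its own planted library copies; across chains, same-composition
triplet pairs are verified to be beyond the RMSD threshold by a safe
margin.

`make_planted_library` gives every pure (non-pocket-boundary) query
triplet a fixed number of rigidly moved, noise-perturbed library copies,
split between binding and non-binding labels by a designed fraction:
pocket triplets draw from 0.32–0.92 (rounded up), background triplets
from 0.00–0.28 (rounded down), and one pocket and one background residue
are pinned exactly to the band edges — so the generative decision boundary
on Pr sits sharply at 0.30, recoverable by the threshold optimiser.  One
spatially isolated background residue per chain (the *decoy*) receives a
binding fraction of 0.5; the copy counts of its neighbours' other triplets
are inflated so the decoy's sequence neighbours stay below the boundary,
making the decoy a false positive that only the spatial clustering filter
can remove.  With the default copy noise (σ = 0.1 Å per coordinate,
verified < `rmsd_max` per copy) the realized propensities equal the
designed ones exactly, which the tests assert to 1e-12.

`make_composition_contrast` plants, for every pure query triplet, equal
numbers of geometry-matched copies carrying the true label and
geometrically displaced copies (middle residue shifted 3 Å, verified
beyond the RMSD threshold, connectivity preserved) carrying the opposite
label.  Every observed amino-acid composition then has a composition-only
potential of exactly ½ while geometric matching still separates pocket
from background — isolating the contribution of geometry from that of
composition.

What the generator does **not** emulate: real side-chain rotamers,
packing, secondary structure, surface/burial, conformational change
between apo and holo forms, or the long-tailed match-count distributions
of a PDB-scale library.  Passing tests therefore demonstrate correctness
of the machinery (filters, matching, counting, optimisation, clustering),
not real-data benchmark performance; benchmark-scale figures require a
user-supplied full library and apo/holo dataset, which the evaluation
harness accepts.

## Numerical choices

* Superposition uses the SVD form of the Kabsch algorithm with the
  smallest singular direction flipped when needed to keep the rotation
  proper (determinant +1; mirror images do not superpose to zero).  The
  RMSD is evaluated on the explicitly rotated coordinates, which stays
  accurate to machine precision near zero, unlike residual-trace formulas.
  Degenerate (collinear) point sets have a non-unique optimal rotation but
  a well-defined RMSD.
* All stated strict/inclusive comparisons are implemented exactly as
  stated above; ties in representative selection, threshold optimisation,
  radius scanning and cavity ranking have deterministic documented breaks.
* The clustering filter is single-pass by default (one discard step); an
  iterative fixed-point variant is available behind a flag.
* Matching is exact despite the composition index: indexing only prunes
  pairs that could never satisfy identical-type pairing (asserted equal to
  exhaustive search over 100 random instances).
* Problem sizes in tests and fixtures (6 chains × 20 residues, 25 library
  copies per triplet) were chosen as the smallest cohorts on which all
  planted-parameter recoveries are sharp and deterministic.

## Known limitations

* Per-chain labelling ignores inter-chain ligand contacts within a
  biological assembly; no quaternary-structure expansion is performed.
* No solvent-accessibility computation: triplets are enumerated over all
  standard residues, not a surface subset.
* Modified amino acids are dropped entirely (the identical-type pairing
  rule cannot handle them); chains of CA-only traces score nothing.
* The composition-only baseline scores unseen compositions as 0.
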