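# Methods

This note records the models and procedures `modelsup` implements, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not establish.

## Alignment by residue number

All inputs are predicted models of regions of one source sequence, so two
residues are *equivalent* exactly when they carry the same author residue
number (and insertion code).  No sequence or structure alignment is
attempted: position-based pairing is what the superposition is supposed to
mean, and anything cleverer would silently repair numbering errors the user
needs to know about.  Consistent numbering is therefore a precondition;
the aligner warns when fewer than three columns are shared by two or more
models, the symptom of an offset numbering scheme.  Columns carried by a
single model are kept — they must be coloured — but never enter scoring or
fitting.

## Per-column consistency score

The divergence score answers, per position: *do every two models agree on
where this residue sits relative to the region they both model well?*

For each model pair (p, q) with shared columns C (at least 3):

1. **Window-consensus initialisation.**  A rigid Kabsch fit is computed for
   every contiguous window of 7 shared columns, each fit is scored by its
   total kernel support Σᵢ 1/(1 + (δᵢ/σ)²) over all of C, and the
   best-supported fit wins.  A single least-squares fit over all of C would
   split its error between a divergent segment and the agreeing majority,
   leaving residuals too uniform to discriminate; a window lies inside one
   rigid segment, and the majority segment's windows collect the most
   support.  (An earlier design scored superposition-free internal CA–CA
   distance differences; it was abandoned because a rigidly displaced tail
   keeps its internal distances and perturbs distances to remote residues
   only at second order when the displacement is perpendicular to an
   elongated structure — exactly the unfolded-tail case the trimming
   exists for.  Local-frame view vectors detect such displacements but
   amplify coordinate noise over long range through frame wobble.)
2. **Robust refinement.**  Three rounds of iteratively reweighted Kabsch
   fitting, weights being the previous round's kernel values — a Cauchy
   IRLS whose fixed round count keeps the procedure exactly deterministic.
3. **Kernel scores.**  Column i receives
   S_pq(i) = 1/(1 + (δᵢ/σ)²) ∈ (0, 1], with δᵢ the residual CA deviation
   and σ = 2 Å by default.  The kernel shape follows the
   distance-difference weighting of the SSAP structure-comparison score;
   σ sets the deviation at which a column counts as half-divergent and is
   exposed as `--sigma`.

The per-column score is **s_i = min over pairs of S_pq(i)**: a position is
conserved only if *every* pair of models agrees there.  A mean would let
two models that happen to place a divergent segment similarly outvote a
third that disagrees — with three models, one such chance agreement is
common enough to matter.  Everything is computed from pairwise rigid fits,
so the scores are invariant (to ~1e-14) under arbitrary rigid motions of
any input model, and trimming cannot be biased by the frame the models
arrived in.  Pairs sharing fewer than 3 columns, or only degenerate
(collinear) geometry, contribute nothing and are logged.

## Trimming

Iteratively: score the currently included columns, drop those with
s_i < 0.5 (`--score-threshold`), re-score the survivors, stop at a fixed
point or after 10 rounds.  Exclusion is monotone.  A floor of
max(3, 30% of scoreable columns) (`--keep-floor`) guarantees a fittable
set; when the threshold would cut below the floor the highest-scoring
columns are kept, ties resolved toward retaining lower sequence positions.
Defaults (σ = 2 Å, threshold 0.5) place well-modelled cores
(δ ≈ noise, S ≈ 0.95) far above threshold and displaced segments
(δ ≳ 2 Å) below it.

## Ensemble superposition

Reference-free joint fitting on the included columns: models are first
placed by walking the overlap graph outward from the first model (edge =
≥ 3 shared included columns; the graph must be connected, otherwise the
error lists the disconnected components), then refined by alternating
(a) a Kabsch fit of every model onto the current per-column mean structure
over the columns it covers and (b) recomputing the mean, until the mean
moves < 1e-6 Å RMS (far below PDB coordinate precision) or 50 iterations.
Joint fitting means no single low-quality model owns the frame; afterwards
all transforms are composed with the inverse of the first model's so the
first model is anchored bit-identically — output is reproducible and easy
to diff.  Reported statistics: ensemble RMSD about column means over the
included columns and over all shared columns, and the pairwise RMSD
matrix.  Fits are unweighted; score-weighted fitting was deliberately left
out to keep "included" the single, inspectable fitting decision.

## Shared rainbow

Each modelled position gets weight w = s (its consistency score) or a
floor w = 0.05 for singleton/unscored positions — positions modelled by
one resource carry no evidence of agreement and are treated as divergent.
The gradient parameter is the cumulative normalised weight, t(first) = 0,
t(last) = 1, monotone; hue runs linearly 240° (blue) → 0° (red) in HSV at
full saturation/value, so t = 0.5 is pure green.  Uniform scores recover
the plain rainbow exactly.  The same (seq_pos → RGB) table is used by the
PyMOL script and the PNG renderer, so a residue has one colour everywhere.

## Alignment lines

One Euclidean minimal spanning tree per column with ≥ 2 members, built on
superposed CA coordinates with Prim's algorithm; equal-weight candidate
edges are taken in lexicographic model-id order, so output is
deterministic.  Lines are drawn between CA atoms.  Trimmed-out columns are
drawn by default — long lines on divergent columns are the disagreement
signal — and `--lines included` restricts to the fitted set.  The CGO line
set is grouped into a single PyMOL object literally named `alignment` so
the viewer exposes a toggle button of that name.

## Classification reconciliation

Residues are (structure, chain, position) triples; ranges are 1-based
inclusive.  Domain-vs-domain overlaps are interval intersections summed
across matching chains.  Superfamily-pair statistics aggregate these over
all domain pairs with any overlap; a domain is *mapped* to a partner
superfamily with ≥ 1 shared residue (the overlap fractions carry the
stringency), and its overlap fraction is the share of its residues covered
by the union of the partner superfamily's domains.  A domain is *not yet
classified* w.r.t. the other resource when none of its chains carries any
domain of that resource; such domains leave the silver denominator.
Consensus pairs are mutual unique maxima of shared-residue similarity,
ties broken by total mapped domains, remaining ties treated as ambiguous
(no consensus, logged).  Tiers are graded with inclusive thresholds
(default 0.80, `--threshold`); an empty classifiable set on either side
fails the silver test (0/0 is a fail, logged).  Real SCOP/CATH release
files are out of scope; the TSV format (domain_id, superfamily_id,
structure_id, chain_id, start, end per segment) is the interchange.

## Synthetic data

`make_ensemble` emulates the regime the toolkit targets: an idealized
α-helical CA trace (rise 1.5 Å, radius 2.3 Å, 100°/residue — only relative
perturbations matter) as the conserved core, per-model isotropic CA noise
(default σ = 0.2 Å, a tight prediction ensemble), a tail rigidly displaced
by a default 8 Å in a per-model uniform random direction (a confidently
wrong placement, as in unfolded termini), per-model coverage windows for
patchwork ensembles, and a random rigid pre-transform per model (models
arrive in unrelated frames).  A minimal N/CA/C/O backbone is fabricated
around each CA so files parse as ordinary PDB.  All randomness flows from
an explicit seed; same seed, byte-identical files.

What this does *not* emulate: real side chains, secondary-structure
variety, correlated (non-isotropic) prediction error, partially melted
rather than rigidly displaced divergence, and numbering disagreements.
Passing tests therefore demonstrate the geometric machinery — not that
σ = 2 Å / threshold 0.5 are optimal for any particular resource's models;
both are exposed as configuration.

`make_classifications` constructs one superfamily pair per requested tier,
each on its own structures so pairs cannot interact: gold pairs use
near-identical segments (fractions ≥ 0.9), silver-not-gold pairs use
fractions {1, 1, 1, 0.5} (mean 0.875 ≥ 0.8, min 0.5 < 0.8),
bronze-not-silver pairs map 3 of 5 classifiable domains (0.6 < 0.8) using
a non-overlapping helper superfamily to make the unmapped domains
classifiable, and no-consensus instances use an exact similarity tie,
which the ambiguity rule turns into "no best partner".

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent oracle:
Kabsch against an exhaustive z-y-z Euler grid (2° steps, centroid
translation, analytic fold-in of one angle) on 20 five-point instances;
MSTs against enumeration of all n^(n−2) labelled trees via Prüfer
sequences (3–7 points, 100 columns); the tier pipeline against a direct
residue-set transcription of the criteria (200 random instances, ≤ 5
superfamilies and ≤ 8 domains per side); trimming against the generator's
ground-truth labels (20 replicate ensembles, 3 models × 40 residues);
whole-pipeline determinism by byte comparison of repeated runs.  These
sizes keep the full suite around ten seconds while exercising every
branch; `scripts/acceptance.py` re-measures the same quantities end to
end.

## Known limitations

* Residue-number alignment cannot recover from renumbered models.
* The divergence score sees rigid-segment disagreement; two models melting
  a region into different random coils both get low pair scores (correct),
  but a region divergent in *flexibility* rather than placement is not
  distinguished from noise at the σ scale.
* min-over-pairs makes one outlier model mark a region divergent for the
  whole ensemble — intended for trimming, but it means one bad model
  shrinks the coloured "conserved" spectrum for everyone.
* Insertion codes are carried through structural comparison but not
  supported in classification residue ranges (integer positions only).
* The PNG renderer is a CA-trace sketch (orthographic, painter's sort),
  not a molecular renderer.
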