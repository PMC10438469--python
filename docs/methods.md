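# Methods

This note documents the models and procedures implemented in `typetracker`,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Data model

A *track* is one cell's life between divisions: a contiguous run of frames
with one 3D nuclear position (μm) per frame. Forks are strictly binary;
daughters start one frame after the mother ends. Tracks that end before the
last frame without daughters must state why (`death` or `lost`); when the
input does not say, `lost` is assumed, the conservative choice because lost
cells cannot anchor type inference. Time is stored in frames; hours are
derived from `frame_interval_h` (default 0.2 h per frame, i.e. 12-minute
imaging). Coordinates are assumed anisotropy-corrected by the upstream
tracker; no z-scaling is applied here. Divisions are resolved at frame
granularity — sub-frame division timing is not represented.

## End-point typing

**Thresholds.** Positivity is strict (`intensity > threshold`). When the
user supplies no thresholds and no boolean columns, per-marker thresholds
are derived from the staining table itself: Otsu initialisation, refined by
two-class mean iteration (binned Otsu can land inside the negative cluster's
edge), with the final cut placed midway between the two classes' boundary
values. A guard on Otsu's effectiveness measure η (between-class variance
over total variance; default minimum 0.85) handles markers with *no*
positive population — without it, any automatic threshold would split the
background noise itself and flood the table with false positives. Visual
positivity assessment is inherently irreproducible, so thresholds are
explicitly user-governed; the automatic values are a starting point, not a
calibration.

**Decision table.** The table in the README is total: each of the 64 marker
combinations maps to exactly one label, with everything outside the seven
recognised patterns collapsing to `unknown` plus a logged conflict. KRT20 is
deliberately unconstrained for enterocytes (which co-express it) and for
Paneth cells (where WGA⁺Lyz⁺ dominates the call).

**Matching.** Stained cells are assigned to tracked end-point cells by the
Hungarian algorithm on a square, gate-padded cost matrix: leaving any cell
unmatched costs more than any feasible set of matches, so cardinality is
maximised first and total distance second; pairs beyond
`max_match_distance` (default 10 μm, about one nuclear diameter) are
infeasible. The gate plus the exported ambiguity report replace the manual
curation a human would otherwise do after fixation-induced deformation. An
optional rigid translation pre-alignment (centroid shift) is off by default.
Determinism: inputs are id-sorted and the cost matrix carries a ~1e-12
lexicographic bias, so exact cost ties resolve to the lowest
(endpoint id, stain id) pairs regardless of input order. Nuclear-marker
brightness is not used as matching evidence — it is optional, instrument-
dependent information that cannot be standardised across datasets.

## Backpropagation

Rules are local to one fork and applied leaves-to-roots (see README). Rule
order is same-type, then stem, then TA; the order is documented and tested
but never actually ambiguous, because a (stem, TA) fork triggers the stem
rule first. Design choices where the procedure was open:

- `unknown` daughters behave like dead ones (the mother inherits the other
  daughter's type) but the mother is flagged *low-confidence*, preserving an
  audit trail; two `unknown` daughters leave the mother `unknown` — no type
  is ever invented.
- Two daughters with distinct terminally differentiated types fit no rule;
  the mother becomes `unknown` and the fork is recorded as a conflict. (Such
  forks do not arise under the package's lineage model; on real data they
  would indicate typing errors.)
- A commitment is a point event placed at `floor((first + last) / 2)` of the
  daughter's observed span — "halfway the cell cycle", extended to partially
  observed cycles. Within a track the type is piecewise-constant.
- Tracks present at the movie start simply begin their first interval at
  frame 0; a root track has no fork context, so a commitment inside it is
  undetectable by construction (see *Limitations*).

## Crypt-villus axis

A natural cubic spline interpolates the 3–6 control points under chordal
parameterisation and is resampled into a dense polyline (spacing 0.25 μm,
well below the 0.5 μm grid the projection accuracy requires). Projection
finds the nearest polyline vertex, then refines exactly on the two flanking
segments; against a 0.01 μm brute-force grid the arc-length error stays
below 0.03 μm in the tests (tolerance 0.1 μm). Projection uses 3D distances
by default with a 2D (xy-plane) option, since axes are typically annotated
at the crypt's central z-plane. The zero point (bottom-most cell) is
recomputed every frame, and positions are normalised by the zeroed neck arc
length, so `r_norm` is 0 at the crypt bottom and 1 at the neck in every
frame of every crypt. Frames lacking an annotation reuse the nearest one
within ±5 frames, else raise. Migration speed defaults to the
first-to-last-frame displacement over elapsed time (the definition used in
the analyses); a least-squares `regression` variant exists for robustness
but is not the default.

## Neighbor analysis

The neighbor score of a pair (A, B) against a third cell S is
(d(A,S)+d(B,S))/d(A,B) ≥ 1. A pair are neighbors when the minimum over all
other cells in the frame exceeds the cutoff (default 2) and the partner is
among the focal cell's 20 nearest cells. Two readings were possible for
"the twenty closest": we take it as the candidate-partner set only — the
blocking set S is every other cell in the frame, because restricting S
could only add spurious edges at the tissue boundary. The cutoff comparison
is inclusive at the boundary up to a 1e-9 tolerance: in an ideal hexagonal
packing the blockers of an adjacent pair form equilateral triangles with
score exactly 2, and those pairs *are* adjacent — interior cells then have
six neighbors, as expected for the basal side of a curved epithelium, while
square-lattice diagonals (score √2) remain excluded. Exact boundary scores
are measure-zero in real data; the tolerance only disambiguates ideal
geometry.

Separation rates: partners are selected `round(1 h / frame_interval)` frames
after a focal cell's birth (nuclei need ~1 h to return to the basal side
after mitosis); horizons are measured from selection; if a followed cell
divides, one daughter continues the pair, drawn from a single seeded RNG per
run; "still neighbors" is evaluated at the single frame nearest the horizon,
not over an interval. Pairs whose follow window leaves the movie, or whose
lineage dies or is lost, are excluded and counted.

## Synthetic organoid generator

The generator emulates the statistical structure the pipeline assumes — it
is the package's benchmark, not a mechanical model of the epithelium.

Geometry: cells live on a tube of radius 12 μm, crypt 40 μm + villus 80 μm,
with the per-frame axis annotation running along the centerline and the neck
at the crypt/villus junction. Movies default to 60 h at 0.2 h/frame,
starting from 12 stem cells near the crypt bottom (~300 tracks by the end).

Lineage model: stem and TA cells cycle with lognormal times (means 15.5,
14.1 h; enterocytes 12.5 h; other committed types 15 h; CV 0.15 — the
proliferative and secretory cycle times are deliberately similar, with
enterocytes slightly faster). Commitments are exponential hazards per
allowed transition (defaults ~0.03/h for stem→TA and TA→enterocyte, a few
×10⁻³/h for the secretory fates). Three structural rules make the model
commit-then-sort:

1. **Commitment precedes division.** A commitment only takes effect in a
   cell that will divide again inside the movie; committed terminal types
   then run a bounded number of further generations (enterocytes up to 5,
   secretory types 1–2) before arresting. Consequently end-point sisters
   always share a type — the end-point sister same-type fraction is 1.0 *by
   construction* at zero noise, and the corresponding test asserts exact
   equality, not a tolerance.
2. **Lateral inhibition between sisters.** Once one sister commits, the
   other cannot commit within its own track (its descendants can). Every
   fork therefore separates a committed lineage from one that keeps the
   mother's type, which is exactly the configuration the fork rules invert.
3. **One commitment per track.** A committed cell cannot commit again before
   dividing; chained transitions (stem → TA → enterocyte) occur across
   generations, as the fork rules can only localise one transition per
   track.

Markers mature slowly: a committed cell stains for its new type only once
the commitment is older than `maturation_delay_h` (default 20 h — matching
the observation that terminally differentiated cells are rarely stained
younger than ~20 h); before that it stains all-negative (TA-like), and its
previous markers are assumed off immediately. Staining intensities are drawn
from well-separated bands (negative U(0,5), positive U(80,120) a.u.), so
automatic thresholding is exercised realistically.

Motion: advection toward the villus at `0.02 μm/h per proliferating cell
below`, scaled by per-type motility (enterocyte/goblet 1.3, TA 1.0, EEC 0.5,
stem 0.25, IMPC 0.1, Paneth 0.0 — the planted ordering of migration
speeds), the simplest mechanism consistent with proliferation-driven flow
from the crypt bottom. Isotropic positional jitter (0.35 μm/frame SD), soft
nuclear exclusion at 6 μm, and an opposite-signed tangential drift of
0.35 rad/h for Paneth and IMPC sisters (the planted sister-scatter that
makes type-stratified separation testable).

**Observability of planted commitments.** A planted event can be recovered
by *any* end-point staining method only if (a) the committed track has a
mother — root-track commitments leave no fork to infer them from; (b) some
descendant survives to the movie end; and (c) the commitment is old enough
at fixation for its markers to have matured (always true for TA, which
stains all-negative from the start). Recovery is therefore reported against
the observable events; on noiseless defaults the pipeline recovers 100% of
them in the correct tracks, and recovery degrades monotonically as label
noise rises (flipped-cell sets are nested across noise rates for a fixed
seed, so the monotonicity is a property of the inference, not of sampling
luck).

What passing these tests does **not** show about real data: the generator
has no global organoid rotation or fixation deformation (only optional
Gaussian stain jitter), no marker-intensity overlap between classes, no
segmentation errors, perfectly binary forks, and an idealised tube geometry
with exact axis annotations. Real match rates, conflict counts and recovery
will be lower; the synthetic results certify the inference machinery, not
microscope performance.

## Numerical choices and degenerate inputs

- Strict `>` at positivity thresholds; ties are negative.
- Matching: penalty `max_match_distance × (n+m) + 1` per unmatched cell;
  forbidden pairs cost three penalties; tie bias 1e-12.
- Neighbor cutoff tolerance 1e-9 (see above).
- Spline fitting requires ≥3 control points and rejects coincident
  consecutive points; a single-vertex polyline falls back to vertex
  distance.
- `zero_and_normalize` rejects frames where the neck is at or below the
  bottom-most cell.
- Empty staining tables, frames with a single cell, forests without
  divisions, and all-negative markers are all defined (warning + empty or
  `unknown` results, never a crash).
- The simulator refuses configurations exceeding 10⁵ cells.

## Limitations

- Transient early fates (stem/TA held only briefly) can be missed when no
  descendant retains them at the end point; death and track loss make this
  worse, because aborted lineages propagate no type information backward.
- Reversible type changes are invisible: the fork rules assume types only
  progress (stem → TA → differentiated).
- Commitments inside root tracks (cells present at the movie start) cannot
  be localised — there is no mother to differ from.
- The typing is hard (one label per track segment); no probabilistic or
  soft typing, and no re-typing from intermediate-frame live markers.
- Statistical significance testing of group differences is out of scope;
  the package reports the measured distributions.
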