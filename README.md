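# typetracker

Infer per-cell types *over time* in time-lapse recordings of intestinal
organoids by propagating end-point antibody-staining identities backward
along tracked lineage trees, then quantify the spatiotemporal
differentiation program: where lineages commit, how cells migrate along the
crypt-villus axis, and how neighbor and sister pairs rearrange.

The package is for quantitative biologists who already have (i) tracked
nuclei from 3D time-lapse microscopy (per-frame positions, frame-to-frame
links, division forks, death flags), (ii) an end-point staining table from
multiplexed immunofluorescence, and (iii) per-frame annotations of the
crypt-villus axis. It also ships a synthetic organoid generator with full
ground truth, so every inference step can be validated end to end without
microscope data.

## The method

**End-point typing.** Each stained cell carries a six-marker panel — Olfm4,
Cga (chromogranin A), Aldoβ (aldolase β), KRT20, WGA and Lyz (lysozyme) —
thresholded per marker (fixed values, or automatic two-class thresholds with
an effectiveness guard). The panel maps to a type through a decision table:

| type        | panel                                        |
|-------------|----------------------------------------------|
| stem        | Olfm4⁺ only                                  |
| EEC         | Cga⁺ only                                    |
| enterocyte  | Aldoβ⁺ (KRT20 ±), rest −                     |
| Paneth      | WGA⁺ Lyz⁺ (KRT20 ±), rest −                  |
| goblet      | WGA⁺ KRT20⁺ Lyz⁻, rest −                     |
| IMPC        | WGA⁺ only (immature mucus-producing cell)    |
| TA          | all six negative (transit-amplifying)        |

Any other combination is a logged conflict (`unknown`). Stained cells are
linked to tracked end-point cells by a globally optimal one-to-one matching
(Hungarian algorithm) that minimises total Euclidean distance under a hard
gate `max_match_distance` (default 10 μm ≈ one nucleus); unmatched cells are
reported.

**Type backpropagation.** Types flow from the leaves toward the roots. Along
a track the type is carried back unchanged; at each division fork the
mother's type follows from the daughters' inferred types:

1. both daughters the same type → the mother has that type;
2. exactly one daughter a stem cell → the mother is a stem cell;
3. one daughter TA, the other not stem → the mother is TA;
4. a dead, lost or untypeable daughter does not constrain the fork — the
   mother inherits the other daughter's type (flagged low-confidence).

When a daughter's type differs from its mother's, a commitment event is
placed halfway through the daughter's observed lifetime, with its 3D
position — this is the moment and place the lineage changed fate.

**Spatial analyses.** Per frame, a natural cubic spline through 3–6
annotated control points is reparameterised to arc length; every cell is
projected to its nearest point on the curve, giving an axis coordinate
*rᵢ* (zeroed at the bottom-most cell of the frame) and a residual distance
*d*. Positions are normalised by the crypt-neck distance so the neck sits at
1 in every frame. Migration speed is Δr/Δt between a track's first and last
frames. Neighbors are pairs of nuclei with no other nucleus in between,
tested by the neighbor score (d(A,S) + d(B,S)) / d(A,B) minimised over all
third cells S: pairs above the cutoff 2 are adjacent (a third cell exactly
midway scores the minimum, 1). Separation rates follow neighbor pairs (or
same-type sister pairs) from 1 h after birth to fixed horizons, substituting
a random daughter when a partner divides.

**Synthetic organoids.** The generator grows cells on a crypt+villus tube
under a commit-then-sort model: proliferating stem/TA cells commit before a
further division (stem → TA / Paneth / IMPC / EEC; TA → enterocyte / goblet
/ EEC), daughters inherit the committed fate, markers mature ~20 h after
commitment, and cells advect villus-ward at a rate set by the proliferating
cells below them, with type-dependent motility and extra tangential scatter
for Paneth/IMPC sisters. Ground-truth type intervals and commitment events
are returned for scoring.

## Worked example

Run the whole pipeline on a synthetic organoid (simulate → end-point typing
→ backpropagation → axis positions → separation rates → statistics):

```bash
typetracker run --seed 17 --out-dir demo/
```

prints (abridged):

```json
{
  "seed": 17,
  "n_tracks": 292,
  "n_endpoints": 152,
  "match_rate": 1.0,
  "n_transitions": 34,
  "n_conflicts": 0,
  "sister_same_type_fraction": 1.0,
  "commitment_recovery": 1.0,
  "neighbor_persistence": {"2.0": 0.59, "10.0": 0.28},
  "sister_persistence": {
    "paneth": {"2.0": 0.0, "10.0": 0.0},
    "ta":     {"2.0": 0.44, "10.0": 0.30}
  }
}
```

Reading the numbers: 292 tracks were simulated over 60 h; all 152 cells
alive at the movie end were matched to a stained cell (`match_rate` 1.0)
with no conflicting marker panels; backpropagation inferred 34 commitment
events and recovered 100% of the planted, observable ground-truth
commitments (`commitment_recovery`); every end-point sister pair shared its
sister's type (`sister_same_type_fraction` 1.0), as the commit-then-divide
model dictates; and Paneth sisters — scattered tangentially by the generator
— separate much faster than TA pairs (`sister_persistence`). The output
directory holds the typed forest, transition events, axis positions,
separation tables and a provenance record (config + seed) that reproduces
the run exactly.

Each stage is also available separately (`typetracker simulate`,
`type-endpoints`, `backprop`, `axis`, `neighbors`, `separation`, `stats`);
see `typetracker --help`. Input formats are plain CSV (documented in
`src/typetracker/io.py`) plus a tracker-style JSON dialect
(`docs/tracker_json_schema.json`).

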