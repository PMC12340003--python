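# Default QC rubric for 60-day cortical organoids.
#
# Five criteria (A Morphology, B Size/Growth, C Cellular populations,
# D Cytoarchitectural organization, E Viability/Cytotoxicity), each split into
# indices scored 0 (poor) .. 5 (high quality).  Per-index minima and the
# morphology composite (9/15) are rubric values; composites for B-E default to
# the sum of their index minima and should be overridden by users with a
# calibrated rubric.  Bin edges for the quantitative indices are declared,
# uncalibrated defaults.
name: cortical-organoid-day60
version: 1
early_exit_level: index

criteria:
  - id: A
    name: Morphology
    composite_min: 9
    indices:
      - {id: A1, name: Density and compactness, min_score: 3, quantitative: false}
      - {id: A2, name: Border integrity, min_score: 2, quantitative: false}
      - {id: A3, name: Absence of cysts, min_score: 3, quantitative: false}
  - id: B
    name: Size and growth profile
    indices:
      - {id: B1, name: Size, min_score: 3, quantitative: true}
      - {id: B2, name: Growth, min_score: 3, quantitative: true}
  - id: C
    name: Cellular populations
    indices:
      - {id: C1, name: Expected cell types, min_score: 4, quantitative: false}
      - {id: C2, name: Astrocytic reactivity, min_score: 4, quantitative: true}
  - id: D
    name: Cytoarchitectural organization
    indices:
      - {id: D1, name: Cellular density, min_score: 3, quantitative: true}
      - {id: D2, name: Cell-less regions, min_score: 3, quantitative: true}
      - {id: D3, name: Border integrity, min_score: 3, quantitative: false}
      - {id: D4, name: Internal cysts, min_score: 3, quantitative: false}
      - {id: D5, name: Rosettes, min_score: 3, quantitative: false}
  - id: E
    name: Cellular viability and cytotoxicity
    indices:
      - {id: E1, name: DNA damage, min_score: 4, quantitative: true}

# Initial QC: non-invasive pre-study selection on A and B (max 25, pass >= 16).
# Final QC: post-study evaluation over all criteria; reference_max 50 is the
# achievable maximum when B and D5 are not assessed; total_min rescales
# proportionally (rounded up) when the achievable maximum differs.
modes:
  initial:
    criteria: [A, B]
    total_min: 16
    reference_max: 25
  final:
    criteria: [A, B, C, D, E]
    total_min: 35
    reference_max: 50

# Score bins for quantitative indices: five ordered edges cut the measurement
# axis into scores 0..5; a value exactly on an edge takes the higher score.
# B1/B2 are batch-relative: the measurement is |value - batch median| in units
# of the batch MAD, stepping down one score per additional 0.5 MAD.
bins:
  D1: {direction: higher, edges: [8000, 8750, 9500, 10500, 11500], units: cells/mm^2}
  D2: {direction: lower, edges: [2, 5, 10, 20, 30], units: '%'}
  C2: {direction: lower, edges: [10, 12.5, 15, 17.5, 20], units: '%'}
  E1: {direction: higher, edges: [0.5, 1.0, 1.5, 2.0, 3.0], units: sd_ratio}
  B1: {direction: lower, edges: [0.5, 1.0, 1.5, 2.0, 2.5], units: batch_mad, relative: batch}
  B2: {direction: lower, edges: [0.5, 1.0, 1.5, 2.0, 2.5], units: batch_mad, relative: batch}
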