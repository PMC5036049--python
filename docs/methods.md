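# Methods

## Problem and model

Catalytic residues — the handful of amino acids that carry out an enzyme's
chemistry — are rare (a few per chain, typically 1–4% of residues) and sit
in characteristic places: concave pockets, densely contacted positions,
evolutionarily conserved columns, neighborhoods enriched in charged and
hydrophilic types (H, D, R, E, K, C, Y). This package scores every residue
of a single protein chain by fusing four per-residue predictors that each
read one of these signals:

1. **Structural feature predictor** — an RBF-kernel SVM over structural
   descriptors of the residue and its strongest spatial contacts.
2. **Sequence feature predictor** — an RBF-kernel SVM over a sliding
   sequence window of profile and physicochemical descriptors.
3. **Structural template predictor** — binary transfer of catalytic
   annotations from the most similar structure in a template library.
4. **Sequence template predictor** — the same transfer rule driven by
   profile–profile alignment similarity.

### Contact geometry: Delaunay tessellation and facet counts

All heavy atoms of the chain are tetrahedralized (Qhull, via
`scipy.spatial.Delaunay`). Two atoms share a Voronoi facet exactly when
they are joined by a Delaunay edge — the diagrams are geometric duals — so
the package counts, for every residue pair, the number of atom pairs (one
atom from each residue) joined by a Delaunay edge. This count measures
contact strength; a residue's *microenvironment* keeps neighbors with at
least `facet_cutoff` shared facets (default 9), which filters weak,
sliver-like contacts. Degenerate point sets (coplanar/cospherical) are
retried once with a 1e-6 Å jitter seeded from the structure id, a
reproducible analogue of Qhull's joggle.

A subtlety worth recording: qhull's explicit Voronoi output omits true
unbounded ridges having fewer than two finite vertices, so the test oracle
that rebuilds facet counts by explicit Voronoi construction bounds the
diagram with far sentinel points (a ladder of radii) and settles residual
candidates with an exact bisector linear program. The Delaunay dual used by
the implementation, the bounded explicit construction, and the LP agree.

### Microenvironment score

For a residue of type *m* with qualifying neighbors, the pair-frequency
matrix F has F(m, n) = number of neighbors of type *n*. During training,
each catalytic residue contributes a weight matrix

    W(m, n) = N_mn / ((N_m + pc)(N_n + pc))

where N_mn is its count of type-*n* neighbors and N_m, N_n are type counts
in the neighborhood (query included), with pseudocount pc = 0.5 guarding
sparse neighborhoods; W_DT is the elementwise mean over all catalytic
residues of the training set. The score of any residue is the inner
product Σ F(m,n)·W_DT(m,n) — high when the neighborhood composition
resembles trained catalytic neighborhoods. The weighting function is
injectable so alternative normalizations (e.g. log-odds propensities) can
be swapped without touching callers.

### Network topology

The residue interaction network has an edge wherever two residues share at
least `facet_cutoff` facets. Per residue the package computes degree,
closeness (Wasserman–Faust within-component scaling, bounded in [0, 1] on
disconnected graphs), normalized shortest-path betweenness, and the
clustering coefficient. Catalytic residues tend toward high
closeness/betweenness/degree and low clustering (their neighbors line a
pocket and rarely touch each other).

### Multi-scale Laplacian norms

With CA coordinates p_i, Gaussian weights w_ij = exp(−‖p_i−p_j‖²/σ²) over
all j ≠ i define the weighted center c_i = Σ w_ij p_j / Σ w_ij; the
Laplacian norm is ‖p_i − c_i‖. The five scale factors σ are the empirical
quantiles (linear interpolation) of the chain's pairwise CA-distance
distribution at {0, 2⁻⁶, 2⁻⁴, 2⁻², 1}: from nearest-neighbor-dominated to
centroid-dominated. Small large-scale norms mark concave, pocket-like
positions. Weights are computed with a per-row shift by the smallest
squared distance before normalization — a constant factor per row that
cancels in the weighted mean but prevents underflow of the whole row at
small σ (weights below ~1e-12 of the row maximum vanish harmlessly). The
normalized (weighted-mean) form is used because the quantity is defined as
a distance to a weighted center.

### Sequence descriptors

Per-column conservation from a query-anchored MSA: Shannon entropy,
relative entropy, and Jensen–Shannon divergence (equal mixing weights)
against a background distribution; gaps are excluded from frequencies,
query-gap columns dropped, >90%-gap columns flagged. PSSMs are read from
the PSI-BLAST ASCII dialect and canonicalized to alphabetical column
order. Static features: residue-type one-hot, Kyte–Doolittle hydropathy,
net side-chain charge, Grantham polarity, catalytic propensity (log2 ratio
of catalytic to overall type frequency, trained from annotations; a
heuristic prior ships as fallback), relative sequential position, length,
and global composition. Running PSI-BLAST/HHblits/SPalign is out of scope:
profiles and alignment hits are consumed from files or synthesized by the
fixture module. Externally computed descriptors (solvent accessibility,
pockets, B-factors, …) can enter as extra file-supplied columns but none
is bundled.

### Feature vectors, scaling, SVMs

PSSM columns pass through the logistic function; other non-binary columns
are Z-scored with training statistics and then squashed by the logistic;
binary columns pass through; zero-variance columns map to 0.5. Logistic
outputs are clamped to the open unit interval (`nextafter` bounds) because
the exponential saturates in double precision beyond |x| ≈ 37. Scaling
statistics are frozen at training time and reused verbatim at prediction.

The structural vector concatenates the target's feature block with the
blocks of its `window_structure` = 4 highest-facet-count neighbors (ties
by residue index), zero-padding missing slots with an indicator bit. The
sequence vector is a sliding window of half-width `window_sequence` = 9
(19 positions), likewise padded with per-position indicator bits.

Negatives are subsampled uniformly at random (seeded) to 6 per positive;
the SVM uses C = 2 and RBF γ = 0.03125 with Platt (sigmoid) probability
calibration over five deterministic internal folds
(`CalibratedClassifierCV(SVC(), ensemble=False)`).

### Template transfer and fusion

Hits are ranked by similarity (ties by template id); only the top hit is
used. A query position scores 1 iff it maps onto an annotated catalytic
residue of that template, else 0 (unaligned positions included); an empty
hit list yields zeros with a −∞ sentinel similarity. Per channel,

    hunter = w·fscore + (1−w)·tscore   if best_similarity ≥ cutoff
    hunter = fscore                     otherwise

with (α = 0.55, SP cutoff = 0.6) for the structural and (β = 0.57,
HH cutoff = 0.87) for the sequence channel — template opinions are
suppressed when no reliable template exists. The final score blends the
channels with γ = 0.5. Aligned-but-non-catalytic and unaligned positions
are not distinguished (both contribute 0).

### Evaluation

Recall/precision/F1/accuracy/MCC at a configurable threshold (default 0.5;
degenerate denominators give 0) and rank-based ROC AUC. Cross-validation
partitions *structures*, never residues; the pair-weight matrix, propensity
table, scaling statistics and both SVMs are re-fit inside every training
fold, and template hits pointing at a test-fold structure are excluded
before top-hit selection. Pooled AUC over all test residues is reported
alongside per-fold AUCs with their standard error (both conventions, since
either may be quoted as a headline).

## Synthetic benchmark

The fixture module emulates the statistical signatures above without any
external data. Each pseudo-protein is a self-avoiding spiral walk over a
sphere shell (spacing ≈ 3.8 Å; shell radius sized to the chain length),
with a spherical-cap indentation of depth `pocket_depth` = 5 Å around a
mid-latitude axis; the residues deepest in the cap (≈ 4% of the chain,
`catalytic_fraction`) are labelled catalytic. Pocket residues draw their
type from a background distribution reweighted toward H, D, E, K, R, C, Y;
the rest use the background. Each residue carries backbone pseudo-atoms
(N, CA, C, O at typical bond lengths along the chain) plus 1–4 side-chain
pseudo-atoms sized by residue volume — real residues average ~8 heavy
atoms, and without that atom count the facet-count distribution never
reaches the contact cutoff. MSAs are 50 mutated copies (per-column
substitution rate 0.35, scaled down by `conservation_boost` = 0.85 at
catalytic columns, 2% gaps); PSSMs are per-column log2 odds against the
background with one pseudo-observation. Template hits pair each query with
a perturbed near-identity homolog (similarity drawn above the channel
cutoff, ~5% simulated gaps) and low-similarity decoys. All randomness
flows from one seed; a fixed seed reproduces the benchmark byte-for-byte.

What the benchmark does *not* emulate: real protein packing and rotamer
chemistry, realistic phylogenetic correlation in MSAs, structure-quality
noise, or hard template regimes (remote homology with partial, shifted
alignments). Passing tests therefore demonstrate that the pipeline
recovers planted geometric, compositional and evolutionary signal and that
its components obey their contracts — not field performance on curated
catalytic-site datasets, which additionally depends on external search
engines and databases.

## Numerical and design choices

- Facet cutoff 9 for both the microenvironment and network edges,
  configurable.
- Microenvironment ties (equal facet counts) break by ascending residue
  index; fold assignment, negative subsampling and fixture generation are
  all driven by explicit seeds.
- Altloc resolution keeps the highest-occupancy variant, ties broken by
  altloc label; hydrogens are discarded; MSE→M, SEC→C; other non-standard
  residues are dropped with a warning; residues lacking CA are excluded
  (they cannot carry Laplacian or window features).
- Residue indexing is internal, 0-based and contiguous; author seq ids are
  kept for reporting only, so insertion codes cannot corrupt windows.
- The structural window counts *neighbors* (4 neighbor blocks after the
  target block); the sequence window is a half-width (19 positions total).
  Both are config values.
- Quantile scale factors use linear interpolation between order
  statistics; duplicate CA coordinates would give σ = 0 and are rejected.
- MCC with a zero denominator is defined as 0; AUC requires both classes.

## Problem sizes

Default study conditions: 40 structures of 80–120 residues (≈ 4,000
residues, ≈ 160 catalytic), 5-fold structure-grouped CV. The full
evaluation runs in well under a minute per seed on one CPU; the test suite
repeats it over three seeds.

## Known limitations

- Single chain per query; multi-chain active sites and ligands are out of
  scope, as are mmCIF input and NMR multi-model handling (first model
  only).
- Alignment engines are not executed; template quality is whatever the
  supplied hit files contain.
- The shipped catalytic-propensity prior is a fallback heuristic; train it
  from annotations for any serious use.
- Probability calibration on small positive sets (tens of residues) is
  coarse; scores are best treated as rankings near the decision boundary.
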