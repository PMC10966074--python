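# Methods

This note records the models implemented in `mws3`, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the simulators do — and do not — emulate.

## Read structure and barcode correction (`chipio`)

A read pair carries three identity layers: a 10-nt preindex (BC#1), an
18-nt bead barcode (BC#2, three 6-nt split-pool segments), and a molecule
identity. The RNA layout places a 17-nt random molecule-tag region at the
start of read 1 — its first 6 nt double as the UMI — followed by the bead
barcode; read 2 opens with the preindex. The ATAC layout packs bead barcode
then preindex at the start of read 1; molecule identity comes from aligned
fragment coordinates supplied as a fragments-style table (alignment itself
is out of scope). Both tag lengths are layout parameters because the two
roles of the random bases (deduplication UMI vs. well-marking tag) need not
share one length; the defaults are `umi_len=6`, `feature_tag_len=17`.

Barcodes are corrected segment-wise against whitelists with a maximum
Hamming radius of 1 (default): an observed segment maps to the unique entry
within the radius and is dropped on zero or tied candidates — ambiguity
never guesses, preventing barcode cross-talk. Bead segments use 96-entry
6-mer whitelists drawn from a fixed 98-word code with minimum pairwise
Hamming distance 3, built greedily over the full 6-mer space in a fixed
pseudorandom order. Distance ≥ 3 makes every single-base error uniquely
correctable, which the tests verify exhaustively (no linear [6,4,3] code
over a 4-letter alphabet exists, hence the greedy nonlinear construction).
Preindex whitelists are 384 random 10-mers kept at pairwise distance ≥ 3 by
rejection sampling.

Fragments use 0-based half-open coordinates throughout (fragments-TSV
convention). All writers/readers satisfy write∘read = identity on valid
records; malformed lines raise with their line number.

## Well deconvolution (`welldeconv`)

Per-bead feature sets are 17-nt tag strings (RNA) or fragment coordinate
triples (ATAC). ATAC spike-in 14-mers are pooled into the same feature set
by default (`union`); a `refine` mode instead keeps them as a confirmation
set and requires candidate pairs found on coordinates to also share at
least one spike-in — provided because the role of the spike-ins as primary
or secondary evidence is a genuine design fork. Beads are ranked by
deduplicated units (unique tags/fragments) and the top n (default 20,000;
tumor preset 10,000) retained.

Pairwise Jaccard indices are computed through an inverted feature→bead
index, so cost scales with feature occurrences rather than bead pairs; a
brute-force double loop serves as the test oracle and the two must agree
exactly. Merging uses connected components (order-independent closure of
pairwise links) rather than an order-dependent sweep; components above
`max_beads=6` are dropped entirely and recorded as overloaded. The
representative barcode of a well is its lexicographically smallest member;
all tie rules are fixed, so identical inputs give byte-identical partitions.

**Thresholding.** Three strategies are exposed:

- `max_distance` — the classic knee: sort values descending, take log₁₀,
  normalize both axes, return the value at the point of maximum
  perpendicular distance to the chord joining the curve's endpoints.
- `second_diff` — maximum discrete second difference of the same curve.
- `otsu` (driver default) — exact two-class split of the log₁₀ values
  maximizing between-class variance, computed on the sorted values without
  binning; the returned threshold is the largest lower-class value, so
  "strictly above" retains exactly the upper class.

The geometric knee is correct when the background forms a sharp corner, but
on simulated chips the background mode (pairs sharing one insertion site by
chance) is heavy and decays smoothly; the max-distance point then lands
*inside* the background and the retained graph percolates. The
variance-based split is insensitive to the background's internal shape and
lands in the inter-mode gap whenever one exists; both strategies behave
identically on cleanly bimodal inputs, and the degenerate constant input
returns the maximum (retaining nothing) under every strategy.

Cells are (preindex, well-representative) pairs. RNA counts are
UMI-collapsed per (cell, gene, UMI); ATAC fragments are re-keyed by cell
barcode with duplicate coordinates aggregated into counts.

## Quality control and barnyard estimation (`qc`)

Filters are organized by assay and sample class, all inclusive minima:
RNA ≥ 500 transcripts (tumor samples: ≥ 300 detected genes); ATAC
species-mixing ≥ 3,000 reads; ATAC wild-type tissue ≥ 1,000 unique
fragments and TSS enrichment ≥ 7; ATAC tumor ≥ 800 and ≥ 4. A cell is
retained iff it passes every active rule, which makes filtering monotone in
each threshold. TSS enrichment is consumed as precomputed metadata, not
computed here.

Species classification uses the assay's deduplicated unit (UMIs or
fragments): cells below the assay quality floor are `low_quality` and
excluded from everything downstream; a cell is species-specific when its
majority share strictly exceeds the purity cutoff (0.80 — "more than 80%",
so exactly 80% is a collision); everything else is a collision. The
collision rate is the raw observed fraction among classified cells — no
Poisson multiplet correction is applied, matching how such rates are
reported from mixing experiments.

## Chip simulator (`synthdata.simulate_chip`)

Wells draw a bead count (0–8) and nucleus count (0–3) from configurable
distributions (defaults: most occupied wells hold < 4 beads; 10,000 wells).
Each nucleus emits `molecules_per_nucleus` sequenced captures (default 300)
drawn with replacement from its pool of distinct molecules
(`distinct_molecule_fraction`, default 0.5 — i.e. ~2 captures per
molecule); each capture lands on a uniformly random bead of the well.
Same-well feature sharing therefore arises from one molecule being captured
on several beads, which is the physical signal bead merging exploits.
Capture is uniform across a well's beads because capture kinetics are not
modeled; the molecule→bead assignment is a single draw that a weighting
hook could replace.

RNA molecules carry a random 17-mer tag (first 6 nt = UMI) and a gene from
the nucleus's species; cross-well tag collisions are birthday-bounded over
4¹⁷ and absent in practice. ATAC fragment positions are drawn from a finite
pool of accessible sites (default 200,000 across 5 chromosomes), so
unrelated nuclei occasionally reuse an insertion — this chance-sharing
background is what ranked-Jaccard thresholding separates signal from, and
it is the regime the method faces on real chromatin data where accessible
sites recur across nuclei. Spike-in oligos (ATAC) are generated per well
and attached once to every bead of the well, marking co-residence even in
wells without nuclei. An optional ambient pool (off by default) redirects a
fraction of RNA captures to arbitrary beads chip-wide.

A noise-free *RNA* simulation produces no background pairs at all; ranked
curves with only a signal mode have no knee, and thresholding degenerates.
The deconvolution driver accepts an explicit threshold for this case, and
the end-to-end recovery checks run the ATAC assay where the background
exists. Passing them shows the pipeline separates chance sharing from
co-residence; it does not exercise barcode-error-induced background, PCR
chimeras, or uneven capture.

Randomness is organized as one root seed spawning independent streams per
well (plus separate streams for chip structure, whitelists and ambient
molecules), so each well's draws are independent of well order and every
output is byte-reproducible from the seed. Sequencing errors mutate emitted
barcode/tag bases at `per_base_error_rate` (default 0 — error handling is
tested through the correction layer, not the simulator default).

Truth records one row per emitted read (origin well, nucleus, capturing
bead), so read conservation and capture locality are directly assertable.
`simulate_barnyard` plants an exact collision design instead: collision
cells split their units ~50/50 between species, singlets carry a small
cross-species contamination (default 1%).

## CNV study simulator (`synthdata.simulate_cnv_study`)

Genes are laid out on 5 chromosomes × 4 cytobands (2,000 genes default).
Expression is `μ_g · 2^(a·[clone] + ε)` with log-normal gene baselines and
`ε ~ N(0, noise_sd)` in log₂ units (default 0.1) — amplitude and noise
share one scale, so `amplitude=0.3` is a 3σ per-gene effect. The default
design places 1,800 tumor / 1,200 adjacent / 600 wild-type cells and plants
one dominant clone (amplitude on 2/20 cytobands = 10% of regions;
prevalence 0.72 in tumor, 0.08 in adjacent) plus four *distinct* low-burden
subclones (half amplitude, one cytoband each, ~1% prevalence, two of them
shared with adjacent tissue). A cell is truth-malignant iff it carries any
clone.

The subclones are not decoration. The classifier's anchors are tissue
*means*; in a strictly two-population simulation those means coincide with
the score-mode centers and roughly half of each mode sits on the wrong side
of its anchor — a knife-edge that no amount of iteration resolves. The
method presumes what real tumors have: a spread of partial CNV burden
(subclonal lineages, field effects in the margin) whose pseudobulks survive
the outlier correction and pull each expectation off its mode center. Each
planted subclone clusters into its own pseudobulk, so the pull scales with
the number of distinct lineages, not with their cell count. The price is
honest: subclone cells end `intermediate` (neither label), bounding
cell-level accuracy at ≈ 0.97 under the defaults. Homogeneous-tumor data is
a documented failure mode of the method itself, not of the implementation.

The matrix is continuous (normalized-expression-like), not counts: noise is
exactly the stated log-normal, with no extra sampling layer. Real data adds
count noise, dropout, and cell-type expression structure that the
clustering would have to overcome first; passing recovery checks here shows
the classification logic is correct, not that the workflow is robust to
those effects.

## Pseudobulk CNV classification (`cnvclass`)

`build_pseudobulks` Ward-clusters cells within each (sample × cell type)
group on Euclidean distances and cuts the tree into the requested number of
pseudobulks; groups with fewer cells than pseudobulks are dropped and
recorded. Clustering operates on log₂(1+x) by default (variance
stabilization; configurable to raw), while profiles are the exact sums of
untransformed member-cell columns, normalized to `normalization_total` —
default 1×10⁷, exposed as a parameter because the normalization constant is
stated ambiguously in the platform literature ("10e6").

`estimate_cnv_windowed` is a deliberately simple relative-expression
estimator standing in the role usually played by heavier CNV callers: log₂
ratio to the mean of reference (adjacent-tissue) pseudobulks with a
pseudocount of 1, smoothed by a centered moving average (window 101 genes,
edges truncated to the available span, never crossing a chromosome
boundary), scaled into [−1, 1] by the matrix's maximum absolute value so
that zero stays neutral (a per-gene scaling variant is available). The
classifier is tool-agnostic: any externally produced region × pseudobulk
matrix can be imported in its place. The renormalization applied per sample
in the original workflow is unstated there; this log-ratio/scaling chain is
the package's documented choice.

Scores are quadratic sums over cytoband-aggregated values. Expectations are
tissue means with one round of inclusive outlier removal (adjacent
pseudobulks scoring ≥ the initial malignant expectation; tumor pseudobulks
≤ the initial normal expectation), then recomputed once; emptying a tissue
is an error. With identical tissue score sets the trimming is symmetric and
the ordering invariant (normal ≤ malignant) still holds; the degenerate
equal-expectation case is flagged, not hidden.

`iterative_classify` cuts the Ward tree over pseudobulk region-profiles
into min(k, n) clusters (k = 50 default; min avoids k > n degeneracy),
labels clusters by mean score against the expectations (boundaries
inclusive on both sides), and re-clusters the unresolved remainder until a
round resolves nothing or `max_recursion` (default 5 — the cap is required
but its value unstated in the source workflow) is reached. Survivors stay
`intermediate`, and cells inherit their pseudobulk's label.

## Cross-modal concordance and transfer (`crossmodal`)

Per method, region-level CNV values are scaled to [−2, 2] by maximum
absolute value (zero-preserving), averaged per cytoband, and summarized as
effect = mean over malignant pseudobulks − mean over normal pseudobulks.
Only cytobands present in every method are compared. Spearman ρ is computed
per method pair (undefined — reported as NaN — for constant vectors, which
have no ranks); a cytoband is `dup_effect`/`del_effect` only when *every*
method's effect has the same strict sign — a zero counts as disagreement,
the conservative reading of "same trend".

`knn_value_transfer` maps values through a shared embedding (computed
elsewhere — CCA/anchor finding is consumed, not implemented): each query
receives the unweighted mean of its k (default 50) nearest reference values
under Euclidean distance, with ties broken by reference index (stable
sort), making the transfer deterministic.

## Problem sizes and determinism

The packaged checks run at desk scale by choice: 1,000-well chips
(~300,000 reads) for end-to-end deconvolution, 3,600 cells / 200
pseudobulks for the CNV study, 42 cytobands / 20 seeds for concordance,
5,000 cells for the barnyard design. All stages are seed-deterministic end
to end, including gzip output (fixed mtime) and JSON key order; rerunning
any CLI command with the same seed and inputs reproduces every output file
byte for byte.

## Known limitations

- The windowed CNV estimator has no HMM/segmentation; focal events smaller
  than the smoothing window are attenuated, and the global max-abs scaling
  couples all pseudobulks through one normalizer.
- Expectation-anchored classification fails on homogeneous tumors (see
  above) and inherits any impurity of the adjacent-tissue reference.
- The binomial-interval check on barnyard estimation is itself a ~95%
  coverage statement: over random seeds, ~1 in 20 honest runs falls outside.
- Simulators emulate capture topology and clone structure, not sequence
  content: no transcript sequences, aligner artifacts, PCR duplication
  families beyond UMI duplication, or doublet expression profiles.
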