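# Methods

## The algorithm

Plain grey-value thresholding of a micro-CT volume faces a dilemma when the
structure of interest is a set of distinct bones separated by thin,
lower-intensity sutures: a threshold high enough to disarticulate the bones
destroys their definition, while a threshold low enough to capture full bone
definition merges them across the sutures. Boundary-preserving threshold
iteration resolves this by separating the two roles of the threshold in time.

Given an initial threshold IT, a target threshold TT ≤ IT, an iteration
count NI and a segment count NS:

1. **Seed.** The superlevel set `{v : grey(v) ≥ IT}` is decomposed into
   connected components; the NS largest become seed segments, labeled
   1..NS by descending voxel count. Optionally each segment is expanded by
   a one-voxel shell (dilation) before iterating.
2. **Schedule.** The threshold step is `TS = (IT − TT) / NI`, and the
   threshold at iteration CI is `CIT = IT − TS × CI` for CI = 0..NI, so the
   run descends from IT to TT in NI equal decrements.
3. **Growth.** At each iteration, every voxel of the current superlevel set
   that is connected (through the set) to an existing segment is claimed by
   a simultaneous multi-source breadth-first expansion of all segments.
   Labels, once assigned, are never changed.

Because wavefronts from different segments can only meet, never cross, any
separation present in the seed is preserved to the end, while each segment
eventually fills its share of the TT superlevel set: the final union of
segments is exactly the set of TT-components that contain at least one seed
voxel. This yields two structural guarantees the test suite verifies
against an independent flood-fill oracle:

* **Union identity / worst case.** The result never selects anything that a
  direct TT threshold would not select, and covers every TT-component the
  seed touches. Consequently the union is independent of NI; NI only moves
  the inter-segment boundaries (more iterations ≈ a boundary that follows
  the intensity landscape more closely).
* **Degenerate collapses.** IT = TT reduces to plain thresholding with
  largest-component selection; NI = 1 is a single multi-source growth at TT.

## Numerical and semantic choices

* **Threshold comparison is inclusive (`≥ t`).** This makes IT = TT
  degenerate cleanly to an ordinary threshold.
* **CIT rounding.** Thresholds are integer grey values; `IT − TS·CI` is
  rounded half-up and the final entry forced to TT exactly, so the endpoint
  thresholds hold regardless of floating-point error. The *reported* integer
  step is `floor(TS)` (e.g. 53 for (35000 − 27000)/150); the schedule itself
  keeps the exact rational step.
* **Growth semantics.** "Each segment grows" is ambiguous between
  sequential per-segment passes (order-dependent) and simultaneous
  wavefronts. The engine uses simultaneous, level-synchronous wavefronts:
  each BFS level, every unclaimed in-mask voxel adjacent to a claimed voxel
  takes the smallest adjacent label. Tie-breaking to the smaller label makes
  the result bit-reproducible and independent of any internal ordering.
  Implementation: a neighbourhood minimum filter over a sentinel-encoded
  label array, one filter pass per BFS level.
* **Connectivity** defaults to 26 (faces + edges + corners) for both
  component labeling and growth, configurable to 6 or 18. 26 is the most
  permissive choice and the least likely to fragment thin bone.
* **Component ordering.** Components are labeled in decreasing size; ties
  break by raster-scan order of each component's first voxel, so labeling
  is deterministic. Label 1 is always the largest seed segment.
* **Dilation** is applied once to the seed, before iterating. A shell voxel
  wanted by two or more segments is *contested* and stays background —
  dilation can therefore never fuse segments, keeping the
  boundary-preservation contract even in its least predictable feature.
* **Empty seed.** If no voxel reaches IT the run aborts with an error
  advising a lower initial threshold; if fewer than NS components exist,
  all are kept and a warning is recorded in the run report.

## Input conversion

Working precision is unsigned 16-bit. 8-bit input is widened without
rescaling (it occupies 0–255 of the range). Signed 16-bit and 32-bit float
input require a user-chosen `(low, high)` window: values are **clipped** to
the window, then mapped affinely so low → 0 and high → 65535, rounding
half-up. Clipping (rather than wrapping or erroring) was chosen because the
appropriate window depends on where the bone grey values sit, and values
outside it are by definition not of interest; this is a documented
convention users should know when picking the window. Downsampling for the
size sweep is block-mean with round-half-up — a simple, exactly testable
reduction; interpolating resamplers (e.g. Lanczos) are a visual-quality
concern outside this package's scope.

## The phantom generator

`phantoms.make_phantom` renders the intensity structure the algorithm
assumes: spherical high-intensity *bodies* (bone, default 40,000) joined by
cylindrical intermediate-intensity *bridges* (sutures, default 30,000) over
a low background (5,000), then degrades the render with Gaussian blur
(sharpness, in voxels) followed by additive Gaussian noise (contrast
resolution, in grey values), clipped to [0, 65535]. Noise after blur keeps
the two scan-quality axes independent. Defaults are a clean render
(noise 0, blur 0) on a 48³ grid with two radius-6 bodies 20 voxels apart
and a 3-voxel bridge; the default thresholds used throughout the tests
(IT 35,000, TT 27,000) bracket the bridge intensity the same way the
human-skull configuration brackets its suture grey values. Ground truth
assigns bridge voxels to the nearest body centre — a convention, fair to a
wavefront whose meeting line approximates equidistance, not an anatomical
claim.

What the phantom does *not* emulate: partial-volume gradients at real bone
boundaries, beam hardening, ring artefacts, anisotropic voxels, and the
complex multi-bone topology of a real skull. Passing phantom tests
demonstrates the algorithm's structural guarantees and boundary behaviour,
not segmentation accuracy on clinical data.

## Dice scoring

Per-segment Dice `2|A∩B|/(|A|+|B|)` with segments matched by greedy
descending-overlap assignment (each side matched at most once, ties broken
deterministically by label). Greedy rather than optimal assignment is
adequate at the segment counts involved and keeps the matching trivially
reproducible. Reference segments with no match score 0 in the
mean-with-missing average and are omitted from mean-without-missing, so
`mean_with_missing ≤ mean_without_missing` always.

## Problem sizes

The oracle comparisons run the engine against pure-Python re-derivations
(naive BFS, flood fill) on ~100 random volumes up to 20³ and on 48³
phantoms; property tests use NI up to 100. These sizes make every
structural guarantee checkable exhaustively while the full suite stays in
the seconds range. The engine itself is vectorised (one `scipy.ndimage`
filter pass per BFS level) and handles larger volumes; memory is the
practical limit, and resampling below ~2 GB is advisable for interactive
parameter tuning.

## Known limitations

* Segments fused in reality (e.g. synostosed sutures with no grey-value
  gap) cannot be separated by any threshold schedule; that is a physics
  limit of the method, not of the implementation.
* A segment can still "overflow" through a bright artefactual connection
  that survives the initial threshold; the remedy is a higher IT or a
  manual seed.
* The per-level minimum-filter growth touches the whole volume each BFS
  level; very long thin corridors are its worst case.
* Labels export as uint16 TIFF, capping NS at 65,535.
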