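# Methods

## Model

A decorated filament is modelled as a planar axis carrying a
one-dimensional site lattice. Binding sites sit at arc-length positions
`s = i · step` with `step = 82 Å` (the tubulin α/β-heterodimer length);
functional sites — the ones that can hold an outer dynein arm — are the
every-`r`-th sites with `r = 3`, giving the repeat
`repeat = r · step = 246 Å`. The repeat is *defined* as `r · step` and
never as an independent number: the field speaks of "8 nm" and "24 nm",
but all internal arithmetic uses 82 and 246 Å so that site indices stay
exact integers. Particles are records with a micrograph position
(pixels), a filament identity, an arc-length coordinate (Å), a register
class and a provenance (`picked` or `expanded`).

### Axes

Picked filaments give two coordinates (start/end); the default axis is
the straight chord between them. Splayed filaments bend, so a polyline
mode accepts arbitrary support points; parameterization is
piecewise-linear and exact, and `arc_of`/`point_at` are mutual inverses
up to float precision. Segmentation places centers at
`s_i = i · step, i = 0 … ⌊L/step⌋` — starting at the picked start point
and including the far endpoint when `L` is an exact multiple; this is a
deterministic choice with maximal coverage (endpoint handling is
otherwise arbitrary). A lateral gate (default one box half-width,
256 px · pixel size) rejects points too far off-axis to belong to the
filament.

### Register unification

3-D classification of 8-nm particles separates bound arms into `r`
classes, one per register of the box within the repeat. A `RegisterMap`
sends external class labels to phases `0 … r−1` (or `non-particle`,
dropped and counted). Each particle of phase `k` moves along its own
axis by `Δ · step` where Δ is the *minimum-magnitude* integer with
`k + Δ ≡ k_ref (mod r)` — unique for odd `r`; for even `r` the tie
breaks toward the negative shift. Which class is the reference register
is a free parameter (default phase 0): the procedure is symmetric under
that choice. Shifted particles falling off the axis are dropped and
counted. Snapping replaces `s` by the nearest multiple of `step`
(half-integer ties toward smaller `s`, for determinism); after
unify + snap every surviving, correctly-labeled record satisfies
`(s/step) mod r = k_ref` exactly — the integer invariant the tests
check. Mislabeled records land off-phase instead; coordinate curation
cannot detect them, which is precisely why a density-based verifier
exists downstream.

### Neighbor recovery

Bound arms cluster: if a site is occupied, its axial neighbors at ±1
and ±2 repeats frequently are too. Candidates are therefore proposed at
`s ± m · repeat` (default `m ∈ {1, 2}`) from every current particle,
only along the particle's own axis (no cross-filament proposals), and
screened by an injected verifier — a predicate standing in for
mask-focused classification plus manual micrograph inspection, which
are image-domain steps outside this package's scope. Accepted
candidates are merged, snapped and deduplicated; the cycle repeats
until a round accepts nothing new (or `max_rounds = 10`). The dedup
priority (picked before expanded, then lower record index) makes the
curated set monotone: earlier records always survive collisions with
later proposals. With a perfect verifier the procedure is equivalent to
breadth-first reachability on the occupied-site graph with edges ±1,
±2 — it recovers exactly the occupied sites of every maximal occupied
run containing ≥ 1 seed, and nothing else. Runs with no seed are
unreachable; that bound is the ceiling on recall.

### Deduplication

Greedy sweep in priority order; a record is kept iff its Euclidean
micrograph-plane distance to every already-kept record in scope is
≥ `d_min = step/2 = 41 Å` — merging same-site duplicates while never
merging adjacent lattice sites. Scope defaults to `same_filament`,
because crossing filaments hold distinct complexes even when their
boxes overlap in projection; `same_micrograph` is available by flag.
The greedy sweep is idempotent and leaves all in-scope pairs ≥ `d_min`
apart (both property-tested against an independent O(n²) oracle).

### QC

Spacings are successive differences of per-filament sorted arc
coordinates, pooled into a histogram with 10 Å bins anchored at zero;
the modal spacing is the **center of the highest-count bin** (ties to
the smaller spacing), so a clean 246 Å lattice reports 245 Å — the bin
center of [240, 250). The 10 Å default separates the 82 Å and 246 Å
peaks cleanly. Clusters are maximal runs of consecutive occupied repeat
indices `j = round(s/repeat)`; particles farther than `step/2` from any
repeat site are excluded and counted (these are typically mislabeled
registers). Recovery scoring matches curated particles to occupied
truth sites one-to-one, greedily by distance within 41 Å on the same
filament; greedy matching is deterministic and adequate at these
densities (optimal assignment would differ only in pathological ties).

## Synthetic data

The generator emulates the *coordinate-level* structure of splayed
axonemes on micrographs; it renders no images or densities.

* **Filaments** are circular arcs — one curvature parameter with an
  exact closed form — sampled as 20 Å polylines, clipped to the field.
  Default radius 3–30 µm: gentle bending, as in vitreous ice. Splines
  were rejected as unnecessary freedom.
* **Occupancy** of repeat sites follows a two-state Markov chain:
  `P(occupied | previous unoccupied) = p_start`,
  `P(occupied | previous occupied) = p_stay`. This is the simplest
  process producing clustered occupancy with tunable run length (mean
  `1/(1 − p_stay)`, geometric). Defaults `p_start = 0.3`,
  `p_stay = 0.8` (mean cluster of 5) are plausible placeholders for
  sensitivity sweeps; no quantitative occupancy model for partially
  disassembled axonemes is established.
* **Observations**: one record per occupied site, positioned at the
  site plus a whole-step register offset (the box that "detected" the
  arm sits in a random one of the three registers), plus isotropic
  Gaussian localization noise (default σ = 2 Å). Register labels are
  correct with probability `1 − ε` (default ε = 0.05). A fraction
  (default 0.5) of occupied-site records is flagged as the initial seed
  set; unoccupied sites spawn spurious seeds at rate 0.01. Unoccupied
  sites otherwise produce no record: the stream being modelled starts
  at classified bound-arm particles, while the full-filament box stream
  is produced separately by segmentation.
* **Randomness**: a seed-sequence tree ordered (micrograph, filament)
  so that adding micrographs never perturbs earlier ones; identical
  config ⇒ byte-identical outputs.
* **Verifier**: the ground-truth-backed verifier accepts candidates
  within 41 Å of an occupied site, optionally corrupted with stated
  false-accept/false-reject rates; decisions are keyed by hashed site
  identity so repeated queries for the same site never flip-flop.

What passing on this generator does **not** show: robustness to
filament-tracing errors (axes here are exact), to anisotropic or
non-Gaussian localization error, to crossing-filament misassignment of
particles to axes, or to the image-domain failure modes of the real
verifier (classification). It does validate the lattice arithmetic,
the rescue logic, dedup semantics and the bookkeeping end to end.

## Numerical choices

* Site arithmetic uses `⌈s/step − 1/2⌉` for nearest-site snapping
  (ties toward smaller `s`) and a 10⁻⁹ absolute guard when counting
  sites on an axis of float length.
* STAR and CSV numeric cells are written at shortest round-trip
  precision and parsed with correctly-rounded conversion, so table
  round-trips are bit-exact (`pandas.to_numeric`'s fast parser is not,
  and is deliberately avoided).
* Degenerate inputs: a filament shorter than one step yields a single
  particle at `s = 0`; an empty table flows through every stage and
  yields an empty report; a zero-length chord is rejected at parse
  time.

## Problem sizes

The test suite and the acceptance script run on desk-scale instances
chosen to give stable statistics: ~50 filaments (≈ 750 repeat sites)
for periodicity, 10⁴ sites/particles for calibration checks, 100–200
randomized instances for the oracle-equivalence properties. All
complete in well under a minute on one CPU.

## Known limitations

* Axes are planar; no 3-D axoneme geometry (nine-fold doublet
  arrangement) is modelled.
* The register labels of real data must come from external
  classification; the package never computes them.
* Recall is bounded by seed coverage of clusters (see above); the
  pipeline reports this ceiling rather than trying to exceed it.
* Real-mode recovery requires a user-supplied verifier; the built-in
  options are accept-all and reject-all (the latter reduces the
  pipeline to unify + dedup + QC).
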