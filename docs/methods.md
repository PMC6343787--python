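# Methods

This note documents the models and procedures implemented in `meshcarto`,
the parameters that matter, the design choices that were genuinely open,
and what the simulator does and does not emulate.

## Conventions

The incident beam runs along +z; the detector is a flat plane normal to
the beam at `detector_distance`, pixels are 0-based and continuous with x
along the fast axis. Grid nodes are `(row, col)`, 0-based. Each mesh row is
acquired as its own small goniometer sweep that restarts at `omega_start`,
so the angle of the image at `(row, col)` is
`omega_start + col * omega_per_image`; nodes in the same column share their
orientation. This per-row-sweep convention is what makes the ω-gated
linkage (below) able to connect a crystal across rows: under a cumulative
row-major assignment, adjacent rows would differ by `n_cols · ω_step`,
which exceeds the 0.5° gate for any realistic scan, and no multi-row
crystal could ever cluster as one.

## Multi-pattern detection

A still image of one crystal shows spots only at reciprocal-lattice nodes,
so difference-diffraction-vector (DDV) lengths concentrate in discrete
peaks; a superposition of lattices adds inter-lattice DDVs whose length
distribution is approximately linear over the short range analysed
(1–40 × 10⁻³ Å⁻¹). The statistic `K = k₀ S / N²` normalizes the fitted
baseline slope `k₀` by spot density `N/S` and count `N`, with
`S = 2π λ⁻² (1 − cos 2θ_max)` the Ewald-cap area containing the spots. The
decision threshold is `K > 1.4 × 10⁻⁴ Å⁻¹`.

Parameters (defaults): 100 histogram bins over `[0, 1/25)` Å⁻¹; baseline
fit restricted to bins whose centres fall in `[10⁻³, 4·10⁻²]` Å⁻¹ with at
least 3 usable bins; nodes with fewer than 10 spots skip the K test
(the slope of a near-empty histogram is noise) and are treated as
single-pattern; `S` is computed per image. DDVs at or beyond the histogram
range are discarded, not clamped; bins are half-open, so edge assignment is
deterministic.

Baseline bins are located **once**, on the mesh-wide cumulative histogram,
and reused for every per-image fit. Intra-lattice DDV lengths are
distances between reciprocal-lattice nodes — orientation invariants — so
the peak positions line up across all images of a scan (and across the
random orientations of the calibration simulation). Fitting each image at
bins chosen from its *own* sparse histogram would be biased: the local
minima of a counting histogram are almost surely its zero-count bins,
which drags the fitted slope to zero.

### AMPD variant

Local minima are found with the multiscale local-extremum scalogram
(AMPD): entry (k, i) is 0 when sample i exceeds both of its k-th
neighbours; the scale λ minimizing the row sum is selected; indices that
are extrema at all scales up to λ are reported. Three deliberate
adaptations for count histograms:

* the random penalty entries of the original formulation are replaced by a
  constant — the argmin over row sums is unchanged and the result is
  reproducible;
* scale selection uses the canonical strict comparisons with penalized
  boundaries, but extrema *extraction* tolerates ties (within a relative
  tolerance of 10⁻⁹) and treats out-of-range comparisons as satisfied:
  noiseless histograms contain exact-tie zero runs between peaks, and
  those runs *are* the baseline; extrema close to the signal edge would
  otherwise be discarded at large scales. Endpoint samples are never
  reported, so monotonic signals yield no extrema;
* no detrending — for a DDV histogram the trend is precisely the baseline
  slope being measured.

## Distance score and regions

Diffracting, non-multipattern nodes are grouped into 8-connected regions
(diagonal adjacency counts; configurable to 4). For a node pair, the image
with fewer spots is the reference (ties: first argument, documented — the
score can differ slightly depending on which side is the reference when
counts are equal); for each reference spot the nearest compared-image ray
is found on a KD-tree over unit vectors (chord length is monotone in angle,
so chord-nearest is angle-nearest); deviations are capped at the 0.1° gate
and D is their RMS. One-to-one matching is *not* enforced. Pairs involving
an empty spot list propagate as "no comparison" and enter the matrix at the
gate (maximally dissimilar). D is symmetric for unequal spot counts and
confined to [0, 0.1°] by construction.

## Clustering

Within a region, hierarchical agglomerative clustering uses a weighted
average linkage: inter-cluster distance is `Σ wᵢⱼ Dᵢⱼ / Σ wᵢⱼ` over cross
pairs with `wᵢⱼ = 1` iff `|ωᵢ − ωⱼ| ≤ 0.5°`, else 0 — images taken at
goniometer angles further apart see disjoint slices of reciprocal space,
so their D carries no information. When *every* cross pair is gated out
the distance falls back to the 0.1° gate, so incomparable clusters are
never merged below the cutoff (a conservative choice; the alternative of
treating them as mergeable would chain unrelated nodes). Merge ties break
on the smallest cluster-index pair, making the dendrogram deterministic
across platforms. The linkage is implemented directly (O(n³) with
vectorized scans; mesh regions are at most a few hundred nodes) because
off-the-shelf linkage implementations cannot express pairwise weight
masks; with all weights 1 it reduces exactly to unweighted average linkage,
which is asserted against scipy in the tests. Flat crystals are maximal
merges below the 0.093° cutoff; singleton clusters are kept as crystals.
Crystals split across disconnected regions remain separate entries.

## Shape fitting

Each crystal's score diagram is approximated by the semi-ellipsoid
`E = H sqrt(max(0, 1 − u²/a² − v²/b²))` with `(u, v)` the node offset from
`(x₀, y₀)` rotated by φ. The objective is `Σ αᵢ (Eᵢ − scoreᵢ)²` over the
crystal's own nodes (α = 1) and the no-diffraction nodes of its bounding
box dilated by 2 nodes (α = `penalty_weight`, default 10, target 0);
multi-pattern nodes and nodes of other crystals are excluded entirely. The
penalty is what pins the fit when the crystal's own nodes underdetermine
it (collinear or single-node crystals). Six parameters are optimized —
H, x₀, y₀, a, b, φ — by differential evolution with a fixed seed
(`de_seed`, default 0), bounds: centre inside the dilated bounding box,
semi-axes in (0.3, max grid dimension), H in (0, 2·max score], φ in
[0°, 180°); population 20, up to 300 generations, then a local polish.
The (a, b, φ) ↔ (b, a, φ+90°) degeneracy is canonicalized to a ≥ b with
φ ∈ [0°, 180°). If the optimizer raises, a flagged bounding-box fallback
(centre of mass, half-extent axes) is reported instead of failing the run.
Ranking is by `I = (2/3)πabH`, descending, ties by crystal id.

## Synthetic mesh scans

The simulator provides every test input. A still image is generated by the
Ewald construction: all reciprocal-lattice nodes with `|q| ≤ 1/d_min` are
enumerated (cached per unit cell — the admissible Miller set is rotation
invariant), and a node diffracts when its angular offset from the Ewald
sphere, `||q − c| − 1/λ| / |q|` with `c` the sphere centre, is below an
excitation half-width that lumps mosaicity and bandwidth into a single
still-image window. The scattered ray `k_out = q + k_in` is projected onto
the detector; off-detector and backscattered spots are dropped; spot
intensity falls off quadratically with the offset. Crystals are tilted
ellipses on the mesh; a node's score is the exact semi-ellipsoid thickness
sum `Σ H_k sqrt(max(0, 1 − u²/a² − v²/b²))`, so the fitting stage's target
surface is exact by construction. Overlap nodes receive the exact union of
spot lists (no occlusion or absorption — lattice superposition is all the
K statistic needs). Optional uniform noise spots exercise the D-score cap
and K robustness. A crystal may carry an orientation gradient (degrees per
grid unit along its major axis, about the goniometer axis) to emulate
gradually bent lattices. Everything is deterministic given the seed.

Default study conditions: wavelength 1.0 Å, PILATUS3 2M-like detector
(1475 × 1679 px, 0.172 mm), detector distance set for 1.7 Å resolution at
the nearest edge, excitation half-width 0.05°, and a thermolysin-like unit
cell (93, 93, 130 Å, γ = 120°), giving ≈700 spots per image. The cell
choice matters for the K statistic: its shot noise scales as `S/N²`, and
with a small cell (~200 spots/image) a single stray histogram count moves
K by ~10⁻⁴ Å⁻¹ — the order of the decision threshold itself — whereas at
~700 spots/image the single-lattice K is cleanly separated from the
two-lattice regime. Values are typical of the mesh-scan experiments the
method targets.

The satellite-ratio calibration enforces the spot-count ratio by randomly
subsampling the satellite's spot list, framing everything in spot counts
without modelling crystal volume.

### What the simulator does not emulate

Physical intensities (partiality, polarization, absorption), detector
point spread and pixel quantization of spot centroids, salt/ice rings
(removed upstream in real pipelines), mosaic peak shapes, and background.
Passing tests therefore demonstrate the geometry and statistics of the
method — reciprocal-space mapping, DDV peak/baseline separation, ray-angle
similarity, ω-gated clustering, shape recovery — not robustness to
centroiding noise or to imperfect upstream spot finding. Spot-position
noise would broaden DDV peaks by roughly a pixel's reciprocal equivalent
(~5 × 10⁻⁴ Å⁻¹ at these settings, 1–2 histogram bins), which the
baseline-region machinery tolerates by construction, but that regime is
not exercised quantitatively here.

## Numerical choices and degenerate inputs

* Histogram bin assignment is half-open; overflow is discarded.
* The flat-signal guard in AMPD returns no extrema when the signal's range
  is below tolerance.
* A region of one node skips the matrix/linkage and becomes one crystal.
* Empty scans produce an empty report and exit code 0 at the CLI; input
  errors exit 2, stage failures 3.
* `score_floor` is exclusive: a node "diffracts" when score > floor
  (default 0, i.e. any nonzero score counts).
* The RMS in D is clamped to the gate to guard the `D ≤ gate` invariant
  against floating-point round-up.
* Reports serialize with sorted keys and fixed formats, so identical
  inputs give byte-identical `crystals.json` (asserted in tests).

## Problem sizes used in the test suite

Simulated grids of 3 × 3 up to 12 × 14 nodes with 1–8 crystals; 200 image
pairs for the null distance-score distribution; 50 replicates per ratio
for the K calibration; 20 random crystals for shape-fit recovery; 20
seeded scans for end-to-end crystal-count recovery; 100 random matrices
(n ≤ 12) for the linkage cross-check. These sizes mirror the micromesh
scans the method targets while keeping the default suite in a few minutes
on one core.

## Known limitations

* The D score's reference-image tie-break makes D very slightly
  asymmetric when both images have the same spot count.
* The dendrogram cutoff (0.093°) sits close to the score's saturation
  value (0.1°), so the split/merge decision for large, slightly bent
  crystals is inherently delicate — the simulator shows both behaviours
  (a smooth 1° bend stays one crystal under a rotated-row acquisition; an
  abrupt 1° step splits).
* Cross-region crystal merging is out of scope: a crystal split across
  disconnected regions is reported twice.
* Automatic cutoff selection is not attempted; the cutoff is a fixed,
  configurable parameter.
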