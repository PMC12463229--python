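# Methods

## Diagram model and conventions

A link diagram is stored combinatorially: each crossing keeps its four
incident arc-ends in counterclockwise rotational order starting from the
incoming under-strand (positions 0–3, the common planar-diagram text
convention `X(a,b,c,d)`), plus a handedness sign. A right-handed (+1)
crossing has its incoming over-strand at position 3; equivalently the
sign is the sign of det(over-direction, under-direction) in the plane.
Crossing-free circles are carried as an explicit free-loop counter so
that smoothing, bracket evaluation and the Khovanov complex remain
correct when circles detach.

The 0-smoothing joins end pairs (0,1) and (2,3); the 1-smoothing joins
(0,3) and (1,2). With the conventions above the 0-smoothing is the
bracket's `a`-coefficient smoothing (the one obtained by rotating the
over-strand counterclockwise onto the under-strand). These labels are
fixed by two worked anchors checked in the tests: a single right-handed
curl has bracket `−a³`, and the left trefoil's q-bracket is
`(q⁻² − 1 − q⁴)(q + q⁻¹)`.

**The smoothing operator ρ is the oriented resolution**: the 1-smoothing
at a left-handed crossing and the 0-smoothing at a right-handed one.
Two independent arguments force this choice. Geometrically it is the
only resolution compatible with strand orientations, so the remaining
crossings keep their signs (1-smoothing one crossing of the left trefoil
leaves the negative Hopf link; 0-smoothing it leaves a two-curl unknot).
Algebraically, the state subcube that is closed under the Khovanov
differential at a coordinate is the `s_x = 1` subcube, and for a
left-handed crossing that subcube reproduces the smoothed link's complex
with equal homological heights and a q-degree shift of −1. Note that
some presentations label this operator "ρ₀" at left-handed crossings
while simultaneously using the insert-1 cube embedding; the cube
embedding is the definition that survives scrutiny, and it is the one
implemented.

Orientation handling: PD text input derives arc orientations from the
under-strand data and propagates them; a strand that never passes under
anything (possible in split or fully-layered links) has a genuinely free
orientation, which the parser resolves toward ascending arc ids. The
four-crossing unlink fixture is one such diagram, which is why it is
committed with explicit signs rather than as PD text. Plat closures of
braids re-derive signs from an actual traversal
(`with_consistent_orientation`), since caps reverse strand directions.

## Polynomials

All polynomial arithmetic is exact (`fractions.Fraction`); there is no
floating point anywhere in the invariants. The bracket is evaluated both
as a closed state sum and (as an independently tested code path) by the
skein recursion. The unnormalized Jones polynomial uses
`Ĵ = (−1)^(n−) q^(n+ − 2n−) ⟨L⟩_q`; the exponent sign is fixed by the
left trefoil's value `(−1)³ q⁻⁶ ⟨L⟩ = q⁻¹+q⁻³+q⁻⁵−q⁻⁹`. The Jones
polynomial in `t` keeps quarter-integer exponents as integer multiples
of 1/4. The empty diagram (no crossings, no circles) evaluates to 1 in
both bracket normalizations (empty product); a diagram of k circles
gives `(−a²−a⁻²)^(k−1)` and `(q+q⁻¹)^k` respectively.

## Khovanov homology

Basis vectors are (state, circle labeling) pairs; circles are identified
across cube edges by their arc content, ordered by smallest contained
arc id. Heights run over `[−n−, n+]` (negative heights are essential:
the trefoil's homology lives at k ≤ 0), q-degree is
`(#v₊ − #v₋) + ℓ(s) + n₊ − 2n₋`, and the edge maps are the Frobenius
merge/split with checkerboard signs `(−1)^(s₁+…+s_{i−1})`. The
differential preserves q-degree, so homology is computed blockwise per
(height, degree): field coefficients by sparse exact column reduction
(rank-nullity), integral coefficients by Smith normal form (sympy) of
the incoming block, whose invariant factors > 1 are the torsion. The
default crossing bound for building a complex is 14 (the basis grows as
`Σ_s 2^(γ(s))`); practical interactive sizes are ≤ 10 crossings.

## Filtrations and EKH

A weighted link smooths crossing sets by thresholding: ascending mode
smooths `f(x) ≤ a` (natural for traversal weights), descending mode
smooths `f(x) ≥ a` (natural for distance weights, where isolated
crossings — large nearest-neighbour radius — go first). Equal weights
are smoothed in one event; the result is order-independent because the
smoothing operators commute. The final stage is always a crossingless
collection of circles.

Distance weights come in two conventions: `full` is the literal
nearest-neighbour distance in the projection plane, `half` (default)
divides by two, i.e. the radius at which disks grown simultaneously
around all crossings first touch. The `half` scale is the one on which
the critical distances of the worked seven-crossing example are quoted,
and `critical_radii` (the k smallest half pairwise distances) reproduces
all eight of its printed values to three decimals. Distances are always
planar (2D); the weights ignore the discarded depth axis.

For an all-left-handed diagram the tower of stage complexes is a genuine
filtration of the ambient complex: stage i is spanned by the states with
coordinate 1 at every smoothed crossing, is closed under the
differential, and its intrinsic q-degree is the ambient degree plus the
number of smoothed crossings. The EKH barcode is computed by the
standard persistence column reduction run over the increasing tower
(most smoothed complex first), independently per ambient q-degree block.
Bars store: homological height, the inclusive stage interval on which
the class is alive, the corresponding parameter interval, a
`reaches_original` flag (the free `(−∞, b]` summands), and the per-stage
q-degree profile. Zero-length bars (alive at a single stage) are kept so
that the number of bars alive at any stage and height equals that
stage's homology dimension — the invariant every consistency test
checks; plotting or feature extraction can drop them via
`Barcode.positive_length()`.

**Mixed handedness.** Smoothing a right-handed crossing realizes the
smaller complex as a *quotient* of the larger one (the forced cube
coordinate is 0, and that subspace is not closed under the
differential), so the natural chain map points the other way and a tower
that smooths right-handed crossings is a zigzag, not a filtration. No
single-direction persistence module, and hence no barcode in the usual
sense, exists for it. The implementation therefore:

* computes barcodes only for all-left-handed towers and raises a clear
  error otherwise (`diagram.mirror()` is the standard workaround when
  the mirror invariant is acceptable);
* generalizes `ekh_rank(a, b)` to subquotient towers — right-handed
  forced coordinates are quotiented first — which is valid whenever the
  crossings smoothed strictly inside the window are left-handed, and in
  particular makes the diagonal `H_{a,a}` (= stage homology) available
  for any diagram;
* always provides stage-wise summaries (`poincare_over_filtration`,
  stage homology tables), which need no maps at all.

The four-crossing unlink example is the reason this matters: its
solution family necessarily mixes handedness (an exhaustive search over
all planar 4-crossing shadows with one or two components shows no
all-left-handed diagram satisfies its defining properties), so the
"every stage of the first weighting is trivial" statement is asserted as
what it says — every stage homology, hence every diagonal EKH group, is
concentrated in height 0, the unlink signature — rather than as an empty
barcode.

## Projection of space curves

Curves are closed polygonal lines; closure joins last to first point.
Projection keeps two coordinate axes and uses the third as depth
("over" = larger depth value). All pairwise intersections of
non-adjacent segments are found by a quadratic scan; regularity demands
interior intersection parameters, distinct depths, and pairwise-distinct
crossing points. A failed projection is retried after a seeded random 3D
rotation about the centroid (default 20 retries, starting at 10⁻³ rad
and doubling), which preserves inter-crossing distances far better than
point jitter. Sampling density is the caller's responsibility; no
resampling or smoothing is applied, so under-sampled curves can project
to diagrams of the wrong knot type.

## Fixtures and synthetic data

The built-in table is generated programmatically and self-checked
(component count, writhe, unnormalized Jones) at load time: unknots with
0–2 crossings, both Hopf links, both trefoils (the left one doubling as
the PD-parser reference), the figure-eight (braid closure of
`(σ₁σ₂⁻¹)²`), a 7-crossing 7₆ diagram, and the four-crossing unlink
discussed above. The 7₆ diagram is a 4-strand plat closure found by
scanning small twist-region words for determinant 19 — evaluated as
`|⟨L⟩_a|` at `a = e^{iπ/4}` — which identifies the knot uniquely among
those admitting 7-crossing diagrams, without a table lookup. Parametric
curves (`synthetic_curve`) supply a (2,3) torus knot whose default
chirality projects to the all-left trefoil, a flat circle, and
drift-corrected closed random walks; these emulate backbone-like closed
polylines but not the local geometry of real nucleic-acid backbones
(fixed bond lengths, helical correlation), so passing tests demonstrate
correctness of the machinery, not biological realism of the curves.

Randomized tests draw trace closures of random 3-strand braid words
(≤ 6 crossings; the all-negative variant when a filtration is needed).
The structural checks — `d∘d = 0`, `χ_q = Ĵ` on 100 random diagrams,
barcode/stage consistency and rank functoriality on random weighted
towers, universal-coefficient consistency ℚ/𝔽₂/ℤ on the fixture table —
run in well under a minute at these sizes; sizes were chosen so the
whole suite stays interactive while still exercising every code path
(states grow as 2^n, so each extra crossing doubles the work).

## Known limitations

* Diagram reconstruction from Gauss codes (planarity realization) is
  out of scope; Gauss codes are emitted, not consumed.
* Reduced Khovanov homology, Lee/Bar-Natan deformations and s-invariants
  are not implemented.
* Integral EKH is undefined here (no interval decomposition over ℤ);
  persistence requires field coefficients (ℚ default, 𝔽p optional).
* Mixed-handedness towers have no barcode (see above); they are a
  mathematical obstruction, not an implementation gap.
* The determinant-based 7₆ identification pins the knot only up to
  mirror image; chirality of that fixture is whatever the committed plat
  word produces (writhe −3).
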