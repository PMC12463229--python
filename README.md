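# ekhom — evolutionary Khovanov homology for knot data analysis

Knotted curves are everywhere in structural biology — supercoiled DNA,
RNA pseudoknots, entangled protein backbones — but classical knot
invariants see only the topology of a curve, not its geometry: a hugely
contorted unknot and a round circle get identical Jones polynomials and
identical (trivial) Khovanov homology. `ekhom` implements *evolutionary
Khovanov homology* (EKH), a multiscale refinement in the spirit of
persistent homology: a link diagram is untangled crossing by crossing
along a filtration driven by a geometric weighting of its crossings, and
the Khovanov homology of the resulting tower of links is decomposed into
a barcode. Unknotted but geometrically entangled curves can carry highly
non-trivial barcodes, which is what makes the invariant useful as a
feature map for curve-shaped data.

## What is computed

For an oriented link diagram `L` with `n±` right/left-handed crossings:

* **Kauffman bracket** `⟨L⟩ = Σ_s a^(α(s)−β(s)) (−a²−a⁻²)^(γ(s)−1)` over
  the 2^n smoothing states, the **Kauffman polynomial**
  `X_L(a) = (−a)^(−3w(L)) ⟨L⟩`, the **Jones polynomial**
  `V_L(t) = X_L(t^(−1/4))`, and the q-normalized forms
  `Ĵ(L) = (−1)^(n−) q^(n+−2n−) ⟨L⟩_q` and `J = Ĵ/(q+q⁻¹)`, all in exact
  rational arithmetic.
* **Khovanov homology**: the cube-of-resolutions cochain complex with
  merge/split Frobenius differentials, homology over ℚ, 𝔽p (blockwise
  exact rank-nullity) and ℤ (Smith normal form; free ranks plus torsion),
  with the graded Betti polynomials `β_k(q)`, the Poincaré polynomial
  `Kh(L) = Σ_k qdim H^k · t^k` and the graded Euler characteristic
  `χ_q(L) = Ĵ(L)`.
* **Smoothing filtrations**: a weight per crossing — explicit, from
  planar inter-crossing distances (disk-growth radii), or from Gauss-code
  traversal order ("unzipping") — yields a tower of *a-indexed links*
  obtained by applying the oriented smoothing ρ at the thresholded
  crossings.
* **Evolutionary Khovanov homology**: the image ranks
  `H_{a,b}^k = im(H^k(more smoothed) → H^k(less smoothed))`, the
  `(a,b)`-evolutionary Jones polynomial, and the barcode of the
  persistence module (standard column reduction over the filtered
  complex), with each bar carrying its homological height and a
  stage-dependent q-degree profile (the inclusions shift q-degree by ±1
  per smoothing).
* **Curve input**: closure and planar projection of 3D polylines (xyz
  tables or PDB backbones reduced to P/Cα atoms), with seeded random
  rotations to escape irregular projections.

## Worked example

The left-handed trefoil with unzipping weights 1, 2, 3:

```python
>>> from ekhom import (fixture_table, WeightedLink, barcode,
...                    unnormalized_jones_q, build_complex, homology)
>>> trefoil = fixture_table()["trefoil_left"].diagram
>>> unnormalized_jones_q(trefoil).pretty()
'q^-1 + q^-3 + q^-5 - q^-9'
>>> for row in homology(build_complex(trefoil), "Z").to_rows():
...     if row["rank"] or row["torsion"]:
...         print(row)
{'k': -3, 'l': -9, 'rank': 1, 'torsion': ''}
{'k': -2, 'l': -7, 'rank': 0, 'torsion': '2'}
{'k': -2, 'l': -5, 'rank': 1, 'torsion': ''}
{'k': 0, 'l': -3, 'rank': 1, 'torsion': ''}
{'k': 0, 'l': -1, 'rank': 1, 'torsion': ''}
```

Integral Khovanov homology of the trefoil: four free classes and one
2-torsion class at height −2, q-degree −7. The weighted filtration
`L → ρ_{x1}L → ρ_{x2}ρ_{x1}L → ρ_{x3}ρ_{x2}ρ_{x1}L` untangles the
trefoil through the Hopf link into disjoint circles; its barcode:

```python
>>> w = WeightedLink(trefoil, {1: 1, 2: 2, 3: 3}, "ascending")
>>> for b in barcode(w).bars:
...     print(b.height, (b.stage_lo, b.stage_hi), b.degree_profile)
-3 (0, 0) {0: -9}
-2 (0, 1) {0: -5, 1: -4}
-2 (1, 1) {1: -6}
 0 (0, 3) {0: -3, 1: -2, 2: -1, 3: 0}
 0 (0, 3) {0: -1, 1: 0, 2: 1, 3: 2}
 0 (3, 3) {3: -2}
 0 (3, 3) {3: 0}
```

Exactly three bars span the window between the original trefoil (stage 0)
and the Hopf-link stage (stage 1), with q-degrees −1, −3, −5 at the
original link — the classes of `H(L)` that lift to the smoothed link —
and the `(0,1)`-evolutionary Jones polynomial is `q^-1 + q^-3 + q^-5`.
The short bar at height −2 with degree −6 is the Hopf-stage class that
dies (it maps onto the 2-torsion of the trefoil, hence vanishes over ℚ).

The same machinery from the shell:

```sh
ekhom jones fixture:trefoil_left
ekhom khovanov fixture:trefoil_left --coeff Z
ekhom ekh fixture:trefoil_left --mode unzip --out barcode.json
ekhom pipeline --source curve.csv --mode distance --out-dir results/
```

A four-crossing *unlink* fixture (`fixture:example31`) shows the
headline phenomenon: under one crossing ordering every filtration stage
stays unlink-trivial, while another ordering passes through the Hopf
link, whose `H_{2,2}` has rank 4 with two classes at height −2 —
non-trivial evolutionary homology for a topologically trivial link.

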