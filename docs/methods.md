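# Methods

## Model overview and assumptions

`statefate` treats differentiation as transport of a cell-density field
over a continuous state space.  The state space is a diffusion-map
embedding of log-scale expression (`log2(g+1)`), truncated at two
components and affinely rescaled per component to `[0, 1]` so that
coordinates, bandwidths and anchor states are comparable across datasets.
The homeostatic distribution `u_s` — an isotropic Gaussian KDE of the
embedded cells — is read as the carrying-capacity landscape of the
system, and `U = −ln u_s` as its quasi-potential.  Three processes move
density: drift toward the landscape (`v₁`), active differentiation along
the lineage graph (`v₂`, damped by a matured-cell feedback signal), and
isotropic diffusion `ν` for phenotypic instability.  Growth is logistic
against `u_s` with an apoptosis term capped at `d̄`.

Assumptions worth keeping in mind: the sampled cells are representative
of homeostasis (the KDE *is* the target state); two components suffice to
order stemness and the major myeloid split; rates are piecewise-constant
per annotated cell type; pseudotime `t` is dimensionless model time, not
wall-clock biology.

### Sign of the homeostatic drift

With `U = −ln u_s`, the advection–diffusion pair admits `u_s` as a
stationary state only for drift *down* the potential, `v₁ = −ν∇U`
(the Fokker–Planck/Boltzmann relation `u_s ∝ e^{−U/…}` with the sign
convention matched to `D = ν`).  The package therefore uses the negative
sign; stationarity of the landscape is verified by the test suite.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `ν` | phenotypic diffusivity | (rescaled coordinate)²/pseudotime | 0.005 |
| `r(θ)` | proliferation rate per type | 1/pseudotime | 0.2 (HSC) … 0.8 (matured) |
| `a(θ)` | self-renewal fraction | — | 0.9 progenitors, 1.0 matured |
| `κ` | feedback gain in `s = 1/(1+κm)` | 1/mass | 100 |
| `d̄` | apoptosis cap | — | 1 (pure logistic) |
| `h` | KDE bandwidth | rescaled coordinate | 0.05 |
| seed fraction | initial stem seed as share of local capacity | — | 0.1 |
| grid / edge mesh | discretization | — | 100×100, 100 pts per unit length |
| kNN `k`, PAGA threshold | graph abstraction | — | 15, 0.01 (pipeline) |

`r` and `a` per cell type, `κ` and `ν` are not identifiable from a single
expression snapshot; they were fixed once by the normal-hematopoiesis
calibration protocol: starting from the 10% stem seed, the per-type mass
fractions at `t = 100` must recover the homeostatic fractions in both
geometries (they land within ~2–3 percentage points).  The stem/matured
ordering (`r` increasing, `a = 1` in terminal compartments so matured
cells do not differentiate further) is the biologically meaningful part;
the exact values matter only through that calibration.  Large `κ` makes
the differentiation term strong while the matured compartments are empty
and negligible at homeostasis — without that feedback, the residual `v₂`
flux piles density past the terminal clusters (there is no death above
capacity when `d̄ = 1`) and distorts the equilibrium ratios.

The connectivity threshold is applied to the PAGA-style
observed/expected edge ratio.  The expected count scales with the total
number of kNN edges, so the informative scale of the ratio shrinks as
`N` grows; the pipeline default (0.01) keeps every true lineage edge at
`N = 3000` while the maximum-score spanning tree removes spurious weak
edges.  `build_metric_graph`'s own signature default remains 0.3, which
is appropriate at a few hundred cells.  Connectivity is scored on the
kNN graph of the full log-expression matrix (the usual input to graph
abstraction); only centroids and edge lengths live in the truncated
embedding.

## Synthetic data

The generator emulates what the downstream stages need from real
hematopoietic scRNA-seq: a rooted lineage tree (HSC → MPP → {Lymph, CMP →
{MEP → Ery, GMP → {Neu, Mo}}}) with homeostatic mass fractions (stem
~10%; MEP+Ery jointly 10%, making the leukemia-prone region a tenth of
the population); per-cell pseudotime increasing along the tree;
housekeeping, stemness-graded and branch-specific sigmoid gene programs
whose activation is centred inside each type's pseudotime band (so
trajectories are continuous across branch points); negative-binomial
counts (variance `μ + φμ²`, default `φ = 0.3`) with dropout (default
0.05).  It does **not** emulate per-gene count distributions of any real
dataset, batch effects, doublets, cell-cycle structure, or ambient RNA.
Passing tests therefore demonstrate that the machinery recovers known
structure from data of this geometry and noise class — not robustness to
every artifact of real experiments.

## Numerics

* **Fluxes.**  Conservative finite volumes with two flux options.  The
  default is an exponential-fitting (Scharfetter–Gummel) flux
  `F = (ν/Δx)[B(−Pe)u_L − B(Pe)u_R]`, `B(x) = x/(eˣ−1)`, with the `v₁`
  part of the face velocity taken from potential differences
  `−ν(U_{i+1}−U_i)/Δx`.  This is positivity-preserving, reduces to
  first-order upwind at large cell Péclet number, and makes the KDE
  landscape an *exact* discrete stationary state of the drift–diffusion
  pair — the calibration then measures the model, not grid error.  Plain
  first-order upwind plus centred diffusion is available
  (`scheme="upwind"`) and is the scheme whose convergence order the test
  suite checks.
* **Time stepping.**  Explicit Euler under the guard
  `dt ≤ 0.9·min(Δx²/4ν, Δx/max|V|)`; a step violating the bound raises
  with the admissible value.  `s(t)` uses the state at the beginning of
  the step.  Undershoots below zero within round-off are clipped and
  counted.
* **Boundary.**  Zero Dirichlet ring on the grid (ghost value 0); a
  reflecting test mode exists for exact-conservation checks.  Because
  extreme cells sit on the embedding's bounding box, the 10%-padded
  default grid carries a little density at the rim; the advection-only
  stationarity property is exact only when the rim density is negligible
  (the property tests pad by 0.25 for that reason), while in full runs
  the reaction term refills any rim leakage.
* **Graph junctions.**  One shared unknown per node with a
  finite-volume node cell equal to the sum of adjacent half-cells:
  density continuity holds by construction, flux balance discretely, and
  with `R = 0` total mass is conserved to machine precision (every face
  flux appears once with each sign).  Terminal nodes reflect because no
  exterior face exists.  One-sided differences at nodes use interior
  values.  Node capacity/rates average the adjacent edge endpoints.
* **Potential floor.**  `U` is floored via
  `u_s ← max(u_s, 10⁻¹²·max u_s)` so it stays finite off-support.
* **Edge restriction.**  Grid fields are bilinearly interpolated along
  straight centroid-to-centroid segments; the restricted `u_{s,k}` is
  renormalized to unit total mass over the graph so both geometries
  measure mass on the same scale.
* **Eigenvector conventions.**  Diffusion maps use α = 1 density
  normalization; eigenvector signs are fixed so the root compartment
  sits at the low end of each component (sign is otherwise arbitrary);
  the Nyström raw coordinate is `p_row·ψ_l`, which equals the
  eigenvalue-scaled training coordinate exactly at training rows, so the
  affine `[0,1]` rescale makes projection consistent to machine
  precision.  Re-embedding versus extension for perturbed cells is a
  genuinely open choice; the extension was chosen because it keeps the
  normal space fixed while perturbed cells move through it.

## Leukemia scenarios: design choices

* **Capacity increase (MEP/Ery).**  Implemented as
  `u_s ← u_s(1 + (fold−1)w)` with `w` the region's KDE-ratio weight
  field (graph: half-edges of the region's nodes), after which `U`, `∇U`
  and hence `v₁` are rebuilt.  The measured region fold at the new
  equilibrium is diluted below the nominal fold by the soft region
  boundary (`∫u_s w² < ∫u_s w`), landing near 8–9 for fold 10.
* **Leukemic fraction.**  Three measures are reported: the soft
  weight-field mass share, the graph's closest-node share, and a
  closest-centroid classification on the grid.  The classification
  measure is the headline one because the leukemic population includes
  the emergent abnormal neighbours of MEP/Ery, not only density under
  the original soft weights; with the 10% homeostatic leukemic region it
  passes 50% after the 10-fold increase.
* **Aberrant advection.**  `v_aml1` smooths per-cell displacement
  vectors `P(g̃)−P(g)` onto the grid by Nadaraya–Watson regression;
  `v_aml2 = f_θ*(θ)·(θ*−θ)/‖θ*−θ‖` aims Gaussian-weighted unit vectors
  at a target state (zero vector at `θ*` itself).  The default `θ*` is
  chosen deterministically as the unoccupied grid pocket (clearance
  ≥ 2h from every cell) closest to the MEP/Ery centroid — an empty state
  adjacent to the occupied landscape, which the field can actually
  reach.  `σ² = 0.05` by default.  Both composition forms are exposed:
  `V = v₁ + c_aml·v_aml` (default) and `V = c_aml·v_aml` alone
  (`include_v1=False`).
* **Capacity of the emergent abnormal state.**  Multiplying the
  near-zero `u_s` at an unoccupied `θ*` by a fold is a no-op, so the
  field scenario raises capacity the other way the death term allows:
  the apoptosis cap is lowered along the Gaussian profile,
  `d̄(θ) = 1 − w(θ)(1 − 1/fold)`, reaching `1/fold` at `θ*`.  Cells
  collected at the abnormal state then keep proliferating at rate
  `r(1−d̄)` regardless of crowding, which is what lets total mass grow
  past the normal capacity; without it, mass accumulated at `θ*` can
  neither die nor grow (`d` capped at 1) and the total stalls near the
  normal level.  Growth is then unbounded, so scenario runs stop once
  total mass exceeds 500× the pre-AML value and the reported maxima are
  lower bounds.  The over-proliferation boost `r_aml f_θ*(θ)·u`
  multiplies growth near `θ*` and reaches the stop threshold much
  earlier (it is interpreted as a growth-rate addition; an additive
  source independent of `u` was considered and rejected because it
  creates mass where no cells ever arrive).
* **Scenario timeline and baselines.**  The AML switch happens at
  `t = 10` of the normal recovery (seeded at `t = 0` with 10% of local
  capacity in the stem clusters; the seed's total mass is
  `0.1 × ∫u_s w_stem`).  Field-scenario mass ratios are reported
  relative to the pre-AML total `ρ(t_onset)`.
* **Differentiation block.**  Graph: advective velocity clamped to
  `min(V, 0)` on edges entering blocked nodes.  Continuum: the component
  of `V` with positive projection onto the blocked cluster's
  weight-field gradient is removed.

## Problem sizes

The acceptance script uses the reference configuration (3000 cells, 200
genes, 100×100 grid, 100 points per unit edge, `t = 100` calibration)
and completes in about two minutes on one CPU.  The pytest suite shares
one smaller fitted pipeline (800 cells, 120 genes, 60×60 grid, 60 points
per unit) across tests so the whole suite stays under a minute; the
properties checked are size-independent and the acceptance configuration
reproduces them at scale.

## Known limitations

* Truncation at two components merges lineages that separate only in
  higher components (Lymph overlaps MPP in the synthetic default);
  per-type weights soften but do not remove this.
* The calibration fixes ratios, not absolute time scales; pseudotime is
  anchored to the recovery protocol, and rates from the literature would
  need a unit conversion before use.
* `d̄ = 1` means overshoot above capacity cannot decay; scenarios that
  need decay must set `d̄ > 1` explicitly.
* The graph geometry cannot represent states off its edges; emergent
  abnormal states are a continuum-only analysis, as the comparison
  intends.
* The PAGA-ratio threshold is scale-dependent (see above); at very
  different `N` it may need adjusting along with the kNN `k`.
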