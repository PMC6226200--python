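# Methods

## The community steady-state model

gutcom models a microbial community at balanced growth: every species
grows at the same specific rate `μ` (1/h) while holding a fixed fraction
`p_k` of total community biomass.  Per-gram flux bounds (mmol/gDW/h)
therefore scale with abundance — a species at abundance `p_k` contributes
aggregate fluxes `V^k` (mmol/h per unit total biomass) bounded by
`l^k_j p_k ≤ V^k_j ≤ u^k_j p_k` — and a shared extracellular lumen couples
the species: each species exchange reaction moves a metabolite between the
species and the lumen (secretion positive), and each lumen metabolite has
exactly one community exchange reaction bounded below by minus the diet's
maximum uptake rate and above by a secretion cap.

Key consequences of this construction:

* Because bounds scale linearly with `p_k`, abundance caps do not limit
  per-gram physiology; they limit how much of the community a species can
  be.  A one-species community therefore reproduces the species'
  standalone FBA growth rate exactly (asserted to 1e-6 in the tests).
* Total biomass is normalized to 1, so single-species diet rates
  (mmol/gDW/h) and community diet rates (mmol/h per unit biomass) share
  one scale.
* At fixed `μ` the model is an LP whose feasible growth rates form an
  interval `[0, μ_max]`; `μ_max` is found by bisection on the query
  "can total abundance reach 1 at this μ?".

## Diet and crossfeeding policy

Species-level uptake caps combine three sources, in order:

1. a metabolite the diet supplies: `min(model transporter cap, diet rate)`
   — the min preserves the species' own transport limits;
2. a crossfed metabolite (amino acids and common fermentation byproducts):
   raised to at least the common crossfeed bound, 10 mmol/gDW/h by
   default, reflecting the absence of species- and metabolite-specific
   uptake kinetics;
3. blocked SCFAs (butyrate and propionate analogs): uptake 0 for every
   species, on the assumption that host absorption outcompetes microbial
   re-consumption.  Secretion bounds are untouched, so net SCFA synthesis
   stays reportable.

Everything else (neither fed nor crossfed) cannot be taken up.  The
community uptake bound is the diet rate (0 if absent); the community
secretion bound is a large cap (1000 mmol/h per unit biomass) — the
formulation needs *some* finite cap to exclude unbounded LPs, and 1000 is
far above any attainable flux in the fixtures.  Diets are plain two-column
TSV; models are SBML Level 3 + FBC (read/written through cobrapy) or an
equivalent flat JSON dialect.

## Numerical choices

* LPs are solved with HiGHS through `scipy.optimize.linprog`,
  single-threaded and deterministic, with primal/dual feasibility
  tolerances tightened to 1e-9.
* Bisection on `μ`: at most 60 iterations to a tolerance of 1e-6 1/h.
  The upper bracket starts at the best single-species growth under the
  crossfeed-relaxed bound templates (lumen balance dropped) and doubles
  until infeasible.  At the fixed point the LP is re-solved with
  `Σ p = 1` to extract a solution.
* Accepted solutions must satisfy `|Σ p − 1| ≤ 1e-4` (the campaign's
  discard rule) and metabolite-balance / growth-coupling residuals
  ≤ 1e-6 (`assert_solution`).
* Degenerate optima (non-unique abundance splits) are returned as the
  solver's vertex; uniqueness is decided only by abundance FVA, which at
  the toy fixtures' optima collapses to `p_min = p_max`.
* Abundance FVA fixes growth as an **equality** at `f·μ_max`.  Possibility
  is therefore not guaranteed monotone in `f`, so coexistence cutoffs are
  reported on an explicit grid (10%…99.99% by default) together with a
  monotonicity flag, rather than by bisection.  The possible/essential
  threshold ("exceeds 1%") is strict.
* ATPM (non-growth maintenance) is a hard lower bound: a diet that cannot
  support it makes the LP infeasible, which is reported distinctly from
  zero growth.  Maintenance tuning bisects the ATPM bound until standalone
  growth hits the target (±1e-6), returning 0 with an "unattainable" flag
  when even zero maintenance cannot reach it, and the largest feasible
  drain when the target is 0.

## The tradeoff sampler

FVA maxima `p_max` at a growth fraction `f` are converted to randomized
upper bounds `p_U_j = min(1, 2 r_j p_max_j / Σ_i p_max_i)` with
i.i.d. `r_j ~ U[0,1]`.  The factor 2 makes the unclamped bounds average to
the normalized FVA maxima (`E[2r] = 1`; verified to 2% over 1e4 draws).
Whole vectors are redrawn (up to 1000 attempts) until `Σ p_U ≥ 1`, which
preserves the distribution conditional on feasibility rather than
rescaling individual draws; clamping at 1 reflects that abundances are
fractions.  The default campaign runs 900 cases over fractions 0.60–0.99,
weighted toward low fractions (150/150/125/125/100/100/100/25/25); tests
and the acceptance analysis use a reduced schedule of 10 cases per level.
Each case draws from an RNG seeded by hashing (master seed, case index),
making campaigns bit-reproducible and order-independent; the discard rule
is applied to the returned solution's abundance sum.  The bounds are
heuristic — they do not guarantee Pareto-optimal growth/diversity pairs.

## Metrics

Equitability `D_com = (1/N)/Σ p_i²` (inverse Simpson scaled by species
count) ranges from 1/N to 1; richness counts species above 1% abundance.
SCFA fractions divide each tracked SCFA's net community synthesis by the
summed synthesis of the acetate/butyrate/propionate triple and are flagged
undefined when nothing is produced.  Crossfeeding matrices hold each
species' lumen-exchange flux per crossfed metabolite (uptake negative);
column sums equal community exchange fluxes by lumen conservation, and
|rate| statistics include the zero entries of non-exchanging species (a
documented choice; the averaging is entrywise across solutions before the
statistics).  Growth-fraction bins are half-open `[c−0.01, c+0.01)` around
15 centers 0.71…0.99 (width 0.02 inferred from the centers' spacing; a
fraction exactly on the first left edge belongs to the first bin).  The
tradeoff line is ordinary least squares of `D_com` on growth fraction
below 0.97.  "Correlates with single-species growth" is implemented as
Spearman rank correlation with a seeded permutation p-value (1e4
permutations), robust to the many exactly-zero abundances of optimal
communities.

## Synthetic communities

The generator emulates the structural features the analyses rely on, not
real stoichiometry: each toy species imports one substrate, converts it to
biomass at a fixed yield with byproducts secreted in proportion to growth,
and pays maintenance as a substrate drain.  Standalone growth is
`yield · (min(cap, diet) − ATPM)` in closed form, zero-growth-at-
maintenance species set cap = ATPM, and obligate crossfeeders import a
byproduct absent from the diet.  The 3-species `toy3` fixture is fully
solvable by hand: unconstrained `μ_max = 0.4` as a monoculture of the fast
species; capping it at 0.5 gives `μ_max = 0.3` with a non-unique
partner split (both the crossfeeder's uptake cap and the slow specialist's
transporter cap bind at exactly 0.3).  The 8-species `demo8` fixture adds
three tagged SCFA analogs with distinct producers, two obligate
crossfeeders, and a zero-growth maintainer; its optimum is a monoculture
(`μ = 0.5`), so campaigns display the growth-diversity tradeoff, and its
discrete spectrum of single-species rates makes achieved campaign growth
fractions cluster just below 0.76/0.80/0.84/0.90 — the 0.75-, 0.79- and
0.89-centered bins are the well-populated ones.

Because biomass is a single lumped reaction, the toys have no internal
alternative pathways: passing tests demonstrate the correctness of the
community formulation, the FVA/sampler machinery and the metrics, not the
realism of genome-scale reconstructions (real models add thousands of
reactions, curved tradeoff fronts and metabolite competition the toys do
not emulate).

## Verification strategy

Every load-bearing quantity has an independent route: community optima and
FVA ranges are checked against a brute-force scan of the abundance simplex
(step 0.01) that eliminates abundance variables into flux bounds and
solves with a different solver (GLPK) than the implementation (HiGHS);
fixture growth rates are checked against closed forms; conservation
invariants are asserted on every accepted solution the suite produces.
Problem sizes were chosen so the whole pipeline (including two campaign
runs for the determinism check) completes in a few minutes on one CPU.

## Known limitations

No pH or thermodynamic constraints, no dynamic (dFBA) extension, no
reaction-level FVA, no true Pareto front for the growth-diversity
tradeoff, and no attempt to reproduce curated genome-scale
reconstructions — those are inputs, not outputs, of this package.
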