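# Methods

## Model family

Three food-web modules share the same bioenergetic core.  State
variables are biomass densities (same arbitrary density unit throughout;
100 corresponds to the reference algal carrying capacity).  Time is in
days, temperature in °C, body mass in μg dry mass.

**Resources.**  Two algal resources renew semichemostatically,
`dRj/dt = δ(Rjmax(T) − Rj) − grazing`.  There is no direct
resource–resource competition; warming effects on the algae are carried
entirely by the carrying capacities `Rjmax(T) = Rref·exp(−c_j (T − 20))`.
Both curves pass through `Rref` at 20 °C, so when the resource
interaction is on (`c_L > c_S`) the large resource dominates below 20 °C
and the small resource above — the crossover is pinned by construction
and re-solved numerically from the curves as a self-check.

**Consumers.**  Every compartment (a species, or one life stage) is
characterized solely by its body mass.  Feeding is an encounter-weighted
Monod (type II) response: with diet weights `(wS, wL)` the effective
food density is `E = wS·RS + wL·RL`, total mass-specific intake
`Imax·E/(H + E)`, split across the two resources in proportion to their
weighted densities.  An alternative mode saturating each resource
independently is available as a configuration switch
(`functional_response_mode="independent"`); all shipped analyses use the
shared-saturation default.  Net biomass production is `ν = β·I − m`;
negative ν is starvation loss.  Background mortality μ is constant and
mass-independent.

**Stage structure.**  Juvenile and adult compartments of one species are
coupled by food-dependent maturation and reproduction in the standard
two-stage biomass approximation: maturation rate
`γ(ν_J, μ_J) = (ν_J − μ_J)/(1 − z^(1−μ_J/ν_J))` with `z = M_J/M_A`,
extended continuously through `ν_J = μ_J` (limit `μ_J/ln(1/z)`) and
clamped to zero for starving juveniles; adults never grow — positive
adult production appears instantaneously as new juvenile biomass, while
negative adult production shrinks the adult stage.

**Diet preference.**  In Communities I and II the small species/stage
weights the resources `(p, 1−p)` and the large one `(1−p, p)` with
`p ∈ [0.5, 1]`: identical diets at 0.5, disjoint at 1.  Community III
spans three size classes (0.1 / 1 / 10 μg); the extreme classes are
specialists (JS on RS, AL on RL) and the two equal-mass middle classes
(AS, JL) blend as `((1±p)/2, (1∓p)/2)` with `p ∈ [0, 1]`, making their
diets literally identical at p = 0 and disjoint at p = 1.  The two
statements "no intraspecific competition at p = 0" and "AS and JL diets
identical at p = 0" cannot both hold exactly with two resources; the
default mapping honours the second and weakens, rather than eliminates,
intraspecific overlap.  A `swap` mapping (AS `(p, 1−p)`, JL `(1−p, p)`),
under which intraspecific overlap vanishes at p = 0 instead, is a
configuration switch.

## Mass and temperature scaling

Whole-organism rates scale as `M^0.7`; the biomass equations therefore
use mass-specific rates `∝ M^(0.7−1)`, so that same-mass compartments
are dynamically identical per unit biomass.

* Metabolism: `m = m0 · M^(e(T)−1) · exp(E_a/k (1/T_ref − 1/T))` with
  activation energy `E_a = 0.56 eV`, `T_ref = 20 °C` (Kelvin inside the
  exponential).  By default `e(T) = 0.7`; with the metabolic-exponent
  interaction on, `e(T) = 0.7 + 0.01·(T − 20)` per °C, an alternative
  interaction mechanism that raises the relative maintenance cost of
  large consumers when warm.
* Maximum ingestion: `Imax = i0 · M^(0.7−1) · u(T − T_opt(M))` with a
  unimodal kernel u.  The default kernel is Gaussian with scale
  `thermal_width` (12 °C); a left-skewed variant (half the width on the
  warm side, emulating steep supra-optimal decline) is a switch.  The
  symmetric Gaussian is the simplest shape satisfying every constraint
  the analyses rely on; none of the reported behaviours requires
  asymmetry.
* Thermal optimum: `T_opt(M) = 20 − 4·log10(M)` °C when the optimum–size
  interaction is on (24/20/16 °C at 0.1/1/10 μg), flat 20 °C otherwise.

## Parameters

| parameter | symbol | default | unit | rationale |
|---|---|---|---|---|
| supply rate | δ | 0.1 | d⁻¹ | slow algal turnover relative to feeding |
| carrying capacity at 20 °C | Rref | 100 | density | sets the biomass scale |
| capacity decline, small / large | c_S, c_L | 0.02 / 0.06 | °C⁻¹ | small-cell dominance of warm algal communities; equal curves (0.02) with the interaction off |
| half-saturation | H | 40 | density | intake half-saturated well below carrying capacity |
| conversion efficiency | β | 0.6 | – | typical zooplankton assimilation×production |
| background mortality | μ | 0.01 | d⁻¹ | small against metabolism (0.05 at reference) |
| metabolic coefficient | m0 | 0.05 | d⁻¹ | ~5 % body mass per day at 1 μg, 20 °C |
| ingestion coefficient | i0 | 2.979 | d⁻¹ | solved from the p = 1 invasion condition so the 1 μg consumer's upper thermal limit is 41.2 °C |
| thermal width | – | 12 | °C | broad performance curve; persistence from 0 °C to the low 40s |
| mass ratio | z | 0.1 | – | juvenile 1/10 of adult mass (masses 1 and 10 μg; 0.1/1/10 in Community III) |

Values carry a provenance tag.  The shipped defaults are
`calibrated-default`: chosen once as realistic pelagic-plankton values
and pinned to the printed anchors (optimum triplet, 0.56 eV, exponent
0.7, 20 °C crossover, the 41.2 °C small-consumer limit, the qualitative
warming responses of each community).  A user-supplied transcription of
the original parameter table (`transcribed-table`) is loaded verbatim and
validated against the same anchors, with violations listed.

## Equilibrium analysis

Equilibria are found by forward integration (LSODA, rtol 1e-10) in
doubling time windows up to 1e5 days, followed by a Newton-type polish
(`scipy.optimize.root`, hybr) on the compartments above the extinction
threshold `ε = 1e-9·Rref`; sub-threshold compartments are truncated to
exactly zero and the reduced system re-verified.  Forward integration
keeps the solver on attractors; the polish brings `max|rhs|` to
round-off (accepted below 1e-8 × state scale).  A bounded,
non-contracting trajectory is reported as a non-equilibrium attractor
with its time-averaged state rather than raised as an error; none of the
shipped analyses encounters one.

Stability combines (i) eigenvalues of the central finite-difference
Jacobian restricted to persistent compartments (stable iff all real
parts < −1e-8) and (ii) a transversal invasion check for extinct
compartments — an unstructured consumer invades when `ν − μ > 0` at the
ambient resources, an extinct stage pair when the dominant eigenvalue of
its 2×2 linearization is positive.  Without (ii), multistart can report
boundary states (e.g. a one-species state inside the coexistence region)
as spuriously stable.

Multistart search uses canonical starts (standard inoculum,
juvenile-heavy 100:1, adult-heavy, low and high biomass) plus seeded
log-uniform random states, de-duplicated at relative L∞ distance 1e-4.
Temperature sweeps warm-start each equilibrium from its neighbour
(natural-parameter continuation) with extinct compartments re-seeded at
1e-3·Rref so invasion boundaries are detected; forward and backward
sweeps are compared and both branches reported where they disagree
(hysteresis).  Boundaries in the (T, p) plane are located by sign-change
bracketing on a grid and refined by bisection in T (default 0.01 °C).

Mean individual body mass is `Σ B_i / Σ (B_i/M_i)` over consumer
compartments — the biomass model tracks no numbers, so `B/M` is the
implied abundance of a compartment with individual mass M.
`dominance_shift_temperature` is direction-aware: it reports the
warming-driven flip of interest (toward the smaller species, or toward
adults), since a reversal in the opposite direction can exist elsewhere
on the gradient.

## Review fixture

The literature-summary table is synthetic: 164 observation rows whose
level × outcome marginals equal the published counts exactly
(interspecific 91/14/18, intraspecific 20/17/4).  The
experimental/observational split within each cell is *not* published at
that resolution; the fixture assigns it with fixed fractions (70 %
observational among interspecific smaller-shifts, 35 % among
larger-shifts, 50 % elsewhere), consistent with the qualitative
statement that the smaller-shift excess is strongest in observational
studies, and shuffles row order with the seed.  The 136-article count is
attached as metadata only; observations are the analysis unit.  Passing
tallies demonstrate bookkeeping, not anything about the underlying
literature.

## What the synthetic scenarios do and do not show

The generator reproduces the study conditions — community composition,
mass classes, preference ranges, interaction switches — not field data.
Passing tests show that the mechanisms (stage-specific competitive
asymmetry reversed by size-dependent warming) produce the claimed
qualitative shifts in this model family; they say nothing about
seasonal succession, size-selective predation, individual-level shrinking
(deliberately excluded), or food webs richer than two resources and
three consumer size classes.

## Findings specific to this parameterization

* With mass-independent background mortality the small consumer is
  always the marginally better competitor (equal-R* neutrality is broken
  by μ), so even without any size–temperature interaction a hairline
  dominance reversal toward the small species occurs within ~1 °C of
  joint extinction (~40.3 vs 41.3 °C).  The substantive contrast stands:
  the *mid-range* flip (23.6 °C at p = 0.85) requires the interaction.
* In Community III the decline of mean body mass under coexistence holds
  at low-to-intermediate preference (monotone at p = 0.3; endpoint
  decline at p = 0.5, the midpoint of the range, where the shipped
  analyses evaluate it).  At high preference (≥ 0.7) the intraspecific
  shift toward adults outweighs the species shift near the warm edge of
  coexistence and mean mass turns back up before the large species is
  lost.
* Bistability of the stage-structured consumer appears for p ≳ 0.85 at
  warm temperatures, and vanishes when μ is raised to 0.05 d⁻¹.

## Problem sizes

Shipped analyses and tests use grids chosen for resolution adequate to
the claims: boundary scans at 1–2 °C spacing refined by bisection to
0.01–0.05 °C, sweeps at 0.25–1 °C steps, plane rasters up to 21 × 6
cells, multistart with 5 canonical plus 4–8 random starts, and 100
random draws for the closed-form equilibrium cross-check.

## Known limitations

Continuation of unstable branches, codimension-2 bifurcation
classification, cycles (none arise at the defaults), individual-level
size change, and more than two resources or consumer species are out of
scope.  The exact unimodal ingestion kernel and the original numeric
parameter table are not reproduced; all quantitative boundaries other
than the pinned anchors therefore characterize the calibrated defaults,
not the original parameterization.
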