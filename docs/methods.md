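# Model and methods

`lignosacc` simulates the enzymatic saccharification of a lignocellulose
microfibril as a continuous-time Markov jump process and calibrates the
model to saccharification time-courses and ssNMR crystallinity indices.
This note records the model, its assumptions, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Substrate model

A microfibril is a bundle of parallel polymer chains on a triangular
(hexagonally close-packed) lattice cross-section:

- **Core**: 18 cellulose chains (24 or 36 in the alternative modes),
  arranged as a close-packed 3 x 6 block, each a linear chain of
  `length_fibril` glycosidic bonds (default 200, i.e. 201 glucose
  units).  The block has a well-defined boundary; "outward" neighbour
  relations follow layer order and, within a layer, distance from the
  bundle axis (ties broken lexicographically so the relation is acyclic).
- **Inner shell**: one ring of lattice slots around the core, filled
  with hemicellulose segments (length drawn uniformly from 10-50
  monomers) placed at random free positions until the composition-derived
  monomer budget is met.
- **Outer shell**: a second ring holding lignin monolignol runs, placed
  the same way.  Unfilled slot positions are gaps.

Monomer budgets derive from the measured mass composition: hemicellulose
(matrix polysaccharide) and lignin monomer counts equal the cellulose
monomer count times their mass ratios to cellulose, with equal mass per
monomer assumed across polymers.  The acetate fraction is carried but
unused.  Because only ratios to cellulose enter, compositions whose
totals deviate from 100% need no renormalisation.  For the pure
commercial celluloses the apparent lignin of the composition assay is an
artifact and is zeroed; the AVICEL + Organosolv-lignin mixture (1:1 by
mass) instead halves the AVICEL fractions and sets lignin to 0.5.

**Crystallinity.** Each chain receives exactly `round(CF x n_bonds)`
crystalline bonds.  Amorphous bonds sit at the chain ends (split evenly,
odd remainder to the left end), except that a fraction `N_defect` of
outer chains embeds a fraction `mu_defect` of its amorphous allotment as
1-3 contiguous interior defect patches, placed uniformly without overlap
inside the crystalline mid-region.  Crystalline bonds are digested at a
rate scaled by the digestibility ratio `r_ca` in [0, 1] (0: indigestible,
1: same as amorphous).  Hemicellulose crystallinity is assigned
independently per `CF_hemi` (not conditioned on lattice contact with
cellulose, which the data cannot constrain).

The substrate-average crystallinity compared against the ssNMR
crystallinity index is the crystalline fraction of carbohydrate bonds
(cellulose + hemicellulose); lignin has no crystallinity in the model,
so it is excluded even though the index is measured on total biomass.

**Free-floating mode.** For dissolved substrates the same polymer
inventory is built without a lattice: every bond is exposed, and lignin
enters only as a dissolved adsorber pool.

## Accessibility and steric hindrance

Enzymes are hard spheres of radius `r_enzyme` (default 2.5 nm) against
monomers of radius 0.6 nm, giving a steric window of
`h = ceil(r_enzyme / (2 r_monomer))` monomers (3 at the defaults).
Accessibility is solvent-connected reachability:

- a site on a surface chain (outer shell) is always open;
- a shielded site is open once some outward-neighbour chain is **vacant
  and itself open** over the full window around that site, i.e. the
  opening is wide enough for the enzyme and connected to the solvent.

Both vacancy (monomers leave the lattice only when solubilised) and
openness are monotone, so open flags are set once and propagated inward;
an incremental worklist maintains them and a from-scratch fixpoint serves
as the test oracle.  This makes enzyme size an access limiter: larger
enzymes need wider openings, which both delays digestion and lowers the
48-h yield of shielded substrates.  A bound cellobiohydrolase also
excludes other enzymes within `h` monomers on its own chain and on
laterally adjacent chains (its sphere covers a surface patch).

Lignin sites never vacate, so material under a lignin run is reachable
only around its edges — lignin caps the attainable yield as well as
slowing the approach to it.

## Enzyme cocktail and events

Four activities act on the substrate (default proportions 0.135 EG,
0.353 CBH, 0.100 BGL, 0.412 XYL of 50 molecules per microfibril):

- **EG** (endoglucanase) cuts any exposed cellulose bond except the two
  endmost at each fragment end.
- **CBH** (cellobiohydrolase) attaches to an accessible free cellulose
  fragment end (either end; reducing/non-reducing ends are not
  distinguished) and processively releases cellobiose at `k_CBH_proc`
  per hour, scaled by `r_ca` when the next bond is crystalline.  It
  detaches when fewer than three monomers remain or the path ahead is
  shielded or sterically blocked.
- **BGL** (beta-glucosidase) splits one cellobiose into two glucose.
- **XYL** (hemicellulase, treated as non-specific) cuts any exposed
  hemicellulose bond, endmost included.

Fragments of one or two monomers are soluble and leave the lattice
immediately (glucose / cellobiose for cellulose; counted as xylose units
for hemicellulose).  Glucose equivalents are conserved exactly:
remaining lattice cellulose + 2 x cellobiose + glucose is constant.

**Propensities.** Bond-cleaving activities use a pseudo
Michaelis-Menten form shared per target: each eligible target of enzyme
`y` contributes `3600 kcat_y [y]_eff / (Km_y + S_y)` per hour, with
`S_y` the eligible-target count.  This reduces to mass action for
`S << Km` and caps at the turnover rate for `S >> Km`.  Michaelis
constants are interpreted in substrate-count units at microfibril scale:
a single simulated microfibril has no rigorous volume, and the
calibration absorbs the concentration-to-count scale.  CBH attachment
and processive cleavage are parameterised separately (an attachment
kcat/Km pair plus a processive rate).

**End-product inhibition.** Glucose and cellobiose reduce the effective
cellulase concentrations; cellobiose inhibits EG and CBH (competing for
the cellulases that share it), glucose inhibits EG, CBH and BGL:

    [EG]  = [EG]0  - w_EG^cbs  [EG]0 [cbs] / ([EG]0 + [CBH]0 + [cbs])
                   - w_EG^glc  [EG]0 [glc] / ([EG]0 + [CBH]0 + [BGL]0 + [glc])

and analogously for CBH and (glucose only) BGL.  Inhibitor pools are
counts on the same scale as enzyme counts.  At extreme inhibitor loads
the expressions can go negative; effective concentrations are clamped at
zero (regime outside the model's intended range, noted in logs).

**Lignin adsorption** is re-equilibrated deterministically after every
event rather than simulated as timed binding events, because only the
stoichiometry (one enzyme per `lignin_adhesion_rate` = 100-350 exposed
monolignols) is specified, not rate constants.  Sequestered enzymes are
removed from the nominal counts, split across types in proportion to
abundance, before the inhibition equations apply.

## Stochastic simulation

Exact direct-method SSA.  The event catalogue is kept as indexed sets
per event class (EG amorphous/crystalline, XYL amorphous/crystalline,
CBH attach, CBH step by next-bond state, BGL), updated only around the
applied event's neighbourhood; within a class all targets share one
propensity, so class selection is an 8-way categorical draw and member
selection is uniform.  Waiting times are exponential in the propensity
sum.  A run ends at the time horizon (default 48 h), at an event budget,
or when the propensity sum reaches zero (all digestible, reachable
substrate consumed).

Trajectories sample the step-function pools at requested output times by
linear interpolation.  Reproducibility: one master seed; replicate
streams derive via `numpy` `SeedSequence.spawn`; identical seeds give
bit-identical trajectories.

## Default kinetic constants

The calibrated kinetics behind the study's fitted curves are not
published (only admissible ranges), so the package ships one documented
generic default set, chosen so that a pre-treated lignocellulose
substrate digests sigmoidally on the 48-h assay scale and cellobiose is
cleared by BGL rather than accumulating (as observed experimentally):

| parameter | default | units |
|---|---|---|
| kcat_EG, kcat_XYL | 0.001 | 1/s |
| Km_EG, Km_XYL | 500 | targets |
| kcat_CBH (attach) | 0.001 | 1/s |
| Km_CBH (attach) | 500 | ends |
| k_CBH_proc | 10 | cleavages/h |
| kcat_BGL | 1.0 | 1/s |
| Km_BGL | 100 | cellobiose count |
| all omega | 0.2 | - |
| r_enzyme | 2.5 | nm |

In-silico experiments therefore assert directions and orderings, not the
absolute curves of the original figures.

## Calibration

`SaccharificationModel.fit` runs a generational random search.  Each
generation perturbs the incumbent parameter vector (multiplicative
log-normal steps for rate-like parameters, additive uniform steps for
fractions, reflected at the bounds), evaluates `n_subgenerations`
candidates, and adopts the best candidate only if it improves the
incumbent; the global minimum over all generations is the fit.  The
objective is

    sum_samples sum_timepoints (sim_mean - data_mean)^2
      + lambda * sum_samples (CF_avg - CI)^2        [percent scale]

with `sim_mean` a replicate average and `lambda` scaled automatically so
the crystallinity penalty matches the curve term at initialisation
(overridable).  Kinetic and inhibition parameters are shared across the
samples of a model (one pre-treatment condition); CF and r_ca are per
sample.  One fixed evaluation-seed block (common random numbers) makes
the objective deterministic within a fit, so the accepted-objective
trace is non-increasing by construction; the price is that the fit
conditions on one noise realisation, acceptable at the replicate counts
used.  The originating description of the acceptance rule speaks of the
sub-generation with the lowest "variance"; the surrounding procedure
compares "differences" between simulation and data, and this package
implements lowest objective.

## Synthetic data

`datasets.generate_synthetic_timecourses` runs the simulator at known
true parameters, samples 8 assay times over 48 h (0.5, 1, 2, 4, 8, 16,
24, 48), and adds independent Gaussian observation noise (default sd 2
percentage points, 3 replicates), clipped to [0, 100].  It emulates the
assay layout of the wet-lab protocol but not: pipetting/dilution error
structure (noise is i.i.d. Gaussian), substrate heterogeneity between
replicates (all replicates share the true substrate parameters), or
inter-batch enzyme-activity drift.  Passing the recovery tests therefore
shows the estimator is consistent under the model, not that the model is
correct for real biomass.

## Problem sizes in tests and the acceptance script

Simulation studies run on reduced substrates chosen as the package's
standard test sizes: direction sweeps use a lignin-rich untreated-wood
composition with 50-bond chains and a cocktail of 12 molecules
(preserving the enzyme:substrate ratio of the full-size system, 50
molecules per 200-bond fibril); parameter recovery uses free-floating
30-bond chains, a 35-generation x 8-candidate search with 6-replicate
objectives, repeated over 5 master seeds.  The digestibility ratio is
only weakly identified near the top of its range — once crystalline
bonds digest within the assay window, further increases barely change
the curve — so its recovery is assessed on a multiplicative (factor)
scale, and CF, which the crystallinity penalty pins directly, is
recovered much more tightly.  Sweep grids are spaced widely
(e.g. radii 2.5, 7.5, 15, 25 nm) so that directional orderings of
20-replicate means are resolved well above replicate noise.

## Known limitations

- The lattice is a cross-section stack of straight chains: no chain
  kinks, twist, or explicit hydrogen-bond network, and no cellulose
  polymorph distinction.
- Hemicellulose chemistry is generic xylan; the mixed-linkage-glucan
  flag is accepted but maps to identical kinetics.
- Lignin never desorbs from enzymes and is never degraded; its coverage
  is static.
- Accessibility is per-column reachability on the lattice: lateral
  tunnelling of enzymes through connected vacancies across columns is
  not modelled.
- The CBH footprint blocks symmetric windows; real cellobiohydrolases
  are directional.
- Inhibition equations can leave the physical regime at extreme
  inhibitor loads and are clamped.
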