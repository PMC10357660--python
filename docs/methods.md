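# Methods

`evocpm` simulates the evolution of cell-behaviour regulation at the
onset of multicellularity: spatially embedded cells on a 2-D lattice
carry evolvable adhesion bitstrings and an evolvable Boolean gene
regulatory network (GRN), and compete for survival and reproduction in
a seasonally changing chemoattractant environment.  This note records
the model equations as implemented, the parameters that matter, the
numerical and design choices that were genuinely open, and what the
desk-scale tests do and do not demonstrate.

## Cellular Potts engine

Cells are sets of lattice sites sharing a positive integer spin; spin 0
is the inert medium.  Per Monte Carlo step (MCS), `L x L` lattice sites
are drawn at random; each drawn site may receive the spin of a random
Moore neighbour.  A copy attempt changing the lattice is accepted with
probability `min(1, exp(-(dH + Y)/T))` where

* `dH` is the change in the Hamiltonian
  `H = sum_c lambda (A(c) - A_T(c))^2 + sum_<x,x'> J(s(x), s(x'))`
  (area constraint plus adhesion energy over heterotypic Moore
  neighbour pairs, each pair counted once), and
* `Y = -mu_p cos(theta_p) - mu_chi cos(theta_c)` is the work-term bias
  of the *extending* cell when it is migratory; growing and quiescent
  cells and the medium contribute no work terms.  `theta_p` and
  `theta_c` are the angles between the vector from the cell's centre of
  mass to the target site and, respectively, the persistence vector and
  the perceived-gradient vector.

Numerical choices:

* **Neighbourhood.**  Moore (8-neighbour) for both copy-source
  selection and the adhesion interface sum.
* **Boundaries.**  Closed: copies from outside the lattice are never
  proposed; border sites have fewer neighbours.  The gradient peak sits
  on a boundary, which rules out wrapping.  A side effect worth knowing
  about: because cell-medium contact costs energy (`J_cm >= 8`), a cell
  pressed flat against a wall loses perimeter energy and can stick
  there; test geometries therefore keep single-cell assays away from
  the walls.
* **Site sampling.**  The naive `L x L` random-draw scheme is used
  directly (no boundary edge-list): the compiled skip path for
  same-spin draws costs nanoseconds, so the edge-list optimisation
  would change little while adding an equivalence risk.
* **Work-term sign convention.**  The bias applies to extensions of the
  migratory cell only; retractions (medium or another cell copying into
  it) are unbiased.  Whenever the perceived gradient over the cell's
  own sites is exactly flat, a uniformly random angle replaces
  `theta_c` for that attempt.
* **Randomness.**  The kernel uses an inlined xorshift64* stream; site
  coordinates come from multiply-shift scaling of disjoint 32-bit
  halves of one draw (division-free, bias ~2^-32).  All other draws
  come from per-subsystem PCG64 streams spawned deterministically from
  one master seed (kernel, placement/division, mutation, environment,
  culling), so adding draws to one subsystem never perturbs another and
  a run is bit-reproducible given (seed, config).  Checkpoints store
  every stream's state and round-trip exactly.
* **Bookkeeping.**  Areas, coordinate sums and chi-weighted sums are
  maintained incrementally per accepted copy and can be audited against
  from-scratch recomputation (`Simulation.audit`); the test suite holds
  the incremental `dH` to a full-Hamiltonian oracle at 1e-9.

## Adhesion

Each cell carries a receptor and a ligand bitstring of length nu = 24.
With `D(R, I)` the Hamming distance,

    J_cc(a, b) = J_alpha + 2 nu - D(R_a, I_b) - D(R_b, I_a)   in [4, 52]
    J_cm(a)    = J_alpha' + sum_{i=1..6} F(i) I_i             in [8, 20]

with `F = (4, 3, 2, 1, 1, 1)` applied to the first six ligand bits
(position 1 of F maps to ligand index 0).  The surface tension
`gamma = J_cm - J_cc / 2` is positive for mutually adhering cells.
When adhesion cannot evolve, every interface uses the fixed
non-adhesive energies `J_cc = 36, J_cm = 14` (gamma = -4) regardless of
the bitstrings.  Bit mutation flips each of the 48 bits independently
(probability `mu_RI` per bit) in exactly one randomly chosen daughter
at division.

For experiment setups specified only by a target gamma, a
representative genome is built greedily (receptor all zeros; ligand
prefix chosen against the F weights; remaining required mismatches in
the ligand tail); any integer gamma in [-18, 18] is realizable.

## Gene regulatory network and cell behaviour

The network has 2 sensory nodes (average chemoattractant concentration
under the cell; divisions already done this season), 3 Boolean
regulatory nodes (fully connected, self-loops included) and a Boolean
output node fed by the regulatory nodes: 18 weights, 4 thresholds and 2
input scalings, 24 evolvable real parameters in total.  Updates are
synchronous; a node switches on iff its weighted input strictly exceeds
its threshold (ties give 0).  Each cell updates its network every 20
MCS at a private phase offset drawn at birth (not inherited), breaking
artificial synchrony.

Output 0 makes the cell migratory.  Output 1 sustained for `eta_init` =
10000 MCS commits the cell to growth: its target area rises by one site
every `eta_grow / A_T` = 400 MCS until `2 A_T`; division triggers when
the target area has doubled *and* the realized area is at least 90% of
it (the model's "grown to twice the original size" refers to realized
size; the 0.9 tolerance absorbs membrane fluctuations).  If the output
falls back to 0 mid-growth, the cell reverts to migration and the
target area shrinks at the same rate it grew (rate unspecified in the
model description; symmetry is the simplest choice).  Re-entry restarts
the `eta_init` wait from zero.  A cell whose division cap (3 per
season) is spent but whose output stays 1 is quiescent: neither
migrating nor dividing.  Growing and quiescent cells have
`mu_p = mu_chi = 0`.

Division splits the cell at the median of site projections onto its
principal axis (plane perpendicular to the long axis; ties broken by an
infinitesimal random jitter), which guarantees near-equal halves for
arbitrary shapes.  Both daughters: target area back to `A_T`, GRN
states and streak reset to 0, division counter incremented.  GRN
mutation adds N(0, sigma) to each parameter independently with
probability `mu_omega`, in the same single daughter that receives bit
mutations.  Parameters are unbounded (no clamping is described for the
model).  Cells that fall below 5 sites are culled as debris; whole-cell
area is used as the criterion rather than per-fragment connected
components, which would require per-MCS labelling; with T = 16 against
J in [4, 52] and lambda = 4, fragmentation is rare.

## Environment and seasons

The chemoattractant field is integer-valued and static within a season:
`chi(d) = 1 + (k_chi d_max / 100)(1 - d / d_max)` with the peak at the
midpoint of one lattice boundary and `d_max` the distance to the
farthest site.  Non-integer values are stochastically rounded *up with
probability equal to the fractional part*, making the stored integer an
unbiased sample of `chi` (the printed description of the rounding
direction is internally inconsistent with unbiasedness; the unbiased
convention is used).  Cells perceive only the field under their own
sites: the sensory input is the arithmetic mean, and the chemotaxis
vector runs from the cell's centre of mass to the chi-weighted centre
of mass of those sites.

A season is `tau_s` MCS of cell dynamics.  At its end each cell dies
independently with probability
`P(d) = p_min + (p_max - p_min) d^3 / (d_scale^3 + d^3)` of its
centre-of-mass distance to the peak (culling draws are made in cell-id
order from a dedicated stream).  Survivors keep positions, genomes and
persistence vectors; their division counters and GRN states reset; the
peak relocates to a uniformly random side (repeats allowed) and the
field is rebuilt.  Extinction terminates a run with a well-formed
record.  Initial populations default to 50 cells with uniform random
GRN parameters in [-1, 1] and random bitstrings, planted as compact
blocks of exactly `A_T` sites at non-overlapping random positions
(equivalent to, and cheaper than, growing single-site seeds to target
size before the first season).

## Parameters

All defaults are the model's canonical values: `L = 500`, `T = 16`,
`lambda = 4`, `A_T = 50`, `mu_p = 3`, `tau_p = 50`, `mu_chi = 1`,
`k_chi = 5`, `eta_init = 10000`, `eta_grow = 20000`, `p_min = 0.05`,
`p_max = 1.0`, `mu_RI = 0.01`, `mu_omega = 0.02`, `sigma = 0.05`,
3 divisions per season.  `tau_s` defaults to 180000 MCS and `d_scale`
to 40 (the short-season, high-death condition under which the
polarised strategies emerge); the studied alternatives (250000/500000
MCS, `d_scale` 80) are plain config values.  The architecture constants
(`nu = 24`, `nu' = 6`, `J_alpha = 4`, `J_alpha' = 8`) are fixed by the
adhesion scheme and validated rather than tunable.

## Desk-scale test conditions

Full-scale runs (500 x 500, hundreds of seasons, 15 replicates) are
cluster-scale.  The package's own test conditions are:

* **Energetics, death model, oracle equivalence, Metropolis
  statistics**: exact or Monte-Carlo checks at 3-binomial-SE tolerance;
  lattices up to 40 x 40, seconds each.
* **Single-cell chemotaxis**: 150 x 150 lattice, start 110 sites from
  the peak (field values there are ~5, well above the floor of 1, so
  the perceived direction is informative), 5000 MCS, 50 replicates.
* **Adhesion evolution** (directional): 150 x 150, `tau_s = 60000`,
  `d_scale = 12` (the high-death value scaled by lattice ratio),
  populations of 50 seeded with a concentration-threshold strategy
  (threshold 6, about 65% of the local peak concentration) and random
  bitstrings; 5 replicates, majority vote on reaching median
  gamma > 0.  Extinctions count as failures; under these harsh
  conditions occasional extinction is the expected behaviour, as in
  the full-scale model.
* **Regime-flip continuations** (directional): 150 x 150,
  `tau_s = 90000` and the scaled low-death `d_scale = 24`.  The scaled
  season must exceed three division rounds
  (`3 (eta_init + eta_grow) = 90000` MCS) for the divide-versus-migrate
  economy to exist at all, and desk-scale populations (tens of cells)
  cannot persist long enough under the scaled high-death setting for
  multi-season evolution to be observable.  The division-late ancestor
  is the threshold fixture at concentration 7 (~75% of peak); the
  division-early ancestor is the division-counter fixture.  Three
  replicates per direction, majority vote on the within-run trend of
  the median first-division time.

What passing these tests shows: the energetics, regulation, selection
and inheritance machinery reproduce the model's defined quantities
exactly, and the *direction* of the short-horizon evolutionary
responses.  What they do not show: full-scale population sizes,
division-timing distributions, or the slow regulatory reversal after a
switch away from adhesion - the model itself reports that reversal can
take hundreds of generations, far beyond desk horizons, and at
desk-scale population sizes the median division time carries several
thousand MCS of season-geometry noise.  The synthetic fixtures
(division counter, concentration threshold, constitutive states) are
handcrafted regulatory genomes with known truth tables; they emulate
the *kinds* of strategies that evolve, not any particular evolved
genome.

## Known limitations

* No diffusion, decay or consumption of the chemoattractant; the field
  is static within a season by construction.
* No connectivity constraint on cells; fragmentation is handled by the
  whole-cell debris rule above.
* The competition placement ("adjacent blocks opposite the peak") and
  the clonal-cluster seeding geometry are canonical choices documented
  in `experiments.py`; the model description does not fix them.
* Wall-sticking (see above) is a real feature of closed-boundary CPMs
  with positive cell-medium energies; quantitative single-cell assays
  should avoid trajectories that hug walls.
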