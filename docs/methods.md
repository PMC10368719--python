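# Methods

## Model overview

`holosim` is a constructive, multilevel model of obligate endosymbiosis.
Nothing above the molecular level is prescribed: hosts and symbionts are
cells that must *execute* a correct cell cycle to divide, and holobiont
stability, symbiont-number control, r/K strategies and genome-size
asymmetry all emerge (or fail to emerge) from the interplay of gene
regulation, explicit genome replication and spatial nutrient competition.

### Bead genomes

A genome is an ordered string of beads:

* **regulatory genes** — one of five core cell-cycle regulator types
  (0..4), each with an integer activation threshold >= 1 and a current
  activity bit;
* **household genes** — no regulatory role; they represent all
  non-cell-cycle functions;
* **binding sites** — each targets one regulator type with an integer
  weight in [-2, 2] \ {0} and regulates the nearest regulatory gene
  *downstream* of it on the string.

The genome is replicated by a single fork.  Replication happens only while
the cell expresses the S stage, at a speed equal to the cell's current
nutrient share (beads per time step); fractional credit carries over, so
low-influx sectors slow replication down rather than stalling it.  Beads
already passed by the fork are present in two copies.

### Stochastic regulation

Each time step, every binding site is independently bound with probability
A/(A + K), where A is the number of active copies of its target type
genome-wide and K is the half-saturation constant.  A gene copy switches on
iff the summed weight of its bound sites reaches its threshold; all gene
copies update synchronously.  A copy created by the fork inherits the
activity of its template at the moment the fork passes it, and both copies
subsequently update independently, so replication timing feeds back on
regulation through copy number.

**Choice of K (default 0.02).**  K is the model's noise dial: K -> 0 is the
deterministic limit (any active target binds), larger K makes binding
unreliable.  Measured on the shipped primitive network, per-cycle success
is ~0.91 at K = 0.02, ~0.83 at K = 0.05, and collapses to ~0 at K = 1
(cells fall into the all-off state within a few steps).  Holobiont
demography requires each host division to (on average) produce two viable
holobionts; that branching factor crosses 1 only when per-cycle success is
high, and scaled evolution runs establish reliably at K = 0.02 while most
go extinct at K = 0.05.  We therefore fixed K = 0.02 once, from these
demographic measurements.  K is config-exposed (`regulation.half_saturation`),
and K <= 0 selects the exact deterministic limit used by the test fixtures.

### Stages, division and death

The four stages G1, S, G2, M are signatures of the 5-bit core activity
pattern (one bit per regulator type; a type is "on" if any copy of any gene
of that type is active).  The default signature table ships as a versioned
TSV.  A cell that reaches the M signature divides iff it has fully
replicated its genome *and* has visited G1, S and G2 since its last
division, in that order of first visits (revisits are allowed); otherwise
reaching M is premature and the cell dies.  Cells also die at random with
probability d = 0.001 per step.

One deliberate extension: with all thresholds >= 1, the all-off expression
state is provably permanent (an inactive type can never be bound).  A cell
entering it can never divide, so the model treats complete regulatory
shutdown as death.  Without this rule, shut-down cells persist as inert
occupants for ~1/d steps, whole holobionts freeze, and clonal populations
collapse by regulatory attrition rather than by any ecological process;
with it, "a genome that cannot cycle" cleanly implies rapid extinction.

### Holobionts and space

A holobiont is one host plus >= 1 symbionts on a single lattice site.  The
default arena is a 25 x 275 grid (6875 sites) with eleven 25-column sectors
of ascending influx {1, 2, 5, 10, 20, 30, 40, 50, 60, 80, 100}.  Rows (the
short axis) are periodic; the gradient axis is not, and 3x3 neighborhoods
truncate at the open edges.  Each step the influx of a site is divided
equally over all cells in its 3x3 neighborhood; a cell's share sums the
contributions of up to nine sites, and influx of empty neighborhoods is
lost (no storage, no diffusion).

When the host divides, the offspring holobiont overgrows a uniformly chosen
neighboring site, killing any occupant, and each symbiont moves to the
offspring independently with probability p = 0.5.  A holobiont dies when
its host dies, its last symbiont dies, or its combined household count
(host + mean over symbionts) falls below H_min = 100 — enforced every step
by default (config flag `household_at_division_only` restricts the check to
division events).  A free-living mode disables the holobiont layer (single
cells, per-cell household minimum 50).

Update order within one step (AUT): shares are computed synchronously from
the pre-step configuration; every cell draws random death and then advances,
in uniformly random order; symbiont divisions are applied, then host
divisions in random order (a later division may overwrite an earlier
placement); finally dead and household-inviable holobionts are removed.

### Mutation

Applied independently to each daughter genome at division, per bead:
duplication (tandem) and deletion at 5e-4 each, binding-site weight shift
(+-1, skipping 0), regulator threshold shift (+-1, min 1) and binding-site
target flip at 1e-3 each, plus a per-genome innovation (insert one random
site at a random position) at 1e-3.  Duplication and deletion are
independent events — a bead hit by both nets out to one copy — so the
expected size change is exactly zero when the two rates are equal.  The
`prokaryote_like` regime multiplies every rate by ten.  These values are
package choices (the corresponding upstream rates are unpublished); they
are config-exposed and never hard-coded downstream.

## Analytics

For a cell tracked alone at fixed share n (default 1e4 AUT), an *attempt*
runs from birth/reset to division or death; tau is the mean duration of
completed cycles and rho the fraction of successful attempts.  The
phenomenological population model

    dN/dt = (rho/tau) N (1 - N) - ((1 - rho)/tau) N - delta N

yields the reproduction number R0 = rho/(delta tau + 1 - rho), the
instantaneous growth rate r = (2 rho - 1 - delta tau)/tau =
(rho/tau)(1 - 1/R0) (the two forms are asserted identical to 1e-12), and
the stable equilibrium N* = max(0, r tau/rho).  When the R0 denominator
vanishes, r = rho/tau is returned with a divergence flag.  The fastest
possible cycle is tau_min = 3 + L/n (one step each in G1, G2, M plus L/n
S-steps), giving the efficiency e = tau_min/tau, averaged over
n in {100, 50, 20, 10, 5, 2, 1}; conditions where no cycle completed are
excluded and reported.

Phase diagrams track host and symbiont independently over a condition grid
and locate crossings of r_H(n) = r_S(n).  A crossing is *stable* when
r_S - r_H increases through zero with n: a symbiont surplus lowers the
per-cell nutrient level and must push r_S below r_H to self-correct.
Conditions where a genome never completes a cycle are treated as
unboundedly negative growth for crossing detection, and the rho > 0.5
validity range is marked per curve.

**What "equilibrating at the crossing" means quantitatively.**  With
inheritance p = 0.5, half of a parent's symbionts leave at each host
division, so a demographically stable holobiont needs its symbionts to
double per host cycle.  For clonal pairs built from deterministic clocks
(flat growth plateaus above a sharp viability edge), the per-cell nutrient
level therefore cycles within [n*, 2n*] above the stable crossing n*
rather than sitting exactly on it; the time-median lands near 1.4 n*, and —
as in the full model — the level is independent of influx while the
symbiont number absorbs the difference.  The acceptance test asserts
exactly this: one stable crossing, clonal persistence, equilibrated
cell-weighted nutrient level inside [n*, 2n*], and influx-independence.

Holobiont profiling seeds a one-column strip of clones (mutation off) in a
uniform-influx arena per sector, measures invasion speed as the linear-fit
slope of the front-most occupied column from the first advance until the
front reaches 90% of the strip, then averages density, symbionts per host
and leftover per-cell share over the final quarter of the run.  Asymmetry
statistics use log2(L_host/L_symbiont) against e_host - e_symbiont and
plain Pearson correlation (two-sided p, N reported).

## Fixtures

The shipped primitive wiring is a hand-built cyclic activation chain over
the five regulator types with three inhibitory sites.  Exhaustive
enumeration of the 2^5 core states shows a single non-trivial limit cycle
G1 -> S -> G2 -> M (period 4, basin 31/32); the all-off state is a fixed
point for *any* wiring with positive thresholds, which is why it doubles as
the death state.  Two further verified clocks are built programmatically: a
period-5 variant (one gap state) and a period-10 variant used as the slow
host of constructed host/symbiont pairs.  Clock fixtures re-simulate their
recorded trajectory at load and refuse tampered genomes.  The clock attains
e = 1 exactly at n = L, where tau_min = 3 + L/L = 4 equals its period.

## Synthetic data and what the tests do and do not show

Everything here runs on genomes the package builds itself: the clocks above
and populations evolved from them.  These reproduce the *mechanisms* —
replication-limited cycling, holobiont-level selection, symbiont-number
control, the household-viability ratchet — at desk scale.  They do not
reproduce the published end states (10^7-AUT adaptation, evolved
generalists/specialists, the quantitative correlation table), which require
cluster-scale replicates; the operations that would compute those
statistics are implemented and tested on synthetic inputs instead.

## Problem sizes

Defaults follow the printed setup (25 x 275 grid, 1e4-AUT tracking windows,
1e7-AUT durations as config defaults).  The test suite and acceptance
checks run scaled-down versions chosen as desk-scale experiments: evolution
on a 25 x 50 grid with a five-sector gradient {2, 10, 30, 50, 100} for
2000 AUT x 10 seeds (the expansion signal is present well before 2000 AUT,
driven by the household-viability ratchet: founders sit exactly at the
combined minimum of 100, so household deletions are lethal while
duplications are safe), clonal equilibration on 12 x 20 arenas for 1500
AUT, and calibration measurements of >= 1e5 cell-steps / >= 1e4 division
events.

## Numerical and design notes

* Binding draws are vectorized per cell in a compiled kernel; one uniform
  per (gene copy, assigned site) pair per step, consumed in fixed order for
  reproducibility.  All randomness derives from one master seed through
  named substreams (ecology, expression, mutation).
* Sites with no downstream regulator are inert but heritable (they can gain
  a target by later insertions).
* Division consumes the parent: the first daughter takes over the parent's
  bead objects, the second receives copies; both reset fork state, age and
  visited stages, and the daughters inherit the two per-copy activity
  vectors.
* Tie-breaks: cell event order, division order and overgrowth targets are
  uniform draws from the ecology stream; placement conflicts resolve in
  that order (a later division may kill an earlier offspring).
* Degenerate inputs: empty genomes are legal and inviable; a genome with no
  regulators is absorbed immediately; 1-2-row lattices drop wrapped
  duplicate neighbors.
* Known limitations: no nutrient storage or diffusion; no symbiont
  exchange between holobionts; no explicit host-symbiont signaling; no
  nucleotide-level sequence; endosymbiotic gene transfer only arises
  indirectly through duplication and deletion.
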