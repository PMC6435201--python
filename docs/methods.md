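# Methods

## The charge-difference method

The simulator never writes down a differential equation for the membrane
potential or the cell volume.  It tracks the *amounts* of Na⁺, K⁺ and Cl⁻
moved across the membrane during each short time step and converts the net
transferred charge into a potential change through the membrane
capacitance (`E_m ← E_m + dQ/c`), and the net osmolyte change into a
volume change through water flux.  Bulk electroneutrality is therefore an
*outcome* — held to within the tiny capacitive charge, about 0.007 mM for
80 mV on the reference cell — rather than an imposed constraint.  Each step
applies, in this fixed order and exactly once:

1. all fluxes, evaluated from the beginning-of-step state ("conditions
   unchanged within a step");
2. mass accumulation, exogenous buildups, and the charge tally
   `dQ = (dNa + dK − dCl)·e`;
3. the E_m update, then osmotic volume relaxation.

The order is part of the method's identity.  There is no sub-iteration and
no adaptive higher-order solver: a resting state is a literal fixed point
of the discrete map, which is why converged steady states are independent
of the step size and reproduce analytic equilibria (Donnan products,
chord-conductance potentials) to near machine precision.  Discretisation
only affects transients; halving the step changes 20-minute concentrations
by well under 0.1% at the default steps.

One deliberate modelling assumption inherited with the method: E_m is a
state variable initialised by the caller and only ever incremented by
dQ/c.  For scenarios whose published initial conditions are resting states,
the package initialises E_m at the charge-balance (chord) potential of the
given concentrations, which is where the membrane would charge to within
milliseconds anyway.

## Model components and their assumptions

* **Channels** are linear ("chord") conductances in the electrochemical
  driving force, voltage-insensitive and constant, in ions s⁻¹ V⁻¹
  (2×10¹⁰ ions/(s·V) = 3.2 nS; input resistance 312.5 MΩ).  This is
  appropriate for cells without prominent voltage-gated behaviour
  (photoreceptors, glia, many non-spiking neurons); it is not a
  Goldman–Hodgkin–Katz flux model.
* **Na⁺/K⁺-ATPase**: activity `Ap = Rp/(1 + h_Na/[Na⁺]_i)³` — third-order
  saturating dependence on intracellular Na⁺, with `h_Na = 8 mM` the
  eighth-maximal point (`Ap = Rp/8` at `[Na⁺]_i = h_Na`).  `Rp`
  (the "rate") is the molecule count × turnover ceiling; `Ap` (the
  "activity") is the realised cycles/s and equals ATP molecules spent per
  second.  Stoichiometry `x:y` is arbitrary; `(x−y)·Ap·e` is the pump
  current.
* **Cotransporters** (NKCC, KCC) are electroneutral and linear in the
  base-10 log of their concentration-product ratios, hence each has a hard
  thermodynamic Cl⁻ limit where the ratio reaches 1.  Activities are
  unbounded-linear in the driving force (no saturation is modelled).
* **Impermeant species**: an intracellular anion pool of mean valence `z`
  (< 0) and neutral osmolytes on both sides.  Their amounts change only
  through explicit buildups; concentration changes otherwise reflect pure
  volume changes.
* **Water**: osmotic volume relaxation with time constant `tau`.  The
  per-step factor `chV = 1 − (1 − osV)·VoR·st` is the explicit-Euler form
  of `dvol/dt = −(vol − vol_eq)/tau`, and matches that exponential closed
  form to discretisation error.  `tau < st` is treated as instant water
  (`chV = osV`, osmolarity equalised every step); `tau > 10⁸ s` as a
  water-tight membrane (`VoR = 0`), which is what permits a classical
  Donnan equilibrium with a standing osmotic gradient.
* **Buildups** model exogenous osmolyte sources (four kinds: external
  neutral, external NaCl, internal neutral, internal charged anion).  They
  are electroneutral by construction — the internal anion buildup brings
  `−z` Na⁺ along per anion — and therefore never contribute to `dQ`.
* Bicarbonate/pH chemistry and voltage-gated kinetics are out of scope;
  the bath is infinite (an isolated cell in a dish), so extracellular
  concentrations change only via buildups.

A term for a pump-mediated Cl⁻ flux appears in the source formulation of
the Cl⁻ accumulation sum but is defined nowhere; since the pump carries no
Cl⁻, it is implemented as identically zero.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `st` | s | 1e-3 (transients 1e-4–5e-4) | explicit stepping must resolve the membrane RC time (3.75 ms at 3.2 nS/12 pF); steady states are st-independent |
| `c` | F | 1.2e-11 | 6×10⁻⁶ cm² of membrane at 2 µF/cm² |
| `vol` | L | 7.5e-13 | 10 µm cube, 25% organelles |
| `T` | K | 309.85 | 61.48 mV per decade |
| `h_Na` | mM | 8 | pump's Na⁺ half-occupation constant |
| `tau` | s | 1 (scenarios) | realistic neuronal/glial water permeability; 0 and >1e8 give the instant/water-tight limits |
| `steady_tol` | mM/s | 1e-9 | per-ion net flux below this for 10 consecutive 0.5 s checks declares a steady state; tight enough that analytic cross-checks agree to <3×10⁻⁵ mV |

## Numerical choices

* Concentrations are carried in mM end to end; the single ion-count →
  concentration conversion is `1e3/(vol·L)` inside the accumulation step.
* Physical constants are used at the rounded precisions conventional for
  this model family (R = 8.314, F = 96485, L = 6.02×10²³, e = 1.6×10⁻¹⁹).
  `F` serves the Nernst logarithms and `e` the charge bookkeeping; their
  product inconsistency (`e·L/F − 1 ≈ −0.17%`) is inherited from the
  rounding and is far below every tolerance used.
* A step that would push an intracellular concentration below 10⁻⁹ mM is
  rejected and retried as halved sub-steps (up to 60 halvings); `chV ≤ 0`
  (volume annihilated in one step) is a fatal error signalling a step far
  too large for the chosen `tau`.
* The inner loop is a numba-compiled kernel; the pure-Python `step()` is
  the readable reference implementation of the same map, and the suite
  asserts bit-for-bit agreement between the two over hundreds of steps.
* Steady-state detection: all three per-ion net fluxes, expressed as
  concentration rates, below `steady_tol` for `steady_checks` consecutive
  checks.  Divergence is reported, not looped on: volume beyond 10× the
  initial value, or monotone volume growth through the entire time budget
  with fluxes still unbalanced, is classified as unbounded swelling (the
  fate of any pump-free cell permeable to Na⁺, Cl⁻ and water; its swelling
  decelerates as [Cl⁻]_i approaches [Cl⁻]_o, so the 10× threshold alone
  can take unbounded simulated time to trip).
* Rate finding is plain bisection on a user predicate of the steady state,
  with an endpoint sign check; predicates used here (e.g. steady `Na_i −
  K_i` against pump rate) are monotone on the brackets employed.
* Scenario sweeps tabulate both the swept *rate* and the realised
  *activity*; published curves are plotted against activity, and the two
  differ by the concentration-dependent occupancy factor.

## Scenario conventions

The registry encodes the canonical experiments with their published
initial compositions.  Two recurring conventions: "simplified" (monovalent
impermeant anion, no external neutral osmolyte — osmolarity–charge
symmetric) and "realistic" (z = −1.5 plus 6 mM external neutral osmolyte —
asymmetric, `k_a = 1.5` passive).  Cation-only scenarios with z ≠ −1 or
external osmolyte derive their scaled initial concentrations from osmotic
balance rather than hard-coding them.  Steady-state drivers integrate up
to one simulated hour by default; the long Donnan runs use 20–90 simulated
minutes at 1 ms steps.  These horizons are the sizes at which the reported
quantities are converged to the precision quoted alongside them.

Where a published figure legend and the accompanying text disagree
slightly (the "realistic" post-gCl-opening resting state is printed both
as E_m = −46.15 mV and, via its legend composition Cl⁻ᵢ = 25.7 mM, as
E_Cl = −47.1 mV), the package reproduces the legend composition; the
tests pin the state by its composition and by the equilibrium identity
E_Cl = E_m rather than by the looser of the two printed potentials.

## What the scenarios do and do not show

All inputs here are idealised configurations, not recordings: fixed
conductances, a single well-mixed compartment, an infinite bath, no pH or
bicarbonate coupling, no surface-area or cytoskeletal mechanics, and water
handled as a single relaxation time.  Passing tests demonstrate internal
consistency of the method and exact agreement with the analytic
equilibrium theory under these idealisations — not quantitative prediction
for any particular cell type.  The parameter values (312.5 MΩ input
resistance, 12 pF, retinal-flavoured conductance ratios) put the numbers
in a physiologically plausible range for small neurons.

## Known limitations

* Explicit fixed-step integration: stability requires `st` comfortably
  below `c/(g_total·e)`; with very large conductances (e.g. gCl = 10¹¹
  ions/(s·V)) use `st ≤ 0.1 ms`.
* Near-threshold steady-state detection can accept slightly different
  endpoints of a very slow mode (sub-`steady_tol` drift), visible as
  ~0.03 mM spread when the same resting state is approached from different
  initial Cl⁻ with a small gCl.
* Cotransporter activities do not saturate; extreme rates are thermodynamically
  capped but not kinetically.
* The seed in `SimSettings` is reserved; nothing in the core is stochastic.
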