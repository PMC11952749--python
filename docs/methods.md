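# Methods

## Model and assumptions

`pursuitval` treats a temporal decision-making world as a recurrent
renewal environment.  An agent is always either inside a pursuit
(investing its duration to collect its reward at the end-state) or in a
default pursuit, where reward may accrue at rate ρ_d and new pursuit
opportunities of type *i* arrive at frequency *f_i* per unit default
time.  Worlds are recurrent by construction: every policy returns the
agent to the default state, so long-run reward rates are well defined.
Absorbing worlds, within-pursuit dynamics (patch residence, give-up
times), and sequential revision after initiation are out of scope: the
only decision modeled is whether to *initiate* a pursuit.

Units are abstract — rewards in reward units, times in time units, all
rates reward/time.  Rewards may be negative everywhere (punishments);
durations may not.  Frequencies are interpreted as Poisson encounter
rates, which makes the closed-form global rate

    ρ_g(A) = (Σ_{i∈A} f_i r_i + ρ_d) / (Σ_{i∈A} f_i t_i + 1)

the exact renewal-reward expectation; the "+1" in the denominator is the
one unit of default time over which the frequencies are defined.  Any
positive frequency is accepted, including ones high enough that default
time is a negligible share of a traversal.

### Subjective value and time's cost

Subjective value is defined as the immediate-reward equivalent of a
pursuit, so a zero-duration pursuit is legal and values to its own
reward in every expression.  The in/outside form is evaluated as
`(r_in − ρ_out·t_in) · t_out/(t_in+t_out)` and the apportionment cost as
`t_in·(ρ_g − ρ_out)` rather than its expanded algebraic equivalent;
both choices avoid cancellation between large intermediate products, and
the identities (two sv forms equal; opportunity + apportionment = time
cost = ρ_g·t_in) are asserted in the test suite at 1e-9/1e-10 tolerance
rather than trusted.

### Policies

Decision comparisons carry an absolute indifference tolerance on rates,
`tol = 1e-9` by default, so exact-equality cases report "indifferent"
instead of being resolved by floating-point noise.  The iterative Forgo
policy starts from accepting everything and removes, among pursuits
whose local rate falls below their current outside rate, the one with
the lowest local rate (ties by index).  The end state is independent of
removal order; determinism of the path is a convenience.  Its optimality
is not assumed: an exhaustive 2ⁿ search (`simulate.brute_force_optimal_accept_set`,
ties broken toward smaller then lexicographically earlier subsets) is run
against it on hundreds of random worlds in the tests.

The critical outside rate for a choice pair is closed form (the tying
equation is linear in ρ_out).  The critical outside *time* is found by
bracketing a sign change of sv_SS − sv_LL on a 200-point geometric grid
over (1e-6, 1e6) and polishing with Brent's method to 1e-10; a
zero-outside-reward closed form cross-checks it in the tests.  The
preference-reversal delay (a common unrewarded delay added to both
pursuits) is closed form.

## Apparent discounting

The delay of an offered outcome is modeled as the pursuit's full
duration (its temporal displacement); there is no separate pre-/post-
reward split.  The discounting curve is sv(t)/r pointwise — computed
through the valuation module, not re-derived — over a delay grid
defaulting to 0…4·t_out in 41 points.  The hyperbolic-k fit is
unweighted least squares of 1/(1+k·t) on the value scale with k ≥ 0
(scipy `curve_fit`), initialized at 1/t_out; no fitting protocol beyond
this is implied, and negative discount values are fitted as-is (the
standard hyperbola simply cannot reach them, which is the point of the
comparison).  Steepness orderings for the Magnitude and Sign effects are
asserted pointwise on delay grids, which is the sense in which the
constructions display them; no integral or slope-at-zero definition of
"steepness" is imposed.

## Misestimation agents

Only the perceived global rate is specified by the six-row error family,
so the decision architecture mirrors the optimal agent's with perceived
quantities substituted: Choice compares perceived global rates under the
two policies; Forgo compares the perceived local rate of the pursuit
against the perceived outside rate.  At ω = 1 every variant reduces
exactly to the optimal agent.

The Malapportionment agent is the `outside_both_rate_preserved` variant
with ω < 1 — perceived outside (ω·r_out, ω·t_out), both local rates
exactly true — and is equivalently expressible as
`inside_both_rate_preserved` with ω > 1; both are exposed.

One modeling choice deserves emphasis.  In the delay-effect construction
a common unrewarded delay is appended to both options.  For the optimal
agent its placement is provably irrelevant (a common additive time enters
only the traversal total, so the reversal delay is identical whether the
delay is booked inside the pursuits or outside them).  For a
misestimating agent the placement matters.  This package books the
common delay with the *outside*: it is time spent in neither considered
pursuit, and the Malapportionment hypothesis is precisely that such
non-pursuit time is underweighted.  Under that reading the agent's
perceived reversal delay is

    d̂* = x/ω − t_out,   x = [(r_SS + ω r_out)·t_LL − (r_LL + ω r_out)·t_SS] / (r_LL − r_SS),

which exceeds the optimal reversal delay for ω < 1 and grows as ω
shrinks — a *more* pronounced delay effect, consistent with the muted
Magnitude/Sign effects and steeper discounting the same agent shows.
Booking the delay inside the pursuits instead would make the
underweighting agent reverse *earlier* than optimal, which contradicts
the rest of its behavioral profile; that alternative is therefore not
used.

A related boundary case: the perceived discounting curve of the
underweighting agent lies strictly below the optimal curve only while
the subjective value is positive.  Both curves cross zero at the same
delay r/ρ_out (the numerator is shared), and beyond it the perceived
curve is merely closer to zero.  Tests assert the steepness ordering on
the positive region.

## Synthetic worlds

Property tests and oracles draw random worlds from
`io.generate_random_world`: durations uniform on (0.1, 10), rewards on
(−5, 10) (mixed sign, so punishment handling is always exercised),
frequencies on (0.05, 2), default rates on (0, 1), all per-seed
deterministic.  These emulate the scale of laboratory intertemporal
worlds — a handful of pursuit types with order-unit rates — and nothing
more: there is no reward stochasticity within a pursuit type, no
learning or estimation noise, no non-stationarity, and no queuing of
encounters during a pursuit (a mid-pursuit arrival is simply never
generated, matching the assumption that encounters happen from the
default pursuit).  Passing tests therefore certify the decision *theory*
and its implementation, not any claim about fitting empirical choice
data.

## Oracles and problem sizes

The Monte-Carlo oracle simulates 10⁵–2·10⁵ encounters per world with
exponential waits; its standard error comes from batch means over 100
batches, which absorbs the renewal correlation a naive per-step SE would
ignore.  Agreement with the closed form is asserted at 3 SEs across 20
random worlds, with a single fresh-seed retry per world to absorb the
~1% of honest 3-sigma excursions.  Exhaustive policy search is run on
200 random worlds of up to 12 pursuit types (4096 subsets each), and the
sv-form equivalence on 10⁴ random pursuit-context pairs at 1e-10
relative tolerance.  These sizes make the whole suite run in a few
seconds while leaving each check statistically meaningful.

## Known limitations

* Initiate-or-not only: no within-pursuit state, abandonment, or
  post-initiation information.
* The misestimation family perturbs point estimates by a single
  multiplicative factor; it does not model estimation *noise* or
  learning dynamics that could produce such biases.
* ω is not fitted to data; the package generates predictions, not
  parameter estimates.
* Steepness orderings are established on tested parameter grids, not as
  symbolic theorems.
* The standard-hyperbola comparison is the only discounting fit offered;
  exponential or quasi-hyperbolic fits are out of scope.
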