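# pursuitval

Reward-rate-optimal valuation of initiating pursuits.

`pursuitval` is a library and command-line tool for normative temporal
decision-making, in the tradition of optimal-foraging prey models.  It is
aimed at behavioral scientists, computational neuroscientists, and
economists who want a tested reference implementation of what a
reward-rate-maximizing agent *should* do when deciding whether to start a
pursuit — and of how specific estimation errors would distort that
behavior.

## The model

A world is a recurrent environment of **pursuits**: paths that cost a
duration *t* and yield a reward *r* (possibly negative), encountered at
frequencies *f₁…fₙ* from a default (waiting) pursuit that pays at rate
ρ_d.  A policy of accepting a subset *A* of pursuit types attains the
global reward rate

    ρ_g = (Σ_{i∈A} f_i r_i + ρ_d) / (Σ_{i∈A} f_i t_i + 1).

Parcelling the world into a considered pursuit (*r_in*, *t_in*) and
everything outside it (*r_out*, *t_out*) gives the equivalent form
ρ_g = (r_in + r_out)/(t_in + t_out), a weighted average of the inside and
outside local rates with weights w_in = t_in/(t_in + t_out) and 1 − w_in.

The worth of initiating a pursuit is its **subjective value** — the
immediate reward an agent should treat as equivalent to the pursuit:

    sv = r_in − ρ_g t_in = (r_in − ρ_out t_in) · t_out/(t_in + t_out).

Time's cost ρ_g·t_in splits exactly into an **opportunity cost**
ρ_out·t_in (what not taking the pursuit would have earned over its
duration) and an **apportionment cost** (ρ_g − ρ_out)·t_in (the remainder,
driven by the share of traversal time the pursuit occupies).

From these follow:

* **Forgo policy** — take a pursuit iff ρ_in > ρ_out (equivalently
  sv > 0); iterating this over a multi-pursuit world attains the global
  maximum over all 2ⁿ accept policies.
* **Choice policy** — between a smaller-sooner (SS) and larger-later (LL)
  pursuit, pick the one whose acceptance yields the higher ρ_g;
  equivalent to comparing the marginal rate (r_LL−r_SS)/(t_LL−t_SS)
  against ρ_g*, and to comparing subjective values.
* **Apparent discounting** — normalizing sv by the outcome yields
  D(t) = (1 − ρ_out t/r)/(1 + t/t_out): a hyperbola with curvature
  1/t_out scaled by a linear opportunity-cost term.  With no outside
  reward it is exactly the standard hyperbola 1/(1 + k·t) with
  k = 1/t_out.  Hyperbolic discounting and the Magnitude, Sign, and Delay
  effects all fall out of this expression — they are signatures of
  rate-maximization, not of irrationality.
* **Misestimation agents** — six models multiply one rate-enabling
  quantity (inside/outside reward and/or time) by an error factor ω.  The
  two rate-preserving variants distort only how time is *apportioned*:
  they leave Forgo behavior exactly optimal while biasing Choice toward
  SS — the *Malapportionment* account of observed impatience.

## Worked example

`examples/pursuit_in_context.yaml` describes a pursuit worth 4 reward
units over 4 time units whose outside yields 0.7 reward units over 3 time
units:

```text
$ pursuitval value --spec examples/pursuit_in_context.yaml
    subjective_value   1.31428571
         global_rate   0.671428571
    occupancy_weight   0.571428571
           time_cost   2.68571429
    opportunity_cost   0.933333333
  apportionment_cost   1.75238095
```

Accepting this pursuit sustains a global rate of 0.671 reward/time, of
which the pursuit occupies 57% of traversal time.  Its 4-unit reward is
worth 1.314 units *paid now*: the 2.686 units of time's cost decompose
into 0.933 forgone outside earnings plus 1.752 of apportionment cost.
Since sv > 0 (the inside rate 1.0 beats the outside rate 0.233), the
pursuit should be taken:

```text
$ pursuitval forgo --spec examples/pursuit_in_context.yaml
take
```

Sweeping the outside reward rate for an SS (2.5 after 2.5) vs LL (5 after
8.5) pair with a 6-unit outside walks through the full behavioral
repertoire — LL-preferring at low rates, then SS, then forgoing LL, then
forgoing both:

```text
$ pursuitval regions --spec examples/choice.yaml --rates 0,0.4,0.8,1.3
outside_rate,omega,choice,forgo_ll,forgo_ss
0.0,1.0,LL,take,take
0.4,1.0,SS,take,take
0.8,1.0,SS,forgo,take
1.3,1.0,SS,forgo,forgo
```

A Monte-Carlo traversal of a two-pursuit world whose closed-form rate is
exactly 1.0 serves as an independent check of the rate algebra:

```text
$ pursuitval simulate --spec examples/forgo_world.yaml -n 100000 --seed 1
empirical_rate 1.00132564  se 0.00179  reward 266304  time 265951  n 100000  seed 1
```

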