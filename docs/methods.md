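# Methods

## The model

`pubbias` treats a published literature as the outcome of a simple
generative pipeline under null-hypothesis significance testing.  A
hypothesis is true with prior probability θ.  A study testing a true
hypothesis reports positive evidence with probability equal to its
statistical power 1−β; a study testing a false hypothesis reports
positive evidence with probability α, the test's type-1 error rate.
Three identities follow:

- total positive-evidence rate: `P_total = θ(1−β) + α(1−θ)`;
- posterior probability that a positive finding is true (Bayes):
  `post = θ(1−β) / P_total`;
- replication probability of a positive finding in an independent study
  with power 1−β_r and level α_r: `R = post(1−β_r) + α_r(1−post)`.

Feeding the posterior into the replication identity couples the three
unknowns (θ, β, post).  If the replication rate R is observed and a
prior is assumed, the original power is the single remaining unknown
and can be recovered by root-finding.  `core.solve_naive` does this for
the zero-variance case (every study shares one power value).

Defaults follow the replication-project conventions: α_o = 0.05 for the
original two-sided tests, α_r = 0.025 for the replications (directional
hypotheses tested two-tailed), R = 0.36, and a literature containing
90% positive findings.

## Power variance

Real literatures do not share one power value.  The variance-aware layer
replaces the posterior with its expectation over a density f of
per-study power:

    E[post] = ∫ f(p) · θp / (θp + α_o(1−θ)) dp,
    E[R]    = E[post] · p_r + α_r (1 − E[post]),

where p_r is a *scalar* replication power tied to the mean original
power μ through a power link: identical (p_r = μ), perfect (p_r = 1), or
an additive offset (p_r = μ + δ, with δ between 0.06 and 0.10 reflecting
the typically larger replication samples; midpoint 0.08).  The solver
(`solver.solve_scenario`) root-finds μ so that E[R] matches the observed
rate; E[R] is monotone increasing in μ under every link, so bracketed
Brent iteration with tolerance 1e−13 is safe.  Offsets are never
clamped inside the solver: a required p_r above 1 is reported as an
infeasible solution (a value, not an exception, so sweeps over prior
grids always complete).

### Distribution families and the shape-scale convention

Per-study power follows one of three families (`distributions`):

- `point` — the zero-variance limit;
- `beta:<s>` — a Beta with one free shape s and mean μ;
- `bimodal:<s_lo>,<s_hi>:<m_lo>,<m_hi>` — a two-component Beta mixture
  with components pinned at fixed means (defaults 0.145/0.905; the
  extreme-variance variant 0.0975/0.9525) and mixture weight
  w = (m_hi−μ)/(m_hi−m_lo) chosen so the overall mean is μ.

A Beta "with shape s and mean μ" is ambiguous: the model's density is
written over the type-2 error rate β, so s can attach to the β-scale
Beta (power ∼ Beta(s·μ/(1−μ), s), the default here, `shape_scale="type2"`)
or to the power-scale Beta (power ∼ Beta(s, s·(1−μ)/μ),
`shape_scale="power"`).  The conventions coincide at μ = ½ and differ in
how the skew trades against the mean elsewhere.  The type-2 default for
the free-mean family was chosen because it reproduces the documented
behaviour of the flagship analyses distinctly better across the
θ ≤ 0.1 scenarios; the mixture presets use power-scale component shapes
because their components sit near the endpoints, where the type-2
convention would introduce an integrable singularity at zero power and
visibly distort the conservative outer bias band.  Both conventions are
one config token apart (`beta:0.5` vs `beta:0.5@power`).

Under the power-scale convention the likely-range family Beta(s = ½) has
variance 0.094 at a mean power of 35%, inside the 0.09–0.12 band
estimated from meta-meta-analytic power surveys; that band statement is
specific to the power-scale convention (the type-2 variance at the same
mean is 0.129).

### Quadrature

Expectations are computed per Beta component with Gauss–Jacobi rules
whose weight *is* the component density: endpoint singularities
(shape < 1) are absorbed analytically and the remaining integrand — a
smooth rational function of power — converges to near machine precision
at 64 nodes.  A node-doubling check guards each evaluation; when the two
estimates disagree by more than 1e−8 (priors near 1 push the integrand
pole toward the interval), the affected components fall back to adaptive
QUADPACK integration with the algebraic endpoint weight, accepted when
the reported error is below 1e−6 of the component mass.  The solver
restricts Beta-family means to [1e−3, 0.999] so derived shape parameters
stay in a numerically safe range; point masses use the full (0, 1].

### Mean-field form versus the generative process

The expected-reproducibility formula is deliberately mean-field: it
multiplies the study-averaged posterior by a scalar replication power.
A faithful simulation of the pipeline behaves differently, because
positive findings over-sample high-power studies: among true hypotheses,
the well-powered ones are the ones that turn positive, so the empirical
share of true positives and the empirical replication rate both exceed
the mean-field expectations whenever power varies between studies (at
θ = 0.1 with the likely-range variance the gap is large: an empirical
replication rate near 0.50 against a mean-field 0.36).  The simulator
(`montecarlo.simulate`) therefore offers two couplings:

- `coupling="study"` (default) — the faithful process; its empirical
  rates are validated against the selection-weighted closed forms in
  `expectation.selection_weighted_summaries`;
- `coupling="mean_field"` — a seeded validator of the mean-field
  closed forms: positivity occurs at the marginal rate, truth given a
  positive follows the per-study Bayes posterior, and true findings
  replicate at the scalar mean replication power.

Both predictions ship inside every `SimulationResult` so the gap is
quantified rather than hidden.  Per-study replication power under offset
links is clipped at 1 (the scalar solver-side check still reports
μ + δ > 1 as infeasible).  Random draws are consumed in a fixed order —
truth, power, outcome, publication, replication — so seeds are portable.
Negative results are published with probability 1/suppression_odds;
positives always.

## Publication-bias odds

The expected positive rate P = θμ + α_o(1−θ) is linear in power, so it
holds under any power variance.  Comparing P with the literature's
positive share L (default 0.90) gives the suppression odds
B = ((1−P)/P) / ((1−L)/L), read as "B negative observations per negative
result published"; B = 1 means the literature mirrors production, and at
L = 0.9 the expression reduces to 9(1−P)/P.  The formula is reconstructed
from the "rescaled to odds" description of the source analysis and
validated against its three printed anchors (≈88 at P = 9.3%; the 55–98
likely band; the 81:1 arithmetic at P = 0.10).  `bias.binomial_bias_test`
is the one-sided exact lower-tail binomial test of an observed
replication count against a null reproducibility rate — one-sided
because the only alternative of interest is reproducibility *below* the
null; the default count k = 35 is round(0.36·97), since the source
reports the rate rather than the count.

The correlation-power helper uses the Fisher z approximation (normal
with variance 1/(n−3), two-sided critical value), the standard choice in
power calculators; it is exact at r = 0 and within about a point of the
noncentral-t answer in the relevant range, which is why the 6–10 point
replication-power increment it reproduces carries a ±2 point tolerance.

## Numerical conventions

- Root-finding: Brent with xtol 1e−13 after verifying a sign change on
  the bracket; feasibility bounds by bisection on θ to 1e−4.
- Prior grids: 200 log-spaced points on [0.025, 0.975] by default (the
  sweep x-axis is read on a log scale).
- Reported percentages round half-even to the printed precision of the
  quantities they reproduce (one decimal for the analytic identities,
  integers for solver-derived percentages and odds).
- Preset bands: likely = offsets {0.06, 0.10} × Beta(½); alternative =
  the same offsets × {Beta(1), bimodal 0.145/0.905}; extreme = offsets ×
  bimodal 0.0975/0.9525; zero variance = offsets × point; outer =
  {identical, perfect} × {point, extreme}.

## What the simulator does and does not emulate

The generator draws binary truth, per-study power, binary outcomes,
publication thinning and one replication per published positive.  It
does not model effect sizes, sample sizes, p-value distributions, or
correlated repeat observations within a study — the framework operates
on power directly, and the suppression metric assumes independent
observations (correlated observations would make the bias estimates
conservative).  Passing simulation tests therefore shows internal
consistency of the closed forms and the generative reading, not that
real literatures satisfy the model's assumptions (binary hypotheses,
power independent of the prior, a single homogeneous suppression
mechanism).

## Reproduction quality and known limitations

With the default conventions the package reproduces the analytic worked
examples exactly (89.5%, 90.5%, 99.4%), the binomial bias bound, the
perfect-replication floor (50%), the type-1 replication share (1.2%),
the externally-anchored bias odds (88 at θ = 0.07; 98 at θ = 0.05), and
the high-replication-rate ranges (positive evidence 9–16%, bias 48–90 at
R = 0.46).  Solver-derived quantities at θ = 0.1 land within about one
point of the published 59%/52% pair.  A residual systematic gap of about
1.5 power points remains at θ = 0.20 (minimum likely-range power 49.5%
against a published 48%; the matching bias endpoint 53.7 against 55),
which no reconstruction of the original computation examined here
removes; the conservative outer bias band reaches a minimum of 15.8
against a published "more than 16".  Interval estimates are out of
scope: the method yields expectations, not posterior distributions, so
no credible intervals are attached to solved quantities.
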