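# Methods

## The model

`skillmix` sizes the whole-time-equivalent (WTE) dental workforce needed to
deliver evidence-based, caries-risk-stratified preventive care to the child
population of England, under alternative delegation ("skill-mix") scenarios
across three cadres: dentists, dental hygienists/therapists (DH/DThs,
modelled jointly), and extended-duties dental nurses (EDDNs).

Demand is needs-led, not utilisation-led.  For age band $a$, risk level
$\ell \in \{\text{high}, \text{low}\}$, care component $c$ and cadre $g$:

$$D_g \;=\; \sum_{c,a,\ell} P_a \, \rho_{a\ell} \, \alpha \, s_{ca\ell g}\, t_{ca\ell g}$$

where $P_a$ is the band population, $\rho_{a\ell}$ the risk-stratum
fraction ($\rho_{a,\text{high}}=r_a$, $\rho_{a,\text{low}}=1-r_a$),
$\alpha$ the attendance rate, $s_{ca\ell g}\in[0,1]$ the scenario's
delegation share (summing to 1 over cadres in every in-scope cell) and
$t_{ca\ell g}$ the per-child annual minutes for the component.  The
workforce then solves the linear programme

$$\min \sum_g x_g \quad \text{s.t.} \quad H_g\, x_g \ge D_g,\; x_g \ge 0,$$

with $H_g$ the annual NHS clinical minutes per WTE of cadre $g$.  With
shares fixed before optimisation the programme separates per cadre, with
closed form $x_g = D_g / H_g$; the package solves the LP with HiGHS
(`scipy.optimize.linprog`) and keeps the closed form as an independent
verification oracle, mirroring the verify-feasibility discipline of
operational-research practice (every returned solution is re-checked
against the constraints).  Decision variables are continuous WTE; the
integers in reports arise from reporting-time rounding (default
round-half-up "nearest"; "ceil" available, since requirement arguments
often round up).

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| dentist NHS hours | 26.7 | h/week | average NHS commitment, pre-pandemic data |
| EDDN NHS hours | 26.7 | h/week | dental nurses mirror dentist working patterns |
| DH/DTh NHS hours | 11.8 | h/week | ~25 h/week at a 47.2% NHS share (share is a config override) |
| annual leave | 4.4 | weeks, all cadres | stated working-pattern input |
| working year | 52 − leave | weeks | bank holidays/sickness excluded for fidelity to the stated inputs |
| overall high-risk rate | 31.02 → 16.56 | %, linear 2023→2050 | epidemiology-derived mean; endpoint one standard deviation lower |
| attendance rate | 1.0 | fraction | universal annual attendance is the plan's stated premise; demand is degree-1 homogeneous in it |
| urgent-care uplift | 0 (off) | fraction of population | optional extension; enabling it requires an urgent-visit duration (the analysis scripts use 30 min) |
| sealant time | 9.3 | min/sealant; 4 sealants amortised over 5 y (5-9), 12 over 8 y (10-17), high risk only |
| restorative care | 30 | min/year, high-risk children in every band |
| EDDN confirmatory exam | 2 | min, replacing the clinical exam when EDDNs deliver without a same-pathway examiner |
| VBA (tobacco/vaping) | 0.3 | min/year, every 10-17-year-old; the short duration reflects the high never-smoker share, not an extra weighting |

Annual capacity per WTE is `hours × 60 × (52 − leave)`: 76,255.2 min for
dentists and EDDNs, 33,700.8 min for DH/DThs.  All cadres are assumed to
dedicate 100% of NHS clinical time to children.

## Population and risk structure

The 2022 census anchor lists bands 0-4, 5-9 and 10-14 but totals 0-17; the
15-17 band is derived by subtraction (1,881,621) so bands conserve the
printed total.  Projection anchors (2023, 2030, 2040, 2050) give totals
only; totals between anchors are linearly interpolated and split into
bands using the shares of the most recent band-level anchor (2022).  No
extrapolation outside the anchor span.  Care-plan age bands are {0-4, 5-9,
10-17}; the 10-14 and 15-17 population bands are merged pro-rata by
single-year span (uniform-age assumption, also used for varnish
eligibility fractions: ages 1-4 are 4/5 of the 0-4 band, ages 3-4 are
2/5).

Band-level high-risk fractions come from supplementary epidemiology not
reproduced in the sources available here; the fixture applies the overall
31.02% uniformly across bands.  Under a changed overall rate all band
fractions scale proportionally (capped at 1) — how age-specific risk
evolves is not specified, and proportional scaling preserves the age
profile.

## The timing table and its synthetic stand-in

The full component-by-component timing evidence exists only in an
unpublished supplementary table.  `england_fixture()` therefore returns a
*partial* timing table containing exactly the stated durations, plus an
explicit list of missing cells — gaps are never silently filled.
`standin_timing_table()` completes it synthetically: every stated value is
used exactly, and the unreported unit times (examination 15 min,
radiographs 2.5 min, varnish 5 min/application, oral-health advice 6 min,
diet advice 6.9 min) are plausible round values whose residual closes the
stated 89.65-minute dentist high-risk 10-17 plan exactly
(15 + 2.5 + 3×5 + 13.95 + 6 + 6.9 + 0.3 + 30 = 89.65).  DH/DTh unit times
mirror the dentist values; EDDN times mirror DH/DTh except the
examination.  Workforce numbers computed from the stand-in are
approximations conditional on that decomposition — with it, the
dentist-only scenario needs 8,014 WTE in 2023 — and are clearly labelled
as such in the analysis outputs.  Radiographs are charged to high-risk
5-17-year-olds only (never 0-4s); whether the low-risk plan includes them
is unstated, and excluding them is this package's choice.

## Scenarios

Six built-in delegation patterns (a-f), in increasing skill-mix use:
(a) dentists deliver everything; (b) DH/DThs deliver everything;
(c) DH/DThs examine and provide radiographs, sealants and restorative
care, EDDNs the rest; (d) dentists examine, EDDNs apply varnish, DH/DThs
the rest; (e) 10% of high-risk children receive their whole plan from
dentists, the remainder delegated as in (c); (f) dentists assess everyone,
DH/DThs provide radiographs, sealants and restorations, EDDNs everything
else in their scope.  Scope of practice is validated structurally: EDDNs
may deliver varnish, advice, VBA and the confirmatory exam only, so
radiographs in (c) and (f) necessarily sit with DH/DThs.  Scenario (e)'s
"remaining" children follow (c)'s split, the closest stated pattern.  The
EDDN confirmatory exam is charged only when EDDNs deliver care in a cell
whose examination is routed to no dentist or DH/DTh (a config toggle; no
built-in scenario triggers it, since each routes the initial exam to a
dentist or DH/DTh).  Shares are deterministic fractions, not stochastic
routing.

## Synthetic-data generators

`SynthConfig` defaults emulate the study conditions: the 2022 population
total with its band shares (largest-remainder rounding makes integer band
counts conserve the total exactly); band risk fractions drawn from
Normal(0.3102, 0.1446) clipped to [0,1] (the stated mean, and the
standard deviation implied by the 16.56% endpoint); unit timings uniform
in [0.3, 30] minutes (the span of the stated component durations) scaled
by per-cadre speed ratios, with amortisation, varnish frequencies and the
EDDN exam rule enforced structurally so generated tables always pass the
same validation as real inputs.  The generators emulate the *structure* of
the real inputs, not their survey error or patient-level heterogeneity, so
passing tests demonstrate correct mechanics, not epidemiological accuracy.
An end-to-end self-test plants a known WTE vector, sets capacities
$H_g = D_g / x^*_g$, and verifies the pipeline recovers it to 1e-6
relative across seeds.

## Numerical choices

Feasibility is checked to 1e-6 absolute minutes; the LP-vs-oracle
comparison to 1e-9 relative.  Share conservation tolerates 1e-9.  Reports
print continuous WTE and risk rates to 2 decimals and reported WTE as
integers, with sorted rows so identical inputs give byte-identical files.
Zero demand yields zero WTE; positive demand on a zero-capacity cadre is
reported as infeasible status, not an exception.  Analysis scripts run the
four anchor years rather than all 28 to keep tables readable; any year in
the span is runnable.

## Limitations

Regional variation, adult care, cost comparisons, inter-appointment
transfer time, appointment scheduling and surgery-space constraints are
out of scope.  Headcount-to-WTE conversion, part-time distributions and
attrition are not modelled.  DH and DTh scopes are merged although
hygienists cannot provide the restorative elements.  The stand-in timing
decomposition, and the uniform band risk profile, are the two places where
the bundled inputs are synthetic rather than sourced; both are replaceable
by CSV inputs in the documented schemas.
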