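# skillmix

Needs-led, risk-based workforce modelling for child dental prevention.

Most of childhood tooth decay is preventable, yet delivering the
evidence-based preventive care plan to every child in England is a
workforce question: who does the work — dentists, dental
hygienists/therapists (DH/DThs), or extended-duties dental nurses
(EDDNs) — and how many whole-time equivalents (WTE) of each are needed?
`skillmix` answers this with a needs-led model: population × caries-risk
mix × per-child care minutes gives each cadre's annual demand $D_g$, and a
linear programme

$$\min \textstyle\sum_g x_g \quad \text{s.t.} \quad H_g x_g \ge D_g,\; x_g \ge 0$$

finds the minimum workforce whose annual clinical capacity $H_g$ (minutes
per WTE per year) meets it.  Six built-in delegation scenarios (a–f) span
no skill mix (dentists or DH/DThs do everything) to maximum delegation
(EDDNs deliver everything in their scope).  It is written for health
services researchers and workforce planners; every input — population,
risk profile, timing table, capacities, scenario — is a small CSV/YAML
file that can be replaced as new evidence emerges.

## Worked example

Workforce for the moderate skill-mix scenario (c) — DH/DThs examine and
treat, EDDNs deliver the preventive advice and varnish — for 2023:

```python
from skillmix import RunConfig, run_single

result, demand, meta = run_single(RunConfig(scenario="c", year=2023))
print(meta["risk_rate_used"], result.wte_reported, result.combined_total)
```

```
31.02 {'dentist': 0, 'dh_dth': 9823, 'eddn': 3673} 13496
```

Read: at the 31.02% high-caries-risk rate, a 2023 child population of
about 12.06 million needs roughly 9,823 WTE DH/DThs plus 3,673 WTE EDDNs
(13,496 combined) to deliver the full preventive plan with no dentist
involvement.  These figures use the bundled *synthetic stand-in* timing
table: the published per-component timing evidence is supplementary and
not reproduced here, so the stand-in anchors every stated duration exactly
(9.3 min per sealant amortised over the age band, 30 min/year restorative,
the 89.65-minute dentist high-risk 10-17 plan total) and fills the
unreported unit times with documented approximations — see
`docs/methods.md`.  Supply your own table via
`RunConfig(timings="timings.csv")` to use sourced evidence.

The same engine runs from the shell:

```
skillmix run --scenario c --year 2023
skillmix project --scenario a --from 2023 --to 2050 --risk-start 2023:31.02 --risk-end 2050:16.56 --out projection.csv
skillmix scenarios
```

## Analysis scripts

Narrative drivers under `analysis/` write their tables to `results/`:

- `01_scenarios_2023.py` — all six scenarios for 2023 at the 31.02% risk rate;
- `02_projection_2023_2050.py` — anchor-year projections to 2050, with the
  risk rate held at 31.02% versus declining linearly to 16.56%;
- `03_access_sensitivity.py` — attendance-rate scaling (only ~52.7% of
  children currently attend annually) and a 3% urgent-care uplift.

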