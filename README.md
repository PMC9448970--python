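# msmr

Multistate mark-recapture analysis of adult survival and reproductive
skipping in a two-colony seabird monitoring design. The package covers the
full chain:

1. **`msmr.synthetic`** — truth-known simulation of the study design:
   latent three-state trajectories (breeder / nonbreeder / prebreeder plus
   an absorbing dead state), dated nest-check and ground-reader detection
   records, and occasion-level encounter histories.
2. **`msmr.states`** — classification of detection records into annual
   observed states (nest evidence or the ≥6-detection-days / 12–120-day
   span ground-reader rule), exclusion filters (double-marked individuals,
   multi-colony breeders) and MARK-style `.inp` / CSV encounter histories.
3. **`msmr.model`** — the three-state Arnason–Schwarz model: symbolic
   formulas over `state`, `time`, `colony` and standardized biomass
   covariates (`sardine`, `anchovy`, `combined_biomass`), fixed parameters
   masked out of the design, a forward-recursion likelihood over latent
   states, quasi-Newton maximum likelihood with multi-start, delta-method
   SEs/CIs, predicted covariate curves and per-colony slopes.
4. **`msmr.gof_selection`** — contingency-style goodness-of-fit components
   (Test3G.SR, Test3G.Sm, TestM.ITEC, TestM.LTEC) with documented pooling,
   the variance inflation factor ĉ = χ²/df, QAICc, and the stepwise
   recapture → survival → transition selection procedure (within
   ΔQAICc < 2 the fewest-parameter model wins).
5. **`msmr.cli`** — one-command orchestration, config snapshots and
   hashes, structured logs, tables and figure regeneration.

## Command line

```sh
msmr simulate --seed 1 --out out-sim            # truth-known dataset
msmr assign   --config config.yaml              # records -> histories
msmr gof      --config config.yaml              # GOF components + c-hat
msmr fit      --config config.yaml --phi colony # fit one model
msmr select   --config config.yaml              # stepwise QAICc selection
msmr report   --out out                         # regenerate report.md
msmr all      --config config.yaml              # everything
```

A minimal config:

```yaml
detections: out-sim/detections.csv   # or histories: path/to/histories.inp
biomass: biomass.csv                 # columns: year, sardine, anchovy
out_dir: out
seed: 1
fixed: study                         # the study's fixed-parameter set
candidates:
  p:   ["state + time * colony", "state + colony"]
  phi: ["colony", "time * colony", "sardine * colony", "combined_biomass * colony"]
  psi: ["state * colony", "state * time * colony"]
```

Model formulas combine factors additively (`+`) or interactively (`*`),
e.g. `phi: state + sardine * colony`. Survival interval *i* (season *y* →
*y+1*) carries the November survey of year *y*; covariates are z-scored
over the supplied years.

### Encounter-history `.inp` dialect

One line per individual:

```
/* <individual_id> */ SSSSSSSS f_R f_S ;
```

`S` is the observed state digit per occasion (`0` not encountered,
`1` breeder, `2` nonbreeder, `3` prebreeder) and `f_R f_S` are 1/0
frequency columns for the colony groups (Robben Island, Stony Point — in
that order). A CSV mirror (`individual_id, colony, code_2013..code_2020`)
is written alongside.

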