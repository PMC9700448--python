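# edflow

Discrete-event simulation of emergency-department-to-inpatient admission
flow: a seven-stage queueing pathway (registration, triage, assessment,
referral to medicine, decision to admit, room allocation, physical transfer)
with shift-based resource pools, ward/AAU/AMAU bed pools, and a scenario
engine for staffing and bed-capacity interventions.

## Model overview

Patients arrive at the ED (exponential or diurnal-profile inter-arrival
times), traverse the seven stages in order, draw an inpatient destination
(ward 45% / AAU 35% / AMAU 20%), and hold a bed from room allocation until
an exponential length of stay elapses after delivery. The primary outcome is
the **patient experience time (PET)**: ED arrival to delivery into the
assigned bed.

Two execution modes:

- **direct** — every stage consumes a sampled sojourn from a symmetric
  triangular distribution moment-matched to the observed per-stage mean ± SD
  (no contention). The expected total PET is the sum of the seven stage
  means, 976 minutes. This is the validated base model.
- **queueing** — every stage is a FIFO multi-server station; the intrinsic
  service time is the same fitted triangular scaled by a per-station
  multiplier chosen by calibration so that base-staffing steady-state
  sojourns (waiting + service) reproduce the observed stage means. Staffing
  and bed scenarios act on this mode, compared under common random numbers.

A known source-data conflict is resolved in favour of internal consistency:
the study reports a mean PET of 15.3 h (= 918 min), which contradicts its
own 976-min base-model chain (sum of the published per-stage means, also the
published base-scenario PET) and the 17 h median. This package targets the
internally consistent 976-min chain throughout; the 918-min figure is not
used anywhere.

## Command line

```bash
# base model, direct mode, scaled-down protocol
edflow simulate --scenario 0 --mode direct --reps 2 --horizon 30 --seed 1 --out out/

# calibrate queueing-mode service-time multipliers, then rank scenarios
edflow calibrate --out calibration.json
edflow compare --scenarios 0,4,5,6,9,10 --calibration calibration.json --out out/

# synthetic one-year patient-level dataset (CSV: patient_id, date,
# seven per-stage durations in minutes, total_pet)
edflow generate-observed --days 365 --seed 1 --out observed.csv

# Welch t-test validation of direct-mode simulation vs synthetic observed data
edflow validate --reps 2 --horizon 30 --seed 1 --out out/

# PET curve over added ward beds
edflow bed-sweep --max-beds 40 --step 10 --calibration calibration.json
```

Every run writes a `manifest.json` (config echo + seed + version) from which
it can be reproduced exactly. Event logs export as JSON-lines or CSV with
`--write-events`.

Model parameters (stage moments, staffing, bed pools, arrival presets,
scenario library) ship as editable YAML in `src/edflow/data/`; pass
`--config my.yaml` to override.

## Package layout

| module | contents |
| --- | --- |
| `edflow.stochastic` | triangular/exponential/diurnal variate generation, moment fitting, named seed streams |
| `edflow.des` | generic DES engine: future-event list, FIFO multi-server stations, shift schedules, shared pools, bed pools, gate, event log |
| `edflow.model` | the concrete seven-stage model, scenario application, service-time calibration |
| `edflow.analysis` | replication protocol, PET summaries, shares, Welch validation, scenario comparison, bed-expansion search |
| `edflow.observed` | synthetic patient-level "observed" dataset generator and CSV round-trip |
| `edflow.cli` | `edflow` command-line entry points |
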