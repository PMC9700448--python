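# Default parameters of the ED-to-inpatient admission flow model.
# Durations in minutes unless noted. Staffing counts are per shift and
# constant across the day's shifts.

subprocesses:
  - name: registration
    resource: clerk
    observed_mean: 14.0
    observed_sd: 1.9
    servers: 16        # 4 clerks x 4 registration units
  - name: triage
    resource: nurse
    observed_mean: 17.0
    observed_sd: 3.7
    servers: 24        # 6 nurses x 4 triage locations
  - name: assessment
    resource: physician
    observed_mean: 14.2
    observed_sd: 4.5
    servers: 20
  - name: referral_to_medicine
    resource: medical_registrar
    observed_mean: 175.3
    observed_sd: 38.1
    servers: 1
  - name: decision_to_admit
    resource: medical_registrar
    observed_mean: 525.5
    observed_sd: 93.5
    servers: 1         # single registrar on duty; the duplicated table row is read as a misprint
    # admission decisions are made on the day shift after morning rounds;
    # the backlog accumulating over the other 16 hours is what staffing
    # scenarios drain at different speeds
    per_shift_servers: [0, 1, 0]   # shifts: 00-08, 08-16, 16-24
  - name: room_allocation
    resource: nurse
    observed_mean: 163.6
    observed_sd: 28.8
    # room preparation is a coordination delay done in parallel across the
    # wards (bed manager, housekeeping, ward nurses); capacity does not bind
    servers: null
  - name: physical_transfer
    resource: nurse
    observed_mean: 66.4
    observed_sd: 12.2
    # porter transfers run in parallel; capacity does not bind
    servers: null

arrivals:
  preset: admitted_only
  full:
    mean_interarrival: 5.78
  admitted_only:
    admissions_per_day: 52
    # diurnal cycle: this share of each day's arrivals falls in the peak
    # window; set peak_share to null for a homogeneous Poisson stream
    peak_start_hour: 16
    peak_end_hour: 24
    peak_share: 0.75

routing:
  ed_boarding_capacity: 250
  annual_visits: 386889
  annual_referrals: 30185
  annual_admissions: 19058

bed_pools:
  - pool: ward
    bed_count: 173
    admission_share: 0.45
  - pool: AAU
    bed_count: 24
    admission_share: 0.35
  - pool: AMAU
    bed_count: 51
    admission_share: 0.20

# Exponential mean length of stay per pool; beds free up after this.
# Short-stay units turn over faster than wards: each pool's bed load
# (admissions/day x share x LOS) must stay below its bed count or the bed
# queue is unstable (72 h in the 24-bed AAU would mean utilization ~2.3).
length_of_stay_hours:
  ward: 72
  AAU: 24
  AMAU: 48

# The admitting team: a pooled physician group shared by the referral and
# decision-to-admit stations, working the same shifts as the decision stage.
# Its physicians also care for boarded patients and coordinate transfers, so
# only the efficiency fraction of their time is net station throughput.
admitting_team_size: 1
admitting_team_efficiency: 0.5
admitting_team_policy: fifo
admitting_team_shifts: null

shifts_per_day: 3

protocol:
  replications: 10
  horizon_days: 180
  warmup_days: 7
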