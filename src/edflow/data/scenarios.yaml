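# Scenario library: staffing and bed-capacity interventions.
# server_deltas add servers per shift to a station's pool; bed_deltas add
# beds to a ward pool; admitting_team enables the pooled physician group
# shared by the referral and decision-to-admit stations.

"0":
  description: Base model (without intervention)
"1":
  description: Add a clerk to the registration subprocess
  server_deltas: {registration: 1}
"2":
  description: Add a nurse to the triage subprocess
  server_deltas: {triage: 1}
"3":
  description: Add a nurse to the assessment subprocess
  server_deltas: {assessment: 1}
"4":
  description: Add an ED physician to the referral-to-medicine subprocess
  server_deltas: {referral_to_medicine: 1}
"5":
  description: Add one physician to the decision-to-admit subprocess
  server_deltas: {decision_to_admit: 1}
"6":
  description: Add two physicians to the decision-to-admit subprocess
  server_deltas: {decision_to_admit: 2}
"7":
  description: Add a nursing assistant to the room-allocation subprocess
  server_deltas: {room_allocation: 1}
"8":
  description: Add a nursing assistant to the physical-transfer subprocess
  server_deltas: {physical_transfer: 1}
"9":
  description: Implement an admitting team in the ED
  admitting_team: true
"10":
  description: Combined intervention (scenarios 6 and 9)
  server_deltas: {decision_to_admit: 2}
  admitting_team: true
"a":
  description: Add 31 inpatient ward beds
  bed_deltas: {ward: 31}
"b":
  description: Add 22 ward beds and create an admitting team
  bed_deltas: {ward: 22}
  admitting_team: true
"c":
  description: Add 14 ward beds and two decision-to-admit physicians
  bed_deltas: {ward: 14}
  server_deltas: {decision_to_admit: 2}
"d":
  description: Add 10 ward beds, an admitting team and two decision-to-admit physicians
  bed_deltas: {ward: 10}
  server_deltas: {decision_to_admit: 2}
  admitting_team: true
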