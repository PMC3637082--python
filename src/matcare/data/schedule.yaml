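# Default visit schedule: WHO focused-ANC model of four goal-oriented
# visits at gestational-age windows (completed weeks).  Schedule is
# deployment configuration: replace this file to use a denser national
# schedule.  A woman is overdue when today lies past the end of the first
# window with no completed visit.
schedule_version: "1.0"
visits:
  - {visit: 1, start_week: 8, end_week: 12}
  - {visit: 2, start_week: 24, end_week: 26}
  - {visit: 3, start_week: 30, end_week: 32}
  - {visit: 4, start_week: 36, end_week: 38}
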