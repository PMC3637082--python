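"""Replay a stalled labor on the electronic partograph.

The trace starts at 4 cm (active-phase onset), reaches 6 cm at 2 hours,
then stops progressing.  Against the default geometry (alert line rising
1 cm/h from 4 cm, action line parallel 4 h later) the trace falls into
the alert zone and finally crosses the action line: the alert prompt asks
for detailed reassessment, the action prompt demands urgent referral.
"""

from datetime import datetime

from matcare import LaborSession, Measurement, evaluate_labor
from matcare.defaults import default_catalog, default_ruleset

session = LaborSession(datetime(2024, 3, 1, 6, 0),
                       [Measurement(0, 4, fhr=140),
                        Measurement(2, 6, fhr=144)]
                       + [Measurement(t, 6, fhr=150)
                          for t in (3, 4, 5, 6, 7)])

result = evaluate_labor(session, ruleset=default_ruleset(),
                        catalog=default_catalog())

prompts = {}
for p in result.prompts:
    prompts.setdefault(p.t, []).append(p)
for z in result.zones:
    action = "-" if z.action_line is None else f"{z.action_line:.1f}"
    print(f"t={z.t:4.1f} h  d={z.dilatation:4.1f} cm  "
          f"alert={z.alert_line:4.1f}  action={action:>4}  zone={z.zone}")
    for p in prompts.get(z.t, []):
        print(f"      >> [{p.kind}] {p.message}")

print(f"\naction line first crossed at t={result.first_action_time()} h")
# At 4 h the point (6 cm) lies below the alert line (8 cm): alert zone.
# At 6 h it meets the action line (6 cm): on-line counts as crossed.
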