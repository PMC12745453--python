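"""Score one plot's observed activities into intensity indices.

Each observation record is (activity code, participant count); codes
1xx/2xx/3xx are exercise/leisure/social. The indices weight counts by
each activity's MET value, so OBI/EBI/LBI/SBI are in MET.persons.
"""

from parkscape import default_met_table, score_plot
from parkscape.behavior import BehaviorRecord, behavior_summary

records = [
    BehaviorRecord("plot-A", "weekend-08:00-10:00", 112, 18),  # social dancing
    BehaviorRecord("plot-A", "weekend-08:00-10:00", 102, 7),   # tai chi
    BehaviorRecord("plot-A", "weekend-08:00-10:00", 202, 12),  # sitting
    BehaviorRecord("plot-A", "weekend-08:00-10:00", 302, 5),   # group conversation
]

met = default_met_table()  # stand-in table; pass your own for real studies
scores = score_plot(records, met)
print(f"EBI = {scores.EBI:.1f}  LBI = {scores.LBI:.1f}  "
      f"SBI = {scores.SBI:.1f}  OBI = {scores.OBI:.1f}  (MET.persons)")
print("OBI is exactly EBI + LBI + SBI:", scores.OBI == scores.EBI + scores.LBI + scores.SBI)

print("\nShares of observed participants by activity:")
print(behavior_summary(records).to_string(index=False))
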