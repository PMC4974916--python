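"""Quality-control filtering of encounter logs.

Raw tag downloads mix tag-to-tag logs with error messages, multi-pulse
averages and records captured while an array was being carried around.
The cleaning step keeps single-pulse tag-to-tag logs inside the trial
window and tallies every removal under the first failing rule.
"""

from proxcal import datasets, logstore

logs = datasets.example_logs()
print(f"{len(logs)} example encounter logs; first record:")
first = logs[0]
print(f"  receiver {first.this_id} heard tag {first.enc_id} at RSSI "
      f"{first.rssi_mean:g} dB, t = {logstore.ticks_to_seconds(first.first_time):.3f} s")

retained, report = logstore.clean_logs(logs, window=(0, 2**62), tag_type_codes={1})
print(f"\nCleaning: retained {report.n_retained}/{report.n_input} "
      f"({report.n_multi_pulse_removed} multi-pulse averages removed)")
print("Retained logs are all single pulses:",
      all(logstore.is_single_pulse(lg) for lg in retained))

# The averaging firmware option, emulated: three pulses of 8, 1 and 3 dB
pulses = [logstore.TagLog(10, 61, t, t, v, v, v, 1)
          for t, v in [(0, 8.0), (64 * 20, 1.0), (64 * 40, 3.0)]]
(agg,) = logstore.aggregate_pulses(pulses, max_pulses=3)
print(f"\nAggregating pulses (8, 1, 3) dB -> max {agg.rssi_max:g}, "
      f"min {agg.rssi_min:g}, mean {agg.rssi_mean:g}")
print("Filtering on the mean of an averaged log is conservative: the mean")
print("never exceeds the strongest pulse in the sequence.")
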