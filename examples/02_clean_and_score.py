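"""Simulate a dot-probe cohort, clean the reaction times, score the bias.

Trials are discarded in order: error responses, RTs outside (200, 2000) ms,
then a single 2-SD pass per participant x timepoint x trial-type cell.
Participants with more than 20% of any cell discarded are excluded. The
bias index is mean RT(incongruent) - mean RT(congruent) on retained trials:
positive = attention drawn toward the threatening (disgusted) face.
"""

import abmtrial as ab

alloc = ab.allocate_blocks(100, seed=7)
trials = ab.generate_trials(alloc, ab.RtGenModel(), seed=7)
print(f"simulated {len(trials)} trials for {alloc.shape[0]} participants "
      "(100 per timepoint, types balanced 50/50)")

cleaned, report = ab.clean_trials(trials)
by_reason = cleaned["discard_reason"].value_counts()
print("\ndiscards by reason:")
for reason in ("error", "absolute_bounds", "sd_outlier"):
    print(f"  {reason:16s} {by_reason.get(reason, 0):5d}")
print(f"participants excluded (>20% of a cell): {len(report.excluded)}")

bias = ab.bias_table(cleaned, exclude=report.excluded_participants)
pre = bias[bias["timepoint"] == "pre"]["bias_index"]
print(f"\npre-training bias index: mean {pre.mean():+.1f} ms, SD {pre.std():.1f} ms")
print("near-zero mean and a ~40-50 ms SD mirror a cohort with no group-level")
print("attentional bias and the usual dot-probe measurement noise.")
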