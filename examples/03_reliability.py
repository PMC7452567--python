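"""Split-half reliability of the bias index, and Cronbach's alpha.

The bias index is a difference of two noisy means, so its internal
consistency is notoriously poor. We estimate it by 5000 random stratified
splits of each participant's pre-training trials (Spearman-Brown corrected
average), then derive the standard error of measurement and the reliable
change threshold that the Jacobson-Truax classification uses.
"""

import abmtrial as ab

alloc = ab.allocate_blocks(100, seed=11)
trials = ab.generate_trials(alloc, ab.RtGenModel(), seed=12)
cleaned, report = ab.clean_trials(trials)
pre = cleaned[cleaned["timepoint"] == "pre"]

est = ab.split_half_reliability(pre, n_splits=5000, seed=13,
                                exclude=report.excluded_participants)
print(f"split-half reliability (5000 splits, Spearman-Brown): r = {est.value:.3f}")

bias = ab.bias_table(cleaned, exclude=report.excluded_participants)
sd0 = bias.loc[bias["timepoint"] == "pre", "bias_index"].std()
se_m = ab.sem(float(sd0), est.value)
s_diff = ab.sdiff(se_m)
print(f"baseline bias SD = {sd0:.1f} ms -> SE_M = {se_m:.1f} ms, S_diff = {s_diff:.1f} ms")
print(f"a participant must change by >= {1.96 * s_diff:.0f} ms to count as reliably changed —")
print("with reliability this low, almost no individual change is detectable.\n")

scores = ab.generate_scores(alloc, ab.ScoreGenModel(), seed=14, with_items=True)
items = scores[scores["assessment"] == 0].filter(like="item_")
alpha = ab.cronbach_alpha(items)
print(f"questionnaire internal consistency (48 items): alpha = {alpha.value:.3f}")
print("high alpha means a tight reliable-change band for the anxiety score.")
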