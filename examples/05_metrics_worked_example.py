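"""Worked evaluation-metric example on a reconstructed confusion matrix.

With 15 laser and 85 non-laser infants, a model detecting 11 of 15 cases
with 10 false alarms gives the metric suite below, including Agresti-Coull
95% intervals and a mid-p McNemar comparison against a weaker model.
"""

from ropvitals.metrics import confusion_metrics, mcnemar_midp
from ropvitals.metrics import round_half_away as r2

res = confusion_metrics(tp=11, fp=10, fn=4, tn=75)
print(f"sensitivity        {r2(res.sensitivity):.2f}  "
      f"({r2(res.intervals['sensitivity'][0]):.2f}-{r2(res.intervals['sensitivity'][1]):.2f})")
print(f"specificity        {r2(res.specificity):.2f}  "
      f"({r2(res.intervals['specificity'][0]):.2f}-{r2(res.intervals['specificity'][1]):.2f})")
print(f"balanced accuracy  {r2(res.balanced_accuracy):.2f}")
print(f"MCC                {r2(res.mcc):.2f}")
print(f"PPV / NPV          {r2(res.ppv):.2f} / {r2(res.npv):.2f}")

# paired comparison: 5 infants classified correctly only by this model,
# 1 only by the other -> two-sided mid-p McNemar
print(f"\nmid-p McNemar, discordant pairs (5, 1): p = {mcnemar_midp(5, 1):.3f}")
# p > 0.05: the apparent advantage is not statistically convincing at this
# sample size — discordant pairs are few
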