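"""Simulate a poaching season and summarise its temporal structure.

Draws a 77-day spring season of Poisson gunshot events for two sites
(seasonal bump peaking in late April, diel profile concentrated in the
morning), thins it with an imperfect detector, and reports the seasonal
window fraction, diel concentration, and detector thinning rate.
"""

from pamharvest import SeasonSimSpec, diel_summary, seasonal_summary, simulate_season
from pamharvest.harvest import weekday_summary

spec = SeasonSimSpec(sites={"coastal": 60.0, "inland": 15.0},
                     true_recall=0.624, seed=0)
truth, detected = simulate_season(spec)

frac, daily = seasonal_summary(truth, "2021-04-10", "2021-05-05")
hist, day_frac = diel_summary(truth)

print(f"events (truth)        : {len(truth)} across {len(spec.sites)} sites")
print(f"events (detected)     : {len(detected)} "
      f"(thinning rate {len(detected) / len(truth):.3f}, true recall 0.624)")
print(f"in 10 Apr - 5 May     : {frac:.1%} of all gunshots")
print(f"between 7 am and 5 pm : {day_frac:.1%}")
print(f"busiest day           : {daily.idxmax().date()} ({daily.max()} shots)")
print(f"busiest hour          : {hist.idxmax()}:00 ({hist.max()} shots)")
print(f"weekday counts        : {weekday_summary(truth).to_dict()}")
print("The generating intensity concentrates 86% of shots in the late-April")
print("window and >93% before 5 pm; the detected log is an independent")
print("Bernoulli thinning of the truth at the detector's recall.")
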