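"""Estimate the 2021 illegal turtle-dove harvest from the packaged counts.

Runs the full estimation chain on the packaged Ionian Islands tables:
detected gunshots -> recall-adjusted gunshots -> killed (1 per 5 shots)
and killed-or-injured (1 per 3 shots) birds at the monitored sites ->
island-wide totals via the fraction of hunting sites (posta) monitored.
"""

from pamharvest import harvest_table, percent_of_breeding_stock
from pamharvest.datasets import ionian_counts, ionian_strata

counts = ionian_counts()
configs, recall, precision = ionian_strata()

per_stratum = (counts[counts["year"] == 2021]
               .groupby("stratum", sort=False)["detected_gunshots"].sum())
detected = {label: int(per_stratum.get(label, 0)) for label in configs}

estimates, total = harvest_table(detected, configs, recall, precision)

header = f"{'stratum':<22}{'detected':>9}{'adjusted':>9}{'killed':>8}{'k-or-i':>8}"
print(header)
for est in estimates + [total]:
    d = est.display()
    print(f"{d['label']:<22}{d['detected_gunshots']:>9}{d['adjusted_gunshots']:>9}"
          f"{d['killed_extrapolated']:>8}{d['killed_or_injured_extrapolated']:>8}")

pct = percent_of_breeding_stock(total.killed_or_injured_extrapolated, 763250)
print(f"\nrecall = {recall:.1%}, adjustment factor = {round(1 / recall, 3)}")
print(f"harvest as % of the affected breeding stock "
      f"(763,250 pairs, 2 birds/pair): {pct}%")
print("Killed and killed-or-injured bracket the harvest under the 1:5 and")
print("1:3 shots-per-bird assumptions; all intermediates stay unrounded")
print("until display, which the island totals are sensitive to.")
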