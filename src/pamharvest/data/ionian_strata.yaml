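# Harvest-estimation assumptions for the Ionian Islands acoustic grid,
# 2021 season. Posta fractions are field/expert judgments of the share
# of each island's hunting sites the grid monitors; shot ratios are the
# published dove-hunting kill (1:5) and killed-or-injured (1:3) rates.
recall: 0.624
factor_precision: 3
strata:
  zakynthos_south_coast:
    posta_fraction: 0.20
  zakynthos_inland:
    posta_fraction: 0.10
  antipaxi:
    posta_fraction: 0.30
  paxi:
    posta_fraction: 0.25
  othoni:
    posta_fraction: 0.50
  mathraki:
    posta_fraction: 0.50
defaults:
  shots_per_kill: 5
  shots_per_killed_or_injured: 3
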