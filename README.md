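# pamharvest

Passive-acoustic-monitoring (PAM) pipeline for quantifying illegal gun
hunting of migratory birds, built around the Ionian Islands turtle-dove
(*Streptopelia turtur*) spring-poaching case: a grid of autonomous 8 kHz
sensors records soundscapes 15 h/day across a spring migration season,
gunshots are found by spectrogram template matching, detector
performance is calibrated (recall, detection range), and verified
gunshot counts are converted into an estimate of birds killed.

It is written for conservation scientists and analysts who need a
reproducible, auditable chain from raw acoustic detections to a
harvest number — and for methodologists who want to probe how that
chain behaves under controlled synthetic conditions.

## The estimation model

For each stratum of monitored hunting sites ("posta"), with detected
gunshot count `D`, detector recall `r`, shots-per-bird ratio `k`, and
monitored posta fraction `q`:

```
adjusted gunshots   A = D * round(1/r, 3)        (recall correction)
birds at monitored sites  B = A / k              (k = 5 killed, 3 killed-or-injured)
island-wide estimate      H = B / q              (posta extrapolation)
```

All intermediates are carried at full precision; rounding (half away
from zero) happens only at display. Detector recall `r` is
TP / (TP + FN) against a manually verified subset; the detection range
is a Bernoulli-logit model `p(d) = logit⁻¹(β₀ + β₁ d)` fitted to
control gunshots fired at known distances, whose 50%-probability
distance (truncated at the farthest distance tried) gives the
effective monitored area `π r²`.

Because the original field recordings are not public, the package
includes a first-class synthetic-data module: band-limited impulsive
gunshot transients with 1/d amplitude decay in Gaussian noise,
control-shot experiments drawn from a known logistic truth, and
multi-site Poisson seasons with a late-April intensity bump and a
morning-heavy diel profile, thinned by a known recall. Every stage is
tested against that known truth.

## Worked example

`examples/03_harvest_estimate.py` runs the full chain on the packaged
2021 Ionian counts:

```
stratum                detected adjusted  killed  k-or-i
zakynthos_south_coast     14012    22461   22461   37435
zakynthos_inland           2115     3390    6781   11301
antipaxi                   2351     3769    2512    4187
paxi                       1476     2366    1893    3155
othoni                      240      385     154     256
mathraki                    711     1140     456     760
TOTAL                     20905    33511   34257   57095

recall = 62.4%, adjustment factor = 1.603
harvest as % of the affected breeding stock (763,250 pairs, 2 birds/pair): 3.7%
```

Reading the TOTAL row: 20,905 verified gunshots imply 33,511 shots
after recall correction, bracketing 34,257 birds killed to 57,095
killed-or-injured across the five islands once each stratum is
extrapolated by its posta fraction — about 3.7% of the breeding stock
of the populations migrating through.

The other examples cover detection on a synthetic scene
(`01_scene_detection.py`), detection-range calibration
(`02_detection_range.py`), and season simulation with temporal
summaries (`04_season_patterns.py`). The same stages are scriptable
from the shell:

```
pamharvest run-all --out results/ --seed 1
pamharvest detect --audio recordings/ --threshold 0.4 --out detections.csv
pamharvest estimate --out results/
```

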