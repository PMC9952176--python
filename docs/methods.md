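# Methods

## The problem

Spring gun-poaching pressure on migrating turtle doves is estimated
from continuous acoustic recordings at known hunting sites. The chain
has four statistical components: (1) an automated gunshot detector
whose hits are verified by review; (2) a recall calibration that says
what fraction of true gunshots the detector finds; (3) a detection-range
calibration that says how far out a sensor hears shots, hence what area
each sensor monitors; (4) an extrapolation that converts recall-adjusted
gunshot counts into birds killed and scales monitored-site figures to
whole islands. This package implements all four, plus a synthetic-data
generator that stands in for the (undeposited) field recordings.

## Gunshot detection

Recordings are PCM mono at 8 kHz. The detector slides an exemplar
spectrogram patch over the recording's log-magnitude STFT and scores
each alignment by Pearson correlation, clipped below at zero so scores
live in [0, 1]; windows with zero variance score 0 by convention.
Alignments are computed exactly (frame count = ⌊(n − window)/hop⌋ + 1)
and the correlation is evaluated with FFT convolution plus moving-sum
norms, so hour-scale files run in seconds in bounded memory (recordings
are chunked with one-template overlaps, and seam duplicates removed by
onset proximity).

Numerical choices:

* **STFT analysis window 256 samples (32 ms), hop 64, Hann.** Gunshots
  are impulsive; a 32 ms window resolves their onset while keeping
  ~90 frequency bins in the 200–3000 Hz analysis band. Review-display
  spectrograms traditionally use much longer windows (e.g. 2048
  samples), which are fine for human eyes but far too coarse for
  frame-level scoring; the analysis window is therefore an independent,
  configurable setting.
* **Log floor.** Power spectrograms are floored at 1e−12 before the
  log, placing digital silence at a constant −120 dB. Raising the floor
  was found to compress the score contrast between shot and noise
  windows, so the floor is kept low and the template is built from
  clean exemplars.
* **Operating threshold 0.4.** Kept as the field operating point. On
  synthetic scenes at a peak signal-to-noise ratio of ~34 dB
  (250–300 m shots over noise RMS 0.005) true shots score ≈ 0.42–0.46
  while the noise-only null tops out near 0.06 over an hour, so the
  threshold separates cleanly at realistic ranges; recall degrades as
  distance pushes the score toward the threshold, which is exactly the
  behaviour the recall calibration exists to correct.
* **Peak picking.** Local maxima above threshold survive a
  non-maximum-suppression refractory of half the template duration
  (0.2 s — one physical shot, one peak); surviving peaks closer than
  the 0.5 s separation default merge into one selection window whose
  `n_gunshots` counts the merged peaks, mirroring review windows that
  can hold many rapid shots. The sum of `n_gunshots` over events always
  equals the number of accepted peaks.

Selection tables are read and written in the Raven-style tab-separated
format (`Selection`, `Begin Time (s)`, `End Time (s)`, `Low Freq (Hz)`,
`High Freq (Hz)` plus score/count/sensor annotations); missing
mandatory columns and non-numeric (e.g. comma-decimal) fields raise
named format errors.

## Recall and the adjustment factor

Recall is pooled over the verified subset: TP/(TP+FN) under greedy
one-to-one matching of detection times to truth times in order of
increasing time difference, within a 1.0 s tolerance (gunshots are
sub-second events and shooters pause between volleys; the tolerance is
configurable). The adjustment factor is the reciprocal of recall.
When adjusting counts the factor is **rounded to 3 decimals before
application** — the convention under which every cell of the published
harvest table reproduces exactly (e.g. recall 62.4% → factor 1.603;
14,012 detected → 22,461 adjusted, where the unrounded reciprocal gives
22,455). `factor_precision=None` applies the exact reciprocal instead,
making adjustment and Bernoulli thinning exact inverses; the unbiasedness
tests use that mode.

## Detection range and monitored area

Control shots at known distances give Bernoulli outcomes fitted with a
logit link by maximum likelihood (IRLS, convergence 1e−8). Complete
separation — all shots detected out to the farthest distance tried, as
happens with human review, or any perfect distance split — is detected
beforehand; the fit then returns a flagged model with the slope capped
at 0.05/m and its midpoint at the class boundary instead of diverging.
The effective radius is the closed-form distance where p(d) falls to
0.5, truncated at the farthest distance actually tried (1100 m in the
packaged configuration): an experiment cannot support claims beyond its
observed range. The monitored area is π(r/1000)², reported to one
decimal km².

Two distinct detector properties deliberately stay separate: the
*algorithmic recall* (fraction of verified shots the template detector
finds) corrects counts, while the *audible radius* (how far shots are
detectable at all, from the all-found human review) sets the monitored
area used when judging posta fractions. Collapsing them would
double-count the detector's misses.

## Harvest estimation

Per stratum: adjusted = detected × factor; killed = adjusted/5;
killed-or-injured = adjusted/3; island-wide = monitored/posta_fraction.
The shots-per-bird ratios (5 to kill, 3 to kill-or-injure) come from
published dove-hunting kill rates and are config values, as are the
posta fractions (0.10–0.50 across the packaged strata), which encode
field judgment about what share of an island's hunting sites the grid
hears. Totals sum full-precision components and round last; a
regression test pins the one table cell (inland, 6,781) that changes if
an intermediate is rounded early. Display rounding is half away from
zero everywhere, the unique convention consistent with every published
cell.

Between-season change is (b − a)/a × 100 on raw summed counts; the
overall 2021→2022 figure excludes sites missing either season (sensor
malfunction) or with a zero baseline (change undefined), and reports
which. The harvest-vs-breeding-stock percentage divides birds by
**individuals** (2 × breeding pairs) by default — the reading consistent
with the published 3.7% — with the literal per-pair reading available
via `per_pair=True` (it roughly doubles the figure).

## Synthetic data: what it emulates and what it does not

* **Gunshot pulse**: a 4th-order Butterworth band-pass (200–3000 Hz) of
  a unit impulse under an exponential decay (12 s⁻¹), peak-normalised
  and scaled by 1/d spherical spreading from a 100 m reference. It is
  impulsive, broadband, deterministic and amplitude-controllable —
  sufficient for exercising a template detector — but it is not a
  physical muzzle-blast model: no ground reflection, directivity,
  atmospheric absorption or terrain shadowing (the field calibration
  site was flat and open, which this idealisation matches best).
* **Scenes**: white Gaussian noise at a configurable RMS with pulses
  added at specified onsets/distances; normalised only if superposition
  exceeds full scale. Real soundscapes have coloured, nonstationary
  noise and confusable transients (thunder, fireworks, bird-scarers);
  synthetic recall and false-positive figures therefore certify the
  detector's mechanics, not its field performance.
* **Seasons**: per site and day, Poisson counts with mean
  base_intensity × s(day), where s is a Gaussian bump (σ = 7 days,
  peak 22 April) on a constant floor (0.0333 of bump height),
  normalised to mean 1 over the 77-day season (15 March–31 May,
  end-exclusive, matching 77 × 15 h of recording). The floor/width
  defaults place 86% of the generating intensity inside 10 April–5 May;
  the field data's sharp day-to-day spikes are *not* modelled — only
  the window fractions downstream summaries consume. Clock times draw
  from 15 hourly diel weights (uniform over 07:00–17:00 carrying 93% of
  mass, the evening 7%). Detection logs are independent Bernoulli
  thinnings at a configurable recall (default 0.624).
* **Seeding**: one root seed; each (site, day) gets its own stream
  derived from (root, crc32(site), day ordinal), so adding a site
  leaves every other site's events bit-identical.

## Problem sizes

The test suite and acceptance script use desk-scale problems chosen to
make the statistics decisive at interactive runtimes: four 60 s scenes
(40 shots) plus one shot-free noise hour for detector recall and false
positives; 100 replicate control experiments of 480 shots for logistic
recovery (median relative error ≈ 5% per coefficient); 60 simulated
seasons for end-to-end unbiasedness (mean within 2 standard errors of
the known harvest); 200 seasons for the Poisson-mean and thinning
checks. The published-table arithmetic runs in milliseconds.

## Known limitations

* No precision/false-discovery modelling: counts are corrected by
  recall only, as in the estimation protocol being reproduced.
* Posta fractions and kill rates are consumed as configuration, not
  estimated; uncertainty in them dominates the real-world error budget
  and is outside the package's scope (the killed vs killed-or-injured
  bracket is the only interval reported).
* The logistic range model assumes a monotone decline with distance and
  ignores shot orientation and weather.
* Greedy time matching is order-optimal for well-separated events but
  can undercount matches in pathological overlapping configurations; an
  enumeration cross-check in the tests bounds it by the true maximum
  matching.
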