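# confseek

Synthetic EEG study of decision confidence and information-seeking, with
the complete analysis chain used to test whether a **post-decisional neural
marker of confidence predicts the decision to sample more evidence**.

The package is for researchers in cognitive/computational neuroscience who
want a fully generative, seed-reproducible testbed for this family of
analyses: a color-mean discrimination task with a paid "see the stimulus
again" option, a stochastic observer whose confidence drives information-
seeking, a forward EEG model with confidence-coupled components, and the
statistics that operate on such data — ERP cluster-based permutation tests,
time-resolved single-trial regression, and sliding-window spatial-filter
decoding with temporal generalization.

## The model and statistics in brief

**Observer.** On a trial with mean color position `C` (category boundary
0.5) and element variance `V`, the observer draws evidence
`e ~ N(C − 0.5, σ(V))` with `σ(V) = s·√V`, chooses `sign(e)`, and reports
confidence as a noisy saturating function of the evidence-to-noise ratio
`|e|/σ(V)` on a −50..50 scale. On free-choice trials (75%) it pays one
point to re-view an easier stimulus (`C′ = C ± 0.01`, `V′ = V − 0.0167`)
whenever confidence falls below a threshold; accuracy earns ±5 points
(650 points = £1). A between-block staircase on inverse efficiency
(median RT / p(correct)) equates the low-mean and high-variance cells.

**EEG.** 32 channels; each trial's signal is a stimulus-locked
centroparietal positivity (P3-like, 300–600 ms, amplitude
`α0 + a_P3·z_conf`) plus a response-locked positivity (Pe-like, error
positivity, 250–700 ms, amplitude `α0 − a_Pe·z_conf`: *low* confidence →
*large* Pe) in spatially and temporally correlated noise, synthesized on a
continuous timeline and cut on the stimulus, response and choice clocks.

**Decoding.** A logistic-regression spatial filter (one weight per channel,
linear derivation) is trained on 106 ms window-averaged signals and scored
with Az (ROC area) at every test window, giving a train-time × test-time
generalization matrix; within-condition matrices use repeated stratified
10-fold CV, across-condition matrices train on high/low confidence
(no-choice trials) and test on see-again/respond (free-choice trials) with
class-balanced resampling. True matrices are compared with shuffled-label
null matrices via a paired t per pixel; 8-connected clusters above the
element threshold (p = .01) are scored by mass Σ|t| and tested against the
max-mass sign-flip permutation null. The same machinery (1-D adjacency,
element p = .05) serves the ERP contrasts at CPz.

## Worked example

The numbered drivers under `analysis/` run a desk-scale study
(8 participants × 5 blocks × 64 trials, 250 Hz) end to end and write their
tables under `results/`:

```
$ python analysis/01_simulate_study.py
simulated 8 participants, 2560 trials
primary accuracy 0.797, final accuracy 0.859
see-again rate on free-choice trials 0.423
mean session payout £1.61

$ python analysis/02_behavior.py
condition means (over participants):
                      acc_primary  median_rt_ms  mean_conf_z  p_see_again
mean_level var_level
high       high             0.812        537.75       -0.451        0.406
           low              0.914        567.25        0.013        0.296
low        high             0.684        566.25       -0.608        0.535
           low              0.778        595.50       -0.415        0.454
logistic see_again ~ confidence_z: beta = -0.924, p = 4.51e-50
```

Accuracy falls and RT, seeking and (negatively) confidence track difficulty
in both factors, and confidence strongly negatively predicts seeking — the
behavioral coupling the EEG analyses rest on. The ERP and decoding drivers
then recover the neural structure:

```
$ python analysis/03_erp.py
confidence, stimulus-locked: cluster 492-532 ms (sign +1, p=0.008), ...
confidence, response-locked: cluster 408-568 ms (sign -1, p=0.008)
seeking,    response-locked: cluster 376-588 ms (sign -1, p=0.008)
regression (confidence): 404-552 ms (p=0.008), 568-632 ms (p=0.008)

$ python analysis/04_decoding_within.py
confidence, response-locked: peak group Az 0.621; 2 significant cluster(s), best p = 0.016
seeking,    response-locked: peak group Az 0.671; 1 significant cluster(s), best p = 0.000
confidence: post vs pre decoding, 2 px: Az 0.615 vs 0.467, t(7) = 6.27, p = 0.0004

$ python analysis/05_decoding_across.py
across, response-locked: peak group Az 0.600; cluster train 353-633 ms / test 313-553 ms (p=0.008)
across, stimulus-locked: peak group Az 0.526; no significant cluster
across with difficulty confound, EEG residualized: ... (p=0.008)
across with confidence-EEG coupling removed: no significant cluster
```

Read together: the stimulus-locked P3 is *more* positive and the
response-locked Pe *less* positive for high confidence; confidence and
information-seeking are decodable only after the response; a classifier
trained on confidence transfers to seeking in that same post-response
window, survives regressing out stimulus difficulty, and vanishes when the
generative confidence–EEG coupling is switched off — the across-condition
transfer really is carried by the confidence signal.

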