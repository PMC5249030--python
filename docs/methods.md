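# Methods

## Model

### Target-decoy premise

The package assumes a composite target-decoy search: decoy hits come from
reversed protein sequences, so an incorrect assignment is equally likely
to land on a target or a decoy sequence. Decoy counting then estimates
the number of wrong targets above any threshold, giving
`FDR(t) = D_t / (N_t − D_t)` with inclusive (≥ t) counting. Counting is
done on raw operating points — the estimate is deliberately **not**
monotonized into q-values, because threshold selection works on the raw
sweep ("most accepted targets subject to estimated FDR ≤ goal") and
monotonization would change the reported counts. Degenerate conventions:
FDR is 0 when nothing is accepted, and capped at 1.0 when only decoys
are.

### Cost-sensitive network

A 6→H→1 feed-forward network with sigmoid activations on both layers
maps the six scores to (0, 1). Defaults: H = 4 hidden nodes, learning
rate 0.3, momentum 0.2, 1000 epochs. The training set is the dataset to
be analyzed itself (class 1 = target, class 0 = decoy); there is no
cross-validation, because the labels being fit are not the quantity of
interest — most class-1 records are in truth incorrect, and the point of
the high false-positive cost is precisely to let the model "misclassify"
them toward class 0.

The cost matrix (CFP for misclassified decoys, CFN = 1 for misclassified
targets, zero for correct predictions) is realized as **instance
reweighting** of the loss, not minimum-expected-cost prediction:
reweighting preserves a continuous output, which the ROC sweep needs.
The loss is the weighted mean squared error; with integer weights,
training is numerically identical to training on a dataset with each
record replicated weight-many times (the tests assert this to 1e-8).

Numerical choices:

- Inputs are affinely mapped to [−1, 1] by their per-score min/max over
  the training data; the transform is stored in the model and reused at
  prediction time. A constant score column maps to 0.
- Optimization is full-batch gradient descent with classical momentum:
  one update per epoch from the weight-normalized mean gradient. This is
  exactly deterministic given the seed, vectorizes in numpy (per-record
  online updates at these epoch counts would be orders of magnitude
  slower in Python), and makes the weight/duplication equivalence exact.
  A per-record (online) update order would converge somewhat differently;
  nothing downstream depends on the specific optimizer beyond determinism
  and the separability sanity checks.
- Weights and biases initialize uniformly in [−0.5, 0.5] from the seeded
  generator; outputs are clipped to [1e−9, 1 − 1e−9].
- Models serialize to versioned JSON and round-trip exactly (floats via
  `repr`).

### Cost sweep and model selection

For CFP = 1…10 (CFN fixed at 1) a model is trained **with the same
derived seed**, so the sweep isolates the cost effect from the random
initialization. Each model is ranked by its mean accepted-target count
over the five integer FDR grid points 1–5%; the argmax wins, ties going
to the smaller CFP. CFP = 1 is the unweighted baseline, so the selected
model's mean sensitivity is ≥ the baseline's by construction. The final
model is the already-trained winner — retraining "a final model" with a
fresh seed would invalidate the saved threshold.

### Threshold selection and range correction

Among operating points with estimated FDR ≤ the goal (default 1%, the
usual sensitivity/precision trade-off), the one accepting the most
targets is selected; ties break toward the higher threshold (the goal
FDR is achievable at several probabilities and the spec of the original
procedure does not say which to take — the max-sensitivity rule is the
declared choice). If no point qualifies, the point with the smallest
estimated FDR is returned, flagged.

The threshold-selector range correction is the unique continuous
piecewise-linear map with the three stated anchors: observed minimum → 0,
threshold → 0.5, observed maximum → 1. It is order-preserving, so ROC
curves and AUC are invariant, and `{adjusted ≥ 0.5}` equals
`{raw ≥ t}` exactly. Degenerate halves (threshold at the observed minimum
or maximum) map constantly to their boundary value with a warning.
Out-of-range values (future data scored with a frozen map) are clipped
to [0, 1]. Decoys receive adjusted probabilities too, for auditing, but
only targets are reported as identifications. Only the fixed-threshold
mode of the threshold selector is implemented; the measure-optimizing
mode is out of scope.

## Synthetic data

The generator emulates a composite target-decoy search output in which
the decoy premise holds *by construction*: incorrect targets and decoys
are drawn i.i.d. from one shared parameter set, and exactly
`round(frac_correct · n_targets)` targets (default 15%, below the ~20%
seen in real runs) are drawn from the "correct" distributions.

Default score model (engineering choices, not literature claims; all
overridable):

| score | correct | incorrect/decoy |
|---|---|---|
| xcorr | Gamma(8, 0.45) + 1.5 | N(1.6, 0.4) truncated at 0 |
| delta_cn | Beta(5, 15) + 0.05, clipped to [0,1] | Beta(1.2, 20) |
| perc_ions | Beta(8, 4) | Beta(3, 8) |
| sp_rank | 1 + Geometric(0.7) | 1 + Geometric(0.15) |
| delta_m | N(0, 0.005 Da) (≈5 ppm of a 1 kDa precursor) | U(−1.1, 1.1) Da |
| rt_pvalue | Beta(1, 9) | U(0, 1) |

Charges are sampled from {2, 3}; peptide strings are random
tryptic-looking sequences (plumbing only). The phospho-like preset
shrinks the correct-population ΔCn to Beta(2, 18) + 0.02, mimicking the
ΔCn suppression of near-isobaric multi-site phosphopeptide candidates,
and marks phosphopeptides Sequest-style with `*`.

What a green test establishes — and what it does not: the generator has
no spectrum model, no retention-time model, and no attempt to fit real
Sequest score distributions; its inter-score correlations are zero within
each population. Calibration results on it validate the *arithmetic and
wiring* of decoy counting, threshold selection, and range correction
under the exchangeability assumption, not performance on real data.

A note on calibration limits: with `n_decoys = n_targets` and 15% correct
targets, there are more decoys (5000) than incorrect targets (4250), so
the decoy-counting estimate carries a positive bias of roughly
`(n_decoys − n_incorrect) · q / tp` at incorrect-acceptance rate q. The
bias is negligible in the method's 0–5% operating range (< 1pp) but grows
to ~15pp at the loosest thresholds; calibration tests therefore target
the operating range.

## Data handling

The canonical format is a TSV with a fixed header; decoy status is a pure
function of the accession prefix (default `REV_`, configurable — the
convention for reversed-sequence decoys). `NA`/empty is rejected in
required score columns. An optional idXML reader maps common Sequest
score names from `UserParam` entries onto the canonical columns and keeps
only the best hit per spectrum (the canonical table assumes one best hit
per spectrum throughout). Stratification splits by phospho marker and
precursor charge, keeping +2/+3 by default and flagging strata with fewer
than 10 target PSMs as unusable for training.

## Known limitations

- The RT p-value is consumed, never computed; no spectrum-level formats
  (mzML, pepXML, mzIdentML) are handled.
- No protein inference; the calibrated probabilities are the hand-off
  point.
- No PEP/local-FDR or mixture modeling — the decoy-counting estimate is
  global by design.
- At sharply reduced epoch counts the network can underfit on some seeds
  (few accepted targets); the decoy-counting estimate remains calibrated
  in that regime, but sensitivity suffers. The published defaults
  (1000 epochs) are recommended for real use.
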