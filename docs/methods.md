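# Methods

This note documents the models and procedures implemented in
`lifehorizon`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data experiments do and do not
demonstrate.

## Problem formulation

Life-expectancy prediction is cast as discrete multi-class
classification over a 50-month horizon rather than as regression or
survival analysis. Each deceased patient's final five years are divided
into 61 thirty-day bins anchored backward from the date of death
(bin 61 = the 30 days ending at death). A sliding 10-month window with
stride 1 yields, per patient, exactly one training sample for every
months-to-death label 1–50; the window whose final month contains the
death itself (label 0) is excluded, so the model never sees the death
month. The maximum predictable horizon, 50, is the 61-month history
minus the 10-month window minus the excluded death month.

Death-anchoring is deliberate: it aligns labels exactly with
months-to-death and gives every patient the same 61-vector, 50-sample
structure. The cost is that the binning is not calendar-aligned across
patients; since all features are within-patient frequencies this has no
cross-patient consequence.

## Structured features

Events are grouped into eight categories: ICPC diagnosis, ICPC reason
for encounter, ICD code, ICPC intervention, ICPC medical history,
medication, lab result, and consultation type. Codes of the shape
`[letter][number].[decimals]` can be abstracted at five levels: the full
code, letter+number (decimals dropped), the body-system letter alone,
a thematic element looked up from the code's numeric component, or
letter + element. The default configuration uses letter+number for
diagnoses / reasons for encounter / ICD, letter+element for
interventions and medical history, dosage-stripped lowercase names for
medications, and keeps lab results only when flagged irregular or
abnormal — the combination found to work best in the study this package
operationalizes. The shipped element table maps ICPC numeric component
ranges (1–29 symptom/complaint, 30–49 standard procedure, 50–59
treatment, 60–69 test result/administrative, 70–99 diagnosis) and is a
plain editable TSV, since no canonical table is distributed with ICPC.

Four per-category frequency cut-offs are available: none, absolute
occurrence ≥ 100 (the default), relative frequency ≥ 1% of the category
mass, and dropping the least frequent features that jointly cover ≤ 25%
of the category mass (ties drop the lexicographically larger feature
first). Cut-offs are computed per category, over the corpus the
vocabulary is built from — by convention the development split only, so
the held-out test patients never influence the feature space.

Counts are normalized by dividing every (month, category) block by its
maximum, mapping values to [0, 1] with at least one 1 per non-empty
block. The source description of this normalization is ambiguous between
a within-month and a whole-history denominator; the within-month reading
is the default here because it also annuls month-to-month differences in
contact intensity, and the whole-history alternative is exposed as
`normalize_monthly(..., per_history=True)`.

## Free-text features

Documents pass through, in order: boilerplate stripping (letters only;
pattern-based greeting/address headers and sign-off footers),
lower-casing and tokenization, abbreviation expansion, synonym mapping,
lexicon-based spelling correction (unique nearest lexicon word within a
configurable Levenshtein distance; ties and misses leave the token
unchanged), and an optional annotator hook where a lemmatizer or POS
tagger can be plugged in (the default passes tokens through —
reimplementing a Dutch tagger is out of scope). Each stage preserves
token order and is idempotent, so the pipeline is too. The shipped
lexicons are small and illustrative; production use should supply
domain lexicons via the same TSV format.

Three keyword-feature strategies mirror the three reduction approaches
of the study:

* **Frequency**: top-*n* content words by corpus frequency (stop-words
  excluded; ties lexicographic).
* **Entropy (KL)**: words ranked ascending by Kullback–Leibler
  divergence between their pooled temporal distribution over
  months-to-death (1–50, all patients' documents pooled by
  death-anchored month) and a reference distribution. The reference is
  configurable; the default puts linearly increasing mass toward death
  (reference ∝ 51 − *m* for months-to-death *m*), encoding that a
  prognostically relevant word is used more as death approaches, with a
  uniform alternative. Additive smoothing of one pseudo-count per bin is
  applied before scoring so the divergence is always finite. Note the
  selection favours words whose temporal profile *matches* the
  reference; a word confined to the last two or three months diverges
  from the linear reference more than a uniformly used word does, so
  "concentrated near death" and "low KL to the reference" are not the
  same property.
* **Embedding**: skip-gram word2vec with negative sampling (minimum
  count 10, context window 5, 100/200/300 dimensions, 300 default),
  trained single-threaded under a fixed seed for reproducibility. The
  trainer uses a fixed (not sampled) context window and the conventional
  unigram^0.75 negative-sampling distribution. A month's text is the
  arithmetic mean of its in-vocabulary word vectors.

Keyword counts are concatenated after the structured features and
max-normalized per month like a ninth category; embedding means are
concatenated unnormalized (they are already small and signed, and
max-division would be meaningless for them). Keyword counts are
frequency-valued, not binary, consistent with the frequency-count
treatment of every other category.

## The LSTM horizon classifier

A stacked two-layer LSTM (50 units per layer, tanh cell activation,
sigmoid gates, no peepholes, no dropout) reads the 10 monthly vectors;
a dense layer projects the final step's hidden state onto 50 logits and
a softmax turns them into a horizon distribution. The loss is
cross-entropy between that final-step distribution and the one-hot
label; a variant that also penalizes intermediate steps exists behind
`loss_all_steps` but is not the tested configuration. Optimization is
Adam (β₁ = 0.9, β₂ = 0.999) with batch size 5, per-epoch reshuffling,
and the final short batch kept. Weights initialize from a truncated
normal (±2 sd, sd 0.1 — the sd is a package choice, as no value is
canonical) and all biases at 0.1.

The parity defaults are a learning rate of 10⁻⁵ and 10 epochs.
Convergence and signal-recovery experiments use an elevated rate of
10⁻³, because at 10⁻⁵ the loss moves too little on small synthetic
cohorts for a meaningful test; both are plain configuration values.

Argmax ties resolve toward the earlier month — the pessimistic
direction, which in a care-planning context is the safer default. The
certainty of a prediction is the softmax maximum; it is a relative, not
calibrated, confidence measure.

Forward pass, backpropagation through time, and Adam are implemented in
numpy, single-threaded; together with seeded initialization and
shuffling this makes build + train + predict bit-reproducible. The
gradients are verified against central finite differences in the test
suite for both loss variants.

## Evaluation protocol

The 10% of patients with the most recent death dates (ceil(0.10·N),
ties broken by patient id) form the held-out test set, mimicking
deployment on new patients; ten-fold cross-validation partitions the
remaining development cohort for model and feature selection. Evaluation
is per window sample, so each test patient contributes 50 outcomes and
the pooled actual-label histogram is flat at the test-cohort size.

The quotient *Q* = actual/predicted classifies a prognosis as accurate
(0.67 ≤ *Q* ≤ 1.33, boundaries read as inclusive and isolated in one
function so the exclusive reading is a one-line change), overly
optimistic (*Q* < 0.67: the patient died sooner than predicted) or
overly pessimistic (*Q* > 1.33). The proportional margin is deliberately
more tolerant of errors at long horizons. Reports add RMSE and mean
deviation with the sign convention predicted − actual (positive =
overestimated life expectancy), the predicted/actual histograms, and
Pearson correlations (with two-sided p) for actual-vs-predicted and for
certainty against actual, predicted, and |actual − predicted|. When a
derived series is constant (e.g. perfect predictions make
|actual − predicted| identically zero) that row reports NaN rather than
failing the other rows; constant primary series raise.

The quotient-accuracy of a uniform random predictor against uniform
labels — the chance level any trained model must beat — is computed by
exhaustive enumeration of all 2,500 (actual, predicted) pairs, not
assumed: it is ≈ 29.2%, far above 1/50, because the proportional band
covers many pairs at long horizons. Note that a model with no prognostic
information can exceed even this bar simply by preferring long horizons
where the band is widest; beating chance is a necessary, not
sufficient, sign of signal.

## Synthetic cohort generator

The generator emulates the descriptive statistics of the study cohort:
52% female; age at death normal (sd 8 years, truncated at 18) with
means 81 (women) and 76 (men), giving an overall mean of ≈ 78.6; about
121 consultations per patient over the 61 months (uniform monthly
Poisson rates by default, with an optional per-month hazard multiplier
for realism experiments); a document on 75% of consultations, 85% notes
/ 15% letters; ICPC/ICD-shaped codes drawn from a small per-category
vocabulary; letters wrapped in greeting/sign-off boilerplate. Death
dates spread uniformly over a fixed three-year window so the recency
split is meaningful; birth dates derive from death date minus sampled
age. The source material states both "three consultations per month" and
121 per five years (≈ 2/month); the generator calibrates to 121 and the
discrepancy is left unreconciled. The sd of 8 years and the background
event rates (1.2 coded events, 0.3 labs, 0.5 medications per
consultation, 70/15/15 normal/irregular/abnormal lab flags) are package
choices where no value is stated, picked to be unremarkable for a
general-practice population.

A **plantable prognostic signal** makes recovery experiments possible:
a marker code emitted (with configurable penetrance) in exactly the
month a configurable offset before death, and terminal keywords whose
per-document emission probability ramps linearly from 0 at
`keyword_ramp_start` months out to a peak at death. The marker code must
not occur in the background vocabulary, so presence and timing of the
signal are exactly known.

What the generator does **not** emulate: clinically coherent disease
trajectories (codes are exchangeable background noise), realistic Dutch
clinical language, comorbidity structure, inter-category correlation,
living patients, and any real prognostic structure beyond the planted
signal. Consequently, passing the signal-recovery tests shows the
pipeline can extract temporal structure it is known to contain — it
says nothing about performance on real records, whose headline accuracy
figures require the private cohort and are out of scope here.

## Problem sizes used in the checks

Structural checks run on a 1,270-patient cohort (so the 10% recency
split holds out exactly 127 patients and the pooled label histogram is
flat at 127); generator calibration uses 2,000 patients with agreement
required within three standard errors; signal recovery uses 500 patients
with a fully penetrant marker five months before death, learning rate
10⁻³ and 10 epochs, requiring held-out quotient accuracy above the
enumerated chance level and ≥ 90% of marker-bearing windows (labels
1–5) predicted within ±1 month; end-to-end determinism is checked by
running the full pipeline twice at 50 patients / 2 epochs and comparing
report bytes. These sizes are the package's chosen study conditions for
a desk-scale, fully reproducible run.

## Numerical and degenerate-input choices

* Logit stabilization subtracts the row max before softmax; sigmoid
  arguments are clipped at ±30; cross-entropy adds 10⁻¹² inside the log.
* KL terms with zero word-mass contribute zero; zero reference mass
  under positive word mass raises (prevented by smoothing).
* Events dated within the five calendar years but before the start of
  bin 1's 30-day grid fold into bin 1; events outside five years raise.
* All-zero (month, category) blocks stay zero under normalization.
* Empty feature-count maps yield empty retained sets, not errors; an
  empty cohort yields an empty vocabulary.
* A consultation history shorter than the window raises rather than
  padding.
* One master seed derives per-stage seeds via CRC32 of "stage:seed", so
  stages are independently reproducible and any seed stays below 2³¹.

## Known limitations

* The quotient margin rewards long-horizon guessing; comparisons
  between models should always be read alongside RMSE and the deviation
  sign.
* The from-scratch skip-gram trainer is a faithful but slow
  implementation intended for the corpus sizes the generator produces,
  not for multi-million-word corpora.
* Spelling correction is lexicon + edit distance with conservative
  tie-breaking; it will not fix real-word errors or agglutinative Dutch
  compounds.
* The evaluation treats window samples as independent although 50 of
  them share a patient; confidence intervals on pooled percentages
  would need clustering by patient and are not implemented.
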