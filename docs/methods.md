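# Methods

## Variant identity and input handling

A variant is identified by the exact tuple (normalized chromosome, 1-based
position, reference allele, one alternate allele). Chromosome names are
normalized by stripping a leading `chr`, so `chr17` and `17` compare equal;
alleles are case-folded to upper and restricted to A/C/G/T/N. Multi-allelic
VCF records are split into one key per alternate allele; symbolic and
breakend alts are skipped with a counted warning. No left-alignment or indel
normalization is performed: single-nucleotide variants are the intended
input, and indels are matched literally. Genotype columns are ignored — the
presence of a record means the sample carries the variant, matching the
presence/absence encoding downstream. Records whose FILTER is neither PASS
nor missing are excluded by default; this is a flag (`pass_only`) because
upstream pipelines differ in whether they pre-filter.

## Feature panel (Mutation Collection)

The occurrence count of a site is the number of **distinct samples**
carrying it, not the number of mutation events; this is the natural reading
of ranking sites "by frequency of occurrence" in a cohort and is what the
column sums of the encoded matrix verify against. Ties in count are broken
by genomic order (numeric chromosomes first, then X/Y/MT, then position,
ref, alt), which makes the ranking deterministic across platforms and gives
top-K panels the prefix-nesting property (`top_k(k₁)` is a prefix of
`top_k(k₂)` for k₁ < k₂).

Two selection rules exist: `top_k` for the per-cancer (specific) models and
`min_occurrence` with a **strict** `count > m` cut (m = 2 by convention) for
the pooled cancer-vs-healthy and multi-cancer models. Specific-model panels
are built from the case cohort only — control-private sites never become
feature columns — and, in the bundled workflows, from the *training* cases
only, so held-out samples cannot influence the panel.

## Network and training

The classifier is four ReLU hidden layers plus a linear output layer feeding
softmax; "four fully connected layers and a softmax regression layer" is
ambiguous about whether the output layer is counted, and this design treats
it as four hidden + one output. Hidden widths are configurable; the package
default (512, 256, 128, 64) suits a 10,000-dimension panel, and the bundled
synthetic studies use (128, 64, 32, 16) against their 1,000-dimension panels
(mixture: (256, 128, 64, 32)).

Optimisation is plain minibatch gradient descent — no momentum or adaptive
rules — on mean cross-entropy (natural log, predictions clipped to
[1e−12, 1]) plus the L2 penalty λ·Σw² over weights only. The learning rate
follows R = r·d^(g/s) with optional staircase flooring. After every step
each parameter's shadow copy is updated by S ← d·S + (1 − d)·V with no
warm-up bias correction (the printed rule is implemented literally); all
inference uses the shadow parameters. Defaults, recorded as engineering
choices: r = 0.1, d = 0.96, s = 200, λ = 1e−4, d_ema = 0.99, batch 128.
Weights initialise from a truncated Gaussian (σ = 0.1, resampled beyond 2σ)
with biases 0.1, seeded; initialisation, batch sampling and splits all
derive from one seed, so runs are bit-reproducible.

Gradients are exact (verified against central finite differences to 1e−5
relative error over 100 seeded trials); a non-finite loss aborts with a
diagnostic rather than propagating NaNs.

## Evaluation conventions

Binary decisions are `score > threshold` (strict). Argmax and top-N ties
resolve to the lowest class index. The ROC sweep groups tied scores into a
single step and integrates by trapezoid, which makes it equal to the
Mann–Whitney U statistic divided by n⁺·n⁻ (ties counted half) — the
property the test suite asserts to 1e−9. The ROC is computed as TPR vs FPR;
a plotting flag mirrors the x-axis into the sensitivity-vs-specificity
presentation some reports use (the AUC is unchanged). The confusion matrix
is oriented rows = predicted, columns = true. Cross-model aggregation
reports the arithmetic mean and the **sample** (n−1) standard deviation:
only that estimator reproduces the published summary pairs from the
published per-model values, which the acceptance suite checks. With
single-class truth, the undefined rate is NaN with a warning rather than a
silent 0 or 1; macro averages skip NaN classes, and both macro and micro
(pooled one-vs-rest) specificities are emitted for multi-class models
because aggregation conventions differ between reports.

## Synthetic cohort generator

Each cancer-like class owns `n_signature` signature sites that its samples
carry independently with probability `penetrance`; every sample additionally
carries each of `n_background` background sites with probability `bg_rate`;
healthy samples carry background only. Sites are independent Bernoulli draws
with no linkage, trinucleotide context, subclonality or sequencing-error
model — the encoding treats sites independently, so richer structure would
not change what the tests can show. Coordinates are synthetic but valid
(22 autosomes, positions spaced 100 bp); written VCFs are minimal valid 4.2
files and byte-identical for a given seed.

The standard study conditions are 12 classes plus healthy, 100 samples each,
200 signature sites per class at penetrance 0.9, and 5,000 background sites
at rate 0.02. Pairs of classes can share an exact rounded fraction of their
signature sites; the defaults (0.7, 0.2, 0.1 for three class pairs) mirror
the sharing hierarchy observed between uterine, colon and breast tumor
panels, with one dominant pair. Sharing is realised by lending contiguous
slices of one class's own sites into another's list, so configured pairs
share exactly `round(f·n_signature)` sites and unconfigured pairs stay
disjoint; a class can lend and borrow as capacity allows, and
over-constrained configurations raise an error rather than silently
approximating.

**What passing tests do and do not show.** Under these conditions every
class has ≥ 60 private signature sites at penetrance 0.9 against a 0.02
background, so the Bayes error of every task is effectively zero: specific
models reaching ≥ 99% and panels recovering ≥ 95% of planted sites
demonstrate that the pipeline loses essentially nothing end-to-end, not that
real tumor cohorts are this separable. In particular, the 12-way mixture
model also sits at the accuracy ceiling here, whereas on real data
multi-class accuracy is far below the binary models'; that gap is driven by
low per-site recurrence and heavy-tailed sharing across many class pairs,
which this generator — deliberately simple and fully controlled — does not
emulate.

## Problem sizes in the bundled runs

The test suite and the acceptance script train the 12 specific models on
top-1000 panels for 400 steps (batch 128) and the mixture model on the
pooled `> 2` panel (~7,200 dimensions) for 1,500 steps; the dimension sweep
re-trains each specific model at K ∈ {50, 100, 200, 500, 1000} by slicing
the K-prefix of the top-1000 panel (exact, thanks to prefix nesting). These
budgets were pinned once on the separable reference task and are stated here
as the package's standard experiment sizes.

## Known limitations

* MAF ingestion, annotation, liftover and indel normalization are out of
  scope; inputs must already be VCF 4.x point-mutation files.
* The optimisation is CPU-bound, dense numpy; it is meant for panels up to
  ~10⁴ dimensions and cohorts up to ~10⁴ samples, not genome-scale feature
  spaces.
* The simulator's independence assumptions make its tasks easier than real
  cohorts at matched parameter values (see above).
* One overlap fraction per class pair is supported, with slice-lending
  capacity limits; arbitrary overlap graphs (e.g. three-way shared cores)
  are rejected when they over-constrain a class's site budget.
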