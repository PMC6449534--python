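# Methods

`evitriage` implements an evidence-centric text-classification pipeline for
biocuration of molecular-interaction literature. This note documents the
models, the synthetic benchmark that stands in for the curated corpora, the
numerical choices, and the limits of what the synthetic results show.

## The two tasks

**Passage-level method classification.** Curated molecular-interaction
records are anchored to subfigures (e.g. "Fig. 2B"), which links each record
to the figure's caption and to the narrative text around in-text references
to that subfigure. Aligning records with text through this shared key is a
form of distant supervision: it yields labeled passages without manual
annotation. The classification targets are experimental-method codes from a
PSI-MI-style controlled vocabulary, grouped from fine codes to coarser
classes by a supplied mapping (the cardinalities mirrored here: 44
participant-detection codes grouped to 8, and 84 interaction-detection codes
grouped to 17), plus binary yes/no heads for single common methods such as
western blotting.

**Document triage.** Given a full-text article, decide whether it contains
molecular-interaction evidence worth a curator's time. Whole articles are
too long to classify naively, so the document is reduced to an ordered list
of passages from one of eight text sources: title, abstract, title+abstract,
MeSH terms, all body paragraphs, figure captions, evidence fragments, or
captions and fragments combined. The driving hypothesis is that text
directly describing evidence (captions, fragments) is a stronger triage
signal than general document text.

## Evidence fragments

An evidence fragment is the run of sentences around a figure reference that
directly describes that figure's evidence. The reference grammar accepts
"Fig", "Fig.", "Figure(s)", "Figs", case-insensitive, figure numbers 1–999,
and panel letters with comma lists and dash ranges ("2B", "4A,B", "1C–E",
"2A and B"). Fragment delineation is deliberately simple and deterministic:

* a fragment starts at a sentence containing one or more references and
  extends through following reference-free sentences;
* it ends at the paragraph boundary or at the next sentence referring to a
  different (figure, panels) key set, whichever comes first;
* consecutive sentences with the same key merge into one fragment; a
  sentence referencing several keys yields one fragment per key over the
  same sentence run, so every detected reference is covered exactly once;
* a config option (`FragmentPolicy(include_preceding=True)`) prepends one
  sentence of context. The default is reference-sentence-onward; whether
  preceding context helps is an open empirical question, so both behaviors
  are available.

Panel-level caption splitting is not attempted: a reference to "Fig. 3B"
links to the whole caption of figure 3, tagged with panel B. Supplementary
figures ("Fig. S1") and roman-numeral labels live in a separate namespace
and are excluded from caption linkage by default. Table references and
cross-paragraph discourse are out of scope.

## Embeddings

Word-vector tables are consumed in the standard whitespace-delimited text
format (with or without a count/dim header, gzip-transparent). Row 0 is a
reserved all-zeros padding vector. Lookup lowercases tokens; documents keep
their original case. Out-of-vocabulary policy is declared per table: `zero`
(default — with a frozen embedding layer an OOV gradient would be discarded
anyway), `mean` (arithmetic mean of all non-pad rows), or `hash_bucket` (16
deterministic random bucket vectors keyed by a stable hash). Sequences are
truncated head-keep at `max_len` (default 300 tokens: passage-level texts of
300 words or less are where these classifiers work well) and tail-padded
with zeros. Embeddings are frozen during training by default; a flag enables
fine-tuning, which on small corpora mostly buys memorization.

## Architectures

All networks are built on an in-package reverse-mode autodiff core over
numpy (`evitriage.nn`), with every layer's gradient verified against central
finite differences in the test suite.

**Passage classifier** (two deliberately plain heads):

* CNN: embedding → parallel 1-D convolutions of widths {3, 4, 5} (64
  filters each by default) → global max pooling → dropout → dense (ReLU) →
  softmax;
* LSTM: embedding → LSTM (128 units by default), reading the hidden state
  at each sequence's last real token → dropout → dense (ReLU) → softmax.

**Triage network**: each selected passage is embedded and encoded by a 1-D
convolution (width 3, 32 filters) followed by a bidirectional LSTM (16 units
per direction, concatenated final states, so the passage vector has width
2 × units). Passage vectors are aggregated into one document vector by
additive attention,

    score_i = vᵀ tanh(W h_i + b),   weights = softmax(scores),
    doc_vector = Σ_i weight_i · h_i,

and a fully connected layer converts the document vector into a relevance
probability. The attention weights are returned with every prediction so a
curator can see which passages drove the decision. The scorer is
position-free: permuting passages permutes the weights identically and
leaves the document vector unchanged. A masked-mean aggregation is available
as an ablation baseline. Single-passage sources (title, abstract,
title+abstract, MeSH) degenerate gracefully — attention over one passage is
the identity — and the title and MeSH sources use a simple CNN encoder
(convolution + max pooling) as the cheap baseline; abstract-based sources
use the CNN-BiLSTM encoder.

Documents are capped at 64 passages (first 64 in document order, logged):
attention is precisely the device that makes full-text classification
tractable under memory limits, but an explicit cap keeps the worst case
bounded.

## Training and evaluation

Optimizer: Adam, batch size 32 (passages) or 16 (documents), L2 penalty
1e-4 on weight matrices (not biases), dropout constrained to [0.25, 0.5]
unless explicitly overridden — the band that regularizes these small
corpora without starving learning. Early stopping watches validation loss
(patience 3 by default) and restores the best-validation weights. Splits
are stratified 70/15/15 train/validation/test, seeded. Because random
initialization matters at these data sizes, every evaluation runs n
restarts that differ only in seed and reports accuracy mean ± sample
standard deviation (std over restarts, labeled as such); the split is fixed
by the config seed so restart spread reflects initialization and batching
alone. Decisions threshold at probability 0.5 (configurable). Argmax ties
break to the lowest class index. Everything is single-threaded numpy, so a
rerun with the same config reproduces a report bit-for-bit (timestamps
aside).

## The synthetic benchmark

Real corpora for both tasks are not redistributable, so the package ships a
generator that emulates their structure while keeping every stage testable:

* background text is Zipfian nonsense tokens (exponent 1.05, vocabulary
  400), which isolates classifier behavior from linguistic confounds;
* documents carry title, abstract, MeSH-like terms, 3–5 paragraphs, 2–3
  figures with 2-sentence captions, and in-text references ("( Fig. 2A )")
  consistent with the caption map, so evidence extraction runs end to end;
* the triage class balance defaults to 537:451 positive:negative, matching
  the curated triage training set it stands in for, so majority baselines
  are comparable;
* class signal is a set of reserved tokens per class, disjoint from each
  other and from frequent background tokens. For triage, positives receive
  a signal token in each sentence of a targeted passage independently with
  probability p; the targeted passages are either all passages of the
  configured location kinds (`signal_placement="all"`) or exactly one
  randomly chosen passage per positive document (`"one"`). At p=1 every
  targeted passage is guaranteed signal; at p=0 positives and negatives are
  distributionally identical (checked by a χ² test on abstract unigrams).
  The per-sentence formulation makes p a smooth signal-strength dial while
  letting the "one" placement model a single decisive caption — under the
  standard benchmark (placement "one", p=0.8, 2-sentence captions) a
  positive document bears signal with probability 1−(1−0.8)² = 0.96, which
  bounds achievable triage accuracy at ≈0.98 under the 537:451 balance.

The standard benchmark conditions live in `evitriage.benchmarks`: 1000
triage documents (800 train / 200 test), 50-dimensional toy vectors for
triage and 100-dimensional for method classification (the field's common
word-vector sizes), method corpora of 1600 (8-class) and 2720 (17-class)
balanced passages with p=1. Toy vectors are unit-norm Gaussian draws; these
sizes keep the full evaluation within minutes on one CPU core while leaving
headroom over the recovery thresholds.

Per-architecture optimizer settings in the benchmark: the CNN trains stably
at learning rate 3e-3; the LSTM needs 1e-2 and a higher epoch cap to
converge on these corpora. Both are recorded in every report.

**What passing these benchmarks does and does not show.** Recovery of
planted token signal shows the pipeline is wired correctly end to end —
extraction finds the right passages, encoders expose token identity,
attention localizes the decisive passage, training converges — and the
permutation nulls show the accuracy is not an artifact. It does not show
performance on real biomedical language, where signal is distributed,
correlated and noisy: the synthetic generator has no syntax, no polysemy,
no distributional overlap between classes, and its captions are short. The
published accuracies on the curated corpora (triage ≈0.82 from captions,
method classification ≈0.89) depend on those corpora and are not
reproducible from this repository.

## Numerical and degenerate-input choices

* Softmax is computed max-shifted; attention weights sum to 1 within 1e-6
  on every forward pass.
* An empty passage selection yields a single empty (all-padding) passage
  with a warning, which produces a valid, bias-driven probability — a
  documented degenerate contract rather than an error.
* Duplicate tokens in a word-vector file keep the first occurrence (with a
  warning); inconsistent row dimensionality is an error naming the line.
* MeSH terms can enter as tokenized words (default) or as whole-phrase
  units (`mesh_as_phrases=True`); which the original pipelines used is
  unknowable from the outside, so both are exposed.
* Descending panel ranges ("D–B") are rejected rather than silently
  reordered.
* Sequence lengths for the recurrent readout are inferred from nonzero
  embedding rows; an OOV token mapped to the zero vector therefore counts
  as padding for readout placement only.

## Known limitations

* The fragment heuristic never crosses paragraph boundaries and ignores
  discourse ("as shown above"); table and supplementary-figure evidence is
  not linked.
* The autodiff core is CPU-only and loops over LSTM time steps in Python;
  it is sized for corpora of thousands of passages, not millions.
* Subword composition for OOV tokens is not implemented; FastText-style
  vectors are consumed as whole-word tables only.
* The attention cap (64 passages) silently ignores later passages in
  pathological documents (the count is logged).
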