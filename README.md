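# evitriage

Evidence-centric text classification for biocuration of the
molecular-interaction literature.

Biocurators of interaction databases face two recurring text problems:
deciding which of an incoming stream of full-text papers actually contain
interaction evidence (**triage**), and identifying the experimental
**detection method** behind an individual figure panel so it can be encoded
as a PSI-MI-style controlled-vocabulary term. In both cases the decisive
text is usually the material that directly describes evidence — figure
captions and the narrative sentences surrounding figure references
("evidence fragments") — rather than the document at large.

`evitriage` provides the full pipeline:

* **Corpus model** — a `Document` type (title, abstract, MeSH terms,
  ordered paragraphs, per-figure captions) with readers for a JATS-subset
  XML and a plain-text fixture dialect, biomedical-aware tokenization
  (`IL-2`, `p53` and `1A` stay single tokens) and sentence splitting with
  character spans.
* **Evidence extraction** — a deterministic grammar for figure/panel
  references (`Fig. 2B`, `Figures 1A and 1C–E`, panel ranges `B–D`) and a
  sentence-run heuristic that delineates one evidence fragment per
  (figure, panels) key, never crossing paragraph boundaries.
* **Embeddings** — word-vector tables in the standard text format with
  declared padding/OOV contracts (zero, mean, or hash-bucket).
* **Passage classification** — CNN and LSTM heads over frozen embeddings
  for method-code prediction, with fine-to-grouped label schemes (e.g. 44
  participant-detection codes → 8 groups, 84 interaction-detection codes →
  17 groups) and binary yes/no heads.
* **Document triage** — per-passage CNN–bidirectional-LSTM encoding over a
  chosen text source (title, abstract, MeSH, all paragraphs, captions,
  evidence fragments, or captions + fragments), aggregated into a single
  document vector by additive attention

  score_i = vᵀ tanh(W h_i + b), weights = softmax(scores),
  doc_vector = Σ weight_i · h_i,

  followed by a fully connected decision layer. Attention weights are
  returned with every prediction, showing which passages drove the call.
* **Synthetic corpora** — generators that plant controllable token signal
  in a chosen text source at the 537:451 positive:negative balance of the
  curated triage set, so every stage is testable without restricted data.
* **Experiment runner** — seeded multi-restart evaluation (accuracy mean ±
  std over restarts), YAML configs, reproducible reports, and a thin
  `evitriage` CLI (`extract`, `synth`, `run`, `report`).

The neural layers (convolutions, LSTMs, attention) run on an in-package
reverse-mode autodiff core over numpy; every layer's gradient is checked
against finite differences in the test suite.

## Worked example

Train the caption-source triage network on a synthetic corpus where only
captions of positive documents carry signal, then inspect the attention of
a correctly classified positive test document
(`examples/03_triage_with_attention.py`):

```text
held-out triage accuracy: 0.831 (CNNBiLSTM + attention, source=captions)

document doc00024: P(relevant) = 0.792
  caption 0: attention 0.030
  caption 1: attention 0.963 <-- carries signal
  caption 2: attention 0.007
```

The held-out accuracy (here on a deliberately small 300-document corpus;
the standard 1000-document benchmark reaches ≈0.93) shows the classifier
recovered the planted signal, and the attention weights localize exactly
the caption that carries it — the same mechanism that would point a curator
at the decisive figure of a real paper.

Parsing and extraction are equally direct
(`examples/01_parse_and_extract.py`):

```text
Figure references found in the Results paragraph:
  figure 1, panels ['A']: 'Fig. 1A'
  figure 1, panels ['C', 'D', 'E']: '1C–E'
  figure 2, panels ['B']: 'Fig. 2B'

Evidence fragments (the sentences describing each figure):
  Fig 1A: 'MDM2 co-precipitated with p53 (Fig. 1A and 1C–E). Binding was dose-dependent.'
  ...
```

See `examples/` for method classification and the experiment runner, and
`docs/methods.md` for the models, benchmark design and limitations.

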