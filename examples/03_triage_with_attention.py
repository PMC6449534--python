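"""Document triage with attention over figure captions.

Generates a small synthetic corpus in which only the captions of positive
documents carry signal tokens, trains the caption-source CNN-BiLSTM +
attention network, and inspects the attention weights of one positive test
document: the signal-bearing caption should dominate.
"""

import numpy as np

from evitriage import TriageConfig, classify_document, select_passages
from evitriage.synth import (SynthConfig, generate_triage_corpus,
                             toy_embedding_table, triage_vocabulary)
from evitriage.triage import evaluate_triage_multirestart

corpus_cfg = SynthConfig(n_docs=300, seed=4, signal_location=("caption",),
                         signal_placement="one", signal_probability=1.0)
docs, labels = generate_triage_corpus(corpus_cfg)
table = toy_embedding_table(triage_vocabulary(corpus_cfg), dim=50, seed=11)

model_cfg = TriageConfig(text_source="captions", max_len=32,
                         learning_rate=3e-3, epochs=20,
                         early_stopping_patience=5, seed=4)
report, models, (tr_idx, te_idx) = evaluate_triage_multirestart(
    docs, labels, model_cfg, n_restarts=1, table=table,
    test_fraction=0.2, return_models=True)
print(f"held-out triage accuracy: {report.mean:.3f} "
      f"({report.model_configuration}, source={report.text_source})")

model = models[0]
signal = set(corpus_cfg.signal_tokens)
# show a positive test document the model got right
doc = next(docs[i] for i in te_idx if labels[i] == 1
           and classify_document(model, docs[i])[0] >= 0.5)
prob, attention = classify_document(model, doc)
print(f"\ndocument {doc.doc_id}: P(relevant) = {prob:.3f}")
for j, passage in enumerate(select_passages(doc, "captions")):
    marker = " <-- carries signal" if signal & set(passage.tokens) else ""
    print(f"  caption {j}: attention {attention.weights[j]:.3f}{marker}")

# The attention weight concentrates on the caption containing the planted
# signal token — the same mechanism that tells a curator which part of a
# real paper drove the triage decision.
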