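"""Independent reference CBOW trainer used as a cross-check oracle.

Deliberately written along a different path from the package trainer:
plain numpy, per-document vectorization, fixed (non-dynamic) context
windows, no frequency subsampling, negatives drawn per update from a
numpy Generator. It shares only the model *definition* (predict center
from mean context vector, logistic loss against k noise samples), so
nearest-neighbor agreement between the two trainers is evidence about
the trained geometry, not about shared code.
"""

import numpy as np


def train_reference_cbow(corpus, dim=32, window=5, min_count=10, negative=5,
                         epochs=5, alpha=0.05, seed=1):
    """Return (token_list, V x dim input-vector matrix)."""
    from collections import Counter

    freq = Counter(t for doc in corpus for t in doc)
    tokens = sorted((t for t, c in freq.items() if c >= min_count),
                    key=lambda t: (-freq[t], t))
    t2i = {t: i for i, t in enumerate(tokens)}
    V = len(tokens)
    counts = np.array([freq[t] for t in tokens], dtype=np.float64)
    noise_p = counts ** 0.75
    noise_p /= noise_p.sum()

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    docs = [[t2i[t] for t in doc if t in t2i] for doc in corpus]
    docs = [d for d in docs if len(d) >= 2]
    n_updates = sum(len(d) for d in docs) * epochs
    step = 0
    for _ in range(epochs):
        for doc in docs:
            ids = np.array(doc)
            for pos in range(len(ids)):
                lo, hi = max(0, pos - window), min(len(ids), pos + window + 1)
                ctx = np.concatenate([ids[lo:pos], ids[pos + 1:hi]])
                if len(ctx) == 0:
                    continue
                lr = alpha * max(1.0 - step / n_updates, 1e-4)
                step += 1
                h = W_in[ctx].mean(axis=0)
                targets = np.concatenate([[ids[pos]],
                                          rng.choice(V, size=negative, p=noise_p)])
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                z = W_out[targets] @ h
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                g = (labels - p) * lr
                grad_h = g @ W_out[targets]
                W_out[targets] += np.outer(g, h)
                W_in[ctx] += grad_h
    return tokens, W_in
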