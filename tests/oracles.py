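"""Independent reference implementations used only as test oracles.

These are written directly from the defining equations — per-template
counting with explicit self-match exclusion — independently of the
package's vectorised/tree code paths, and are deliberately simple rather
than fast.
"""

import math

import numpy as np


def _vectors(x, m, tau):
    """All embedding vectors (x(i), x(i+tau), ..., x(i+(m-1)tau))."""
    n = len(x)
    return [np.array([x[i + k * tau] for k in range(m)], dtype=float)
            for i in range(n - (m - 1) * tau)]


def _phi_hard(vectors, n_templates, r):
    """Average over templates of the fraction of non-self vectors within r."""
    total = 0.0
    for i in range(n_templates):
        count = 0
        for j in range(n_templates):
            if j == i:
                continue
            if np.max(np.abs(vectors[i] - vectors[j])) <= r:
                count += 1
        total += count / (n_templates - 1)
    return total / n_templates


def _phi_fuzzy(vectors, n_templates, r, n_exp, remove_baseline):
    vecs = [v - v.mean() if remove_baseline else v for v in vectors]
    total = 0.0
    for i in range(n_templates):
        s = 0.0
        for j in range(n_templates):
            if j == i:
                continue
            d = np.max(np.abs(vecs[i] - vecs[j]))
            s += math.exp(-min((d / r) ** n_exp, 745.0))
        total += s / (n_templates - 1)
    return total / n_templates


def sampen_oracle(x, m, r, tau=1):
    """Brute-force double-loop sample entropy (nats); NaN when undefined."""
    x = np.asarray(x, dtype=float)
    nt = len(x) - m * tau
    phi_m = _phi_hard(_vectors(x, m, tau)[:nt], nt, r)
    phi_m1 = _phi_hard(_vectors(x, m + 1, tau), nt, r)
    if phi_m <= 0 or phi_m1 <= 0:
        return float("nan")
    return math.log(phi_m) - math.log(phi_m1)


def fuzzyen_oracle(x, m, r, n_exp=2.0, tau=1, remove_baseline=True):
    """Brute-force double-loop fuzzy entropy (nats)."""
    x = np.asarray(x, dtype=float)
    nt = len(x) - m * tau
    phi_m = _phi_fuzzy(_vectors(x, m, tau)[:nt], nt, r, n_exp, remove_baseline)
    phi_m1 = _phi_fuzzy(_vectors(x, m + 1, tau), nt, r, n_exp, remove_baseline)
    return math.log(phi_m) - math.log(phi_m1)


def auc_rank_oracle(scores, labels):
    """AUC as the tie-corrected pairwise ranking probability."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
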