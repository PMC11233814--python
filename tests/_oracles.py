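"""Independent brute-force oracles used to cross-check vectorized code.

Written as literal nested loops over the defining formulas, deliberately
sharing no code with the package implementations they verify.
"""

import math

import numpy as np


def supcon_loss_bruteforce(z, labels, theta, tau):
    """Triple-loop supervised contrastive loss over unit embeddings ``z``."""
    m = len(z)
    total = 0.0
    for r in range(m):
        positives = [
            p for p in range(m) if p != r and abs(labels[p] - labels[r]) < theta
        ]
        if not positives:
            continue
        term = 0.0
        for p in positives:
            denom = sum(
                math.exp(float(np.dot(z[r], z[a])) / tau) for a in range(m) if a != r
            )
            term += math.log(math.exp(float(np.dot(z[r], z[p])) / tau) / denom)
        total += -term / len(positives)
    return total


def paired_t_bruteforce(a, b):
    """Textbook paired t statistic: mean(diff) / (sd(diff)/sqrt(n)), dof n-1."""
    diff = [x - y for x, y in zip(a, b)]
    n = len(diff)
    mean = sum(diff) / n
    var = sum((x - mean) ** 2 for x in diff) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, n - 1


def pearson_bruteforce(x, y):
    """Covariance over product of standard deviations, no library calls."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def single_feature_permutation_importance(predict_fn, x_test, y_test, metric, n_rounds, rng):
    """Classical per-feature permutation importance (mean metric decrease)."""
    base = metric(y_test, predict_fn(x_test))
    d = x_test.shape[1]
    scores = np.zeros(d)
    for j in range(d):
        drops = []
        for _ in range(n_rounds):
            perm = x_test.copy()
            perm[:, j] = perm[rng.permutation(len(perm)), j]
            drops.append(base - metric(y_test, predict_fn(perm)))
        scores[j] = np.mean(drops)
    return scores
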