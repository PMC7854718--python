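"""Independent brute-force reference implementations used only by tests.

These share no code with the package: every step (standardization,
rescaling, encoding, tensor copies, centroids, spectral projectors,
scores) is written out naively so the optimized implementations can be
checked against them.
"""

import numpy as np


def brute_encode(x, encoding):
    x = [float(v) for v in x]
    s = sum(v * v for v in x)
    if encoding == "stereographic":
        a = [2.0 * v / (s + 1.0) for v in x] + [(s - 1.0) / (s + 1.0)]
    elif encoding == "amplitude":
        norm = (s + 1.0) ** 0.5
        a = [v / norm for v in x] + [1.0 / norm]
    else:
        raise ValueError(encoding)
    d = len(a)
    rho = [[a[i] * a[j] for j in range(d)] for i in range(d)]
    return np.array(rho)


def brute_kron_power(rho, m):
    out = np.array(rho)
    for _ in range(m - 1):
        r1, c1 = out.shape
        r2, c2 = rho.shape
        new = np.zeros((r1 * r2, c1 * c2))
        for i in range(r1):
            for j in range(c1):
                for k in range(r2):
                    for l in range(c2):
                        new[i * r2 + k, j * c2 + l] = out[i, j] * rho[k, l]
        out = new
    return out


def brute_hqc(X_train, y_train, X_test, rescale=1.0, encoding="amplitude",
              n_copies=1, weighting="equiprobable", standardize=True):
    """Naive-loop Helstrom classification; returns (scores, labels, bound)."""
    X_train = np.array(X_train, dtype=float)
    X_test = np.array(X_test, dtype=float)
    y_train = np.array(y_train)
    if standardize:
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_train = (X_train - mean) / sd
        X_test = (X_test - mean) / sd
    X_train = X_train * rescale
    X_test = X_test * rescale

    classes = sorted(set(y_train.tolist()))
    assert len(classes) == 2
    rhos = {}
    for cls in classes:
        members = [brute_kron_power(brute_encode(x, encoding), n_copies)
                   for x, y in zip(X_train, y_train) if y == cls]
        rhos[cls] = sum(members) / len(members)
    if weighting == "equiprobable":
        w = {classes[0]: 0.5, classes[1]: 0.5}
    else:
        w = {cls: float(np.sum(y_train == cls)) / len(y_train) for cls in classes}

    lam = w[classes[1]] * rhos[classes[1]] - w[classes[0]] * rhos[classes[0]]
    eigvals, eigvecs = np.linalg.eigh((lam + lam.T) / 2)
    p_pos = np.zeros_like(lam)
    for i, ev in enumerate(eigvals):
        if ev > 1e-12:
            v = eigvecs[:, i]
            p_pos += np.outer(v, v)
    p_neg = np.eye(lam.shape[0]) - p_pos
    bound = w[classes[1]] * np.trace(p_pos @ rhos[classes[1]]) + \
        w[classes[0]] * np.trace(p_neg @ rhos[classes[0]])

    scores, labels = [], []
    for x in X_test:
        rho = brute_kron_power(brute_encode(x, encoding), n_copies)
        s = float(np.trace(p_pos @ rho))
        scores.append(s)
        labels.append(classes[1] if s > 0.5 else classes[0])
    return np.array(scores), np.array(labels), float(bound)


def brute_glcm_descriptors(window, offset=(0, 1), levels=None):
    """Pair-enumeration GLCM descriptors for one window."""
    window = np.array(window)
    if levels is None:
        levels = int(window.max()) + 1
    dr, dc = offset
    h, w = window.shape
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs.append((int(window[r, c]), int(window[r2, c2])))
    counts = {}
    for ij in pairs:
        counts[ij] = counts.get(ij, 0) + 1
    n = len(pairs)
    p = {ij: k / n for ij, k in counts.items()}
    contrast = sum((i - j) ** 2 * pij for (i, j), pij in p.items())
    energy = sum(pij**2 for pij in p.values())
    homogeneity = sum(pij / (1 + abs(i - j)) for (i, j), pij in p.items())
    mu_i = sum(i * pij for (i, j), pij in p.items())
    mu_j = sum(j * pij for (i, j), pij in p.items())
    var_i = sum((i - mu_i) ** 2 * pij for (i, j), pij in p.items())
    var_j = sum((j - mu_j) ** 2 * pij for (i, j), pij in p.items())
    if var_i > 0 and var_j > 0:
        correlation = sum((i - mu_i) * (j - mu_j) * pij for (i, j), pij in p.items()) / (
            (var_i * var_j) ** 0.5
        )
    else:
        correlation = 0.0
    return contrast, correlation, energy, homogeneity


def rank_auroc(labels, scores):
    """Mann-Whitney form of the AUROC with the midrank tie correction."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
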