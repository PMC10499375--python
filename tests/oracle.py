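"""Independent brute-force oracle for the transfer-entropy estimator.

Pure-python re-implementation by direct enumeration: for every row, scan
all other rows for the k nearest, form the simplex-weighted prediction,
apply the smoother variance-inflation adjustment, and take the mean
log-ratio. Kept free of any code from the package's uic module.
"""

import math

VARIANCE_FLOOR = 1e-12


def oracle_sigma2(X, y, k):
    """Adjusted mean squared LOO simplex error by direct enumeration."""
    T = len(y)
    if len(X) and len(X[0]) == 0 or not len(X):
        errs = []
        for i in range(T):
            pred = sum(y[j] for j in range(T) if j != i) / (T - 1)
            errs.append((y[i] - pred) ** 2 / (1 + 1 / (T - 1)))
        return max(sum(errs) / T, VARIANCE_FLOOR)
    errs = []
    for i in range(T):
        dists = sorted(
            (math.dist(X[i], X[j]), j) for j in range(T) if j != i
        )
        nn = dists[:k]
        d1 = nn[0][0]
        if d1 == 0:
            w = [1.0] * k
        else:
            w = [math.exp(-d / d1) for d, _ in nn]
        s = sum(w)
        wn = [wi / s for wi in w]
        pred = sum(wi * y[j] for wi, (_, j) in zip(wn, nn))
        inflation = 1 + sum(wi * wi for wi in wn)
        errs.append((y[i] - pred) ** 2 / inflation)
    return max(sum(errs) / T, VARIANCE_FLOOR)


def oracle_te(X_full, X_reduced, y, k):
    """TE = 0.5 ln(sigma2_reduced / sigma2_full), everything brute force."""
    s2f = oracle_sigma2(X_full, y, k)
    s2r = oracle_sigma2(X_reduced, y, k)
    return 0.5 * math.log(s2r / s2f)
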