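"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — double loops, explicit
confusion-matrix arithmetic, threshold sweeps — and shares no code with
the implementation it checks.
"""

import numpy as np


def cosine_oracle(profiles: np.ndarray) -> np.ndarray:
    n = len(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            ni = np.sqrt(sum(x * x for x in profiles[i]))
            nj = np.sqrt(sum(x * x for x in profiles[j]))
            if ni == 0 or nj == 0:
                out[i, j] = 0.0
            else:
                dot = sum(a * b for a, b in zip(profiles[i], profiles[j]))
                out[i, j] = min(max(dot / (ni * nj), 0.0), 1.0)
    return out


def tanimoto_oracle(fingerprints: np.ndarray) -> np.ndarray:
    sets = [frozenset(np.flatnonzero(fp)) for fp in fingerprints]
    n = len(sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            elif not sets[i] | sets[j]:
                out[i, j] = 0.0
            else:
                out[i, j] = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
    return out


def outer_product_oracle(xd: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Maps for one pair: xd (P, h), xs (Q, h) -> (P*Q, h, h)."""
    p, h = xd.shape
    q = xs.shape[0]
    out = np.zeros((p * q, h, h))
    for a in range(p):
        for b in range(q):
            for r in range(h):
                for c in range(h):
                    out[a * q + b, r, c] = xd[a, r] * xs[b, c]
    return out


def confusion_matrix(true, pred, n_classes=5):
    cm = np.zeros((n_classes, n_classes), dtype=float)
    for t, p in zip(true, pred):
        cm[t - 1, p - 1] += 1
    return cm


def metrics_oracle(true, scores):
    """All eight metrics from first principles."""
    true = np.asarray(true)
    scores = np.asarray(scores)
    pred = np.array([int(np.argmax(row)) + 1 for row in scores])
    cm = confusion_matrix(true, pred)
    n = cm.sum()
    acc = np.trace(cm) / n

    precisions, recalls, f1s, supports = [], [], [], []
    for c in range(5):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
        supports.append(cm[c, :].sum())
    supports = np.array(supports)
    weighted_f1 = float(np.sum(np.array(f1s) * supports) / n)
    macro_f1 = float(np.mean(f1s))
    macro_precision = float(np.mean(precisions))
    macro_recall = float(np.mean(recalls))

    p_o = acc
    p_e = float(np.sum(cm.sum(0) * cm.sum(1)) / n**2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0

    # multiclass (R_k) Matthews correlation
    t_k = cm.sum(1)
    p_k = cm.sum(0)
    c_ = np.trace(cm)
    num = c_ * n - np.dot(t_k, p_k)
    den = np.sqrt(n**2 - np.dot(p_k, p_k)) * np.sqrt(n**2 - np.dot(t_k, t_k))
    mcc = num / den if den > 0 else 0.0

    auprs = []
    for c in range(1, 6):
        y = (true == c).astype(int)
        if y.sum() == 0:
            continue
        auprs.append(aupr_oracle(y, scores[:, c - 1]))
    macro_aupr = float(np.mean(auprs)) if auprs else 0.0

    return {
        "acc": float(acc),
        "weighted_f1": weighted_f1,
        "macro_f1": macro_f1,
        "kappa": float(kappa),
        "mcc": float(mcc),
        "macro_precision": macro_precision,
        "macro_recall": macro_recall,
        "macro_aupr": macro_aupr,
    }


def aupr_oracle(y_bin, scores):
    """Threshold sweep recomputing TP/FP/FN at every distinct score,
    then trapezoidal integration over the (recall, precision) points."""
    y_bin = np.asarray(y_bin)
    scores = np.asarray(scores)
    pos = int(y_bin.sum())
    points = [(0.0, 1.0)]
    for thr in sorted(set(scores), reverse=True):
        keep = scores >= thr
        tp = int(((y_bin == 1) & keep).sum())
        fp = int(((y_bin == 0) & keep).sum())
        points.append((tp / pos, tp / (tp + fp)))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return float(area)
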