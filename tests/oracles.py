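"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (loops, exhaustive sweeps) and shares
no code with the implementation under test.
"""

import numpy as np


def brute_confusion(labels, preds):
    tp = fp = tn = fn = 0
    for l, p in zip(labels, preds):
        if l and p:
            tp += 1
        elif l and not p:
            fn += 1
        elif not l and p:
            fp += 1
        else:
            tn += 1
    out = {}
    out["accuracy"] = 100 * (tp + tn) / (tp + tn + fp + fn) if (tp + tn + fp + fn) else None
    out["specificity"] = 100 * tn / (tn + fp) if (tn + fp) else None
    out["precision"] = 100 * tp / (tp + fp) if (tp + fp) else None
    out["recall"] = 100 * tp / (tp + fn) if (tp + fn) else None
    p, r = out["precision"], out["recall"]
    out["f_measure"] = (2 * p * r / (p + r)) if (p is not None and r is not None and p + r > 0) else None
    return out


def brute_average_precision(labels, probs):
    """Step-wise PR area: sum over distinct thresholds of (dR) * P."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(probs.tolist()), reverse=True):
        preds = probs >= t
        tp = int(np.sum(labels[preds]))
        fp = int(np.sum(preds)) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return 100.0 * ap


def brute_best_f(labels, probs):
    """Exhaustive sweep over distinct probabilities; ties -> higher threshold."""
    labels = np.asarray(labels)
    best_f, best_t = -1.0, None
    for t in sorted(set(np.asarray(probs, dtype=float).tolist())):
        m = brute_confusion(labels, np.asarray(probs) >= t)
        p, r = m["precision"], m["recall"]
        f = 2 * p * r / (p + r) if (p is not None and r is not None and p + r > 0) else 0.0
        if f >= best_f - 1e-12:
            if f > best_f + 1e-12 or (best_t is not None and t > best_t):
                best_t = t
            best_f = max(best_f, f)
    return best_t, best_f


def brute_fpr_per_hour(probs, events, threshold, fs=256.0, stride=64, segment_s=30.0, occupancy=0.5):
    bin_s = stride / fs
    bins_per_seg = int(round(segment_s / bin_s))
    binary = [p >= threshold for p in probs]
    n_seg = len(binary) // bins_per_seg
    false = 0
    for s in range(n_seg):
        seg = binary[s * bins_per_seg : (s + 1) * bins_per_seg]
        if sum(seg) / len(seg) > occupancy:
            t0, t1 = s * segment_s, (s + 1) * segment_s
            hit = any(on < t1 and t0 < off for on, off in events)
            if not hit:
                false += 1
    hours = len(binary) * bin_s / 3600.0
    return false / hours


def brute_ictal_start_count(duration, shift, window=4.0):
    """Enumerate starts onset + k*shift while the window fits."""
    if duration < window - 1e-9:
        return 0
    k = 0
    while k * shift + window <= duration + 1e-9:
        k += 1
    return k


def count_conv_params(c_in, c_out, kernel):
    return c_out * c_in * kernel + c_out


def count_bn_params(c):
    return 2 * c  # gamma + beta
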