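"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain Python loops over voxels/pairs,
deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math


def brute_mean_hu(values, labels, side="both"):
    """Mean HU over masked voxels by explicit iteration."""
    total, count = 0.0, 0
    ni, nj, nk = values.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                lab = labels[i, j, k]
                if lab == 0:
                    continue
                if side == "left" and lab != 1:
                    continue
                if side == "right" and lab != 2:
                    continue
                total += float(values[i, j, k])
                count += 1
    if count == 0:
        raise ZeroDivisionError("empty region")
    return total / count


def brute_volume_ml(labels, spacing, side="both"):
    count = 0
    ni, nj, nk = labels.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                lab = labels[i, j, k]
                if lab == 0:
                    continue
                if side == "left" and lab != 1:
                    continue
                if side == "right" and lab != 2:
                    continue
                count += 1
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0


def brute_fraction_pct(values, labels, threshold, direction, side="both"):
    hit, count = 0, 0
    ni, nj, nk = values.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                lab = labels[i, j, k]
                if lab == 0:
                    continue
                if side == "left" and lab != 1:
                    continue
                if side == "right" and lab != 2:
                    continue
                count += 1
                v = float(values[i, j, k])
                if direction == "below" and v < threshold:
                    hit += 1
                if direction == "above" and v > threshold:
                    hit += 1
    return 100.0 * hit / count


def brute_auc(pos, neg):
    """Pair-counting AUC: concordant pairs + half ties over all pairs."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_youden(pos, neg, higher_indicates_disease):
    """Exhaustive Youden scan with the inclusive-on-disease-side rule.

    Returns (cutoff, tp, fp, fn, tn). Ties prefer higher specificity,
    then the more extreme cutoff toward the diseased side.
    """
    sign = 1.0 if higher_indicates_disease else -1.0
    op = [sign * v for v in pos]
    on = [sign * v for v in neg]
    best = None
    for c in sorted(set(op + on)):
        tp = sum(1 for v in op if v >= c)
        fp = sum(1 for v in on if v >= c)
        fn = len(op) - tp
        tn = len(on) - fp
        sens = tp / len(op)
        spec = tn / len(on)
        key = (sens + spec, spec, c)
        if best is None or key > best[0]:
            best = (key, (sign * c, tp, fp, fn, tn))
    return best[1]


def brute_spearman(xs, ys):
    """Spearman rho from mid-ranks, via the Pearson formula on ranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(xs), midranks(ys)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def mixture_tail_mc(rng, mu, sigma, delta, p, threshold, n_draws):
    """Monte-Carlo estimate of P(X < threshold) for the expiratory mixture."""
    trapped = rng.random(n_draws) < p
    x = rng.normal(mu, sigma, n_draws)
    x[~trapped] += delta
    return 100.0 * float((x < threshold).mean())
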