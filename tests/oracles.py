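"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in plain Python (loops, the
``math`` module, direct textbook formulas) rather than vectorized
numpy, so that agreement with the package implementations is evidence
of correctness and not of shared code.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

G = 9.81
EMA_ALPHA = 0.1


# ---------------------------------------------------------------------------
# scalar helpers (plain-Python statistics)

def _mean(xs):
    return sum(xs) / len(xs)


def _var(xs):
    m = _mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def _std(xs):
    return math.sqrt(_var(xs))


def _skew(xs):
    m = _mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0.0:
        return 0.0
    m3 = sum((x - m) ** 3 for x in xs) / len(xs)
    return m3 / m2 ** 1.5


def _kurt(xs):
    m = _mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0.0:
        return 0.0
    m4 = sum((x - m) ** 4 for x in xs) / len(xs)
    return m4 / m2 ** 2


def _corr(xs, ys):
    sx, sy = _std(xs), _std(ys)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    mx, my = _mean(xs), _mean(ys)
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / len(xs)
    return cov / (sx * sy)


def _slope(xs, dt):
    ts = [k * dt for k in range(len(xs))]
    tm, xm = _mean(ts), _mean(xs)
    num = sum((t - tm) * (x - xm) for t, x in zip(ts, xs))
    den = sum((t - tm) ** 2 for t in ts)
    return num / den


def _sign_changes(ds):
    """Count of adjacent strictly-opposite-sign pairs; zeros break runs."""
    count = 0
    for a, b in zip(ds[:-1], ds[1:]):
        if a * b < 0:
            count += 1
    return count


def _cumtrapz(xs, dt):
    out = [0.0]
    for a, b in zip(xs[:-1], xs[1:]):
        out.append(out[-1] + 0.5 * (a + b) * dt)
    return out


def _rms(xs):
    return math.sqrt(sum(x * x for x in xs) / len(xs))


def _dft_power(xs):
    """Full-spectrum |X_k|^2 of a sequence, by direct summation."""
    L = len(xs)
    powers = []
    for k in range(L):
        acc = 0j
        for n, x in enumerate(xs):
            acc += x * cmath.exp(-2j * math.pi * k * n / L)
        powers.append(abs(acc) ** 2)
    return powers


def _spectral(xs, rate):
    L = len(xs)
    m = _mean(xs)
    xc = [x - m for x in xs]
    power = _dft_power(xc)
    energy = sum(power[1:]) / L
    half = L // 2
    if half < 1:
        return energy, 0.0, 0.0, 0.0
    bins = list(range(1, half + 1))
    p = [power[k] for k in bins]
    freqs = [k * rate / L for k in bins]
    ptot = sum(p)
    mean_f = sum(f * pw for f, pw in zip(freqs, p)) / ptot if ptot > 0 else 0.0
    peak_i = 0
    for i in range(1, len(p)):
        if p[i] > p[peak_i]:
            peak_i = i
    return energy, mean_f, freqs[peak_i], p[peak_i]


# ---------------------------------------------------------------------------
# 199-feature oracle

def feature_oracle(window, rate=50.0):
    """Compute the 199-feature vector from the documented formulas."""
    W = [list(map(float, row)) for row in np.asarray(window)]
    L = len(W)
    dt = 1.0 / rate
    duration = L * dt
    acc = [row[:3] for row in W]
    gyr = [row[3:] for row in W]
    acc_vm = [math.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2) for a in acc]
    gyr_vm = [math.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2) for g in gyr]
    sigs = [
        [a[0] for a in acc], [a[1] for a in acc], [a[2] for a in acc],
        [g[0] for g in gyr], [g[1] for g in gyr], [g[2] for g in gyr],
        acc_vm, gyr_vm,
    ]
    out = []

    # terminal value of each signal
    for s in sigs:
        out.append(s[-1])
    # skewness, kurtosis
    for s in sigs:
        out.append(_skew(s))
    for s in sigs:
        out.append(_kurt(s))
    # min, max, mean, variance, std
    for s in sigs:
        out.append(min(s))
    for s in sigs:
        out.append(max(s))
    for s in sigs:
        out.append(_mean(s))
    for s in sigs:
        out.append(_var(s))
    for s in sigs:
        out.append(_std(s))
    # correlations V-ML, V-AP, ML-AP for acc then gyr
    for tri in (sigs[0:3], sigs[3:6]):
        ap, ml, v = tri
        out.append(_corr(v, ml))
        out.append(_corr(v, ap))
        out.append(_corr(ml, ap))
    # slope of each signal
    for s in sigs:
        out.append(_slope(s, dt))
    # total angular change
    out.append(sum(v * dt for v in gyr_vm))
    # resultant angular acceleration: max ||delta omega|| / dt
    out.append(max(
        math.sqrt(sum((b[j] - a[j]) ** 2 for j in range(3))) / dt
        for a, b in zip(gyr[:-1], gyr[1:])
    ))
    # ASMA / SMA
    means = [_mean([a[j] for a in acc]) for j in range(3)]
    out.append(_mean([sum(abs(a[j] - means[j]) for j in range(3)) for a in acc]))
    out.append(_mean([sum(abs(a[j]) for j in range(3)) for a in acc]))
    # absolute vertical acceleration
    out.append(_mean([abs(a[2] - G) for a in acc]))
    # double-integrated dynamic acceleration per axis
    disp = [
        _cumtrapz(_cumtrapz([a[j] - means[j] for a in acc], dt), dt)
        for j in range(3)
    ]
    rng_d = [max(d) - min(d) for d in disp]
    out.append(math.hypot(rng_d[0], rng_d[1]))
    # peak-to-peak, RMS
    for s in sigs:
        out.append(max(s) - min(s))
    for s in sigs:
        out.append(_rms(s))
    # ratio index: raw channels vs the sensor SumVM max; SumVM: crest factor
    for j, s in enumerate(sigs[:6]):
        denom = max(acc_vm) if j < 3 else max(gyr_vm)
        out.append(max(abs(x) for x in s) / denom if denom > 0 else 0.0)
    for s in sigs[6:]:
        m = _mean(s)
        out.append(max(s) / m if m > 0 else 0.0)
    # resultant angle change between first and last acc samples
    n0 = math.sqrt(sum(x * x for x in acc[0]))
    n1 = math.sqrt(sum(x * x for x in acc[-1]))
    if n0 > 0 and n1 > 0:
        dot = sum(a * b for a, b in zip(acc[0], acc[-1])) / (n0 * n1)
        out.append(math.acos(min(1.0, max(-1.0, dot))))
    else:
        out.append(0.0)
    # fluctuation frequency: mean crossings per second
    for s in sigs:
        m = _mean(s)
        out.append(_sign_changes([x - m for x in s]) / duration)
    # resultant delta changes
    out.append(math.sqrt(sum((acc[-1][j] - acc[0][j]) ** 2 for j in range(3))))
    out.append(math.sqrt(sum((gyr[-1][j] - gyr[0][j]) ** 2 for j in range(3))))
    # postural sway block
    for j in range(3):
        out.append(means[j])
    for j in range(3):
        out.append(disp[j][-1])
    for j in range(3):
        out.append(rng_d[j])
    sway = [sum(abs(b - a) for a, b in zip(disp[j][:-1], disp[j][1:]))
            for j in range(3)]
    for j in range(3):
        out.append(sway[j])
    for j in range(3):
        out.append(sway[j] / duration)
    # slope changes, zero crossings, waveform length
    for s in sigs:
        out.append(float(_sign_changes([b - a for a, b in zip(s[:-1], s[1:])])))
    for s in sigs:
        m = _mean(s)
        out.append(float(_sign_changes([x - m for x in s])))
    for s in sigs:
        out.append(sum(abs(b - a) for a, b in zip(s[:-1], s[1:])))
    # spectral stats, grouped stat-major
    spect = [_spectral(s, rate) for s in sigs]
    for stat in range(4):
        for sp in spect:
            out.append(sp[stat])
    # resultant aggregates
    gm = [_mean([g[j] for g in gyr]) for j in range(3)]
    gs = [_std([g[j] for g in gyr]) for j in range(3)]
    am = means
    asd = [_std([a[j] for a in acc]) for j in range(3)]
    out.append(math.sqrt(sum(x * x for x in gm)))
    out.append(math.sqrt(sum(x * x for x in gs)))
    out.append(math.sqrt(sum(x * x for x in am)))
    out.append(math.sqrt(sum(x * x for x in asd)))
    out.append(_mean([math.hypot(a[0], a[1]) for a in acc]))
    # EMA of acc SumVM
    ema = acc_vm[0]
    for v in acc_vm[1:]:
        ema = EMA_ALPHA * v + (1.0 - EMA_ALPHA) * ema
    out.append(ema)
    # rotational angle of acc SumVM
    angles = []
    for a, vm in zip(acc, acc_vm):
        ratio = a[2] / vm if vm > 0 else 1.0
        angles.append(math.acos(min(1.0, max(-1.0, ratio))))
    out.append(_mean(angles))
    # Z-score of the final acc SumVM sample
    sd = _std(acc_vm)
    out.append((acc_vm[-1] - _mean(acc_vm)) / sd if sd > 0 else 0.0)
    # magnitude of angular displacement
    ang = [_cumtrapz([g[j] for g in gyr], dt)[-1] for j in range(3)]
    out.append(math.sqrt(sum(x * x for x in ang)))

    assert len(out) == 199
    return np.array(out)


# ---------------------------------------------------------------------------
# windowing enumeration

def count_windows_bruteforce(n_samples, length, hop):
    """Enumerate window start positions one by one."""
    count = 0
    start = 0
    while start + length <= n_samples:
        count += 1
        start += hop
    return count


# ---------------------------------------------------------------------------
# Relief-F, O(W^2) with explicit loops

def relieff_oracle(X, y, k=10):
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, f = X.shape
    classes = sorted(set(y.tolist()))
    prior = {c: (y == c).sum() / n for c in classes}
    span = [max(X[:, j]) - min(X[:, j]) for j in range(f)]
    span = [s if s != 0 else 1.0 for s in span]
    W = [0.0] * f

    def norm_diff(i, j):
        return [abs(X[i, col] - X[j, col]) / span[col] for col in range(f)]

    for i in range(n):
        dists = []
        for j in range(n):
            dists.append(sum(norm_diff(i, j)))
        for c in classes:
            others = [j for j in range(n) if y[j] == c and j != i]
            if not others:
                continue
            others.sort(key=lambda j: (dists[j], j))  # stable: index tie-break
            near = others[:min(k, len(others))]
            mean_diff = [0.0] * f
            for j in near:
                nd = norm_diff(i, j)
                for col in range(f):
                    mean_diff[col] += nd[col] / len(near)
            if c == y[i]:
                for col in range(f):
                    W[col] -= mean_diff[col]
            else:
                w = prior[c] / (1.0 - prior[y[i]])
                for col in range(f):
                    W[col] += w * mean_diff[col]
    return np.array(W) / n


# ---------------------------------------------------------------------------
# multiclass MCC, direct element-wise Gorodkin sums

def mcc_oracle(confusion):
    C = np.asarray(confusion, float)
    K = C.shape[0]
    # covariance between truth and prediction indicator variables
    cov_tp = 0.0
    cov_tt = 0.0
    cov_pp = 0.0
    for k in range(K):
        for l in range(K):
            for m in range(K):
                cov_tp += C[k, k] * C[l, m] - C[k, l] * C[m, k]
    for k in range(K):
        row_k = sum(C[k, :])
        other_rows = sum(sum(C[kp, :]) for kp in range(K) if kp != k)
        cov_tt += row_k * other_rows
        col_k = sum(C[:, k])
        other_cols = sum(sum(C[:, kp]) for kp in range(K) if kp != k)
        cov_pp += col_k * other_cols
    denom = math.sqrt(cov_tt) * math.sqrt(cov_pp)
    if denom == 0:
        return 0.0
    return cov_tp / denom
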