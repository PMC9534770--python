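"""Independent brute-force reference implementations.

Deliberately naive (explicit Python loops, textbook formulas) so they share
no code path with the package; the tests compare the two routes on random
small instances.
"""

from __future__ import annotations

import math



def naive_corr(a, b) -> float:
    """Pearson r from the raw covariance formula."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov / math.sqrt(va * vb)


def naive_extrema(x):
    """Local maxima/minima with plateau midpoints, boundaries as minima.

    For each plateau (maximal run of equal values) not touching either
    boundary, compare against the neighboring distinct values; the extremum
    index is the plateau midpoint rounded leftward.
    """
    x = list(map(float, x))
    n = len(x)
    maxima, minima = [], []
    i = 1
    # walk over plateaus starting after the first run
    runs = []
    start = 0
    for j in range(1, n):
        if x[j] != x[start]:
            runs.append((start, j - 1))
            start = j
    runs.append((start, n - 1))
    for k in range(1, len(runs) - 1):
        s, e = runs[k]
        left = x[runs[k - 1][0]]
        right = x[runs[k + 1][0]]
        mid = (s + e) // 2
        if left < x[s] and x[s] > right:
            maxima.append(mid)
        elif left > x[s] and x[s] < right:
            minima.append(mid)
    minima = sorted(set([0] + minima + [n - 1]))
    return maxima, minima


def naive_detect(smoothed, threshold):
    """Directly scan for supra-threshold maxima and flanking minima."""
    maxima, minima = naive_extrema(smoothed)
    events = []
    for m in maxima:
        if smoothed[m] <= threshold[m]:
            continue
        left = max((q for q in minima if q < m), default=0)
        right = min((q for q in minima if q > m), default=len(smoothed) - 1)
        if events and left <= events[-1][1]:
            s, e, p = events[-1]
            events[-1] = (s, max(e, right),
                          m if smoothed[m] > smoothed[p] else p)
        else:
            events.append((left, right, m))
    return events


def naive_population_rate(spikes):
    return [sum(spikes[i][t] for i in range(len(spikes)))
            for t in range(len(spikes[0]))]


def naive_profile(spikes, trials, window, n_sounds):
    """Per-(neuron, sound) response counts by direct trial scanning."""
    n_neurons = len(spikes)
    counts = [[0] * n_sounds for _ in range(n_neurons)]
    for sound_id, onset in trials:
        for i in range(n_neurons):
            if any(spikes[i][t] for t in range(onset, min(onset + window, len(spikes[i])))):
                counts[i][sound_id - 1] += 1
    return counts


def naive_mad(values) -> float:
    values = list(map(float, values))
    m = sum(values) / len(values)
    return sum(abs(v - m) for v in values) / len(values)


def naive_regression_mad(x, y) -> float:
    """OLS of y on x via textbook formulas; mean absolute vertical residual."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    return sum(abs(b - (slope * a + intercept)) for a, b in zip(x, y)) / n


def naive_participation(spikes, events, trials, window):
    """p_spont / p_evoked by explicit window scanning."""
    n_neurons = len(spikes)
    n_frames = len(spikes[0])
    p_spont, p_evoked = [], []
    for i in range(n_neurons):
        hits = sum(
            1 for (s, e) in events
            if any(spikes[i][t] for t in range(s, min(e + 1, n_frames)))
        )
        p_spont.append(hits / len(events))
        resp = sum(
            1 for (_, onset) in trials
            if any(spikes[i][t] for t in range(onset, min(onset + window, n_frames)))
        )
        p_evoked.append(resp / len(trials))
    return p_spont, p_evoked


def naive_assembly(spikes, start, end):
    return [1 if any(spikes[i][t] for t in range(start, end + 1)) else 0
            for i in range(len(spikes))]


def naive_kurtosis(values) -> float:
    values = list(map(float, values))
    n = len(values)
    m = sum(values) / n
    m2 = sum((v - m) ** 2 for v in values) / n
    m4 = sum((v - m) ** 4 for v in values) / n
    return m4 / m2 ** 2
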