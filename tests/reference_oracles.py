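"""Independent oracles and frozen reference statistics shared by tests."""

import numpy as np

# cohort-table contingency counts (presence/absence per cluster) and the
# Pearson chi-squared statistics they imply
CHI2_CASES = {
    "cognitive_fluctuations": ([[32, 13], [63, 11], [36, 2]], 8.614),
    "visual_hallucinations": ([[31, 16], [39, 36], [19, 21]], 3.461),
    "parkinsonism": ([[43, 4], [68, 8], [31, 9]], 4.473),
    "probable_rbd": ([[35, 10], [57, 13], [25, 10]], 1.362),
    "apoe4": ([[18, 31], [38, 34], [13, 25]], 4.770),
    "sex": ([[35, 14], [60, 16], [24, 16]], 4.696),
    "ad_copathology": ([[2, 27], [9, 51], [2, 31]], 2.352),
}

# per-group (mean, sd, n) summaries and the one-way ANOVA F they imply
ANOVA_SUMMARY_CASES = {
    "age": ([(73.43, 8.02, 49), (69.05, 7.52, 76), (63.68, 8.23, 40)], 17.048),
    "mmse": ([(21.57, 5.49, 49), (22.93, 5.27, 75), (24.50, 4.38, 40)], 3.579),
    "disease_duration": ([(5.11, 3.63, 32), (5.09, 3.46, 59),
                          (7.25, 6.00, 32)], 2.961),
    "education": ([(15.02, 3.61, 49), (13.24, 3.90, 76),
                   (12.60, 3.80, 40)], 5.117),
    "wmh": ([(21.37, 15.41, 49), (14.55, 13.13, 76), (12.43, 7.96, 40)], 6.230),
}


def brute_force_average_linkage(D):
    """O(n^3) group-average agglomeration, lowest-index tie-break."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    active = list(range(n))
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i)}
    heights = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                key = frozenset((active[ai], active[aj]))
                d = dist[key]
                if best is None or d < best[0]:
                    best = (d, active[ai], active[aj])
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            wi, wj = len(clusters[i]), len(clusters[j])
            dist[frozenset((next_id, k))] = (wi * dik + wj * djk) / (wi + wj)
        clusters[next_id] = merged
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return np.array(heights)


def brute_force_bh(p, alpha):
    """Benjamini-Hochberg by explicit enumeration over all thresholds."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj, reject
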