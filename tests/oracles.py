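"""Independent brute-force oracles used to cross-check the pipeline.

Every function here recomputes a result by the most naive correct means
available (exhaustive enumeration, transitive closure, step-by-step
recomputation) and is kept free of the implementation code paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def feature_clusters_oracle(df, ppm_tol, max_scan_gap, scan_interval):
    """Transitive closure of the pairwise merge relation, O(n^2)."""
    n = len(df)
    run = df["run_id"].to_numpy()
    charge = df["charge"].to_numpy()
    mass = df["mono_mass_da"].to_numpy(float)
    rt = df["rt_min"].to_numpy(float)
    tol = ppm_tol * 1e-6
    gap = (max_scan_gap + 1) * scan_interval * (1 + 1e-9)

    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if run[i] != run[j] or charge[i] != charge[j]:
                continue
            if abs(mass[i] - mass[j]) > tol * max(mass[i], mass[j]):
                continue
            if abs(rt[i] - rt[j]) > gap:
                continue
            parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def match_pairs_oracle(features, classes, ppm_tol, min_rt_overlap):
    """Exhaustive candidate enumeration + greedy one-to-one assignment."""
    rows = features.reset_index(drop=True)
    n = len(rows)
    cands = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = rows.iloc[i], rows.iloc[j]
            if a["run_id"] != b["run_id"] or a["charge"] != b["charge"]:
                continue
            dm = b["mass"] - a["mass"]
            hits = [
                (c.label, (dm - c.delta) / b["mass"] * 1e6)
                for c in classes
                if abs(dm - c.delta) <= ppm_tol * 1e-6 * b["mass"]
            ]
            if len(hits) != 1:
                continue  # no class, or ambiguous
            label, err = hits[0]
            ov = min(a["rt_end"], b["rt_end"]) - max(a["rt_start"], b["rt_start"])
            shorter = min(a["rt_end"] - a["rt_start"], b["rt_end"] - b["rt_start"])
            if ov < min_rt_overlap * shorter:
                continue
            cands.append(
                (
                    abs(err),
                    abs(a["rt_apex"] - b["rt_apex"]),
                    a["feature_id"],
                    b["feature_id"],
                    label,
                )
            )
    cands.sort()
    used = set()
    picked = []
    for _, _, fa, fb, label in cands:
        if fa in used or fb in used:
            continue
        used.add(fa)
        used.add(fb)
        picked.append((fa, fb, label))
    return sorted(picked)


def attach_oracle(pairs, ids, ppm_tol, rt_tol):
    """Nearest-in-ppm assignment of each id to a pair, O(n_ids * n_pairs)."""
    out = []
    p = pairs.reset_index(drop=True)
    for _, row in ids.iterrows():
        best = None
        for k in range(len(p)):
            pr = p.iloc[k]
            if pr["run_id"] != row["run_id"] or pr["charge"] != row["charge"]:
                continue
            err = (
                min(
                    abs(pr["mass_light"] - row["mono_mass_da"]),
                    abs(pr["mass_heavy"] - row["mono_mass_da"]),
                )
                / row["mono_mass_da"]
                * 1e6
            )
            if err > ppm_tol:
                continue
            rt_d = abs(pr["rt_apex"] - row["rt_min"])
            if rt_d > rt_tol:
                continue
            key = (err, rt_d)
            if best is None or key < best[0]:
                best = (key, k)
        if best is not None:
            out.append((row["run_id"], row["sequence"], int(p.iloc[best[1]]["light_id"])))
    return sorted(out)


def hcluster_oracle(matrix, metric="pearson", linkage="average"):
    """Agglomeration recomputing every cluster-pair linkage from the
    original pairwise distances at every step."""
    from silacq.downstream import pairwise_distances  # metric shared by contract

    d0 = pairwise_distances(np.asarray(matrix, float), metric)
    n = d0.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                ds = [d0[p, q] for p in clusters[a] for q in clusters[b]]
                if linkage == "average":
                    val = sum(ds) / len(ds)
                elif linkage == "single":
                    val = min(ds)
                else:
                    val = max(ds)
                if best is None or val < best[0]:
                    best = (val, a, b)
        val, a, b = best
        merges.append((a, b, val, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def hypergeom_upper_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / math.comb(N, n)


def bh_oracle(pvals):
    """Hand application of the step-up formula."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def normalize_scale_oracle(values, target=0.5):
    """Root-bracketing solution for the ratio-space scale factor."""
    x = np.asarray(values, float)
    rho = x / (1 - x)

    def g(c):
        return float(np.mean(c * rho / (1 + c * rho))) - target

    lo, hi = 1e-12, 1e12
    return brentq(g, lo, hi, xtol=1e-15, rtol=1e-15)


def anova_f_oracle(a, b):
    """Textbook sum-of-squares computation, kept deliberately naive."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    grand = (sum(a) + sum(b)) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
    return (ssb / 1) / (ssw / (na + nb - 2))


def trapezoid_oracle(trace):
    """Independent numerical integration of the trace."""
    pts = sorted((float(t), float(a)) for t, a in trace)
    if len(pts) == 1:
        return pts[0][1]
    total = 0.0
    for (t0, a0), (t1, a1) in zip(pts, pts[1:]):
        total += (a0 + a1) * (t1 - t0) / 2.0
    return total
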