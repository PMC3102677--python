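"""Chromatographic feature building and SILAC pair quantification.

Per-scan deisotoped detections are merged into persistent features
(connected components of the "same run/charge, masses within ppm, scans
within the allowed gap" relation), integrated by the trapezoidal rule,
and matched into light/heavy pairs by the five label mass-shift classes.

Features and pairs are plain :class:`pandas.DataFrame` tables.

Feature columns
    ``feature_id, run_id, charge, mass, rt_apex, rt_start, rt_end,
    area, n_scans, trace`` — ``mass`` is the area-weighted mean of the
    per-scan masses and ``trace`` holds the (rt, area) points.

Pair columns
    ``run_id, charge, light_id, heavy_id, mass_light, mass_heavy,
    shift_class, ppm_error, rt_apex, area_light, area_heavy, ria`` —
    ``ppm_error`` is signed and relative to the heavy mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .peptide_chem import ShiftClass, shift_classes

__all__ = [
    "PairParams",
    "build_features",
    "integrate_area",
    "match_pairs",
    "compute_ria",
    "FEATURE_COLUMNS",
    "PAIR_COLUMNS",
]

FEATURE_COLUMNS = [
    "feature_id",
    "run_id",
    "charge",
    "mass",
    "rt_apex",
    "rt_start",
    "rt_end",
    "area",
    "n_scans",
    "trace",
]

PAIR_COLUMNS = [
    "run_id",
    "charge",
    "light_id",
    "heavy_id",
    "mass_light",
    "mass_heavy",
    "shift_class",
    "ppm_error",
    "rt_apex",
    "area_light",
    "area_heavy",
    "ria",
]


@dataclass
class PairParams:
    """Tolerances for light/heavy pair matching.

    ppm_tol reuses the single instrument-accuracy figure (5 ppm);
    min_rt_overlap is the required elution overlap as a fraction of the
    shorter feature's RT span.
    """

    ppm_tol: float = 5.0
    min_rt_overlap: float = 0.5
    classes: list[ShiftClass] = field(default_factory=shift_classes)

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be > 0")
        if not 0 < self.min_rt_overlap <= 1:
            raise ValueError("min_rt_overlap must be in (0, 1]")


def integrate_area(trace) -> float:
    """Trapezoidal integral of a (rt, area) trace.

    A single point integrates to its own area value.
    """
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("trace must be a non-empty sequence of (rt, area) points")
    if len(pts) == 1:
        return float(pts[0, 1])
    order = np.argsort(pts[:, 0], kind="stable")
    rt, a = pts[order, 0], pts[order, 1]
    return float(np.sum(0.5 * (a[1:] + a[:-1]) * (rt[1:] - rt[:-1])))


def build_features(
    detections: pd.DataFrame,
    ppm_tol: float = 5.0,
    max_scan_gap: int = 2,
    scan_interval: float = 2.0 / 60.0,
) -> pd.DataFrame:
    """Merge per-scan detections into persistent features.

    Two rows of the same run and charge belong to the same feature when
    their masses agree within ``ppm_tol`` (relative to the larger mass)
    and their retention times are within ``(max_scan_gap + 1)`` scan
    intervals, transitively.  No merging happens across runs or charges.
    """
    if len(detections) == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    df = detections.reset_index(drop=True)
    tol = ppm_tol * 1e-6
    rt_gap = (max_scan_gap + 1) * scan_interval * (1.0 + 1e-9)

    group_key, _ = pd.factorize(
        df["run_id"].astype(str) + "\x00" + df["charge"].astype(str)
    )
    mass = df["mono_mass_da"].to_numpy(float)
    rt = df["rt_min"].to_numpy(float)
    n = len(df)

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    order_all = np.lexsort((mass, group_key))
    bounds = np.flatnonzero(np.diff(group_key[order_all])) + 1
    for seg in np.split(order_all, bounds):
        m = mass[seg]
        t = rt[seg]
        # j > i with m[j] <= m[i] / (1 - tol)  <=>  (m[j]-m[i]) <= tol*m[j]
        hi = np.searchsorted(m, m / (1.0 - tol), side="right")
        counts = hi - np.arange(len(seg)) - 1
        counts = np.maximum(counts, 0)
        if counts.sum() == 0:
            continue
        i_loc = np.repeat(np.arange(len(seg)), counts)
        j_loc = _window_partners(counts)
        ok = np.abs(t[i_loc] - t[j_loc]) <= rt_gap
        rows_i.append(seg[i_loc[ok]])
        rows_j.append(seg[j_loc[ok]])

    if rows_i:
        ii = np.concatenate(rows_i)
        jj = np.concatenate(rows_j)
        graph = coo_matrix((np.ones(ii.size, dtype=np.int8), (ii, jj)), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)

    return _aggregate_components(df, labels, mass, rt)


def _window_partners(counts: np.ndarray) -> np.ndarray:
    """For each i with counts[i] partners, the indices i+1 .. i+counts[i]."""
    total = int(counts.sum())
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    row = np.repeat(np.arange(counts.size), counts)
    return row + 1 + (np.arange(total) - starts[row])


def _aggregate_components(df: pd.DataFrame, labels: np.ndarray, mass, rt) -> pd.DataFrame:
    area = df["area"].to_numpy(float)
    order = np.lexsort((rt, labels))
    lab_s, rt_s, area_s, mass_s = labels[order], rt[order], area[order], mass[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(lab_s)) + 1])
    n_scans = np.diff(np.concatenate([starts, [len(lab_s)]]))

    # trapezoid per component; single-scan components keep their area value
    seg_w = 0.5 * (area_s[1:] + area_s[:-1]) * (rt_s[1:] - rt_s[:-1])
    same = lab_s[1:] == lab_s[:-1]
    seg_w = np.where(same, seg_w, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(seg_w)])
    ends = np.concatenate([starts[1:], [len(lab_s)]])
    f_area = cum[ends - 1] - cum[starts]
    f_area = np.where(n_scans == 1, area_s[starts], f_area)

    w_mass = np.add.reduceat(mass_s * area_s, starts)
    w = np.add.reduceat(area_s, starts)
    f_mass = np.where(w > 0, w_mass / np.where(w > 0, w, 1.0), mass_s[starts])

    # apex = RT of the max-area scan
    apex_idx = _argmax_per_segment(area_s, starts, ends)
    traces = np.split(np.column_stack([rt_s, area_s]), starts[1:])

    first = order[starts]
    out = pd.DataFrame(
        {
            "feature_id": np.arange(len(starts)),
            "run_id": df["run_id"].to_numpy()[first],
            "charge": df["charge"].to_numpy()[first],
            "mass": f_mass,
            "rt_apex": rt_s[apex_idx],
            "rt_start": rt_s[starts],
            "rt_end": rt_s[ends - 1],
            "area": f_area,
            "n_scans": n_scans,
        }
    )
    out["trace"] = traces
    return out


def _argmax_per_segment(values, starts, ends):
    # first occurrence of the per-segment maximum
    seg_id = np.repeat(np.arange(len(starts)), ends - starts)
    seg_max = np.maximum.reduceat(values, starts)
    is_max = values == seg_max[seg_id]
    idx = np.flatnonzero(is_max)
    keep = np.concatenate([[True], np.diff(seg_id[idx]) > 0])
    return idx[keep]


def compute_ria(area_light: float, area_heavy: float) -> float:
    """Relative isotope abundance: light / (light + heavy)."""
    if area_light < 0 or area_heavy < 0:
        raise ValueError("areas must be non-negative")
    total = area_light + area_heavy
    if total == 0:
        raise ValueError("RIA undefined when both areas are zero")
    return area_light / total


def match_pairs(features: pd.DataFrame, params: PairParams | None = None) -> pd.DataFrame:
    """Match light/heavy feature pairs by shift class.

    Candidates require equal run and charge, a mass difference within
    ``ppm_tol`` (relative to the heavy mass) of exactly one class delta,
    and RT-interval overlap of at least ``min_rt_overlap`` times the
    shorter feature's span.  Conflicts are resolved one-to-one greedily
    by ascending \\|ppm error\\| (ties: apex distance, then feature ids),
    so each feature joins at most one pair.
    """
    params = params or PairParams()
    if len(features) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    out = []
    for _, grp in features.groupby(["run_id", "charge"], sort=True, observed=True):
        out.append(_match_group(grp, params))
    out = [o for o in out if len(o)]
    if not out:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(out, ignore_index=True)[PAIR_COLUMNS]


def _match_group(grp: pd.DataFrame, params: PairParams) -> pd.DataFrame:
    tol = params.ppm_tol * 1e-6
    order = np.argsort(grp["mass"].to_numpy(), kind="stable")
    g = grp.iloc[order]
    m = g["mass"].to_numpy(float)
    apex = g["rt_apex"].to_numpy(float)
    r0 = g["rt_start"].to_numpy(float)
    r1 = g["rt_end"].to_numpy(float)
    fid = g["feature_id"].to_numpy()
    area = g["area"].to_numpy(float)

    cand_i, cand_j, cand_cls, cand_err = [], [], [], []
    for ci, cls in enumerate(params.classes):
        lo = np.searchsorted(m, (m + cls.delta) / (1.0 + tol), side="left")
        hi = np.searchsorted(m, (m + cls.delta) / (1.0 - tol), side="right")
        counts = np.maximum(hi - lo, 0)
        if counts.sum() == 0:
            continue
        i_loc = np.repeat(np.arange(m.size), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        j_loc = lo[i_loc] + (np.arange(int(counts.sum())) - starts[i_loc])
        keep = i_loc != j_loc
        i_loc, j_loc = i_loc[keep], j_loc[keep]
        err = ((m[j_loc] - m[i_loc]) - cls.delta) / m[j_loc] * 1e6
        keep = np.abs(err) <= params.ppm_tol
        i_loc, j_loc, err = i_loc[keep], j_loc[keep], err[keep]
        ov = np.minimum(r1[i_loc], r1[j_loc]) - np.maximum(r0[i_loc], r0[j_loc])
        shorter = np.minimum(r1[i_loc] - r0[i_loc], r1[j_loc] - r0[j_loc])
        keep = ov >= params.min_rt_overlap * shorter
        cand_i.append(i_loc[keep])
        cand_j.append(j_loc[keep])
        cand_err.append(err[keep])
        cand_cls.append(np.full(int(keep.sum()), ci))

    if not cand_i:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    i = np.concatenate(cand_i)
    j = np.concatenate(cand_j)
    err = np.concatenate(cand_err)
    cls_idx = np.concatenate(cand_cls)
    if i.size == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    # a (light, heavy) mass difference matching two classes is ambiguous:
    # drop every such candidate
    key = i.astype(np.int64) * len(m) + j
    _, inv, cnt = np.unique(key, return_inverse=True, return_counts=True)
    unambiguous = cnt[inv] == 1
    i, j, err, cls_idx = i[unambiguous], j[unambiguous], err[unambiguous], cls_idx[unambiguous]
    if i.size == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    rank = np.lexsort((fid[j], fid[i], np.abs(apex[i] - apex[j]), np.abs(err)))
    used = np.zeros(m.size, dtype=bool)
    picked = []
    for k in rank:
        a, b = i[k], j[k]
        if used[a] or used[b]:
            continue
        used[a] = used[b] = True
        picked.append(k)
    if not picked:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    picked = np.array(picked)
    i, j, err, cls_idx = i[picked], j[picked], err[picked], cls_idx[picked]
    labels = [params.classes[c].label for c in cls_idx]
    return pd.DataFrame(
        {
            "run_id": grp["run_id"].iloc[0],
            "charge": grp["charge"].iloc[0],
            "light_id": fid[i],
            "heavy_id": fid[j],
            "mass_light": m[i],
            "mass_heavy": m[j],
            "shift_class": labels,
            "ppm_error": err,
            "rt_apex": apex[i],
            "area_light": area[i],
            "area_heavy": area[j],
            "ria": area[i] / (area[i] + area[j]),
        }
    )
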