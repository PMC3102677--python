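"""Accurate-mass-and-time database construction and filtering.

Attaches peptide identifications to SILAC pairs within mass/RT
tolerances, aggregates labeled pairs across runs into per-(sequence,
charge) AMT entries, applies the exclusion rules (minimum presence
across runs, maximum RT span, wash/equilibration windows), and merges
technical duplicates at 5 ppm / 5 min by averaging their ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptide_chem import monoisotopic_mass

__all__ = [
    "FilterParams",
    "attach_ids",
    "build_amt",
    "filter_amt",
    "merge_technical",
    "LABELED_COLUMNS",
]

LABELED_COLUMNS = [
    "run_id",
    "charge",
    "light_id",
    "heavy_id",
    "mass_light",
    "mass_heavy",
    "shift_class",
    "rt_apex",
    "area_light",
    "area_heavy",
    "ria",
    "sequence",
    "accession",
    "id_score",
    "id_mass",
    "id_rt",
]


@dataclass(frozen=True)
class FilterParams:
    """AMT exclusion rules.

    min_presence
        Minimum fraction of analyzed runs in which the peptide was
        observed (default 0.25, i.e. 25% of all runs).
    max_rt_span
        Maximum allowed spread (max - min, minutes) of the contributing
        retention times (default 10).
    excluded_rt_windows
        RT windows (minutes) treated as wash / re-equilibration phases;
        entries whose mean RT falls inside any window are dropped.
    """

    min_presence: float = 0.25
    max_rt_span: float = 10.0
    excluded_rt_windows: tuple[tuple[float, float], ...] = (
        (0.0, 10.0),
        (120.0, math.inf),
    )

    def __post_init__(self) -> None:
        if not 0 < self.min_presence <= 1:
            raise ValueError("min_presence must be in (0, 1]")
        if self.max_rt_span <= 0:
            raise ValueError("max_rt_span must be > 0")


def attach_ids(
    pairs: pd.DataFrame,
    ids: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 5.0,
    log: list | None = None,
) -> pd.DataFrame:
    """Attach identifications to pairs of the same run.

    An identification attaches to the pair whose light or heavy mass is
    within ``ppm_tol`` of the identification's mass (ppm relative to the
    identification mass) and whose RT apex is within ``rt_tol`` minutes;
    the nearest-in-ppm pair wins, RT distance breaks ties (logged).  At
    most one identification per (pair, sequence) is kept — the highest
    scoring one.
    """
    if len(pairs) == 0 or len(ids) == 0:
        return pd.DataFrame(columns=LABELED_COLUMNS)
    tol = ppm_tol * 1e-6
    chunks = []
    for run, id_grp in ids.groupby("run_id", sort=True):
        p = pairs[pairs["run_id"] == run]
        if len(p) == 0:
            continue
        p = p.reset_index(drop=True)
        # one sorted mass axis covering both channels
        mass_l = p["mass_light"].to_numpy()
        mass_h = p["mass_heavy"].to_numpy()
        ch_mass = np.concatenate([mass_l, mass_h])
        ch_pair = np.concatenate([np.arange(len(p)), np.arange(len(p))])
        order = np.argsort(ch_mass, kind="stable")
        ch_mass, ch_pair = ch_mass[order], ch_pair[order]
        apex = p["rt_apex"].to_numpy()
        charge = p["charge"].to_numpy()

        hit_pair: list[int] = []
        hit_id: list[int] = []
        id_mass_arr = id_grp["mono_mass_da"].to_numpy()
        id_rt_arr = id_grp["rt_min"].to_numpy()
        id_charge_arr = id_grp["charge"].to_numpy()
        for k in range(len(id_grp)):
            m_id, rt_id = id_mass_arr[k], id_rt_arr[k]
            lo = np.searchsorted(ch_mass, m_id * (1 - tol), side="left")
            hi = np.searchsorted(ch_mass, m_id * (1 + tol), side="right")
            if hi <= lo:
                continue
            cand = np.unique(ch_pair[lo:hi])
            cand = cand[charge[cand] == id_charge_arr[k]]
            cand = cand[np.abs(apex[cand] - rt_id) <= rt_tol]
            if cand.size == 0:
                continue
            errs = np.minimum(np.abs(mass_l[cand] - m_id), np.abs(mass_h[cand] - m_id)) / m_id * 1e6
            best = errs == errs.min()
            cand = cand[best]
            if cand.size > 1:
                if log is not None:
                    log.append(
                        f"id row {k}@{run}: {cand.size} pairs at equal ppm, attached to nearest RT"
                    )
                cand = cand[[int(np.argmin(np.abs(apex[cand] - rt_id)))]]
            hit_pair.append(int(cand[0]))
            hit_id.append(k)
        if not hit_pair:
            continue
        chunk = p.take(hit_pair)[
            [
                "run_id", "charge", "light_id", "heavy_id", "mass_light", "mass_heavy",
                "shift_class", "rt_apex", "area_light", "area_heavy", "ria",
            ]
        ].reset_index(drop=True)
        id_rows = id_grp.iloc[hit_id].reset_index(drop=True)
        chunk["sequence"] = id_rows["sequence"]
        chunk["accession"] = id_rows["accession"]
        chunk["id_score"] = id_rows["score"]
        chunk["id_mass"] = id_rows["mono_mass_da"]
        chunk["id_rt"] = id_rows["rt_min"]
        chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(columns=LABELED_COLUMNS)
    out = pd.concat(chunks, ignore_index=True)
    # one id per (pair, sequence): keep the best-scoring record
    out = (
        out.sort_values("id_score", ascending=False)
        .drop_duplicates(["run_id", "light_id", "heavy_id", "sequence"])
        .reset_index(drop=True)
    )
    return out[LABELED_COLUMNS]


def build_amt(
    labeled: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate labeled pairs into AMT entries.

    Returns ``(entries, observations)``.  ``entries`` has one row per
    (sequence, charge) with the accession of the highest-scoring match,
    the theoretical light mass, mean observed mass/RT, RT span and
    presence (fraction of analyzed runs with an observation).
    ``observations`` holds the per-run values (ria, mass, rt) keyed by
    ``entry_id``.
    """
    n_runs = len(manifest)
    if len(labeled) == 0:
        entries = pd.DataFrame(
            columns=[
                "entry_id", "sequence", "charge", "accession", "theo_mass",
                "obs_mass", "mean_rt", "rt_span", "presence", "n_runs",
            ]
        )
        obs = pd.DataFrame(columns=["entry_id", "sequence", "charge", "run_id", "ria", "mass", "rt"])
        return entries, obs

    df = labeled.copy()
    key, uniques = pd.factorize(
        df["sequence"].astype(str) + "\x00" + df["charge"].astype(str), sort=True
    )
    df["entry_id"] = key

    # several pairs of one run may carry the same sequence: average them
    obs = (
        df.groupby(["entry_id", "sequence", "charge", "run_id"], as_index=False, observed=True)
        .agg(ria=("ria", "mean"), mass=("mass_light", "mean"), rt=("rt_apex", "mean"))
    )

    best = df.sort_values("id_score", ascending=False).drop_duplicates("entry_id")
    acc = best.set_index("entry_id")["accession"]

    agg = obs.groupby("entry_id").agg(
        sequence=("sequence", "first"),
        charge=("charge", "first"),
        obs_mass=("mass", "mean"),
        mean_rt=("rt", "mean"),
        rt_min_=("rt", "min"),
        rt_max_=("rt", "max"),
        n_runs=("run_id", "nunique"),
    )
    entries = pd.DataFrame(
        {
            "entry_id": agg.index,
            "sequence": agg["sequence"],
            "charge": agg["charge"],
            "accession": acc.reindex(agg.index),
            "theo_mass": [monoisotopic_mass(s) for s in agg["sequence"]],
            "obs_mass": agg["obs_mass"],
            "mean_rt": agg["mean_rt"],
            "rt_span": agg["rt_max_"] - agg["rt_min_"],
            "presence": agg["n_runs"] / n_runs,
            "n_runs": agg["n_runs"],
        }
    ).reset_index(drop=True)
    return entries, obs


def filter_amt(
    entries: pd.DataFrame,
    observations: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the three AMT exclusion rules.

    Drops entries with presence below ``min_presence``, RT span above
    ``max_rt_span``, or mean RT inside an excluded window.  Returns the
    surviving entries, their observations, and per-rule drop counts
    (an entry may count against several rules).
    """
    params = params or FilterParams()
    presence_bad = entries["presence"] < params.min_presence
    span_bad = entries["rt_span"] > params.max_rt_span
    rt = entries["mean_rt"]
    window_bad = pd.Series(False, index=entries.index)
    for lo, hi in params.excluded_rt_windows:
        window_bad |= (rt >= lo) & (rt <= hi)
    bad = presence_bad | span_bad | window_bad
    counts = {
        "low_presence": int(presence_bad.sum()),
        "rt_span": int(span_bad.sum()),
        "excluded_window": int(window_bad.sum()),
        "total_dropped": int(bad.sum()),
    }
    kept = entries[~bad].reset_index(drop=True)
    obs = observations[observations["entry_id"].isin(set(kept["entry_id"]))].reset_index(drop=True)
    return kept, obs, counts


def merge_technical(
    observations: pd.DataFrame,
    manifest: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 5.0,
    log: list | None = None,
) -> pd.DataFrame:
    """Average technical duplicates of each entry within a sample.

    A sample is one (sample_type, bio_rep).  Duplicate observations of
    an entry merge (arithmetic mean of RIA, mass and RT) when their
    masses agree within ``ppm_tol`` and RTs within ``rt_tol``; otherwise
    they are kept as separate rows and logged.

    Returns one row per (entry_id, sample_type, bio_rep[, unmerged
    duplicate]) with columns ``entry_id, sequence, charge, sample_type,
    bio_rep, ria, mass, rt, n_obs``.
    """
    if len(observations) == 0:
        return pd.DataFrame(
            columns=["entry_id", "sequence", "charge", "sample_type", "bio_rep", "ria", "mass", "rt", "n_obs"]
        )
    meta = manifest.set_index("run_id")[["sample_type", "bio_rep"]]
    df = observations.join(meta, on="run_id")

    grp = df.groupby(["entry_id", "sample_type", "bio_rep"], observed=True)
    mass_rel = (grp["mass"].transform("max") - grp["mass"].transform("min")) / grp["mass"].transform("mean")
    rt_span = grp["rt"].transform("max") - grp["rt"].transform("min")
    n = grp["run_id"].transform("size")
    mergeable = (n == 1) | ((mass_rel <= ppm_tol * 1e-6) & (rt_span <= rt_tol))

    merged = (
        df[mergeable]
        .groupby(["entry_id", "sequence", "charge", "sample_type", "bio_rep"], as_index=False, observed=True)
        .agg(ria=("ria", "mean"), mass=("mass", "mean"), rt=("rt", "mean"), n_obs=("run_id", "size"))
    )
    rest = df[~mergeable]
    if len(rest):
        if log is not None:
            for key, sub in rest.groupby(["entry_id", "sample_type", "bio_rep"], observed=True):
                log.append(f"technical duplicates outside tolerance, kept separate: {key}")
        rest = rest.assign(n_obs=1)[
            ["entry_id", "sequence", "charge", "sample_type", "bio_rep", "ria", "mass", "rt", "n_obs"]
        ]
        merged = pd.concat([merged, rest], ignore_index=True)
    return merged.sort_values(["entry_id", "sample_type", "bio_rep"]).reset_index(drop=True)
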