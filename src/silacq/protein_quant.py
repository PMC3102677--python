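"""Protein-level relative isotope abundance (RIA).

Rolls peptide RIAs up to proteins (arithmetic mean), removes peptide
outliers by a leave-one-out two-standard-deviation rule, flips
reverse-labeled samples, rescales every sample so its mean protein RIA
is 0.5, and averages biological replicates.

Normalization acts in ratio space: every RIA r maps to
``c*rho / (1 + c*rho)`` with ``rho = r / (1 - r)`` and a single
multiplicative factor c found by monotone bisection.  This keeps values
inside (0, 1) and preserves ranks, unlike an additive shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationResult",
    "rollup",
    "trim_outliers",
    "orient",
    "orient_values",
    "normalize_sample",
    "build_protein_table",
    "average_biological",
]

MIN_PEPTIDES_FOR_TRIM = 3


@dataclass(frozen=True)
class NormalizationResult:
    scale: float
    achieved_mean: float
    iterations: int


def orient(ria: float, orientation: str) -> float:
    """Map a RIA onto the forward (light = resistant) orientation.

    forward and control ("none") values pass through; reverse values are
    complemented.
    """
    if orientation == "reverse":
        return 1.0 - ria
    if orientation in ("forward", "none"):
        return ria
    raise ValueError(f"unknown orientation: {orientation!r}")


def orient_values(ria: np.ndarray, reverse_mask: np.ndarray) -> np.ndarray:
    return np.where(reverse_mask, 1.0 - np.asarray(ria, float), ria)


def trim_outliers(values) -> tuple[np.ndarray, float]:
    """Leave-one-out 2-SD peptide trimming for one protein in one sample.

    For each peptide the mean and sample SD of the *other* peptides are
    computed; peptides deviating from that mean by more than twice that
    SD are all removed in a single pass and the mean is recomputed.
    Below three peptides nothing is trimmed.  A zero SD of the others
    with any deviation marks an outlier (strict inequality).

    Guard: outliers must be a minority.  If the rule would flag more
    than floor(n/2) peptides (which happens for near-equally-spaced
    small sets, where every extreme trips the 2-SD bound) the group is
    left untrimmed, so trimming can never remove a majority.

    Returns ``(kept_mask, mean_of_kept)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no peptide values")
    if n < MIN_PEPTIDES_FOR_TRIM:
        return np.ones(n, dtype=bool), float(x.mean())
    s, ss = x.sum(), (x**2).sum()
    mean_o = (s - x) / (n - 1)
    var_o = (ss - x**2 - (n - 1) * mean_o**2) / (n - 2)
    sd_o = np.sqrt(np.maximum(var_o, 0.0))
    keep = np.abs(x - mean_o) <= 2.0 * sd_o
    if int((~keep).sum()) > n // 2:
        keep = np.ones(n, dtype=bool)
    return keep, float(x[keep].mean())


def rollup(
    peptide_table: pd.DataFrame, *, trim: bool = True
) -> pd.DataFrame:
    """Protein RIA per sample = mean of constituent peptide RIAs.

    ``peptide_table`` needs columns accession, sample_type, bio_rep,
    ria.  With ``trim`` the leave-one-out outlier rule is applied within
    each (accession, sample_type, bio_rep) group before averaging.

    Returns columns accession, sample_type, bio_rep, ria, n_peptides,
    n_trimmed.
    """
    df = peptide_table
    cols = ["accession", "sample_type", "bio_rep"]
    if not trim:
        out = df.groupby(cols, as_index=False, observed=True).agg(
            ria=("ria", "mean"), n_peptides=("ria", "size")
        )
        out["n_trimmed"] = 0
        return out

    grp = df.groupby(cols, observed=True)
    x = df["ria"].to_numpy(float)
    n = grp["ria"].transform("size").to_numpy()
    s = grp["ria"].transform("sum").to_numpy()
    ss_col = df["ria"] ** 2
    ss = ss_col.groupby([df[c] for c in cols], observed=True).transform("sum").to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_o = (s - x) / (n - 1)
        var_o = (ss - x**2 - (n - 1) * mean_o**2) / (n - 2)
    sd_o = np.sqrt(np.maximum(var_o, 0.0))
    outlier = (np.abs(x - mean_o) > 2.0 * sd_o) & (n >= MIN_PEPTIDES_FOR_TRIM)

    # majority guard (see trim_outliers): a group where the rule flags
    # more than half its peptides is left untrimmed
    rm_per_group = (
        pd.Series(outlier, index=df.index)
        .groupby([df[c] for c in cols], observed=True)
        .transform("sum")
        .to_numpy()
    )
    outlier &= rm_per_group <= n // 2

    kept = df[~outlier]
    out = kept.groupby(cols, as_index=False, observed=True).agg(
        ria=("ria", "mean"), n_peptides=("ria", "size")
    )
    removed = (
        df.assign(_rm=outlier)
        .groupby(cols, as_index=False, observed=True)["_rm"]
        .sum()
        .rename(columns={"_rm": "n_trimmed"})
    )
    out = out.merge(removed, on=cols, how="left")
    out["n_trimmed"] = out["n_trimmed"].fillna(0).astype(int)
    return out


def normalize_sample(
    values, target: float = 0.5, tol: float = 1e-12, max_iter: int = 300
) -> tuple[np.ndarray, NormalizationResult]:
    """Rescale one sample's protein RIAs so their mean hits ``target``.

    Solves for the multiplicative ratio-space factor c by bisection
    (the mean is strictly increasing in c).  Boundary values 0 and 1 are
    fixed points of the transform; a sample consisting only of such
    values cannot be normalized and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("RIA values must lie in [0, 1]")
    interior = (x > 0) & (x < 1)
    if not interior.any():
        raise ValueError("all RIA values are 0 or 1; normalization undefined")

    rho = np.where(interior, x / np.where(interior, 1.0 - x, 1.0), 0.0)

    def mean_at(c: float) -> float:
        out = np.where(interior, c * rho / (1.0 + c * rho), x)
        return float(out.mean())

    lo = hi = 1.0
    it = 0
    while mean_at(hi) < target and it < 200:
        hi *= 2.0
        it += 1
    while mean_at(lo) > target and it < 400:
        lo /= 2.0
        it += 1
    c = 1.0
    for _ in range(max_iter):
        it += 1
        c = 0.5 * (lo + hi)
        g = mean_at(c) - target
        if abs(g) <= tol:
            break
        if g < 0:
            lo = c
        else:
            hi = c
    normalized = np.where(interior, c * rho / (1.0 + c * rho), x)
    return normalized, NormalizationResult(c, float(normalized.mean()), it)


def build_protein_table(
    sample_obs: pd.DataFrame, *, trim: bool = True, normalize: bool = True
) -> tuple[pd.DataFrame, dict[tuple, NormalizationResult]]:
    """Peptide sample observations -> per-sample protein RIA table.

    ``sample_obs`` needs accession, sample_type, bio_rep, ria (one row
    per peptide per sample, e.g. the output of technical-replicate
    merging joined with accessions).  Rolls up with optional trimming,
    then normalizes each (sample_type, bio_rep) sample to mean RIA 0.5.

    Returns the protein table (accession, sample_type, bio_rep, ria,
    n_peptides, n_trimmed) and the per-sample normalization results.
    """
    prot = rollup(sample_obs, trim=trim)
    norms: dict[tuple, NormalizationResult] = {}
    if normalize and len(prot):
        pieces = []
        for key, grp in prot.groupby(["sample_type", "bio_rep"], observed=True):
            vals, res = normalize_sample(grp["ria"].to_numpy())
            norms[key] = res
            grp = grp.copy()
            grp["ria"] = vals
            pieces.append(grp)
        prot = pd.concat(pieces, ignore_index=True)
    return prot, norms


def average_biological(
    protein_table: pd.DataFrame,
    mixed_types: tuple[str, ...] = ("mix_fwd", "mix_rev"),
) -> pd.DataFrame:
    """Mean/SD of protein RIA across replicate samples per sample type.

    SD is the sample standard deviation (ddof=1; NaN for a single
    replicate).  Also records, per accession, how many replicate-samples
    of mixed vs control type carry a value.
    """
    agg = protein_table.groupby(["accession", "sample_type"], as_index=False, observed=True).agg(
        mean_ria=("ria", "mean"),
        sd_ria=("ria", lambda v: v.std(ddof=1)),
        n_reps=("ria", "size"),
    )
    is_mixed = protein_table["sample_type"].isin(mixed_types)
    counts = (
        protein_table.assign(_mixed=is_mixed)
        .groupby("accession", observed=True)["_mixed"]
        .agg(n_samples_mixed="sum", n_samples_control=lambda v: int((~v).sum()))
        .reset_index()
    )
    return agg.merge(counts, on="accession", how="left")
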