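"""Differential expression statistics on protein RIA values.

Per-protein one-way ANOVA of the mixed samples (orientation-corrected)
against the self-mixed controls, the signed RIA <-> fold-change
transform, an empirical control-distribution fold cutoff, and the
significance calls combining the p-value screen with the fold screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protein_quant import orient_values

__all__ = [
    "CutoffResult",
    "anova_protein",
    "ria_to_fold",
    "fold_to_ria_bounds",
    "control_cutoff",
    "differential_analysis",
    "call_significant",
    "SMALLEST_P",
]

#: p-value reported for a degenerate ANOVA (zero within-group variance
#: with unequal group means)
SMALLEST_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class CutoffResult:
    """Fold cutoff derived from the pooled control RIA distribution."""

    ria_low: float
    ria_high: float
    fold_cutoff: float
    confidence: float


def anova_protein(mixed, control) -> tuple[float, float]:
    """Two-group one-way ANOVA: F = MS_between / MS_within, df (1, n-2).

    Degenerate inputs: zero within-group variance with unequal means
    reports the smallest representable positive p; two identical
    constant groups report (0, 1).
    """
    a = np.asarray(mixed, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    # ssw of constant groups is only zero up to float rounding
    if ssw <= 1e-18 * (ssb + ssw):
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), SMALLEST_P
    f = ssb / (ssw / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p


def ria_to_fold(ria: float) -> float:
    """Signed fold change of a RIA: ratio rho = ria/(1-ria); +rho when
    rho >= 1, else -1/rho.  \\|fold\\| >= 1 always."""
    if not 0 < ria < 1:
        raise ValueError("ria must be strictly inside (0, 1)")
    rho = ria / (1.0 - ria)
    return rho if rho >= 1.0 else -1.0 / rho


def fold_to_ria_bounds(fold_cutoff: float) -> tuple[float, float]:
    """RIA bounds equivalent to a +/- fold cutoff: (1/(1+f), f/(1+f))."""
    if fold_cutoff < 1.0:
        raise ValueError("fold cutoff must be >= 1")
    f = fold_cutoff
    return 1.0 / (1.0 + f), f / (1.0 + f)


def control_cutoff(control_rias, confidence: float = 0.99) -> CutoffResult:
    """Empirical-quantile cutoff from the pooled control distribution.

    The (1-confidence)/2 and (1+confidence)/2 quantiles of the pooled
    per-protein control RIAs give the bounds; the fold cutoff is the
    larger fold magnitude of the two.
    """
    x = np.asarray(control_rias, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no control values")
    if not 0 <= confidence < 1:
        raise ValueError("confidence must be in [0, 1)")
    if x.size < 50:
        warnings.warn(f"only {x.size} control values; cutoff is unstable", stacklevel=2)
    lo_q = (1.0 - confidence) / 2.0
    ria_low, ria_high = np.quantile(x, [lo_q, 1.0 - lo_q])
    fold = max(abs(ria_to_fold(float(ria_high))), abs(ria_to_fold(float(ria_low))))
    return CutoffResult(float(ria_low), float(ria_high), float(fold), confidence)


def differential_analysis(
    protein_table: pd.DataFrame,
    *,
    mixed_types: tuple[str, ...] = ("mix_fwd", "mix_rev"),
    reverse_types: tuple[str, ...] = ("mix_rev",),
    control_types: tuple[str, ...] = ("ctrl_cddp", "ctrl_hela"),
    min_mixed: int = 3,
    min_control: int = 3,
    log_ratio: bool = False,
) -> pd.DataFrame:
    """Per-protein ANOVA of oriented mixed vs control sample RIAs.

    ``protein_table`` is the per-(accession, sample_type, bio_rep)
    protein RIA table.  Reverse-labeled mixed samples are complemented
    before grouping so both orientations measure the same quantity.
    Proteins observed in fewer than ``min_mixed`` mixed or
    ``min_control`` control replicate-samples are excluded.  With
    ``log_ratio`` the ANOVA runs on log(ria/(1-ria)) instead of RIA.

    Returns one row per included protein: accession, n_mixed,
    n_control, mean_mixed_ria, sd_mixed_ria, F, p, degenerate, fold.
    """
    df = protein_table[protein_table["sample_type"].isin(mixed_types + control_types)].copy()
    df["oriented"] = orient_values(
        df["ria"].to_numpy(), df["sample_type"].isin(reverse_types).to_numpy()
    )
    rows = []
    for acc, grp in df.groupby("accession", observed=True, sort=True):
        mixed = grp.loc[grp["sample_type"].isin(mixed_types), "oriented"].to_numpy()
        control = grp.loc[grp["sample_type"].isin(control_types), "oriented"].to_numpy()
        if mixed.size < min_mixed or control.size < min_control:
            continue
        if log_ratio:
            f, p = anova_protein(np.log(mixed / (1 - mixed)), np.log(control / (1 - control)))
        else:
            f, p = anova_protein(mixed, control)
        mean_mixed = float(mixed.mean())
        rows.append(
            {
                "accession": acc,
                "n_mixed": mixed.size,
                "n_control": control.size,
                "mean_mixed_ria": mean_mixed,
                "sd_mixed_ria": float(mixed.std(ddof=1)),
                "F": f,
                "p": p,
                "degenerate": p == SMALLEST_P,
                "fold": ria_to_fold(mean_mixed) if 0 < mean_mixed < 1 else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "n_mixed", "n_control", "mean_mixed_ria", "sd_mixed_ria",
            "F", "p", "degenerate", "fold",
        ],
    )


def call_significant(
    results: pd.DataFrame, alpha: float = 0.01, cutoff: CutoffResult | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the p-value and fold screens and summarize.

    pass_p: p < alpha.  pass_fold: mean mixed RIA outside the cutoff's
    [ria_low, ria_high] band (always False without a cutoff).  The
    direction follows the mean mixed RIA against 0.5.
    """
    out = results.copy()
    out["pass_p"] = out["p"] < alpha
    if cutoff is not None:
        out["pass_fold"] = (out["mean_mixed_ria"] < cutoff.ria_low) | (
            out["mean_mixed_ria"] > cutoff.ria_high
        )
    else:
        out["pass_fold"] = False
    out["direction"] = np.select(
        [out["mean_mixed_ria"] > 0.5, out["mean_mixed_ria"] < 0.5],
        ["up", "down"],
        default="unchanged",
    )
    sig = out[out["pass_p"]]
    summary = {
        "n_tested": int(len(out)),
        "n_significant": int(len(sig)),
        "n_up": int((sig["direction"] == "up").sum()),
        "n_down": int((sig["direction"] == "down").sum()),
        "n_pass_both_up": int(((sig["direction"] == "up") & sig["pass_fold"]).sum()),
        "n_pass_both_down": int(((sig["direction"] == "down") & sig["pass_fold"]).sum()),
        "alpha": alpha,
        "fold_cutoff": cutoff.fold_cutoff if cutoff is not None else None,
    }
    return out, summary
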