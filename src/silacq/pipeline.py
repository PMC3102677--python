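"""End-to-end composition of the quantification stages.

Detections -> features -> SILAC pairs -> labeled pairs -> AMT entries
(filtered, technical replicates merged) -> protein table (trimmed,
normalized) -> differential calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import amt_db, diff_stats, pair_quant, protein_quant
from .synthetic_data import CONTROL_TYPES, MIX_REV, MIXED_TYPES

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    pairs: pd.DataFrame
    labeled: pd.DataFrame
    entries: pd.DataFrame
    sample_obs: pd.DataFrame
    protein_table: pd.DataFrame
    protein_summary: pd.DataFrame
    results: pd.DataFrame
    summary: dict
    cutoff: diff_stats.CutoffResult | None
    filter_counts: dict
    norms: dict
    log: list = field(default_factory=list)


def run_pipeline(
    detections: pd.DataFrame,
    identifications: pd.DataFrame,
    manifest: pd.DataFrame,
    *,
    pair_params: pair_quant.PairParams | None = None,
    filter_params: amt_db.FilterParams | None = None,
    feature_ppm_tol: float = 5.0,
    max_scan_gap: int = 2,
    scan_interval: float = 2.0 / 60.0,
    id_ppm_tol: float = 5.0,
    id_rt_tol: float = 5.0,
    trim: bool = True,
    normalize: bool = True,
    alpha: float = 0.01,
    confidence: float = 0.99,
    min_mixed: int = 3,
    min_control: int = 3,
) -> PipelineResult:
    """Run the full quantification pipeline on one experiment's tables."""
    log: list = []
    features = pair_quant.build_features(
        detections, ppm_tol=feature_ppm_tol, max_scan_gap=max_scan_gap, scan_interval=scan_interval
    )
    pairs = pair_quant.match_pairs(features, pair_params)
    del features
    labeled = amt_db.attach_ids(pairs, identifications, ppm_tol=id_ppm_tol, rt_tol=id_rt_tol, log=log)
    entries, obs = amt_db.build_amt(labeled, manifest)
    entries, obs, filter_counts = amt_db.filter_amt(entries, obs, filter_params)
    sample_obs = amt_db.merge_technical(obs, manifest, log=log)

    acc = entries.set_index("entry_id")["accession"]
    sample_obs = sample_obs.assign(accession=sample_obs["entry_id"].map(acc))

    protein_table, norms = protein_quant.build_protein_table(
        sample_obs, trim=trim, normalize=normalize
    )
    protein_summary = protein_quant.average_biological(protein_table, mixed_types=MIXED_TYPES)

    cutoff = None
    control_pool = protein_table.loc[
        protein_table["sample_type"].isin(CONTROL_TYPES), "ria"
    ].to_numpy()
    if control_pool.size:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cutoff = diff_stats.control_cutoff(control_pool, confidence=confidence)

    results = diff_stats.differential_analysis(
        protein_table,
        mixed_types=MIXED_TYPES,
        reverse_types=(MIX_REV,),
        control_types=CONTROL_TYPES,
        min_mixed=min_mixed,
        min_control=min_control,
    )
    results, summary = diff_stats.call_significant(results, alpha=alpha, cutoff=cutoff)
    return PipelineResult(
        pairs=pairs,
        labeled=labeled,
        entries=entries,
        sample_obs=sample_obs,
        protein_table=protein_table,
        protein_summary=protein_summary,
        results=results,
        summary=summary,
        cutoff=cutoff,
        filter_counts=filter_counts,
        norms=norms,
        log=log,
    )
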