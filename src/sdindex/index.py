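"""The Stroke Dysbiosis Index (SDI) and median stratification.

For a sample with percent relative abundances, a signature with
stroke-enriched set S and control-enriched set C gives

    SDI = ( mean_{g in S} abundance_g  -  mean_{g in C} abundance_g ) x 100

Signature genera absent from the sample contribute 0 percent, and the
denominators are always |S| and |C| of the signature in use, so scores
stay comparable across cohorts scored with the same signature. Patients
are stratified at the median SDI: at or above the median is the high
(SDI-H) stratum, below is the low (SDI-L) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import RelAbundanceTable
from .signature import Signature

HIGH = "SDI-H"
LOW = "SDI-L"


@dataclass(frozen=True)
class SDIScoreSet:
    """Per-sample SDI values with the median threshold and strata."""

    sdi: pd.Series
    median_threshold: float
    stratum: pd.Series  # SDI-H / SDI-L per patient sample


def compute_sdi(sample, signature: Signature) -> float:
    """SDI of a single sample (mapping/Series of percent abundances)."""
    if not signature.stroke_enriched or not signature.control_enriched:
        raise ValueError("signature must be non-empty on both sides")
    get = sample.get if hasattr(sample, "get") else lambda g, d=0.0: d
    s_mean = sum(float(get(g, 0.0)) for g in signature.stroke_enriched)
    s_mean /= len(signature.stroke_enriched)
    c_mean = sum(float(get(g, 0.0)) for g in signature.control_enriched)
    c_mean /= len(signature.control_enriched)
    return (s_mean - c_mean) * 100.0


def compute_sdi_table(rel_table: RelAbundanceTable, signature: Signature) -> pd.Series:
    """Vectorised SDI for every sample of a relative-abundance table."""
    if not signature.stroke_enriched or not signature.control_enriched:
        raise ValueError("signature must be non-empty on both sides")
    df = rel_table.data
    s_cols = [g for g in signature.stroke_enriched if g in df.columns]
    c_cols = [g for g in signature.control_enriched if g in df.columns]
    s_sum = df[s_cols].sum(axis=1) if s_cols else pd.Series(0.0, index=df.index)
    c_sum = df[c_cols].sum(axis=1) if c_cols else pd.Series(0.0, index=df.index)
    sdi = (s_sum / len(signature.stroke_enriched)
           - c_sum / len(signature.control_enriched)) * 100.0
    sdi.name = "sdi"
    return sdi


def stratify_by_median(scores) -> tuple[float, pd.Series]:
    """Split patient scores at their median; ties go to the high stratum.

    Returns ``(threshold, strata)`` where stratum is ``SDI-H`` iff
    ``score >= threshold``. Raises on fewer than two patients or when all
    scores are identical (degenerate stratification).
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need >= 2 patients to stratify")
    if np.ptp(scores.to_numpy()) == 0:
        raise ValueError("degenerate stratification: all scores identical")
    threshold = float(scores.median())
    strata = pd.Series(np.where(scores >= threshold, HIGH, LOW), index=scores.index)
    strata.name = "stratum"
    return threshold, strata


def score_and_stratify(
    rel_table: RelAbundanceTable,
    signature: Signature,
    patient_ids,
    threshold: float | None = None,
) -> SDIScoreSet:
    """Score all samples and stratify the patient subset.

    ``threshold=None`` computes the patient median; passing a threshold
    applies a pre-fixed cut (e.g. scoring a validation cohort with the
    training median).
    """
    sdi = compute_sdi_table(rel_table, signature)
    patient_ids = [p for p in patient_ids if p in sdi.index]
    patient_scores = sdi.loc[patient_ids]
    if threshold is None:
        threshold, strata = stratify_by_median(patient_scores)
    else:
        strata = pd.Series(
            np.where(patient_scores >= threshold, HIGH, LOW), index=patient_scores.index
        )
        strata.name = "stratum"
    return SDIScoreSet(sdi=sdi, median_threshold=float(threshold), stratum=strata)
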