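"""Differential-genus testing and dysbiosis-signature assembly.

A signature is two disjoint, directed genus sets: genera enriched in the
case (stroke) group and genera enriched in the control group. Genera are
tested one at a time with the Mann-Whitney / Wilcoxon rank-sum test on
relative abundances and selected at a Benjamini-Hochberg FDR threshold
(0.1 by default). Direction is the group with the larger mean relative
abundance, so the signature is self-consistent with the index formula
that averages those abundances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import RelAbundanceTable

CASE = "stroke-enriched"
CONTROL = "control-enriched"


@dataclass(frozen=True)
class Signature:
    """Directed genus signature: case-enriched set S, control-enriched set C."""

    stroke_enriched: tuple[str, ...]
    control_enriched: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        overlap = set(self.stroke_enriched) & set(self.control_enriched)
        if overlap:
            raise ValueError(f"genera in both directions: {sorted(overlap)}")
        object.__setattr__(self, "stroke_enriched", tuple(self.stroke_enriched))
        object.__setattr__(self, "control_enriched", tuple(self.control_enriched))

    def __len__(self) -> int:
        return len(self.stroke_enriched) + len(self.control_enriched)

    def to_json(self, path) -> None:
        doc = {
            "stroke_enriched": list(self.stroke_enriched),
            "control_enriched": list(self.control_enriched),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            tuple(doc["stroke_enriched"]),
            tuple(doc["control_enriched"]),
            doc.get("provenance", {}),
        )


def load_preset_signature() -> Signature:
    """The published 18-genus stroke signature (7 stroke- and 11
    control-enriched genera) shipped with the package."""
    ref = resources.files("sdindex").joinpath("data/stroke_signature_18.json")
    with resources.as_file(ref) as path:
        return Signature.from_json(path)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both groups together hold <= 12
    observations with no ties, otherwise the tie-corrected normal
    approximation. Returns ``(U, p)``; degenerate input where every value
    is identical returns ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_signature(
    rel_table: RelAbundanceTable,
    labels,
    q_threshold: float = 0.1,
    case_label: str = "stroke",
    direction_stat: str = "mean",
) -> tuple[Signature, pd.DataFrame]:
    """Per-genus rank-sum test + BH-FDR; assemble the directed signature.

    Parameters
    ----------
    rel_table : RelAbundanceTable
        Percent relative abundances, preprocessed.
    labels : mapping or Series
        Group per sample id; exactly two distinct labels, one of which is
        ``case_label``.
    q_threshold : float
        Strict FDR cut: a genus enters the signature iff ``fdr_p < q``.
    direction_stat : {"mean", "median"}
        Group summary deciding enrichment direction.

    Returns
    -------
    (Signature, DataFrame)
        The signature and the full per-genus audit table with columns
        ``statistic, p_value, fdr_p, direction, mean_case, mean_control,
        selected``.
    """
    labels = pd.Series(labels)
    labels = labels.loc[rel_table.sample_ids]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    if case_label not in groups:
        raise ValueError(f"case label {case_label!r} not present")
    control_label = [g for g in groups if g != case_label][0]

    df = rel_table.data
    case_rows = df.loc[labels == case_label]
    ctrl_rows = df.loc[labels == control_label]
    summ = np.mean if direction_stat == "mean" else np.median

    records = []
    for genus in df.columns:
        u, p = rank_sum_test(case_rows[genus].to_numpy(), ctrl_rows[genus].to_numpy())
        mc, mn = summ(case_rows[genus]), summ(ctrl_rows[genus])
        if mc > mn:
            direction = CASE
        elif mn > mc:
            direction = CONTROL
        else:
            direction = "tied"
        records.append((genus, u, p, direction, float(mc), float(mn)))
    res = pd.DataFrame(
        records,
        columns=["genus", "statistic", "p_value", "direction", "mean_case", "mean_control"],
    ).set_index("genus")
    res["fdr_p"] = bh_fdr(res["p_value"].to_numpy())
    res["selected"] = res["fdr_p"] < q_threshold

    tied = res.index[res["selected"] & (res["direction"] == "tied")]
    if len(tied):
        warnings.warn(
            f"significant genera with equal group {direction_stat}s excluded: {list(tied)}"
        )
        res.loc[tied, "selected"] = False

    sig = Signature(
        tuple(res.index[res["selected"] & (res["direction"] == CASE)]),
        tuple(res.index[res["selected"] & (res["direction"] == CONTROL)]),
        provenance={
            "threshold": q_threshold,
            "test": "wilcoxon-rank-sum + BH-FDR",
            "direction_stat": direction_stat,
            "n_case": int(len(case_rows)),
            "n_control": int(len(ctrl_rows)),
        },
    )
    return sig, res[["statistic", "p_value", "fdr_p", "direction",
                     "mean_case", "mean_control", "selected"]]
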