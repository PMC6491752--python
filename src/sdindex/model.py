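"""Model/Results interface tying the pipeline together.

``StrokeDysbiosisIndex`` is constructed from a genus count table and a
case/control grouping; ``fit()`` runs the published recipe — filter taxa
below 0.1% of the grand total, rarefy to 4,800 reads, convert to percent
relative abundance, select the differential-genus signature at
FDR < 0.1, score every sample, and split patients at the median — and
returns an ``SDIResults`` carrying the signature, the per-genus test
audit, the scores and the discrimination diagnostics, with ``score()``
for applying the fitted signature to a held-out cohort and ``summary()``
for a printable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance as prep
from .abundance import AbundanceTable, RelAbundanceTable
from .clinical import RocResult, roc_auc, spearman
from .index import HIGH, LOW, SDIScoreSet, score_and_stratify
from .signature import Signature, rank_sum_test, select_signature


class StrokeDysbiosisIndex:
    """Case-control dysbiosis index model for genus-level 16S tables.

    Parameters
    ----------
    table : AbundanceTable
        Raw genus counts, samples x genera.
    groups : Series or mapping
        Group per sample id; two levels, ``case_label`` marks patients.
    min_count_fraction, rarefaction_depth :
        Preprocessing knobs (defaults 0.001 and 4,800, the published
        recipe).
    """

    def __init__(
        self,
        table: AbundanceTable,
        groups,
        case_label: str = "stroke",
        control_label: str = "control",
        min_count_fraction: float = 0.001,
        rarefaction_depth: int = 4800,
    ):
        self.table = table
        self.groups = pd.Series(groups).reindex(table.sample_ids)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        self.case_label = case_label
        self.control_label = control_label
        self.min_count_fraction = min_count_fraction
        self.rarefaction_depth = rarefaction_depth

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, metadata: pd.DataFrame, group_col: str = "group", **kw
    ) -> "StrokeDysbiosisIndex":
        """Build from a samples x genera counts frame and a metadata frame
        indexed by (or containing) ``sample_id``."""
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        return cls(AbundanceTable(counts), meta[group_col], **kw)

    def preprocess(self, seed: int = 0) -> RelAbundanceTable:
        """filter -> rarefy -> percent relative abundance."""
        return prep.preprocess(
            self.table, self.min_count_fraction, self.rarefaction_depth, seed
        )

    def fit(self, q_threshold: float = 0.1, seed: int = 0) -> "SDIResults":
        rel = self.preprocess(seed)
        labels = self.groups.loc[rel.sample_ids]
        signature, genus_tests = select_signature(
            rel, labels, q_threshold=q_threshold, case_label=self.case_label
        )
        patients = labels.index[labels == self.case_label]
        if signature.stroke_enriched and signature.control_enriched:
            scores = score_and_stratify(rel, signature, patients)
        else:
            # no usable index (e.g. a null cohort): keep the audit trail
            scores = None
        return SDIResults(
            model=self,
            signature=signature,
            genus_tests=genus_tests,
            rel_table=rel,
            scores=scores,
        )


@dataclass
class SDIResults:
    """Fitted signature, scores and diagnostics."""

    model: StrokeDysbiosisIndex
    signature: Signature
    genus_tests: pd.DataFrame
    rel_table: RelAbundanceTable
    scores: SDIScoreSet | None
    _cache: dict = field(default_factory=dict, repr=False)

    def _require_scores(self) -> SDIScoreSet:
        if self.scores is None:
            raise ValueError(
                "signature is empty on at least one side; no usable index"
            )
        return self.scores

    # -- convenience views -------------------------------------------------

    @property
    def labels(self) -> pd.Series:
        return self.model.groups.loc[self.rel_table.sample_ids]

    @property
    def case_scores(self) -> pd.Series:
        return self._require_scores().sdi[self.labels == self.model.case_label]

    @property
    def control_scores(self) -> pd.Series:
        return self._require_scores().sdi[self.labels == self.model.control_label]

    # -- diagnostics -------------------------------------------------------

    def roc(self) -> RocResult:
        """Case-vs-control discrimination of the index on this cohort."""
        y = (self.labels == self.model.case_label).astype(int)
        return roc_auc(self._require_scores().sdi.to_numpy(), y.to_numpy())

    def group_comparison(self) -> dict:
        """Median SDI per group plus the rank-sum comparison."""
        u, p = rank_sum_test(self.case_scores, self.control_scores)
        return {
            "median_case": float(self.case_scores.median()),
            "median_control": float(self.control_scores.median()),
            "U": u,
            "p_value": p,
        }

    def score(
        self, table: AbundanceTable, seed: int = 0, threshold: float | None = None
    ) -> SDIScoreSet:
        """Score a new cohort with the fitted signature.

        The new table goes through the same preprocessing; by default the
        new cohort is stratified at its own patient median — pass
        ``threshold=self.scores.median_threshold`` to reuse the training
        cut. Patients are all scored samples here; restrict afterwards if
        the new cohort mixes cases and controls.
        """
        rel = prep.preprocess(
            table, self.model.min_count_fraction, self.model.rarefaction_depth, seed
        )
        return score_and_stratify(rel, self.signature, rel.sample_ids, threshold)

    def spearman_with(self, clinical: pd.Series) -> tuple[float, float]:
        """Spearman correlation of patient SDI with a clinical score."""
        joined = pd.concat(
            [self.case_scores.rename("sdi"), clinical.rename("y")], axis=1, join="inner"
        ).dropna()
        return spearman(joined["sdi"], joined["y"])

    def summary(self) -> str:
        if self.scores is None:
            return (
                "Stroke Dysbiosis Index — fit summary\n" + "=" * 52
                + f"\nsignature: empty ({len(self.genus_tests)} genera tested,"
                " nothing passed the FDR threshold); no index computed"
            )
        comp = self.group_comparison()
        auc = self.roc().auc
        strata = self.scores.stratum
        lines = [
            "Stroke Dysbiosis Index — fit summary",
            "=" * 52,
            f"samples (post-rarefaction): {len(self.rel_table.sample_ids)}"
            f"  [{self.model.case_label}: {len(self.case_scores)},"
            f" {self.model.control_label}: {len(self.control_scores)}]",
            f"genera tested: {len(self.genus_tests)}",
            f"signature: {len(self.signature)} genera"
            f" ({len(self.signature.stroke_enriched)} case-enriched,"
            f" {len(self.signature.control_enriched)} control-enriched)",
            f"median SDI: {comp['median_case']:.2f} ({self.model.case_label})"
            f" vs {comp['median_control']:.2f} ({self.model.control_label}),"
            f" rank-sum p = {comp['p_value']:.3g}",
            f"ROC AUC (case vs control): {100 * auc:.1f}%",
            f"patient median threshold: {self.scores.median_threshold:.2f}"
            f"  ({HIGH}: {(strata == HIGH).sum()}, {LOW}: {(strata == LOW).sum()})",
        ]
        return "\n".join(lines)
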