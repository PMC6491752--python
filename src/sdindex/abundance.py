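"""Abundance-table containers, IO and preprocessing.

The preprocessing chain mirrors the standard QIIME-1 era workflow for
genus-level 16S tables: collapse OTUs to genus (with the ``Un <Family>``
fallback for taxa unclassified at genus rank), drop globally rare taxa,
rarefy every sample to a common depth, and convert to relative abundance
in percent.
"""

from __future__ import annotations

import json
import logging
import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column-0 headers that mark a taxa-rows x sample-columns TSV layout
_TAXON_HEADERS = ("#Genus", "#OTU ID", "#Taxon")


class AbundanceTableError(ValueError):
    """Malformed abundance table input."""


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa (genus labels). Values must be
        non-negative integers; row/column labels must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise AbundanceTableError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise AbundanceTableError(f"duplicate taxa: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=1e-9):
                raise AbundanceTableError("counts must be integer-valued")
            df = df.round().astype(np.int64)
            object.__setattr__(self, "data", df)
        if values.size and (df.to_numpy() < 0).any():
            raise AbundanceTableError("negative counts are not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    # -- IO --------------------------------------------------------------

    @classmethod
    def read(cls, path, format: str | None = None) -> "AbundanceTable":
        """Read a table from TSV or BIOM-style sparse JSON.

        The format is sniffed from the first byte when not given
        (``{`` means JSON). TSV orientation is auto-detected from the
        ``#Genus`` / ``#OTU ID`` header convention (taxa as rows).
        """
        if format is None:
            with open(path) as fh:
                first = fh.read(1)
            format = "biom-json" if first == "{" else "tsv"
        if format == "tsv":
            return cls._read_tsv(path)
        if format == "biom-json":
            return cls._read_biom_json(path)
        raise AbundanceTableError(f"unknown format: {format!r}")

    @classmethod
    def _read_tsv(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        header = str(df.index.name or "")
        if header in _TAXON_HEADERS or header.startswith("#"):
            df = df.T  # taxa were rows
        df.index.name = None
        df.columns.name = None
        return cls(df)

    @classmethod
    def _read_biom_json(cls, path) -> "AbundanceTable":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)), dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "sparse":
            for i, j, v in doc["data"]:
                if v != int(v):
                    raise AbundanceTableError("non-integer count in BIOM data")
                mat[int(i), int(j)] = int(v)
        else:
            mat[:] = np.asarray(doc["data"])
        df = pd.DataFrame(mat.T, index=samples, columns=taxa)
        return cls(df)

    def write_tsv(self, path) -> None:
        """Write taxa-rows x sample-columns TSV with a ``#Genus`` header."""
        out = self.data.T.rename_axis(index="#Genus")
        out.to_csv(path, sep="\t")

    def write_biom_json(self, path) -> None:
        """Write a minimal BIOM 1.0 style sparse-JSON document."""
        mat = self.data.T.to_numpy()
        rows, cols = np.nonzero(mat)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(self.taxa), len(self.sample_ids)],
            "rows": [{"id": t, "metadata": None} for t in self.taxa],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": [[int(i), int(j), int(mat[i, j])] for i, j in zip(rows, cols)],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass(frozen=True)
class RelAbundanceTable:
    """Samples x taxa matrix of relative abundances in percent (0-100)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if len(sums) and not np.allclose(sums, 100.0, atol=1e-6):
            raise AbundanceTableError("each sample must sum to 100 percent")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)


# -- preprocessing operations ---------------------------------------------

_RANK_RE = re.compile(r"\s*([a-z])__(.*?)\s*$")


def _parse_lineage(lineage: str) -> dict[str, str]:
    ranks: dict[str, str] = {}
    for field in lineage.split(";"):
        m = _RANK_RE.match(field)
        if m:
            ranks[m.group(1)] = m.group(2)
        else:
            field = field.strip()
            if field:
                ranks.setdefault("_plain", field)
    return ranks


def genus_label(lineage: str) -> str:
    """Genus label for a lineage string, ``Un <Family>`` when the genus is
    unclassified, ``Unassigned`` when family is missing too.

    Accepts greengenes-style ``k__...;f__Rikenellaceae;g__`` strings or
    plain ``Family;Genus`` fields.
    """
    ranks = _parse_lineage(lineage)
    genus = ranks.get("g", "")
    family = ranks.get("f", "")
    if genus:
        return genus
    if family:
        return f"Un {family}"
    return "Unassigned"


def collapse_to_genus(table: AbundanceTable, taxonomy: dict[str, str]) -> AbundanceTable:
    """Sum OTU counts into genus-level taxa.

    ``taxonomy`` maps each input taxon to its lineage string. Counts are
    conserved per sample; taxa unclassified at genus rank are pooled per
    family under ``Un <Family>``.
    """
    missing = [t for t in table.taxa if t not in taxonomy]
    if missing:
        raise AbundanceTableError(f"taxa without lineage: {missing}")
    labels = {t: genus_label(taxonomy[t]) for t in table.taxa}
    collapsed = table.data.T.groupby(table.data.columns.map(labels), sort=False).sum().T
    collapsed.columns.name = None
    return AbundanceTable(collapsed)


def filter_low_abundance(
    table: AbundanceTable, min_count_fraction: float = 0.001
) -> AbundanceTable:
    """Drop taxa whose total count is below a fraction of the grand total.

    A taxon is retained iff ``sum_over_samples(count) >=
    min_count_fraction * grand_total`` (threshold inclusive) — the
    whole-table semantics of the classic QIIME-1 OTU filter. Samples are
    never removed here.
    """
    if not 0 <= min_count_fraction < 1:
        raise ValueError("min_count_fraction must be in [0, 1)")
    totals = table.data.sum(axis=0)
    threshold = min_count_fraction * float(totals.sum())
    keep = totals[totals >= threshold].index
    return AbundanceTable(table.data.loc[:, keep])


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stream keyed on (seed, sample id) so sample order never matters
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(sample_id).encode())])
    )


def rarefy(table: AbundanceTable, depth: int = 4800, seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to a common depth.

    Samples with fewer than ``depth`` total counts are dropped and logged.
    Deterministic given ``seed``; each sample draws from an independent
    stream derived from ``(seed, sample_id)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    if not len(keep):
        raise AbundanceTableError("no samples survive rarefaction")
    rows = {}
    for sid in keep:
        counts = table.data.loc[sid].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows[sid] = counts
        else:
            rng = _sample_rng(seed, sid)
            rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    out.columns = table.data.columns
    return AbundanceTable(out)


def to_relative(table: AbundanceTable) -> RelAbundanceTable:
    """Convert counts to relative abundance in percent (rows sum to 100)."""
    totals = table.sample_totals
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise AbundanceTableError(f"zero-total sample(s): {bad}")
    rel = 100.0 * table.data.div(totals, axis=0)
    return RelAbundanceTable(rel)


def preprocess(
    table: AbundanceTable,
    min_count_fraction: float = 0.001,
    depth: int = 4800,
    seed: int = 0,
) -> RelAbundanceTable:
    """filter -> rarefy -> percent relative abundance, in that order."""
    return to_relative(rarefy(filter_low_abundance(table, min_count_fraction), depth, seed))
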