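"""Community-level beta-diversity analyses.

Unweighted UniFrac distances against a genus-level tree, classical PCoA,
a seeded PERMANOVA (Adonis) with the +1-smoothed permutation p-value, and
the stratified distance-to-control comparison used to ask whether
low-index patients sit closer to healthy controls than high-index
patients do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .abundance import AbundanceTable
from .signature import rank_sum_test


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def unweighted_unifrac(tree: TreeNode, table: AbundanceTable) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between all samples.

    Presence is count > 0; distance = branch length unique to either
    sample's leaf set divided by branch length in the union. Every table
    taxon must be a leaf of ``tree`` (extra leaves are allowed).
    """
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in table.taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    return beta_diversity(
        "unweighted_unifrac",
        table.data.to_numpy(),
        ids=table.sample_ids,
        taxa=table.taxa,
        tree=tree,
    )


def pcoa(dist: DistanceMatrix, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers the squared-distance (Gower) matrix and
    eigendecomposes it. Returns ``(coordinates, eigenvalues)``: all
    eigenvalues are reported (negative ones flag non-Euclidean input) but
    only axes with positive eigenvalue carry coordinates; ``k`` caps the
    number of returned axes.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(dist)  # validates symmetry / zero diagonal
    n = dist.shape[0]
    if k is not None and k > n - 1:
        raise ValueError("k must be <= n - 1")
    res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    coords = res.samples
    pos = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = coords.loc[:, pos]
    if k is not None:
        coords = coords.iloc[:, :k]
    coords.index = list(dist.ids)
    return coords, eigvals


def _group_ss(sq: np.ndarray, idx: np.ndarray) -> float:
    sub = sq[np.ix_(idx, idx)]
    return sub.sum() / (2.0 * len(idx))


def _pseudo_f(sq: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = sq.shape[0]
    ss_total = sq.sum() / (2.0 * n)
    ss_within = sum(
        _group_ss(sq, np.flatnonzero(codes == g)) for g in range(n_groups)
    )
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA (Adonis): permutation test of group location on a
    distance matrix.

    pseudo-F comes from the within/between squared-distance
    decomposition; ``p = (#{permuted F >= observed} + 1) /
    (n_permutations + 1)``. Deterministic given ``seed``.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(dist)
    labels = pd.Series(labels)
    if set(labels.index) >= set(dist.ids):
        labels = labels.loc[list(dist.ids)]
    codes, uniques = pd.factorize(labels.to_numpy())
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [uniques[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    sq = dist.data ** 2
    f_obs, r2 = _pseudo_f(sq, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _pseudo_f(sq, rng.permutation(codes), n_groups)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)


def distances_to_reference(
    dist: DistanceMatrix,
    strata,
    reference,
) -> dict:
    """Patient-to-control distance samples per stratum plus a rank-sum
    comparison between the two strata's distance distributions.

    ``strata`` maps patient sample ids to their stratum label (two
    strata); ``reference`` is the control sample-id set, disjoint from
    the patients. Returns ``{stratum: distances, "U": U, "p_value": p}``.
    """
    strata = pd.Series(strata)
    reference = list(reference)
    if set(strata.index) & set(reference):
        raise ValueError("strata and reference sets must be disjoint")
    names = list(strata.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two strata, got {names}")
    df = dist.to_data_frame()
    out: dict = {}
    for name in names:
        ids = list(strata.index[strata == name])
        if not ids:
            raise ValueError(f"empty stratum: {name}")
        out[name] = df.loc[ids, reference].to_numpy().ravel()
    u, p = rank_sum_test(out[names[0]], out[names[1]])
    out["U"], out["p_value"] = u, p
    return out
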