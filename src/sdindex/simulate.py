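"""Synthetic case-control microbiome cohorts with known ground truth.

The generator emulates what a genus-collapsed 16S study of acute stroke
patients versus healthy controls yields: a samples x genera count table
drawn from a Dirichlet-multinomial (so replicate samples are
overdispersed relative to a plain multinomial, which rank tests must
cope with), a planted directional signature whose genera are shifted up
in cases or down in cases on the log2 scale, per-sample sequencing
depths drawn uniformly over a range, and clinical metadata whose
severity (NIHSS on admission) and discharge outcome (mRS) are noisy
monotone functions of each patient's true dysbiosis index.

Defaults reproduce the study's design: a 104-patient / 90-control
training cohort (83/70 for validation), 18 planted differential genera
(7 up in cases, 11 up in controls) and clinical correlations with the
true index in the weak-to-moderate range seen in practice (Spearman
r ~ 0.2-0.45).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .abundance import AbundanceTable
from .index import compute_sdi_table
from .abundance import RelAbundanceTable
from .signature import Signature, load_preset_signature

#: fixed proportional-odds cutpoints on the latent outcome scale mapping
#: to mRS 0..6; chosen so roughly a quarter of patients land above mRS 2
_MRS_CUTPOINTS = np.array([-2.2, -0.8, 1.1, 2.2, 3.4, 4.6])

#: NIHSS intercept (median mild stroke around 4) on the admission scale
_NIHSS_INTERCEPT = 4.0


@dataclass(frozen=True)
class ClinicalLink:
    """Strength of the coupling between the true index and the clinic.

    ``beta_severity`` is NIHSS points per SD of true SDI;
    ``beta_outcome`` is the log-odds slope of the latent mRS scale per SD
    of true SDI; ``noise_sd`` is the NIHSS noise SD in points.
    """

    beta_severity: float = 1.0
    beta_outcome: float = 0.7
    noise_sd: float = 3.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic case-control cohort."""

    n_cases: int = 104
    n_controls: int = 90
    n_genera: int = 60
    planted_signature: Signature | None = None  # default: packaged 7+11 preset
    effect_log2fc: float = 1.5
    base_concentration: np.ndarray | None = None  # default: log-normal draw
    sequencing_depth_range: tuple[int, int] = (6000, 12000)
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    seed: int = 0
    #: seed for the population-level draws (base genus concentrations);
    #: defaults to ``seed``. A validation cohort shares the training
    #: cohort's population_seed so both sample the same population.
    population_seed: int | None = None

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        lo, hi = self.sequencing_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid sequencing depth range")
        sig = self.signature
        if len(sig) > self.n_genera:
            raise ValueError("n_genera must cover the planted signature (>= 18 for the preset)")
        if self.base_concentration is not None:
            conc = np.asarray(self.base_concentration, dtype=float)
            if len(conc) != self.n_genera or (conc <= 0).any():
                raise ValueError("base_concentration must be positive, length n_genera")

    @property
    def signature(self) -> Signature:
        return self.planted_signature or load_preset_signature()


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: count table, clinical metadata, and truth."""

    table: AbundanceTable
    clinical: pd.DataFrame  # one row per sample, indexed by sample_id
    truth: dict  # {"true_sdi": Series, "planted_signature": Signature}


def _genus_names(spec: CohortSpec) -> list[str]:
    sig = spec.signature
    names = list(sig.stroke_enriched) + list(sig.control_enriched)
    names += [f"Genus{i:03d}" for i in range(1, spec.n_genera - len(names) + 1)]
    return names


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; byte-identical given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sig = spec.signature
    names = _genus_names(spec)
    n_genera = len(names)
    n = spec.n_cases + spec.n_controls

    if spec.base_concentration is not None:
        base = np.asarray(spec.base_concentration, dtype=float)
    else:
        # log-normal prior: a fat tail of rare genera exercises the
        # low-abundance filter downstream. Drawn from the population
        # seed so cohorts sampled from one population share it.
        pop_seed = spec.seed if spec.population_seed is None else spec.population_seed
        pop_rng = np.random.default_rng(np.random.SeedSequence([int(pop_seed), 0xBA5E]))
        base = pop_rng.lognormal(mean=0.0, sigma=1.6, size=n_genera)
        base = np.maximum(base, 1e-3)
    s_idx = [names.index(g) for g in sig.stroke_enriched]
    c_idx = [names.index(g) for g in sig.control_enriched]
    # keep planted genera common enough to survive filtering
    base[s_idx] = np.maximum(base[s_idx], 0.5)
    base[c_idx] = np.maximum(base[c_idx], 0.5)

    fold = 2.0 ** float(spec.effect_log2fc)
    alpha_case = base.copy()
    alpha_case[s_idx] *= fold
    alpha_case[c_idx] /= fold

    sample_ids = [f"P{i:03d}" for i in range(1, spec.n_cases + 1)] + \
                 [f"C{i:03d}" for i in range(1, spec.n_controls + 1)]
    groups = np.array(["stroke"] * spec.n_cases + ["control"] * spec.n_controls)

    lo, hi = spec.sequencing_depth_range
    depths = rng.integers(lo, hi + 1, size=n)
    props = np.empty((n, n_genera))
    counts = np.empty((n, n_genera), dtype=np.int64)
    for i in range(n):
        alpha = alpha_case if groups[i] == "stroke" else base
        props[i] = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], props[i])
    table = AbundanceTable(pd.DataFrame(counts, index=sample_ids, columns=names))

    # true SDI from the latent Dirichlet proportions (in percent units)
    rel = RelAbundanceTable(pd.DataFrame(100.0 * props, index=sample_ids, columns=names))
    true_sdi = compute_sdi_table(rel, sig)

    clinical = _draw_clinical(rng, sample_ids, groups, true_sdi, spec.clinical_link)
    return SyntheticCohort(
        table=table,
        clinical=clinical,
        truth={"true_sdi": true_sdi, "planted_signature": sig},
    )


def _draw_clinical(
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: np.ndarray,
    true_sdi: pd.Series,
    link: ClinicalLink,
) -> pd.DataFrame:
    n = len(sample_ids)
    case = groups == "stroke"
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    df["group"] = groups

    # cases skew slightly older / more comorbid, as in real cohorts
    df["age"] = np.round(
        np.where(case, rng.normal(59, 12, n), rng.normal(56, 8, n))
    ).clip(18, 80).astype(int)
    df["sex"] = (rng.random(n) < 0.77).astype(int)  # 1 = male
    df["hypertension"] = (rng.random(n) < np.where(case, 0.79, 0.28)).astype(int)
    df["diabetes"] = (rng.random(n) < np.where(case, 0.44, 0.05)).astype(int)
    df["cad"] = (rng.random(n) < np.where(case, 0.04, 0.01)).astype(int)
    df["smoking"] = (rng.random(n) < 0.35).astype(int)
    df["alcohol"] = (rng.random(n) < 0.20).astype(int)

    z = np.zeros(n)
    sdi_cases = true_sdi.to_numpy()[case]
    if case.sum() > 1 and np.std(sdi_cases) > 0:
        z[case] = (sdi_cases - sdi_cases.mean()) / sdi_cases.std()

    # labs: WBC weakly tracks severity; others are background covariates
    df["wbc"] = np.round(rng.normal(np.where(case, 7.9, 6.6), 1.6, n)
                         + 0.4 * z, 2).clip(2, 25)
    df["glucose"] = np.round(rng.normal(np.where(case, 6.0, 4.9), 1.4, n), 2).clip(3, 25)
    df["cr"] = np.round(rng.normal(np.where(case, 77, 73), 15, n), 1).clip(30, 300)
    df["ua"] = np.round(rng.normal(np.where(case, 357, 387), 80, n), 1).clip(100, 800)
    df["tg"] = np.round(rng.lognormal(0.35, 0.4, n), 2)
    df["tc"] = np.round(rng.normal(np.where(case, 4.6, 5.0), 1.0, n), 2).clip(2, 10)
    df["hdl"] = np.round(rng.normal(np.where(case, 0.91, 1.14), 0.25, n), 2).clip(0.3, 3)
    df["ldl"] = np.round(rng.normal(np.where(case, 3.0, 3.3), 0.8, n), 2).clip(0.5, 8)
    df["hba1c"] = np.round(rng.normal(np.where(case, 6.3, 5.5), 1.0, n), 1).clip(4, 14)

    nihss = np.round(
        _NIHSS_INTERCEPT + link.beta_severity * z + rng.normal(0, link.noise_sd, n)
    ).clip(0, 42)
    latent = link.beta_outcome * z + rng.logistic(0, 1, n)
    mrs = (latent[:, None] > _MRS_CUTPOINTS[None, :]).sum(axis=1)
    recovery = np.round(rng.normal(1.5, 1.5, n)).clip(0, None)

    df["nihss_in"] = np.where(case, nihss, np.nan)
    df["nihss_out"] = np.where(case, np.clip(nihss - recovery, 0, 42), np.nan)
    df["mrs_out"] = np.where(case, mrs, np.nan)
    return df


def generate_genus_tree(genus_names, seed: int = 0) -> TreeNode:
    """Random rooted bifurcating tree over the genus names.

    Built by repeated random pairwise joins with exponential branch
    lengths; deterministic given ``seed``. A tree over n genera has
    exactly n leaves and n-1 internal nodes.
    """
    genus_names = list(genus_names)
    if len(genus_names) < 2:
        raise ValueError("need at least 2 genus names")
    if len(set(genus_names)) != len(genus_names):
        raise ValueError("duplicate genus names")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(";".join(genus_names).encode())])
    )
    nodes = []
    for name in genus_names:
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(0.2) + 0.01)
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.2) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def write_cohort(cohort: SyntheticCohort, outdir, tree: TreeNode | None = None) -> None:
    """Write table (TSV + BIOM-style JSON), metadata TSV and tree Newick."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.table.write_tsv(outdir / "table.tsv")
    cohort.table.write_biom_json(outdir / "table.biom.json")
    meta = cohort.clinical.reset_index()
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth = cohort.truth["true_sdi"].rename("true_sdi").reset_index()
    truth.columns = ["sample_id", "true_sdi"]
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if tree is not None:
        tree.write(str(outdir / "tree.nwk"))


def validation_spec(spec: CohortSpec, seed_offset: int = 1) -> CohortSpec:
    """An 83/70 validation-cohort spec drawn from the same population
    (shared base concentrations) with fresh subjects."""
    pop = spec.seed if spec.population_seed is None else spec.population_seed
    return replace(spec, n_cases=83, n_controls=70,
                   seed=spec.seed + seed_offset, population_seed=pop)
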