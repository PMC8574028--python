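"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a paired control/treatment RNA-seq study across many
genotypes: a handful of *modules* of co-regulated genes respond coherently
to treatment, some genes belong to more than one module, and a few modules
causally drive each phenotypic trait.

The signal is planted on the log-fold-change scale — the quantity the
pipeline actually networks on — not on raw expression:

1.  every module u gets an *activity* vector over genotypes, a_u ~ N(0, 1);
2.  a member gene's true LFC row is loading · a_u (summed over its modules)
    plus N(0, gene_noise_sd) noise; background genes are pure noise;
3.  control means are log-normal per gene with additional per-genotype
    expression variability (2^N(0, genotype_expr_sd), emulating natural
    expression variation across a diversity panel; it cancels in the
    treatment/control ratio); treatment means are control · 2^LFC; observed
    counts are negative-binomial around the mean times a per-sample scale
    factor (library size / composition bias);
4.  each trait's log2 response is the sum of its causal modules' activities
    plus N(0, trait_noise_sd), emitted as a control/treatment value pair
    whose log2 ratio is exactly that response.

Everything is reproducible from the config seed, and the generator returns
the ground truth (memberships, causal map, scale factors, true LFC) so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, PhenotypeTable, SampleSheet
from .association import SelectionResult
from .hlc import AffiliationMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters for the generator.

    Defaults describe a desk-scale analogue of a diversity-panel salt-stress
    experiment: 1,000 genes, 40 genotypes with 2 replicates per condition,
    3 traits, and 8 planted modules of 8–15 genes with 30% of module genes
    joining a second module.
    """

    n_genes: int = 1000
    m_genotypes: int = 40
    r_replicates: int = 2
    n_modules: int = 8
    module_size_range: tuple[int, int] = (8, 15)
    overlap_prob: float = 0.3
    module_effect_sd: float = 1.0
    gene_noise_sd: float = 0.25
    nb_dispersion: float = 0.02
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    genotype_expr_sd: float = 0.6
    sample_scale_factor_range: tuple[float, float] = (0.7, 1.4)
    causal_modules_per_trait: int = 2
    trait_noise_sd: float = 0.3
    n_traits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_prob <= 1:
            raise ValueError("overlap_prob must lie in [0, 1]")
        positive = {
            "n_genes": self.n_genes,
            "m_genotypes": self.m_genotypes,
            "r_replicates": self.r_replicates,
            "n_modules": self.n_modules,
            "n_traits": self.n_traits,
            "module_effect_sd": self.module_effect_sd,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.module_size_range[0] < 2 or self.module_size_range[1] < self.module_size_range[0]:
            raise ValueError("module_size_range must be (lo, hi) with 2 <= lo <= hi")
        if self.n_modules * self.module_size_range[1] > self.n_genes:
            raise ValueError("module sizes exceed the gene pool")
        if self.causal_modules_per_trait > self.n_modules:
            raise ValueError("causal_modules_per_trait exceeds n_modules")


@dataclass(frozen=True)
class GroundTruth:
    memberships: dict[str, list[int]]  # gene -> planted module indices
    module_genes: list[list[str]]  # per planted module, its member genes
    causal_map: dict[str, list[int]]  # trait -> causal module indices
    scale_factors: np.ndarray  # per sample, true library scale
    true_lfc: pd.DataFrame  # genes × genotypes
    activities: np.ndarray = field(repr=False, default=None)  # modules × genotypes


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate(config: SyntheticConfig) -> tuple[CountMatrix, SampleSheet, PhenotypeTable, GroundTruth]:
    """Draw one synthetic study (counts, sheet, phenotypes, ground truth)."""
    rng = np.random.default_rng(config.seed)
    n, m, r = config.n_genes, config.m_genotypes, config.r_replicates
    width = len(str(n))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(n)]
    genotype_ids = [f"G{str(j + 1).zfill(len(str(m)))}" for j in range(m)]

    # module activities and memberships
    activities = rng.standard_normal((config.n_modules, m))
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    module_genes: list[list[str]] = []
    memberships: dict[str, list[int]] = {}
    cursor = 0
    for u, size in enumerate(sizes):
        members = list(range(cursor, cursor + int(size)))
        cursor += int(size)
        module_genes.append([gene_ids[i] for i in members])
        for i in members:
            memberships.setdefault(gene_ids[i], []).append(u)
    # overlap: a module gene may also join one other module
    if config.n_modules > 1:
        for u, genes in enumerate(list(module_genes)):
            for g in list(genes):
                if rng.random() < config.overlap_prob:
                    other = int(rng.integers(0, config.n_modules - 1))
                    if other >= u:
                        other += 1
                    if other not in memberships[g]:
                        memberships[g].append(other)
                        module_genes[other].append(g)
    module_genes = [sorted(genes) for genes in module_genes]

    # true LFC rows
    true_lfc = rng.normal(0.0, config.gene_noise_sd, size=(n, m))
    for g, mods in memberships.items():
        i = gene_ids.index(g)
        for u in mods:
            loading = config.module_effect_sd * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
            true_lfc[i] += loading * activities[u]

    # sample sheet: control block then treatment block, genotype order preserved
    records = []
    for cond in ("control", "treatment"):
        for g in genotype_ids:
            for rep in range(1, r + 1):
                records.append(
                    {
                        "sample": f"{g}_{cond}_r{rep}",
                        "genotype": g,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(records))

    # counts
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    # natural per-genotype expression variation; cancels in the LFC ratio
    genotype_expr = np.power(2.0, rng.normal(0.0, config.genotype_expr_sd, size=(n, m)))
    sf_lo, sf_hi = config.sample_scale_factor_range
    scale = rng.uniform(sf_lo, sf_hi, size=len(sheet.sample_ids))
    sample_pos = {s: k for k, s in enumerate(sheet.sample_ids)}
    counts = np.zeros((n, len(sheet.sample_ids)), dtype=np.int64)
    for j, g in enumerate(genotype_ids):
        control_mean = base * genotype_expr[:, j]
        treatment_mean = control_mean * np.power(2.0, true_lfc[:, j])
        for cond, mean in (("control", control_mean), ("treatment", treatment_mean)):
            for s in sheet.samples_for(g, cond):
                k = sample_pos[s]
                counts[:, k] = _negative_binomial(rng, mean * scale[k], config.nb_dispersion)
    count_matrix = CountMatrix(gene_ids=gene_ids, samples=sheet, values=counts)

    # traits
    trait_names = [f"trait{t + 1}" for t in range(config.n_traits)]
    causal_map: dict[str, list[int]] = {}
    control_vals = np.zeros((m, config.n_traits))
    treatment_vals = np.zeros((m, config.n_traits))
    for t, trait in enumerate(trait_names):
        causal = sorted(
            rng.choice(config.n_modules, size=config.causal_modules_per_trait, replace=False).tolist()
        )
        causal_map[trait] = causal
        z = activities[causal].sum(axis=0) + rng.normal(0.0, config.trait_noise_sd, size=m)
        baseline = 10.0 * (t + 1)
        control_vals[:, t] = baseline
        treatment_vals[:, t] = baseline * np.power(2.0, z)
    phenotypes = PhenotypeTable(
        genotype_ids=genotype_ids,
        trait_names=trait_names,
        control_values=control_vals,
        treatment_values=treatment_vals,
    )

    truth = GroundTruth(
        memberships={g: sorted(mods) for g, mods in memberships.items()},
        module_genes=module_genes,
        causal_map=causal_map,
        scale_factors=scale,
        true_lfc=pd.DataFrame(true_lfc, index=gene_ids, columns=genotype_ids),
        activities=activities,
    )
    return count_matrix, sheet, phenotypes, truth


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union) if union else 0.0


@dataclass(frozen=True)
class RecoveryScore:
    module_jaccards: list[float]  # per planted module, best-match vs detected
    mean_module_jaccard: float
    causal_gene_jaccard_per_trait: dict[str, float]
    mean_causal_gene_jaccard: float
    overlap_detection_rate: float


def score_recovery(
    truth: GroundTruth, f: AffiliationMatrix, selection: SelectionResult | None = None
) -> RecoveryScore:
    """Score detected modules and trait selections against the ground truth.

    * per planted module: the best Jaccard between its gene set and any
      detected module's gene set;
    * per trait: the Jaccard between the union of genes of the planted
      causal modules and the union of genes of the selected modules;
    * overlap detection: fraction of truly multi-module genes detected with
      at least two memberships.
    """
    detected = [set(genes) for genes in f.module_genes.values()]
    module_jaccards = []
    for genes in truth.module_genes:
        planted = set(genes)
        best = max((_jaccard(planted, d) for d in detected), default=0.0)
        module_jaccards.append(best)
    mean_module = float(np.mean(module_jaccards)) if module_jaccards else 0.0

    causal_per_trait: dict[str, float] = {}
    if selection is not None:
        for trait, causal in truth.causal_map.items():
            planted_genes = {g for u in causal for g in truth.module_genes[u]}
            selected_mods = selection.modules_per_trait.get(trait, [])
            selected_genes = {g for mod in selected_mods for g in f.module_genes[mod]}
            causal_per_trait[trait] = _jaccard(planted_genes, selected_genes)
    mean_causal = float(np.mean(list(causal_per_trait.values()))) if causal_per_trait else 0.0

    multi = [g for g, mods in truth.memberships.items() if len(mods) > 1]
    if multi:
        per_gene = {g: 0 for g in multi}
        gene_pos = {g: i for i, g in enumerate(f.gene_ids)}
        counts = np.asarray(f.values).sum(axis=1)
        for g in multi:
            if g in gene_pos:
                per_gene[g] = int(counts[gene_pos[g]])
        overlap_rate = float(np.mean([per_gene[g] >= 2 for g in multi]))
    else:
        overlap_rate = 0.0

    return RecoveryScore(
        module_jaccards=module_jaccards,
        mean_module_jaccard=mean_module,
        causal_gene_jaccard_per_trait=causal_per_trait,
        mean_causal_gene_jaccard=mean_causal,
        overlap_detection_rate=overlap_rate,
    )
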