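"""Stage (A): count normalization, replicate averaging, filtering, log fold changes.

The normalization is the median-of-ratios method: each sample's size factor is
the median, over reference genes, of that sample's counts divided by the
gene's geometric mean across all samples.  Reference genes are those with a
strictly positive geometric mean, i.e. genes with no zero count in any sample.
This corrects both library size and RNA composition bias.

Expression changes are summarised per genotype as log2 fold changes
``l_ij = log2((t_ij + pc) / (c_ij + pc))`` of averaged, normalized treatment
over control values, with a pseudocount ``pc`` guarding against zeros.
Phenotype changes are the analogous per-trait log2 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .data import (
    CONTROL,
    TREATMENT,
    CountMatrix,
    LfcMatrix,
    NormalizedMatrix,
    PhenoLfcTable,
    PhenotypeTable,
)


class LfcFilterMode(str, Enum):
    """Direction of the LFC inter-quartile-range filter.

    ``remove_low_variance`` drops genes whose LFC IQR is at or below the
    threshold (genes that barely respond to treatment carry no co-expression
    signal).  ``remove_high_variance`` drops genes above the threshold
    instead; both directions are provided because either reading of the
    filter is defensible, and the choice materially changes the gene pool.
    """

    REMOVE_LOW_VARIANCE = "remove_low_variance"
    REMOVE_HIGH_VARIANCE = "remove_high_variance"


@dataclass(frozen=True)
class FilterParams:
    """Gene-filter thresholds for stages (A).

    quantile_ratio_max: genes with Q75/Q25 below this are low-variance → removed.
    low_expr_value / low_expr_frac: genes with more than ``low_expr_frac`` of
        columns below ``low_expr_value`` are low-expression → removed.
    lfc_iqr_threshold: IQR threshold for the LFC filter.
    pseudocount: added to both numerator and denominator of every log ratio.
    """

    quantile_ratio_max: float = 1.5
    low_expr_value: float = 10.0
    low_expr_frac: float = 0.8
    lfc_iqr_threshold: float = 0.25
    lfc_filter_mode: LfcFilterMode = LfcFilterMode.REMOVE_LOW_VARIANCE
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.quantile_ratio_max <= 0 or self.lfc_iqr_threshold <= 0:
            raise ValueError("filter thresholds must be positive")
        if not 0 < self.low_expr_frac <= 1:
            raise ValueError("low_expr_frac must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        # accept plain strings for the mode
        object.__setattr__(self, "lfc_filter_mode", LfcFilterMode(self.lfc_filter_mode))


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factor per sample.

    Raises if no gene is nonzero in every sample (no reference gene exists).
    """
    v = np.asarray(counts.values, dtype=float)
    reference = (v > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; median-of-ratios "
            "normalization needs at least one such reference gene (consider a "
            "pseudocount or different input)"
        )
    logs = np.log(v[reference])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return factors


def normalize_and_average(counts: CountMatrix, sf: np.ndarray) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Divide each column by its size factor (D1), then average replicates (D2).

    D2 columns are ordered all control genotypes first, then all treatment
    genotypes, preserving genotype order.
    """
    sf = np.asarray(sf, dtype=float)
    if (sf <= 0).any() or not np.isfinite(sf).all():
        raise ValueError("size factors must be strictly positive and finite")
    d1_values = np.asarray(counts.values, dtype=float) / sf[np.newaxis, :]
    sheet = counts.samples
    d1 = NormalizedMatrix(
        gene_ids=counts.gene_ids,
        columns=sheet.sample_ids,
        values=d1_values,
        averaged=False,
    )
    sample_pos = {s: k for k, s in enumerate(sheet.sample_ids)}
    genotypes = sheet.genotypes
    blocks = []
    labels = []
    for cond in (CONTROL, TREATMENT):
        for g in genotypes:
            cols = [sample_pos[s] for s in sheet.samples_for(g, cond)]
            blocks.append(d1_values[:, cols].mean(axis=1))
            labels.append(f"{g}|{cond}")
    d2 = NormalizedMatrix(
        gene_ids=counts.gene_ids,
        columns=labels,
        values=np.column_stack(blocks),
        averaged=True,
        genotypes=genotypes,
    )
    return d1, d2


def _quartiles(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q25 = np.percentile(rows, 25, axis=1)
    q75 = np.percentile(rows, 75, axis=1)
    return q25, q75


def filter_expression(d2: NormalizedMatrix, params: FilterParams) -> NormalizedMatrix:
    """Drop low-variance and low-expression genes from the averaged matrix.

    Low variance: Q75/Q25 < ``quantile_ratio_max`` (Q25 = 0 with Q75 > 0 is an
    infinite ratio, so such genes pass this rule).  Low expression: strictly
    more than ``low_expr_frac`` of the columns below ``low_expr_value``.
    """
    v = np.asarray(d2.values, dtype=float)
    if v.shape[0] == 0:
        raise ValueError("cannot filter an empty expression matrix")
    q25, q75 = _quartiles(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q25 > 0, q75 / np.where(q25 > 0, q25, 1.0), np.where(q75 > 0, np.inf, 1.0))
    low_variance = ratio < params.quantile_ratio_max
    frac_low = (v < params.low_expr_value).mean(axis=1)
    low_expression = frac_low > params.low_expr_frac
    keep = ~(low_variance | low_expression)
    if not keep.any():
        raise ValueError(
            "expression filtering removed every gene; relax quantile_ratio_max "
            "or the low-expression thresholds"
        )
    return NormalizedMatrix(
        gene_ids=[g for g, k in zip(d2.gene_ids, keep) if k],
        columns=d2.columns,
        values=v[keep],
        averaged=d2.averaged,
        genotypes=d2.genotypes,
    )


def lfc_expression(d2_filtered: NormalizedMatrix, pseudocount: float = 1.0) -> LfcMatrix:
    """Genes × genotypes log2 fold change of treatment over control."""
    c = d2_filtered.condition_block(CONTROL)
    t = d2_filtered.condition_block(TREATMENT)
    values = np.log2((t + pseudocount) / (c + pseudocount))
    return LfcMatrix(
        gene_ids=d2_filtered.gene_ids,
        genotype_ids=list(d2_filtered.genotypes),
        values=values,
    )


def filter_lfc(l0: LfcMatrix, params: FilterParams) -> LfcMatrix:
    """IQR filter on LFC rows, in the direction given by ``lfc_filter_mode``."""
    v = np.asarray(l0.values, dtype=float)
    if v.shape[0] == 0:
        raise ValueError("cannot filter an empty LFC matrix")
    q25, q75 = _quartiles(v)
    iqr = q75 - q25
    if params.lfc_filter_mode is LfcFilterMode.REMOVE_LOW_VARIANCE:
        keep = iqr > params.lfc_iqr_threshold
    else:
        keep = iqr <= params.lfc_iqr_threshold
    if not keep.any():
        raise ValueError(
            "LFC filtering removed every gene; adjust lfc_iqr_threshold or the filter mode"
        )
    return LfcMatrix(
        gene_ids=[g for g, k in zip(l0.gene_ids, keep) if k],
        genotype_ids=l0.genotype_ids,
        values=v[keep],
    )


def lfc_phenotypes(pheno: PhenotypeTable, pseudocount: float = 0.0) -> PhenoLfcTable:
    """Per-genotype, per-trait log2 ratio of treatment to control phenotype values."""
    c = np.asarray(pheno.control_values, dtype=float) + pseudocount
    t = np.asarray(pheno.treatment_values, dtype=float) + pseudocount
    bad = (c <= 0) | (t <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive phenotype value after pseudocount for genotype "
            f"{pheno.genotype_ids[i]!r}, trait {pheno.trait_names[j]!r}"
        )
    return PhenoLfcTable(
        genotype_ids=pheno.genotype_ids,
        trait_names=pheno.trait_names,
        values=np.log2(t / c),
    )
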