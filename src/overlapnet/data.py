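"""Shared domain containers for the pipeline.

Every container is a thin, validated wrapper around a :class:`pandas.DataFrame`
or :class:`numpy.ndarray`.  Validation happens at construction so downstream
stages can assume well-formed inputs.  Conventions used throughout:

* gene order and genotype order are preserved exactly as given;
* condition labels are the literal strings ``"control"`` and ``"treatment"``;
* genotype order is the order of first appearance in the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
CONDITIONS = (CONTROL, TREATMENT)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _unique_in_order(values: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of each sequencing sample to genotype × condition × replicate.

    The sheet requires a balanced design: every genotype appears under both
    conditions and every (genotype, condition) cell has the same replicate
    count ``r >= 1``.
    """

    frame: pd.DataFrame  # columns: sample, genotype, condition, replicate

    def __post_init__(self) -> None:
        required = ["sample", "genotype", "condition", "replicate"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"sample sheet is missing columns {missing}")
        df = self.frame
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
            )
        if (df["replicate"].astype(float) < 1).any() or (
            df["replicate"].astype(float) != df["replicate"].astype(int)
        ).any():
            raise ValidationError("replicate indices must be positive integers")
        counts = df.groupby(["genotype", "condition"], sort=False).size()
        for g in self.genotypes:
            for cond in CONDITIONS:
                if (g, cond) not in counts.index:
                    raise ValidationError(
                        f"genotype {g!r} has no {cond} samples"
                    )
        if counts.nunique() != 1:
            raise ValidationError(
                "unbalanced design: every genotype×condition pair must have "
                f"the same replicate count, got {sorted(set(counts))}"
            )

    @property
    def genotypes(self) -> list[str]:
        return _unique_in_order(self.frame["genotype"].tolist())

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_replicates(self) -> int:
        return int(
            self.frame.groupby(["genotype", "condition"], sort=False).size().iloc[0]
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample"].tolist()

    def samples_for(self, genotype: str, condition: str) -> list[str]:
        df = self.frame
        sel = df[(df["genotype"] == genotype) & (df["condition"] == condition)]
        return sel.sort_values("replicate")["sample"].tolist()


@dataclass(frozen=True)
class CountMatrix:
    """Raw RNA-seq read counts, genes × samples, with its sample sheet.

    Column order follows the sheet, not the source file.
    """

    gene_ids: list[str]
    samples: SampleSheet
    values: np.ndarray  # int, genes × (2·m·r)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValidationError("gene ids must be unique")
        v = np.asarray(self.values)
        if v.shape != (len(self.gene_ids), len(self.samples.sample_ids)):
            raise ValidationError(
                f"count matrix shape {v.shape} inconsistent with "
                f"{len(self.gene_ids)} genes × {len(self.samples.sample_ids)} samples"
            )
        if v.size and v.min() < 0:
            i, j = np.unravel_index(int(np.argmin(v)), v.shape)
            raise ValidationError(
                f"negative count for gene {self.gene_ids[i]!r} in sample "
                f"{self.samples.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.samples.sample_ids
        )


@dataclass(frozen=True)
class NormalizedMatrix:
    """Normalized expression values.

    Before replicate averaging (``averaged=False``) columns are sample ids;
    after averaging (``averaged=True``) there is one column per
    genotype × condition, all control genotypes first, then all treatment
    genotypes, genotype order preserved.
    """

    gene_ids: list[str]
    columns: list[str]
    values: np.ndarray
    averaged: bool
    genotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.columns)):
            raise ValidationError("normalized matrix shape mismatch")
        if v.size and (not np.isfinite(v).all() or v.min() < 0):
            raise ValidationError("normalized values must be finite and non-negative")
        if self.averaged and len(self.columns) != 2 * len(self.genotypes):
            raise ValidationError("averaged matrix must have 2·m columns")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.columns)

    def condition_block(self, condition: str) -> np.ndarray:
        """Genes × genotypes block for one condition (averaged matrices only)."""
        if not self.averaged:
            raise ValueError("condition blocks exist only after averaging")
        m = len(self.genotypes)
        if condition == CONTROL:
            return np.asarray(self.values, dtype=float)[:, :m]
        if condition == TREATMENT:
            return np.asarray(self.values, dtype=float)[:, m:]
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-genotype trait values under both conditions (m × p blocks)."""

    genotype_ids: list[str]
    trait_names: list[str]
    control_values: np.ndarray
    treatment_values: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.genotype_ids), len(self.trait_names))
        for name, block in (
            ("control", self.control_values),
            ("treatment", self.treatment_values),
        ):
            b = np.asarray(block, dtype=float)
            if b.shape != shape:
                raise ValidationError(f"{name} phenotype block has shape {b.shape}, expected {shape}")
            if b.size and not np.isfinite(b).all():
                raise ValidationError(f"{name} phenotype block contains non-finite values")


@dataclass(frozen=True)
class LfcMatrix:
    """Genes × genotypes log2 fold changes (treatment over control)."""

    gene_ids: list[str]
    genotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.genotype_ids)):
            raise ValidationError("LFC matrix shape mismatch")
        if v.size and not np.isfinite(v).all():
            raise ValidationError("LFC matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.genotype_ids)

    def rows_for(self, genes: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [idx[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in LFC matrix") from None
        return np.asarray(self.values, dtype=float)[rows, :]


@dataclass(frozen=True)
class PhenoLfcTable:
    """Genotypes × traits log2 phenotype fold changes."""

    genotype_ids: list[str]
    trait_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genotype_ids), len(self.trait_names)):
            raise ValidationError("phenotype LFC table shape mismatch")
        if v.size and not np.isfinite(v).all():
            raise ValidationError("phenotype LFC table contains non-finite values")

    def trait_column(self, trait: str) -> np.ndarray:
        j = self.trait_names.index(trait)
        return np.asarray(self.values, dtype=float)[:, j]


@dataclass(frozen=True)
class GeneReport:
    """Final per-gene report plus a summary block.

    ``table`` has one row per selected gene: gene_id, module ids, associated
    traits, DEG flag, max |LFC| across genotypes.  ``summary`` carries the
    per-trait counts, DEG fraction and Fisher enrichment p-values.
    """

    table: pd.DataFrame
    summary: dict

    def __post_init__(self) -> None:
        required = {"gene_id", "modules", "traits", "deg", "max_abs_lfc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"gene report table missing columns {sorted(missing)}")
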