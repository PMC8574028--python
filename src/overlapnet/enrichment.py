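"""Stage (E): DEG flagging, Fisher exact enrichment, and the final gene report.

A gene is differentially expressed (DEG) when the absolute log2 fold change
reaches the threshold (default 2, i.e. a four-fold change) in at least one
genotype.  Enrichment of a property (DEG status, or membership in a
user-supplied list of known treatment-related genes) among the selected
genes is tested with a one-sided Fisher exact test: the p-value is the
upper hypergeometric tail P(X >= a) for the 2×2 table

                 property   no property
    selected        a            b
    unselected      c            d

with population N = a+b+c+d, K = a+c property genes, and n = a+b draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneReport, LfcMatrix
from .association import SelectionResult
from .hlc import AffiliationMatrix


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # selected and property
    b: int  # selected, no property
    c: int  # unselected and property
    d: int  # unselected, no property

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have a positive total")


def deg_flags(l1: LfcMatrix, threshold: float = 2.0) -> dict[str, bool]:
    """Per-gene DEG flag: max_j |l_ij| >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("DEG threshold must be positive")
    max_abs = np.abs(np.asarray(l1.values, dtype=float)).max(axis=1)
    return {g: bool(v >= threshold) for g, v in zip(l1.gene_ids, max_abs)}


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value, P(X >= a).

    Degenerate margins (no draws or no property genes) give p = 1 by
    convention.
    """
    total = t.a + t.b + t.c + t.d
    k_property = t.a + t.c
    n_selected = t.a + t.b
    if n_selected == 0 or k_property == 0:
        return 1.0
    p = float(stats.hypergeom.sf(t.a - 1, total, k_property, n_selected))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def build_report(
    selection: SelectionResult,
    f: AffiliationMatrix,
    deg: dict[str, bool],
    l1: LfcMatrix,
    known_genes: Iterable[str] | None = None,
) -> GeneReport:
    """Final gene report: one row per selected gene plus a summary block.

    The summary reconciles per-trait gene counts, the DEG fraction among the
    selected genes, and the Fisher p-value for DEG enrichment of the
    selected set against the full post-filter gene universe.  When a list of
    known treatment-related genes is supplied, a second Fisher test against
    that list is added under the same universe.
    """
    max_abs = dict(
        zip(l1.gene_ids, np.abs(np.asarray(l1.values, dtype=float)).max(axis=1))
    )
    rows = []
    for g in selection.selected_genes:
        rows.append(
            {
                "gene_id": g,
                "modules": ",".join(selection.gene_modules[g]),
                "traits": ",".join(selection.gene_traits[g]),
                "deg": bool(deg.get(g, False)),
                "max_abs_lfc": float(max_abs.get(g, np.nan)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "modules", "traits", "deg", "max_abs_lfc"]
    )

    universe = list(l1.gene_ids)
    selected = set(selection.selected_genes)
    deg_set = {g for g in universe if deg.get(g, False)}
    a = len(selected & deg_set)
    b = len(selected - deg_set)
    c = len(deg_set - selected)
    d = len(set(universe) - selected - deg_set)
    deg_table = ContingencyTable(a, b, c, d)
    summary: dict = {
        "n_selected": len(selected),
        "n_universe": len(universe),
        "per_trait_gene_counts": {
            t: len({g for m in mods for g in f.module_genes[m]})
            for t, mods in selection.modules_per_trait.items()
        },
        "per_trait_module_counts": {
            t: len(mods) for t, mods in selection.modules_per_trait.items()
        },
        "deg_selected": a,
        "deg_fraction_selected": (a / len(selected)) if selected else 0.0,
        "deg_contingency": [a, b, c, d],
        "deg_fisher_p": fisher_one_sided(deg_table) if selected else 1.0,
    }
    if known_genes is not None:
        known = set(known_genes) & set(universe)
        ka = len(selected & known)
        kb = len(selected - known)
        kc = len(known - selected)
        kd = len(set(universe) - selected - known)
        summary["known_genes_in_universe"] = len(known)
        summary["known_selected"] = ka
        summary["known_contingency"] = [ka, kb, kc, kd]
        summary["known_fisher_p"] = (
            fisher_one_sided(ContingencyTable(ka, kb, kc, kd)) if selected else 1.0
        )
    return GeneReport(table=table, summary=summary)
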