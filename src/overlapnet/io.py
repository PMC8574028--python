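"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain and diff-able: TSV matrices with ``gene_id``
as the first column, a long-format phenotype table, an edge-list TSV, GMT for
module membership, and JSON for the selection report.  Floats are written at
repr precision (17 significant digits) so read→write→read round-trips are
exact to at least 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CONDITIONS,
    CountMatrix,
    GeneReport,
    LfcMatrix,
    NormalizedMatrix,
    PhenoLfcTable,
    PhenotypeTable,
    SampleSheet,
    ValidationError,
)

FLOAT_FMT = "%.17g"


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV with columns sample, genotype, condition, replicate."""
    df = pd.read_csv(path, dtype={"sample": str, "genotype": str, "condition": str})
    return SampleSheet(df)


def read_counts(counts_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    """Read a raw count TSV against its sample sheet.

    The counts file is tab-separated with ``gene_id`` as first column and one
    column per sample.  Column order of the result follows the sheet; extra
    columns in the file are ignored, missing ones are an error.
    """
    sheet = read_sample_sheet(sheet_path)
    df = pd.read_csv(counts_path, sep="\t", dtype={"gene_id": str})
    if df.columns[0] != "gene_id":
        raise ValidationError(
            f"first column of {counts_path} must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    missing = [s for s in sheet.sample_ids if s not in df.columns]
    if missing:
        raise ValidationError(
            f"sample(s) {missing} from the sheet are absent from the counts header"
        )
    df = df[sheet.sample_ids]
    values = df.to_numpy()
    float_vals = np.asarray(values, dtype=float)
    if not np.isfinite(float_vals).all():
        i, j = np.argwhere(~np.isfinite(float_vals))[0]
        raise ValidationError(
            f"non-numeric count for gene {df.index[i]!r} in sample {df.columns[j]!r}"
        )
    if (float_vals < 0).any():
        i, j = np.argwhere(float_vals < 0)[0]
        raise ValidationError(
            f"negative count for gene {df.index[i]!r} in sample {df.columns[j]!r}"
        )
    if (float_vals != np.round(float_vals)).any():
        i, j = np.argwhere(float_vals != np.round(float_vals))[0]
        raise ValidationError(
            f"non-integer count for gene {df.index[i]!r} in sample {df.columns[j]!r}"
        )
    return CountMatrix(
        gene_ids=df.index.tolist(),
        samples=sheet,
        values=float_vals.astype(np.int64),
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a long-format phenotype table (genotype, trait, condition, value).

    Comma- or tab-separated (sniffed from the header line).  Every
    genotype × trait × condition cell must be present exactly once.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype={"genotype": str, "trait": str, "condition": str})
    required = ["genotype", "trait", "condition", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table is missing columns {missing}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels {sorted(bad)} in phenotype table")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        row = df[values.isna()].iloc[0]
        raise ValidationError(
            "non-numeric phenotype value for "
            f"({row['genotype']}, {row['trait']}, {row['condition']})"
        )
    df = df.assign(value=values)
    dup = df.duplicated(["genotype", "trait", "condition"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate phenotype cell ({row['genotype']}, {row['trait']}, {row['condition']})"
        )
    genotypes = list(dict.fromkeys(df["genotype"]))
    traits = list(dict.fromkeys(df["trait"]))
    blocks = {}
    for cond in CONDITIONS:
        pivot = df[df["condition"] == cond].pivot(
            index="genotype", columns="trait", values="value"
        )
        try:
            pivot = pivot.loc[genotypes, traits]
        except KeyError:
            pivot = pivot.reindex(index=genotypes, columns=traits)
        if pivot.isna().any().any():
            g = pivot.index[pivot.isna().any(axis=1)][0]
            t = pivot.columns[pivot.isna().any(axis=0)][0]
            raise ValidationError(f"missing phenotype cell ({g}, {t}, {cond})")
        blocks[cond] = pivot.to_numpy(dtype=float)
    return PhenotypeTable(
        genotype_ids=genotypes,
        trait_names=traits,
        control_values=blocks["control"],
        treatment_values=blocks["treatment"],
    )


def _write_matrix_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def write_normalized(d: NormalizedMatrix, path: str | Path) -> Path:
    path = Path(path)
    _write_matrix_tsv(d.to_frame(), path)
    return path


def write_lfc(l: LfcMatrix, path: str | Path) -> Path:
    path = Path(path)
    _write_matrix_tsv(l.to_frame(), path)
    return path


def read_lfc(path: str | Path) -> LfcMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    return LfcMatrix(
        gene_ids=df.index.tolist(),
        genotype_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_pheno_lfc(p: PhenoLfcTable, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(p.values, index=p.genotype_ids, columns=p.trait_names)
    frame.to_csv(path, sep="\t", index_label="genotype", float_format=FLOAT_FMT)
    return path


def read_pheno_lfc(path: str | Path) -> PhenoLfcTable:
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str}).set_index("genotype")
    return PhenoLfcTable(
        genotype_ids=df.index.tolist(),
        trait_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_edge_list(
    gene_ids: Sequence[str], weights: np.ndarray, path: str | Path, min_weight: float = 0.0
) -> Path:
    """Write ``gene_a<TAB>gene_b<TAB>weight`` for every upper-triangle pair above min_weight."""
    path = Path(path)
    w = np.asarray(weights, dtype=float)
    iu, ju = np.triu_indices(len(gene_ids), k=1)
    keep = w[iu, ju] > min_weight
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{gene_ids[i]}\t{gene_ids[j]}\t{float(w[i, j])!r}\n")
    return path


def write_modules_tsv(modules: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("module_id\tgene_id\n")
        for module_id, genes in modules.items():
            for g in genes:
                fh.write(f"{module_id}\t{g}\n")
    return path


def write_modules_gmt(
    modules: Mapping[str, Sequence[str]], path: str | Path, description: str = "overlapnet module"
) -> Path:
    """Write modules in GMT format: name, description, then one field per gene."""
    path = Path(path)
    with path.open("w") as fh:
        for module_id, genes in modules.items():
            fields = [module_id, description, *genes]
            fh.write("\t".join(fields) + "\n")
    return path


def read_modules_gmt(path: str | Path) -> dict[str, list[str]]:
    modules: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        modules[fields[0]] = fields[2:]
    return modules


def write_eigengenes(
    genotype_ids: Sequence[str], module_ids: Sequence[str], values: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    frame = pd.DataFrame(values, index=genotype_ids, columns=module_ids)
    frame.to_csv(path, sep="\t", index_label="genotype", float_format=FLOAT_FMT)
    return path


def write_selection_json(selection: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(selection, indent=2, sort_keys=True) + "\n")
    return path


def write_gene_report(report: GeneReport, table_path: str | Path, summary_path: str | Path) -> tuple[Path, Path]:
    table_path, summary_path = Path(table_path), Path(summary_path)
    report.table.to_csv(table_path, sep="\t", index=False, float_format=FLOAT_FMT)
    summary_path.write_text(json.dumps(report.summary, indent=2, sort_keys=True) + "\n")
    return table_path, summary_path


def write_outputs(result, out_dir: str | Path) -> dict[str, str]:
    """Persist every stage artifact of a pipeline result; return a manifest.

    Writes the normalized matrix, LFC matrix, phenotype LFC table, weighted and
    binary edge lists, module membership (TSV and GMT), eigengenes, the
    per-trait selection JSON, and the gene report (TSV + summary JSON).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"output directory {out_dir} is not writable: {exc}") from exc

    manifest: dict[str, str] = {}

    def record(key: str, path: Path) -> None:
        manifest[key] = str(path)

    record("normalized", write_normalized(result.d2, out_dir / "normalized.tsv"))
    record("lfc", write_lfc(result.l1, out_dir / "lfc.tsv"))
    record("pheno_lfc", write_pheno_lfc(result.pheno_lfc, out_dir / "pheno_lfc.tsv"))
    record(
        "edges_weighted",
        write_edge_list(
            result.adjacency.gene_ids,
            result.adjacency.values,
            out_dir / "edges_weighted.tsv",
            min_weight=result.cutoff,
        ),
    )
    record(
        "edges_binary",
        write_edge_list(
            result.network.gene_ids,
            result.network.values.astype(float),
            out_dir / "edges_binary.tsv",
            min_weight=0.5,
        ),
    )
    modules = result.affiliation.module_genes
    record("modules_tsv", write_modules_tsv(modules, out_dir / "modules.tsv"))
    record("modules_gmt", write_modules_gmt(modules, out_dir / "modules.gmt"))
    record(
        "eigengenes",
        write_eigengenes(
            result.eigengenes.genotype_ids,
            result.eigengenes.module_ids,
            result.eigengenes.values,
            out_dir / "eigengenes.tsv",
        ),
    )
    record(
        "selection",
        write_selection_json(result.selection.to_dict(), out_dir / "selection.json"),
    )
    table_path, summary_path = write_gene_report(
        result.report, out_dir / "gene_report.tsv", out_dir / "summary.json"
    )
    record("gene_report", table_path)
    record("summary", summary_path)
    return manifest
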