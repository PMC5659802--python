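"""Readers and writers: VCF, BED gene definitions, phenotype TSV, results.

Coordinates are BED-style 0-based half-open internally; VCF's 1-based
positions are converted at the boundary.  Only the GT field is read;
phased and unphased calls are treated identically and half-calls are
missing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import DegenerateGeneError, GenotypeBlock, code_genotypes

__all__ = [
    "GeneDefinition",
    "RunManifest",
    "read_gene_definitions",
    "read_phenotypes",
    "read_vcf_genes",
    "write_vcf",
    "write_results",
]


@dataclass
class GeneDefinition:
    """A BED interval naming one gene (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be below end")


@dataclass
class RunManifest:
    """Provenance record written alongside every results table."""

    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    gene_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_gene_definitions(path) -> list[GeneDefinition]:
    """Read a BED3+1 file (chrom, start, end, gene name)."""
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    return [
        GeneDefinition(r.gene_id, r.chrom, int(r.start), int(r.end))
        for r in table.itertuples()
    ]


def read_phenotypes(path, trait_columns=None, covariate_columns=None):
    """Read a sample-by-trait TSV (first column = sample id).

    '.' and empty cells are missing; samples with any missing value in a
    selected trait or covariate column are dropped (their count is
    reported via the returned ``n_dropped``).

    Returns ``(traits_df, covariates_df_or_None, n_dropped)``; both
    frames are indexed by sample id.
    """
    table = pd.read_csv(path, sep="\t", na_values=["."], dtype={0: str})
    sample_col = table.columns[0]
    table = table.set_index(sample_col)
    covariate_columns = list(covariate_columns or [])
    if trait_columns is None:
        numeric = table.apply(lambda c: pd.to_numeric(c, errors="coerce"))
        trait_columns = [
            c
            for c in table.columns
            if c not in covariate_columns and numeric[c].notna().any()
        ]
    if not trait_columns:
        raise ValueError("no numeric trait columns found")
    used = list(trait_columns) + covariate_columns
    sub = table[used].apply(lambda c: pd.to_numeric(c, errors="coerce"))
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    sub = sub[complete]
    traits = sub[list(trait_columns)]
    covar = sub[covariate_columns] if covariate_columns else None
    return traits, covar, n_dropped


def _dosage_from_gts(gt_types: np.ndarray) -> np.ndarray:
    """Map cyvcf2 gt_types (0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT) to
    ALT counts with NaN for missing."""
    out = np.full(gt_types.shape, np.nan)
    out[gt_types == 0] = 0.0
    out[gt_types == 1] = 1.0
    out[gt_types == 3] = 2.0
    return out


def read_vcf_genes(vcf_path, genes, samples=None):
    """Extract one GenotypeBlock per gene from a VCF in a single pass.

    Multiallelic and non-SNP records are skipped with a warning count.
    Yields ``(block, meta_dict)`` pairs for genes with at least one
    polymorphic biallelic SNP; empty or degenerate genes are reported in
    the returned log instead.

    Returns ``(blocks, log)`` where ``blocks`` is a list of
    ``(GenotypeBlock, meta)`` and ``log`` maps gene ids to diagnostics.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), samples=list(samples) if samples is not None else None)
    sample_ids = np.asarray(vcf.samples)
    per_gene: dict[str, dict] = {
        g.gene_id: {"calls": [], "positions": [], "gene": g} for g in genes
    }
    by_chrom: dict[str, list[GeneDefinition]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    n_skipped_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped_multi += 1
            continue
        pos0 = variant.POS - 1  # VCF is 1-based
        for g in by_chrom.get(variant.CHROM, []):
            if g.start <= pos0 < g.end:
                rec = per_gene[g.gene_id]
                rec["calls"].append(_dosage_from_gts(variant.gt_types))
                rec["positions"].append(variant.POS)
    if n_skipped_multi:
        warnings.warn(
            f"skipped {n_skipped_multi} multiallelic/non-SNP record(s)",
            stacklevel=2,
        )
    blocks = []
    log: dict[str, str] = {}
    if n_skipped_multi:
        log["_skipped_records"] = str(n_skipped_multi)
    for gene_id, rec in per_gene.items():
        if not rec["calls"]:
            log[gene_id] = "no qualifying variants"
            continue
        calls = np.vstack(rec["calls"]).T  # samples x SNPs
        positions = np.asarray(rec["positions"])
        order = np.argsort(positions)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                block = code_genotypes(
                    calls[:, order],
                    positions[order],
                    sample_ids=sample_ids,
                    gene_id=gene_id,
                )
        except DegenerateGeneError:
            log[gene_id] = "degenerate (all monomorphic)"
            continue
        g = rec["gene"]
        blocks.append((block, {"chrom": g.chrom, "start": g.start, "end": g.end}))
    return blocks, log


def write_vcf(block: GenotypeBlock, path, chrom: str = "1") -> None:
    """Write a GenotypeBlock as minimal VCF 4.2 text (GT only).

    The block's minor allele is written as ALT, so dosages round-trip:
    0 -> 0/0, 1 -> 0/1, 2 -> 1/1.
    """
    dosage = np.asarray(block.dosage).astype(int)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in block.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, pos in enumerate(block.positions):
            gts = "\t".join(gt_map[d] for d in dosage[:, j])
            fh.write(f"{chrom}\t{int(pos)}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


RESULT_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "n_snps_used",
    "p_dim",
    "k_dim",
    "statistic",
    "df",
    "p_value",
    "neg_log10_p",
    "significant_after_bonferroni",
    "flags",
]


def write_results(results: pd.DataFrame, manifest: RunManifest, out_path) -> None:
    """Write the results TSV (deterministic column order, full-precision
    p-values plus a -log10 column) and the JSON manifest alongside."""
    out_path = str(out_path)
    table = results.copy()
    if len(table):
        with np.errstate(divide="ignore"):
            table["neg_log10_p"] = -np.log10(table["p_value"].to_numpy(float))
    else:
        table = pd.DataFrame(columns=[c for c in RESULT_COLUMNS])
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    table = table[cols]
    table.to_csv(out_path, sep="\t", index=False, float_format="%.17g")
    with open(out_path + ".manifest.json", "w") as fh:
        fh.write(manifest.to_json() + "\n")
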