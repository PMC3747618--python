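"""Reading genotype/phenotype data and writing run reports.

The native layout is a tab-separated matrix with a header row of SNP ids,
one row per individual, and the phenotype as the last column (named
``phenotype``).  Diploid inputs (VCF, PLINK ``.raw`` dosages) are recoded to
binary either in *dominant* mode (any mutant allele -> 1, one column per
site) or *recessive-pair* mode (each site becomes two binary columns, one
per allele copy: homozygous-mutant and carrier indicators).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .logic_tree import to_json_dict
from .regression import Dataset
from .swarm import SwarmReport

PHENOTYPE_COLUMN = "phenotype"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    fmt: str = "tsv",
    recode: str = "dominant",
    phenotype_path: str | Path | None = None,
) -> Dataset:
    """Load a dataset.

    ``fmt`` is one of ``tsv`` (binary matrix, phenotype last column),
    ``vcf`` (genotypes from the VCF, phenotypes from ``phenotype_path`` —
    a text file with one 0/1 per sample line) or ``plink_raw``.  ``recode``
    applies to diploid inputs: ``dominant`` (any mutant -> 1) or
    ``recessive_pair`` (two binary columns per site).
    """
    if fmt == "tsv":
        return _read_tsv(Path(path))
    if fmt == "vcf":
        if phenotype_path is None:
            raise ValueError("a VCF carries no phenotype; pass phenotype_path")
        geno, ids = read_vcf_genotypes(path, recode)
        pheno = np.loadtxt(phenotype_path, dtype=np.int8)
        return Dataset(genotypes=geno, phenotypes=np.atleast_1d(pheno), snp_ids=ids)
    if fmt == "plink_raw":
        return _read_plink_raw(Path(path), recode)
    raise ValueError(f"unknown format {fmt!r}")


def _read_tsv(path: Path) -> Dataset:
    df = pd.read_csv(path, sep="\t")
    if PHENOTYPE_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing '{PHENOTYPE_COLUMN}' column")
    pheno = df[PHENOTYPE_COLUMN].to_numpy()
    geno = df.drop(columns=[PHENOTYPE_COLUMN])
    bad = ~geno.isin([0, 1]).all(axis=0)
    if bad.any():
        raise ValueError(
            f"{path}: non-binary genotype entries in column(s) "
            f"{list(geno.columns[bad])}"
        )
    return Dataset(
        genotypes=geno.to_numpy(dtype=np.int8),
        phenotypes=pheno.astype(np.int8),
        snp_ids=tuple(str(c) for c in geno.columns),
    )


def _recode_dosage(
    dosage: np.ndarray, ids: list[str], recode: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Recode a 0/1/2 dosage matrix to binary columns."""
    if recode == "dominant":
        return (dosage >= 1).astype(np.int8), tuple(ids)
    if recode == "recessive_pair":
        cols = []
        out_ids = []
        for j, sid in enumerate(ids):
            cols.append((dosage[:, j] >= 2).astype(np.int8))  # both copies mutant
            cols.append((dosage[:, j] >= 1).astype(np.int8))  # at least one copy
            out_ids.extend([f"{sid}_hom", f"{sid}_any"])
        return np.stack(cols, axis=1), tuple(out_ids)
    raise ValueError(f"unknown recode mode {recode!r}")


def read_vcf_genotypes(
    path: str | Path, recode: str = "dominant"
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Genotype matrix and SNP ids from a VCF (diploid), recoded to binary."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    dosage_cols = []
    ids = []
    # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dose_of_type = np.array([0, 1, -1, 2])
    for var in vcf:
        dose = dose_of_type[np.asarray(var.gt_types)]
        if (dose < 0).any():
            raise ValueError(f"{path}: missing genotype at {var.ID or var.POS}")
        dosage_cols.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not dosage_cols:
        raise ValueError(f"{path}: no variants")
    dosage = np.stack(dosage_cols, axis=1)
    return _recode_dosage(dosage, ids, recode)


def _read_plink_raw(path: Path, recode: str) -> Dataset:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "PHENOTYPE" not in df.columns:
        raise ValueError(f"{path}: PLINK .raw file lacks a PHENOTYPE column")
    pheno = df["PHENOTYPE"].to_numpy()
    # PLINK codes case/control as 2/1; accept 1/0 as-is.
    if set(np.unique(pheno)) <= {1, 2}:
        pheno = pheno - 1
    snp_cols = [c for c in df.columns if c not in meta]
    dosage = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(dosage).any():
        raise ValueError(f"{path}: missing genotypes are not supported")
    geno, ids = _recode_dosage(dosage.astype(int), snp_cols, recode)
    return Dataset(genotypes=geno, phenotypes=pheno.astype(np.int8), snp_ids=ids)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_dataset_tsv(data: Dataset, path: str | Path) -> None:
    ids = data.snp_ids or tuple(f"X{j + 1}" for j in range(data.n_snps))
    df = pd.DataFrame(data.genotypes, columns=list(ids))
    df[PHENOTYPE_COLUMN] = data.phenotypes
    df.to_csv(path, sep="\t", index=False)


def write_vcf(data: Dataset, path: str | Path) -> None:
    """Minimal haploid VCF export of a binary genotype matrix."""
    ids = data.snp_ids or tuple(f"X{j + 1}" for j in range(data.n_snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i + 1}" for i in range(data.n_individuals))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, sid in enumerate(ids):
            gts = "\t".join(str(int(g)) for g in data.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{sid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


REPORT_SCHEMA = {
    "required": [
        "seed",
        "config",
        "best_model",
        "best_score",
        "agents",
        "importance",
        "interactions",
    ],
    "best_model_required": ["trees", "betas", "beta0", "score", "snps"],
}


def report_to_dict(report: SwarmReport) -> dict:
    def model_dict(model, sc=None):
        return {
            "trees": [to_json_dict(t) for t in model.trees],
            "beta0": model.beta0,
            "betas": list(model.betas),
            "score": sc,
            "snps": sorted(model.distinct_snps()),
        }

    pairs = sorted(
        report.pair_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    triples = sorted(
        report.triple_counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return {
        "seed": report.seed,
        "config": report.config.to_dict(),
        "iterations": report.iterations,
        "converged": report.converged,
        "best_score": report.best_score,
        "best_model": model_dict(report.best_model, report.best_score),
        "best_model_pruned": {
            **model_dict(report.best_model_pruned),
            "log_prior": report.best_log_prior
            if np.isfinite(report.best_log_prior)
            else None,
            "f_statistics": [
                # F is null for a perfectly explained leaf (infinite partial F)
                {"snp_index": j, "F": f if np.isfinite(f) else None}
                for j, f in report.best_f_stats
            ],
        },
        "agents": [
            model_dict(m, s)
            for m, s in zip(report.agent_models, report.agent_scores)
        ],
        "local_bests": [
            model_dict(m, s)
            for m, s in zip(report.local_best_models, report.local_best_scores)
        ],
        "importance": list(map(float, report.importance)),
        "interactions": {
            "pairs": [{"snps": list(k), "count": v} for k, v in pairs],
            "triples": [{"snps": list(k), "count": v} for k, v in triples],
        },
    }


def validate_report(d: dict) -> None:
    """Structural check of a report dict against the shipped schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in d:
            raise ValueError(f"report missing required key {key!r}")
    for key in REPORT_SCHEMA["best_model_required"]:
        if key not in d["best_model"]:
            raise ValueError(f"report best_model missing {key!r}")


def write_report(
    report: SwarmReport, out_dir: str | Path, snp_ids: tuple[str, ...] | None = None
) -> dict[str, Path]:
    """Emit model JSON, ranked-SNP TSV and ranked-interaction TSV.

    Ordering is deterministic: importance descending, ties broken by SNP
    index.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report_to_dict(report)
    validate_report(d)
    paths = {}
    paths["model"] = out / "model.json"
    paths["model"].write_text(json.dumps(d, indent=2))

    imp = report.importance
    order = np.lexsort((np.arange(len(imp)), -imp))
    ids = snp_ids or tuple(f"X{j + 1}" for j in range(len(imp)))
    snp_df = pd.DataFrame(
        {
            "rank": np.arange(1, len(imp) + 1),
            "snp": [ids[j] for j in order],
            "snp_index_1based": order + 1,
            "importance": imp[order],
        }
    )
    paths["snps"] = out / "ranked_snps.tsv"
    snp_df.to_csv(paths["snps"], sep="\t", index=False)

    rows = [
        {
            "snps": ",".join(ids[j] for j in k),
            "order": len(k),
            "count": v,
        }
        for k, v in sorted(
            {**report.pair_counts, **report.triple_counts}.items(),
            key=lambda kv: (-kv[1], kv[0]),
        )
    ]
    paths["interactions"] = out / "ranked_interactions.tsv"
    pd.DataFrame(rows, columns=["snps", "order", "count"]).to_csv(
        paths["interactions"], sep="\t", index=False
    )
    paths["config"] = out / "config.json"
    paths["config"].write_text(
        json.dumps({"seed": report.seed, "config": report.config.to_dict()}, indent=2)
    )
    return paths
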