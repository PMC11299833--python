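"""Readers and writers for the standard formats the tool touches.

Genotypes come from VCF (dosage from ``DS`` when present, else the ``GT``
allele count) or from a plain SNP x sample dosage TSV; kinship from a
square TSV with sample IDs; phenotypes/covariates from a TSV with a binary
outcome column.  Results are written as a deterministic TSV.  All readers
align to a requested sample order and reject, rather than silently
reorder, mismatched sample sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fedglmm.glmm import ScoreRow

log = logging.getLogger("fedglmm")

RESULT_COLUMNS = ["SNP", "CHR", "POS", "REF", "ALT", "N", "AF", "SCORE", "VAR", "PVAL"]


@dataclass
class GenotypeBlock:
    """A chunk of variants: metadata plus a k x n dosage matrix (NaN missing)."""

    snp_ids: list[str]
    chrom: list[str]
    pos: list[int]
    ref: list[str]
    alt: list[str]
    dosages: np.ndarray


def _order_columns(found: list[str], wanted: list[str] | None, what: str) -> np.ndarray:
    if wanted is None:
        return np.arange(len(found))
    pos = {s: i for i, s in enumerate(found)}
    missing = [s for s in wanted if s not in pos]
    if missing:
        raise KeyError(f"{what}: unknown samples {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    return np.array([pos[s] for s in wanted])


def read_genotypes(
    path,
    fmt: str | None = None,
    samples: list[str] | None = None,
    chunk_size: int = 1000,
):
    """Stream genotype chunks from a VCF or a dosage TSV.

    Yields :class:`GenotypeBlock` with columns forced to ``samples`` order.
    VCF: dosage from ``DS`` if present, else the diploid GT alternate-allele
    count; half-calls and ``./.`` become missing; multiallelic records are
    split per ALT with a warning.  TSV: SNP rows x sample columns, blank or
    ``NA`` missing.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        yield from _read_vcf(path, samples, chunk_size)
    elif fmt in ("tsv", "dosage-tsv"):
        yield from _read_dosage_tsv(path, samples, chunk_size)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path, samples, chunk_size):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    order = _order_columns(list(vcf.samples), samples, str(path))
    buf: list[tuple] = []

    def flush():
        ids, chrom, pos, ref, alt, rows = zip(*buf)
        yield GenotypeBlock(
            snp_ids=list(ids), chrom=list(chrom), pos=list(pos),
            ref=list(ref), alt=list(alt), dosages=np.vstack(rows),
        )
        buf.clear()

    for rec in vcf:
        alts = rec.ALT or []
        if len(alts) > 1:
            warnings.warn(
                f"{path}:{rec.CHROM}:{rec.POS} multiallelic; splitting per ALT"
            )
        fmts = rec.FORMAT or []
        for ai, alt in enumerate(alts):
            if "DS" in fmts and ai == 0:
                dose = np.asarray(rec.format("DS"), dtype=float).reshape(-1)[order]
            else:
                gts = np.asarray(rec.genotype.array())
                a1, a2 = gts[:, 0], gts[:, 1]
                dose = np.where(
                    (a1 < 0) | (a2 < 0),
                    np.nan,
                    (a1 == ai + 1).astype(float) + (a2 == ai + 1).astype(float),
                )[order]
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            buf.append((key, rec.CHROM, rec.POS, rec.REF, alt, dose))
            if len(buf) >= chunk_size:
                yield from flush()
    if buf:
        yield from flush()


def _read_dosage_tsv(path, samples, chunk_size):
    reader = pd.read_csv(
        path, sep="\t", index_col=0, chunksize=chunk_size, na_values=["NA", ""]
    )
    order = None
    for df in reader:
        if order is None:
            order = _order_columns([str(c) for c in df.columns], samples, str(path))
        mat = df.to_numpy(dtype=float)[:, order]
        ids = [str(i) for i in df.index]
        yield GenotypeBlock(
            snp_ids=ids,
            chrom=[""] * len(ids),
            pos=[0] * len(ids),
            ref=[""] * len(ids),
            alt=[""] * len(ids),
            dosages=mat,
        )


def write_vcf(path, snp_ids, chrom, pos, ref, alt, dosages, sample_ids) -> None:
    """Emit a minimal GT-only VCF for integer dosage matrices (k x n)."""
    dosages = np.asarray(dosages)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in sample_ids) + "\n")
        for i, sid in enumerate(snp_ids):
            calls = [
                "./." if np.isnan(d) else gt_map[int(round(d))] for d in dosages[i]
            ]
            fh.write(
                f"{chrom[i]}\t{pos[i]}\t{sid}\t{ref[i]}\t{alt[i]}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_kinship(path, sample_order: list[str] | None = None, tol: float = 1e-6):
    """Square kinship TSV -> (matrix aligned to sample_order, ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column sample IDs differ")
    M = df.to_numpy(dtype=float)
    asym = np.max(np.abs(M - M.T))
    if asym > tol:
        raise ValueError(f"{path}: kinship asymmetric by {asym:.3g} (tol {tol})")
    M = 0.5 * (M + M.T)
    if sample_order is not None:
        idx = _order_columns(ids, [str(s) for s in sample_order], str(path))
        M = M[np.ix_(idx, idx)]
        ids = [str(s) for s in sample_order]
    return M, ids


def read_pheno_covar(
    path, outcome_col: str = "outcome", covar_cols: list[str] | None = None
):
    """Phenotype/covariate TSV -> (sample_ids, y, X with intercept).

    Rows with a missing outcome are dropped (and counted in the log);
    1/2 case coding is remapped to 0/1 with a warning; missing covariate
    values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    if outcome_col not in df.columns:
        raise KeyError(f"{path}: no outcome column {outcome_col!r}")
    n_missing = int(df[outcome_col].isna().sum())
    if n_missing:
        log.info("%s: dropped %d rows with missing outcome", path, n_missing)
        df = df.dropna(subset=[outcome_col])
    y = df[outcome_col].to_numpy(dtype=float)
    vals = set(np.unique(y))
    if vals <= {1.0, 2.0}:
        warnings.warn(f"{path}: outcome coded 1/2; remapping to 0/1")
        y = y - 1.0
    elif not vals <= {0.0, 1.0}:
        raise ValueError(f"{path}: non-binary outcome values {sorted(vals - {0.0, 1.0})}")
    if covar_cols is None:
        covar_cols = [c for c in df.columns if c not in (id_col, outcome_col)]
    missing_cols = [c for c in covar_cols if c not in df.columns]
    if missing_cols:
        raise KeyError(f"{path}: missing covariate columns {missing_cols}")
    C = df[covar_cols].to_numpy(dtype=float) if covar_cols else np.empty((len(df), 0))
    if np.isnan(C).any():
        raise ValueError(f"{path}: missing covariate values are not allowed")
    X = np.column_stack([np.ones(len(df)), C])
    return df[id_col].astype(str).to_numpy(), y, X


def write_results(rows: list[ScoreRow], path) -> None:
    """Serialize score rows as a TSV with %.6g floats and literal NA p-values."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            pval = "NA" if r.pval is None else f"{r.pval:.6g}"
            af = "NA" if np.isnan(r.af) else f"{r.af:.6g}"
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.n_used}\t"
                f"{af}\t{r.score_T:.6g}\t{r.var_T:.6g}\t{pval}\n"
            )


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
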