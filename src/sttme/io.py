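"""Readers and writers for the pipeline's on-disk formats.

Spot datasets travel either as a Matrix Market directory (matrix.mtx in
genes x spots orientation, genes.tsv, barcodes.tsv, spot_positions.csv,
spots_meta.csv) or as an h5ad container.  Abundance matrices, variant
tables and cohorts are plain CSV/TSV; variants can also round-trip
through a minimal VCF 4.2 with INFO keys GENE, CSQ, CLNSIG, POP_AF, VAF.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .datasets import CellAbundanceMatrix, compute_qc_metrics
from .variants import REQUIRED_COLUMNS

OBS_META_COLS = ["sample_id", "tissue_type"]


# --- spot datasets ---------------------------------------------------------

def write_mtx_dir(adata: AnnData, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64))  # genes x spots
    (outdir / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    pos = adata.obs[["array_row", "array_col"]] if "array_row" in adata.obs else pd.DataFrame(
        {"array_row": 0, "array_col": 0}, index=adata.obs_names)
    pos.rename_axis("barcode").to_csv(outdir / "spot_positions.csv")
    meta_cols = [c for c in OBS_META_COLS if c in adata.obs]
    adata.obs[meta_cols].rename_axis("barcode").to_csv(outdir / "spots_meta.csv")
    return outdir


def read_mtx_dir(indir: str | Path) -> AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)  # back to spots x genes
    genes = (indir / "genes.tsv").read_text().splitlines()
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    adata = AnnData(X=X, obs=pd.DataFrame(index=barcodes),
                    var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    meta_path = indir / "spots_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col="barcode")
        for c in meta.columns:
            adata.obs[c] = meta.loc[adata.obs_names, c].to_numpy()
    pos_path = indir / "spot_positions.csv"
    if pos_path.exists():
        pos = pd.read_csv(pos_path, index_col="barcode")
        adata.obs["array_row"] = pos.loc[adata.obs_names, "array_row"].to_numpy()
        adata.obs["array_col"] = pos.loc[adata.obs_names, "array_col"].to_numpy()
    compute_qc_metrics(adata)
    return adata


def write_h5ad(adata: AnnData, path: str | Path) -> None:
    adata.write_h5ad(Path(path))


def read_h5ad(path: str | Path) -> AnnData:
    return ad.read_h5ad(Path(path))


# --- abundance matrices ----------------------------------------------------

def write_abundance_csv(matrix: CellAbundanceMatrix, path: str | Path,
                        which: str = "raw") -> None:
    mat = matrix.raw if which == "raw" else matrix.post
    if mat is None:
        raise ValueError("post-processed matrix not computed")
    mat.rename_axis("spot").to_csv(path)


def read_abundance_csv(path: str | Path) -> CellAbundanceMatrix:
    raw = pd.read_csv(path, index_col="spot")
    return CellAbundanceMatrix(raw)


# --- variant tables --------------------------------------------------------

def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> None:
    variants.rename_axis("variant_id").to_csv(path, sep="\t")


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns: {missing}")
    df["clinvar_class"] = df["clinvar_class"].where(df["clinvar_class"].notna(), None)
    return df


_VCF_CONTIGS = "\n".join(f"##contig=<ID=chr{i}>" for i in list(range(1, 23)) + ["X", "Y"])

_VCF_HEADER = f"""##fileformat=VCFv4.2
{_VCF_CONTIGS}
""" + """##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar class">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Minimal single-column VCF 4.2 carrying the annotation in INFO."""
    lines = [_VCF_HEADER.rstrip("\n")]
    for vid, row in variants.iterrows():
        info = [f"GENE={row['gene']}", f"CSQ={row['consequence']}"]
        if row.get("clinvar_class") is not None and not pd.isna(row.get("clinvar_class")):
            info.append(f"CLNSIG={row['clinvar_class']}")
        if row.get("pop_af") is not None and not pd.isna(row.get("pop_af")):
            info.append(f"POP_AF={row['pop_af']:.6g}")
        info.append(f"VAF={row['vaf']:.6g}")
        if "sample_id" in row and not pd.isna(row["sample_id"]):
            info.append(f"SAMPLE={row['sample_id']}")
        lines.append("\t".join([str(row["chrom"]), str(int(row["pos"])), str(vid),
                                str(row["ref"]), str(row["alt"]), ".", ".",
                                ";".join(info)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, info_keys: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an annotated VCF into the variant-table schema.

    ``info_keys`` remaps INFO field names onto {gene, consequence,
    clinvar_class, pop_af, vaf, sample_id}.  Multi-allelic sites are
    split into one record per ALT before filtering.
    """
    from cyvcf2 import VCF

    keys = {"gene": "GENE", "consequence": "CSQ", "clinvar_class": "CLNSIG",
            "pop_af": "POP_AF", "vaf": "VAF", "sample_id": "SAMPLE"}
    keys.update(info_keys or {})
    rows, ids = [], []
    for i, rec in enumerate(VCF(str(path))):
        for alt in rec.ALT:
            row = {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt}
            for field, key in keys.items():
                row[field] = rec.INFO.get(key)
            if row["vaf"] is None:
                raise ValueError(f"record {rec.ID or i} lacks INFO/{keys['vaf']}")
            row["vaf"] = float(row["vaf"])
            row["pop_af"] = float(row["pop_af"]) if row["pop_af"] is not None else None
            rows.append(row)
            ids.append(rec.ID if rec.ID not in (None, ".") else f"v{i:05d}")
    df = pd.DataFrame(rows)
    df.index = ids
    return df


# --- cohorts ---------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "CD68", "CD163", "CD40LG", "efs_days", "efs_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
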