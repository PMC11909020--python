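"""On-disk formats: VCF genotypes, tab-delimited tables, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ValidationError

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path) -> Path:
    """Deterministic tab-delimited write (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(genotypes: GenotypeMatrix, variants: pd.DataFrame, path) -> Path:
    """Write dosages as a VCF with GT and DS FORMAT fields.

    Hard calls 0/1/2 map to 0/0, 0/1 and 1/1; fractional dosages keep DS
    and report the rounded GT.  Missing genotypes are ``./.`` with DS
    ``.``.
    """
    if list(variants["variant_id"]) != list(genotypes.variant_ids):
        raise ValidationError("variant table and genotype columns must align")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prsdiff\n")
        for c in sorted(pd.unique(variants["chrom"]), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        dos = genotypes.dosages
        for j, row in enumerate(variants.itertuples(index=False)):
            cells = []
            for d in dos[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    cells.append(f"{gt_codes[hard]}:{d:.6g}")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t"
                     f"{row.ref_allele}\t{row.alt_allele}\t.\t.\t.\tGT:DS\t"
                     + "\t".join(cells) + "\n")
    return path


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Load a VCF into a dosage matrix, preferring DS over GT.

    Returns the genotypes and a minimal variant table (variant_id, chrom,
    pos, ref_allele, alt_allele).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = [], []
    for var in vcf:
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            ds = np.where(ds < 0, np.nan, ds)
        else:
            gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            ds = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0],
                           default=np.nan)
        cols.append(ds)
        rows.append(dict(variant_id=var.ID or f"{var.CHROM}:{var.POS}",
                         chrom=var.CHROM, pos=var.POS,
                         ref_allele=var.REF, alt_allele=var.ALT[0]))
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, list(variants["variant_id"])), variants


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
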