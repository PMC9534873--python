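"""Reading and writing dosage matrices and cohort tables.

Dosage data travels as VCF 4.2 with a per-sample ``DS`` FORMAT field (one
record per variant; structural C4 haplotypes are encoded as pseudo-variants
with a symbolic ALT such as ``<AL-BL>``), or as plain TSV matrices with a
``sample_id`` key column.  Reading uses cyvcf2; writing emits plain text
VCF.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_dosage_vcf",
    "write_dosage_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
    "##contig=<ID={contig}>\n"
)


def write_dosage_vcf(
    path: str | os.PathLike,
    dosages: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    *,
    contig: str = "6",
    start_pos: int = 31_982_057,
    symbolic_alt: bool = False,
) -> None:
    """Write a samples x variants dosage matrix as a DS-field VCF.

    ``meta``, if given, is indexed by variant id with columns chrom/pos/ref/
    alt; otherwise pseudo-coordinates starting at ``start_pos`` are invented.
    ``symbolic_alt`` encodes each column name as a symbolic ALT (used for
    structural-haplotype pseudo-variants).
    """
    variants = list(dosages.columns)
    samples = list(dosages.index.astype(str))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        if samples:  # FORMAT column is only legal when samples are present
            fh.write("\tFORMAT\t" + "\t".join(samples))
        fh.write("\n")
        mat = dosages.to_numpy(dtype=float)
        for j, vid in enumerate(variants):
            if meta is not None and vid in meta.index:
                row = meta.loc[vid]
                chrom, pos = str(row["chrom"]), int(row["pos"])
                ref, alt = str(row["ref"]), str(row["alt"])
            else:
                chrom, pos = contig, start_pos + j
                ref = "N" if symbolic_alt else "A"
                alt = f"<{vid}>" if symbolic_alt else "G"
            fields = [chrom, str(pos), str(vid), ref, alt, ".", ".", "."]
            if samples:
                fields.append("DS")
                fields.extend(
                    "." if np.isnan(mat[i, j]) else format(mat[i, j], ".6g")
                    for i in range(len(samples))
                )
            fh.write("\t".join(fields) + "\n")


def read_dosage_vcf(path: str | os.PathLike, *, strict: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (samples x variants dosage matrix, variant metadata).

    Dosages come from the ``DS`` FORMAT field, falling back to hard genotypes
    (``GT`` coded 0/1/2) when DS is absent.  Values outside [0, 2] raise in
    ``strict`` mode and are clamped otherwise.  Symbolic ALT alleles
    (``<NAME>``) are reported in the metadata with the angle brackets
    stripped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for k, v in enumerate(vcf, start=1):
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        alt = v.ALT[0] if v.ALT else "."
        meta_rows.append(
            {
                "id": vid,
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": alt.strip("<>") if alt.startswith("<") else alt,
            }
        )
        ids.append(vid)
        if not samples:
            rows.append(np.empty(0))
            continue
        ds = None
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = v.genotypes
            if gts is None:
                raise ValueError(f"record {k} ({vid}): neither DS nor GT present")
            vals = np.array(
                [a + b if (a >= 0 and b >= 0) else np.nan for a, b, *_ in gts], dtype=float
            )
        bad = (vals < 0) | (vals > 2)
        bad &= ~np.isnan(vals)
        if bad.any():
            if strict:
                raise ValueError(
                    f"record {k} ({vid}): dosage outside [0, 2] for sample(s) "
                    f"{[samples[i] for i in np.where(bad)[0]]}"
                )
            vals = np.clip(vals, 0.0, 2.0)
        rows.append(vals)
    meta = pd.DataFrame(meta_rows).set_index("id") if meta_rows else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt"]
    )
    if rows and samples:
        mat = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    else:
        mat = np.empty((len(samples), len(ids)))
    dosages = pd.DataFrame(mat, index=pd.Index(samples, name="sample_id"), columns=ids)
    return dosages, meta


def read_matrix_tsv(path: str | os.PathLike, index_col: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    if index_col in df.columns:
        df = df.set_index(index_col)
    return df


def write_matrix_tsv(path: str | os.PathLike, df: pd.DataFrame, index_name: str = "sample_id") -> None:
    out = df.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", na_rep=".")
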