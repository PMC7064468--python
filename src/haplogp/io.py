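"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as biallelic VCF (GT-only; inbred lines are 0/0 or 1/1)
or as HapMap-style tab-delimited matrices; phenotypes as tidy CSV with
columns line, eyt, env, rep, block, trait, value, is_check; haplotype
blocks as TSV plus a PLINK ``.blocks``-style file; simulation truth as
JSON.  VCF reading goes through cyvcf2.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ldblocks import HapBlock, HapMatrix, SnpMatrix
from .simdata import SimTruth

PHENO_COLUMNS = ["line", "eyt", "env", "rep", "block", "trait", "value", "is_check"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(geno: SnpMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.line_ids) + "\n")
        gt_map = {1.0: "0/0", 0.0: "0/1", -1.0: "1/1"}
        for j in range(geno.n_snps):
            calls = [
                gt_map.get(geno.codes[i, j], "./.")
                if not np.isnan(geno.codes[i, j]) else "./."
                for i in range(geno.n_lines)
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                f"{geno.ref[j]}\t{geno.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> SnpMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    snp_ids, chroms, pos, ref, alt, cols = [], [], [], [], [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    lut = np.array([1.0, 0.0, np.nan, -1.0])
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        snp_ids.append(v.ID or f"S{v.CHROM}_{v.POS}")
        chroms.append(str(v.CHROM))
        pos.append(int(v.POS))
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(lut[np.asarray(v.gt_types)])
    return SnpMatrix(
        line_ids=line_ids,
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos),
        codes=np.column_stack(cols),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )


def write_hapmap(geno: SnpMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = ["rs#", "alleles", "chrom", "pos"] + list(geno.line_ids)
        fh.write("\t".join(header) + "\n")
        for j in range(geno.n_snps):
            r, a = geno.ref[j], geno.alt[j]
            calls = []
            for i in range(geno.n_lines):
                c = geno.codes[i, j]
                if np.isnan(c):
                    calls.append("NN")
                elif c == 1.0:
                    calls.append(r + r)
                elif c == -1.0:
                    calls.append(a + a)
                else:
                    calls.append(r + a)
            fh.write(
                "\t".join(
                    [geno.snp_ids[j], f"{r}/{a}", str(geno.chrom[j]), str(geno.pos[j])]
                    + calls
                )
                + "\n"
            )


def read_hapmap(path: str | Path) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    line_ids = list(df.columns[4:])
    ref = df["alleles"].str.split("/").str[0].to_numpy(object)
    alt = df["alleles"].str.split("/").str[1].to_numpy(object)
    codes = np.full((len(line_ids), df.shape[0]), np.nan)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, lid in enumerate(line_ids):
            call = row[lid]
            if call == "NN" or pd.isna(call):
                continue
            if call == ref[j] * 2:
                codes[i, j] = 1.0
            elif call == alt[j] * 2:
                codes[i, j] = -1.0
            else:
                codes[i, j] = 0.0
    return SnpMatrix(
        line_ids=line_ids,
        snp_ids=list(df["rs#"]),
        chrom=df["chrom"].to_numpy(object),
        pos=df["pos"].astype(int).to_numpy(),
        codes=codes,
        ref=ref,
        alt=alt,
    )


# ---------------------------------------------------------------------------
# phenotypes, blocks, truth
# ---------------------------------------------------------------------------

def write_pheno_csv(records: pd.DataFrame, path: str | Path) -> None:
    records[PHENO_COLUMNS].to_csv(path, index=False)


def read_pheno_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    df["is_check"] = df["is_check"].astype(bool)
    return df


def write_blocks(blocks: list[HapBlock], tsv_path: str | Path,
                 plink_path: str | Path | None = None) -> None:
    from .ldblocks import blocks_table

    blocks_table(blocks).to_csv(tsv_path, sep="\t", index=False)
    if plink_path is not None:
        with Path(plink_path).open("w") as fh:
            for b in blocks:
                fh.write("* " + " ".join(b.snp_ids) + "\n")


def write_hapmatrix(H: HapMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        H.incidence,
        index=H.line_ids,
        columns=[f"{b}:{a}" for b, a in zip(H.columns["block"], H.columns["allele"])],
    )
    df.to_csv(path, sep="\t")


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    d = asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    Path(path).write_text(json.dumps(d, indent=1))


def write_adjmeans_csv(values: pd.DataFrame, path: str | Path) -> None:
    flat = values.copy()
    flat.columns = [f"{e}|{v}" for e, v in flat.columns]
    flat.to_csv(path)


def read_adjmeans_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 1)) for c in df.columns], names=["eyt", "env"]
    )
    return df
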