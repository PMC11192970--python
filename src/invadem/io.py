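"""Reading and writing the study's file formats.

VCF (biallelic, GT-only; read through cyvcf2), STRUCTURE-style two-row
integer tables, population-map / coordinate CSVs, and YAML truth or
configuration records.  All writers emit plain text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .matrix import GenotypeMatrix, MISSING

__all__ = [
    "write_vcf", "read_vcf", "write_structure", "read_structure",
    "write_popmap", "read_popmap", "write_yaml", "read_yaml",
]


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2 with GT-only biallelic records (REF=A, ALT=T)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invadem\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID=1,length={gm.n_loci + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids) + "\n")
        codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(gm.n_loci):
            gts = "\t".join(codes[int(c)] for c in gm.calls[:, j])
            fh.write(f"1\t{j + 1}\t{gm.locus_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str, popmap: dict[str, str] | str,
             coords: dict[str, tuple[float, float]] | None = None
             ) -> GenotypeMatrix:
    """Read a biallelic VCF into a genotype matrix.

    ``popmap`` maps individual id -> population (or is a path to a
    popmap CSV, whose coordinates are used unless ``coords`` is given).
    """
    from cyvcf2 import VCF

    if isinstance(popmap, str):
        pm, file_coords = read_popmap(popmap)
        coords = coords or file_coords
    else:
        pm = dict(popmap)
    vcf = VCF(path)
    inds = list(vcf.samples)
    missing_pop = [i for i in inds if i not in pm]
    if missing_pop:
        raise ValueError(f"individuals without a population label: {missing_pop[:5]}")
    cols, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        g = np.asarray(var.genotypes)[:, :2]
        dos = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1))
        cols.append(dos.astype(np.int8))
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    calls = np.column_stack(cols) if cols else np.zeros((len(inds), 0), np.int8)
    return GenotypeMatrix(calls, inds, ids, [pm[i] for i in inds], coords or {})


def write_structure(gm: GenotypeMatrix, path: str) -> None:
    """STRUCTURE-style table: two rows per individual, alleles 0/1, -9 missing."""
    with open(path, "w") as fh:
        fh.write("ind\tpop\t" + "\t".join(gm.locus_ids) + "\n")
        for i, ind in enumerate(gm.individual_ids):
            row = gm.calls[i]
            a0 = np.where(row == MISSING, -9, (row >= 1).astype(int))
            a1 = np.where(row == MISSING, -9, (row == 2).astype(int))
            for allele in (a0, a1):
                fh.write(ind + "\t" + gm.pop_labels[i] + "\t"
                         + "\t".join(str(int(x)) for x in allele) + "\n")


def read_structure(path: str, coords: dict | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    loci = list(df.columns[2:])
    inds, pops, rows = [], [], []
    for ind, grp in df.groupby("ind", sort=False):
        if len(grp) != 2:
            raise ValueError(f"individual {ind!r} must have exactly 2 allele rows")
        alleles = grp[loci].to_numpy(int)
        dos = alleles.sum(axis=0).astype(np.int8)
        dos[(alleles < 0).any(axis=0)] = MISSING
        inds.append(str(ind))
        pops.append(str(grp["pop"].iloc[0]))
        rows.append(dos)
    return GenotypeMatrix(np.vstack(rows), inds, loci, pops, coords or {})


def write_popmap(gm: GenotypeMatrix, path: str) -> None:
    rows = []
    for ind, pop in zip(gm.individual_ids, gm.pop_labels):
        lat, lon = gm.coords.get(pop, (np.nan, np.nan))
        rows.append({"population": pop, "individual": ind, "lat": lat, "lon": lon})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_popmap(path: str) -> tuple[dict[str, str], dict[str, tuple[float, float]]]:
    df = pd.read_csv(path)
    pm = dict(zip(df["individual"].astype(str), df["population"].astype(str)))
    coords = {}
    if {"lat", "lon"} <= set(df.columns):
        for _, row in df.drop_duplicates("population").iterrows():
            if np.isfinite(row["lat"]) and np.isfinite(row["lon"]):
                coords[str(row["population"])] = (float(row["lat"]), float(row["lon"]))
    return pm, coords


def write_yaml(obj, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str):
    with open(path) as fh:
        return yaml.safe_load(fh)
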