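"""Readers and writers for the on-disk formats the pipeline touches.

All coordinate conversions live here: VCF positions are 1-based, BED
intervals are 0-based half-open, and both are mapped onto the conventions
of :mod:`ylineage.containers`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import (
    ANCESTRAL,
    CHRY_LENGTH_HG19,
    DERIVED,
    HETEROZYGOUS,
    MISSING,
    RegionMask,
    STRHaplotypeTable,
    VariantMatrix,
)

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> VariantMatrix:
    """Read a (possibly diploid-coded) chrY VCF into a VariantMatrix.

    REF is treated as the ancestral allele unless an ``AA`` INFO tag says
    otherwise.  Diploid heterozygous genotypes are preserved with the
    ``HETEROZYGOUS`` code so the filtering stage can remove them
    explicitly; per-sample ``DP`` is kept when present.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        positions, ids, geno_cols, depth_cols = [], [], [], []
        has_depth = "DP" in vcf.header.formats
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # SNP pipeline: biallelic sites only
            aa = rec.info.get("AA", rec.ref)
            derived_index = 1 if aa == rec.ref else 0
            col = np.empty(len(samples), dtype=np.int8)
            dcol = np.zeros(len(samples), dtype=np.int64)
            for i, s in enumerate(samples):
                call = rec.samples[s]
                alleles = call.get("GT", (None,))
                vals = [a for a in alleles if a is not None]
                if not vals:
                    col[i] = MISSING
                elif len(set(vals)) > 1:
                    col[i] = HETEROZYGOUS
                else:
                    col[i] = DERIVED if vals[0] == derived_index else ANCESTRAL
                if has_depth:
                    dp = call.get("DP")
                    dcol[i] = dp if dp is not None else 0
            positions.append(rec.pos)
            ids.append(rec.id or f"chrY:{rec.pos}")
            geno_cols.append(col)
            depth_cols.append(dcol)
    if positions:
        geno = np.stack(geno_cols, axis=1)
        depth = np.stack(depth_cols, axis=1) if has_depth else None
    else:
        geno = np.zeros((len(samples), 0), dtype=np.int8)
        depth = np.zeros((len(samples), 0), dtype=np.int64) if has_depth else None
    return VariantMatrix(positions=np.asarray(positions, dtype=np.int64),
                         samples=samples, genotypes=geno, depth=depth, ids=ids)


def write_vcf(vm: VariantMatrix, path, contig: str = "chrY") -> None:
    """Write a VariantMatrix as an uncompressed VCF 4.2 text file.

    Alleles are synthetic (``A``/``G``) because the matrix tracks
    ancestral/derived state, not nucleotides; the ancestral allele is
    recorded in the ``AA`` INFO tag.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={CHRY_LENGTH_HG19}>")
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for s in vm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, pos in enumerate(vm.positions):
            rec = out.new_record(contig=contig, start=int(pos) - 1,
                                 alleles=("A", "G"), id=vm.ids[j])
            rec.info["AA"] = "A"
            for i, s in enumerate(vm.samples):
                g = int(vm.genotypes[i, j])
                if g == MISSING:
                    rec.samples[s]["GT"] = (None,)
                elif g == HETEROZYGOUS:
                    rec.samples[s]["GT"] = (0, 1)
                else:
                    rec.samples[s]["GT"] = (g,)
                if vm.depth is not None:
                    rec.samples[s]["DP"] = int(vm.depth[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------


def read_bed_mask(path) -> RegionMask:
    """Read keep-intervals from a BED file (first three columns used)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        rows.append((int(parts[1]), int(parts[2])))
    return RegionMask(np.asarray(rows, dtype=np.int64).reshape(-1, 2))


def write_bed_mask(mask: RegionMask, path, contig: str = "chrY") -> None:
    with open(path, "w") as fh:
        for start, end in mask.intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# STR tables
# ---------------------------------------------------------------------------


def read_str_table(path) -> STRHaplotypeTable:
    """Read the STR CSV (``sample,population[,longitude],<locus...>``)."""
    df = pd.read_csv(path)
    if "longitude" in df.columns:
        df["longitude"] = df["longitude"].astype(float)
    return STRHaplotypeTable(df)


def write_str_table(table: STRHaplotypeTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# haplogroup definition files
# ---------------------------------------------------------------------------


def read_haplogroup_defs(path):
    """Read a TSV of (child, parent, comma-separated defining variants).

    ``parent`` may be ``-`` (or empty) for the root clade.  Returns a
    :class:`ylineage.phylo.HaplogroupTree`.
    """
    from .phylo import HaplogroupTree

    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed haplogroup definition line: {line!r}")
        child, parent, variants = parts
        rows.append((child, parent if parent not in ("-", "") else None,
                     [v.strip() for v in variants.split(",") if v.strip()]))
    return HaplogroupTree.from_edges(rows)


def write_haplogroup_defs(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# child\tparent\tdefining_variants\n")
        for child, parent, variants in tree.edge_rows():
            fh.write(f"{child}\t{parent or '-'}\t{','.join(variants)}\n")
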