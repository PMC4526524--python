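"""Readers and writers for on-disk formats.

Coordinate conventions at the boundary:

* FASTA / BED / BEDPE — 0-based half-open, identical to the internal
  convention (no shift).
* VCF — 1-based; positions are shifted by -1 on read and +1 on write.
* Results TSV — coordinates printed 1-based inclusive for human readers
  (``start + 1``, ``end``), stated in the header comment of the file.

All text readers and writers are gzip-transparent (a ``.gz`` suffix or gzip
magic bytes trigger compression/decompression).
"""

from __future__ import annotations

import gzip
import io
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GenomeModel,
    Gene,
    ReadPairAlignment,
    SampleInfo,
    SampleSheet,
    StrainVariantSet,
    Variant,
)

PathLike = Union[str, Path]


def _opener(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read chromosome sequences; lowercase bases are normalized to uppercase."""
    sequences: dict[str, str] = {}
    with _opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
            sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        warnings.warn(f"FASTA {path} contains no sequences", stacklevel=2)
    return sequences


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _opener(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene annotation (BED12) and enhancers (BED6)


def write_genes_bed12(genes: Iterable[Gene], path: PathLike) -> None:
    """Genes as BED12: thickStart/thickEnd unused, blocks are exons."""
    with _opener(path, "wt") as fh:
        for g in genes:
            exons = sorted(g.exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.symbol}\t0\t{g.strand}\t{start}\t{end}\t0\t"
                f"{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_genes_bed12(path: PathLike) -> list[Gene]:
    genes: list[Gene] = []
    with _opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            tss = start if strand == "+" else end - 1
            genes.append(Gene(symbol=name, chrom=chrom, strand=strand, tss=tss, exons=exons))
    return genes


def write_bed6(intervals: Iterable[tuple], path: PathLike) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED6."""
    with _opener(path, "wt") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: PathLike) -> list[tuple[str, int, int, str]]:
    out = []
    with _opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED requires >=3 columns")
            start, end = int(f[1]), int(f[2])
            if start > end:
                raise ValueError(f"{path}:{ln}: start > end")
            out.append((f[0], start, end, f[3] if len(f) > 3 else "."))
    return out


# ---------------------------------------------------------------------------
# VCF


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: StrainVariantSet, chrom_lengths: dict[str, int], path: PathLike,
              sample_name: str = "STRAIN") -> None:
    """Write variants as VCF v4.2 (positions converted to 1-based)."""
    with _opener(path, "wt") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name + "\n")
        recs = sorted(variants.records, key=lambda v: (v.chrom, v.pos))
        for v in recs:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tDP={v.depth}\t"
                f"GT:DP\t{v.genotype}:{v.depth}\n"
            )


def read_vcf_variants(path: PathLike, min_depth: int = 3,
                      require_homozygous: bool = True) -> StrainVariantSet:
    """Read a VCF, keeping records passing the genotype/depth filters.

    Mirrors the strain-variant filtration used to define strain-distinguishing
    variants: homozygous alternate genotype with read-depth evidence of at
    least ``min_depth`` reads ("at least 3 reads of coverage" by default).
    Positions are converted to internal 0-based.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a hard dependency
        raise
    kept: list[Variant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if rec.ALT is None or len(rec.ALT) == 0:
                continue
            # depth: FORMAT DP of first sample, falling back to INFO DP
            depth = None
            try:
                dp = rec.format("DP")
                if dp is not None:
                    depth = int(dp[0][0])
            except Exception:
                depth = None
            if depth is None or depth < 0:
                info_dp = rec.INFO.get("DP")
                depth = int(info_dp) if info_dp is not None else 0
            if depth < min_depth:
                continue
            gts = rec.genotypes[0] if rec.genotypes else [1, 1, False]
            alleles = [a for a in gts[:-1] if a is not None and a >= 0]
            hom_alt = len(alleles) > 0 and all(a == 1 for a in alleles)
            if require_homozygous and not hom_alt:
                continue
            gt_str = "/".join(str(a) for a in alleles) if alleles else "1/1"
            kept.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS - 1,
                    ref=rec.REF,
                    alt=str(rec.ALT[0]),
                    genotype=gt_str,
                    depth=depth,
                )
            )
    finally:
        vcf.close()
    return StrainVariantSet(kept)


# ---------------------------------------------------------------------------
# BEDPE


def write_bedpe(pairs: Iterable[ReadPairAlignment], path: PathLike) -> None:
    """BEDPE, 0-based half-open; score column carries the uniqueness flag (1/0)."""
    with _opener(path, "wt") as fh:
        for p in pairs:
            score = 1 if p.unique else 0
            fh.write(
                f"{p.chrom1}\t{p.start1}\t{p.end1}\t{p.chrom2}\t{p.start2}\t{p.end2}\t"
                f"{p.name}\t{score}\t{p.strand1}\t{p.strand2}\n"
            )


def read_bedpe(path: PathLike, sample_id: str = "") -> list[ReadPairAlignment]:
    pairs: list[ReadPairAlignment] = []
    with _opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{ln}: BEDPE requires 10 columns, got {len(f)}")
            s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            if s1 > e1 or s2 > e2:
                raise ValueError(f"{path}:{ln}: start > end")
            pairs.append(
                ReadPairAlignment(
                    chrom1=f[0], start1=s1, end1=e1,
                    chrom2=f[3], start2=s2, end2=e2,
                    name=f[6], unique=f[7] not in ("0", "0.0"),
                    sample_id=sample_id, strand1=f[8], strand2=f[9],
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Sample sheet


def read_sample_sheet(path: PathLike) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    infos = [
        SampleInfo(
            sample_id=row["sample_id"],
            strain=row["strain"],
            treatment=row["treatment"],
            path=row.get("path") if isinstance(row.get("path"), str) else None,
        )
        for _, row in df.iterrows()
    ]
    return SampleSheet(infos)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results tables


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"  # 3 significant digits, scientific


def write_results_tsv(results: pd.DataFrame, path: PathLike) -> None:
    """Write per-probe test results, one row per probe.

    Coordinates are printed 1-based inclusive; p-values in scientific
    notation with 3 significant digits. Rows are ordered by (chrom, start).
    """
    cols = [
        "probe_id", "chrom", "start", "end", "feature", "gene_symbol", "gene_class",
        "mean_norm_a", "mean_norm_b", "log2fc", "p", "p_adjusted", "call",
    ]
    df = results.copy()
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    with _opener(path, "wt") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("\t".join(cols) + "\n")
        for _, r in df.iterrows():
            fields = [
                str(r["probe_id"]), str(r["chrom"]),
                str(int(r["start"]) + 1), str(int(r["end"])),
                "" if pd.isna(r["feature"]) else str(r["feature"]),
                "" if pd.isna(r["gene_symbol"]) else str(r["gene_symbol"]),
                "" if pd.isna(r["gene_class"]) else str(r["gene_class"]),
                f"{r['mean_norm_a']:.4g}" if pd.notna(r["mean_norm_a"]) else "",
                f"{r['mean_norm_b']:.4g}" if pd.notna(r["mean_norm_b"]) else "",
                f"{r['log2fc']:.4f}" if pd.notna(r["log2fc"]) else "",
                _fmt_p(r["p"]) if pd.notna(r["p"]) else "",
                _fmt_p(r["p_adjusted"]) if pd.notna(r["p_adjusted"]) else "",
                "" if pd.isna(r["call"]) else str(r["call"]),
            ]
            fh.write("\t".join(fields) + "\n")


def write_counts_tsv(values: pd.DataFrame, path: PathLike) -> None:
    values.to_csv(path, sep="\t", index_label="probe_id")


def read_counts_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")
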