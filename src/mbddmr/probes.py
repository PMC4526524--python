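"""Probe construction and annotation.

Two probe sets are built independently, mirroring the study design:

* **genome tiles** — consecutive, non-overlapping 2.2 kb windows covering
  each chromosome (the final partial tile is kept);
* **promoter probes** — one window per gene spanning 2 kb transcriptionally
  upstream to 200 bp downstream of the TSS (2.2 kb total, truncated at
  chromosome edges).

CpG sites are enumerated per strain on the variant-substituted sequence, so
CpG dinucleotides created (or destroyed) by strain-distinguishing SNPs are
handled explicitly. Genome tiles are assigned to a single genomic feature by
the fixed priority promoter > exon > intron > enhancer > intergenic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from intervaltree import IntervalTree

from .model import CpGSiteSet, GenomeModel, Probe, StrainVariantSet, Variant, CountMatrix

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200
TILE_LENGTH = 2200

FEATURE_PRIORITY = ("promoter", "exon", "intron", "enhancer", "intergenic")


def tile_genome(genome: GenomeModel, tile_length: int = TILE_LENGTH) -> list[Probe]:
    """Cut every chromosome into consecutive non-overlapping tiles.

    Tiles exactly partition each chromosome: the last tile is truncated to the
    chromosome end and kept whenever it is at least 1 bp long.
    """
    if tile_length <= 0:
        raise ValueError(f"tile_length must be positive, got {tile_length}")
    probes: list[Probe] = []
    for chrom in genome.chroms:
        L = genome.chrom_length(chrom)
        for i, start in enumerate(range(0, L, tile_length)):
            end = min(start + tile_length, L)
            probes.append(
                Probe(id=f"tile:{chrom}:{i}", chrom=chrom, start=start, end=end, kind="genome_tile")
            )
    return probes


def promoter_window(tss: int, strand: str, chrom_length: int,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Window covering ``upstream`` bases before and ``downstream`` bases from the TSS.

    The TSS (first transcribed base) counts as the first downstream base. On
    the minus strand the window is mirrored: upstream lies at higher
    coordinates. Truncated to ``[0, chrom_length)``.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        # downstream bases are tss, tss-1, ..., tss-(downstream-1);
        # upstream bases are tss+1 ... tss+upstream
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        raise ValueError(f"gene strand must be '+' or '-', got {strand!r}")
    return max(0, start), min(chrom_length, end)


def promoter_probes(genome: GenomeModel, classify=None) -> list[Probe]:
    """One promoter probe per gene, carrying gene symbol and gene class."""
    if classify is None:
        from .summarize import classify_gene_symbol as classify
    probes = []
    for g in genome.genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.symbol} lacks a strand")
        start, end = promoter_window(g.tss, g.strand, genome.chrom_length(g.chrom))
        probes.append(
            Probe(
                id=f"prom:{g.symbol}", chrom=g.chrom, start=start, end=end,
                kind="promoter", gene_symbol=g.symbol, gene_class=classify(g.symbol),
                feature="promoter",
            )
        )
    return probes


# ---------------------------------------------------------------------------
# CpG enumeration


def _substitute_snps(seq: str, variants: list[Variant]) -> str:
    """Apply SNP alternate alleles to a chromosome sequence (indels ignored)."""
    if not variants:
        return seq
    chars = list(seq)
    seen: set[int] = set()
    for v in variants:
        if not v.is_snp:
            continue  # indels excluded from CpG logic
        if v.pos in seen:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        seen.add(v.pos)
        if chars[v.pos].upper() != v.ref.upper():
            raise ValueError(
                f"variant ref mismatch at {v.chrom}:{v.pos}: genome has "
                f"{chars[v.pos]!r}, variant claims {v.ref!r}"
            )
        chars[v.pos] = v.alt.upper()
    return "".join(chars)


def _scan_cpg(seq: str) -> np.ndarray:
    """Positions of the C of every CG dinucleotide (0-based)."""
    return np.array([m.start() for m in re.finditer("CG", seq.upper())], dtype=np.int64)


def enumerate_cpg_sites(genome: GenomeModel, variants: Optional[StrainVariantSet],
                        strain: str) -> CpGSiteSet:
    """Enumerate CpG positions on the strain-substituted sequence.

    Sites absent from the reference sequence but present under the strain's
    alternate alleles are marked ``snp_created``.
    """
    by_chrom = variants.by_chrom() if variants is not None else {}
    out = CpGSiteSet(strain=strain)
    for chrom, seq in genome.sequences.items():
        ref_sites = _scan_cpg(seq)
        chrom_vars = by_chrom.get(chrom, [])
        if chrom_vars:
            strain_seq = _substitute_snps(seq, chrom_vars)
            sites = _scan_cpg(strain_seq)
        else:
            sites = ref_sites
        ref_set = set(ref_sites.tolist())
        prov = np.array(
            ["reference" if p in ref_set else "snp_created" for p in sites.tolist()],
            dtype=object,
        )
        out.positions[chrom] = sites
        out.provenance[chrom] = prov
    return out


def flag_cpg_effect(genome: GenomeModel, variant: Variant) -> Variant:
    """Set cpg_creating / cpg_destroying flags by local dinucleotide comparison."""
    if not variant.is_snp:
        return variant
    seq = genome.sequences[variant.chrom]
    lo = max(0, variant.pos - 1)
    hi = min(len(seq), variant.pos + 2)
    ref_ctx = seq[lo:hi].upper()
    alt_ctx = ref_ctx[: variant.pos - lo] + variant.alt.upper() + ref_ctx[variant.pos - lo + 1:]
    n_ref = ref_ctx.count("CG")
    n_alt = alt_ctx.count("CG")
    variant.cpg_creating = n_alt > n_ref
    variant.cpg_destroying = n_alt < n_ref
    return variant


def annotate_cpg_counts(probes: Iterable[Probe], ref_sites: CpGSiteSet,
                        alt_sites: CpGSiteSet) -> None:
    """Fill ``n_cpg_ref`` and ``n_cpg_snp_dependent`` on each probe in place.

    ``n_cpg_snp_dependent`` counts alternate-strain sites created by SNPs
    within the probe interval.
    """
    for p in probes:
        p.n_cpg_ref = ref_sites.count_in(p.chrom, p.start, p.end)
        pos = alt_sites.positions.get(p.chrom)
        if pos is None or len(pos) == 0:
            p.n_cpg_snp_dependent = 0
            continue
        lo = np.searchsorted(pos, p.start, side="left")
        hi = np.searchsorted(pos, p.end, side="left")
        prov = alt_sites.provenance[p.chrom][lo:hi]
        p.n_cpg_snp_dependent = int((prov == "snp_created").sum())


# ---------------------------------------------------------------------------
# Feature assignment


@dataclass
class FeatureAnnotation:
    """Interval trees per feature category, used for priority assignment."""

    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    def add(self, feature: str, chrom: str, start: int, end: int) -> None:
        if end <= start:
            return
        self.trees.setdefault(feature, {}).setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, feature: str, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(feature, {}).get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def build_feature_annotation(genome: GenomeModel) -> FeatureAnnotation:
    """Promoter windows, exons and introns from gene models; enhancers from the genome model."""
    ann = FeatureAnnotation()
    for g in genome.genes:
        L = genome.chrom_length(g.chrom)
        ps, pe = promoter_window(g.tss, g.strand, L)
        ann.add("promoter", g.chrom, ps, pe)
        exons = sorted(g.exons)
        for s, e in exons:
            ann.add("exon", g.chrom, s, e)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            ann.add("intron", g.chrom, e1, s2)
    for chrom, s, e in genome.enhancers:
        ann.add("enhancer", chrom, s, e)
    return ann


def assign_feature(probe: Probe, annotation: FeatureAnnotation) -> str:
    """Highest-priority feature with >=1 bp overlap; intergenic if none."""
    for feature in FEATURE_PRIORITY[:-1]:
        if annotation.overlaps(feature, probe.chrom, probe.start, probe.end):
            return feature
    return "intergenic"


def assign_features(probes: Iterable[Probe], annotation: FeatureAnnotation) -> None:
    for p in probes:
        p.feature = assign_feature(p, annotation)


# ---------------------------------------------------------------------------
# Probe selection


def select_probes(probes: list[Probe], counts: CountMatrix,
                  min_pairs: int = 3, min_samples: int = 2) -> list[Probe]:
    """Apply the probe selection filters.

    A probe is kept iff it contains at least one CpG site or one
    SNP-dependent CpG site, and strictly more than ``min_pairs`` read pairs
    aligned in strictly more than ``min_samples`` samples (pooled across all
    arms). Defaults implement the literal "more than 3 ... in more than 2
    samples" reading: >=4 pairs in >=3 samples.
    """
    values = counts.values
    missing = [p.id for p in probes if p.id not in values.index]
    if missing:
        raise ValueError(f"counts missing {len(missing)} probes (first: {missing[0]})")
    kept = []
    for p in probes:
        if p.n_cpg_ref + p.n_cpg_snp_dependent < 1:
            continue
        row = values.loc[p.id]
        if int((row > min_pairs).sum()) > min_samples:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Variant annotation


def annotate_probe_variants(probe: Probe, variants: StrainVariantSet,
                            window: int = 0) -> list[Variant]:
    """Variants within the probe interval extended by ``window`` bp on each side."""
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    lo, hi = probe.start - window, probe.end + window
    return [v for v in variants if v.chrom == probe.chrom and lo <= v.pos < hi]
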