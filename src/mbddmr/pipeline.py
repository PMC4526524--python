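"""End-to-end orchestration: filter -> probes -> count -> test -> summarize.

``analyze_dataset`` runs the whole analysis on in-memory objects and is the
workhorse both for the CLI (which reads the interchange files first) and for
simulation studies. ``run_pipeline`` wraps it with file I/O, a resolved-config
copy and a run manifest so shell runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import counts as counts_mod
from . import formats, nbstats, probes as probes_mod, readfilter, summarize
from .model import CountMatrix, GenomeModel, Probe, SampleSheet, StrainVariantSet

log = logging.getLogger("mbddmr")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults match the study's printed values."""

    genome: str = ""
    genes: str = ""
    enhancers: Optional[str] = None
    variants: Optional[str] = None
    samples: str = ""
    outdir: str = "mbddmr_out"
    seed: int = 1
    tile_length: int = 2200
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    max_gap: int = 600
    min_depth: int = 3
    select_min_pairs: int = 3   # strictly more than
    select_min_samples: int = 2  # strictly more than
    fc_threshold: float = 1.0
    genome_wide_p: float = 1e-2
    promoter_alpha: float = 0.05
    dispersion_prior_weight: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Bundle of everything the pipeline computes."""

    tiles: list[Probe]
    promoters: list[Probe]
    tile_counts: CountMatrix
    promoter_counts: CountMatrix
    selected_tiles: list[Probe]
    selected_promoters: list[Probe]
    filter_tallies: dict[str, readfilter.FilterTally]
    norm_tiles: nbstats.NormalizationFactors
    norm_promoters: nbstats.NormalizationFactors
    dmr_genome_wide: dict[str, pd.DataFrame]   # per strain
    dmr_promoter: dict[str, pd.DataFrame]      # per strain
    interaction: pd.DataFrame
    class_summary: dict[str, pd.DataFrame]     # per strain
    policy: nbstats.CallPolicy
    record_counts: dict[str, int] = field(default_factory=dict)


def _probe_meta(probe_list: list[Probe]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.id for p in probe_list],
            "chrom": [p.chrom for p in probe_list],
            "start": [p.start for p in probe_list],
            "end": [p.end for p in probe_list],
            "feature": [p.feature for p in probe_list],
            "gene_symbol": [p.gene_symbol for p in probe_list],
            "gene_class": [p.gene_class for p in probe_list],
        }
    ).set_index("probe_id", drop=False)


def analyze_dataset(
    genome: GenomeModel,
    variants: Optional[StrainVariantSet],
    samples: SampleSheet,
    pairs_by_sample: dict,
    config: Optional[PipelineConfig] = None,
) -> AnalysisResult:
    """Run filtration, probe building, counting, testing and summarizing."""
    cfg = config or PipelineConfig()
    samples.require_full_design()
    strains = samples.strains
    ref_strain, alt_strain = strains[0], strains[1]

    # CpG site sets per strain (SNP-dependent CpGs belong to the alternate strain)
    sites = {
        ref_strain: probes_mod.enumerate_cpg_sites(genome, None, ref_strain),
        alt_strain: probes_mod.enumerate_cpg_sites(genome, variants, alt_strain),
    }

    # 1. filtration (per sample, against its own strain's sites)
    kept_by_sample: dict[str, list] = {}
    tallies: dict[str, readfilter.FilterTally] = {}
    for info in samples.samples:
        kept, tally = readfilter.filter_read_pairs(
            pairs_by_sample[info.sample_id], sites[info.strain], max_gap=cfg.max_gap)
        kept_by_sample[info.sample_id] = kept
        tallies[info.sample_id] = tally
        log.info("filter %s: kept %d / %d", info.sample_id, tally.n_kept, tally.n_input)

    # 2. probes
    tiles = probes_mod.tile_genome(genome, cfg.tile_length)
    promoters = probes_mod.promoter_probes(genome)
    annotation = probes_mod.build_feature_annotation(genome)
    probes_mod.assign_features(tiles, annotation)
    probes_mod.annotate_cpg_counts(tiles, sites[ref_strain], sites[alt_strain])
    probes_mod.annotate_cpg_counts(promoters, sites[ref_strain], sites[alt_strain])

    # 3. counting: midpoint on disjoint tiles, any-overlap on promoter windows
    tile_counts = counts_mod.count_overlaps(kept_by_sample, tiles, samples, mode="midpoint")
    promoter_counts = counts_mod.count_overlaps(kept_by_sample, promoters, samples,
                                                mode="any_overlap")

    # 4. selection
    selected_tiles = probes_mod.select_probes(tiles, tile_counts,
                                              cfg.select_min_pairs, cfg.select_min_samples)
    selected_promoters = probes_mod.select_probes(promoters, promoter_counts,
                                                  cfg.select_min_pairs, cfg.select_min_samples)
    tile_counts_sel = tile_counts.subset_probes([p.id for p in selected_tiles])
    prom_counts_sel = promoter_counts.subset_probes([p.id for p in selected_promoters])

    policy = nbstats.CallPolicy(
        fc_threshold=cfg.fc_threshold, genome_wide_p=cfg.genome_wide_p,
        promoter_alpha=cfg.promoter_alpha, promoter_m=len(selected_promoters))

    # 5. normalization + dispersion (full 2x2 design)
    def _design(sheet: SampleSheet) -> np.ndarray:
        s = np.array([1.0 if sheet.info(i).strain == ref_strain else 0.0
                      for i in sheet.sample_ids])
        t = np.array([1.0 if sheet.info(i).treatment == "control" else 0.0
                      for i in sheet.sample_ids])
        return np.column_stack([np.ones(len(s)), s, t, s * t])

    results_gw: dict[str, pd.DataFrame] = {}
    results_prom: dict[str, pd.DataFrame] = {}
    summaries: dict[str, pd.DataFrame] = {}
    norm_t = nbstats.normalize(tile_counts_sel)
    norm_p = nbstats.normalize(prom_counts_sel)
    disp_t = nbstats.estimate_dispersion(
        tile_counts_sel, _design(samples), norm_t.offsets.to_numpy(),
        prior_weight=cfg.dispersion_prior_weight)
    disp_p = nbstats.estimate_dispersion(
        prom_counts_sel, _design(samples), norm_p.offsets.to_numpy(),
        prior_weight=cfg.dispersion_prior_weight)

    tile_meta = _probe_meta(selected_tiles)
    prom_meta = _probe_meta(selected_promoters)

    # 6. per-strain control-vs-DEHP tests
    for strain in strains:
        ctl = samples.ids_for(strain, "control")
        dehp = samples.ids_for(strain, "dehp")
        gw = nbstats.test_dmr(tile_counts_sel, ctl, dehp, disp_t, norm_t)
        gw = gw.join(tile_meta.drop(columns="probe_id"))
        gw["call"] = nbstats.call_dmrs(gw, policy, mode="genome_wide")
        results_gw[strain] = gw

        pr = nbstats.test_dmr(prom_counts_sel, ctl, dehp, disp_p, norm_p)
        pr = pr.join(prom_meta.drop(columns="probe_id"))
        pr["p_adjusted"] = np.clip(pr["p"] * policy.promoter_m, 0, 1)
        pr["call"] = nbstats.call_dmrs(pr, policy, mode="promoter")
        results_prom[strain] = pr
        summaries[strain] = summarize.class_summary_table(pr, policy)

    # 7. interaction contrast on promoter probes
    interaction = nbstats.test_interaction(
        prom_counts_sel, disp_p, norm_p, strain_order=strains,
        m=policy.promoter_m, alpha=cfg.promoter_alpha)
    interaction = interaction.join(prom_meta.drop(columns="probe_id"))

    record_counts = {
        "samples": len(samples.samples),
        "pairs_input": sum(t.n_input for t in tallies.values()),
        "pairs_kept": sum(t.n_kept for t in tallies.values()),
        "tiles": len(tiles),
        "promoters": len(promoters),
        "tiles_selected": len(selected_tiles),
        "promoters_selected": len(selected_promoters),
    }

    return AnalysisResult(
        tiles=tiles, promoters=promoters,
        tile_counts=tile_counts, promoter_counts=promoter_counts,
        selected_tiles=selected_tiles, selected_promoters=selected_promoters,
        filter_tallies=tallies, norm_tiles=norm_t, norm_promoters=norm_p,
        dmr_genome_wide=results_gw, dmr_promoter=results_prom,
        interaction=interaction, class_summary=summaries, policy=policy,
        record_counts=record_counts,
    )


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """File-based run: read inputs, analyze, write all outputs plus manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        genome = GenomeModel(sequences=formats.read_fasta(config.genome))
        genome.genes = formats.read_genes_bed12(config.genes)
        if config.enhancers:
            genome.enhancers = [(c, s, e) for c, s, e, _ in formats.read_bed6(config.enhancers)]
        variants = None
        if config.variants:
            variants = formats.read_vcf_variants(config.variants, min_depth=config.min_depth)
            for v in variants:
                probes_mod.flag_cpg_effect(genome, v)
        samples = formats.read_sample_sheet(config.samples)
        pairs = {
            info.sample_id: formats.read_bedpe(info.path, info.sample_id)
            for info in samples.samples
        }
        stage = "analysis"
        result = analyze_dataset(genome, variants, samples, pairs, config)
        stage = "write outputs"
        for strain, df in result.dmr_genome_wide.items():
            tag = strain.replace("/", "_")
            formats.write_results_tsv(df, outdir / f"dmr_genome_wide_{tag}.tsv")
        for strain, df in result.dmr_promoter.items():
            tag = strain.replace("/", "_")
            formats.write_results_tsv(df, outdir / f"dmr_promoter_{tag}.tsv")
            result.class_summary[strain].to_csv(outdir / f"class_summary_{tag}.tsv",
                                                sep="\t", index=False)
        result.interaction.to_csv(outdir / "interaction.tsv", sep="\t", index=False)
        formats.write_counts_tsv(result.tile_counts.values, outdir / "counts_tiles.tsv")
        formats.write_counts_tsv(result.promoter_counts.values, outdir / "counts_promoters.tsv")
        tally_df = pd.DataFrame({k: v.as_dict() for k, v in result.filter_tallies.items()}).T
        tally_df.to_csv(outdir / "filter_stats.tsv", sep="\t", index_label="sample_id")
        config.to_yaml(outdir / "resolved_config.yaml")
        import mbddmr
        manifest = {
            "version": mbddmr.__version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "record_counts": result.record_counts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
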