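import numpy as np
import pytest
from scipy import stats

from mbddmr.model import CpGSiteSet, GenomeModel, SampleInfo, SampleSheet
from mbddmr.probes import enumerate_cpg_sites, promoter_window
from mbddmr.synthio import (
    CaptureModel,
    MethylationProfile,
    SimConfig,
    TruthRecord,
    _expected_capture,
    simulate_genome,
    simulate_mbd_readpairs,
    simulate_methylation,
    simulate_strain_variants,
)


class TestSimConfig:
    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, snp_rate=1.5)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, chrom_length=0)


class TestCaptureModel:
    def test_half_saturation(self):
        cap = CaptureModel(p_background=0.0)
        assert cap.capture_prob(cap.k_half) == pytest.approx(cap.p_max / 2)

    def test_zero_methylation_background_only(self):
        cap = CaptureModel()
        assert cap.capture_prob(0) == pytest.approx(cap.p_background)

    def test_monotone_saturating(self):
        cap = CaptureModel()
        p = cap.capture_prob(np.arange(50))
        assert (np.diff(p) > 0).all() and p[-1] < cap.p_max

    def test_invalid_probability_ordering(self):
        with pytest.raises(ValueError):
            CaptureModel(p_background=0.5, p_max=0.4)

    def test_read_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            CaptureModel(fragment_min=40, read_length=50)


class TestGenome:
    def test_determinism(self):
        cfg = SimConfig(seed=5, n_genes=10, chrom_length=40_000)
        g1 = simulate_genome(cfg)
        g2 = simulate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert [(a.symbol, a.tss, a.strand, a.exons) for a in g1.genes] == [
            (a.symbol, a.tss, a.strand, a.exons) for a in g2.genes
        ]
        assert g1.enhancers == g2.enhancers

    def test_gene_models_complete(self):
        g = simulate_genome(SimConfig(seed=6, n_genes=12, chrom_length=60_000))
        assert len(g.genes) == 12
        for gene in g.genes:
            assert gene.strand in "+-"
            assert len(gene.exons) >= 1
            assert 0 <= gene.tss < g.chrom_length(gene.chrom)

    def test_class_census(self):
        cfg = SimConfig(seed=7, n_genes=10, class_fractions=(0.3, 0.3, 0.3),
                        chrom_length=60_000)
        g = simulate_genome(cfg)
        census = {
            "Vmn": sum(1 for x in g.genes if x.symbol.startswith("Vmn")),
            "Olfr": sum(1 for x in g.genes if x.symbol.startswith("Olfr")),
            "Mir": sum(1 for x in g.genes if x.symbol.startswith("Mir")),
            "other": sum(1 for x in g.genes if x.symbol.startswith("Gene")),
        }
        assert census == {"Vmn": 3, "Olfr": 3, "Mir": 3, "other": 1}

    def test_promoters_cpg_enriched(self):
        g = simulate_genome(SimConfig(seed=8, n_genes=20, chrom_length=150_000))
        sites = enumerate_cpg_sites(g, None, "ref")
        total_cpg = sites.n_sites()
        genome_len = g.total_length()
        prom_cpg = prom_len = 0
        for gene in g.genes:
            a, b = promoter_window(gene.tss, gene.strand, g.chrom_length(gene.chrom))
            prom_cpg += sites.count_in(gene.chrom, a, b)
            prom_len += b - a
        assert prom_cpg / prom_len > 2.5 * (total_cpg / genome_len)

    def test_degenerate_equal_rates(self):
        """Island rate == background rate: promoter density matches genome-wide."""
        cfg = SimConfig(seed=9, n_genes=100, n_chroms=2, chrom_length=400_000,
                        cpg_island_rate=0.01, background_cpg_rate=0.01)
        g = simulate_genome(cfg)
        sites = enumerate_cpg_sites(g, None, "ref")
        genome_density = sites.n_sites() / g.total_length()
        dens = []
        for gene in g.genes:
            a, b = promoter_window(gene.tss, gene.strand, g.chrom_length(gene.chrom))
            dens.append(sites.count_in(gene.chrom, a, b) / (b - a))
        dens = np.array(dens)
        se = dens.std(ddof=1) / np.sqrt(len(dens))
        assert abs(dens.mean() - genome_density) < 2 * se + 1e-4


class TestVariants:
    def test_flags_from_sequence(self):
        cfg = SimConfig(seed=10, chrom_length=60_000, snp_rate=0.002)
        g = simulate_genome(cfg)
        vs = simulate_strain_variants(g, cfg)
        assert len(vs) > 0
        for v in vs:
            assert v.homozygous_alt and v.depth >= 3
            assert g.sequences[v.chrom][v.pos] == v.ref

    def test_census_changes_by_one_per_flagged_snp(self):
        cfg = SimConfig(seed=11, chrom_length=60_000, snp_rate=0.002)
        g = simulate_genome(cfg)
        vs = simulate_strain_variants(g, cfg)
        ref = enumerate_cpg_sites(g, None, "ref")
        alt = enumerate_cpg_sites(g, vs, "alt")
        n_c = sum(1 for v in vs if v.cpg_creating)
        n_d = sum(1 for v in vs if v.cpg_destroying)
        assert n_c > 0 and n_d > 0
        assert alt.n_sites() - ref.n_sites() == n_c - n_d

    def test_affecting_fraction_binomial(self):
        """~1000 SNPs at frac_cpg_affecting=0.3: realized fraction within 99% CI."""
        cfg = SimConfig(seed=12, n_chroms=2, chrom_length=110_000,
                        snp_rate=0.0045, frac_cpg_affecting_snps=0.3)
        g = simulate_genome(cfg)
        vs = simulate_strain_variants(g, cfg)
        n = len(vs)
        assert n > 500
        frac = sum(1 for v in vs if v.cpg_creating or v.cpg_destroying) / n
        half = 2.576 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < half

    def test_tiny_rate_warns_empty(self):
        cfg = SimConfig(seed=13, chrom_length=1000, n_genes=1, snp_rate=1e-7)
        g = simulate_genome(cfg)
        with pytest.warns(UserWarning):
            vs = simulate_strain_variants(g, cfg)
        assert len(vs) == 0


class TestMethylation:
    def _setup(self, seed=14):
        cfg = SimConfig(seed=seed, n_genes=10, chrom_length=60_000)
        g = simulate_genome(cfg)
        vs = simulate_strain_variants(g, cfg)
        return cfg, g, vs

    def test_zero_effect_identical_arms(self):
        cfg, g, vs = self._setup()
        spec = [TruthRecord("chr1", 5000, 7200, injected_log2fc=0.0)]
        profile, _ = simulate_methylation(g, vs, spec, cfg)
        for strain in cfg.strains:
            for chrom in profile.arm_probs[(strain, "control")]:
                assert np.array_equal(
                    profile.probs(strain, "control", chrom),
                    profile.probs(strain, "dehp", chrom),
                )

    def test_interaction_opposite_shift(self):
        cfg, g, vs = self._setup()
        region = (g.genes[0].chrom, *promoter_window(
            g.genes[0].tss, g.genes[0].strand, g.chrom_length(g.genes[0].chrom)))
        spec = [TruthRecord(region[0], region[1], region[2],
                            injected_log2fc=2.0, interaction=True)]
        profile, truth = simulate_methylation(g, vs, spec, cfg)
        s0, s1 = cfg.strains
        assert truth[0].realized_log2fc[s0] > 0 > truth[0].realized_log2fc[s1]
        # shift direction in probabilities agrees
        chrom = region[0]
        pos = profile.sites[s0].positions[chrom]
        sel = (pos >= region[1]) & (pos < region[2])
        d0 = (profile.probs(s0, "control", chrom) - profile.probs(s0, "dehp", chrom))[sel]
        assert d0.mean() > 0
        pos1 = profile.sites[s1].positions[chrom]
        sel1 = (pos1 >= region[1]) & (pos1 < region[2])
        d1 = (profile.probs(s1, "control", chrom) - profile.probs(s1, "dehp", chrom))[sel1]
        assert d1.mean() < 0

    def test_region_outside_genome_rejected(self):
        cfg, g, vs = self._setup()
        with pytest.raises(ValueError, match="outside genome|unknown chromosome"):
            simulate_methylation(
                g, vs, [TruthRecord("chr1", 0, 10**7, injected_log2fc=1.0)], cfg)

    def test_realized_ratio_monte_carlo(self):
        """Injected log2fc=2: Monte-Carlo expected-count ratio within 10% of 4x."""
        cfg, g, vs = self._setup(seed=15)
        cap = CaptureModel()
        gene = g.genes[0]
        chrom = gene.chrom
        region = promoter_window(gene.tss, gene.strand, g.chrom_length(chrom))
        spec = [TruthRecord(chrom, region[0], region[1], injected_log2fc=2.0)]
        profile, truth = simulate_methylation(g, vs, spec, cfg, cap)
        s0 = cfg.strains[0]
        pos = profile.sites[s0].positions[chrom]
        p_ctl = profile.probs(s0, "control", chrom)
        p_dehp = profile.probs(s0, "dehp", chrom)

        rng = np.random.default_rng(99)
        n = 100_000
        lens = np.full(n, int(cap.fragment_mean))
        mids = rng.integers(region[0], region[1], size=n)
        starts = mids - int(cap.fragment_mean) // 2
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + lens, side="left")
        counts = hi - lo
        flat = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        cap_tot = {}
        for label, probs in (("ctl", p_ctl), ("dehp", p_dehp)):
            meth = rng.random(len(flat)) < probs[flat]
            k = np.add.reduceat(meth.astype(np.int64), offsets)
            k[counts == 0] = 0
            cap_tot[label] = cap.capture_prob(k).mean()
        ratio = cap_tot["ctl"] / cap_tot["dehp"]
        assert ratio == pytest.approx(4.0, rel=0.10)


class TestReadPairs:
    def _uniform_profile(self, p_a: float, p_b: float):
        """One 20 kb chromosome, a CpG every 50 bp; halves at prob p_a / p_b."""
        seq = ("A" * 48 + "CG") * 400
        g = GenomeModel(sequences={"chr1": seq})
        strain = "C57BL/6J"
        sites = enumerate_cpg_sites(g, None, strain)
        pos = sites.positions["chr1"]
        probs = np.where(pos < 10_000, p_a, p_b)
        profile = MethylationProfile(
            sites={strain: sites},
            arm_probs={(strain, "control"): {"chr1": probs}},
        )
        return g, profile, strain

    def test_zero_methylation_zero_background_emits_nothing(self):
        g, profile, strain = self._uniform_profile(0.0, 0.0)
        profile.arm_probs[(strain, "control")]["chr1"][:] = 0.0
        cap = CaptureModel(p_background=0.0)
        cfg = SimConfig(seed=20, target_pairs_per_sample=500, n_samples_per_arm=1)
        sheet = SampleSheet([SampleInfo("x", strain, "control")])
        pairs = simulate_mbd_readpairs(g, profile, cap, cfg, sheet)
        assert pairs["x"] == []

    def test_count_ratio_matches_capture_expectation(self):
        """Sampling path vs exact Poisson-binomial expectation of the capture model."""
        g, profile, strain = self._uniform_profile(0.1, 0.9)
        cap = CaptureModel()
        cfg = SimConfig(seed=21, target_pairs_per_sample=4000, n_samples_per_arm=1,
                        libsize_cv=0.0, frac_multimapped=0.0, frac_discordant=0.0)
        sheet = SampleSheet([SampleInfo("x", strain, "control")])
        pairs = simulate_mbd_readpairs(g, profile, cap, cfg, sheet)["x"]
        assert len(pairs) > 1000
        mids = np.array([(p.insert[0] + p.insert[1]) // 2 for p in pairs])
        interior = (mids > 500) & (mids < 19_500) & (np.abs(mids - 10_000) > 500)
        n_a = int(((mids < 10_000) & interior).sum())
        n_b = int(((mids >= 10_000) & interior).sum())

        pos = profile.sites[strain].positions["chr1"]
        probs = profile.probs(strain, "control", "chr1")
        rng = np.random.default_rng(0)
        from mbddmr.synthio import _draw_fragment_lengths
        lens = _draw_fragment_lengths(rng, cap, 600)
        e = {}
        for name, lo_r, hi_r in (("a", 1000, 9000), ("b", 11_000, 19_000)):
            starts = rng.integers(lo_r, hi_r, size=600)
            e[name] = _expected_capture(pos, probs, starts, lens, cap)
        expected_share = e["b"] / (e["a"] + e["b"])
        # observed split within the 99% binomial band around the prediction
        test = stats.binomtest(n_b, n_a + n_b, expected_share)
        assert test.pvalue > 0.01

    def test_capture_monotone_in_methylation(self):
        g, profile, strain = self._uniform_profile(0.2, 0.2)
        cap = CaptureModel()
        pos = profile.sites[strain].positions["chr1"]
        rng = np.random.default_rng(1)
        from mbddmr.synthio import _draw_fragment_lengths
        lens = _draw_fragment_lengths(rng, cap, 300)
        starts = rng.integers(500, 19_000, size=300)
        rates = []
        for level in (0.05, 0.2, 0.5, 0.8, 0.95):
            rates.append(_expected_capture(pos, np.full(len(pos), level),
                                           starts, lens, cap))
        assert rates == sorted(rates)

    def test_library_sizes_vary_lognormally(self, sim):
        sizes = np.array([len(v) for v in sim.pairs_by_sample.values()])
        assert sizes.std() > 0
        # all libraries within plausible log-normal range of the target
        target = sim.config.target_pairs_per_sample
        assert (sizes > target * 0.4).all() and (sizes < target * 2.5).all()
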