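"""Synthetic MBD-capture data with known truth.

The generator emulates the study design end-to-end so every downstream stage
is testable without external data:

* a small genome of two mouse-like strains differing by homozygous SNPs,
  some of which create or destroy CpG dinucleotides;
* CpG-dense promoter windows against a sparser genomic background, with a
  configurable fraction of gene symbols drawn from the three aggregated
  classes (Vmn / Olfr / Mir);
* per-arm (strain x treatment) methylation probabilities per CpG site, with
  effects injected on the logit scale inside designated truth regions so the
  expected captured-fragment counts differ by a requested log2 fold change
  (optionally with opposite sign in the two strains — interaction truth);
* MBD capture of ~200 bp fragments: capture probability saturates in the
  number of methylated CpGs the fragment carries,
  ``p(k) = p_bg + (p_max - p_bg) * k / (k + k_half)``,
  reflecting MBD binding to short methylated-CpG footprints;
* paired 2x50 bp read emission at the fragment ends, with log-normal
  library-size variation across samples.

Everything is driven by one mandatory seed; identical configurations produce
byte-identical outputs. Base-call errors, quality scores and PCR duplicates
are deliberately out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    CpGSiteSet,
    Gene,
    GenomeModel,
    ReadPairAlignment,
    SampleInfo,
    SampleSheet,
    StrainVariantSet,
    Variant,
)
from .probes import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM, enumerate_cpg_sites, flag_cpg_effect, promoter_window

DEFAULT_STRAINS = ("C57BL/6J", "FVB/N")


@dataclass
class SimConfig:
    """Study-condition parameters of the generator (scaled-down sizes).

    Rates are per-bp probabilities. ``n_samples_per_arm`` defaults to 5
    (quintuplicate arms); ``target_pairs_per_sample`` is the expected number
    of captured pairs per library, thousands here versus the ~12-15 M of a
    real MBD-Seq library.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 110_000
    n_genes: int = 30
    cpg_island_rate: float = 0.04
    background_cpg_rate: float = 0.008
    snp_rate: float = 0.002
    frac_cpg_affecting_snps: float = 0.2
    n_samples_per_arm: int = 5
    target_pairs_per_sample: int = 5000
    libsize_cv: float = 0.2
    class_fractions: tuple[float, float, float] = (0.10, 0.15, 0.15)  # Vmn, Olfr, Mir
    n_enhancers: int = 6
    frac_multimapped: float = 0.02
    frac_discordant: float = 0.01
    strains: tuple[str, str] = DEFAULT_STRAINS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("cpg_island_rate", "background_cpg_rate", "snp_rate",
                     "frac_cpg_affecting_snps", "frac_multimapped", "frac_discordant"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_samples_per_arm",
                     "target_pairs_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if sum(self.class_fractions) > 1.0 + 1e-9:
            raise ValueError("class fractions sum to more than 1")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be non-negative")


@dataclass
class CaptureModel:
    """Saturating (Michaelis-Menten) MBD capture of ~200 bp fragments."""

    fragment_mean: float = 200.0
    fragment_sd: float = 30.0
    fragment_min: int = 80
    fragment_max: int = 400
    p_max: float = 0.95
    k_half: float = 2.0
    p_background: float = 0.01
    read_length: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_background < self.p_max <= 1.0):
            raise ValueError("need 0 <= p_background < p_max <= 1")
        if not (self.fragment_min < self.fragment_mean < self.fragment_max):
            raise ValueError("need fragment_min < fragment_mean < fragment_max")
        if self.read_length > self.fragment_min:
            raise ValueError("read_length exceeds the minimum fragment length")

    def capture_prob(self, k) -> np.ndarray:
        """Capture probability for a fragment carrying k methylated CpGs."""
        k = np.asarray(k, dtype=float)
        return self.p_background + (self.p_max - self.p_background) * k / (k + self.k_half)


@dataclass
class TruthRecord:
    """Ground truth for one injected differentially methylated region."""

    chrom: str
    start: int
    end: int
    injected_log2fc: float
    interaction: bool = False
    strain: Optional[str] = None  # None = both strains (same orientation unless interaction)
    realized_log2fc: dict[str, float] = field(default_factory=dict)


@dataclass
class MethylationProfile:
    """Per-arm, per-CpG methylation probabilities for both strains."""

    sites: dict[str, CpGSiteSet]                              # strain -> site set
    arm_probs: dict[tuple[str, str], dict[str, np.ndarray]]   # (strain, treatment) -> chrom -> probs

    def probs(self, strain: str, treatment: str, chrom: str) -> np.ndarray:
        return self.arm_probs[(strain, treatment)][chrom]


@dataclass
class SimResult:
    config: SimConfig
    capture: CaptureModel
    genome: GenomeModel
    variants: StrainVariantSet
    profile: MethylationProfile
    truth: list[TruthRecord]
    samples: SampleSheet
    pairs_by_sample: dict[str, list[ReadPairAlignment]]


# ---------------------------------------------------------------------------
# Genome


def _plant_positions(rng: np.random.Generator, lo: int, hi: int, rate: float) -> list[int]:
    """Bernoulli site positions in [lo, hi-1) with >=2 bp spacing."""
    if hi - 1 <= lo or rate <= 0:
        return []
    hits = lo + np.flatnonzero(rng.random(hi - 1 - lo) < rate)
    out: list[int] = []
    last = -10
    for h in hits:
        if h >= last + 2:
            out.append(int(h))
            last = h
    return out


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Generate chromosomes, gene models and enhancers.

    CpG dinucleotides are planted explicitly (accidental CGs arising from the
    random background are removed first), so promoter CpG density tracks
    ``cpg_island_rate`` and the rest of the genome ``background_cpg_rate``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    alphabet = np.frombuffer(b"ACGT", dtype="S1")

    # gene layout: spread genes across chromosomes
    n_vmn = int(round(config.class_fractions[0] * config.n_genes))
    n_olfr = int(round(config.class_fractions[1] * config.n_genes))
    n_mir = int(round(config.class_fractions[2] * config.n_genes))
    symbols = (
        [f"Vmn2r{i + 1}" for i in range(n_vmn)]
        + [f"Olfr{i + 1}" for i in range(n_olfr)]
        + [f"Mir{i + 100}" for i in range(n_mir)]
        + [f"Gene{i + 1}" for i in range(config.n_genes - n_vmn - n_olfr - n_mir)]
    )
    order = rng.permutation(len(symbols))
    symbols = [symbols[i] for i in order]

    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(alphabet, size=L)
        # remove accidental CG dinucleotides so CpG density is fully planted
        s = seq.tobytes().decode()
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        cg = [i for i in range(L - 1) if s[i] == "C" and s[i + 1] == "G"]
        for pos in cg:
            arr[pos + 1] = b"A"

        # gene placement: evenly spaced slots with jitter
        n_here = per_chrom[ci]
        margin = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM + 1000
        slots = np.linspace(margin, L - margin - 5000, max(n_here, 1))
        promoter_ivs = []
        for k in range(n_here):
            strand = "+" if rng.random() < 0.5 else "-"
            body = int(rng.integers(2000, 5000))
            anchor = int(slots[k] + rng.integers(-300, 300))
            if strand == "+":
                tss = anchor
                exon_bounds = sorted(rng.integers(tss, tss + body, size=4).tolist())
                exons = [(tss, tss + 200)]
                if exon_bounds[1] - exon_bounds[0] > 50:
                    exons.append((exon_bounds[0] + 300, min(exon_bounds[1] + 400, tss + body)))
                exons.append((tss + body - 200, tss + body))
            else:
                tss = anchor + body
                exons = [(tss - 200 + 1, tss + 1)]
                exons.append((anchor, anchor + 200))
            exons = sorted(set((max(0, a), min(L, b)) for a, b in exons if b > a))
            genes.append(Gene(symbol=symbols[gi], chrom=chrom, strand=strand, tss=tss, exons=exons))
            promoter_ivs.append(promoter_window(tss, strand, L))
            gi += 1

        # plant CpGs: island rate in promoters, background elsewhere
        mask = np.zeros(L, dtype=bool)
        for a, b in promoter_ivs:
            mask[a:b] = True
        planted: list[int] = []
        for pos in _plant_positions(rng, 0, L, config.background_cpg_rate):
            if not mask[pos]:
                planted.append(pos)
        for a, b in promoter_ivs:
            planted.extend(_plant_positions(rng, a, b, config.cpg_island_rate))
        for pos in sorted(set(planted)):
            arr[pos] = b"C"
            arr[pos + 1] = b"G"
        # planting may have re-created a CG straddling a planted site boundary; re-scan & fix
        s2 = arr.tobytes().decode()
        planted_set = set(planted)
        for i in range(L - 1):
            if s2[i] == "C" and s2[i + 1] == "G" and i not in planted_set:
                arr[i + 1] = b"A"
        sequences[chrom] = arr.tobytes().decode()

    # enhancers: intergenic intervals
    enhancers = []
    for _ in range(config.n_enhancers):
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        start = int(rng.integers(0, config.chrom_length - 600))
        enhancers.append((chrom, start, start + int(rng.integers(200, 600))))

    return GenomeModel(sequences=sequences, genes=genes, enhancers=enhancers)


# ---------------------------------------------------------------------------
# Strain variants


def simulate_strain_variants(genome: GenomeModel, config: SimConfig) -> StrainVariantSet:
    """Homozygous SNPs for the alternate strain, with CpG effect flags.

    Targets ``snp_rate`` per bp overall; a ``frac_cpg_affecting_snps``
    proportion is placed so as to create or destroy a CpG (half/half where
    candidates allow). Flags are computed from the sequence, not from the
    placement intent. Simulated read depth is Poisson(30)+3, genotype 1/1.
    """
    rng = np.random.default_rng(config.seed + 1)
    total = genome.total_length()
    n_target = int(rng.binomial(total, config.snp_rate))
    if n_target < 1:
        warnings.warn("snp_rate * genome length < 1; emitting empty variant set", stacklevel=2)
        return StrainVariantSet([], strain=config.strains[1])
    n_affect = int(rng.binomial(n_target, config.frac_cpg_affecting_snps))
    n_create = n_affect // 2
    n_destroy = n_affect - n_create

    records: list[Variant] = []
    used: dict[str, set[int]] = {c: set() for c in genome.chroms}

    def free(chrom: str, pos: int) -> bool:
        u = used[chrom]
        return all(pos + d not in u for d in (-2, -1, 0, 1, 2))

    def take(chrom: str, pos: int) -> None:
        used[chrom].add(pos)

    for chrom in genome.chroms:
        seq = genome.sequences[chrom]
        # candidate pools
        cpg_pos = [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
        cpg_pos = [cpg_pos[j] for j in rng.permutation(len(cpg_pos))]
        # creation candidates: X followed by G (X != C, X != G at i-1 C check), or C followed by X
        create_cand = []
        for i in range(1, len(seq) - 2):
            if seq[i + 1] == "G" and seq[i] != "C" and seq[i - 1] != "C":
                create_cand.append((i, "C"))
            elif seq[i - 1] == "C" and seq[i] != "G" and seq[i + 1] != "G":
                create_cand.append((i, "G"))
        create_cand = [create_cand[j] for j in rng.permutation(len(create_cand))]

        share = len(seq) / total
        want_destroy = int(round(n_destroy * share))
        want_create = int(round(n_create * share))
        want_neutral = int(round((n_target - n_affect) * share))

        taken_d = 0
        for pos in cpg_pos:
            if taken_d >= want_destroy:
                break
            if not free(chrom, pos):
                continue
            alt = "T" if seq[pos] == "C" else "A"
            records.append(Variant(chrom, pos, seq[pos], alt,
                                   depth=int(rng.poisson(30)) + 3))
            take(chrom, pos)
            taken_d += 1

        taken_c = 0
        for pos, alt in create_cand:
            if taken_c >= want_create:
                break
            if not free(chrom, pos) or seq[pos] == alt:
                continue
            records.append(Variant(chrom, pos, seq[pos], alt,
                                   depth=int(rng.poisson(30)) + 3))
            take(chrom, pos)
            taken_c += 1

        taken_n = 0
        attempts = 0
        while taken_n < want_neutral and attempts < want_neutral * 50:
            attempts += 1
            pos = int(rng.integers(2, len(seq) - 2))
            if not free(chrom, pos):
                continue
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = Variant(chrom, pos, ref, alt, depth=int(rng.poisson(30)) + 3)
            flag_cpg_effect(genome, v)
            if v.cpg_creating or v.cpg_destroying:
                continue
            records.append(v)
            take(chrom, pos)
            taken_n += 1

    for v in records:
        flag_cpg_effect(genome, v)
    records.sort(key=lambda v: (v.chrom, v.pos))
    return StrainVariantSet(records, strain=config.strains[1])


# ---------------------------------------------------------------------------
# Methylation landscape with injected truth


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """PMF of the number of successes among independent Bernoulli(p_i)."""
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return pmf


def _expected_capture(site_pos: np.ndarray, site_probs: np.ndarray,
                      frag_starts: np.ndarray, frag_lens: np.ndarray,
                      capture: CaptureModel) -> float:
    """Mean capture probability over a fixed set of fragment placements.

    Exact in the methylation draw (Poisson-binomial over the fragment's CpG
    sites); Monte-Carlo only over fragment placement, which callers hold
    fixed across evaluations (common random numbers).
    """
    total = 0.0
    for s, ln in zip(frag_starts, frag_lens):
        lo = np.searchsorted(site_pos, s, side="left")
        hi = np.searchsorted(site_pos, s + ln, side="left")
        if hi == lo:
            total += capture.p_background
            continue
        pmf = _poisson_binomial_pmf(site_probs[lo:hi])
        k = np.arange(len(pmf))
        total += float(np.sum(pmf * capture.capture_prob(k)))
    return total / len(frag_starts)


def _region_fragments(rng: np.random.Generator, start: int, end: int, chrom_len: int,
                      capture: CaptureModel, n: int = 400):
    """Fragment placements whose midpoints fall in the region (the counting
    rule downstream), used to calibrate injected effects."""
    lens = _draw_fragment_lengths(rng, capture, n)
    mids = rng.integers(start, end, size=n)
    starts = np.clip(mids - lens // 2, 0, chrom_len - lens)
    return starts, lens


def _draw_fragment_lengths(rng: np.random.Generator, capture: CaptureModel, n: int) -> np.ndarray:
    a = (capture.fragment_min - capture.fragment_mean) / capture.fragment_sd
    b = (capture.fragment_max - capture.fragment_mean) / capture.fragment_sd
    lens = stats.truncnorm.rvs(a, b, loc=capture.fragment_mean, scale=capture.fragment_sd,
                               size=n, random_state=rng)
    return np.round(lens).astype(np.int64)


def simulate_methylation(
    genome: GenomeModel,
    variants: Optional[StrainVariantSet],
    truth_spec: Sequence[TruthRecord],
    config: SimConfig,
    capture: Optional[CaptureModel] = None,
) -> tuple[MethylationProfile, list[TruthRecord]]:
    """Per-arm CpG methylation probabilities with injected truth regions.

    Baseline probabilities are shared by all four arms. Inside each truth
    region the control/DEHP logits are shifted by ±delta/2, with delta solved
    (per strain) so the expected captured-fragment rate ratio of the two arms
    equals ``2**injected_log2fc``; interaction regions get the opposite
    orientation in the second strain. The realized expected-count log-ratio
    is recorded per strain on the returned truth records.
    """
    capture = capture or CaptureModel()
    rng = np.random.default_rng(config.seed + 2)
    strains = config.strains
    sites = {s: enumerate_cpg_sites(genome, variants if s == strains[1] else None, s)
             for s in strains}

    # baseline: moderate methylation, clipped away from 0/1 for finite logits
    baseline: dict[str, dict[str, np.ndarray]] = {}
    for s in strains:
        baseline[s] = {}
        for chrom, pos in sites[s].positions.items():
            baseline[s][chrom] = np.clip(rng.beta(4.0, 4.0, size=len(pos)), 0.02, 0.98)

    arm_probs = {
        (s, t): {c: baseline[s][c].copy() for c in baseline[s]}
        for s in strains for t in ("control", "dehp")
    }

    truth_out: list[TruthRecord] = []
    for rec in truth_spec:
        if rec.chrom not in genome.sequences:
            raise ValueError(f"truth region on unknown chromosome {rec.chrom!r}")
        L = genome.chrom_length(rec.chrom)
        if not (0 <= rec.start < rec.end <= L):
            raise ValueError(f"truth region {rec.chrom}:{rec.start}-{rec.end} outside genome")
        rec = replace(rec, realized_log2fc={})
        frag_starts, frag_lens = _region_fragments(rng, rec.start, rec.end, L, capture)
        target_strains = strains if rec.strain is None else (rec.strain,)
        for si, s in enumerate(strains):
            if s not in target_strains:
                rec.realized_log2fc[s] = 0.0
                continue
            pos = sites[s].positions.get(rec.chrom, np.array([], dtype=np.int64))
            lo = np.searchsorted(pos, rec.start, side="left")
            hi = np.searchsorted(pos, rec.end, side="left")
            if hi == lo or rec.injected_log2fc == 0:
                rec.realized_log2fc[s] = 0.0
                continue
            sign = -1.0 if (rec.interaction and si == 1) else 1.0
            lam = sign * rec.injected_log2fc
            base_logit = _logit(baseline[s][rec.chrom])

            def log_ratio(delta: float) -> float:
                probs_hi = baseline[s][rec.chrom].copy()
                probs_lo = baseline[s][rec.chrom].copy()
                probs_hi[lo:hi] = _sigmoid(base_logit[lo:hi] + delta / 2.0)
                probs_lo[lo:hi] = _sigmoid(base_logit[lo:hi] - delta / 2.0)
                e_hi = _expected_capture(pos, probs_hi, frag_starts, frag_lens, capture)
                e_lo = _expected_capture(pos, probs_lo, frag_starts, frag_lens, capture)
                return math.log2(e_hi / e_lo)

            target = abs(lam)
            d_lo, d_hi = 0.0, 4.0
            while log_ratio(d_hi) < target and d_hi < 64.0:
                d_hi *= 2.0
            if log_ratio(d_hi) < target:
                delta = d_hi  # saturated capture: inject the strongest attainable shift
            else:
                from scipy.optimize import brentq
                delta = brentq(lambda d: log_ratio(d) - target, d_lo, d_hi, xtol=1e-3)
            realized = log_ratio(delta)
            if lam < 0:
                delta, realized = -delta, -realized
            cl = arm_probs[(s, "control")][rec.chrom]
            dl = arm_probs[(s, "dehp")][rec.chrom]
            cl[lo:hi] = _sigmoid(base_logit[lo:hi] + delta / 2.0)
            dl[lo:hi] = _sigmoid(base_logit[lo:hi] - delta / 2.0)
            rec.realized_log2fc[s] = float(realized)
        truth_out.append(rec)

    return MethylationProfile(sites=sites, arm_probs=arm_probs), truth_out


def default_truth_spec(genome: GenomeModel, n_dmr: int = 6, n_interaction: int = 2,
                       log2fc: float = 2.0, seed: int = 0) -> list[TruthRecord]:
    """Promoter-window truth regions on non-class genes: plain DMRs plus
    strain-opposite interaction regions. Regions are kept mutually disjoint
    (with a fragment-length margin) so injected effects never cancel."""
    rng = np.random.default_rng(seed)
    others = [g for g in genome.genes if g.symbol.startswith("Gene")]
    if len(others) < n_dmr + n_interaction:
        others = list(genome.genes)
    order = rng.permutation(len(others))
    margin = 500
    recs: list[TruthRecord] = []
    taken: list[tuple[str, int, int]] = []
    for i in order:
        if len(recs) >= n_dmr + n_interaction:
            break
        g = others[int(i)]
        start, end = promoter_window(g.tss, g.strand, genome.chrom_length(g.chrom))
        if any(c == g.chrom and start < e + margin and s - margin < end
               for c, s, e in taken):
            continue
        j = len(recs)
        sign = 1.0 if j % 2 == 0 else -1.0
        recs.append(TruthRecord(chrom=g.chrom, start=start, end=end,
                                injected_log2fc=sign * log2fc,
                                interaction=(j >= n_dmr)))
        taken.append((g.chrom, start, end))
    return recs


# ---------------------------------------------------------------------------
# Read-pair emission


def build_sample_sheet(config: SimConfig) -> SampleSheet:
    infos = []
    short = {config.strains[0]: "s1", config.strains[1]: "s2"}
    for strain in config.strains:
        for treatment in ("control", "dehp"):
            for r in range(config.n_samples_per_arm):
                infos.append(SampleInfo(
                    sample_id=f"{short[strain]}_{treatment}_{r + 1}",
                    strain=strain, treatment=treatment))
    return SampleSheet(infos)


def _genome_capture_rate(profile: MethylationProfile, genome: GenomeModel,
                         strain: str, treatment: str, capture: CaptureModel,
                         rng: np.random.Generator, n: int = 1500) -> float:
    lens = _draw_fragment_lengths(rng, capture, n)
    chroms = genome.chroms
    weights = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=n, p=weights)
    total = 0.0
    for i in range(n):
        chrom = chroms[picks[i]]
        L = genome.chrom_length(chrom)
        s = int(rng.integers(0, max(1, L - lens[i])))
        pos = profile.sites[strain].positions.get(chrom, np.array([], dtype=np.int64))
        probs = profile.probs(strain, treatment, chrom)
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, s + lens[i], side="left")
        if hi == lo:
            total += capture.p_background
        else:
            pmf = _poisson_binomial_pmf(probs[lo:hi])
            total += float(np.sum(pmf * capture.capture_prob(np.arange(len(pmf)))))
    return total / n


def simulate_mbd_readpairs(
    genome: GenomeModel,
    profile: MethylationProfile,
    capture: CaptureModel,
    config: SimConfig,
    samples: Optional[SampleSheet] = None,
) -> dict[str, list[ReadPairAlignment]]:
    """Emit captured read pairs per sample.

    Fragments are drawn uniformly over the genome with truncated-normal
    lengths; each fragment's CpGs are methylated independently per the
    sample's arm profile and the fragment is retained with the saturating
    capture probability. Library sizes vary log-normally with
    ``libsize_cv``. Small configured fractions of pairs are flagged
    non-unique or displaced into discordance to exercise filtration.
    """
    samples = samples or build_sample_sheet(config)
    rng = np.random.default_rng(config.seed + 3)
    chroms = genome.chroms
    weights = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    sigma = math.sqrt(math.log(1.0 + config.libsize_cv ** 2))
    rl = capture.read_length

    out: dict[str, list[ReadPairAlignment]] = {}
    for info in samples.samples:
        arm_rate = _genome_capture_rate(profile, genome, info.strain, info.treatment,
                                        capture, rng)
        lib_factor = float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma))) if sigma > 0 else 1.0
        n_target = int(round(config.target_pairs_per_sample * lib_factor))
        pairs: list[ReadPairAlignment] = []
        if arm_rate <= 0 or n_target == 0:
            out[info.sample_id] = pairs
            continue
        attempts = int(min(np.ceil(n_target / arm_rate * 1.5), 5e6))
        lens = _draw_fragment_lengths(rng, capture, attempts)
        picks = rng.choice(len(chroms), size=attempts, p=weights)
        u_cap = rng.random(attempts)
        u_multi = rng.random(attempts)
        u_disc = rng.random(attempts)
        site_pos = {c: profile.sites[info.strain].positions.get(c, np.array([], dtype=np.int64))
                    for c in chroms}
        site_p = {c: profile.probs(info.strain, info.treatment, c) for c in chroms}
        n_emit = 0
        for i in range(attempts):
            if n_emit >= n_target:
                break
            chrom = chroms[picks[i]]
            L = genome.chrom_length(chrom)
            ln = int(lens[i])
            s = int(rng.integers(0, max(1, L - ln)))
            pos = site_pos[chrom]
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, s + ln, side="left")
            k = int((rng.random(hi - lo) < site_p[chrom][lo:hi]).sum()) if hi > lo else 0
            if u_cap[i] >= float(capture.capture_prob(k)):
                continue
            name = f"{info.sample_id}:{n_emit}"
            unique = u_multi[i] >= config.frac_multimapped
            s2, e2 = s + ln - rl, s + ln
            if u_disc[i] < config.frac_discordant and s + ln + 1200 < L:
                s2, e2 = s2 + 1200, e2 + 1200  # displaced mate: inner gap > 600
            pairs.append(ReadPairAlignment(
                chrom1=chrom, start1=s, end1=s + rl,
                chrom2=chrom, start2=s2, end2=e2,
                name=name, unique=unique, sample_id=info.sample_id))
            n_emit += 1
        out[info.sample_id] = pairs
    return out


def simulate_dataset(config: SimConfig, capture: Optional[CaptureModel] = None,
                     truth_spec: Optional[Sequence[TruthRecord]] = None) -> SimResult:
    """Full generator pipeline: genome, variants, methylation, read pairs."""
    capture = capture or CaptureModel()
    genome = simulate_genome(config)
    variants = simulate_strain_variants(genome, config)
    if truth_spec is None:
        truth_spec = default_truth_spec(genome, seed=config.seed + 4)
    profile, truth = simulate_methylation(genome, variants, truth_spec, config, capture)
    samples = build_sample_sheet(config)
    pairs = simulate_mbd_readpairs(genome, profile, capture, config, samples)
    return SimResult(config=config, capture=capture, genome=genome, variants=variants,
                     profile=profile, truth=truth, samples=samples, pairs_by_sample=pairs)


def write_dataset(sim: SimResult, outdir) -> None:
    """Write the simulated dataset in interchange formats (FASTA, BED, VCF,
    BEDPE per sample, truth TSV, sample sheet)."""
    from . import formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    formats.write_fasta(sim.genome.sequences, outdir / "genome.fa")
    formats.write_genes_bed12(sim.genome.genes, outdir / "genes.bed")
    formats.write_bed6(sim.genome.enhancers, outdir / "enhancers.bed")
    lengths = {c: sim.genome.chrom_length(c) for c in sim.genome.chroms}
    formats.write_vcf(sim.variants, lengths, outdir / "variants.vcf",
                      sample_name=sim.config.strains[1].replace("/", "_"))
    infos = []
    for info in sim.samples.samples:
        path = outdir / f"{info.sample_id}.bedpe"
        formats.write_bedpe(sim.pairs_by_sample[info.sample_id], path)
        infos.append(SampleInfo(info.sample_id, info.strain, info.treatment, str(path)))
    formats.write_sample_sheet(SampleSheet(infos), outdir / "samples.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tinjected_log2fc\tinteraction\t" +
                 "\t".join(f"realized_log2fc_{i}" for i in (1, 2)) + "\n")
        for r in sim.truth:
            realized = [r.realized_log2fc.get(s, 0.0) for s in sim.config.strains]
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.injected_log2fc}\t"
                     f"{int(r.interaction)}\t" + "\t".join(f"{x:.4f}" for x in realized) + "\n")
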