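"""Synthetic genomes, ChIP libraries, expression counts, and reporter tables.

Every downstream stage of the package is exercised on data with a known
answer.  The generator emulates the statistical structure of the study
system:

* a toy genome partitioned into the four chromatin classes, with
  geometric segment lengths (memoryless, configurable mean);
* IP/Input read pairs in which the IP read density per base is proportional
  to a per-class enrichment multiplier (background = 1) and a constant
  spike-in chromatin admixture is carried on dedicated ``spike``
  chromosomes, mirroring hybrid-genome alignment of a two-species library;
* negative-binomial expression counts with class-dependent fold effects
  between two conditions;
* normally-noised reporter fluorescence with a configurable heat-shock
  induction and multiplicative silencing factor.

The IP spike fraction is *derived*, not set: spike read mass is held fixed
while target IP mass scales with the genome-wide mean multiplier, so a
global gain of target signal dilutes the IP spike fraction -- exactly the
signal that spike-in (ChIP-Rx style) normalization exploits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from germchrom.domains import CLASSES, DomainSegment, GeneModel
from germchrom.util import derive_seed

SPIKE_CHROM = "spike1"


@dataclass(frozen=True, slots=True)
class TaggedRead:
    """An aligned read tagged with its species of origin.

    ``species`` is ``"target"`` (study genome) or ``"spike"`` (exogenous
    spike-in chromatin, aligned to dedicated spike chromosomes).
    """

    species: str
    chrom: str
    start: int
    end: int


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults are the study conditions the downstream analyses are verified
    against: an approximately tenfold IP enrichment of PcG chromatin over
    background with mildly enriched inactive/Hp1 chromatin and depleted
    active chromatin; sequencing depths of 5x10^5 reads per library; a 10%
    spike-in admixture; negative-binomial counts around a few hundred reads
    per gene; and a reporter induction of 100 fluorescence units over
    background with 5-unit Gaussian noise.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    state_mean_length: int = 20_000
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "active": 0.45,
            "inactive": 0.35,
            "PcG": 0.10,
            "Hp1": 0.10,
        }
    )
    enrichment_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "active": 0.2,
            "inactive": 2.0,
            "PcG": 10.0,
            "Hp1": 2.0,
        }
    )
    read_length: int = 75
    ip_depth: int = 500_000
    input_depth: int = 500_000
    spike_fraction: float = 0.10
    genes_per_class: int = 500
    expression_mean: float = 200.0
    expression_dispersion: float = 0.1
    class_log2fc: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CLASSES}
    )
    reporter_background: float = 10.0
    reporter_base_induction: float = 100.0
    silencing_factor: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("chromosome count and length must be positive")
        if self.state_mean_length <= 0 or self.read_length <= 0:
            raise ValueError("segment mean length and read length must be positive")
        if self.ip_depth < 0 or self.input_depth < 0:
            raise ValueError("library depths must be non-negative")
        if not math.isclose(sum(self.class_weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_weights must sum to 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class_weights must be non-negative")
        if not (0.0 <= self.spike_fraction < 1.0):
            raise ValueError("spike_fraction must lie in [0, 1)")
        if not (0.0 < self.silencing_factor <= 1.0):
            raise ValueError("silencing_factor must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.genes_per_class < 0:
            raise ValueError("genes_per_class must be non-negative")


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(config.seed, stage))


def generate_genome(
    config: SyntheticConfig,
) -> tuple[list[DomainSegment], list[GeneModel]]:
    """Partition each chromosome into class-labeled segments and place genes.

    Segment lengths are geometric with the configured mean; adjacent
    segments always differ in class; the final segment is truncated so the
    partition sums exactly to the chromosome length.  Each gene's collapsed
    interval lies entirely within one segment of its intended class;
    isoforms extend the collapsed interval by random slop on either side.
    """
    if config.chrom_length < config.state_mean_length:
        raise ValueError("chrom_length smaller than one mean segment length")
    rng = _rng(config, "genome")
    classes = list(CLASSES)
    weights = np.array([config.class_weights[c] for c in classes])
    segments: list[DomainSegment] = []
    p = 1.0 / config.state_mean_length
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        pos = 0
        prev: str | None = None
        while pos < config.chrom_length:
            length = int(rng.geometric(p))
            end = min(pos + length, config.chrom_length)
            while True:
                cls = classes[rng.choice(len(classes), p=weights)]
                if cls != prev:
                    break
            segments.append(DomainSegment(chrom, pos, end, cls))
            prev = cls
            pos = end

    genes: list[GeneModel] = []
    by_class: dict[str, list[DomainSegment]] = {c: [] for c in classes}
    for seg in segments:
        if len(seg) >= 200:
            by_class[seg.cls].append(seg)
    for cls in classes:
        pool = by_class[cls]
        if not pool:
            if config.genes_per_class > 0:
                warnings.warn(
                    f"no segment of class {cls} large enough to host genes; "
                    "class skipped"
                )
            continue
        lengths = np.array([len(s) for s in pool], dtype=float)
        probs = lengths / lengths.sum() if pool else None
        for g in range(config.genes_per_class):
            seg = pool[rng.choice(len(pool), p=probs)]
            lo = min(500, len(seg))
            hi = min(5000, len(seg))
            glen = int(rng.integers(lo, hi + 1)) if hi > lo else hi
            gstart = seg.start + int(rng.integers(0, len(seg) - glen + 1))
            collapsed = (seg.chrom, gstart, gstart + glen)
            n_iso = int(rng.integers(1, 4))
            isoforms = [collapsed]
            for _ in range(n_iso - 1):
                left = int(rng.integers(0, 2001))
                right = int(rng.integers(0, 2001))
                isoforms.append(
                    (
                        seg.chrom,
                        max(0, gstart - left),
                        min(config.chrom_length, gstart + glen + right),
                    )
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g_{cls}_{g}",
                    isoforms=isoforms,
                    collapsed=collapsed,
                    cls=cls,
                    length_for_tpm=glen,
                    strand=strand,
                )
            )
    return segments, genes


def mean_multiplier(
    segments: list[DomainSegment], multipliers: dict[str, float]
) -> float:
    """Length-weighted genome-wide mean of the per-class IP multipliers."""
    total = sum(len(s) for s in segments)
    return sum(len(s) * multipliers[s.cls] for s in segments) / total


def ip_spike_fraction(
    spike_fraction: float,
    segments: list[DomainSegment],
    multipliers: dict[str, float],
) -> float:
    """Expected spike read fraction in the IP library.

    Spike chromatin mass is held fixed while target IP mass scales with the
    genome-wide mean multiplier <m>: with input spike odds S/T =
    f/(1 - f), the IP fraction is (S/T) / (S/T + <m>).
    """
    if spike_fraction == 0.0:
        return 0.0
    odds = spike_fraction / (1.0 - spike_fraction)
    return odds / (odds + mean_multiplier(segments, multipliers))


def _place_uniform(
    rng: np.random.Generator,
    n: int,
    chrom_lengths: dict[str, int],
    read_length: int,
    species: str,
) -> list[TaggedRead]:
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    out: list[TaggedRead] = []
    for i, ci in enumerate(idx):
        chrom = chroms[ci]
        L = chrom_lengths[chrom]
        start = int(rng.integers(0, L))
        out.append(TaggedRead(species, chrom, start, min(start + read_length, L)))
    return out


def simulate_chip_pair(
    segments: list[DomainSegment],
    config: SyntheticConfig,
    multipliers: dict[str, float] | None = None,
    stage: str = "chip",
) -> tuple[list[TaggedRead], list[TaggedRead]]:
    """Simulate one IP/Input library pair with spike-in.

    Input target reads are uniform over the genome; IP target reads are
    placed with per-base rate proportional to the class multiplier
    (``multipliers`` overrides the configured ones, e.g. for a knockdown).
    Spike reads live on a dedicated spike chromosome; their expected
    fraction equals ``spike_fraction`` in Input and the derived
    :func:`ip_spike_fraction` in IP.  Each returned library has exactly the
    configured depth.
    """
    if not segments:
        raise ValueError("empty segment list")
    mult = multipliers if multipliers is not None else config.enrichment_multipliers
    rng = _rng(config, stage)
    chrom_lengths: dict[str, int] = {}
    for seg in segments:
        chrom_lengths[seg.chrom] = max(chrom_lengths.get(seg.chrom, 0), seg.end)
    spike_lengths = {SPIKE_CHROM: config.chrom_length}

    # Input library: uniform target placement + spike admixture.
    n_spike_in = int(round(config.input_depth * config.spike_fraction))
    n_target_in = config.input_depth - n_spike_in
    input_reads = _place_uniform(
        rng, n_target_in, chrom_lengths, config.read_length, "target"
    )
    input_reads += _place_uniform(
        rng, n_spike_in, spike_lengths, config.read_length, "spike"
    )

    # IP library: segment sampled by length x multiplier, then uniform within.
    f_ip = ip_spike_fraction(config.spike_fraction, segments, mult)
    n_spike_ip = int(round(config.ip_depth * f_ip))
    n_target_ip = config.ip_depth - n_spike_ip
    ip_reads: list[TaggedRead] = []
    if n_target_ip > 0:
        mass = np.array([len(s) * mult[s.cls] for s in segments], dtype=float)
        seg_idx = rng.choice(len(segments), size=n_target_ip, p=mass / mass.sum())
        offsets = rng.random(n_target_ip)
        for si, u in zip(seg_idx, offsets):
            seg = segments[si]
            start = seg.start + int(u * len(seg))
            end = min(start + config.read_length, chrom_lengths[seg.chrom])
            ip_reads.append(TaggedRead("target", seg.chrom, start, end))
    ip_reads += _place_uniform(
        rng, n_spike_ip, spike_lengths, config.read_length, "spike"
    )
    return ip_reads, input_reads


def simulate_expression(
    genes: list[GeneModel],
    config: SyntheticConfig,
    n_reps_per_condition: int = 3,
    stage: str = "expression",
):
    """Negative-binomial gene x sample counts for two conditions.

    Condition-1 means are per-gene baselines (log-normal spread around the
    configured mean); condition-2 means multiply the baseline by
    ``2**class_log2fc`` for the gene's class.  Variance follows the NB
    mean-dispersion relation Var = mu + dispersion * mu^2.
    """
    # imported here to keep module dependencies acyclic
    from germchrom.expression import ExpressionMatrix

    if n_reps_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if config.expression_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(config, stage)
    n_genes = len(genes)
    # per-gene baseline spread; sigma 0.5 gives a realistic dynamic range
    baselines = config.expression_mean * rng.lognormal(-0.125, 0.5, size=n_genes)
    lfc = np.array([config.class_log2fc.get(g.cls, 0.0) for g in genes])
    size = 1.0 / config.expression_dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        p = size / (size + mu)
        return rng.negative_binomial(size, p)

    columns = {}
    sample_condition = {}
    for r in range(n_reps_per_condition):
        name = f"cond1_rep{r + 1}"
        columns[name] = draw(baselines)
        sample_condition[name] = "cond1"
    mu2 = baselines * np.power(2.0, lfc)
    for r in range(n_reps_per_condition):
        name = f"cond2_rep{r + 1}"
        columns[name] = draw(mu2)
        sample_condition[name] = "cond2"

    import pandas as pd

    counts = pd.DataFrame(columns, index=[g.gene_id for g in genes])
    gene_meta = pd.DataFrame(
        {
            "cls": [g.cls for g in genes],
            "length": [max(g.length_for_tpm, 1) for g in genes],
        },
        index=[g.gene_id for g in genes],
    )
    sample_meta = pd.DataFrame(
        {"condition": pd.Series(sample_condition)},
    )
    return ExpressionMatrix(counts=counts, gene_meta=gene_meta, sample_meta=sample_meta)


def simulate_reporter(
    lines: list[str],
    stages: list[str],
    genotypes: list[str],
    config: SyntheticConfig,
    n_replicates: int = 6,
    silencing=None,
    n_baseline_replicates: int | None = None,
    stage: str = "reporter",
):
    """Per-ovary reporter fluorescence records for a line/stage/genotype grid.

    Non-heat-shocked intensity ~ Normal(background, noise_sd); heat-shocked
    intensity ~ Normal(background + base_induction * s, noise_sd) where the
    silencing factor ``s`` may be a scalar or a callable
    ``s(line, stage, genotype)``.  Intensities are floored at zero.

    ``n_baseline_replicates`` sizes the non-heat-shocked arm separately
    (default: same as ``n_replicates``).  In the assay the baseline pools
    every non-heat-shocked cell of a stage, so it is often estimated from
    more measurements than there are induction replicates -- which matters
    for the downstream t-test's calibration (see the induction-statistic
    notes in the package docs).
    """
    from germchrom.reporter import ReporterRecord

    if n_replicates < 3:
        raise ValueError("need >= 3 replicates per cell of the design")
    if n_baseline_replicates is None:
        n_baseline_replicates = n_replicates
    if n_baseline_replicates < 1:
        raise ValueError("need >= 1 baseline replicate")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if silencing is None:
        silencing = config.silencing_factor
    sfun = silencing if callable(silencing) else (lambda l, s, g: silencing)
    rng = _rng(config, stage)
    records: list[ReporterRecord] = []
    for line in lines:
        for st in stages:
            for gt in genotypes:
                s = float(sfun(line, st, gt))
                for hs in (False, True):
                    mu = config.reporter_background + (
                        config.reporter_base_induction * s if hs else 0.0
                    )
                    n = n_replicates if hs else n_baseline_replicates
                    vals = rng.normal(mu, config.noise_sd, size=n)
                    for r, v in enumerate(vals):
                        records.append(
                            ReporterRecord(
                                line_id=line,
                                stage=st,
                                genotype=gt,
                                heat_shock=hs,
                                intensity=max(0.0, float(v)),
                                replicate_id=f"rep{r + 1}",
                            )
                        )
    return records


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
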