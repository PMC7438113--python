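"""Readers, writers, pipeline configuration, and end-to-end orchestration.

Interval files are BED (0-based, half-open, 3-12 columns tolerated); tabular
outputs are TSV with '#'-prefixed metadata lines before the column header.
``run_pipeline`` chains the synthetic generator through every analysis stage
and writes a machine-readable manifest (parameters, input sizes, sha256
digests of every output) so identical configurations are verifiably
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from germchrom import __version__ as _pkg_version
from germchrom.domains import (
    DomainSegment,
    ExclusionMask,
    GeneModel,
    GenomicBin,
    annotate_bins,
    flag_pre_bins,
    make_bins,
)
from germchrom.enrichment import (
    SampleLibrary,
    call_domains,
    enrichment_table,
    fold_change_summary,
    share_domains,
)
from germchrom.expression import (
    gene_fold_change,
    relative_median_trajectory,
    size_factors,
    tpm,
)
from germchrom.reporter import ReporterRecord, contrast_table, trajectory_table
from germchrom.synthetic import (
    SyntheticConfig,
    TaggedRead,
    generate_genome,
    simulate_chip_pair,
    simulate_expression,
    simulate_reporter,
)
from germchrom.util import derive_seed

log = logging.getLogger("germchrom")


class BedParseError(ValueError):
    pass


@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None
    extra: tuple[str, ...] = ()

    def fields(self) -> list[str]:
        out = [self.chrom, str(self.start), str(self.end)]
        opt = [self.name, self.score, self.strand]
        # keep a contiguous prefix of the optional columns
        while opt and opt[-1] is None:
            opt.pop()
        out += ["." if v is None else str(v) for v in opt]
        out += list(self.extra)
        return out


def read_bed(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> list[BedInterval]:
    """Parse a BED3-BED12 file; parse errors name the offending line."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            if start < 0:
                raise BedParseError(f"line {lineno}: negative start coordinate")
            if end <= start:
                raise BedParseError(f"line {lineno}: end <= start")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise BedParseError(f"line {lineno}: unknown chromosome {chrom!r}")
            name = parts[3] if len(parts) > 3 else None
            score = parts[4] if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 else None
            out.append(
                BedInterval(
                    chrom, start, end, name, score, strand, tuple(parts[6:])
                )
            )
    return out


def write_bed(path: str | Path, intervals: Iterable[BedInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(iv.fields()) + "\n")


# -- typed wrappers over BED/TSV ------------------------------------------


def write_segments(path: str | Path, segments: Sequence[DomainSegment]) -> None:
    """Segments as BED4 (4th column = chromatin class)."""
    write_bed(
        path, (BedInterval(s.chrom, s.start, s.end, s.cls) for s in segments)
    )


def read_segments(path: str | Path) -> list[DomainSegment]:
    return [
        DomainSegment(iv.chrom, iv.start, iv.end, iv.name)
        for iv in read_bed(path)
    ]


def write_bins(path: str | Path, bins: Sequence[GenomicBin]) -> None:
    """Bins as BED5 (name = class, score column = PRE flag)."""
    write_bed(
        path,
        (
            BedInterval(b.chrom, b.start, b.end, b.cls or ".", str(int(b.pre_flag)))
            for b in bins
        ),
    )


def read_bins(path: str | Path) -> list[GenomicBin]:
    out = []
    for iv in read_bed(path):
        cls = None if iv.name in (None, ".") else iv.name
        flag = bool(int(iv.score)) if iv.score not in (None, ".") else False
        out.append(GenomicBin(iv.chrom, iv.start, iv.end, cls, flag))
    return out


def write_reads(path: str | Path, reads: Iterable[TaggedRead]) -> None:
    """Reads as BED4 (name = species tag)."""
    write_bed(
        path, (BedInterval(r.chrom, r.start, r.end, r.species) for r in reads)
    )


def read_reads(path: str | Path) -> list[TaggedRead]:
    return [
        TaggedRead(iv.name or "target", iv.chrom, iv.start, iv.end)
        for iv in read_bed(path)
    ]


def write_genes(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Genes as TSV: one row per gene, isoforms packed as start-end pairs."""
    rows = []
    for g in genes:
        chrom = g.isoforms[0][0]
        c_start, c_end = (g.collapsed[1], g.collapsed[2]) if g.collapsed else (-1, -1)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": chrom,
                "strand": g.strand,
                "cls": g.cls or ".",
                "collapsed_start": c_start,
                "collapsed_end": c_end,
                "length_for_tpm": g.length_for_tpm,
                "isoforms": ";".join(f"{s}-{e}" for _, s, e in g.isoforms),
            }
        )
    write_tsv(path, pd.DataFrame(rows), meta={"format": "gene-models"})


def read_genes(path: str | Path) -> list[GeneModel]:
    frame = read_tsv(path)
    genes = []
    for _, row in frame.iterrows():
        isoforms = [
            (row["chrom"], int(p.split("-")[0]), int(p.split("-")[1]))
            for p in str(row["isoforms"]).split(";")
        ]
        collapsed = (
            None
            if int(row["collapsed_start"]) < 0
            else (row["chrom"], int(row["collapsed_start"]), int(row["collapsed_end"]))
        )
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                isoforms=isoforms,
                collapsed=collapsed,
                cls=None if row["cls"] == "." else row["cls"],
                length_for_tpm=int(row["length_for_tpm"]),
                strand=row["strand"],
            )
        )
    return genes


def write_tsv(
    path: str | Path, frame: pd.DataFrame, meta: dict | None = None, index: bool = False
) -> None:
    """TSV with '#'-prefixed metadata lines before the header row."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_reporter(path: str | Path, records: Sequence[ReporterRecord]) -> None:
    frame = pd.DataFrame(
        {
            "line_id": [r.line_id for r in records],
            "stage": [r.stage for r in records],
            "genotype": [r.genotype for r in records],
            "heat_shock": [int(r.heat_shock) for r in records],
            "intensity": [r.intensity for r in records],
            "replicate_id": [r.replicate_id for r in records],
        }
    )
    write_tsv(path, frame, meta={"format": "reporter-records"})


def read_reporter(path: str | Path) -> list[ReporterRecord]:
    frame = read_tsv(path)
    return [
        ReporterRecord(
            line_id=row["line_id"],
            stage=row["stage"],
            genotype=row["genotype"],
            heat_shock=bool(row["heat_shock"]),
            intensity=float(row["intensity"]),
            replicate_id=str(row["replicate_id"]),
        )
        for _, row in frame.iterrows()
    ]


# -- pipeline config and orchestration ------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic inputs + analysis knobs)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    bin_width: int = 5000
    bin_step: int = 500
    spike_norm: bool = True
    domain_threshold: float = 2.0
    min_domain_span: int = 10_000
    pseudocount: float | None = None
    n_boot: int = 200
    prior_count: float = 0.5
    n_reps_per_condition: int = 3
    knockdown_multipliers: dict[str, float] | None = None
    seed: int = 0
    out_dir: str = "germchrom_out"

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.bin_step <= 0:
            raise ValueError("bin width and step must be positive")
        if self.domain_threshold <= 0:
            raise ValueError("domain threshold must be positive")
        if self.n_boot <= 0:
            raise ValueError("n_boot must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        return cls(synthetic=syn, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic dataset and write the output bundle.

    Stages: genome simulation -> binning/classification -> control and
    knockdown ChIP enrichment -> domain calls and sharing -> per-class
    fold-change summary -> expression fold changes and relative-median
    trajectory -> reporter trajectory and contrasts.  Returns the manifest
    (also written as JSON), which records parameters, stage sizes, the
    spike normalization factors used, and a sha256 digest per output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = dataclasses.replace(config.synthetic, seed=derive_seed(config.seed, "synthetic"))
    manifest: dict = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    log.info("stage genome: %d chromosomes x %d b", syn.n_chromosomes, syn.chrom_length)
    segments, genes = generate_genome(syn)
    write_segments(out / "segments.bed", segments)
    write_genes(out / "genes.tsv", genes)
    chrom_sizes = {f"chr{i+1}": syn.chrom_length for i in range(syn.n_chromosomes)}
    manifest["stages"]["genome"] = {"n_segments": len(segments), "n_genes": len(genes)}

    log.info("stage bins: width %d step %d", config.bin_width, config.bin_step)
    bins = make_bins(chrom_sizes, config.bin_width, config.bin_step)
    bins = annotate_bins(bins, segments)
    # PRE summits: one per PcG segment midpoint in the synthetic genome
    summits = [
        (s.chrom, (s.start + s.end) // 2) for s in segments if s.cls == "PcG"
    ]
    bins = flag_pre_bins(bins, summits)
    write_bins(out / "bins.bed", bins)
    from collections import Counter

    class_counts = Counter(b.cls for b in bins)
    log.debug("per-class bin counts: %s", dict(class_counts))
    manifest["stages"]["bins"] = {
        "n_bins": len(bins),
        "class_counts": {str(k): v for k, v in class_counts.items()},
        "n_summits": len(summits),
    }

    log.info("stage chip: control and knockdown IP/Input pairs")
    ip_c, in_c = simulate_chip_pair(segments, syn, stage="chip-control")
    kd_mult = config.knockdown_multipliers
    if kd_mult is None:
        kd_mult = dict(syn.enrichment_multipliers)
        kd_mult["PcG"] = kd_mult["PcG"] / 2.0  # default: halve PcG IP rate
    ip_k, in_k = simulate_chip_pair(segments, syn, multipliers=kd_mult, stage="chip-kd")
    lib_ip_c = SampleLibrary("control_IP", "IP", ip_c)
    lib_in_c = SampleLibrary("control_Input", "Input", in_c)
    lib_ip_k = SampleLibrary("kd_IP", "IP", ip_k)
    lib_in_k = SampleLibrary("kd_Input", "Input", in_k)
    write_reads(out / "reads_control_ip.bed", ip_c)
    write_reads(out / "reads_control_input.bed", in_c)

    spike_norm = config.spike_norm and syn.spike_fraction > 0
    table_c = enrichment_table(
        lib_ip_c, lib_in_c, bins, spike_norm=spike_norm, epsilon=config.pseudocount
    )
    table_k = enrichment_table(
        lib_ip_k, lib_in_k, bins, spike_norm=spike_norm, epsilon=config.pseudocount
    )
    for name, tab in (("control", table_c), ("kd", table_k)):
        frame = tab.to_frame()
        write_tsv(
            out / f"enrichment_{name}.tsv",
            frame,
            meta={"alpha": tab.alpha, "epsilon": tab.epsilon},
        )
        bg = frame[["chrom", "start", "end", "enrichment"]]
        bg.to_csv(
            out / f"enrichment_{name}.bedgraph", sep="\t", index=False, header=False
        )
    manifest["stages"]["chip"] = {
        "alpha_control": table_c.alpha,
        "alpha_kd": table_k.alpha,
        "spike_norm": spike_norm,
    }

    log.info("stage domains: threshold %.2f", config.domain_threshold)
    calls = {
        "control": call_domains(
            segments, table_c, config.domain_threshold, config.min_domain_span
        ),
        "kd": call_domains(
            segments, table_k, config.domain_threshold, config.min_domain_span
        ),
    }
    call_rows = []
    for sample, cs in calls.items():
        for c in cs:
            call_rows.append(
                {
                    "sample": sample,
                    "chrom": c.domain.chrom,
                    "start": c.domain.start,
                    "end": c.domain.end,
                    "cls": c.domain.cls,
                    "mean_enrichment": c.mean_enrichment,
                    "enriched": "" if c.enriched is None else int(c.enriched),
                    "n_bins": c.n_bins,
                }
            )
    write_tsv(out / "domain_calls.tsv", pd.DataFrame(call_rows))
    sharing = share_domains(calls)
    write_tsv(
        out / "domain_sharing.tsv",
        pd.DataFrame(
            [
                {
                    "shared_all": sharing["shared_all"],
                    "union": sharing["union"],
                    "pct_shared": sharing["pct_shared"],
                }
            ]
        ),
    )
    manifest["stages"]["domains"] = {
        k: sharing[k] for k in ("shared_all", "union", "pct_shared")
    }

    lfc, fc_summary = fold_change_summary(
        table_k, table_c, classes=("active", "inactive", "PcG"), split_pre=True
    )
    write_tsv(out / "bin_fold_change_summary.tsv", fc_summary, index=True)

    log.info("stage expression: %d genes", len(genes))
    expr = simulate_expression(genes, syn, config.n_reps_per_condition)
    write_tsv(out / "counts.tsv", expr.counts, index=True)
    write_tsv(out / "gene_meta.tsv", expr.gene_meta, index=True)
    tpm_table = tpm(expr.counts, expr.gene_meta["length"])
    write_tsv(out / "tpm.tsv", tpm_table, index=True)
    factors = size_factors(expr.counts)
    fc = gene_fold_change(
        expr.counts,
        expr.samples_for("cond2"),
        expr.samples_for("cond1"),
        factors=factors,
        prior_count=config.prior_count,
    )
    write_tsv(out / "gene_fold_change.tsv", fc.to_frame(), index=True)
    traj = relative_median_trajectory(
        {"cond2": fc},
        expr.gene_meta["cls"],
        n_boot=config.n_boot,
        seed=derive_seed(config.seed, "bootstrap"),
    )
    write_tsv(out / "relative_median_trajectory.tsv", traj)
    manifest["stages"]["expression"] = {
        "n_genes": len(genes),
        "size_factors": {k: float(v) for k, v in factors.items()},
    }

    log.info("stage reporter")
    records = simulate_reporter(
        ["line1"], ["GSC", "St5"], ["control", "kd"], syn, stage="reporter"
    )
    write_reporter(out / "reporter_records.tsv", records)
    write_tsv(
        out / "reporter_trajectory.tsv",
        trajectory_table(records, stage_order=["GSC", "St5"]),
    )
    write_tsv(
        out / "reporter_contrasts.tsv", contrast_table(records, "control")
    )
    manifest["stages"]["reporter"] = {"n_records": len(records)}

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
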