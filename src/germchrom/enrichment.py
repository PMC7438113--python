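"""Spike-in-normalized per-bin ChIP enrichment and domain-level summaries.

The central quantity is the per-bin enrichment

    E_b = (alpha * RPM_IP_b + eps) / (RPM_Input_b + eps)

where RPM is reads per million sequenced in the library, ``eps`` is a small
pseudocount (default: the RPM equivalent of one read in the smaller
library), and ``alpha`` is the spike-in normalization factor

    alpha = (spike fraction in Input) / (spike fraction in IP).

Because a genome-wide gain of target signal dilutes the IP spike fraction,
multiplying IP coverage by ``alpha`` restores absolute scale: total-signal
differences between samples survive the per-million scaling.  Reads are
assigned to every overlapping bin whose interval contains the read midpoint,
so with a 5 kb / 500 b lattice each read lands in up to ten bins.

Domain-level calls average E over the class-assigned bins lying fully inside
a domain and threshold the mean; sharing summaries count domains enriched in
all, some, or none of a set of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from germchrom.domains import CLASSES, MIXED, DomainSegment, GenomicBin
from germchrom.synthetic import TaggedRead


@dataclass
class SampleLibrary:
    """A sequencing library: tagged reads plus species tallies.

    Midpoint arrays are cached per chromosome for fast interval counting;
    only ``species == "target"`` reads are ever counted against genomic
    bins.
    """

    sample_id: str
    role: str  # "IP" or "Input"
    reads: list[TaggedRead]
    _midpoints: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def target_count(self) -> int:
        return sum(1 for r in self.reads if r.species == "target")

    @property
    def spike_count(self) -> int:
        return sum(1 for r in self.reads if r.species == "spike")

    @property
    def total(self) -> int:
        return len(self.reads)

    @property
    def spike_fraction(self) -> float:
        return self.spike_count / self.total if self.total else 0.0

    def midpoints(self) -> dict[str, np.ndarray]:
        """Sorted target-read midpoints per chromosome (cached)."""
        if self._midpoints is None:
            by: dict[str, list[int]] = {}
            for r in self.reads:
                if r.species == "target":
                    by.setdefault(r.chrom, []).append((r.start + r.end) // 2)
            self._midpoints = {
                c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()
            }
        return self._midpoints


@dataclass
class EnrichmentTable:
    """Per-bin spike-normalized IP/Input enrichment for one sample."""

    bins: list[GenomicBin]
    alpha: float
    epsilon: float
    enrichment: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if len(self.bins) != len(self.enrichment):
            raise ValueError("bins and enrichment length mismatch")

    def classes(self) -> np.ndarray:
        return np.asarray([b.cls for b in self.bins], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "cls": [b.cls for b in self.bins],
                "pre_flag": [b.pre_flag for b in self.bins],
                "enrichment": self.enrichment,
            }
        )


@dataclass
class DomainCall:
    """Enrichment call for one domain.

    ``enriched`` is ``None`` (undefined) when the domain contains no usable
    bin; the invariant enriched <=> mean_enrichment >= threshold holds
    whenever the call is defined.
    """

    domain: DomainSegment
    mean_enrichment: float
    enriched: bool | None
    threshold: float
    n_bins: int = 0


def count_reads_per_bin(
    library: SampleLibrary, bins: Sequence[GenomicBin]
) -> np.ndarray:
    """Count target-read midpoints falling in each bin.

    A read contributes to *every* bin containing its midpoint (overlapping
    bins each count it); spike reads never count.
    """
    mids = library.midpoints()
    counts = np.zeros(len(bins), dtype=np.int64)
    # group bin indices per chromosome for vectorized searchsorted
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        by_chrom.setdefault(b.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        m = mids.get(chrom)
        if m is None or len(m) == 0:
            continue
        starts = np.asarray([bins[i].start for i in idx])
        ends = np.asarray([bins[i].end for i in idx])
        counts[idx] = np.searchsorted(m, ends, side="left") - np.searchsorted(
            m, starts, side="left"
        )
    return counts


def rpm_scale(counts: np.ndarray, total: int) -> np.ndarray:
    """Scale raw counts to reads per million of ``total`` sequenced reads."""
    if total <= 0:
        raise ValueError("library total must be positive for RPM scaling")
    return np.asarray(counts, dtype=float) * 1e6 / total


def spike_normalization_factor(ip: SampleLibrary, input: SampleLibrary) -> float:
    """Spike-in normalization factor alpha applied to IP coverage.

    alpha = (spike_count_input / total_input) / (spike_count_ip / total_ip).
    Equal spike fractions give alpha = 1; a diluted IP spike fraction (the
    signature of a genome-wide gain in target signal) gives alpha > 1.
    """
    if ip.spike_count == 0 or input.spike_count == 0:
        raise ValueError(
            "no spike-in reads in IP or Input; run without spike normalization "
            "(alpha = 1) instead"
        )
    return (input.spike_count / input.total) / (ip.spike_count / ip.total)


def default_pseudocount(ip: SampleLibrary, input: SampleLibrary) -> float:
    """RPM equivalent of a single read in the smaller library."""
    smaller = min(ip.total, input.total)
    if smaller <= 0:
        raise ValueError("cannot derive pseudocount from an empty library")
    return 1e6 / smaller


def bin_enrichment(
    bins: Sequence[GenomicBin],
    ip_rpm: np.ndarray,
    input_rpm: np.ndarray,
    alpha: float = 1.0,
    epsilon: float = 0.0,
) -> EnrichmentTable:
    """Per-bin enrichment E = (alpha * RPM_IP + eps) / (RPM_Input + eps)."""
    ip_rpm = np.asarray(ip_rpm, dtype=float)
    input_rpm = np.asarray(input_rpm, dtype=float)
    if len(ip_rpm) != len(input_rpm) or len(ip_rpm) != len(bins):
        raise ValueError("IP, Input, and bin lists must align")
    if epsilon == 0.0 and np.any(input_rpm == 0):
        raise ValueError("zero Input coverage with zero pseudocount")
    e = (alpha * ip_rpm + epsilon) / (input_rpm + epsilon)
    return EnrichmentTable(list(bins), alpha, epsilon, e)


def enrichment_table(
    ip: SampleLibrary,
    input: SampleLibrary,
    bins: Sequence[GenomicBin],
    spike_norm: bool = True,
    epsilon: float | None = None,
) -> EnrichmentTable:
    """Full per-bin enrichment computation from two libraries.

    Counts target-read midpoints per bin, scales to RPM of each library's
    total sequenced reads, applies the spike normalization factor (or
    alpha = 1 with ``spike_norm=False``), and forms the pseudocounted
    ratio.
    """
    alpha = spike_normalization_factor(ip, input) if spike_norm else 1.0
    eps = default_pseudocount(ip, input) if epsilon is None else epsilon
    ip_rpm = rpm_scale(count_reads_per_bin(ip, bins), ip.total)
    in_rpm = rpm_scale(count_reads_per_bin(input, bins), input.total)
    return bin_enrichment(bins, ip_rpm, in_rpm, alpha=alpha, epsilon=eps)


def class_density(
    table: EnrichmentTable,
    classes: Sequence[str] = CLASSES,
    grid_size: int = 512,
    bw_method="silverman",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class smoothed density of log2 enrichment.

    Each class's curve is normalized to unit area independently, so curves
    show the *proportion* of bins of that class at each enrichment level,
    not raw bin numbers.  Gaussian kernel in log2 space, Silverman
    bandwidth.  Empty classes are omitted with a warning.
    """
    cls_arr = table.classes()
    loge = np.log2(table.enrichment)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in classes:
        vals = loge[cls_arr == cls]
        if len(vals) == 0:
            warnings.warn(f"no bins of class {cls!r}; omitted from density")
            continue
        lo, hi = vals.min(), vals.max()
        pad = max(1.0, 0.2 * (hi - lo))
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        if np.ptp(vals) == 0:
            # degenerate: all mass at one point; represent as a narrow kernel
            dens = np.zeros_like(grid)
            width = (grid[-1] - grid[0]) / (grid_size - 1)
            dens[np.argmin(np.abs(grid - vals[0]))] = 1.0 / width
        else:
            kde = gaussian_kde(vals, bw_method=bw_method)
            dens = kde(grid)
        area = np.trapezoid(dens, grid)
        out[cls] = (grid, dens / area)
    return out


def call_domains(
    domains: Sequence[DomainSegment],
    table: EnrichmentTable,
    threshold: float = 2.0,
    min_span: int = 10_000,
) -> list[DomainCall]:
    """Mean-enrichment call per domain.

    Considers domains spanning at least ``min_span`` bases.  The mean runs
    over class-assigned (non-mixed) bins of the domain's class lying fully
    inside the domain; a domain with no usable bin yields an undefined call
    (``enriched=None``, NaN mean).
    """
    bins_by_chrom: dict[str, list[tuple[int, GenomicBin]]] = {}
    for i, b in enumerate(table.bins):
        bins_by_chrom.setdefault(b.chrom, []).append((i, b))
    calls: list[DomainCall] = []
    for dom in domains:
        if len(dom) < min_span:
            continue
        vals = [
            table.enrichment[i]
            for i, b in bins_by_chrom.get(dom.chrom, ())
            if b.start >= dom.start
            and b.end <= dom.end
            and b.cls == dom.cls
        ]
        if vals:
            mean = float(np.mean(vals))
            calls.append(
                DomainCall(dom, mean, mean >= threshold, threshold, len(vals))
            )
        else:
            calls.append(DomainCall(dom, float("nan"), None, threshold, 0))
    return calls


def share_counts(enriched: pd.DataFrame) -> dict:
    """Sharing summary from a boolean domain x sample matrix.

    Rows are domains, columns samples, entries "enriched in that sample".
    Domains enriched nowhere do not enter the union.  Returns counts of
    domains enriched in all samples, the union, per-sample counts, a
    breakdown by number of supporting samples, and
    ``pct_shared = 100 * |shared in all| / |union|``.
    """
    enriched = enriched.astype(bool)
    n_samples = enriched.shape[1]
    per_domain = enriched.sum(axis=1)
    union = int((per_domain > 0).sum())
    shared_all = int((per_domain == n_samples).sum())
    return {
        "n_samples": n_samples,
        "shared_all": shared_all,
        "union": union,
        "per_sample": enriched.sum(axis=0).to_dict(),
        "by_support": per_domain.value_counts().sort_index().to_dict(),
        "pct_shared": 100.0 * shared_all / union if union else float("nan"),
    }


def share_domains(calls_by_sample: Mapping[str, Sequence[DomainCall]]) -> dict:
    """Cross-sample sharing of enriched domains.

    Domains are matched across samples by coordinates.  Undefined calls
    count as not enriched in that sample.
    """
    cols = {}
    for sample, calls in calls_by_sample.items():
        cols[sample] = {
            (c.domain.chrom, c.domain.start, c.domain.end): bool(c.enriched)
            for c in calls
        }
    frame = pd.DataFrame(cols).fillna(False)
    return share_counts(frame)


def fold_change_summary(
    table_a: EnrichmentTable,
    table_b: EnrichmentTable,
    classes: Sequence[str] = ("inactive", "PcG"),
    split_pre: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-bin log2(E_A / E_B) with boxplot statistics per class.

    With ``split_pre=True`` the PcG class is subdivided into PRE-containing
    bins (reported as ``"PRE"``) and PRE-lacking bins (reported as
    ``"PcG"``).  The notch half-width 1.58 * IQR / sqrt(n) approximates a
    95% confidence interval of the median.
    """
    if len(table_a.bins) != len(table_b.bins) or any(
        a.key() != b.key() for a, b in zip(table_a.bins, table_b.bins)
    ):
        raise ValueError("enrichment tables must share an identical bin list")
    lfc = np.log2(table_a.enrichment) - np.log2(table_b.enrichment)
    cls_arr = table_a.classes()
    pre = np.asarray([b.pre_flag for b in table_a.bins], dtype=bool)
    groups: list[tuple[str, np.ndarray]] = []
    for cls in classes:
        m = cls_arr == cls
        if cls == "PcG" and split_pre:
            groups.append(("PcG", m & ~pre))
            groups.append(("PRE", m & pre))
        else:
            groups.append((cls, m))
    rows = []
    for name, m in groups:
        vals = lfc[m]
        n = len(vals)
        if n == 0:
            rows.append(
                {"cls": name, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "notch": np.nan}
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "cls": name,
                "n": n,
                "median": med,
                "q1": q1,
                "q3": q3,
                "notch": 1.58 * (q3 - q1) / np.sqrt(n),
            }
        )
    return lfc, pd.DataFrame(rows).set_index("cls")


def peak_matrix(
    library: SampleLibrary,
    summits: Sequence[tuple[str, int]],
    chrom_sizes: Mapping[str, int],
    window: int = 20_000,
    binsize: int = 200,
) -> np.ndarray:
    """Raw read-depth matrix in windows centered on peak summits.

    Row i profiles read-midpoint counts around summit i over +/- window/2 in
    ``binsize`` columns; raw counts, not RPM.  Columns extending past a
    chromosome end are padded with NaN.
    """
    if not summits:
        raise ValueError("need at least one summit")
    if window <= 0 or binsize <= 0 or window % binsize:
        raise ValueError("window must be a positive multiple of binsize")
    half = window // 2
    ncol = window // binsize
    mids = library.midpoints()
    mat = np.zeros((len(summits), ncol), dtype=float)
    for i, (chrom, pos) in enumerate(summits):
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        L = chrom_sizes[chrom]
        edges = pos - half + binsize * np.arange(ncol + 1)
        counts = (
            np.searchsorted(m, edges[1:], side="left")
            - np.searchsorted(m, edges[:-1], side="left")
        ).astype(float)
        out_of_range = (edges[:-1] < 0) | (edges[1:] > L)
        counts[out_of_range] = np.nan
        mat[i] = counts
    return mat


def order_rows_by_sum(matrix: np.ndarray) -> np.ndarray:
    """Row indices sorted by descending row sum (NaN-ignoring)."""
    return np.argsort(-np.nansum(matrix, axis=1), kind="stable")


def tss_window_enrichment(
    ip: SampleLibrary,
    input: SampleLibrary,
    tss_list: Sequence[tuple[str, str, int, str]],
    chrom_sizes: Mapping[str, int],
    alpha: float | None = None,
    epsilon: float | None = None,
    width: int = 500,
) -> pd.DataFrame:
    """IP/Input enrichment in the single window immediately downstream of each TSS.

    ``tss_list`` rows are (gene_id, chrom, position, strand).  For a +
    strand TSS at p the window is [p, p+width); for a - strand TSS,
    [p-width, p).  Windows running off the chromosome are reported with
    ``defined=False`` and NaN enrichment.
    """
    if alpha is None:
        alpha = spike_normalization_factor(ip, input)
    eps = default_pseudocount(ip, input) if epsilon is None else epsilon
    ip_mids = ip.midpoints()
    in_mids = input.midpoints()
    rows = []
    for gene_id, chrom, pos, strand in tss_list:
        if strand == "+":
            start, end = pos, pos + width
        elif strand == "-":
            start, end = pos - width, pos
        else:
            raise ValueError(f"unknown strand {strand!r} for {gene_id}")
        L = chrom_sizes.get(chrom, 0)
        if start < 0 or end > L:
            rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
                 "enrichment": np.nan, "defined": False}
            )
            continue

        def _count(mids: Mapping[str, np.ndarray]) -> int:
            m = mids.get(chrom, np.empty(0, dtype=np.int64))
            return int(
                np.searchsorted(m, end, side="left")
                - np.searchsorted(m, start, side="left")
            )

        ip_rpm = _count(ip_mids) * 1e6 / ip.total
        in_rpm = _count(in_mids) * 1e6 / input.total
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "enrichment": (alpha * ip_rpm + eps) / (in_rpm + eps),
                "defined": True,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
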