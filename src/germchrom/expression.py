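"""Expression quantification: TPM, median-of-ratios normalization, fold changes.

The differential quantities used downstream are distributional, not
per-gene significance calls: per-gene log2 fold changes between two
condition groups (means of normalized counts with a small prior), per-class
medians, and "relative median" trajectories in which each class's median
fold change at a developmental stage is divided by the active-class median
at the same stage (so active is 1 by construction and repressed classes
fall below 1 as silencing strengthens).  Confidence intervals for the
relative medians come from a seeded nonparametric bootstrap over genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with gene metadata (class, TPM length)."""

    counts: pd.DataFrame
    gene_meta: pd.DataFrame  # columns: cls, length
    sample_meta: pd.DataFrame  # columns: condition

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_meta.index):
            raise ValueError("counts and gene_meta must share a gene index")
        if not set(self.counts.columns) <= set(self.sample_meta.index):
            raise ValueError("every sample needs metadata")
        if (self.gene_meta["length"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return [s for s in self.counts.columns if meta.loc[s, "condition"] == condition]


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample."""
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return rate * 1e6 / totals


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the geometric mean of each gene's counts across
    samples (genes with any zero excluded); a sample's factor is the median
    over genes of its count divided by the reference.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logc = np.log(arr[nonzero])
    ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def gene_fold_change(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change A vs B on normalized counts.

    FC_g = (mean normalized count in A + prior) / (mean in B + prior),
    reported as log2.  The prior bounds the log-ratio for zero-count genes.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if factors is None:
        factors = size_factors(counts[list(group_a) + list(group_b)])
    norm = counts.div(factors, axis=1)
    mean_a = norm[list(group_a)].mean(axis=1)
    mean_b = norm[list(group_b)].mean(axis=1)
    return np.log2((mean_a + prior_count) / (mean_b + prior_count)).rename("log2fc")


def relative_median_trajectory(
    fc_by_stage: dict[str, pd.Series],
    gene_classes: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    active_class: str = "active",
    min_genes: int = 10,
) -> pd.DataFrame:
    """Per-stage, per-class relative median fold changes with bootstrap 95% CI.

    For each stage (a per-gene log2 FC series against a common baseline) and
    class: the class median fold change divided by the active-class median
    at the same stage.  The active class is exactly 1 at every stage by
    construction.  CIs come from ``n_boot`` resamples of genes (both the
    class and the active reference are resampled); classes with fewer than
    ``min_genes`` genes are marked unreliable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    classes = [active_class] + sorted(
        c for c in gene_classes.unique() if c != active_class
    )
    for stage, fc in fc_by_stage.items():
        cls_aligned = gene_classes.reindex(fc.index)
        by_class = {c: fc[cls_aligned == c].to_numpy() for c in classes}
        act = by_class.get(active_class, np.empty(0))
        if len(act) == 0:
            raise ValueError(f"stage {stage!r} has no {active_class!r} genes")
        act_med = np.median(act)
        for cls in classes:
            vals = by_class[cls]
            if len(vals) == 0:
                continue
            rel = float(2 ** (np.median(vals) - act_med))
            if cls == active_class:
                rows.append(
                    {"stage": stage, "cls": cls, "rel_median": 1.0,
                     "ci_lo": 1.0, "ci_hi": 1.0, "n_genes": len(vals),
                     "reliable": len(vals) >= min_genes}
                )
                continue
            boots = np.empty(n_boot)
            for b in range(n_boot):
                bv = vals[rng.integers(0, len(vals), len(vals))]
                ba = act[rng.integers(0, len(act), len(act))]
                boots[b] = 2 ** (np.median(bv) - np.median(ba))
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {"stage": stage, "cls": cls, "rel_median": rel,
                 "ci_lo": lo, "ci_hi": hi, "n_genes": len(vals),
                 "reliable": len(vals) >= min_genes}
            )
    return pd.DataFrame(rows)
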