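"""Heat-shock reporter induction statistics.

A silencing reporter (heat-shock promoter driving GFP) is read out as mean
fluorescence per germ-cell region; the unit of replication is the ovary
pair.  Induction for one line/stage/genotype is

    I_r = intensity_r(+hs) - mean(intensity(-hs))

i.e. each heat-shocked replicate minus the pooled mean of the
non-heat-shocked arm, making the statistic invariant to additive
background.  Genotype contrasts (e.g. control vs germline knockdown) use an
unpaired two-tailed pooled-variance t-test on the induction replicates, with
significance tiers * (p < 0.05), ** (p < 0.01), and N.S. otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ReporterRecord:
    line_id: str
    stage: str
    genotype: str
    heat_shock: bool
    intensity: float
    replicate_id: str

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class InductionSummary:
    line_id: str
    stage: str
    genotype: str
    inductions: np.ndarray
    mean: float
    sd: float
    n: int


def induction(records: Sequence[ReporterRecord]) -> InductionSummary:
    """Induction summary for one line/stage/genotype.

    Requires at least one record in each heat-shock arm; all records must
    belong to the same cell of the design.
    """
    keys = {(r.line_id, r.stage, r.genotype) for r in records}
    if len(keys) != 1:
        raise ValueError("records span multiple line/stage/genotype cells")
    line, stage, genotype = keys.pop()
    baseline_vals = [r.intensity for r in records if not r.heat_shock]
    hs_vals = [r.intensity for r in records if r.heat_shock]
    if not baseline_vals:
        raise ValueError("missing non-heat-shocked arm")
    if not hs_vals:
        raise ValueError("missing heat-shocked arm")
    baseline = float(np.mean(baseline_vals))
    ind = np.asarray(hs_vals, dtype=float) - baseline
    sd = float(np.std(ind, ddof=1)) if len(ind) > 1 else float("nan")
    return InductionSummary(
        line, stage, genotype, ind, float(ind.mean()), sd, len(ind)
    )


def significance_tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def genotype_contrast(
    summary_control: InductionSummary, summary_kd: InductionSummary
) -> tuple[float, float, str]:
    """Unpaired two-tailed pooled-variance t-test between two genotypes.

    Returns (t, p, tier) comparing control minus knockdown induction
    replicates.
    """
    a, b = summary_control.inductions, summary_kd.inductions
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 induction replicates per group")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), significance_tier(float(p))


def _group(records: Iterable[ReporterRecord]):
    groups: dict[tuple[str, str, str], list[ReporterRecord]] = {}
    for r in records:
        groups.setdefault((r.line_id, r.stage, r.genotype), []).append(r)
    return groups


def trajectory_table(
    records: Iterable[ReporterRecord],
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format mean +/- SD induction per (line, stage, genotype).

    One row per design cell with both heat-shock arms present; rows ordered
    by ``stage_order`` when given (for overlaying developmental
    trajectories colored by the chromatin class of the insertion site).
    """
    rows = []
    for (line, stage, genotype), recs in _group(records).items():
        s = induction(recs)
        rows.append(
            {"line_id": line, "stage": stage, "genotype": genotype,
             "mean_induction": s.mean, "sd": s.sd, "n": s.n}
        )
    frame = pd.DataFrame(rows)
    if stage_order is not None and not frame.empty:
        frame["stage"] = pd.Categorical(
            frame["stage"], categories=list(stage_order), ordered=True
        )
        frame = frame.sort_values(["line_id", "stage", "genotype"]).reset_index(
            drop=True
        )
    return frame


def contrast_table(
    records: Iterable[ReporterRecord],
    control_genotype: str,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Control-vs-knockdown contrasts for every line/stage with both genotypes.

    Raw-threshold significance tiers by default (matching the convention of
    testing each site independently); optional Benjamini-Hochberg
    adjustment of the p values across all contrasts.
    """
    groups = _group(records)
    summaries: dict[tuple[str, str, str], InductionSummary] = {
        key: induction(recs) for key, recs in groups.items()
    }
    rows = []
    for (line, stage, genotype), s in sorted(summaries.items()):
        if genotype == control_genotype:
            continue
        ctrl = summaries.get((line, stage, control_genotype))
        if ctrl is None:
            continue
        t, p, tier = genotype_contrast(ctrl, s)
        rows.append(
            {"line_id": line, "stage": stage, "genotype": genotype,
             "control": control_genotype, "t": t, "p": p, "tier": tier,
             "mean_control": ctrl.mean, "mean_kd": s.mean}
        )
    frame = pd.DataFrame(rows)
    if bh_correct and not frame.empty:
        frame["p_adj"] = stats.false_discovery_control(frame["p"].to_numpy())
        frame["tier_adj"] = [significance_tier(p) for p in frame["p_adj"]]
    return frame
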