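"""Median-split Kaplan-Meier survival analysis and threshold-based
differential expression.

For each panel gene, patients are split at the gene's median expression
(ties to the low group) and the two arms are compared with the standard
two-group log-rank test.  The product-limit estimator and the log-rank
statistic are implemented from first principles here; per-gene log-rank
p-values are reported uncorrected, mirroring the per-gene presentation
convention of median-split survival screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    AssociationRecord,
    OmicsMatrix,
    SurvivalTable,
    benjamini_hochberg,
)
from .pathway import median_split

logger = logging.getLogger("clockscape")


@dataclass
class KmCurve:
    """Product-limit survival curve over the distinct event times."""

    group: str
    times: np.ndarray       # increasing distinct event times
    survival: np.ndarray    # S(t) just after each event time, non-increasing
    at_risk: np.ndarray     # risk-set size just before each event time

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "time": self.times, "survival": self.survival,
             "at_risk": self.at_risk}
        )


def km_estimate(table: SurvivalTable, group: str = "") -> KmCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects leave the risk set after their censoring time;
    ties between events and censorings at the same time follow the usual
    convention that censored subjects are still at risk at that time.
    """
    df = table.data
    if df.empty:
        raise ValueError("empty survival table")
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)

    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv[i] = s
        at_risk[i] = n_i
    return KmCurve(group=group, times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(a: SurvivalTable, b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time, the observed event count in group ``a``
    is compared with its hypergeometric expectation given the pooled risk
    set; chi2 = (sum(O - E))^2 / sum(V), p from the upper tail of
    chi-square with 1 df.  Zero total variance (no informative event
    time) returns (0, 1).
    """
    ta = a.data["time"].to_numpy(dtype=float)
    ea = a.data["event"].to_numpy(dtype=int)
    tb = b.data["time"].to_numpy(dtype=float)
    eb = b.data["event"].to_numpy(dtype=int)
    if (ea.sum() + eb.sum()) == 0:
        raise ValueError("log-rank test needs at least one event")

    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    event_times = np.unique(all_times[all_events == 1])

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        if n1 == 0 or n2 == 0 or n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def restricted_mean_survival(curve: KmCurve, horizon: float) -> float:
    """Area under the KM step function on [0, horizon]."""
    rmst = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(curve.times, curve.survival):
        if t >= horizon:
            break
        rmst += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    rmst += prev_s * (horizon - prev_t)
    return rmst


@dataclass
class SurvivalResult:
    gene: str
    curves: tuple[KmCurve, KmCurve]  # (high, low)
    logrank_chi2: float
    p_value: float
    n_high: int
    n_low: int
    direction: str  # "high_better" | "low_better" | "none"

    def summary_dict(self) -> dict:
        return {
            "gene": self.gene,
            "logrank_chi2": self.logrank_chi2,
            "p_value": self.p_value,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "direction": self.direction,
        }


def survival_by_median_split(
    expr: OmicsMatrix,
    surv: SurvivalTable,
    config: AnalysisConfig,
    alpha: float = 0.05,
) -> list[SurvivalResult]:
    """Per panel gene: median-split patients into high/low expression arms,
    estimate both KM curves and run the log-rank test.

    ``direction`` compares the restricted mean survival of the two arms
    when the raw log-rank p <= alpha, and is "none" otherwise.  P-values
    are reported per gene without multiplicity correction.
    """
    shared = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if len(shared) < 20:
        raise ValueError(f"need >= 20 overlapping samples, got {len(shared)}")
    sdf = surv.data.set_index("sample").loc[shared].reset_index()

    results = []
    for gene in config.gene_panel:
        if gene not in expr.values.index:
            logger.warning("panel gene %s absent from expression; skipped", gene)
            continue
        g = expr.values.loc[gene, shared].dropna()
        if g.nunique() < 2:
            logger.warning("gene %s has constant expression; skipped", gene)
            continue
        high_ids, low_ids = median_split(g)
        high = SurvivalTable(sdf[sdf["sample"].isin(high_ids)].reset_index(drop=True))
        low = SurvivalTable(sdf[sdf["sample"].isin(low_ids)].reset_index(drop=True))
        chi2, p = logrank_test(high, low)
        hi_curve = km_estimate(high, group="high")
        lo_curve = km_estimate(low, group="low")
        direction = "none"
        if p <= alpha:
            horizon = float(
                min(high.data["time"].max(), low.data["time"].max())
            )
            if horizon > 0:
                rm_hi = restricted_mean_survival(hi_curve, horizon)
                rm_lo = restricted_mean_survival(lo_curve, horizon)
                if rm_hi != rm_lo:
                    direction = "high_better" if rm_hi > rm_lo else "low_better"
        results.append(
            SurvivalResult(
                gene=gene,
                curves=(hi_curve, lo_curve),
                logrank_chi2=chi2,
                p_value=p,
                n_high=len(high.data),
                n_low=len(low.data),
                direction=direction,
            )
        )
    return results


def survival_to_frame(results: list[SurvivalResult]) -> pd.DataFrame:
    cols = ["gene", "logrank_chi2", "p_value", "n_high", "n_low", "direction"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.summary_dict() for r in results])[cols]


def curves_to_frame(results: list[SurvivalResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        for curve in r.curves:
            df = curve.as_frame()
            df.insert(0, "gene", r.gene)
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["gene", "group", "time", "survival", "at_risk"])
    return pd.concat(frames, ignore_index=True)


def differential_expression(
    expr: OmicsMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
    config: AnalysisConfig,
    pseudocount: float = 1e-3,
) -> list[AssociationRecord]:
    """Threshold-based differential expression between two sample groups.

    Effect = log2((mean_a + eps) / (mean_b + eps)) with eps = 1e-3 in
    expression units; p from a two-sided Wilcoxon rank-sum test; BH FDR
    across genes.  A gene passes the joint filter when
    |effect| > log2fc_threshold and fdr <= fdr_threshold.
    """
    a_ids = [s for s in group_a_ids if s in expr.values.columns]
    b_ids = [s for s in group_b_ids if s in expr.values.columns]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("need >= 3 samples per group")

    raw = []
    for gene in expr.feature_ids:
        a = expr.values.loc[gene, a_ids].dropna().to_numpy()
        b = expr.values.loc[gene, b_ids].dropna().to_numpy()
        if a.size < 3 or b.size < 3:
            raw.append((gene, np.nan, np.nan, np.nan, a.size + b.size))
            continue
        effect = float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))
        stat, p = stats.ranksums(a, b)
        raw.append((gene, float(stat), effect, float(p), a.size + b.size))

    fdrs = benjamini_hochberg([r[3] for r in raw])
    return [
        AssociationRecord(
            gene=g, target="group_a_vs_group_b", statistic=s, effect=e,
            p_value=p, fdr=float(q), n=int(n),
        )
        for (g, s, e, p, n), q in zip(raw, fdrs)
    ]


def significant_de(
    records: list[AssociationRecord], config: AnalysisConfig
) -> list[AssociationRecord]:
    """The records passing |log2FC| > threshold AND fdr <= threshold."""
    return [
        r
        for r in records
        if np.isfinite(r.effect)
        and np.isfinite(r.fdr)
        and abs(r.effect) > config.log2fc_threshold
        and r.fdr <= config.fdr_threshold
    ]
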