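"""Cosinor rhythmicity detection for time-stamped expression.

Fits the single-component cosinor model

    y(t) = M + beta_c * cos(omega t) + beta_s * sin(omega t),   omega = 2 pi / period

by ordinary least squares.  Amplitude A = sqrt(beta_c^2 + beta_s^2) and
acrophase (peak time of the fitted cosine, hours after t = 0) follow from
the coefficient pair; rhythmicity is tested with the F-test of the two
rhythm terms against the intercept-only model on (2, n - 3) degrees of
freedom.  The default period is 24 h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, OmicsMatrix, benjamini_hochberg

logger = logging.getLogger("clockscape")


@dataclass
class CosinorFit:
    gene: str
    mesor: float
    amplitude: float
    acrophase_hours: float  # in [0, period)
    p_value: float
    r_squared: float
    n: int
    fdr: float = np.nan

    def as_dict(self) -> dict:
        return asdict(self)


class DegenerateSamplingError(ValueError):
    """All time points coincide modulo the period; the rhythm terms are
    not identifiable."""


def fit_cosinor(
    values: np.ndarray,
    times_hours: np.ndarray,
    period_hours: float = 24.0,
    gene: str = "",
) -> CosinorFit:
    """Least-squares cosinor fit of one series.

    Requires n >= 4 and at least 3 distinct time points modulo the
    period (two cosinor coefficients plus the mesor must be
    identifiable).  Missing values are dropped pairwise.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times_hours, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    keep = ~np.isnan(y) & ~np.isnan(t)
    y, t = y[keep], t[keep]
    n = y.size
    if n < 4:
        raise ValueError(f"need >= 4 observations, got {n}")
    phase = np.round(np.mod(t, period_hours), 9)
    if np.unique(phase).size < 3:
        raise DegenerateSamplingError(
            "degenerate sampling: fewer than 3 distinct time points modulo the period"
        )

    omega = 2.0 * np.pi / period_hours
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))

    mesor, bc, bs = (float(b) for b in beta)
    amplitude = float(np.hypot(bc, bs))
    # peak of M + A*cos(omega*(t - phi)); phi = atan2(bs, bc)/omega
    acrophase = float(np.mod(np.arctan2(bs, bc) / omega, period_hours))

    # scale-aware zero test: a constant series leaves only rounding noise
    flat_tol = np.finfo(float).eps * n * (1.0 + abs(float(y.mean()))) ** 2
    if tss <= flat_tol or rss >= tss:  # flat signal or no explained variance
        f, p, r2 = 0.0, 1.0, 0.0
    else:
        df1, df2 = 2, n - 3
        f = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
        p = float(stats.f.sf(f, df1, df2))
        r2 = 1.0 - rss / tss
    return CosinorFit(
        gene=gene,
        mesor=mesor,
        amplitude=amplitude,
        acrophase_hours=acrophase,
        p_value=p,
        r_squared=float(r2),
        n=int(n),
    )


def rhythm_panel(
    timeseries: OmicsMatrix,
    times_hours: pd.Series | np.ndarray,
    config: AnalysisConfig,
) -> list[CosinorFit]:
    """Fit a cosinor per gene row and BH-adjust p-values across the panel.

    ``times_hours`` maps the matrix's sample IDs to collection times; a
    per-gene fit failure downgrades to a missing row rather than aborting
    the panel.
    """
    if isinstance(times_hours, pd.Series):
        t = times_hours.reindex(timeseries.sample_ids).to_numpy(dtype=float)
    else:
        t = np.asarray(times_hours, dtype=float)
        if t.size != timeseries.n_samples:
            raise ValueError("times length must match sample count")

    fits: list[CosinorFit] = []
    for gene in timeseries.feature_ids:
        try:
            fits.append(
                fit_cosinor(
                    timeseries.values.loc[gene].to_numpy(),
                    t,
                    period_hours=config.rhythm_period_hours,
                    gene=gene,
                )
            )
        except (ValueError, DegenerateSamplingError) as exc:
            logger.warning("cosinor fit failed for %s: %s", gene, exc)
            fits.append(
                CosinorFit(gene, np.nan, np.nan, np.nan, np.nan, np.nan, 0)
            )
    fdrs = benjamini_hochberg([f.p_value for f in fits])
    for f, q in zip(fits, fdrs):
        f.fdr = float(q)
    return fits


def fits_to_frame(fits: list[CosinorFit]) -> pd.DataFrame:
    cols = ["gene", "mesor", "amplitude", "acrophase_hours", "p_value", "fdr", "r_squared", "n"]
    if not fits:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([f.as_dict() for f in fits])[cols]
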