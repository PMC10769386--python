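"""Cohort statistics: marker ratios, group comparisons, correlations, and
Kaplan-Meier / Mantel-Haenszel survival analysis.

Sample-level ratios divide positive-cell counts (e.g. NOS2+/CD8+,
COX2+/CD8+, and the cancer-stemness variants against CD44v6/EpCAM); a zero
denominator is flagged rather than silently divided. Group comparisons use
Mann-Whitney (exact for combined n <= 20 without ties) or Welch's t;
correlations are Pearson with the t-distribution p-value.

Survival: Kaplan-Meier product-limit curves per group and a hazard ratio
from the pooled Mantel-Haenszel observed/expected tables at event times,

    HR = (O1/E1) / (O2/E2),    CI = exp(log HR +/- 1.96 * sqrt(1/E1 + 1/E2)),

with log-rank and Gehan-Breslow-Wilcoxon (at-risk-weighted) p-values. This
is the classical KM-based procedure (as implemented by common biostatistics
packages), deliberately not a Cox regression; five-year analyses apply
administrative censoring at 60 months before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsError",
    "DEFAULT_RATIOS",
    "SurvivalResult",
    "sample_ratios",
    "group_compare",
    "pearson_r2",
    "dichotomize_at_median",
    "km_curve",
    "km_hazard",
    "administrative_censor",
    "expression_ratio_survival",
]


class StatsError(ValueError):
    pass


DEFAULT_RATIOS = (
    ("NOS2", "CD8"),
    ("COX2", "CD8"),
    ("NOS2", "CD44V6"),
    ("NOS2", "EPCAM"),
    ("COX2", "CD44V6"),
    ("COX2", "EPCAM"),
)


def sample_ratios(
    positivity: pd.DataFrame,
    ratios: tuple[tuple[str, str], ...] = DEFAULT_RATIOS,
    teff: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample positive-cell counts, percentages and count ratios.

    ``positivity`` is the boolean per-cell table from
    :func:`spatialtme.gating.positivity_table`. When ``teff`` is given, the
    CD3+CD8+PD1- variant ratios (suffix ``_teff``) use it as denominator.
    Zero denominators yield ``inf`` and a flag column.
    """
    markers = [c for c in positivity.columns if c not in ("cell_id", "sample_id")]
    df = positivity.copy()
    if teff is not None:
        df["_teff"] = np.asarray(teff, dtype=bool)
    grouped = df.groupby("sample_id", sort=True)
    out = grouped[markers].sum().astype(int)
    out.columns = [f"n_{m}" for m in markers]
    out["n_cells"] = grouped.size()
    for m in markers:
        out[f"pct_{m}"] = 100.0 * out[f"n_{m}"] / out["n_cells"]
    if teff is not None:
        out["n_teff"] = grouped["_teff"].sum().astype(int)
    for num, den in ratios:
        if f"n_{num}" not in out.columns or f"n_{den}" not in out.columns:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = out[f"n_{num}"] / out[f"n_{den}"]
        out[f"ratio_{num}_{den}"] = np.where(out[f"n_{den}"] > 0, r, np.inf)
        out[f"ratio_{num}_{den}_flag"] = np.where(
            out[f"n_{den}"] > 0, "ok", "zero_denominator"
        )
        if teff is not None and den == "CD8":
            with np.errstate(divide="ignore", invalid="ignore"):
                rt = out[f"n_{num}"] / out["n_teff"]
            out[f"ratio_{num}_teff"] = np.where(out["n_teff"] > 0, rt, np.inf)
    return out.reset_index()


def group_compare(
    x: np.ndarray, y: np.ndarray, method: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sided two-group comparison; returns (statistic, p).

    Mann-Whitney uses the exact null distribution when the combined sample
    is small (n <= 20) and has no ties, otherwise the normal approximation
    with mid-ranks and tie correction. Welch's t requires n >= 2 per group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("empty group")
    if method == "mann_whitney":
        combined = np.concatenate([x, y])
        exact = combined.size <= 20 and np.unique(combined).size == combined.size
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if method == "welch_t":
        if x.size < 2 or y.size < 2:
            raise StatsError("welch_t needs >= 2 values per group")
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise StatsError(f"unknown method {method!r}")


def pearson_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, r^2, two-sided p from t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise StatsError("pearson_r2 needs n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("non-finite value in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def dichotomize_at_median(values: np.ndarray) -> np.ndarray:
    """High/low split at the median; ties go low (value > median -> high)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatsError("need >= 2 values to dichotomize")
    return v > np.median(v)


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate: (time, at_risk, deaths,
    survival). Starts at S=1; steps only at event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    rows = [(0.0, int(times.size), 0, 1.0)]
    s = 1.0
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "deaths", "survival"])


@dataclass
class SurvivalResult:
    curves: dict  # group -> km_curve DataFrame
    hr: float  # group1 vs group2, (O1/E1)/(O2/E2)
    ci: tuple[float, float]
    p_logrank: float
    p_gbw: float
    o_e: dict = field(default_factory=dict)  # O1, E1, O2, E2, V
    groups: tuple[str, str] = ("", "")
    flag: str = "ok"  # 'ok' | 'no_events'


def administrative_censor(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate follow-up at ``horizon`` months (later events censored)."""
    times = np.asarray(times, dtype=float).copy()
    events = np.asarray(events, dtype=bool).copy()
    over = times > horizon
    times[over] = horizon
    events[over] = False
    return times, events


def km_hazard(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
    group_order: tuple[str, str] | None = None,
    horizon_months: float | None = None,
) -> SurvivalResult:
    """Two-group survival comparison: KM curves, Mantel-Haenszel O/E hazard
    ratio with 95% CI, log-rank and Gehan-Breslow-Wilcoxon p-values.

    ``group_order = (g1, g2)`` fixes the HR direction (g1 vs g2); swapping
    the groups inverts the HR exactly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups).astype(str)
    labels = list(dict.fromkeys(groups)) if group_order is None else list(group_order)
    if len(set(labels)) != 2:
        raise StatsError("km_hazard requires exactly two groups")
    g1, g2 = labels
    for g in (g1, g2):
        if (groups == g).sum() == 0:
            raise StatsError(f"group {g!r} has zero subjects")
    if horizon_months is not None:
        times, events = administrative_censor(times, events, horizon_months)

    is1 = groups == g1
    curves = {
        g1: km_curve(times[is1], events[is1]),
        g2: km_curve(times[~is1], events[~is1]),
    }
    if not events.any():
        return SurvivalResult(
            curves=curves,
            hr=np.nan,
            ci=(np.nan, np.nan),
            p_logrank=np.nan,
            p_gbw=np.nan,
            groups=(g1, g2),
            flag="no_events",
        )

    # pooled risk-set tables at each distinct event time
    event_times = np.unique(times[events])
    O1 = E1 = V = 0.0
    W_stat = W_var = 0.0  # Gehan-Breslow-Wilcoxon (weights = at-risk count)
    for t in event_times:
        at_risk = times >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & is1).sum())
        d = float(((times == t) & events).sum())
        d1 = float(((times == t) & events & is1).sum())
        e1 = d * n1 / n
        v = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / max(n - 1.0, 1.0)
        O1 += d1
        E1 += e1
        V += v
        W_stat += n * (d1 - e1)
        W_var += n * n * v
    O2 = float(events.sum()) - O1
    E2 = float(events.sum()) - E1

    if E1 == 0 or E2 == 0 or O1 == 0 or O2 == 0:
        hr = (O1 / E1) / (O2 / E2) if (E1 > 0 and E2 > 0 and O2 > 0) else np.nan
        ci = (np.nan, np.nan)
    else:
        hr = (O1 / E1) / (O2 / E2)
        se = np.sqrt(1.0 / E1 + 1.0 / E2)
        ci = (float(hr * np.exp(-1.959963984540054 * se)), float(hr * np.exp(1.959963984540054 * se)))

    chi_lr = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p_logrank = float(stats.chi2.sf(chi_lr, df=1))
    chi_w = W_stat**2 / W_var if W_var > 0 else 0.0
    p_gbw = float(stats.chi2.sf(chi_w, df=1))
    return SurvivalResult(
        curves=curves,
        hr=float(hr),
        ci=ci,
        p_logrank=p_logrank,
        p_gbw=p_gbw,
        o_e={"O1": O1, "E1": E1, "O2": O2, "E2": E2, "V": V},
        groups=(g1, g2),
    )


def expression_ratio_survival(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    numerator: str,
    denominator: str,
    horizon_months: float | None = 60.0,
) -> SurvivalResult:
    """Gene-expression ratio survival analysis (validation-cohort stage).

    Per-sample ratio = expr(numerator)/expr(denominator) on the matrix's
    native scale; samples with non-positive denominator expression are
    dropped with a warning; the cohort is split at the median ratio (high vs
    low) and compared with :func:`km_hazard`.
    """
    import warnings

    from spatialtme.io_model import gene_row

    num = gene_row(expr, numerator).to_numpy(dtype=float)
    den = gene_row(expr, denominator).to_numpy(dtype=float)
    samples = np.array(expr.columns, dtype=str)
    ok = den > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} samples with non-positive "
            f"{denominator} expression",
            stacklevel=2,
        )
    ratio = num[ok] / den[ok]
    samples = samples[ok]
    if np.unique(ratio).size == 1:
        raise StatsError("degenerate split: all expression ratios identical")
    high = dichotomize_at_median(ratio)
    if high.all() or (~high).all():
        raise StatsError("degenerate split: median dichotomization is one-sided")
    clin = clinical.set_index("sample_id").loc[samples]
    return km_hazard(
        clin["time_months"].to_numpy(dtype=float),
        clin["event"].to_numpy(dtype=bool),
        np.where(high, "high", "low"),
        group_order=("high", "low"),
        horizon_months=horizon_months,
    )
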