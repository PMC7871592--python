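"""Group comparisons and the cross-metric redundancy analysis.

Redundancy between coupling metrics is probed with bivariate correlations
computed per connection (electrode pair): Spearman's rho for linear-linear
pairs, the Jammalamadaka-SenGupta circular-circular correlation for two
angle-valued metrics, and the Mardia circular-linear correlation for mixed
pairs.  P-values are left unadjusted by design (the analysis emulates using
a single metric at a time).  A consensus matrix then averages each metric
pair's correlation over the three connections and flags it only when the
correlation is significant in every connection.

Group (genotype-style) comparisons dispatch on the metric's geometry:
Welch's t for linear metrics, the Watson-Williams test for circular ones,
and a two-factor mixed ANOVA (group x within-condition) with
Sidak-adjusted pairwise contrasts for paired-direction designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .spike_phase import phase_angle_compare

__all__ = [
    "CorrelationCell",
    "circ_corr_cc",
    "circ_corr_cl",
    "correlate_metrics",
    "consensus",
    "compare_groups",
    "mixed_anova_sidak",
]


@dataclass
class CorrelationCell:
    metric_a: str
    metric_b: str
    rho: float
    p: float
    n: int
    method: str
    connection: str = ""


def circ_corr_cc(alpha_deg, beta_deg) -> tuple[float, float]:
    """Jammalamadaka-SenGupta circular-circular correlation and p-value.

    rho = sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2 * sum sin^2);
    the p-value uses the large-sample normal approximation.  Invariant
    under independent rotations of either variable.
    """
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    b = np.deg2rad(np.asarray(beta_deg, dtype=float))
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3")
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho = float((sa * sb).sum() / denom)
    l20 = (sa**2).mean()
    l02 = (sb**2).mean()
    l22 = (sa**2 * sb**2).mean()
    if l22 <= 0:
        return rho, np.nan
    z = np.sqrt(n * l20 * l02 / l22) * rho
    p = float(2 * sst.norm.sf(abs(z)))
    return rho, p


def circ_corr_cl(alpha_deg, x) -> tuple[float, float]:
    """Mardia circular-linear correlation (non-negative) and p-value.

    R^2 = (r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2) with
    r_cx = corr(cos a, x) etc.; n R^2 ~ chi2(2) under independence.
    """
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    x = np.asarray(x, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3")
    rcx = np.corrcoef(np.cos(a), x)[0, 1]
    rsx = np.corrcoef(np.sin(a), x)[0, 1]
    rcs = np.corrcoef(np.cos(a), np.sin(a))[0, 1]
    r2 = (rcx**2 + rsx**2 - 2 * rcx * rsx * rcs) / (1 - rcs**2)
    r2 = float(np.clip(r2, 0.0, 1.0))
    p = float(sst.chi2.sf(n * r2, 2))
    return float(np.sqrt(r2)), p


def correlate_metrics(
    table: pd.DataFrame,
    circular_cols: set[str] | None = None,
    connection: str = "",
) -> list[CorrelationCell]:
    """All pairwise correlations among metric columns of ``table``.

    Each row is one observation unit (an electrode pair / animal); each
    column one metric.  Columns named in ``circular_cols`` hold angles in
    degrees.  Method dispatch: spearman (lin-lin), circ_circ, circ_lin.
    Constant columns yield NaN cells.  P-values are unadjusted.
    """
    circular_cols = circular_cols or set()
    cols = list(table.columns)
    out = []
    for i, ca in enumerate(cols):
        for cb in cols[i + 1 :]:
            sub = table[[ca, cb]].dropna()
            n = len(sub)
            a_circ, b_circ = ca in circular_cols, cb in circular_cols
            if n < 3:
                out.append(CorrelationCell(ca, cb, np.nan, np.nan, n, "insufficient", connection))
                continue
            xa, xb = sub[ca].to_numpy(), sub[cb].to_numpy()
            if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                out.append(CorrelationCell(ca, cb, np.nan, np.nan, n, "constant", connection))
                continue
            if a_circ and b_circ:
                rho, p = circ_corr_cc(xa, xb)
                method = "circ_circ"
            elif a_circ or b_circ:
                ang, lin = (xa, xb) if a_circ else (xb, xa)
                rho, p = circ_corr_cl(ang, lin)
                method = "circ_lin"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = sst.spearmanr(xa, xb)
                method = "spearman"
            out.append(CorrelationCell(ca, cb, float(rho), float(p), n, method, connection))
    return out


def consensus(
    cells_by_connection: dict[str, list[CorrelationCell]],
    alphas=(0.01, 0.001),
) -> pd.DataFrame:
    """Average each metric pair's rho across connections; flag only if the
    correlation is significant in *every* connection.

    Metric pairs missing from any connection are dropped with a warning.
    Returns a frame with mean_rho and one boolean column per alpha.
    """
    frames = {}
    for conn, cells in cells_by_connection.items():
        frames[conn] = {(c.metric_a, c.metric_b): c for c in cells}
    common = set.intersection(*(set(f) for f in frames.values()))
    dropped = set.union(*(set(f) for f in frames.values())) - common
    if dropped:
        warnings.warn(f"{len(dropped)} metric pair(s) missing from some connection; dropped")
    rows = []
    for pair in sorted(common):
        cs = [frames[conn][pair] for conn in frames]
        rhos = [c.rho for c in cs]
        ps = [c.p for c in cs]
        row = {
            "metric_a": pair[0],
            "metric_b": pair[1],
            "mean_rho": float(np.nanmean(rhos)),
            "n_connections": len(cs),
        }
        for alpha in alphas:
            row[f"all_significant_{alpha:g}"] = bool(
                all(np.isfinite(p) and p < alpha for p in ps)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(values_a, values_b, kind: str = "linear") -> dict:
    """Two-group comparison dispatched on the metric's geometry.

    kind="linear": Welch's unequal-variance t test.
    kind="circular": Watson-Williams two-sample test (angles in degrees).
    Returns statistic, p, and group summaries.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if kind == "linear":
        t, p = sst.ttest_ind(a, b, equal_var=False)
        return {
            "test": "welch_t",
            "statistic": float(t),
            "p": float(p),
            "mean_a": float(a.mean()),
            "sem_a": float(a.std(ddof=1) / np.sqrt(a.size)),
            "mean_b": float(b.mean()),
            "sem_b": float(b.std(ddof=1) / np.sqrt(b.size)),
        }
    if kind == "circular":
        res = phase_angle_compare(a, b)
        return {
            "test": "watson_williams",
            "statistic": res["F"],
            "p": res["p"],
            "mean_a": res["mean_a_deg"],
            "mean_b": res["mean_b_deg"],
            "warn_low_concentration": res["warn_low_concentration"],
        }
    raise ValueError(f"unknown metric kind {kind!r}")


def mixed_anova_sidak(df: pd.DataFrame, dv: str, within: str, between: str, subject: str) -> dict:
    """Two-factor mixed ANOVA with Sidak-adjusted pairwise group contrasts.

    The ANOVA (one within factor, e.g. direction or reference; one between
    factor, e.g. genotype) is delegated to pingouin; pairwise Welch t
    contrasts between groups at each within level are Sidak-adjusted and
    reported only when the ANOVA shows a group or interaction effect.
    """
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between, subject=subject)
    p_group = float(aov.loc[aov["Source"] == between, "p_unc"].iloc[0])
    p_inter = float(aov.loc[aov["Source"] == "Interaction", "p_unc"].iloc[0])
    levels = sorted(df[within].unique())
    m = len(levels)
    contrasts = []
    gate_open = (p_group < 0.05) or (p_inter < 0.05)
    for lev in levels:
        sub = df[df[within] == lev]
        groups = sorted(sub[between].unique())
        va = sub.loc[sub[between] == groups[0], dv].to_numpy()
        vb = sub.loc[sub[between] == groups[1], dv].to_numpy()
        t, p = sst.ttest_ind(va, vb, equal_var=False)
        p_sidak = 1.0 - (1.0 - min(p, 1.0)) ** m
        contrasts.append(
            {
                "level": lev,
                "t": float(t),
                "p_unc": float(p),
                "p_sidak": float(min(p_sidak, 1.0)),
                "reported": bool(gate_open),
            }
        )
    return {
        "anova": aov,
        "p_group": p_group,
        "p_interaction": p_inter,
        "contrasts": contrasts,
    }
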