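"""Cohort-level statistics: normality, paired comparisons, correlations.

The analysis mirrors a paired unilateral-disease design: each volume set is
tested for normality (Shapiro-Wilk), affected vs unaffected volumes are
compared with a two-tailed paired t test (significance at p < 0.05), the
linear relationship between excess volumes is quantified with Pearson
correlation plus a least-squares fit and its 95% confidence band, and
non-normally distributed covariates are handled with Spearman rank
correlation. Excess volumes can be normalized by the unaffected arm's
epifascial volume to compare subjects of different arm size. No
multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, LymphmapError
from .volumetry import METRICS

ALPHA = 0.05

#: sample sizes up to which the Spearman p-value is computed by exact
#: permutation enumeration (n! hypotheses) rather than asymptotically
SPEARMAN_EXACT_MAX_N = 8


def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p). Requires 3 <= n <= 5000 and a
    non-constant sample."""
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or not 3 <= len(x) <= 5000:
        raise LymphmapError(f"Shapiro-Wilk needs a 1D sample with 3 <= n <= 5000, "
                            f"got shape {x.shape}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def paired_comparison(affected, unaffected) -> tuple[float, float]:
    """Two-tailed paired t test; returns (t, p).

    Raises :class:`DegenerateDataError` when the paired differences have
    zero variance (including identical samples), where t is 0/0.
    """
    x = np.asarray(affected, dtype=np.float64)
    y = np.asarray(unaffected, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise LymphmapError("paired test needs equal-length 1D samples, n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateDataError("paired differences have zero variance")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


@dataclass
class LinearFit:
    """Least-squares line y = slope*x + intercept with a 95% confidence band."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    x_mean: float
    sxx: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=np.float64) + self.intercept

    def confidence_band(self, x, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean response at ``x``."""
        x = np.asarray(x, dtype=np.float64)
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        half = tcrit * self.residual_sd * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        yhat = self.predict(x)
        return yhat - half, yhat + half


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided permutation p-value by full enumeration of rank orders."""
    ranks = np.arange(n, dtype=np.float64)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.float64)
    # Spearman rho of a permutation of 0..n-1 against the identity
    mean = (n - 1) / 2.0
    denom = np.sum((ranks - mean) ** 2)
    rhos = np.sum((perms - mean) * (ranks - mean), axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def correlate(x, y, method: str = "pearson"):
    """Correlation between two samples.

    ``method='pearson'`` returns (r, p, :class:`LinearFit`); the fit carries
    the least-squares slope/intercept and the standard 95% confidence band
    of the regression line. ``method='spearman'`` returns (rho, p); for
    n <= 8 without ties, p comes from exact permutation enumeration,
    otherwise from the asymptotic approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise LymphmapError("correlation needs equal-length 1D samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant sample: correlation undefined")
    n = len(x)
    if method == "spearman":
        rho, p_asym = stats.spearmanr(x, y)
        no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
        if n <= SPEARMAN_EXACT_MAX_N and no_ties:
            return float(rho), _exact_spearman_p(float(rho), n)
        return float(rho), float(p_asym)
    if method != "pearson":
        raise LymphmapError(f"unknown correlation method {method!r}")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sxx = float(np.sum((x - x.mean()) ** 2))
    residual_sd = math.sqrt(float(np.sum(resid ** 2)) / (n - 2)) if n > 2 else 0.0
    fit = LinearFit(slope=float(slope), intercept=float(intercept),
                    residual_sd=residual_sd, n=n, x_mean=float(x.mean()), sxx=sxx)
    return float(r), float(p), fit


def relative_excess_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Normalize excess volumes by the unaffected arm's epifascial volume.

    Expects columns ``epifascial_excess_ml``, ``fat_excess_ml``,
    ``fluid_excess_ml`` and ``unaffected_epifascial_ml``; returns the input
    with added ``relative_*`` columns (dimensionless).
    """
    denom = cohort["unaffected_epifascial_ml"].to_numpy(dtype=np.float64)
    if np.any(denom <= 0):
        raise DegenerateDataError("unaffected epifascial volume must be positive")
    out = cohort.copy()
    for col, new in (("epifascial_excess_ml", "relative_epifascial_excess"),
                     ("fat_excess_ml", "relative_fat_excess"),
                     ("fluid_excess_ml", "relative_fluid_excess")):
        out[new] = cohort[col].to_numpy(dtype=np.float64) / denom
    return out


def cohort_report(table: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Summary statistics of a cohort volumes table.

    Expects per-subject columns ``<metric>_affected_ml`` and
    ``<metric>_unaffected_ml`` for the six volume metrics. For each set:
    Shapiro-Wilk normality of both arms' values, the paired t test, and the
    mean excess. Adds the Pearson correlation (with fit) between fat and
    fluid excesses when both vary. Degenerate sets are flagged rather than
    raising.
    """
    report: dict = {"n_subjects": int(len(table)), "alpha": alpha, "volumes": {}}
    for m in METRICS:
        a = table[f"{m}_affected_ml"].to_numpy(dtype=np.float64)
        u = table[f"{m}_unaffected_ml"].to_numpy(dtype=np.float64)
        entry: dict = {
            "mean_affected_ml": float(a.mean()),
            "mean_unaffected_ml": float(u.mean()),
            "mean_excess_ml": float((a - u).mean()),
        }
        try:
            entry["shapiro_p_affected"] = test_normality(a)[1]
            entry["shapiro_p_unaffected"] = test_normality(u)[1]
            t, p = paired_comparison(a, u)
            entry.update(t=t, p=p, significant=bool(p < alpha))
        except DegenerateDataError as exc:
            entry["degenerate"] = str(exc)
        report["volumes"][m] = entry

    fat = (table["fat_epifascial_affected_ml"]
           - table["fat_epifascial_unaffected_ml"]).to_numpy(dtype=np.float64)
    fluid = (table["fluid_epifascial_affected_ml"]
             - table["fluid_epifascial_unaffected_ml"]).to_numpy(dtype=np.float64)
    try:
        r, p, fit = correlate(fat, fluid, "pearson")
        report["fat_vs_fluid_excess"] = {
            "pearson_r": r, "p": p, "slope": fit.slope, "intercept": fit.intercept,
            "n_fat_greater": int(np.sum(fat > fluid)),
        }
    except DegenerateDataError as exc:
        report["fat_vs_fluid_excess"] = {"degenerate": str(exc)}
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`cohort_report`."""
    lines = [f"Cohort of {report['n_subjects']} subjects "
             f"(two-tailed paired t, alpha = {report['alpha']})", ""]
    lines.append(f"{'volume set':<20}{'affected':>10}{'unaffected':>12}"
                 f"{'excess':>10}{'t':>8}{'p':>10}")
    for m, e in report["volumes"].items():
        if "degenerate" in e:
            lines.append(f"{m:<20}{e['mean_affected_ml']:>10.1f}"
                         f"{e['mean_unaffected_ml']:>12.1f}"
                         f"{e['mean_excess_ml']:>10.1f}{'degenerate':>18}")
        else:
            star = " *" if e["significant"] else ""
            lines.append(f"{m:<20}{e['mean_affected_ml']:>10.1f}"
                         f"{e['mean_unaffected_ml']:>12.1f}"
                         f"{e['mean_excess_ml']:>10.1f}{e['t']:>8.2f}"
                         f"{e['p']:>10.2g}{star}")
    ff = report.get("fat_vs_fluid_excess", {})
    if "pearson_r" in ff:
        lines += ["", f"fat vs fluid excess: Pearson r = {ff['pearson_r']:.2f} "
                  f"(p = {ff['p']:.2g}); fit slope {ff['slope']:.2f}, "
                  f"intercept {ff['intercept']:.1f} mL; fat > fluid in "
                  f"{ff['n_fat_greater']}/{report['n_subjects']} subjects"]
    return "\n".join(lines) + "\n"


__all__ = ["ALPHA", "SPEARMAN_EXACT_MAX_N", "LinearFit", "test_normality",
           "paired_comparison", "correlate", "relative_excess_table",
           "cohort_report", "format_report"]
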