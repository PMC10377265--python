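"""Model-comparison statistics: descriptives, one-way ANOVA, exact Wilcoxon.

Replicated accuracies of competing classifiers are compared three ways:

* per-model descriptive summaries (min, quartiles by linear interpolation,
  median, max, range, mean, sample SD, SEM, sum);
* a one-way ANOVA across models, computable either from the raw replicate
  values or — when only a printed summary table survives — reconstructed
  from per-group means and SDs with equal n, using
  SS_treat = n * sum_i (mean_i - grand mean)^2 and
  SS_resid = (n - 1) * sum_i sd_i^2;
* a one-sample Wilcoxon signed-rank test of each model's replicates against
  a theoretical median (zero by default). For n <= 25 the p-value is exact:
  the null distribution of W+ over all 2^n equiprobable sign assignments is
  computed in full (via its generating polynomial over doubled ranks, which
  enumerates every assignment's contribution without materializing them);
  above that a normal approximation with continuity and tie corrections is
  used. Zero differences are dropped; ties receive mid-ranks.

For n replicates all on one side of the theoretical median, the exact
two-sided p is 2 * 2^-n — e.g. 10 positive replicates give W+ = 55 and
p = 2/1024, printed as 0.002.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "WilcoxonResult",
    "describe",
    "one_way_anova",
    "anova_from_summaries",
    "wilcoxon_one_sample",
    "comparison_report",
    "format_p",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class GroupSummary:
    n: int
    minimum: float
    p25: float
    median: float
    p75: float
    maximum: float
    range: float
    mean: float
    sd: float
    sem: float
    sum: float


@dataclass(frozen=True)
class AnovaResult:
    ss_treatment: float
    ss_residual: float
    ss_total: float
    df_treatment: int
    df_residual: int
    df_total: int
    ms_treatment: float
    ms_residual: float
    f_ratio: float
    p_value: float


@dataclass(frozen=True)
class WilcoxonResult:
    actual_median: float
    theoretical_median: float
    n: int
    w_plus: float
    w_minus: float
    w_signed: float
    p_value: float          # two-sided (default reporting)
    p_value_one_sided: float
    exact: bool


def describe(values) -> GroupSummary:
    """Descriptive summary; sample SD (n-1), interpolated percentiles."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot describe an empty list")
    n = int(v.size)
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    return GroupSummary(
        n=n,
        minimum=float(v.min()),
        p25=float(np.percentile(v, 25)),
        median=float(np.median(v)),
        p75=float(np.percentile(v, 75)),
        maximum=float(v.max()),
        range=float(v.max() - v.min()),
        mean=float(v.mean()),
        sd=sd,
        sem=sd / math.sqrt(n),
        sum=float(v.sum()),
    )


def _finish_anova(ss_t: float, ss_r: float, df_t: int, df_r: int) -> AnovaResult:
    ms_t = ss_t / df_t
    ms_r = ss_r / df_r
    if ms_r > 0:
        f = ms_t / ms_r
        p = float(sps.f.sf(f, df_t, df_r))
    else:
        f = math.inf if ms_t > 0 else 0.0
        p = 0.0 if ms_t > 0 else 1.0
    return AnovaResult(
        ss_treatment=ss_t, ss_residual=ss_r, ss_total=ss_t + ss_r,
        df_treatment=df_t, df_residual=df_r, df_total=df_t + df_r,
        ms_treatment=ms_t, ms_residual=ms_r, f_ratio=f, p_value=p,
    )


def one_way_anova(groups) -> AnovaResult:
    """Textbook one-way fixed-effects ANOVA from raw per-group values."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    all_v = np.concatenate(arrs)
    grand = all_v.mean()
    ss_t = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrs))
    ss_r = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    return _finish_anova(ss_t, ss_r, len(arrs) - 1, all_v.size - len(arrs))


def anova_from_summaries(means, sds, n_per_group: int) -> AnovaResult:
    """Rebuild the one-way ANOVA from per-group means and SDs (equal n)."""
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have the same length")
    if means.size < 2:
        raise ValueError("ANOVA needs at least two groups")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    k = means.size
    grand = means.mean()  # equal n: grand mean is the mean of means
    ss_t = float(n_per_group * ((means - grand) ** 2).sum())
    ss_r = float((n_per_group - 1) * (sds ** 2).sum())
    return _finish_anova(ss_t, ss_r, k - 1, k * (n_per_group - 1))


def _exact_sf_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments by doubled W+ value.

    Expanding prod_i (1 + x^{2 r_i}) term by term walks every one of the
    2^n sign assignments; coefficient j of the product is the number of
    assignments with W+ = j/2.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for dr in doubled_ranks:
        counts[dr:] += counts[: counts.size - dr].copy()
    return counts


def wilcoxon_one_sample(values, theoretical_median: float = 0.0) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test; exact for n <= 25."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    diffs = v - theoretical_median
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences from the theoretical median are zero")
    ranks = sps.rankdata(np.abs(diffs))  # mid-ranks for ties
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w = min(w_plus, w_minus)
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.round(2.0 * ranks).astype(int)
        counts = _exact_sf_counts(doubled)
        total = Fraction(2) ** n
        dw = int(round(2.0 * w))
        cdf_count = int(round(counts[: dw + 1].sum()))
        p_one = Fraction(cdf_count, int(total))
        p_two = min(2 * p_one, Fraction(1))
        exact = True
        p_one_f, p_two_f = float(p_one), float(p_two)
    else:
        mean = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts ** 3 - tie_counts).sum() / 48.0
        )
        z = (w - mean + 0.5) / math.sqrt(var)
        p_one_f = float(sps.norm.cdf(z))
        p_two_f = min(2.0 * p_one_f, 1.0)
        exact = False
    return WilcoxonResult(
        actual_median=float(np.median(v)),
        theoretical_median=float(theoretical_median),
        n=int(n),
        w_plus=w_plus,
        w_minus=w_minus,
        w_signed=w_plus - w_minus,
        p_value=p_two_f,
        p_value_one_sided=p_one_f,
        exact=exact,
    )


def format_p(p: float) -> str:
    """Report style: values below 1e-4 print as '< 0.0001'."""
    return "< 0.0001" if p < 1e-4 else f"{p:.4g}"


def comparison_report(
    results_by_model: dict[str, list[float]],
    out_dir: str | Path,
    theoretical_median: float = 0.0,
    make_plots: bool = True,
) -> dict:
    """Descriptives + ANOVA + per-model Wilcoxon tables, CSV/JSON/plots.

    ``results_by_model`` maps model name -> replicate accuracies; replicate
    counts must be equal across models.
    """
    if len(results_by_model) < 2:
        raise ValueError("need at least two models to compare")
    counts = {m: len(v) for m, v in results_by_model.items()}
    n0 = next(iter(counts.values()))
    bad = [m for m, c in counts.items() if c != n0]
    if bad:
        raise ValueError(f"unequal replicate counts for model(s): {bad}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    desc_rows = {m: asdict(describe(v)) for m, v in results_by_model.items()}
    desc_df = pd.DataFrame(desc_rows)
    desc_df.to_csv(out_dir / "descriptives.csv")

    anova = one_way_anova(list(results_by_model.values()))
    anova_df = pd.DataFrame(
        {
            "source": ["Treatment", "Residual", "Total"],
            "SS": [anova.ss_treatment, anova.ss_residual, anova.ss_total],
            "DF": [anova.df_treatment, anova.df_residual, anova.df_total],
            "MS": [anova.ms_treatment, anova.ms_residual, ""],
            "F": [anova.f_ratio, "", ""],
            "p": [format_p(anova.p_value), "", ""],
        }
    )
    anova_df.to_csv(out_dir / "anova.csv", index=False)

    wil_rows = {}
    for m, v in results_by_model.items():
        r = wilcoxon_one_sample(v, theoretical_median)
        wil_rows[m] = asdict(r)
    wil_df = pd.DataFrame(wil_rows)
    wil_df.to_csv(out_dir / "wilcoxon.csv")

    bundle = {
        "descriptives": desc_rows,
        "anova": asdict(anova),
        "wilcoxon": wil_rows,
    }
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(bundle, fh, indent=2)

    if make_plots:
        _diagnostic_plots(results_by_model, out_dir)
    return bundle


def _diagnostic_plots(results_by_model: dict[str, list[float]], out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    residuals, fitted = [], []
    for v in results_by_model.values():
        v = np.asarray(v, dtype=np.float64)
        residuals.extend(v - v.mean())
        fitted.extend([v.mean()] * v.size)
    residuals = np.asarray(residuals)
    fitted = np.asarray(fitted)

    fig, ax = plt.subplots(figsize=(4, 4))
    sps.probplot(residuals, plot=ax)
    ax.set_title("QQ plot of ANOVA residuals")
    fig.tight_layout()
    fig.savefig(out_dir / "qq_residuals.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(fitted, residuals, s=12)
    ax.axhline(0.0, color="gray", lw=1)
    ax.set_xlabel("fitted group mean")
    ax.set_ylabel("residual")
    ax.set_title("Residuals vs fitted")
    fig.tight_layout()
    fig.savefig(out_dir / "residuals_vs_fit.png", dpi=100)
    plt.close(fig)
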