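"""Series-level statistics over per-spot audits.

Agreement between two Ki67% series (e.g. the machine's dD against the
expert-corrected cD) is assessed the standard two ways:

* ordinary least-squares regression of one series on the other, with
  the coefficient of determination R² = 1 - SS_res/SS_tot and the
  slope's t-test p-value, and
* Bland–Altman analysis: bias = mean(y - x), limits of agreement
  bias ± 1.96 · SD(y - x) with the sample (n-1) standard deviation.

Editing effort is summarized across spots: the fraction of cD nuclei
that required an expert edit, per-category breakdowns, and the
*savings fraction* 1 - edits/nuclei — a reviewed mark that needed no
edit is manual marking saved by the machine-generated starting point.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .audit import CATEGORY_EDIT, Category, EditKind, SpotAudit

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float = math.nan
    significant: bool | None = None  # slope t-test at the 0.05 level


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class EffortSummary:
    n_spots: int
    total_cd_nuclei: int
    total_edits: int
    pct_edits: float
    per_category_counts: dict[Category, int]
    per_category_pct: dict[Category, float]
    mean_marks_per_spot: float
    savings_fraction: float

    def rounded_pct(self, category: Category) -> float:
        """Category percentage rounded to one decimal for reporting."""
        return round(self.per_category_pct[category], 1)


def _drop_undefined(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d spot(s) with undefined Ki67%% pairwise", dropped)
    return x[keep], y[keep]


def linear_regression(x, y) -> RegressionResult:
    """OLS regression of y on x between two Ki67% series.

    Undefined (NaN) entries are removed pairwise.  Zero variance in x
    makes the slope unidentifiable and raises; zero variance in y
    yields a flat fit with R² defined as 0 and a warning.
    """
    x, y = _drop_undefined(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs at least 3 defined pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope is unidentifiable")
    if np.ptp(y) == 0:
        warnings.warn("zero variance in y: R^2 defined as 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                n=n, p_value=1.0, significant=False)
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue ** 2)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, n=n, p_value=float(fit.pvalue),
        significant=bool(fit.pvalue < 0.05),
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement of two series: bias and 95% limits.

    Differences are y - x; limits are bias ± 1.96 times the sample
    standard deviation of the differences.
    """
    x, y = _drop_undefined(x, y)
    n = len(x)
    if n < 2:
        raise ValueError(f"Bland-Altman needs at least 2 defined pairs, got {n}")
    diffs = y - x
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             n=n)


def summarize_counts(
    n_spots: int,
    total_cd_nuclei: int,
    per_category_counts: dict[Category, int],
) -> EffortSummary:
    """Effort summary straight from aggregate tallies.

    ``per_category_counts`` may omit categories (treated as zero);
    edits are the RELABEL + DELETE + ADD categories.  Percentages are
    relative to the cD nucleus total; ``savings_fraction`` is
    1 - edits/nuclei floored at 0 (more edits than nuclei means no
    saving, not negative saving).
    """
    if n_spots < 1:
        raise ValueError("need at least one spot")
    if total_cd_nuclei <= 0:
        raise ValueError("total_cd_nuclei must be positive")
    counts = {cat: int(per_category_counts.get(cat, 0)) for cat in Category}
    total_edits = sum(c for cat, c in counts.items()
                      if CATEGORY_EDIT[cat] is not EditKind.NONE)
    pct = {cat: 100.0 * c / total_cd_nuclei for cat, c in counts.items()}
    return EffortSummary(
        n_spots=n_spots,
        total_cd_nuclei=total_cd_nuclei,
        total_edits=total_edits,
        pct_edits=100.0 * total_edits / total_cd_nuclei,
        per_category_counts=counts,
        per_category_pct=pct,
        mean_marks_per_spot=total_cd_nuclei / n_spots,
        savings_fraction=max(0.0, 1.0 - total_edits / total_cd_nuclei),
    )


def summarize_effort(audits: list[SpotAudit]) -> EffortSummary:
    """Aggregate per-spot audits into one effort summary.

    Permutation-invariant over spots: only sums enter the result.
    """
    if not audits:
        raise ValueError("no audits to summarize")
    counts = {cat: sum(a.tallies.get(cat, 0) for a in audits) for cat in Category}
    total_cd = sum(a.n_cd_nuclei for a in audits)
    return summarize_counts(len(audits), total_cd, counts)


def effort_to_json(summary: EffortSummary) -> dict:
    return {
        "n_spots": summary.n_spots,
        "total_cd_nuclei": summary.total_cd_nuclei,
        "total_edits": summary.total_edits,
        "pct_edits": round(summary.pct_edits, 1),
        "savings_fraction": round(summary.savings_fraction, 3),
        "mean_marks_per_spot": round(summary.mean_marks_per_spot, 1),
        "per_category_counts": {c.value: n for c, n in
                                summary.per_category_counts.items()},
        "per_category_pct": {c.value: round(p, 1) for c, p in
                             summary.per_category_pct.items()},
    }


def write_summary_json(summary: EffortSummary,
                       regression: RegressionResult | None,
                       ba: BlandAltmanResult | None,
                       path: str | Path) -> Path:
    obj = {"effort": effort_to_json(summary)}
    if regression is not None:
        obj["regression_cd_on_dd"] = {
            "slope": regression.slope, "intercept": regression.intercept,
            "r_squared": regression.r_squared, "n": regression.n,
            "p_value": regression.p_value, "significant": regression.significant,
        }
    if ba is not None:
        obj["bland_altman_cd_minus_dd"] = {
            "bias": ba.bias, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n,
        }
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2) + "\n")
    return path


def plot_regression(x, y, result: RegressionResult, path: str | Path,
                    xlabel: str = "Ki67% (dD)", ylabel: str = "Ki67% (cD)") -> Path:
    """Scatter + fitted line, written to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _drop_undefined(x, y)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "r-",
            label=f"y = {result.slope:.3f}x + {result.intercept:.2f}\n"
                  f"$R^2$ = {result.r_squared:.3f} (n={result.n})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(x, y, result: BlandAltmanResult, path: str | Path) -> Path:
    """Mean-vs-difference plot with bias and limits of agreement, to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _drop_undefined(x, y)
    means = (x + y) / 2.0
    diffs = y - x
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    for v, style in [(result.bias, "r-"), (result.loa_low, "r--"),
                     (result.loa_high, "r--")]:
        ax.axhline(v, ls=style[1:], color="r", lw=1)
    ax.set_xlabel("mean Ki67% of the two sets")
    ax.set_ylabel("difference (cD - dD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
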