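"""Practical-identifiability diagnostics from the multistart ensemble.

Near-degenerate parameter combinations (the classic K1-k2 exchange ridge)
show up as elongated structures in the cloud of near-optimal fits.  This
module extracts the near-optimal subset (reduced chi-square within 1 of the
best fit), computes pairwise Pearson correlations per organ (with the
shared gamma/tau columns appended), tests their consistency across subjects
with an exact Wilcoxon signed-rank test, and renders heatmaps and 2-D
kernel-density summaries of chosen parameter pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, wilcoxon

from .fitting import FitResult, MultistartEnsemble
from .organs import ORGAN_IDS

__all__ = [
    "CorrelationReport",
    "near_optimal_set",
    "correlation_matrix",
    "significance_across_subjects",
    "pair_density_grid",
    "plot_correlation_heatmap",
    "plot_pair_density",
    "SHARED_PARAMS",
]

SHARED_PARAMS = ("gamma", "tau")


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations over the near-optimal parameter cloud."""

    organ: str
    r: pd.DataFrame  # symmetric, unit diagonal; NaN where undefined
    n_points: int


def near_optimal_set(
    ensemble: MultistartEnsemble, window: float = 1.0
) -> list[FitResult]:
    """Results whose reduced chi-square is within ``window`` of the best.

    The subset depends only on the chi-square values, so swapping the point
    estimate between the best fit and the KDE mode cannot change it.
    """
    cut = ensemble.best.chi2_nu + window
    return [r for r in ensemble.results if r.chi2_nu <= cut]


def organ_columns(spec_names: tuple[str, ...], organ: str) -> list[str]:
    """This organ's parameter names plus the shared corrections."""
    own = [
        n
        for n in spec_names
        if n.endswith(f"_{organ}") and not n.startswith("delay")
    ]
    delays = [n for n in spec_names if n == f"delay_{organ}"]
    return list(SHARED_PARAMS) + delays + own


def correlation_matrix(
    subset: list[FitResult], organ_scope: str
) -> CorrelationReport:
    """Pearson r over the subset for one organ's block (plus gamma, tau).

    A zero-variance parameter leaves its pairs undefined (NaN), not zero.
    """
    if len(subset) < 3:
        raise ValueError(
            f"correlation undefined: near-optimal set has {len(subset)} < 3 points"
        )
    spec = subset[0].params.spec
    cols = organ_columns(spec.names, organ_scope)
    mat = np.array([[r.params[c] for c in cols] for r in subset])
    sd = mat.std(axis=0)
    centered = mat - mat.mean(axis=0)
    cov = centered.T @ centered / len(subset)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.isinf(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationReport(
        organ=organ_scope,
        r=pd.DataFrame(corr, index=cols, columns=cols),
        n_points=len(subset),
    )


def significance_across_subjects(
    reports: list[CorrelationReport], pair: tuple[str, str], alpha: float = 0.05
) -> tuple[bool, float]:
    """Exact two-sided Wilcoxon signed-rank test of r(pair) != 0 over subjects.

    Returns ``(significant, p_value)``.  Requires at least 5 subjects with a
    defined correlation for the pair; zero-valued correlations are dropped,
    as in the standard signed-rank treatment.
    """
    a, b = pair
    rs = []
    for rep in reports:
        if a not in rep.r.index or b not in rep.r.columns:
            raise KeyError(f"pair {pair} not in report for {rep.organ}")
        val = rep.r.loc[a, b]
        if np.isnan(val):
            raise ValueError(
                f"correlation for {pair} undefined in subject report; exclude it"
            )
        rs.append(float(val))
    if len(rs) < 5:
        raise ValueError("need at least 5 subjects for the signed-rank test")
    rs = [r for r in rs if r != 0.0]
    if not rs:
        return False, 1.0
    stat = wilcoxon(rs, alternative="two-sided", method="exact")
    return bool(stat.pvalue < alpha), float(stat.pvalue)


def all_pair_significance(
    reports_by_subject: list[dict[str, CorrelationReport]], organ: str
) -> pd.DataFrame:
    """Significance flags and p-values for every pair in one organ's block.

    Pairs with an undefined correlation in any subject are excluded (NaN p).
    """
    per_subject = [reps[organ] for reps in reports_by_subject]
    cols = list(per_subject[0].r.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            try:
                sig, p = significance_across_subjects(per_subject, (a, b))
            except ValueError:
                sig, p = False, np.nan
            rows.append({"param_a": a, "param_b": b, "p": p, "significant": sig})
    return pd.DataFrame(rows)


def pair_density_grid(
    subset: list[FitResult],
    pair: tuple[str, str],
    n_grid: int = 101,
    pad_sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D Gaussian KDE of a parameter pair over the near-optimal cloud.

    Returns ``(x, y, density)`` on a grid wide enough (``pad_sd`` sample SDs
    beyond the data range) that the density mass on it is ~1.
    """
    xs = np.array([r.params[pair[0]] for r in subset])
    ys = np.array([r.params[pair[1]] for r in subset])
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("pair density undefined for zero-variance parameter")
    kde = gaussian_kde(np.vstack([xs, ys]))
    x = np.linspace(xs.min() - pad_sd * xs.std(), xs.max() + pad_sd * xs.std(), n_grid)
    y = np.linspace(ys.min() - pad_sd * ys.std(), ys.max() + pad_sd * ys.std(), n_grid)
    gx, gy = np.meshgrid(x, y)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return x, y, dens


# ----------------------------------------------------------------------
# plotting


def plot_correlation_heatmap(report: CorrelationReport, ax=None):
    """Correlation heatmap for one organ's parameter block."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    vals = report.r.to_numpy()
    im = ax.imshow(vals, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(report.r.columns)))
    ax.set_xticklabels(report.r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(report.r.index)))
    ax.set_yticklabels(report.r.index, fontsize=7)
    ax.set_title(f"{report.organ} (n={report.n_points})", fontsize=9)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax


def plot_pair_density(subset: list[FitResult], pair: tuple[str, str], ax=None):
    """Scatter + KDE contours of a parameter pair in the near-optimal set."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.6))
    x, y, dens = pair_density_grid(subset, pair)
    ax.contourf(x, y, dens, levels=12, cmap="viridis")
    ax.plot(
        [r.params[pair[0]] for r in subset],
        [r.params[pair[1]] for r in subset],
        ".", ms=3, color="w", alpha=0.6,
    )
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    return ax
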