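"""Trajectory summaries and figure-style outputs.

Reduces a damage trajectory to per-measure curve summaries (mean and SD per
iteration, a rank-correlation trend statistic, and an interior-peak detector
for inverted-U shapes), and renders the classic mean-line-plus-SD-band
panels, one per outcome measure per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .damage import MEASURES, DamageTrajectory

__all__ = ["CurveSummary", "summarize", "trend_permutation_pvalue",
           "render_curves"]


@dataclass
class CurveSummary:
    """Shape statistics of one outcome measure across a damage schedule."""

    measure: str
    mean: np.ndarray
    sd: np.ndarray
    trend_rho: float          # Spearman rank correlation of mean vs iteration
    trend_p: float            # permutation p-value, two-sided
    peak_index: int | None    # interior argmax if it clears both endpoints


def trend_permutation_pvalue(
    mean_curve: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman trend of a curve against iteration, permutation-calibrated.

    Returns ``(rho, p)``; ``alternative`` is "two-sided", "less" (negative
    trend) or "greater".
    """
    x = np.arange(len(mean_curve))
    rho = stats.spearmanr(x, mean_curve).statistic
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for k in range(n_permutations):
        perm[k] = stats.spearmanr(x, rng.permutation(mean_curve)).statistic
    if alternative == "less":
        p = float((np.sum(perm <= rho) + 1) / (n_permutations + 1))
    elif alternative == "greater":
        p = float((np.sum(perm >= rho) + 1) / (n_permutations + 1))
    else:
        p = float((np.sum(np.abs(perm) >= abs(rho)) + 1) / (n_permutations + 1))
    return float(rho), p


def detect_interior_peak(mean_curve: np.ndarray, margin: float = 0.0) -> int | None:
    """Index of an interior maximum exceeding both endpoints by ``margin``."""
    if len(mean_curve) < 3:
        return None
    k = int(np.argmax(mean_curve[1:-1])) + 1
    if (mean_curve[k] > mean_curve[0] + margin
            and mean_curve[k] > mean_curve[-1] + margin):
        return k
    return None


def summarize(
    trajectory: DamageTrajectory,
    peak_margin_sd: float = 0.5,
    seed: int = 0,
) -> dict[str, CurveSummary]:
    """Per-measure curve summaries of a damage trajectory.

    The interior-peak margin is ``peak_margin_sd`` times the mean
    across-realization SD of the measure, so a flat curve whose wiggles stay
    within realization noise reports no peak.
    """
    if trajectory.n_iterations < 3:
        raise ValueError("need at least 3 iterations to summarise a curve")
    out = {}
    for m in MEASURES:
        mean, sd = trajectory.aggregate(m)
        rho, p = trend_permutation_pvalue(mean, seed=seed)
        margin = peak_margin_sd * float(np.nanmean(sd))
        out[m] = CurveSummary(
            measure=m, mean=mean, sd=sd, trend_rho=rho, trend_p=p,
            peak_index=detect_interior_peak(mean, margin=margin),
        )
    return out


def render_curves(
    summaries: dict[str, dict[str, CurveSummary]],
    path: str | Path,
    dpi: int = 150,
) -> Path:
    """Mean-line + SD-band panels: one row per experiment, one column per
    measure. ``summaries`` maps experiment name -> per-measure summaries.
    Writes ``curves.png`` plus one deterministic TSV per experiment.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not summaries:
        raise ValueError("no summaries to render")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_rows = len(summaries)
    fig, axes = plt.subplots(n_rows, len(MEASURES),
                             figsize=(4 * len(MEASURES), 3 * n_rows),
                             squeeze=False)
    for i, (name, per_measure) in enumerate(sorted(summaries.items())):
        rows = {"iteration": np.arange(len(next(iter(per_measure.values())).mean))}
        for j, m in enumerate(MEASURES):
            cs = per_measure[m]
            ax = axes[i][j]
            x = np.arange(len(cs.mean))
            ax.plot(x, cs.mean, "--", color="C0")
            ax.fill_between(x, cs.mean - cs.sd, cs.mean + cs.sd,
                            alpha=0.3, color="C0")
            ax.set_title(f"{name}: {m}", fontsize=9)
            ax.set_xlabel("iteration")
            rows[f"{m}_mean"] = cs.mean
            rows[f"{m}_sd"] = cs.sd
        import pandas as pd
        pd.DataFrame(rows).to_csv(path / f"{name}_curves.tsv", sep="\t",
                                  index=False, float_format="%.10g")
    fig.tight_layout()
    out = path / "curves.png"
    fig.savefig(out, dpi=dpi)
    plt.close(fig)
    return out


def departure_fraction(
    mean: np.ndarray,
    sd: np.ndarray,
    fractions: np.ndarray,
    k: float = 2.0,
    sustain: int = 1,
) -> float:
    """Damage fraction at which a curve first departs its baseline.

    Departure = |mean[i] - mean[0]| > k * band for ``sustain`` consecutive
    iterations, where the band is the larger of the baseline SD and the
    median across-iteration SD (so a single lucky baseline draw cannot
    shrink the band to nothing). Returns ``inf`` when the curve never
    leaves the baseline band.
    """
    band = k * max(float(sd[0]), float(np.median(sd)))
    outside = np.abs(mean - mean[0]) > band
    run = 0
    for i in range(1, len(mean)):
        run = run + 1 if outside[i] else 0
        if run >= sustain:
            return float(fractions[i - sustain + 1])
    return float("inf")
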