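"""Agreement statistics between simulated and observed distributions.

Provides per-segment percentage-point differences and their average,
Spearman rank correlation (mid-ranks for ties), and Bland-Altman analysis
with limits of agreement (mean +/- z*SD, sample SD with n-1 denominator)
and their 95% confidence intervals:

    mean CI:  mean +/- t(0.975, n-1) * SD / sqrt(n)
    LoA CI:   LoA  +/- t(0.975, n-1) * SD * sqrt(1/n + z^2 / (2 (n-1)))
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlandAltman",
    "ValidationReport",
    "pp_differences",
    "average_difference",
    "spearman_rho",
    "bland_altman",
    "validate_distributions",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_of_differences: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    n: int
    z: float = 1.96


@dataclass
class ValidationReport:
    differences: dict[str, float]       # per-segment |simulated - observed|, pp
    average_difference: float           # pp
    spearman_rho: float
    bland_altman: BlandAltman

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bland_altman"] = asdict(self.bland_altman)
        return d


def pp_differences(simulated: dict[str, float],
                   observed: dict[str, float]) -> dict[str, float]:
    """Per-segment absolute difference in percentage points."""
    if set(simulated) != set(observed):
        raise ValueError(
            f"segment sets differ: {sorted(set(simulated) ^ set(observed))}")
    for name, dist in (("simulated", simulated), ("observed", observed)):
        s = sum(dist.values())
        if abs(s - 100.0) > 1e-6 * 100.0:
            raise ValueError(f"{name} distribution sums to {s}, expected 100")
    return {seg: abs(simulated[seg] - observed[seg]) for seg in sorted(simulated)}


def average_difference(diffs) -> float:
    """Arithmetic mean of per-segment absolute differences (pp)."""
    values = list(diffs.values()) if isinstance(diffs, dict) else list(diffs)
    if not values:
        raise ValueError("at least one segment difference is required")
    return float(np.mean(values))


def spearman_rho(a, b) -> float:
    """Spearman rank correlation with mid-rank tie handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("at least 3 paired values are required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def bland_altman(a, b, z: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement of paired measurements (differences d = a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("at least 2 paired values are required")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = mean - z * sd
    loa_high = mean + z * sd
    t = float(sps.t.ppf(0.975, n - 1))
    half_mean = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
    return BlandAltman(
        mean_difference=mean,
        sd_of_differences=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_mean=(mean - half_mean, mean + half_mean),
        ci_loa_low=(loa_low - half_loa, loa_low + half_loa),
        ci_loa_high=(loa_high - half_loa, loa_high + half_loa),
        n=n,
        z=z,
    )


def validate_distributions(simulated: dict[str, float],
                           observed: dict[str, float]) -> ValidationReport:
    """Full agreement report between two per-segment percent distributions."""
    diffs = pp_differences(simulated, observed)
    segs = sorted(simulated)
    sim = [simulated[s] for s in segs]
    obs = [observed[s] for s in segs]
    try:
        rho = spearman_rho(sim, obs)
    except ValueError:
        rho = float("nan")
    return ValidationReport(
        differences=diffs,
        average_difference=average_difference(diffs),
        spearman_rho=rho,
        bland_altman=bland_altman(np.array(sim), np.array(obs)),
    )


def bland_altman_plot(a, b, path, z: float = 1.96) -> None:
    """Scatter of differences vs means with mean, LoA lines and CI bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b, z=z)
    means = (a + b) / 2.0
    diffs = a - b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="k", zorder=3)
    ax.axhline(ba.mean_difference, color="tab:blue")
    for loa, ci in ((ba.loa_low, ba.ci_loa_low), (ba.loa_high, ba.ci_loa_high)):
        ax.axhline(loa, color="tab:blue", linestyle=":")
        ax.errorbar([means.max()], [loa],
                    yerr=[[loa - ci[0]], [ci[1] - loa]],
                    fmt="none", ecolor="tab:red", capsize=3)
    ax.errorbar([means.max()], [ba.mean_difference],
                yerr=[[ba.mean_difference - ba.ci_mean[0]],
                      [ba.ci_mean[1] - ba.mean_difference]],
                fmt="none", ecolor="tab:red", capsize=3)
    ax.set_xlabel("mean of paired values (%)")
    ax.set_ylabel("difference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
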