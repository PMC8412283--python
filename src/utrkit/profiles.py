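"""Germline fluorescence line-profile binning and per-bin statistics.

Reporter quantification draws a line from the distal tip of the germline to
the last oocyte and records one intensity per axial pixel.  Each animal's
profile is partitioned into a fixed number of contiguous bins (20 for
endogenous-reporter strains, 10 for transgene strains) and summarised by the
bin mean; groups of animals are then compared bin by bin.

Two testing chains are provided, matching common two-condition and
shared-control designs:

* two conditions — per-bin two-sample two-tailed pooled-variance Student
  t-test (``per_bin_ttest``);
* several treated conditions vs one control — per-bin one-way ANOVA for
  overall significance, Fisher's LSD pairwise p-values against the control
  using the ANOVA pooled within-group mean square, then a Bonferroni
  adjustment that multiplies each p-value by the number of hypotheses
  (``anova_lsd_bonferroni``).

Degenerate zero-variance bins follow a fixed convention — p = 1 when the
group means agree, p = 0 when they differ — so identical data can never be
called significant.  Significance is adjusted p ≤ 0.05 throughout.

The nuclear/cytoplasmic statistic averages, per animal, the nuclear-over-
cytoplasmic mean-intensity ratio of the two most proximal oocytes, and
compares groups of per-animal ratios with the same pooled t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "LineProfile",
    "BinnedProfile",
    "BinStatsResult",
    "NucCytMeasurement",
    "NucCytResult",
    "bin_profile",
    "group_summary",
    "per_bin_ttest",
    "anova_lsd_bonferroni",
    "nuc_cyt_ratio_test",
    "plot_bin_summary",
]

ALPHA = 0.05  # significance threshold on adjusted p, per the figure legends


class InsufficientDataError(ValueError):
    """Fewer data points than the operation requires."""


@dataclass(frozen=True)
class LineProfile:
    """Per-pixel intensities along the distal→proximal germline axis."""

    animal_id: str
    condition: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
            raise ValueError("intensities must be finite and >= 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_pixels(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class BinnedProfile:
    """Fixed-bin summary of one animal's line profile."""

    animal_id: str
    condition: str
    bin_means: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bin_means", np.asarray(self.bin_means, dtype=float)
        )

    @property
    def n_bins(self) -> int:
        return self.bin_means.size


@dataclass(frozen=True)
class BinStatsResult:
    """Per-bin group summaries and (adjusted) p-values for one comparison.

    ``table`` columns: bin (1-based), per-group mean/sd/n, the test
    statistic, p_raw, p_adj, significant.  ``method`` tags the chain used.
    """

    method: str
    table: pd.DataFrame

    @property
    def significant_bins(self) -> list[int]:
        return self.table.loc[self.table["significant"], "bin"].tolist()


@dataclass(frozen=True)
class NucCytMeasurement:
    """Paired nuclear/cytoplasmic mean intensities for the two most
    proximal oocytes of one animal (oocyte order: rank 1 then rank 2)."""

    animal_id: str
    condition: str
    nuclear: tuple[float, float]
    cytoplasmic: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.nuclear) != 2 or len(self.cytoplasmic) != 2:
            raise ValueError("exactly two oocyte pairs per animal")
        if min(self.cytoplasmic) <= 0:
            raise ValueError(
                f"animal {self.animal_id!r}: cytoplasmic intensity must be > 0"
            )

    @property
    def animal_ratio(self) -> float:
        """Mean over the two oocytes of nuclear/cytoplasmic."""
        return float(
            np.mean([n / c for n, c in zip(self.nuclear, self.cytoplasmic)])
        )


def bin_pixel_slices(n_pixels: int, n_bins: int) -> list[slice]:
    """Contiguous bin boundaries: the first (n_pixels mod n_bins) bins take
    one extra pixel, so bin sizes differ by at most 1."""
    edges = np.cumsum([0] + [len(part) for part in np.array_split(np.empty(n_pixels), n_bins)])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def bin_profile(profile: LineProfile, n_bins: int) -> BinnedProfile:
    """Partition the pixels into ``n_bins`` contiguous runs and average each."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if profile.n_pixels < n_bins:
        raise InsufficientDataError(
            f"animal {profile.animal_id!r}: {profile.n_pixels} pixels "
            f"< {n_bins} bins"
        )
    means = np.array(
        [chunk.mean() for chunk in np.array_split(profile.intensities, n_bins)]
    )
    return BinnedProfile(profile.animal_id, profile.condition, means)


def _stack(binned: Iterable[BinnedProfile]) -> np.ndarray:
    """(n_animals, n_bins) matrix; raises on mixed bin counts."""
    profiles = list(binned)
    if not profiles:
        raise InsufficientDataError("empty group")
    n_bins = {p.n_bins for p in profiles}
    if len(n_bins) != 1:
        raise ValueError(f"mixed n_bins in one group: {sorted(n_bins)}")
    return np.vstack([p.bin_means for p in profiles])


def group_summary(binned: Iterable[BinnedProfile]) -> pd.DataFrame:
    """Per-bin mean and sample SD (n−1) across animals.

    With a single animal the SD column is NaN (flagged undefined).
    """
    data = _stack(binned)
    n = data.shape[0]
    sd = data.std(axis=0, ddof=1) if n >= 2 else np.full(data.shape[1], np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(1, data.shape[1] + 1),
            "mean": data.mean(axis=0),
            "sd": sd,
            "n": n,
        }
    )


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample two-tailed t over columns.

    Zero pooled variance: p = 1 if the means agree else 0 (t = 0 / ±inf).
    """
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise InsufficientDataError("each group needs >= 2 animals")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    df = na + nb - 2
    pooled_var = (ssa + ssb) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def per_bin_ttest(
    group_a: Iterable[BinnedProfile],
    group_b: Iterable[BinnedProfile],
    m: int = 1,
    alpha: float = ALPHA,
) -> BinStatsResult:
    """Per-bin pooled-variance two-tailed t-test between two conditions.

    With ``m = 1`` (a single planned comparison) adjusted p equals raw p;
    larger ``m`` applies the Bonferroni multiply-and-cap rule.
    """
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups disagree on n_bins")
    t, p_raw = _pooled_t(a, b)
    p_adj = np.minimum(1.0, p_raw * m)
    sd_a = a.std(axis=0, ddof=1)
    sd_b = b.std(axis=0, ddof=1)
    table = pd.DataFrame(
        {
            "bin": np.arange(1, a.shape[1] + 1),
            "mean_a": a.mean(axis=0),
            "sd_a": sd_a,
            "n_a": a.shape[0],
            "mean_b": b.mean(axis=0),
            "sd_b": sd_b,
            "n_b": b.shape[0],
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj <= alpha,
        }
    )
    return BinStatsResult(method="t-test", table=table)


def anova_lsd_bonferroni(
    groups: Mapping[str, Iterable[BinnedProfile]],
    control: str,
    m: int | None = None,
    alpha: float = ALPHA,
) -> dict[str, BinStatsResult]:
    """Shared-control chain: per-bin one-way ANOVA, Fisher's LSD vs control,
    Bonferroni by multiplication.

    Per bin, the one-way ANOVA F/p across all conditions gives overall
    significance; each treated condition is then compared to the control
    with Fisher's LSD — a t-test whose denominator uses the ANOVA pooled
    within-group mean square and its N−k degrees of freedom.  Adjusted
    p = min(1, raw p × m); ``m`` defaults to (number of treated conditions)
    × n_bins.  Returns one result per treated condition; each table also
    carries the shared anova_F / anova_p columns.
    """
    if control not in groups:
        raise ValueError(f"control condition {control!r} not among groups")
    stacked = {cond: _stack(profs) for cond, profs in groups.items()}
    n_bins_set = {arr.shape[1] for arr in stacked.values()}
    if len(n_bins_set) != 1:
        raise ValueError("conditions disagree on n_bins")
    n_bins = n_bins_set.pop()
    treated = [c for c in stacked if c != control]
    if not treated:
        raise ValueError("need at least one treated condition")
    for cond, arr in stacked.items():
        if arr.shape[0] < 2:
            raise InsufficientDataError(f"condition {cond!r} has < 2 animals")
    if m is None:
        m = len(treated) * n_bins
    elif m < len(treated) * n_bins:
        warnings.warn(
            f"m={m} is smaller than the {len(treated) * n_bins} comparisons "
            "performed; adjusted p-values are anti-conservative",
            stacklevel=2,
        )

    arrays = list(stacked.values())
    k = len(arrays)
    N = sum(arr.shape[0] for arr in arrays)
    df_within = N - k
    grand_sum = sum(arr.sum(axis=0) for arr in arrays)
    grand_mean = grand_sum / N
    ss_within = sum(
        ((arr - arr.mean(axis=0)) ** 2).sum(axis=0) for arr in arrays
    )
    ss_between = sum(
        arr.shape[0] * (arr.mean(axis=0) - grand_mean) ** 2 for arr in arrays
    )
    msw = ss_within / df_within
    msb = ss_between / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = msb / msw
    anova_p = stats.f.sf(f_stat, k - 1, df_within)
    zero_msw = msw == 0
    f_stat = np.where(zero_msw, np.where(msb == 0, 0.0, np.inf), f_stat)
    anova_p = np.where(zero_msw, np.where(msb == 0, 1.0, 0.0), anova_p)

    ctrl = stacked[control]
    results: dict[str, BinStatsResult] = {}
    for cond in treated:
        arr = stacked[cond]
        diff = arr.mean(axis=0) - ctrl.mean(axis=0)
        se = np.sqrt(msw * (1.0 / arr.shape[0] + 1.0 / ctrl.shape[0]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_within)
        degenerate = se == 0
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
        p_raw = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p_raw)
        p_adj = np.minimum(1.0, p_raw * m)
        table = pd.DataFrame(
            {
                "bin": np.arange(1, n_bins + 1),
                "mean_a": arr.mean(axis=0),
                "sd_a": arr.std(axis=0, ddof=1),
                "n_a": arr.shape[0],
                "mean_b": ctrl.mean(axis=0),
                "sd_b": ctrl.std(axis=0, ddof=1),
                "n_b": ctrl.shape[0],
                "anova_F": f_stat,
                "anova_p": anova_p,
                "t": t,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": p_adj <= alpha,
            }
        )
        results[cond] = BinStatsResult(method="anova-lsd-bonferroni", table=table)
    return results


@dataclass(frozen=True)
class NucCytResult:
    """Per-animal nuclear/cytoplasmic ratios and the group comparison."""

    treated_ratios: np.ndarray
    control_ratios: np.ndarray
    t: float
    p: float


def nuc_cyt_ratio_test(
    treated: Sequence[NucCytMeasurement],
    control: Sequence[NucCytMeasurement],
) -> NucCytResult:
    """Average each animal's two oocyte nuclear/cytoplasmic ratios, then
    compare groups with a pooled two-sample two-tailed t-test."""
    tr = np.array([m.animal_ratio for m in treated])
    ct = np.array([m.animal_ratio for m in control])
    t, p = _pooled_t(tr[:, None], ct[:, None])
    return NucCytResult(
        treated_ratios=tr, control_ratios=ct, t=float(t[0]), p=float(p[0])
    )


def plot_bin_summary(
    summaries: Mapping[str, pd.DataFrame],
    path,
    significant_bins: Sequence[int] = (),
    ylabel: str = "fluorescence intensity (a.u.)",
) -> None:
    """Mean ± SD per bin for each condition; stars mark significant bins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, summ in summaries.items():
        ax.errorbar(
            summ["bin"], summ["mean"], yerr=summ["sd"], label=cond,
            capsize=2, marker="o", markersize=3,
        )
    top = max(
        float((summ["mean"] + summ["sd"].fillna(0)).max())
        for summ in summaries.values()
    )
    for b in significant_bins:
        ax.annotate("*", (b, top * 1.02), ha="center")
    ax.set_xlabel("bin (distal → proximal)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
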