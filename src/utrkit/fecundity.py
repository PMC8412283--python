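"""Brood-size comparisons and the differential-expression threshold filter.

Brood size — total eggs plus larvae produced over a hermaphrodite's fertile
period — is compared between a mutant and control strain with two
nonparametric tests on the pooled per-animal counts: the two-sided
Mann–Whitney U test (exact when the sample-size product is small and the
data are tie-free, otherwise the tie-corrected normal approximation) and
the two-sided two-sample Kolmogorov–Smirnov test (exact for small samples,
asymptotic otherwise).

Downstream of an external differential-expression fit, genes are called
significant when FDR < 0.05 and |log2 fold change| > 0.585 (≈ 1.5-fold);
both inequalities are strict.  Up/down gene sets from two experiments are
intersected per sign, with sign-discordant genes flagged rather than
counted as shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BroodDataset",
    "BroodComparison",
    "DEGSets",
    "OverlapResult",
    "compare_broods",
    "filter_deg",
    "overlap_sets",
]

LFC_MIN = 0.585  # |log2FC| threshold (~1.5-fold), strict
FDR_MAX = 0.05   # FDR threshold, strict

MW_EXACT_MAX_PRODUCT = 400  # exact MW enumeration when n*m <= this and no ties


@dataclass(frozen=True)
class BroodDataset:
    """Per-animal progeny counts for one condition, pooled over biological
    replicates (labels retained for stratified reporting)."""

    condition: str
    counts: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if counts.size and counts.min() < 0:
            raise ValueError("progeny counts must be >= 0")
        object.__setattr__(self, "counts", counts)
        if self.replicates is not None:
            reps = np.asarray(self.replicates, dtype=int)
            if reps.shape != counts.shape:
                raise ValueError("replicate labels must match counts")
            if reps.size and reps.min() < 1:
                raise ValueError("replicate labels start at 1")
            object.__setattr__(self, "replicates", reps)

    @property
    def n(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class BroodComparison:
    """Mann–Whitney and KS results for one mutant-vs-control comparison."""

    mutant: str
    control: str
    n_mutant: int
    n_control: int
    median_mutant: float
    median_control: float
    mw_u: float
    mw_p: float
    mw_method: str
    ks_d: float
    ks_p: float
    ks_method: str


def compare_broods(mutant: BroodDataset, control: BroodDataset) -> BroodComparison:
    """Two-sided Mann–Whitney U and two-sample KS on pooled brood counts.

    MW is exact when n·m ≤ 400 and the pooled data are tie-free, else the
    normal approximation with tie correction is used.  KS uses SciPy's
    small-sample exact computation where available, asymptotic otherwise.
    """
    x, y = mutant.counts, control.counts
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs >= 3 animals")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    mw_method = (
        "exact" if (x.size * y.size <= MW_EXACT_MAX_PRODUCT and not has_ties)
        else "asymptotic"
    )
    mw = stats.mannwhitneyu(x, y, alternative="two-sided", method=mw_method)
    ks = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    ks_method = "exact" if min(x.size, y.size) <= 25 else "asymptotic"
    return BroodComparison(
        mutant=mutant.condition,
        control=control.condition,
        n_mutant=x.size,
        n_control=y.size,
        median_mutant=float(np.median(x)),
        median_control=float(np.median(y)),
        mw_u=float(mw.statistic),
        mw_p=float(mw.pvalue),
        mw_method=mw_method,
        ks_d=float(ks.statistic),
        ks_p=float(ks.pvalue),
        ks_method=ks_method,
    )


@dataclass(frozen=True)
class DEGSets:
    """Up- and down-regulated gene sets after threshold filtering."""

    up: frozenset[str]
    down: frozenset[str]


def filter_deg(
    table: pd.DataFrame,
    lfc_min: float = LFC_MIN,
    fdr_max: float = FDR_MAX,
) -> DEGSets:
    """Strict-threshold DE filter: up = log2fc > lfc_min & fdr < fdr_max;
    down = log2fc < −lfc_min & fdr < fdr_max.

    ``table`` needs columns gene_id, log2fc, fdr; fdr must lie in [0, 1] and
    log2fc be finite.  Genes exactly on a threshold are excluded.
    """
    if not (lfc_min > 0 and fdr_max > 0):
        raise ValueError("thresholds must be > 0")
    missing = {"gene_id", "log2fc", "fdr"} - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    lfc = table["log2fc"].to_numpy(dtype=float)
    fdr = table["fdr"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        raise ValueError("log2fc must be finite")
    if np.any((fdr < 0) | (fdr > 1) | ~np.isfinite(fdr)):
        raise ValueError("fdr must lie in [0, 1]")
    passing = fdr < fdr_max
    genes = table["gene_id"].astype(str)
    return DEGSets(
        up=frozenset(genes[passing & (lfc > lfc_min)]),
        down=frozenset(genes[passing & (lfc < -lfc_min)]),
    )


@dataclass(frozen=True)
class OverlapResult:
    """Signed set overlap between two DE experiments (Venn counts)."""

    shared_up: frozenset[str]
    shared_down: frozenset[str]
    discordant: frozenset[str]
    n_up_a: int
    n_up_b: int
    n_down_a: int
    n_down_b: int

    @property
    def n_shared_up(self) -> int:
        return len(self.shared_up)

    @property
    def n_shared_down(self) -> int:
        return len(self.shared_down)

    @property
    def shared(self) -> frozenset[str]:
        """Sign-consistent shared genes (up∩up ∪ down∩down)."""
        return self.shared_up | self.shared_down


def overlap_sets(
    up_a: frozenset[str] | set[str],
    down_a: frozenset[str] | set[str],
    up_b: frozenset[str] | set[str],
    down_b: frozenset[str] | set[str],
) -> OverlapResult:
    """Per-sign intersections; genes changing direction between experiments
    are flagged discordant and never counted as shared."""
    up_a, down_a = frozenset(up_a), frozenset(down_a)
    up_b, down_b = frozenset(up_b), frozenset(down_b)
    return OverlapResult(
        shared_up=up_a & up_b,
        shared_down=down_a & down_b,
        discordant=(up_a & down_b) | (down_a & up_b),
        n_up_a=len(up_a),
        n_up_b=len(up_b),
        n_down_a=len(down_a),
        n_down_b=len(down_b),
    )
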