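"""ALBATRO: detecting length-biased alterations in transcription output.

Transcription-stalling DNA lesions hit long genes more often than short
ones, so their accumulation leaves a footprint in differential
expression: downregulated genes skew long.  ALBATRO quantifies that
footprint by comparing the gene-length distributions of up- and
downregulated DEGs with a two-sided Mann-Whitney / Wilcoxon rank-sum
test, after a Shapiro-Wilk screen on log10(length) that records why a
nonparametric test is the appropriate choice (gene-length distributions
are not normal).

The comparison is considered *informative* only when both directions
carry at least ``min_genes`` genes (default 100): with fewer genes the
length distributions are too sparse for a meaningful density
comparison, so the p-value is reported but flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEGSet

logger = logging.getLogger(__name__)

#: Minimum genes per direction for an informative comparison.
MIN_GENES = 100

#: Sample-size cap above which the Shapiro-Wilk screen subsamples.
_SHAPIRO_CAP = 5000

#: Both groups at or below this size use the exact rank-sum null.
_EXACT_MAX_N = 25


@dataclass
class LengthBiasResult:
    """Outcome of one up-vs-down gene-length comparison."""

    n_up: int
    n_down: int
    median_up: float | None
    median_down: float | None
    w_statistic: float | None
    p: float | None
    informative: bool
    normality_up_p: float | None = None
    normality_down_p: float | None = None
    density_up: tuple[np.ndarray, np.ndarray] | None = None
    density_down: tuple[np.ndarray, np.ndarray] | None = None
    min_genes: int = MIN_GENES
    n_unresolved: int = 0
    test: str = "Mann-Whitney rank-sum, two-sided (unpaired)"

    def to_dict(self) -> dict:
        d = {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "median_up": self.median_up,
            "median_down": self.median_down,
            "w_statistic": self.w_statistic,
            "p": self.p,
            "informative": self.informative,
            "normality_up_p": self.normality_up_p,
            "normality_down_p": self.normality_down_p,
            "min_genes": self.min_genes,
            "n_unresolved": self.n_unresolved,
            "test": self.test,
        }
        return d


# ---------------------------------------------------------------------------
# exact rank-sum null distribution (tie-aware)

def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p-value, valid with ties.

    Computes the full permutation null of the rank-sum statistic
    W = sum of midranks of *x* by dynamic programming over doubled
    midranks (integers even with ties), equivalent to enumerating all
    C(n1+n2, n1) group assignments.  The two-sided p-value is
    P(|W - E[W]| >= |w_obs - E[W]|) under that null.

    Returns ``(w_obs, p)`` where ``w_obs`` is the observed rank sum of *x*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r2 = np.round(2.0 * ranks).astype(np.int64)  # doubled midranks: integers
    w_obs2 = int(r2[:n1].sum())
    total = int(r2.sum())
    # dp[k, s] = number of size-k subsets with doubled-rank sum s
    max_s = total
    dp = np.zeros((n1 + 1, max_s + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        # iterate k downwards so each item is used once
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    counts = dp[n1]
    n_total = counts.sum()
    mean2 = n1 * (total / (n1 + n2))
    dev = abs(w_obs2 - mean2)
    s_vals = np.arange(max_s + 1)
    extreme = np.abs(s_vals - mean2) >= dev - 1e-9
    p = float(counts[extreme].sum() / n_total)
    return float(w_obs2 / 2.0), min(p, 1.0)


def ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact null when both n <= 25, else the
    normal approximation with tie correction and continuity correction.

    Returns ``(w, p)`` with ``w`` the rank sum of *x*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(np.concatenate([x, y]))) == 1:
        # all values identical: no information
        w = len(x) * (len(x) + len(y) + 1) / 2.0
        return w, 1.0
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        return exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    # scipy reports U for x; convert to the rank-sum of x
    w = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# supporting screens

def normality_screen(
    lengths_log10: np.ndarray, *, max_n: int = _SHAPIRO_CAP, seed: int = 0
) -> tuple[float, float]:
    """Shapiro-Wilk test on log10 lengths; subsamples (seeded) above *max_n*.

    Used to record that gene-length distributions depart from
    normality, motivating the rank-based test; the pipeline proceeds
    with the rank-sum test regardless of the outcome.
    """
    v = np.asarray(lengths_log10, dtype=float)
    if len(v) < 3:
        raise ValueError("normality screen needs n >= 3")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    if len(v) > max_n:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=max_n, replace=False)
    w, p = stats.shapiro(v)
    return float(w), float(p)


def length_density(lengths: np.ndarray, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of log10(length), Silverman bandwidth.

    Returns ``(grid, density)`` on a *n_grid*-point grid spanning the
    data plus three bandwidths on each side; the trapezoidal integral
    of the curve is 1.
    """
    v = np.log10(np.asarray(lengths, dtype=float))
    if len(v) < 2:
        raise ValueError("density needs n >= 2")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    bw = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, n_grid)
    dens = kde(grid)
    return grid, dens


# ---------------------------------------------------------------------------
# the statistic

def albatro(
    degs: DEGSet,
    annotation: pd.DataFrame | dict[str, float],
    min_genes: int = MIN_GENES,
    *,
    densities: bool = True,
    seed: int = 0,
) -> LengthBiasResult:
    """Compare gene-length distributions of up- vs downregulated DEGs.

    Parameters
    ----------
    degs
        The thresholded DEG lists.
    annotation
        Gene annotation table with ``gene_id`` and ``length`` columns,
        or a plain gene -> length (bp) mapping.  DEGs that cannot be
        resolved are dropped with a logged count.
    min_genes
        Minimum genes per direction for an informative call.

    Returns a :class:`LengthBiasResult`; medians are in bp, the
    normality screen and density curves operate on log10(length).
    """
    if isinstance(annotation, pd.DataFrame):
        length_map = dict(zip(annotation["gene_id"], annotation["length"]))
    else:
        length_map = dict(annotation)
    up_len = np.array([length_map[g] for g in degs.up if g in length_map], dtype=float)
    down_len = np.array([length_map[g] for g in degs.down if g in length_map], dtype=float)
    n_unres = (len(degs.up) - len(up_len)) + (len(degs.down) - len(down_len))
    if n_unres:
        logger.info("albatro: dropped %d DEG(s) without annotation", n_unres)

    n_up, n_down = len(up_len), len(down_len)
    informative = n_up >= min_genes and n_down >= min_genes
    if n_up == 0 or n_down == 0:
        return LengthBiasResult(
            n_up=n_up, n_down=n_down,
            median_up=float(np.median(up_len)) if n_up else None,
            median_down=float(np.median(down_len)) if n_down else None,
            w_statistic=None, p=None, informative=False,
            min_genes=min_genes, n_unresolved=n_unres,
        )

    w, p = ranksum_test(up_len, down_len)
    norm_up = norm_down = None
    if n_up >= 3 and np.ptp(up_len) > 0:
        norm_up = normality_screen(np.log10(up_len), seed=seed)[1]
    if n_down >= 3 and np.ptp(down_len) > 0:
        norm_down = normality_screen(np.log10(down_len), seed=seed + 1)[1]
    dens_up = dens_down = None
    if densities and n_up >= 2 and np.ptp(up_len) > 0:
        dens_up = length_density(up_len)
    if densities and n_down >= 2 and np.ptp(down_len) > 0:
        dens_down = length_density(down_len)

    return LengthBiasResult(
        n_up=n_up,
        n_down=n_down,
        median_up=float(np.median(up_len)),
        median_down=float(np.median(down_len)),
        w_statistic=w,
        p=p,
        informative=informative,
        normality_up_p=norm_up,
        normality_down_p=norm_down,
        density_up=dens_up,
        density_down=dens_down,
        min_genes=min_genes,
        n_unresolved=n_unres,
    )
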