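"""Preranked gene-set enrichment, Fisher ORA, and overlap enrichment factors.

The ranking metric follows the study convention of scoring each gene by
its signed log p-value.  Two orientations are offered:

* ``conventional`` (default): ``-log10(p) * sign(log2FC)`` — strongly
  upregulated, highly significant genes get the most *positive*
  statistic, the orientation classic GSEA expects;
* ``as_printed``: ``log10(p) / sign(log2FC)``, the literal formula of
  the source workflow, which inverts the axis (most significant
  upregulated genes most negative).  Retained for literal reproduction.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum with weight exponent 1; significance comes from permutation over
size-matched random gene sets, with NES normalized by the sign-matched
null mean, BH-adjusted p-values, and a max-statistic FWER estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class OverlapEnrichment:
    """Observed vs hypergeometric-expected overlap of two gene lists."""

    n_a: int
    n_b: int
    n_universe: int
    observed: int
    expected: float
    enrichment_factor: float | None
    p_hyper: float

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_universe": self.n_universe,
            "observed": self.observed, "expected": self.expected,
            "enrichment_factor": self.enrichment_factor, "p_hyper": self.p_hyper,
        }


# ---------------------------------------------------------------------------
# ranking

def rank_genes(results: pd.DataFrame, orientation: str = "conventional") -> pd.Series:
    """Build the ranked list from a DE table (signed log10 p metric).

    Returns a Series mapping gene_id -> rank statistic, sorted
    descending; ties are broken by gene ID so the ordering is
    deterministic.  Genes with log2fc exactly 0 score 0; p-values of 0
    are clamped to the smallest positive float (logged).
    """
    if orientation not in ("conventional", "as_printed"):
        raise ValueError(f"unknown orientation {orientation!r}")
    p = results["p"].to_numpy(dtype=float)
    lfc = results["log2fc"].to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise ValueError("log2fc must be finite")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.info("rank_genes: clamped %d zero p-value(s) to float tiny", n_zero)
        p = np.maximum(p, np.finfo(float).tiny)
    sign = np.sign(lfc)
    stat = np.where(sign == 0, 0.0, np.log10(p) / np.where(sign == 0, 1.0, sign))
    if orientation == "conventional":
        stat = -stat
    ranked = pd.Series(stat, index=pd.Index(results["gene_id"], name="gene_id"))
    if ranked.index.duplicated().any():
        raise ValueError("duplicate gene IDs in DE results")
    order = sorted(range(len(ranked)), key=lambda i: (-ranked.iloc[i], ranked.index[i]))
    return ranked.iloc[order]


# ---------------------------------------------------------------------------
# enrichment score

def gsea_es(
    ranked: pd.Series, gene_set, *, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score with running profile and leading edge.

    Hits increment the running sum by ``|stat|**weight / sum(|stat|**weight)``
    over hits; misses decrement by ``1/(N - Nh)``.  ES is the running-sum
    value of largest magnitude; the leading edge contains the hit genes
    up to (ES > 0) or after (ES < 0) the extremum.
    """
    genes = ranked.index.to_numpy()
    stat = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n, nh = len(genes), int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    w = np.abs(stat) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit statistics are zero: uniform hit weights
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    if n == nh:
        # no misses: running sum is the normalized cumulative hit weight
        running = np.cumsum(hit_w) / denom
    else:
        miss_pen = 1.0 / (n - nh)
        running = np.cumsum(hit_w / denom - np.where(hit, 0.0, miss_pen))
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def _es_only(stat: np.ndarray, hit_idx: np.ndarray, abs_stat: np.ndarray) -> float:
    """ES from hit positions only (fast path used by the permutation null)."""
    n = len(stat)
    k = len(hit_idx)
    pos = np.sort(hit_idx)
    w = abs_stat[pos]
    denom = w.sum()
    if denom == 0:
        w = np.ones(k)
        denom = float(k)
    cw = np.cumsum(w) / denom
    if n == k:
        return float(cw[np.argmax(np.abs(cw))])
    miss = 1.0 / (n - k)
    j = np.arange(1, k + 1)
    after = cw - (pos + 1 - j) * miss       # running sum just after each hit
    before = cw - w / denom - (pos - (j - 1)) * miss  # just before each hit
    hi = after.max()
    lo = min(before.min(), after.min() if k else 0.0)
    return float(hi if hi >= -lo else lo)


# ---------------------------------------------------------------------------
# permutation significance

def gsea_permutation(
    ranked: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA over size-matched random gene sets.

    For every set, ``n_perm`` random gene sets of the same size are
    drawn from the ranked universe to form the null ES distribution.
    The permutation p-value is ``(1 + #{|null ES| >= |ES|}) / (n_perm + 1)``
    (two-sided on magnitude, so the smallest attainable p is
    ``1/(n_perm + 1)``); NES divides ES by the mean |null ES| of
    matching sign; BH-adjusted p-values and a max-normalized-statistic
    FWER estimate across sets are also reported.

    Returns a DataFrame with columns
    ``set, size, es, nes, p_perm, p_adj, fwer, leading_edge``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    stat = ranked.to_numpy(dtype=float)
    abs_stat = np.abs(stat)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    normed_null: list[np.ndarray] = []   # per retained set: |null ES| / sign-matched mean
    observed_nes: list[float] = []

    for name, members in sets.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=np.int64)
        if len(idx) == 0:
            warnings.warn(f"gene set {name!r} does not intersect the universe; skipped",
                          UserWarning, stacklevel=2)
            continue
        size = len(idx)
        sub = ranked  # full universe
        es, _running, leading = gsea_es(sub, [genes[i] for i in idx], weight=weight)
        # fresh size-matched null per set: sharing draws across equal-sized
        # sets would correlate their p-values
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _es_only(stat, rng.choice(n, size=size, replace=False), abs_stat)
        p_perm = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) < 10:
            warnings.warn(f"gene set {name!r}: fewer than 10 same-sign null draws; NES omitted",
                          UserWarning, stacklevel=2)
            nes = np.nan
        else:
            nes = es / np.mean(np.abs(same_sign))
        # normalized null for the FWER max statistic
        mean_pos = np.mean(null[null > 0]) if (null > 0).any() else np.nan
        mean_neg = np.mean(np.abs(null[null < 0])) if (null < 0).any() else np.nan
        norm = np.where(null > 0, null / mean_pos,
                        np.where(null < 0, null / mean_neg, 0.0))
        normed_null.append(np.abs(norm))
        observed_nes.append(nes)
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes, "p_perm": p_perm,
             "leading_edge": leading}
        )

    if not rows:
        return pd.DataFrame(columns=["set", "size", "es", "nes", "p_perm",
                                     "p_adj", "fwer", "leading_edge"])
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
    max_stat = np.max(np.vstack(normed_null), axis=0)  # per-permutation max over sets
    fwer = []
    for nes in observed_nes:
        if np.isnan(nes):
            fwer.append(np.nan)
        else:
            fwer.append((1.0 + np.sum(max_stat >= abs(nes))) / (n_perm + 1.0))
    out["fwer"] = fwer
    return out[["set", "size", "es", "nes", "p_perm", "p_adj", "fwer", "leading_edge"]]


# ---------------------------------------------------------------------------
# overrepresentation and overlap

def ora_fisher(
    deg_list, gene_set, universe
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of DEG / gene-set overlap.

    The p-value is the upper-tail hypergeometric probability of seeing
    at least the observed overlap given the universe.  Returns
    ``(odds_ratio, p)``.
    """
    universe = set(universe)
    degs = set(deg_list) & universe
    gset = set(gene_set) & universe
    k = len(degs & gset)
    table = [
        [k, len(degs) - k],
        [len(gset) - k, len(universe) - len(degs) - len(gset) + k],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def ora_fisher_sets(deg_list, sets: dict[str, list[str]], universe) -> pd.DataFrame:
    """Fisher ORA across a gene-set collection, BH-corrected."""
    rows = []
    for name, members in sets.items():
        odds, p = ora_fisher(deg_list, members, universe)
        overlap = len(set(deg_list) & set(members) & set(universe))
        rows.append({"set": name, "size": len(members), "overlap": overlap,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def overlap_enrichment(list_a, list_b, universe) -> OverlapEnrichment:
    """Enrichment factor of the overlap of two gene lists.

    expected = |A| * |B| / N (the hypergeometric mean) and the factor is
    observed / expected; p is the upper-tail hypergeometric probability
    of at least the observed overlap.
    """
    universe = set(universe)
    a = set(list_a)
    b = set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both lists must be subsets of the universe")
    n = len(universe)
    observed = len(a & b)
    expected = len(a) * len(b) / n if n else 0.0
    factor = observed / expected if expected > 0 else None
    p_hyper = float(stats.hypergeom.sf(observed - 1, n, len(a), len(b)))
    return OverlapEnrichment(
        n_a=len(a), n_b=len(b), n_universe=n,
        observed=observed, expected=expected,
        enrichment_factor=factor, p_hyper=p_hyper,
    )
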