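"""Negative-binomial differential expression with Wald tests and BH correction.

The model is the standard RNA-seq NB log-linear regression: for gene *g*
and sample *j*,

    K_gj ~ NB(mu_gj, alpha_g),   var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g

with size factors *s_j* from median-of-ratios normalization, per-gene
dispersions alpha_g estimated by method of moments on normalized counts
and shrunk toward a mean-dispersion trend, and a Wald z test on the
contrast coefficient (reported in log2 units).  Differentially expressed
genes (DEGs) are called at the study thresholds |log2FC| > 0.322 and
BH-adjusted p < 0.05, both strict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The study's fold-change threshold: |log2 FC| > 0.322 (a 1.25-fold change).
LFC_THRESHOLD = 0.322
#: The study's significance threshold on BH-adjusted p.
ALPHA = 0.05

DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "wald_z", "p", "p_adj"]


@dataclass
class DEGSet:
    """Thresholded up/down DEG lists with the thresholds that produced them."""

    up: list[str]
    down: list[str]
    lfc_threshold: float = LFC_THRESHOLD
    alpha: float = ALPHA
    contrast: str = ""

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("a gene cannot be both up- and downregulated")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


# ---------------------------------------------------------------------------
# filtering and normalization

def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes with fewer than *min_total* reads summed over all samples.

    The default keeps transcripts with at least ten reads in total.
    """
    keep = counts.sum(axis=1) >= min_total
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_counts: removed %d / %d genes (total < %d)",
                    n_removed, len(counts), min_total)
    return counts.loc[keep]


def normalize_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median ratio of its counts to the
    per-gene geometric mean, over genes expressed in every sample.  If
    no gene is expressed in all samples, falls back to upper-quartile
    factors with a warning.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    if x.shape[1] == 1:
        return np.ones(1)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no gene expressed in every sample; using upper-quartile size factors",
            UserWarning,
            stacklevel=2,
        )
        uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0
                       for col in x.T])
        return uq / np.exp(np.mean(np.log(uq)))
    logx = np.log(x[all_pos])
    log_geomean = logx.mean(axis=1)
    log_factors = np.median(logx - log_geomean[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean exactly 1
    return np.exp(log_factors)


# ---------------------------------------------------------------------------
# dispersion estimation

def estimate_dispersions(norm_counts: np.ndarray, design: np.ndarray | None = None) -> np.ndarray:
    """Method-of-moments NB dispersions shrunk toward a mean-dispersion trend.

    For each gene, alpha_hat = max((s^2 - mu) / mu^2, floor) on
    normalized counts (residual variance pooled within design groups
    when a design is given), then shrunk halfway (in log space) toward
    the fitted trend alpha(mu) = a1 / mu + a0.
    """
    x = np.asarray(norm_counts, dtype=float)
    mu = x.mean(axis=1)
    if design is not None:
        # pool within-group variances over the distinct design rows
        keys = [tuple(row) for row in np.asarray(design)]
        var = np.zeros(x.shape[0])
        dof = 0
        for key in set(keys):
            idx = [i for i, k in enumerate(keys) if k == key]
            if len(idx) < 2:
                continue
            sub = x[:, idx]
            var += sub.var(axis=1, ddof=1) * (len(idx) - 1)
            dof += len(idx) - 1
        var = var / max(dof, 1)
    else:
        var = x.var(axis=1, ddof=1)
    floor = 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / np.maximum(mu, 1e-12) ** 2
    raw = np.clip(raw, floor, 100.0)
    # trend: alpha = a0 + a1/mu fit by least squares on moderately expressed genes
    ok = (mu > 1) & (raw > floor * 10)
    if ok.sum() >= 10:
        a = np.vstack([np.ones(ok.sum()), 1.0 / mu[ok]]).T
        coef, *_ = np.linalg.lstsq(a, raw[ok], rcond=None)
        a0, a1 = max(coef[0], floor), max(coef[1], 0.0)
        trend = np.clip(a0 + a1 / np.maximum(mu, 1e-12), floor, 100.0)
    else:
        trend = np.full_like(raw, max(np.median(raw), floor))
    shrunk = np.exp(0.5 * (np.log(raw) + np.log(trend)))
    return np.clip(shrunk, floor, 100.0)


# ---------------------------------------------------------------------------
# design handling

def _build_design(
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str],
    group_col: str = "group",
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Build the design matrix: intercept, contrast indicator, covariates.

    Categorical covariates are expanded to treatment-coded indicators.
    Raises on a confounded design, naming the aliased columns — jointly
    collinear covariates (e.g. LEDD together with medication class on a
    fully medicated cohort) cannot be separated and must be modelled
    one at a time.
    """
    case, ref = contrast
    sub = samples[samples[group_col].isin([case, ref])].copy()
    for level, label in ((case, "case"), (ref, "reference")):
        n = int((sub[group_col] == level).sum())
        if n < 2:
            raise ValueError(f"contrast {label} level {level!r} has {n} sample(s); need >= 2")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    cols[f"{group_col}[{case}]"] = (sub[group_col] == case).to_numpy(float)
    for cov in covariates:
        if cov not in sub.columns:
            raise ValueError(f"covariate {cov!r} not in sample metadata")
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 7:
            vals = col.to_numpy(float)
            if not np.isfinite(vals).all():
                raise ValueError(f"covariate {cov!r} has non-finite values")
            cols[cov] = (vals - vals.mean()) / (vals.std() or 1.0)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols[f"{cov}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _find_aliased(X, names)
        raise ValueError(
            "confounded design: columns "
            + ", ".join(aliased)
            + " are collinear; fit them in separate models"
        )
    return X, names, sub


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns that do not add rank (QR with column pivoting)."""
    aliased = []
    basis: list[np.ndarray] = []
    for j, name in enumerate(names):
        trial = np.column_stack(basis + [X[:, j]]) if basis else X[:, [j]]
        if np.linalg.matrix_rank(trial) == len(basis) + 1:
            basis.append(X[:, j])
        else:
            aliased.append(name)
    return aliased or names


# ---------------------------------------------------------------------------
# NB GLM fitting (vectorized IRLS across genes)

def _irls_nb(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-gene NB regressions with a shared design matrix.

    Returns (beta, cov) with beta of shape (G, P) and cov the per-gene
    inverse Fisher information (G, P, P).  IRLS with Fisher scoring:
    weights w = mu / (1 + alpha * mu).
    """
    G, N = counts.shape
    P = X.shape[1]
    # init: log of normalized mean, contrast terms at 0
    beta = np.zeros((G, P))
    mean0 = np.maximum((counts / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean0)
    ridge = 1e-10 * np.eye(P)
    for _ in range(n_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset[None, :] + (counts - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("np,gn,gn->gp", X, w, z, optimize=True)
        new_beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        step = np.abs(new_beta - beta).max()
        beta = new_beta
        if step < tol:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, w, X, optimize=True)
    cov = np.linalg.inv(XtWX + ridge)
    return beta, cov


def fit_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | None = None,
    *,
    group_col: str = "group",
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald differential expression, *case vs reference*.

    Parameters
    ----------
    counts
        Integer gene x sample matrix (already low-count filtered).
    samples
        Metadata with ``sample_id``, the group column and any covariates.
    contrast
        ``(case, reference)`` pair of group labels; log2fc > 0 means
        higher in the case group.
    covariates
        Metadata columns adjusted for; numeric columns are standardized,
        categorical ones expanded to indicators.

    Returns the DE table with columns
    ``gene_id, base_mean, log2fc, se, wald_z, p, p_adj``.
    """
    covariates = covariates or []
    samples = samples.set_index("sample_id", drop=False).loc[list(counts.columns)]
    X, names, sub = _build_design(samples, contrast, covariates, group_col)
    y = counts[sub["sample_id"]].to_numpy(dtype=float)
    if size_factors is None:
        size_factors = normalize_size_factors(y)
    offset = np.log(size_factors)
    norm = y / size_factors[None, :]
    alpha = estimate_dispersions(norm, design=X)
    beta, cov = _irls_nb(y, X, offset, alpha)

    j = names.index(f"{group_col}[{contrast[0]}]")
    ln2 = np.log(2.0)
    log2fc = beta[:, j] / ln2
    se = np.sqrt(np.maximum(cov[:, j, j], 0.0)) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # degenerate genes: no variation at all -> no evidence
    degenerate = y.std(axis=1) == 0
    log2fc[degenerate] = 0.0
    z[degenerate] = 0.0
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    res = pd.DataFrame(
        {
            "gene_id": counts.index.to_numpy(),
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p": p,
        }
    )
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res


def read_de_table(path) -> pd.DataFrame:
    """Read a precomputed DE table (tab-delimited: gene, log2fc, p[, p_adj]).

    Lets externally produced results (e.g. a DESeq2 run) flow into the
    downstream length-bias and enrichment stages.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for cand, target in [
        ("gene", "gene_id"), ("gene_id", "gene_id"),
        ("log2FoldChange", "log2fc"), ("log2fc", "log2fc"),
        ("pvalue", "p"), ("p", "p"),
        ("padj", "p_adj"), ("p_adj", "p_adj"),
    ]:
        if cand in df.columns:
            rename[cand] = target
    df = df.rename(columns=rename)
    missing = {"gene_id", "log2fc", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "p_adj" not in df.columns:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# multiple testing and DEG calling

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1; output in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def call_degs(
    results: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    *,
    contrast: str = "",
) -> DEGSet:
    """Call DEGs with strict thresholds: |log2FC| > lfc_threshold AND p_adj < alpha."""
    sig = results["p_adj"].to_numpy() < alpha
    lfc = results["log2fc"].to_numpy()
    up = results.loc[sig & (lfc > lfc_threshold), "gene_id"].tolist()
    down = results.loc[sig & (lfc < -lfc_threshold), "gene_id"].tolist()
    return DEGSet(up=up, down=down, lfc_threshold=lfc_threshold, alpha=alpha,
                  contrast=contrast)
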