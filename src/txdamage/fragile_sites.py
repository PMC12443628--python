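"""Fragile-site enrichment of downregulated genes.

Common chromosomal fragile sites (CFSs) are late-replicating regions
unusually prone to DNA damage, and they are enriched in very long
genes.  If accumulating damage stalls transcription, the proportion of
*downregulated* DEGs falling inside CFSs should exceed the proportion
of upregulated ones.  The comparison is a standard two-proportion z
test (pooled variance, no continuity correction) at alpha = 0.05,
reported two-sided with the direction carried separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffexpr import DEGSet

logger = logging.getLogger(__name__)


@dataclass
class CFSEnrichmentResult:
    """Two-proportion comparison of CFS membership between DEG directions."""

    n_up: int
    n_down: int
    k_up_cfs: int
    k_down_cfs: int
    prop_up: float
    prop_down: float
    z: float
    p: float
    direction: str  # {"down_enriched", "up_enriched", "none"}
    alpha: float = 0.05
    sidedness: str = "two-sided"  # direction of the original hypothesis is one-sided

    def to_dict(self) -> dict:
        return {
            "n_up": self.n_up, "n_down": self.n_down,
            "k_up_cfs": self.k_up_cfs, "k_down_cfs": self.k_down_cfs,
            "prop_up": self.prop_up, "prop_down": self.prop_down,
            "z": self.z, "p": self.p, "direction": self.direction,
            "alpha": self.alpha, "sidedness": self.sidedness,
        }


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided, no continuity correction.

    z = (p1_hat - p2_hat) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with
    p_hat the pooled proportion.  A pooled proportion of exactly 0 or 1
    carries no information: returns ``(0, 1)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def cfs_enrichment(
    degs: DEGSet, cfs_map: dict[str, str], *, alpha: float = 0.05
) -> CFSEnrichmentResult:
    """Test whether downregulated DEGs sit in fragile sites more often than
    upregulated ones.

    Genes absent from *cfs_map* count as non-CFS; a gene annotated in
    several fragile sites counts once.  Positive z means the
    downregulated proportion is higher.  With fewer than 20 DEGs total
    the normal approximation is unreliable and a warning is emitted.
    """
    if degs.n_up == 0 or degs.n_down == 0:
        raise ValueError("both up and down DEG lists must be non-empty")
    if degs.n_up + degs.n_down < 20:
        warnings.warn(
            "fewer than 20 DEGs: the two-proportion normal approximation is unreliable",
            UserWarning,
            stacklevel=2,
        )
    k_down = sum(1 for g in set(degs.down) if g in cfs_map)
    k_up = sum(1 for g in set(degs.up) if g in cfs_map)
    z, p = two_proportion_z(k_down, degs.n_down, k_up, degs.n_up)
    if p < alpha:
        direction = "down_enriched" if z > 0 else "up_enriched"
    else:
        direction = "none"
    return CFSEnrichmentResult(
        n_up=degs.n_up, n_down=degs.n_down,
        k_up_cfs=k_up, k_down_cfs=k_down,
        prop_up=k_up / degs.n_up, prop_down=k_down / degs.n_down,
        z=z, p=p, direction=direction, alpha=alpha,
    )
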