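"""Synthetic two-visit cohort generator with planted transcription-stalling damage.

The generator emulates the structure of a longitudinal blood-transcriptome
case/control study: negative-binomial counts for healthy controls (HC) and
a Parkinson's disease (PD) arm sampled at an intake visit (visit 1) and a
36-month follow-up (visit 8), with

* a fraction of genes truly differentially expressed at ``+/- base_lfc``
  log2 units,
* a length-coupled extra suppression of long transcripts among the
  downregulated genes (the transcription-stalling damage model:
  ``length_bias_beta`` log2 units per log10(bp) above the median length),
* an excess probability that fragile-site genes are downregulated,
* UPDRS III motor-score trajectories that split PD subjects into mild
  (expected ΔUPDRS <= 1) and severe (expected ΔUPDRS > 1) progressors.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``config.seed``, so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import (
    NO_MEDICATION_CLASS,
    write_bed,
    write_cfs_table,
    write_counts,
    write_gene_table,
    write_metadata,
)

logger = logging.getLogger(__name__)

PD_GROUPS = ("iPD", "GBA", "LRRK2", "prodromal")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Counts are negative binomial with ``variance = mu + dispersion * mu**2``.
    ``length_bias_beta`` is the extra down-shift of the log2 fold change
    per log10(bp) above the median gene length, applied to the genes whose
    planted effect is negative; 0 gives a length-neutral (null) cohort.
    ``visit_effect`` scales the planted effects in visit-8 samples of
    severe-trajectory subjects relative to visit 1.  With ``severe_only``
    the damage is planted exclusively in severe-trajectory subjects.
    """

    n_genes: int = 5000
    n_per_group: int = 20
    baseline_mean_log: float = 4.0      # ln of the median baseline mean count
    baseline_sd_log: float = 1.5        # ln-scale spread of baseline means
    dispersion: float = 0.1             # NB dispersion alpha
    frac_de: float = 0.2
    base_lfc: float = 1.0               # |log2FC| of planted effects
    length_bias_beta: float = 0.0       # log2FC shift per log10(bp) above median
    cfs_frac: float = 0.05              # fraction of genes in a fragile site
    cfs_down_boost: float = 0.0         # extra P(negative effect) for CFS genes
    visit_effect: float = 1.0
    severe_frac: float = 0.67           # fraction of PD subjects on severe trajectories
    updrs_drift_mild: tuple[float, float] = (0.0, 1.0)   # (mean, sd) of ΔUPDRS
    updrs_drift_severe: tuple[float, float] = (5.0, 2.0)
    length_log10_mean: float = 4.2      # gene lengths ~ 10**Normal(mean, sd) bp
    length_log10_sd: float = 0.6
    libsize_sigma: float = 0.15         # ln-scale sd of library-size factors
    case_group: str = "iPD"
    severe_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_de": self.frac_de,
            "cfs_frac": self.cfs_frac,
            "cfs_down_boost": self.cfs_down_boost,
            "severe_frac": self.severe_frac,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("baseline_mean_log", "dispersion", "base_lfc", "length_bias_beta",
                     "visit_effect", "length_log10_mean", "length_log10_sd",
                     "libsize_sigma"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.length_bias_beta < 0:
            raise ValueError("length_bias_beta must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genes < 200:
            warnings.warn(
                "n_genes < 200: downstream analyses require >= 100 genes per "
                "DEG direction and will likely be non-informative",
                UserWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortDataset:
    """Counts, sample metadata, gene annotation and (optionally) ground truth."""

    counts: pd.DataFrame          # genes x samples, integer
    samples: pd.DataFrame         # one row per sample
    genes: pd.DataFrame           # one row per gene (annotation table)
    truth: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs")
        unmatched = set(self.counts.columns) - set(self.samples["sample_id"])
        if unmatched:
            raise ValueError(f"count columns without metadata: {sorted(unmatched)[:10]}")

    def write(self, outdir: str | Path) -> None:
        """Write counts (TSV + MTX triplet), metadata, annotation (BED + table), truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts(self.counts, outdir / "counts.tsv")
        write_counts(self.counts, outdir / "counts.mtx")
        write_metadata(self.samples, outdir / "metadata.csv")
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_bed(self.genes, outdir / "genes.bed")
        cfs = self.genes.dropna(subset=["cfs_label"])
        write_cfs_table(dict(zip(cfs["gene_id"], cfs["cfs_label"])), outdir / "cfs.tsv")
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    log10_len = rng.normal(cfg.length_log10_mean, cfg.length_log10_sd, cfg.n_genes)
    lengths = np.maximum(np.round(10.0 ** log10_len).astype(np.int64), 50)
    chroms = np.array([f"chr{c}" for c in
                       list(range(1, 23)) + ["X"]])[np.arange(cfg.n_genes) % 23]
    starts = rng.integers(1, 100_000_000, cfg.n_genes)
    is_cfs = rng.random(cfg.n_genes) < cfg.cfs_frac
    site_names = np.array([f"FRA{i % 90 + 1}" for i in range(cfg.n_genes)], dtype=object)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": gene_ids,
            "chromosome": chroms,
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
            "cfs_label": np.where(is_cfs, site_names, None),
        }
    )
    return genes


def _plant_effects(cfg: SimulationConfig, genes: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene true effects under the damage model."""
    n = cfg.n_genes
    is_de = rng.random(n) < cfg.frac_de
    p_neg = np.full(n, 0.5)
    p_neg[genes["cfs_label"].notna().to_numpy()] = min(1.0, 0.5 + cfg.cfs_down_boost)
    negative = rng.random(n) < p_neg
    sign = np.where(negative, -1.0, 1.0)
    lfc = np.where(is_de, sign * cfg.base_lfc, 0.0)
    # length-coupled suppression: transcription stalling hits every gene in
    # the damaged arm in proportion to how far its length sits above the
    # median, pushing long genes down and leaving short ones nearly untouched
    log10_len = np.log10(genes["length"].to_numpy())
    centred = log10_len - np.median(log10_len)
    lfc = lfc - cfg.length_bias_beta * centred
    return pd.DataFrame(
        {"gene_id": genes["gene_id"], "true_log2fc": lfc, "is_de": is_de}
    )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a two-visit HC/PD cohort with planted damage effects.

    Returns a :class:`CohortDataset` whose ``truth`` table records each
    gene's planted log2 fold change (the visit-1 case-arm value) and DE
    flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _make_genes(config, rng)
    truth = _plant_effects(config, genes, rng)

    # subjects and samples --------------------------------------------------
    subjects = []
    for i in range(config.n_per_group):
        subjects.append({"subject_id": f"HC{i + 1:03d}", "group": "HC", "severe": False})
    n_severe = int(round(config.severe_frac * config.n_per_group))
    for i in range(config.n_per_group):
        subjects.append(
            {
                "subject_id": f"PD{i + 1:03d}",
                "group": config.case_group,
                "severe": i < n_severe,
            }
        )
    sample_rows = []
    for subj in subjects:
        is_pd = subj["group"] != "HC"
        sex = "M" if rng.random() < 0.6 else "F"
        age = float(np.round(rng.normal(64 if is_pd else 62, 8), 1))
        ledd = float(np.round(rng.lognormal(np.log(400), 0.4), 1)) if is_pd else np.nan
        med = int(rng.integers(1, 8)) if is_pd else NO_MEDICATION_CLASS
        for visit in (1, 8):
            sample_rows.append(
                {
                    "sample_id": f"{subj['subject_id']}_V{visit}",
                    "subject_id": subj["subject_id"],
                    "group": subj["group"],
                    "visit": visit,
                    "sex": sex,
                    "age": age if visit == 1 else age + 3.0,
                    "updrs_iii": 0,       # filled by simulate_updrs_trajectories
                    "ledd": ledd,
                    "medication_class": med,
                    "severe_trajectory": subj["severe"],
                }
            )
    samples = pd.DataFrame(sample_rows)
    samples = simulate_updrs_trajectories(config, samples, rng=rng)

    # per-sample effect dose: 0 for HC, 1 for damaged PD samples at visit 1,
    # visit_effect for severe subjects at visit 8
    is_case = (samples["group"] != "HC").to_numpy()
    is_severe = samples["severe_trajectory"].to_numpy()
    visit8 = (samples["visit"] == 8).to_numpy()
    dose = is_case.astype(float)
    if config.severe_only:
        dose *= is_severe.astype(float)
    dose = np.where(is_case & is_severe & visit8, dose * config.visit_effect, dose)

    # counts ----------------------------------------------------------------
    baseline = rng.lognormal(config.baseline_mean_log, config.baseline_sd_log,
                             config.n_genes)
    libsize = rng.lognormal(0.0, config.libsize_sigma, len(samples))
    libsize /= np.exp(np.mean(np.log(libsize)))  # geometric mean 1
    lfc = truth["true_log2fc"].to_numpy()
    mu = baseline[:, None] * libsize[None, :] * 2.0 ** (lfc[:, None] * dose[None, :])
    alpha = config.dispersion
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    counts_df = pd.DataFrame(counts, index=genes["gene_id"].to_numpy(),
                             columns=samples["sample_id"].to_numpy())
    counts_df.index.name = "gene_id"

    return CohortDataset(counts=counts_df, samples=samples, genes=genes,
                         truth=truth, config=config)


def simulate_updrs_trajectories(
    config: SimulationConfig,
    samples: pd.DataFrame,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill in UPDRS III scores so ΔUPDRS (visit 8 − visit 1) follows the
    configured mild/severe drift distributions.

    Severe-trajectory subjects draw their expected change from
    ``updrs_drift_severe``, mild ones from ``updrs_drift_mild``; scores
    are truncated at zero.  Raises if a PD subject lacks either visit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = samples.copy()
    if "severe_trajectory" not in samples.columns:
        samples["severe_trajectory"] = False

    updrs = pd.Series(0, index=samples.index, dtype=np.int64)
    for subject_id, grp in samples.groupby("subject_id", sort=True):
        visits = set(grp["visit"])
        is_pd = (grp["group"] != "HC").any()
        if is_pd and visits != {1, 8}:
            raise ValueError(
                f"subject {subject_id!r} lacks a visit record (has visits {sorted(visits)})"
            )
        if is_pd:
            base = max(0.0, rng.normal(20.0, 6.0))
            mean, sd = (
                config.updrs_drift_severe
                if bool(grp["severe_trajectory"].iloc[0])
                else config.updrs_drift_mild
            )
            delta = rng.normal(mean, sd) if sd > 0 else float(mean)
        else:
            base = max(0.0, rng.normal(1.0, 1.0))
            delta = rng.normal(0.0, 0.5)
        v1 = int(round(base))
        # ceiling maps the continuous drift to the integer scale so that
        # the integer classification Δ > 1 coincides with drift > 1
        v8 = max(0, v1 + int(np.ceil(delta)))
        for idx, visit in zip(grp.index, grp["visit"]):
            updrs.loc[idx] = v1 if visit == 1 else v8
    samples["updrs_iii"] = updrs
    return samples
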