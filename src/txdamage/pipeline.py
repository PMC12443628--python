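"""End-to-end orchestration: simulate/load → DE → ALBATRO → CFS → GSEA → report.

Each contrast yields one :class:`SignatureReport` summarizing the DNA
damage signature read-outs:

* ``long_gene_suppression`` — ALBATRO informative, median length of
  downregulated DEGs above that of upregulated ones, rank-sum p < alpha;
* ``cfs_down_enriched`` — downregulated DEGs over-represented in common
  fragile sites (two-proportion z, p < alpha, down direction);
* ``repair_pathways_down`` — any gene set tagged as a DNA-repair set
  with NES < 0 and BH-adjusted permutation p < alpha.

All thresholds default to the study values (|log2FC| > 0.322,
alpha 0.05, >= 100 genes per direction, ΔUPDRS cut 1, effect size 0.6)
and live in one config object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import MIN_EFFECT_SIZE, assemble_contrasts, power_check
from .diffexpr import (
    ALPHA,
    LFC_THRESHOLD,
    call_degs,
    filter_low_counts,
    fit_de,
    normalize_size_factors,
)
from .enrichment import gsea_permutation, overlap_enrichment, rank_genes
from .fragile_sites import cfs_enrichment
from .length_bias import MIN_GENES, albatro
from .simulate import CohortDataset, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and stage switches for one pipeline run."""

    lfc_threshold: float = LFC_THRESHOLD
    alpha: float = ALPHA
    min_genes: int = MIN_GENES
    min_effect_size: float = MIN_EFFECT_SIZE
    min_total_counts: int = 10
    scheme: str = "subgroups"          # or "progression"
    visits: tuple[int, ...] = (1, 8)
    covariates: tuple[str, ...] = ()
    gsea_n_perm: int = 1000
    repair_tags: tuple[str, ...] = ("repair", "damage")
    run_gsea: bool = True
    run_cfs: bool = True
    seed: int = 0
    simulation: SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class SignatureReport:
    """Per-contrast summary of the damage-signature read-outs."""

    contrast: str
    n_up: int
    n_down: int
    length_bias: dict | None
    cfs: dict | None
    gsea_repair: list[dict] | None
    power: dict | None
    flags: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_json_default, **kw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    dataset: CohortDataset | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    *,
    outdir: str | Path | None = None,
) -> list[SignatureReport]:
    """Run simulate → DE → ALBATRO → CFS → GSEA for every contrast.

    If *dataset* is None a cohort is simulated from ``config.simulation``
    (seeded with ``config.seed`` when the simulation config carries no
    explicit seed difference).  Stage failures abort with the stage and
    contrast named.  Deterministic given the seed.
    """
    if dataset is None:
        sim = config.simulation or SimulationConfig()
        sim = dataclasses.replace(sim, seed=config.seed)
        dataset = simulate_cohort(sim)

    cfs_map = {}
    if "cfs_label" in dataset.genes.columns:
        with_label = dataset.genes.dropna(subset=["cfs_label"])
        cfs_map = dict(zip(with_label["gene_id"], with_label["cfs_label"]))

    contrasts, manifest = assemble_contrasts(
        dataset.samples, config.scheme, visits=config.visits
    )
    provenance_base = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "manifest": manifest,
    }

    reports: list[SignatureReport] = []
    deg_lists: dict[str, dict] = {}
    universe_by_contrast: dict[str, list[str]] = {}
    for contrast in contrasts:
        label = contrast.label
        try:
            sub_meta = dataset.samples[
                dataset.samples["sample_id"].isin(contrast.sample_ids)
            ].copy()
            is_hc = sub_meta["group"].isin(("HC",))
            sub_meta["contrast_group"] = np.where(is_hc, "HC", contrast.case_group)
            sub_counts = dataset.counts[
                [s for s in dataset.counts.columns if s in set(contrast.sample_ids)]
            ]
            sub_counts = filter_low_counts(sub_counts, config.min_total_counts)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"stage=prepare contrast={label}: {exc}") from exc

        try:
            de = fit_de(
                sub_counts, sub_meta, (contrast.case_group, "HC"),
                covariates=list(config.covariates), group_col="contrast_group",
            )
            degs = call_degs(de, config.lfc_threshold, config.alpha, contrast=label)
        except Exception as exc:
            raise RuntimeError(f"stage=diffexpr contrast={label}: {exc}") from exc

        deg_lists[label] = {"up": degs.up, "down": degs.down}
        universe_by_contrast[label] = de["gene_id"].tolist()

        try:
            lb = albatro(degs, dataset.genes, config.min_genes, densities=False,
                         seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage=length_bias contrast={label}: {exc}") from exc

        cfs_res = None
        if config.run_cfs and degs.n_up > 0 and degs.n_down > 0:
            try:
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", UserWarning)
                    cfs_res = cfs_enrichment(degs, cfs_map, alpha=config.alpha)
            except Exception as exc:
                raise RuntimeError(f"stage=fragile_sites contrast={label}: {exc}") from exc

        gsea_repair = None
        repair_down = False
        if config.run_gsea and gene_sets:
            try:
                ranked = rank_genes(de)
                usable = {
                    name: members
                    for name, members in gene_sets.items()
                    if set(members) & set(ranked.index)
                }
                if usable:
                    gres = gsea_permutation(
                        ranked, usable, n_perm=config.gsea_n_perm, seed=config.seed
                    )
                    tagged = gres[
                        gres["set"].str.lower().str.contains("|".join(config.repair_tags))
                    ]
                    gsea_repair = tagged.drop(columns=["leading_edge"]).to_dict("records")
                    repair_down = bool(
                        ((tagged["nes"] < 0) & (tagged["p_adj"] < config.alpha)).any()
                    )
            except Exception as exc:
                raise RuntimeError(f"stage=gsea contrast={label}: {exc}") from exc

        # retrospective power on the per-sample mean log2 normalized signal
        try:
            sf = normalize_size_factors(sub_counts)
            log_signal = np.log2(sub_counts.to_numpy() / sf[None, :] + 1.0).mean(axis=0)
            case_mask = (sub_meta.set_index("sample_id")
                         .loc[list(sub_counts.columns), "contrast_group"]
                         .to_numpy() != "HC")
            a, b = log_signal[case_mask], log_signal[~case_mask]
            pooled_sd = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            d_obs = abs(a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
            pw = power_check(len(a), len(b), float(d_obs), config.alpha)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"stage=power contrast={label}: {exc}") from exc

        long_gene_suppression = bool(
            lb.informative
            and lb.p is not None
            and lb.p < config.alpha
            and (lb.median_down or 0) > (lb.median_up or 0)
        )
        cfs_down = bool(cfs_res is not None and cfs_res.direction == "down_enriched")
        flags = {
            "long_gene_suppression": long_gene_suppression,
            "cfs_down_enriched": cfs_down,
            "repair_pathways_down": repair_down,
        }
        reports.append(
            SignatureReport(
                contrast=label,
                n_up=degs.n_up,
                n_down=degs.n_down,
                length_bias=lb.to_dict(),
                cfs=cfs_res.to_dict() if cfs_res is not None else None,
                gsea_repair=gsea_repair,
                power=pw.to_dict(),
                flags=flags,
                provenance=provenance_base,
            )
        )

    # cross-visit DEG overlap (same case group, visit 1 vs visit 8)
    overlaps = _cross_visit_overlaps(deg_lists, universe_by_contrast)
    for report in reports:
        report.provenance = dict(report.provenance, cross_visit_overlap=overlaps)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for report in reports:
            (outdir / f"report_{report.contrast}.json").write_text(report.to_json(indent=2))
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default)
        )
    return reports


def _cross_visit_overlaps(
    deg_lists: dict[str, dict], universes: dict[str, list[str]]
) -> dict:
    """DEG-overlap enrichment factors between visit 1 and visit 8 contrasts."""
    out = {}
    v1 = {lab: d for lab, d in deg_lists.items() if lab.endswith("_V1")}
    for lab1, d1 in v1.items():
        lab8 = lab1[:-3] + "_V8"
        if lab8 not in deg_lists:
            continue
        d8 = deg_lists[lab8]
        universe = sorted(set(universes[lab1]) & set(universes[lab8]))
        uset = set(universe)
        a = [g for g in d1["up"] + d1["down"] if g in uset]
        b = [g for g in d8["up"] + d8["down"] if g in uset]
        if not a or not b or not universe:
            continue
        ov = overlap_enrichment(a, b, universe)
        out[f"{lab1}|{lab8}"] = ov.to_dict()
    return out
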