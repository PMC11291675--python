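"""End-to-end orchestration: simulate/load -> prepare -> map -> fine-map -> report.

A run is driven by a :class:`RunConfig` (YAML-serializable), writes TSV result
tables plus a JSON manifest (config, seed, versions, warnings), and is
deterministic: the same config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    GENOME_WIDE_ALPHA,
    SignificanceThresholds,
    forward_conditional,
    marginal_scan,
    AssociationResult,
    permutation_null,
    variance_explained,
)
from .catalog import DosageMatrix, filter_variants, read_catalog
from .enrichment import pbg_proportion
from .io import (
    association_results_frame,
    omnibus_results_frame,
    read_covariates,
    read_dosages,
    read_loco,
    read_phenotypes,
    write_dosages,
    write_manifest,
    write_phenotypes,
    write_table,
)
from .omnibus import sequential_conditional_haplotype
from .phenotypes import LocoOffset, prepare_panel
from .simulate import SimulationConfig, full_variant_matrix, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` holds a simulation config (synthetic cohort) or the
    input paths point at dosage/phenotype/covariate TSVs.
    """

    out_dir: str = "run"
    seed: int = 0
    simulate: dict | None = None  # kwargs for demo_config / SimulationConfig
    catalog_path: str | None = None
    dosage_path: str | None = None
    dosage_meta_path: str | None = None
    phenotype_path: str | None = None
    covariate_path: str | None = None
    loco_path: str | None = None
    genome_wide_alpha: float = GENOME_WIDE_ALPHA
    replication_alpha: float = 0.05
    maf_min: float = 0.01
    r2_min: float = 0.7
    n_expression_pcs: int = 0
    n_perm: int = 0
    max_positions: int = 3
    variant_kinds: list | None = None
    exclude_individuals: list = field(default_factory=list)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig(**(yaml.safe_load(fh) or {}))

    def validate(self):
        for name in ("catalog_path", "dosage_path", "dosage_meta_path",
                     "phenotype_path", "covariate_path", "loco_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{name} does not exist: {p}")
        if self.simulate is None and self.dosage_path is None:
            raise PipelineError("validate", "need either simulate or dosage inputs")
        if not 0 < self.genome_wide_alpha < 1:
            raise PipelineError("validate", "genome_wide_alpha must be in (0,1)")


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    timings: dict[str, float] = {}
    t0 = time.time()

    def stage_done(name):
        timings[name] = round(time.time() - t0, 3)
        logger.info("stage %s done (%.2fs total)", name, timings[name])

    # --- catalog ---------------------------------------------------------
    if cfg.catalog_path:
        catalog = read_catalog(cfg.catalog_path)
    else:
        from .demo import demo_catalog

        catalog = demo_catalog()
    stage_done("catalog")

    # --- cohort ----------------------------------------------------------
    truth = None
    loco = LocoOffset()
    if cfg.simulate is not None:
        from .demo import demo_config

        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim_cfg = demo_config(**sim_kwargs)
        cohort = simulate_cohort(sim_cfg, catalog)
        two_field = cohort.observed_dosages
        panel = cohort.phenotypes
        covariates = cohort.covariates
        truth = cohort.truth
        write_dosages(two_field, out / "dosages_two_field.tsv",
                      out / "dosages_two_field_meta.tsv")
        write_phenotypes(panel, out / "phenotypes_raw.tsv")
    else:
        two_field = read_dosages(cfg.dosage_path, cfg.dosage_meta_path)
        panel = read_phenotypes(cfg.phenotype_path)
        covariates = (read_covariates(cfg.covariate_path)
                      if cfg.covariate_path else None)
        if cfg.loco_path:
            loco = read_loco(cfg.loco_path)
    if cfg.exclude_individuals:
        keep = [i for i in two_field.individuals
                if i not in set(cfg.exclude_individuals)]
        if not keep:
            raise PipelineError("cohort", "exclusion list covers all individuals")
        sel = [two_field.individuals.index(i) for i in keep]
        two_field = DosageMatrix(keep, list(two_field.variants),
                                 two_field.dosage[sel], validate=False)
        panel.values = panel.values.loc[keep]
        if covariates is not None:
            covariates = covariates.loc[keep]
    stage_done("cohort")

    # --- variant derivation + filter ------------------------------------
    try:
        variants = full_variant_matrix(two_field, catalog)
    except KeyError as err:
        raise PipelineError("derive", str(err)) from err
    variants = filter_variants(variants, cfg.maf_min, cfg.r2_min)
    if not variants.variants:
        raise PipelineError("derive", "no variants pass the MAF/R^2 filter")
    write_dosages(variants, out / "dosages_all.tsv", out / "variants_meta.tsv")
    stage_done("derive")

    # --- phenotype preparation ------------------------------------------
    prepared = prepare_panel(panel, covariates, loco,
                             n_expression_pcs=cfg.n_expression_pcs)
    write_phenotypes(prepared, out / "phenotypes_prepared.tsv")
    stage_done("prep")

    # --- single-marker + forward conditional ----------------------------
    thresholds = SignificanceThresholds(cfg.genome_wide_alpha,
                                        len(prepared.proteins),
                                        cfg.replication_alpha)
    kinds = set(cfg.variant_kinds) if cfg.variant_kinds else None
    scan_d = variants if kinds is None else variants.select(lambda v: v.kind in kinds)
    marginal_rows = []
    lead_and_conditional: dict[str, list[AssociationResult]] = {}
    for protein in prepared.proteins:
        y = prepared.values[protein].to_numpy(float)
        beta, se, log10p, valid, n, _ = marginal_scan(y, scan_d.dosage)
        for j, vid in enumerate(scan_d.variant_ids):
            if valid[j]:
                marginal_rows.append(AssociationResult(
                    protein, vid, float(beta[j]), float(se[j]), float(log10p[j]), n))
        chain = forward_conditional(
            y, scan_d, stop_alpha=cfg.genome_wide_alpha,
            first_round_alpha=thresholds.discovery, protein=protein,
        )
        if chain:
            lead_and_conditional[protein] = chain
    write_table(association_results_frame(marginal_rows), out / "marginal.tsv")
    cond_rows = [r for chain in lead_and_conditional.values() for r in chain]
    write_table(association_results_frame(cond_rows), out / "lead_conditional.tsv")
    stage_done("association")

    # --- variance explained ---------------------------------------------
    vd_rows = []
    for protein, chain in lead_and_conditional.items():
        y = prepared.values[protein].to_numpy(float)
        vd = variance_explained(
            y, variants.subset([r.variant for r in chain]), protein=protein)
        vd_rows.append({
            "protein": protein,
            "n_variants": len(vd.ordered_variants),
            "total_fraction": vd.total_fraction,
            "fractions": ",".join(f"{f:.6g}" for f in vd.sequential_ss_fraction),
        })
    write_table(pd.DataFrame(vd_rows,
                             columns=["protein", "n_variants", "total_fraction",
                                      "fractions"]),
                out / "variance_explained.tsv")
    stage_done("variance")

    # --- omnibus fine-mapping -------------------------------------------
    omnibus_rows = []
    for protein in lead_and_conditional:
        y = prepared.values[protein].to_numpy(float)
        results = sequential_conditional_haplotype(
            y, catalog, two_field, stop_alpha=cfg.genome_wide_alpha,
            max_positions=cfg.max_positions, protein=protein,
        )
        omnibus_rows.extend(results)
    write_table(omnibus_results_frame(omnibus_rows), out / "omnibus.tsv")
    stage_done("omnibus")

    # --- permutations ----------------------------------------------------
    perm_rows = []
    if cfg.n_perm > 0:
        ss = np.random.SeedSequence(cfg.seed).spawn(len(lead_and_conditional))
        for child, protein in zip(ss, sorted(lead_and_conditional)):
            y = prepared.values[protein].to_numpy(float)
            null = permutation_null(y, scan_d, cfg.n_perm,
                                    np.random.default_rng(child), protein=protein)
            perm_rows.append({
                "protein": protein,
                "n_perm": null.n_perm,
                "observed_max_log10p": null.observed_max_log10p,
                "null_best_log10p": float(null.null_max_log10p.max()),
                "empirical_p": null.empirical_p,
            })
        write_table(pd.DataFrame(perm_rows), out / "permutations.tsv")
    stage_done("permutation")

    # --- reports ---------------------------------------------------------
    index = {v.id: v for v in variants.variants}
    aa_hits = [r for chain in lead_and_conditional.values() for r in chain
               if index[r.variant].kind == "amino_acid"]
    pbg = pbg_proportion(aa_hits, index) if aa_hits else {"I": np.nan, "II": np.nan}
    summary = {
        "n_proteins": len(prepared.proteins),
        "n_variants_tested": len(scan_d.variants),
        "n_pgenes": len(lead_and_conditional),
        "n_lead_and_conditional": sum(len(c) for c in lead_and_conditional.values()),
        "discovery_threshold": thresholds.discovery,
        "pbg_fraction_class1": pbg["I"],
        "pbg_fraction_class2": pbg["II"],
    }
    if truth is not None:
        summary["truth"] = {p: t for p, t in truth.items() if t}
    write_manifest(out / "manifest.json",
                   version=__version__,
                   config=asdict(cfg),
                   config_hash=_config_hash(cfg),
                   seed=cfg.seed,
                   summary=summary,
                   timings=timings,
                   warnings=warnings)
    stage_done("report")
    return out


def pooled_analysis(cohorts, labels=None) -> pd.DataFrame:
    """Pool individual-level data across cohorts with a cohort indicator.

    ``cohorts`` is a list of ``(PhenotypePanel, DosageMatrix)`` pairs with
    shared protein and variant ids; individuals are concatenated (colliding
    IDs are an error) and every per-variant model carries cohort-indicator
    covariates.  Returns a long marginal-results table.
    """
    if len(cohorts) < 2:
        raise ValueError("pooled_analysis needs >= 2 cohorts")
    labels = labels or [f"cohort{i}" for i in range(len(cohorts))]
    panels = [p for p, _d in cohorts]
    dosages = [d for _p, d in cohorts]
    proteins = panels[0].proteins
    vids = dosages[0].variant_ids
    for p, d in cohorts[1:]:
        if p.proteins != proteins or d.variant_ids != vids:
            raise ValueError("pooled_analysis: cohorts must share protein and "
                             "variant ids")
    all_ids = [i for d in dosages for i in d.individuals]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("pooled_analysis: individual ID collisions across cohorts")
    D = np.vstack([d.dosage for d in dosages])
    Y = pd.concat([p.values for p in panels], axis=0)
    indicator = np.concatenate([
        np.full(d.n_individuals, i) for i, d in enumerate(dosages)
    ])
    dummies = pd.get_dummies(pd.Categorical([labels[i] for i in indicator]),
                             drop_first=True, dtype=float)
    dummies.index = Y.index
    rows = []
    for protein in proteins:
        y = Y[protein].to_numpy(float)
        beta, se, log10p, valid, n, _ = marginal_scan(y, D, covariates=dummies)
        for j, vid in enumerate(vids):
            if valid[j]:
                rows.append({
                    "protein": protein, "variant": vid,
                    "beta": float(beta[j]), "se": float(se[j]),
                    "minus_log10_p": float(log10p[j]), "n": n,
                })
    return pd.DataFrame(rows)
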