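"""Synthetic HLA cohorts with a known causal architecture.

Haplotypes are drawn under Hardy-Weinberg: two gametes per individual, each
sampled independently.  The DRB1-DQA1-DQB1 superlocus is drawn jointly from a
haplotype frequency table (inducing the block's linkage disequilibrium); all
other loci are drawn independently from per-locus allele frequencies.

True genotype dosages are the integer allele counts {0,1,2}; observed dosages
add truncated Gaussian noise (clipped back to [0,2]) to emulate imputation
uncertainty.  Protein phenotypes follow an additive model on the TRUE
dosages — effects act through genotype, analysis sees the noisy dosages:

    y = sum_v beta_v * dosage_v + sum_c gamma_c * cov_c + eps,
    eps ~ N(0, noise_sd^2)

with measurements set missing completely at random at ``missing_rate``
(default 0.032, a typical mean per-protein missingness for plasma proteomic
panels).

One global seed drives a per-purpose stream split (haplotypes, dosage noise,
covariates, phenotype noise, missingness) so that toggling one component
leaves the others' draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    SUPERLOCUS,
    DosageMatrix,
    VariantDef,
    amino_acid_variant_id,
    derive_amino_acid_dosages,
    derive_one_field_dosages,
)
from .phenotypes import PhenotypePanel

_STREAMS = ("haplotypes", "dosage_noise", "covariates", "phenotype_noise", "missingness")


@dataclass
class SimulationConfig:
    """Cohort and phenotype generation parameters.

    ``causal_effects`` maps protein name -> list of (target, beta) with beta
    in phenotype-SD units per dosage unit; a target is either a derived
    variant id or a ``(locus, position, residue)`` triple.  Proteins are
    named P01..Pnn; proteins without listed effects are pure noise.
    """

    n_individuals: int
    allele_freqs: dict  # locus -> {allele: freq}; superlocus loci excluded
    superlocus_haplotypes: list  # (DRB1 allele, DQA1 allele, DQB1 allele, freq)
    causal_effects: dict = field(default_factory=dict)
    covariate_spec: list = field(default_factory=list)  # (name, dist, effect)
    noise_sd: float = 1.0
    dosage_noise_sd: float = 0.05
    missing_rate: float = 0.032
    n_proteins: int = 10
    seed: int = 0

    def __post_init__(self):
        for locus, freqs in self.allele_freqs.items():
            if locus in SUPERLOCUS:
                raise ValueError(
                    f"{locus} is drawn from superlocus_haplotypes, not allele_freqs"
                )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus} allele frequencies sum to {total}, not 1")
        total = sum(h[3] for h in self.superlocus_haplotypes)
        if self.superlocus_haplotypes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"superlocus haplotype frequencies sum to {total}, not 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dosage_noise_sd < 0:
            raise ValueError("dosage_noise_sd must be non-negative")

    @property
    def protein_names(self):
        width = max(2, len(str(self.n_proteins)))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]


@dataclass
class SimulatedCohort:
    """A generated cohort with full ground truth."""

    haplotypes: dict  # locus -> (n, 2) array of allele names
    true_dosages: DosageMatrix  # two-field, integer counts
    observed_dosages: DosageMatrix  # two-field, noisy
    covariates: pd.DataFrame
    phenotypes: PhenotypePanel  # raw layer
    truth: dict  # protein -> list of (variant_id, beta)


def _streams(seed: int):
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def simulate_haplotypes(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Two phased allele vectors per individual, per locus (Hardy-Weinberg)."""
    n = cfg.n_individuals
    haps: dict[str, np.ndarray] = {}
    if cfg.superlocus_haplotypes:
        freqs = np.array([h[3] for h in cfg.superlocus_haplotypes])
        idx = rng.choice(len(freqs), size=(n, 2), p=freqs / freqs.sum())
        # haplotype tuples are ordered (DRB1 allele, DQA1 allele, DQB1 allele, freq)
        for slot, locus in enumerate(("DRB1", "DQA1", "DQB1")):
            names = np.array([h[slot] for h in cfg.superlocus_haplotypes],
                             dtype=object)
            haps[locus] = names[idx]
    for locus in sorted(cfg.allele_freqs):
        alleles = sorted(cfg.allele_freqs[locus])
        freqs = np.array([cfg.allele_freqs[locus][a] for a in alleles])
        draw = rng.choice(len(alleles), size=(n, 2), p=freqs / freqs.sum())
        haps[locus] = np.array(alleles, dtype=object)[draw]
    return haps


def haplotypes_to_dosages(haplotypes: dict, individuals=None) -> DosageMatrix:
    """Count alleles across the two gametes -> integer two-field dosages."""
    n = next(iter(haplotypes.values())).shape[0]
    individuals = list(individuals) if individuals is not None else [
        f"I{i + 1:06d}" for i in range(n)
    ]
    variants, cols = [], []
    for locus in sorted(haplotypes):
        arr = haplotypes[locus]
        for allele in sorted(set(arr.ravel())):
            variants.append(VariantDef(id=allele, kind="two_field", locus=locus))
            cols.append((arr == allele).sum(axis=1).astype(float))
    return DosageMatrix(individuals, variants, np.column_stack(cols))


def add_dosage_noise(
    true_dosages: DosageMatrix, dosage_noise_sd: float, rng: np.random.Generator
) -> DosageMatrix:
    """Entry-wise Gaussian perturbation clipped to [0, 2]; sd 0 is identity."""
    if dosage_noise_sd < 0:
        raise ValueError("dosage_noise_sd must be non-negative")
    if dosage_noise_sd == 0:
        noisy = true_dosages.dosage.copy()
    else:
        noisy = np.clip(
            true_dosages.dosage
            + rng.normal(0.0, dosage_noise_sd, size=true_dosages.dosage.shape),
            0.0, 2.0,
        )
    return DosageMatrix(true_dosages.individuals, list(true_dosages.variants), noisy)


def simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator,
                        individuals) -> pd.DataFrame:
    cols = {}
    for name, dist, _effect in cfg.covariate_spec:
        kind = dist[0]
        if kind == "normal":
            cols[name] = rng.normal(dist[1], dist[2], size=cfg.n_individuals)
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, dist[1], size=cfg.n_individuals).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    return pd.DataFrame(cols, index=individuals)


def resolve_target(target, derived: DosageMatrix) -> str:
    """Map a causal-target spec to exactly one derived variant id."""
    if isinstance(target, str):
        if target in derived.variant_ids:
            return target
        raise KeyError(f"causal target {target!r} not among derived variants")
    locus, position, residue = target
    hits = [
        v.id for v in derived.variants
        if v.kind == "amino_acid" and v.locus == locus
        and v.position == position and v.residues == frozenset({residue})
    ]
    if len(hits) != 1:
        raise KeyError(
            f"causal target ({locus}, {position}, {residue!r}) resolves to "
            f"{len(hits)} derived variants"
        )
    return hits[0]


def full_variant_matrix(two_field: DosageMatrix, catalog,
                        grouped_markers=None) -> DosageMatrix:
    """Two-field + derived one-field + derived amino-acid dosages."""
    return DosageMatrix.concat([
        two_field,
        derive_one_field_dosages(two_field),
        derive_amino_acid_dosages(two_field, catalog, grouped_markers=grouped_markers),
    ])


def simulate_phenotypes(
    true_dosages: DosageMatrix,
    covariates: pd.DataFrame,
    cfg: SimulationConfig,
    catalog,
    rng_noise: np.random.Generator,
    rng_missing: np.random.Generator,
):
    """Additive phenotypes on true dosages; returns (panel, truth)."""
    derived = full_variant_matrix(true_dosages, catalog)
    n = true_dosages.n_individuals
    truth: dict[str, list] = {}
    values = {}
    gamma = {name: eff for name, _d, eff in cfg.covariate_spec}
    for protein in cfg.protein_names:
        y = np.zeros(n)
        resolved = []
        for target, beta in cfg.causal_effects.get(protein, ()):  # genotype effects
            vid = resolve_target(target, derived)
            y += beta * derived.column(vid)
            resolved.append((vid, float(beta)))
        for name in covariates.columns:
            y += gamma.get(name, 0.0) * covariates[name].to_numpy(float)
        y += rng_noise.normal(0.0, cfg.noise_sd, size=n)
        if cfg.missing_rate > 0:
            y[rng_missing.random(n) < cfg.missing_rate] = np.nan
        values[protein] = y
        truth[protein] = resolved
    panel = PhenotypePanel(
        pd.DataFrame(values, index=true_dosages.individuals), layer="raw"
    )
    return panel, truth


def simulate_cohort(cfg: SimulationConfig, catalog=None) -> SimulatedCohort:
    """Generate a full cohort (deterministic given config + seed)."""
    if catalog is None:
        from .demo import demo_catalog

        catalog = demo_catalog()
    rng = _streams(cfg.seed)
    haps = simulate_haplotypes(cfg, rng["haplotypes"])
    true = haplotypes_to_dosages(haps)
    observed = add_dosage_noise(true, cfg.dosage_noise_sd, rng["dosage_noise"])
    covariates = simulate_covariates(cfg, rng["covariates"], true.individuals)
    panel, truth = simulate_phenotypes(
        true, covariates, cfg, catalog, rng["phenotype_noise"], rng["missingness"]
    )
    return SimulatedCohort(
        haplotypes=haps,
        true_dosages=true,
        observed_dosages=observed,
        covariates=covariates,
        phenotypes=panel,
        truth=truth,
    )
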