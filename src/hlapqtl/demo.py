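"""Bundled synthetic HLA catalog and default simulation configuration.

The catalog is synthetic: allele names follow real HLA nomenclature so the
plumbing (one-field grouping, superlocus handling) is exercised realistically,
but the sequences cover only a handful of polymorphic positions per locus and
the haplotype frequencies are invented, loosely shaped like a European cohort.
All two-field allele frequencies are >= 1%, matching the MAF floor of the
variant sets this package analyses.
"""

from __future__ import annotations

from .catalog import Allele
from .simulate import SimulationConfig

# Per-locus: {two_field: {position: residue}}, plus {position: exon}.
# Class I PBG = exons 2+3; class II PBG = exon 2.  Each locus carries at
# least one polymorphic position outside the PBG so the annotation has both
# outcomes on synthetic data.
_SEQS = {
    "A": (
        {
            "A*01:01": {9: "F", 95: "V", 152: "A", 245: "A"},
            "A*02:01": {9: "Y", 95: "L", 152: "V", 245: "A"},
            "A*03:01": {9: "F", 95: "L", 152: "E", 245: "S"},
            "A*24:02": {9: "S", 95: "I", 152: "A", 245: "S"},
        },
        {9: 2, 95: 3, 152: 3, 245: 4},
    ),
    "B": (
        {
            "B*07:02": {45: "E", 70: "Q", 97: "S", 116: "Y", 178: "T"},
            "B*08:01": {45: "E", 70: "N", 97: "T", 116: "D", 178: "K"},
            "B*27:05": {45: "K", 70: "K", 97: "N", 116: "D", 178: "T"},
            "B*44:02": {45: "T", 70: "N", 97: "R", 116: "D", 178: "K"},
        },
        {45: 2, 70: 2, 97: 3, 116: 3, 178: 4},
    ),
    "C": (
        {
            "C*06:02": {99: "S", 156: "L", 304: "G"},
            "C*07:01": {99: "Y", 156: "R", 304: "G"},
            "C*07:02": {99: "Y", 156: "L", 304: "E"},
        },
        {99: 3, 156: 3, 304: 4},
    ),
    "DRB1": (
        {
            "DRB1*03:01": {11: "S", 13: "F", 86: "V", 233: "K"},
            "DRB1*15:01": {11: "S", 13: "H", 86: "G", 233: "K"},
            "DRB1*04:01": {11: "V", 13: "F", 86: "V", 233: "K"},
            "DRB1*04:04": {11: "V", 13: "R", 86: "G", 233: "R"},
            "DRB1*01:01": {11: "L", 13: "H", 86: "V", 233: "K"},
            "DRB1*07:01": {11: "L", 13: "R", 86: "G", 233: "R"},
        },
        {11: 2, 13: 2, 86: 2, 233: 3},
    ),
    "DQA1": (
        {
            "DQA1*01:01": {34: "Q", 52: "R"},
            "DQA1*03:01": {34: "E", 52: "H"},
            "DQA1*05:01": {34: "Q", 52: "S"},
        },
        {34: 2, 52: 2},
    ),
    "DQB1": (
        {
            "DQB1*02:01": {57: "A", 71: "K", 203: "I"},
            "DQB1*03:01": {57: "D", 71: "T", 203: "V"},
            "DQB1*03:02": {57: "A", 71: "R", 203: "V"},
            "DQB1*06:02": {57: "D", 71: "T", 203: "I"},
        },
        {57: 2, 71: 2, 203: 3},
    ),
    "DPB1": (
        {
            "DPB1*04:01": {8: "V", 170: "I"},
            "DPB1*02:01": {8: "L", 170: "I"},
            "DPB1*04:02": {8: "V", 170: "T"},
        },
        {8: 2, 170: 3},
    ),
    "DPA1": (
        {
            "DPA1*01:03": {31: "M", 83: "T"},
            "DPA1*02:01": {31: "Q", 83: "A"},
        },
        {31: 2, 83: 3},
    ),
}


def demo_catalog():
    """The bundled synthetic allele catalog (3-6 alleles per locus)."""
    alleles = []
    for locus, (seqs, exon_of_position) in _SEQS.items():
        for name, seq in seqs.items():
            alleles.append(
                Allele(
                    locus=locus,
                    two_field=name,
                    sequence=dict(seq),
                    exon_of_position={p: exon_of_position[p] for p in seq},
                )
            )
    return alleles


#: Independent-locus allele frequencies (sum to 1 per locus).
DEMO_ALLELE_FREQS = {
    "A": {"A*01:01": 0.30, "A*02:01": 0.40, "A*03:01": 0.18, "A*24:02": 0.12},
    "B": {"B*07:02": 0.25, "B*08:01": 0.20, "B*27:05": 0.15, "B*44:02": 0.40},
    "C": {"C*06:02": 0.25, "C*07:01": 0.35, "C*07:02": 0.40},
    "DPB1": {"DPB1*04:01": 0.45, "DPB1*02:01": 0.30, "DPB1*04:02": 0.25},
    "DPA1": {"DPA1*01:03": 0.70, "DPA1*02:01": 0.30},
}

#: DRB1-DQA1-DQB1 haplotypes with frequencies (sum to 1).  Each DRB1 allele
#: occurs on more than one DQ background so the superlocus LD is strong but
#: not complete.
DEMO_SUPERLOCUS_HAPLOTYPES = [
    ("DRB1*03:01", "DQA1*05:01", "DQB1*02:01", 0.13),
    ("DRB1*03:01", "DQA1*05:01", "DQB1*03:01", 0.05),
    ("DRB1*15:01", "DQA1*01:01", "DQB1*06:02", 0.18),
    ("DRB1*15:01", "DQA1*01:01", "DQB1*03:01", 0.03),
    ("DRB1*04:01", "DQA1*03:01", "DQB1*03:02", 0.10),
    ("DRB1*04:01", "DQA1*03:01", "DQB1*03:01", 0.05),
    ("DRB1*04:01", "DQA1*05:01", "DQB1*02:01", 0.05),
    ("DRB1*04:04", "DQA1*03:01", "DQB1*03:02", 0.05),
    ("DRB1*04:04", "DQA1*03:01", "DQB1*03:01", 0.03),
    ("DRB1*01:01", "DQA1*01:01", "DQB1*03:01", 0.09),
    ("DRB1*01:01", "DQA1*01:01", "DQB1*06:02", 0.07),
    ("DRB1*07:01", "DQA1*03:01", "DQB1*02:01", 0.12),
    ("DRB1*07:01", "DQA1*05:01", "DQB1*03:01", 0.05),
]

#: Default covariates: standardized age and a binary sex indicator, each with
#: a small effect on every protein so that residualization matters.
DEMO_COVARIATE_SPEC = [
    ("age", ("normal", 0.0, 1.0), 0.10),
    ("sex", ("bernoulli", 0.5), -0.10),
]


def demo_config(
    n_individuals: int = 2000,
    n_proteins: int = 10,
    causal_effects: dict | None = None,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Simulation config over the bundled catalog.

    Default causal architecture (overridable): one protein driven by a single
    DRB1 amino acid, one by two independent positions in the DRB1 superlocus
    region, and one by residues at two unlinked class I loci; the rest are
    pure noise.
    """
    if causal_effects is None:
        causal_effects = {
            "P01": [(("DRB1", 11, "V"), 0.4)],
            "P02": [(("A", 9, "F"), 0.4), (("B", 45, "E"), 0.3)],
            "P03": [(("DRB1", 11, "V"), 0.4), (("DRB1", 86, "V"), 0.3)],
        }
    kwargs = dict(
        n_individuals=n_individuals,
        allele_freqs=dict(DEMO_ALLELE_FREQS),
        superlocus_haplotypes=list(DEMO_SUPERLOCUS_HAPLOTYPES),
        causal_effects=causal_effects,
        covariate_spec=list(DEMO_COVARIATE_SPEC),
        n_proteins=n_proteins,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
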