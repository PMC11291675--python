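"""HLA allele catalog: loci, alleles, and variant dosage derivation.

The classical HLA loci encode the MHC class I (HLA-A, -B, -C) and class II
(HLA-DRB1, -DQB1, -DQA1, -DPB1, -DPA1) molecules.  Imputation panels report
each individual's expected count (dosage in [0, 2]) of every two-field allele
(protein-sequence resolution, e.g. ``DRB1*04:01``).  Because two-field alleles
determine the amino-acid sequence, coarser markers are derived from them:

* one-field alleles (``DRB1*04``) — sums of member two-field dosages;
* amino-acid variants — for each polymorphic position of a locus, the dosage
  of residue ``r`` is the summed dosage of all alleles carrying ``r`` there.

Amino-acid variants additionally carry their exon, which determines membership
in the peptide binding groove (PBG): exons 2 and 3 for class I, exon 2 for
class II.  The PBG is the portion of the molecule that contacts presented
peptide antigens, so PBG membership of fine-mapped variants is the headline
mechanistic annotation of an HLA association study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DQB1", "DQA1", "DPB1", "DPA1")
#: The tightly linked class II block fine-mapped jointly.
SUPERLOCUS = ("DRB1", "DQB1", "DQA1")

PBG_EXONS = {"I": frozenset({2, 3}), "II": frozenset({2})}


@dataclass(frozen=True)
class Locus:
    """A classical HLA locus with its class and peptide-binding-groove exons."""

    name: str
    hla_class: str  # "I" or "II"
    pbg_exons: frozenset

    def __post_init__(self):
        if self.name in CLASS_I_LOCI and self.hla_class != "I":
            raise ValueError(f"{self.name} is a class I locus")
        if self.name in CLASS_II_LOCI and self.hla_class != "II":
            raise ValueError(f"{self.name} is a class II locus")
        if self.pbg_exons != PBG_EXONS[self.hla_class]:
            raise ValueError(
                f"PBG exons for class {self.hla_class} must be "
                f"{sorted(PBG_EXONS[self.hla_class])}"
            )


def _make_loci():
    loci = {}
    for name in CLASS_I_LOCI:
        loci[name] = Locus(name, "I", PBG_EXONS["I"])
    for name in CLASS_II_LOCI:
        loci[name] = Locus(name, "II", PBG_EXONS["II"])
    return loci


#: The eight classical loci keyed by name.
LOCI = _make_loci()


@dataclass
class Allele:
    """A two-field HLA allele with its amino-acid sequence.

    ``sequence`` maps position index -> single-letter residue (or a deletion
    symbol, treated as an ordinary residue code); ``exon_of_position`` maps
    every sequenced position to the exon that encodes it.
    """

    locus: str
    two_field: str
    sequence: dict = field(default_factory=dict)
    exon_of_position: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if not self.two_field.startswith(self.locus + "*"):
            raise ValueError(
                f"allele name {self.two_field!r} does not match locus {self.locus}"
            )
        missing = set(self.sequence) - set(self.exon_of_position)
        if missing:
            raise ValueError(
                f"{self.two_field}: positions without exon assignment: {sorted(missing)}"
            )

    @property
    def one_field(self) -> str:
        return one_field_name(self.two_field)


def one_field_name(two_field: str) -> str:
    """``DRB1*04:01`` -> ``DRB1*04``."""
    if "*" not in two_field or ":" not in two_field:
        raise ValueError(f"cannot parse two-field allele name {two_field!r}")
    return two_field.split(":")[0]


@dataclass(frozen=True)
class VariantDef:
    """One tested HLA variant: a one-field allele, a two-field allele, or an
    amino-acid marker (residue set at a position of a locus)."""

    id: str
    kind: str  # one_field | two_field | amino_acid
    locus: str
    position: int | None = None
    residues: frozenset | None = None
    exon: int | None = None
    maf: float | None = None
    imputation_r2: float | None = None

    def __post_init__(self):
        if self.kind not in ("one_field", "two_field", "amino_acid"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "amino_acid":
            if self.position is None or self.residues is None or self.exon is None:
                raise ValueError(
                    f"{self.id}: amino-acid variants need position, residues, exon"
                )
        elif self.position is not None or self.residues is not None or self.exon is not None:
            raise ValueError(f"{self.id}: allele variants carry no position/residues/exon")


def amino_acid_variant_id(locus: str, position: int, exon: int, residues) -> str:
    """Panel-style marker name, e.g. ``AA_DRB1_position13_exon2_FLS``."""
    res = "".join(sorted(residues))
    return f"AA_{locus}_position{position}_exon{exon}_{res}"


@dataclass(frozen=True)
class MhcRegion:
    """The extended MHC region used to call pGenes cis or trans (hg19)."""

    chromosome: str = "6"
    start: int = 28_000_000  # 1-based inclusive
    end: int = 34_000_000
    build: str = "hg19"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("MHC region start must precede end")


MHC_REGION = MhcRegion()


class DosageMatrix:
    """Individuals x variants dosage matrix, entries in [0, 2].

    Thin wrapper around a numpy array plus ordered ``VariantDef`` metadata.
    """

    def __init__(self, individuals, variants, dosage, validate=True):
        self.individuals = list(individuals)
        self.variants = list(variants)
        self.dosage = np.asarray(dosage, dtype=float)
        if self.dosage.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if validate and self.dosage.size:
            lo, hi = self.dosage.min(), self.dosage.max()
            if lo < -1e-9 or hi > 2 + 1e-9:
                raise ValueError(f"dosages outside [0, 2]: range [{lo}, {hi}]")

    @property
    def n_individuals(self):
        return len(self.individuals)

    @property
    def variant_ids(self):
        return [v.id for v in self.variants]

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.index_of(variant_id)]

    def variant(self, variant_id: str) -> VariantDef:
        return self.variants[self.index_of(variant_id)]

    def subset(self, variant_ids) -> "DosageMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return DosageMatrix(
            self.individuals, [self.variants[i] for i in idx], self.dosage[:, idx],
            validate=False,
        )

    def select(self, predicate) -> "DosageMatrix":
        """Subset to variants for which ``predicate(VariantDef)`` is true."""
        keep = [i for i, v in enumerate(self.variants) if predicate(v)]
        return DosageMatrix(
            self.individuals, [self.variants[i] for i in keep], self.dosage[:, keep],
            validate=False,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individuals, columns=self.variant_ids)

    @staticmethod
    def concat(matrices) -> "DosageMatrix":
        """Column-wise concatenation over identical individual lists."""
        first = matrices[0]
        for m in matrices[1:]:
            if m.individuals != first.individuals:
                raise ValueError("cannot concatenate: individual lists differ")
        variants = [v for m in matrices for v in m.variants]
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids after concat: {dup}")
        return DosageMatrix(
            first.individuals, variants, np.hstack([m.dosage for m in matrices]),
            validate=False,
        )


def compute_maf(dosage: np.ndarray) -> float:
    """Allele frequency from dosages (mean/2), folded to the minor side."""
    f = float(np.nanmean(dosage)) / 2.0
    return min(f, 1.0 - f)


def _attach_maf(variants, dosage):
    return [
        replace(v, maf=compute_maf(dosage[:, j])) if v.maf is None else v
        for j, v in enumerate(variants)
    ]


def derive_one_field_dosages(allele_dosages: DosageMatrix) -> DosageMatrix:
    """Sum two-field allele dosages into their one-field groups."""
    for v in allele_dosages.variants:
        if v.kind != "two_field":
            raise ValueError(f"expected two-field variants, got {v.id} ({v.kind})")
    groups: dict[str, list[int]] = {}
    locus_of: dict[str, str] = {}
    for j, v in enumerate(allele_dosages.variants):
        name = one_field_name(v.id)
        groups.setdefault(name, []).append(j)
        locus_of[name] = v.locus
    names = sorted(groups)
    dosage = np.column_stack(
        [allele_dosages.dosage[:, groups[n]].sum(axis=1) for n in names]
    ) if names else np.empty((allele_dosages.n_individuals, 0))
    variants = [VariantDef(id=n, kind="one_field", locus=locus_of[n]) for n in names]
    variants = _attach_maf(variants, dosage)
    return DosageMatrix(allele_dosages.individuals, variants, dosage, validate=False)


def derive_amino_acid_dosages(
    allele_dosages: DosageMatrix,
    catalog,
    grouped_markers=None,
) -> DosageMatrix:
    """Derive amino-acid variant dosages from two-field allele dosages.

    For every locus position with >= 2 distinct residues among the catalog
    alleles, one variant per residue is emitted; its dosage is the sum of
    dosages of alleles carrying that residue.  ``grouped_markers`` optionally
    lists ``(locus, position, residue_set)`` tuples for joint residue-set
    markers (dosage = sum over alleles carrying ANY residue in the set),
    mirroring panel names such as ``AA_DRB1_position13_exon2_FLS``.
    """
    by_name = {a.two_field: a for a in catalog}
    by_locus: dict[str, list[Allele]] = {}
    for v in allele_dosages.variants:
        if v.kind != "two_field":
            raise ValueError(f"expected two-field variants, got {v.id} ({v.kind})")
        allele = by_name.get(v.id)
        if allele is None:
            raise KeyError(f"allele {v.id!r} present in dosages but absent from catalog")
        by_locus.setdefault(v.locus, []).append(allele)

    cols, variants = [], []
    for locus in sorted(by_locus):
        alleles = by_locus[locus]
        col_of = {a.two_field: allele_dosages.index_of(a.two_field) for a in alleles}
        positions = sorted(set().union(*(a.sequence.keys() for a in alleles)))
        for pos in positions:
            residues = {}
            for a in alleles:
                if pos not in a.sequence:
                    raise ValueError(
                        f"incomplete catalog: {a.two_field} has no residue at "
                        f"{locus} position {pos}"
                    )
                residues.setdefault(a.sequence[pos], []).append(a)
            if len(residues) < 2:
                continue  # monomorphic position: no variant
            exons = {a.exon_of_position[pos] for a in alleles}
            if len(exons) != 1:
                raise ValueError(f"{locus} position {pos}: inconsistent exon assignment")
            exon = exons.pop()
            for res in sorted(residues):
                members = residues[res]
                dose = sum(allele_dosages.dosage[:, col_of[a.two_field]] for a in members)
                cols.append(dose)
                variants.append(
                    VariantDef(
                        id=amino_acid_variant_id(locus, pos, exon, {res}),
                        kind="amino_acid", locus=locus, position=pos,
                        residues=frozenset({res}), exon=exon,
                    )
                )

    for locus, pos, residue_set in grouped_markers or ():
        alleles = by_locus.get(locus)
        if not alleles:
            raise KeyError(f"no alleles at locus {locus!r} in dosage matrix")
        members = [a for a in alleles if a.sequence.get(pos) in set(residue_set)]
        if not members:
            raise ValueError(f"no catalog allele carries {set(residue_set)} at "
                             f"{locus} position {pos}")
        exon = members[0].exon_of_position[pos]
        dose = sum(
            allele_dosages.dosage[:, allele_dosages.index_of(a.two_field)]
            for a in members
        )
        cols.append(dose)
        variants.append(
            VariantDef(
                id=amino_acid_variant_id(locus, pos, exon, residue_set),
                kind="amino_acid", locus=locus, position=pos,
                residues=frozenset(residue_set), exon=exon,
            )
        )

    dosage = (np.column_stack(cols) if cols
              else np.empty((allele_dosages.n_individuals, 0)))
    variants = _attach_maf(variants, dosage)
    return DosageMatrix(allele_dosages.individuals, variants, dosage, validate=False)


def filter_variants(d: DosageMatrix, maf_min: float, r2_min: float) -> DosageMatrix:
    """Keep variants with MAF >= maf_min and imputation R^2 >= r2_min.

    Both bounds are inclusive.  A variant without an imputation R^2 passes the
    R^2 filter by convention (logged) — dosages that never went through an
    imputation step carry no R^2.
    """
    keep = []
    no_r2 = []
    for j, v in enumerate(d.variants):
        maf = v.maf if v.maf is not None else compute_maf(d.dosage[:, j])
        if maf < maf_min:
            continue
        if v.imputation_r2 is None:
            no_r2.append(v.id)
        elif v.imputation_r2 < r2_min:
            continue
        keep.append(v.id)
    if no_r2:
        logger.warning("%d variants without imputation R^2 pass the R^2 filter "
                       "by convention (first: %s)", len(no_r2), no_r2[0])
    if not keep:
        logger.warning("filter_variants: no variants pass (maf>=%s, r2>=%s)",
                       maf_min, r2_min)
    return d.subset(keep)


def annotate_pbg(v: VariantDef, loci=None) -> bool:
    """True iff the amino-acid variant lies in the peptide binding groove."""
    if v.kind != "amino_acid":
        raise ValueError(f"PBG membership undefined for {v.kind} variant {v.id}")
    loci = loci or LOCI
    return v.exon in loci[v.locus].pbg_exons


def classify_cis_trans(gene_chrom: str, gene_start: int, gene_end: int,
                       region: MhcRegion = MHC_REGION) -> str:
    """Classify a pGene as cis (inside the extended MHC) or trans.

    Coordinates are 1-based inclusive on the region's build.
    """
    if gene_start > gene_end or gene_start < 0:
        raise ValueError(f"malformed gene coordinates {gene_start}-{gene_end}")
    chrom = str(gene_chrom).removeprefix("chr")
    if chrom != region.chromosome:
        return "trans"
    overlaps = gene_start <= region.end and gene_end >= region.start
    return "cis" if overlaps else "trans"


# ---------------------------------------------------------------------------
# Catalog JSON I/O

def write_catalog(alleles, path) -> None:
    payload = {
        "alleles": [
            {
                "locus": a.locus,
                "two_field": a.two_field,
                "sequence": {str(p): r for p, r in sorted(a.sequence.items())},
                "exon_of_position": {str(p): e for p, e in sorted(a.exon_of_position.items())},
            }
            for a in alleles
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_catalog(path):
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Allele(
            locus=rec["locus"],
            two_field=rec["two_field"],
            sequence={int(p): r for p, r in rec["sequence"].items()},
            exon_of_position={int(p): int(e) for p, e in rec["exon_of_position"].items()},
        )
        for rec in payload["alleles"]
    ]
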