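"""Plain-text file formats: dosage + variant-metadata TSV, phenotype /
covariate / LOCO TSV, BED-like gene tables, GMT gene sets, results tables."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .catalog import DosageMatrix, VariantDef
from .phenotypes import LocoOffset, PhenotypePanel

_FLOAT_FMT = "%.10g"


def write_dosages(d: DosageMatrix, dosage_path, meta_path) -> None:
    """Individuals-as-rows dosage TSV plus a companion variant-metadata TSV."""
    d.to_frame().to_csv(dosage_path, sep="\t", index_label="individual",
                        float_format=_FLOAT_FMT)
    meta = pd.DataFrame([
        {
            "id": v.id,
            "kind": v.kind,
            "locus": v.locus,
            "position": "" if v.position is None else v.position,
            "residues": "" if v.residues is None else "".join(sorted(v.residues)),
            "exon": "" if v.exon is None else v.exon,
            "maf": "" if v.maf is None else v.maf,
            "r2": "" if v.imputation_r2 is None else v.imputation_r2,
        }
        for v in d.variants
    ])
    meta.to_csv(meta_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_dosages(dosage_path, meta_path) -> DosageMatrix:
    frame = pd.read_csv(dosage_path, sep="\t", index_col="individual")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"residues": str})
    variants = []
    for rec in meta.to_dict("records"):
        aa = rec["kind"] == "amino_acid"
        variants.append(VariantDef(
            id=rec["id"], kind=rec["kind"], locus=rec["locus"],
            position=int(rec["position"]) if aa else None,
            residues=frozenset(str(rec["residues"])) if aa else None,
            exon=int(rec["exon"]) if aa else None,
            maf=None if pd.isna(rec.get("maf")) else float(rec["maf"]),
            imputation_r2=None if pd.isna(rec.get("r2")) else float(rec["r2"]),
        ))
    order = [v.id for v in variants]
    return DosageMatrix(list(frame.index.astype(str)), variants,
                        frame[order].to_numpy(float))


def write_phenotypes(panel: PhenotypePanel, path) -> None:
    panel.values.to_csv(path, sep="\t", index_label="individual", na_rep="NA",
                        float_format=_FLOAT_FMT)


def read_phenotypes(path, layer: str = "raw") -> PhenotypePanel:
    frame = pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
    frame.index = frame.index.astype(str)
    return PhenotypePanel(frame, layer=layer)


def write_covariates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="individual", float_format=_FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col="individual")
    out.index = out.index.astype(str)
    return out


def read_loco(path) -> LocoOffset:
    frame = pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
    frame.index = frame.index.astype(str)
    return LocoOffset(frame)


def read_gene_coordinates(path) -> pd.DataFrame:
    """BED-like TSV with columns chrom, start, end, gene (header optional)."""
    first = open(path).readline().split("\t")
    header = 0 if first and first[0].strip().lower() in ("chrom", "chr", "#chrom") else None
    names = ["chrom", "start", "end", "gene"]
    out = pd.read_csv(path, sep="\t", header=header,
                      names=names if header is None else None)
    out.columns = names[: out.shape[1]]
    return out


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def association_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "protein": r.protein,
            "variant": r.variant,
            "beta": r.beta,
            "se": r.se,
            "minus_log10_p": r.log10p,
            "n": r.n,
            "model_tag": r.model_tag,
            "conditioning_set": ",".join(r.conditioning_set),
            "note": r.note or "",
        }
        for r in results
    ])


def omnibus_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "protein": r.protein,
            "locus": r.locus,
            "position": r.position,
            "M": r.M,
            "f_stat": r.f_stat,
            "df1": r.df1,
            "df2": r.df2,
            "minus_log10_p": r.log10p,
            "round": i + 1,
            "conditioning_chain": ",".join(f"{l}:{p}" for l, p in r.conditioning_chain),
            "note": r.note or "",
        }
        for i, r in enumerate(results)
    ])


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_manifest(path, **payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
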