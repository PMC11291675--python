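"""Descriptive and enrichment summaries over fine-mapped pQTL results.

Covers the peptide-binding-groove proportion of fine-mapped amino-acid
variants per HLA class, generic Fisher exact gene-set enrichment against a
panel background with Benjamini-Hochberg correction, overlap tables between
fine-mapped pQTL and fine-mapped trait associations, and pairwise protein
rank-correlation summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import LOCI, VariantDef, annotate_pbg

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    a: int  # in-set & hit
    b: int  # in-set & background-only
    c: int  # out-set & hit
    d: int  # out-set & background-only
    odds_ratio: float
    log10p: float
    fdr_q: float | None = None

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


def pbg_proportion(finemapped, variant_index) -> dict:
    """Fraction of fine-mapped amino-acid variants inside the peptide
    binding groove, per HLA class.

    ``finemapped`` is a list of association results (or variant-id strings);
    ``variant_index`` maps variant id -> VariantDef.  Allele-level variants
    are excluded with a log message.
    """
    ids = [r if isinstance(r, str) else r.variant for r in finemapped]
    if not ids:
        raise ValueError("pbg_proportion: empty input")
    counts = {"I": [0, 0], "II": [0, 0]}  # class -> [in PBG, total]
    n_excluded = 0
    for vid in ids:
        v = variant_index[vid]
        if v.kind != "amino_acid":
            n_excluded += 1
            continue
        cls = LOCI[v.locus].hla_class
        counts[cls][1] += 1
        if annotate_pbg(v):
            counts[cls][0] += 1
    if n_excluded:
        logger.info("pbg_proportion: excluded %d allele-level variants", n_excluded)
    if sum(c[1] for c in counts.values()) == 0:
        raise ValueError("pbg_proportion: no amino-acid variants in input")
    return {
        cls: (inside / total if total else np.nan)
        for cls, (inside, total) in counts.items()
    }


def fisher_set_enrichment(hits, target_set, background, set_name: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test of hit genes against one target set.

    ``hits`` must be a subset of ``background``; the target set is
    intersected with the background before testing.  The two-sided p is the
    sum of hypergeometric table probabilities no larger than the observed
    table's.  The odds ratio is the sample (a*d)/(b*c); a zero cell yields
    inf/nan, flagged rather than 0.5-corrected.
    """
    hits, target_set, background = set(hits), set(target_set), set(background)
    if not hits:
        raise ValueError("fisher_set_enrichment: empty hit set")
    if not background:
        raise ValueError("fisher_set_enrichment: empty background")
    if not hits <= background:
        raise ValueError("fisher_set_enrichment: hits must be a subset of background")
    target = target_set & background
    a = len(target & hits)
    b = len(target - hits)
    c = len(hits - target)
    d = len(background - target - hits)
    _or, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        logger.warning("fisher_set_enrichment %r: zero cell in 2x2 table", set_name)
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(set_name, a, b, c, d, float(odds),
                            float(-np.log10(max(p, 5e-324))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust: empty vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("bh_adjust: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_scan(hits, gene_sets: dict, background) -> list:
    """Fisher enrichment over many sets with BH correction across them."""
    results = [
        fisher_set_enrichment(hits, genes, background, set_name=name)
        for name, genes in gene_sets.items()
    ]
    if results:
        q = bh_adjust([10.0 ** (-r.log10p) for r in results])
        for r, qi in zip(results, q):
            r.fdr_q = float(qi)
    return results


def overlap_finemapped(
    pqtl_table: pd.DataFrame,
    trait_table: pd.DataFrame,
    pqtl_alpha: float = 5e-8,
    trait_significant_col: str = "significant",
    trait_alpha: float | None = None,
) -> pd.DataFrame:
    """Inner-join fine-mapped pQTL and trait tables on variant id, keeping
    rows significant in both; an empty intersection of variant ids warns
    (naming-convention mismatch is the likely cause) and returns empty.

    Expected columns: pqtl_table (variant, protein, minus_log10_p);
    trait_table (variant, trait, minus_log10_p [, significant]).
    """
    shared = set(pqtl_table["variant"]) & set(trait_table["variant"])
    cols = ["variant", "protein", "trait", "pqtl_log10p", "trait_log10p"]
    if not shared:
        logger.warning("overlap_finemapped: no shared variant ids — check the "
                       "variant naming convention of the two tables")
        return pd.DataFrame(columns=cols)
    p = pqtl_table[pqtl_table["minus_log10_p"] > -np.log10(pqtl_alpha)]
    t = trait_table
    if trait_significant_col in t.columns and trait_alpha is None:
        t = t[t[trait_significant_col].astype(bool)]
    elif trait_alpha is not None:
        t = t[t["minus_log10_p"] > -np.log10(trait_alpha)]
    merged = p.merge(t, on="variant", suffixes=("_pqtl", "_trait"))
    out = pd.DataFrame({
        "variant": merged["variant"],
        "protein": merged["protein"],
        "trait": merged["trait"],
        "pqtl_log10p": merged["minus_log10_p_pqtl"],
        "trait_log10p": merged["minus_log10_p_trait"],
    })
    return out.reset_index(drop=True)


def normalize_position_variant_id(locus: str, position: int, residue: str) -> str:
    """Documented normalization for matching external fine-map tables:
    ``LOCUS_pos_RESIDUE`` (e.g. ``B_180_Q``)."""
    return f"{locus}_{position}_{residue}"


def correlation_summary(panel, subset=None) -> dict:
    """Median and quartiles of pairwise complete-case Spearman correlations.

    With ``subset`` given, also compares the subset's pairwise correlations
    against the remaining background pairs by a rank-sum test.
    """
    values = panel.values if hasattr(panel, "values") and not isinstance(panel, pd.DataFrame) else panel
    if isinstance(values, pd.DataFrame) and values.shape[1] < 2:
        raise ValueError("correlation_summary: need >= 2 proteins")
    corr = values.corr(method="spearman", min_periods=3)
    iu = np.triu_indices(corr.shape[0], k=1)
    all_vals = corr.to_numpy()[iu]
    all_vals = all_vals[~np.isnan(all_vals)]
    out = {
        "n_pairs": int(all_vals.size),
        "median": float(np.median(all_vals)),
        "q1": float(np.quantile(all_vals, 0.25)),
        "q3": float(np.quantile(all_vals, 0.75)),
    }
    if subset is not None:
        subset = [p for p in subset if p in corr.columns]
        if len(subset) >= 2:
            sub = corr.loc[subset, subset].to_numpy()[
                np.triu_indices(len(subset), k=1)
            ]
            sub = sub[~np.isnan(sub)]
            mask = corr.columns.isin(subset)
            bg_pairs = [
                corr.iat[i, j]
                for i in range(corr.shape[0]) for j in range(i + 1, corr.shape[0])
                if not (mask[i] and mask[j])
            ]
            bg = np.asarray([v for v in bg_pairs if not np.isnan(v)])
            out["subset_median"] = float(np.median(sub))
            if sub.size and bg.size:
                out["subset_vs_background_p"] = float(
                    stats.mannwhitneyu(sub, bg, alternative="two-sided").pvalue
                )
    return out
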