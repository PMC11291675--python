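"""Conditional-haplotype omnibus fine-mapping of amino-acid positions.

For a given locus position, the two-field alleles are partitioned into M
groups by the residue they carry there; the group dosage of an individual is
the summed dosage of the member alleles.  The omnibus test compares the full
model (covariates + conditioning columns + M-1 group columns, one reference
group dropped) against the null model without any group column, by a nested
variance-ratio (F) test with the p-value computed in log space.

Sequential fine-mapping scans all polymorphic positions, selects the most
significant, then rescans conditioning on the selected positions' groupings
until no position passes the threshold, capping the chain at three
conditionally independent positions per protein.  When the lead position
falls in the tightly linked DRB1-DQA1-DQB1 superlocus, later rounds scan all
positions across the three loci jointly; otherwise rounds stay within the
lead's locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import SUPERLOCUS, DosageMatrix
from .association import GENOME_WIDE_ALPHA, LOG10P_CAP, log10p_from_f

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)
_TOL = 1e-10


@dataclass
class ResidueGrouping:
    """Partition of a locus's alleles by residue at one position."""

    locus: str
    position: int
    groups: dict  # residue -> frozenset of two-field allele names
    group_dosages: pd.DataFrame  # individuals x residues

    @property
    def M(self) -> int:
        return len(self.groups)

    def reference_residue(self) -> str:
        """Most frequent residue group (largest total dosage); the dropped
        reference in model designs.  Ties go to the alphabetically first."""
        totals = self.group_dosages.sum(axis=0)
        return sorted(totals.index, key=lambda r: (-totals[r], r))[0]

    def design_columns(self) -> pd.DataFrame:
        ref = self.reference_residue()
        cols = [r for r in sorted(self.groups) if r != ref]
        out = self.group_dosages[cols].copy()
        out.columns = [f"{self.locus}_pos{self.position}_{r}" for r in cols]
        return out


@dataclass
class OmnibusResult:
    protein: str
    locus: str
    position: int
    M: int
    f_stat: float
    df1: int
    df2: int
    log10p: float
    conditioning_chain: tuple = ()  # ordered (locus, position) pairs
    note: str | None = None

    @property
    def tested(self) -> bool:
        return self.note is None


def group_alleles_by_residue(
    catalog, locus: str, position: int, allele_dosages: DosageMatrix
) -> ResidueGrouping:
    """Group the locus's two-field alleles by residue at the position."""
    alleles = [a for a in catalog if a.locus == locus
               and a.two_field in allele_dosages.variant_ids]
    if not alleles:
        raise ValueError(f"no catalog alleles for locus {locus!r} in the dosage matrix")
    if not any(position in a.sequence for a in alleles):
        raise KeyError(f"position {position} absent from the {locus} catalog")
    groups: dict[str, set] = {}
    for a in alleles:
        if position not in a.sequence:
            raise ValueError(
                f"incomplete catalog: {a.two_field} has no residue at position {position}"
            )
        groups.setdefault(a.sequence[position], set()).add(a.two_field)
    dosages = {
        res: sum(allele_dosages.column(name) for name in members)
        for res, members in groups.items()
    }
    return ResidueGrouping(
        locus=locus,
        position=position,
        groups={r: frozenset(m) for r, m in groups.items()},
        group_dosages=pd.DataFrame(dosages, index=allele_dosages.individuals)[
            sorted(groups)
        ],
    )


def _independent_columns(base: np.ndarray, cols: np.ndarray, names, tol=_TOL):
    """Indices of ``cols`` columns not aliased with ``base`` + earlier cols."""
    X = base
    keep = []
    for j in range(cols.shape[1]):
        c = cols[:, [j]]
        resid = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
        if float(np.sum(resid * resid)) > tol * len(c):
            keep.append(j)
            X = np.hstack([X, c])
        else:
            logger.info("omnibus: column %s aliased, dropped", names[j])
    return keep, X


def omnibus_test(
    y,
    grouping: ResidueGrouping,
    conditioning_groups=(),
    covariates=None,
    protein: str = "",
    cap: float = LOG10P_CAP,
) -> OmnibusResult:
    """Nested-model F test of all residue groups at one position.

    F = [(RSS0 - RSS1)/df1] / [RSS1/df2], where the null model holds the
    covariates and conditioning columns and the full model adds the retained
    group columns.  M = 1, or every group column aliased with the
    conditioning set, yields a no-test marker instead of an error.
    """
    chain = tuple((g.locus, g.position) for g in conditioning_groups)
    if grouping.M < 2:
        return OmnibusResult(protein, grouping.locus, grouping.position, grouping.M,
                             np.nan, 0, 0, 0.0, chain, note="no-test: monomorphic")
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    n = len(yv)
    base_cols = [np.ones((n, 1))]
    base_names = ["(intercept)"]
    if covariates is not None:
        arr = (covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame)
               else np.asarray(covariates, dtype=float))
        if arr.ndim == 1:
            arr = arr[:, None]
        base_cols.append(arr[mask])
        base_names += (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                       else [f"x{j}" for j in range(arr.shape[1])])
    base = np.hstack(base_cols)
    for g in conditioning_groups:
        cond = g.design_columns().to_numpy(float)[mask]
        keep, base = _independent_columns(base, cond, list(g.design_columns().columns))
    group_df = grouping.design_columns()
    gcols = group_df.to_numpy(float)[mask]
    keep, _X = _independent_columns(base, gcols, list(group_df.columns))
    df1 = len(keep)
    if df1 == 0:
        return OmnibusResult(protein, grouping.locus, grouping.position, grouping.M,
                             np.nan, 0, 0, 0.0, chain,
                             note="no-test: aliased with conditioning set")
    full = np.hstack([base, gcols[:, keep]])
    df2 = n - full.shape[1]
    if df2 < 1:
        return OmnibusResult(protein, grouping.locus, grouping.position, grouping.M,
                             np.nan, df1, df2, 0.0, chain,
                             note="no-test: insufficient residual df")
    rss0 = float(np.sum((yv - base @ np.linalg.lstsq(base, yv, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((yv - full @ np.linalg.lstsq(full, yv, rcond=None)[0]) ** 2))
    if rss1 <= _TOL * max(rss0, 1.0):
        return OmnibusResult(protein, grouping.locus, grouping.position, grouping.M,
                             np.inf, df1, df2, cap, chain, note=None)
    f = max((rss0 - rss1) / df1 / (rss1 / df2), 0.0)
    return OmnibusResult(
        protein, grouping.locus, grouping.position, grouping.M,
        f, df1, df2, log10p_from_f(f, df1, df2, cap), chain,
    )


def polymorphic_positions(catalog, locus: str, allele_dosages: DosageMatrix | None = None):
    """Positions of the locus with >= 2 distinct residues among its alleles."""
    alleles = [a for a in catalog if a.locus == locus]
    if allele_dosages is not None:
        present = set(allele_dosages.variant_ids)
        alleles = [a for a in alleles if a.two_field in present]
    positions = sorted(set().union(*(a.sequence.keys() for a in alleles))) if alleles else []
    out = []
    for pos in positions:
        residues = {a.sequence.get(pos) for a in alleles}
        if len(residues - {None}) >= 2:
            out.append(pos)
    return out


def candidate_positions(lead_locus: str, catalog,
                        allele_dosages: DosageMatrix | None = None):
    """Positions scanned in conditional rounds after a lead at ``lead_locus``.

    A lead in the DRB1-DQA1-DQB1 superlocus opens all three loci; any other
    lead restricts the scan to its own locus.
    """
    loci_present = {a.locus for a in catalog}
    if lead_locus not in loci_present:
        raise KeyError(f"unknown locus {lead_locus!r}")
    loci = SUPERLOCUS if lead_locus in SUPERLOCUS else (lead_locus,)
    return [
        (locus, pos)
        for locus in loci
        for pos in polymorphic_positions(catalog, locus, allele_dosages)
    ]


def sequential_conditional_haplotype(
    y,
    catalog,
    allele_dosages: DosageMatrix,
    stop_alpha: float = GENOME_WIDE_ALPHA,
    max_positions: int = 3,
    covariates=None,
    protein: str = "",
) -> list:
    """Sequential conditional-haplotype scan; at most ``max_positions``
    conditionally independent amino-acid positions are reported.

    Round 1 scans all polymorphic positions at all loci; later rounds scan
    the candidate positions of the round-1 locus with all previously
    selected groupings as conditioning columns.
    """
    loci = sorted({a.locus for a in catalog if a.two_field in set(allele_dosages.variant_ids)})
    all_positions = [
        (locus, pos) for locus in loci
        for pos in polymorphic_positions(catalog, locus, allele_dosages)
    ]
    groupings = {
        key: group_alleles_by_residue(catalog, key[0], key[1], allele_dosages)
        for key in all_positions
    }
    thr = -np.log10(stop_alpha)
    selected: list[OmnibusResult] = []
    cond: list[ResidueGrouping] = []
    while len(selected) < max_positions:
        if not selected:
            candidates = all_positions
        else:
            lead_locus = selected[0].locus
            chosen = {(r.locus, r.position) for r in selected}
            candidates = [
                key for key in candidate_positions(lead_locus, catalog, allele_dosages)
                if key not in chosen
            ]
        results = [
            omnibus_test(y, groupings[key], cond, covariates=covariates,
                         protein=protein)
            for key in candidates
        ]
        results = [r for r in results if r.tested]
        if not results:
            break
        best = sorted(results, key=lambda r: (-r.log10p, r.locus, r.position))[0]
        if best.log10p <= thr:
            break
        selected.append(best)
        cond.append(groupings[(best.locus, best.position)])
    return selected
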