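"""Protein phenotype preparation.

Raw protein abundances are turned into the analysis phenotype in four steps:
inverse rank-normal transform (per protein), residualization on covariates,
scaling to mean 0 / SD 1, and subtraction of a precomputed leave-one-
chromosome-out (LOCO) polygenic offset.  Optionally, the top k principal
components of the (mean-imputed) normalized expression matrix are appended to
the covariates before residualization, absorbing latent technical and
disease-related structure.

Missing protein measurements stay missing throughout (complete-case handling
downstream); only the expression PCA mean-imputes, since a PCA needs a
complete matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Blom rank offset, the common convention in pQTL studies.
BLOM_OFFSET = 3.0 / 8.0


@dataclass
class PhenotypePanel:
    """Individuals x proteins value matrix with a processing-layer tag."""

    values: pd.DataFrame  # index: individuals, columns: proteins; NaN = missing
    layer: str = "raw"  # raw | int_transformed | residualized | analysis_ready

    @property
    def individuals(self):
        return list(self.values.index)

    @property
    def proteins(self):
        return list(self.values.columns)

    def missing_rate(self) -> float:
        return float(self.values.isna().to_numpy().mean())


@dataclass
class LocoOffset:
    """Per-protein, per-individual polygenic offsets; zero when absent."""

    values: pd.DataFrame | None = None

    def slice_for(self, protein: str, individuals) -> np.ndarray:
        if self.values is None or protein not in self.values.columns:
            return np.zeros(len(individuals))
        return self.values.loc[individuals, protein].to_numpy(float)


def inverse_rank_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Map values to Gaussian quantiles of their (Blom-offset) ranks.

    Non-missing entries become ``Phi^{-1}((rank - offset) / (m + 1 - 2*offset))``
    with ``m`` the non-missing count; ties share the average rank; missing
    entries stay missing.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = ~np.isnan(v)
    m = int(mask.sum())
    if m < 3:
        raise ValueError(f"inverse_rank_normal needs >=3 non-missing values, got {m}")
    x = v[mask]
    if np.ptp(x) == 0:
        raise ValueError("inverse_rank_normal: constant vector")
    ranks = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (m + 1.0 - 2.0 * offset))
    return out


def _aliased_columns(X: np.ndarray, names, tol: float = 1e-8):
    """Names of columns made redundant by earlier columns (QR with pivoting)."""
    if X.shape[1] == 0:
        return []
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = tol * (diag[0] if diag.size and diag[0] > 0 else 1.0)
    rank = int((diag > thresh).sum())
    return [names[j] for j in piv[rank:]]


def prepare_covariates(table: pd.DataFrame, drop_aliased: bool = True) -> pd.DataFrame:
    """Expand categoricals to indicators and drop rank-deficient columns.

    Categorical/object/bool columns become 0/1 indicators (first level
    dropped).  Columns aliased with earlier ones (including the intercept)
    are removed with a log message; missing covariate values are an error.
    """
    cols = {}
    for name in table.columns:
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dname in dummies.columns:
                cols[dname] = dummies[dname]
        else:
            cols[name] = col.astype(float)
    out = pd.DataFrame(cols, index=table.index)
    if out.isna().any().any():
        bad = sorted(out.columns[out.isna().any()])
        raise ValueError(f"covariates contain missing values: {bad}")
    if drop_aliased and out.shape[1]:
        design = np.column_stack([np.ones(len(out)), out.to_numpy(float)])
        aliased = _aliased_columns(design, ["(intercept)"] + list(out.columns))
        aliased = [a for a in aliased if a != "(intercept)"]
        if aliased:
            logger.warning("dropping aliased covariate columns: %s", aliased)
            out = out.drop(columns=aliased)
    return out


def residualize(y, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on the covariates plus an intercept.

    Complete-case: rows with missing y keep NaN in the output.  A design that
    is rank-deficient even after covariate preparation raises, naming the
    aliased columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        X = np.empty((len(y), 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        X = covariates.to_numpy(float)
        names = list(covariates.columns)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    mask = ~np.isnan(y)
    design = np.column_stack([np.ones(int(mask.sum())), X[mask]])
    aliased = _aliased_columns(design, ["(intercept)"] + names)
    if aliased:
        raise ValueError(f"rank-deficient covariate design; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
    out = np.full(len(y), np.nan)
    out[mask] = y[mask] - design @ beta
    return out


def scale_and_offset(y, loco=None) -> np.ndarray:
    """Z-score non-missing entries, then subtract the LOCO offset."""
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    x = y[mask]
    sd = x.std()
    if sd == 0:
        raise ValueError("scale_and_offset: zero variance")
    out = np.full(len(y), np.nan)
    out[mask] = (x - x.mean()) / sd
    if loco is not None:
        loco = np.asarray(loco, dtype=float)
        out[mask] = out[mask] - loco[mask]
    return out


def expression_pcs(panel: PhenotypePanel, k: int) -> pd.DataFrame:
    """Scores of the top-k PCs of the mean-imputed expression matrix.

    Missing entries are replaced by the per-protein mean, columns centered,
    and an SVD taken; returned scores are ``U_k S_k``, with each component's
    sign fixed so its largest-magnitude protein loading is positive.
    """
    V = panel.values.to_numpy(float).copy()
    n, p = V.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_individuals, n_proteins)={min(n, p)}")
    if k == 0:
        return pd.DataFrame(index=panel.values.index)
    col_mean = np.nanmean(V, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(V))
    V[nan_rows, nan_cols] = col_mean[nan_cols]
    V = V - V.mean(axis=0)
    u, s, vt = np.linalg.svd(V, full_matrices=False)
    if k > int((s > s[0] * 1e-12).sum()):
        raise ValueError(f"k={k} exceeds the rank of the expression matrix")
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    signs[signs == 0] = 1.0
    scores = u[:, :k] * s[:k] * signs
    return pd.DataFrame(
        scores, index=panel.values.index,
        columns=[f"expr_pc{i + 1}" for i in range(k)],
    )


def prepare_panel(
    panel: PhenotypePanel,
    covariates: pd.DataFrame | None = None,
    loco: LocoOffset | None = None,
    n_expression_pcs: int = 0,
    int_offset: float = BLOM_OFFSET,
    scale_before_loco: bool = True,
) -> PhenotypePanel:
    """Full pipeline: INT -> [expression PCs ->] residualize -> scale -> LOCO.

    Returns an ``analysis_ready`` panel whose non-missing entries have mean 0
    and SD 1 per protein (before LOCO subtraction).
    """
    if panel.layer != "raw":
        logger.warning("prepare_panel on layer %r (expected raw)", panel.layer)
    loco = loco or LocoOffset()
    ind = panel.values.index
    normed = pd.DataFrame(
        {p: inverse_rank_normal(panel.values[p].to_numpy(float), offset=int_offset)
         for p in panel.proteins},
        index=ind,
    )
    cov = covariates.loc[ind] if covariates is not None else pd.DataFrame(index=ind)
    cov = prepare_covariates(cov)
    if n_expression_pcs:
        pcs = expression_pcs(PhenotypePanel(normed, "int_transformed"), n_expression_pcs)
        cov = pd.concat([cov, pcs], axis=1)
    out = {}
    for p in panel.proteins:
        resid = residualize(normed[p].to_numpy(float), cov)
        lo = loco.slice_for(p, ind)
        if scale_before_loco:
            out[p] = scale_and_offset(resid, lo)
        else:
            mask = ~np.isnan(resid)
            shifted = resid.copy()
            shifted[mask] -= lo[mask]
            out[p] = scale_and_offset(shifted)
    return PhenotypePanel(pd.DataFrame(out, index=ind), layer="analysis_ready")
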