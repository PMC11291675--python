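"""Single-marker and conditional HLA-pQTL association tests.

Each variant is tested by OLS of the prepared phenotype on its dosage
(plus an intercept and any run-specific covariates); the two-sided t-test
p-value is computed in log space via the survival function, so associations
far beyond double-precision underflow (-log10 p in the thousands, as seen
for strong plasma pQTL) remain representable.  All p-values are carried as
-log10 p throughout.

Forward conditional analysis repeats the scan with previously selected lead
variants as covariates until no remaining variant passes the stopping
threshold.  Variance explained by the ordered lead + conditional variants is
decomposed by sequential (Type-I) sums of squares over the nested model
sequence.  A permutation null shuffles the prepared phenotype across
individuals and retains each iteration's best -log10 p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import DosageMatrix

logger = logging.getLogger(__name__)

#: -log10 p reported for numerically perfect fits (residual SS ~ 0).
LOG10P_CAP = 5000.0

#: Genome-wide significance level for a single phenotype.
GENOME_WIDE_ALPHA = 5e-8

_LN10 = np.log(10.0)
_VAR_TOL = 1e-10  # partial variance below this => constant/aliased dosage


@dataclass
class SignificanceThresholds:
    """Discovery = genome-wide Bonferroni-divided by the protein count."""

    genome_wide: float = GENOME_WIDE_ALPHA
    n_proteins: int = 1
    replication: float = 0.05

    @property
    def discovery(self) -> float:
        return bonferroni_threshold(self.genome_wide, self.n_proteins)


@dataclass
class AssociationResult:
    protein: str
    variant: str
    beta: float
    se: float
    log10p: float  # -log10 two-sided p
    n: int
    conditioning_set: tuple = ()
    model_tag: str = "marginal"
    note: str | None = None

    @property
    def skipped(self) -> bool:
        return self.note is not None and "skip" in self.note


@dataclass
class VarianceDecomposition:
    protein: str
    ordered_variants: list
    sequential_ss_fraction: list

    @property
    def total_fraction(self) -> float:
        return float(sum(self.sequential_ss_fraction))


@dataclass
class PermutationNull:
    protein: str
    n_perm: int
    null_max_log10p: np.ndarray  # per-iteration best -log10 p
    observed_max_log10p: float

    @property
    def empirical_p(self) -> float:
        exceed = int((self.null_max_log10p >= self.observed_max_log10p).sum())
        return (1 + exceed) / (1 + self.n_perm)


@dataclass
class CombinedModelResult:
    hla: AssociationResult
    external: AssociationResult
    label: str  # hla_driven | external_driven | both_independent | neither
    collinear: bool = False


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _log_betainc_small_x(a: float, b: float, x: float) -> float:
    """ln I_x(a, b) via the hypergeometric series, accurate for small x.

    I_x(a,b) = x^a (1-x)^b / (a B(a,b)) * 2F1(a+b, 1; a+1; x); for the small
    x arising from extreme test statistics the 2F1 factor is O(1), so the
    log never underflows.
    """
    from scipy.special import betaln, hyp2f1

    return (a * np.log(x) + b * np.log1p(-x) - np.log(a) - betaln(a, b)
            + np.log(hyp2f1(a + b, 1.0, a + 1.0, x)))


def log10p_from_t(t: float, df: int, cap: float = LOG10P_CAP) -> float:
    """-log10 of the two-sided t-test p, computed in log space.

    Uses the survival function where it is accurate and an incomplete-beta
    expansion for statistics whose p underflows even scipy's logsf; infinite
    t (a numerically perfect fit) reports the cap.
    """
    if not np.isfinite(t):
        return cap
    lp = stats.t.logsf(abs(t), df) + np.log(2.0)
    if not np.isfinite(lp) or lp < -650:
        # two-sided p = I_x(df/2, 1/2) with x = df/(df + t^2)
        x = df / (df + t * t)
        lp = _log_betainc_small_x(df / 2.0, 0.5, x)
    return float(min(-lp / _LN10, cap))


def log10p_from_f(f: float, df1: int, df2: int, cap: float = LOG10P_CAP) -> float:
    """-log10 of the F-test p (upper tail), log-space with underflow guard."""
    if not np.isfinite(f):
        return cap
    lp = stats.f.logsf(f, df1, df2)
    if not np.isfinite(lp) or lp < -650:
        # sf(F) = I_x(df2/2, df1/2) with x = df2/(df2 + df1*F)
        x = df2 / (df2 + df1 * f)
        lp = _log_betainc_small_x(df2 / 2.0, df1 / 2.0, x)
    return float(min(-lp / _LN10, cap))


def _design(n: int, extras) -> tuple[np.ndarray, list]:
    cols = [np.ones(n)]
    names = ["(intercept)"]
    if extras is not None:
        if isinstance(extras, pd.DataFrame):
            arr = extras.to_numpy(float)
            enames = list(extras.columns)
        else:
            arr = np.asarray(extras, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            enames = [f"x{j}" for j in range(arr.shape[1])]
        cols.append(arr)
        names += enames
    return np.column_stack(cols) if len(cols) > 1 else cols[0][:, None], names


def _check_full_rank(X: np.ndarray, names):
    from .phenotypes import _aliased_columns

    aliased = _aliased_columns(X, names)
    if aliased:
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def single_marker_test(
    y,
    dosage,
    extra_covariates=None,
    protein: str = "",
    variant: str = "",
    conditioning_set=(),
    model_tag: str = "marginal",
    min_n: int = 10,
    cap: float = LOG10P_CAP,
) -> AssociationResult:
    """OLS of y on one dosage column (+ intercept + optional covariates).

    Complete-case over y and dosage; a constant dosage yields a flagged-skip
    result rather than an error, while a rank-deficient covariate set raises.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(dosage)
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(f"only {n} complete cases (< {min_n})")
    if extra_covariates is None:
        extras_m = None
    else:
        if isinstance(extra_covariates, pd.DataFrame):
            arr = extra_covariates.to_numpy(float)
        else:
            arr = np.asarray(extra_covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        extras_m = arr[mask]
    C, names = _design(n, extras_m)
    _check_full_rank(C, names)
    x = dosage[mask]
    yv = y[mask]
    # partial out the covariates (Frisch-Waugh): exact OLS for the dosage term
    Cpinv = np.linalg.pinv(C)
    xr = x - C @ (Cpinv @ x)
    yr = yv - C @ (Cpinv @ yv)
    sxx = float(xr @ xr)
    if sxx < _VAR_TOL * n:
        return AssociationResult(
            protein, variant, np.nan, np.nan, 0.0, n,
            tuple(conditioning_set), model_tag, note="skip: constant dosage",
        )
    beta = float(xr @ yr) / sxx
    dfree = n - C.shape[1] - 1
    rss = float(yr @ yr) - beta * beta * sxx
    if rss <= max(_VAR_TOL * float(yr @ yr), 0.0) or rss <= 0:
        return AssociationResult(
            protein, variant, beta, 0.0, cap, n,
            tuple(conditioning_set), model_tag, note="perfect fit",
        )
    se = float(np.sqrt(rss / dfree / sxx))
    t = beta / se
    return AssociationResult(
        protein, variant, beta, se, log10p_from_t(t, dfree, cap), n,
        tuple(conditioning_set), model_tag,
    )


def marginal_scan(y, dosage_cols: np.ndarray, covariates=None, cap: float = LOG10P_CAP):
    """Vectorized per-column OLS: returns (beta, se, log10p, valid, n, df).

    ``dosage_cols`` is complete (no NaN); rows with missing y are dropped.
    Columns whose partial variance vanishes (constant or aliased with the
    covariates) are flagged invalid.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(dosage_cols, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    Dm = D[mask]
    n = int(mask.sum())
    C, names = _design(n, covariates if covariates is None else (
        covariates.loc[mask] if isinstance(covariates, pd.DataFrame) else np.asarray(covariates)[mask]
    ))
    _check_full_rank(C, names)
    Cpinv = np.linalg.pinv(C)
    yr = yv - C @ (Cpinv @ yv)
    Dr = Dm - C @ (Cpinv @ Dm)
    sxx = np.einsum("ij,ij->j", Dr, Dr)
    valid = sxx > _VAR_TOL * n
    sxy = Dr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(valid, sxy / np.where(valid, sxx, 1.0), np.nan)
    dfree = n - C.shape[1] - 1
    syy = float(yr @ yr)
    rss = np.maximum(syy - beta * beta * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dfree / np.where(valid, sxx, 1.0))
        t = np.where(se > 0, beta / se, np.inf)
    log10p = np.full(D.shape[1], 0.0)
    finite = valid & np.isfinite(t)
    lsf = stats.t.logsf(np.abs(t[finite]), dfree) + np.log(2.0)
    vals = np.minimum(-lsf / _LN10, cap)
    bad = ~np.isfinite(lsf) | (lsf < -650)
    if bad.any():  # re-derive entries beyond scipy's logsf accuracy
        tb = np.abs(t[finite])[bad]
        vals[bad] = [log10p_from_t(float(tt), dfree, cap) for tt in tb]
    log10p[finite] = vals
    log10p[valid & ~np.isfinite(t)] = cap
    se = np.where(valid, se, np.nan)
    beta = np.where(valid, beta, np.nan)
    return beta, se, log10p, valid, n, dfree


def select_lead(results) -> AssociationResult:
    """Best association: max -log10 p, ties by larger |beta|, then variant id."""
    results = [r for r in results if not r.skipped]
    if not results:
        raise ValueError("select_lead: empty result list")
    return sorted(results, key=lambda r: (-r.log10p, -abs(r.beta), r.variant))[0]


def forward_conditional(
    y,
    dosages: DosageMatrix,
    stop_alpha: float = GENOME_WIDE_ALPHA,
    variant_kinds=None,
    extra_covariates=None,
    protein: str = "",
    first_round_alpha: float | None = None,
    max_rounds: int | None = None,
) -> list:
    """Forward stepwise conditional scan.

    Round k tests every remaining candidate conditioned on the k-1 variants
    already selected; the lead joins the conditioning set.  Stops when the
    best remaining p exceeds ``stop_alpha`` (``first_round_alpha`` may set a
    stricter discovery threshold for round 1) or when every candidate is
    aliased with the conditioning set (skipped, logged).
    """
    if not 0 < stop_alpha < 1:
        raise ValueError("stop_alpha must be in (0, 1)")
    d = dosages if variant_kinds is None else dosages.select(
        lambda v: v.kind in set(variant_kinds)
    )
    ids = d.variant_ids
    selected: list[AssociationResult] = []
    selected_cols: list[np.ndarray] = []
    remaining = list(range(len(ids)))
    while remaining and (max_rounds is None or len(selected) < max_rounds):
        if isinstance(extra_covariates, pd.DataFrame):
            base = extra_covariates.to_numpy(float)
        elif extra_covariates is not None:
            base = np.asarray(extra_covariates, dtype=float)
            if base.ndim == 1:
                base = base[:, None]
        else:
            base = np.empty((d.n_individuals, 0))
        cond = (np.column_stack([base] + selected_cols)
                if selected_cols or base.size else (base if base.size else None))
        beta, se, log10p, valid, n, _df = marginal_scan(
            y, d.dosage[:, remaining], covariates=cond
        )
        if not valid.any():
            logger.warning("forward_conditional: all remaining candidates aliased")
            break
        results = [
            AssociationResult(
                protein, ids[remaining[j]], float(beta[j]), float(se[j]),
                float(log10p[j]), n,
                tuple(r.variant for r in selected),
                "marginal" if not selected else "conditional",
            )
            for j in np.flatnonzero(valid)
        ]
        lead = select_lead(results)
        alpha = (first_round_alpha if (first_round_alpha is not None and not selected)
                 else stop_alpha)
        if lead.log10p <= -np.log10(alpha):
            break
        selected.append(lead)
        j = ids.index(lead.variant)
        selected_cols.append(d.dosage[:, [j]])
        remaining = [r for r in remaining if ids[r] != lead.variant]
    return selected


def class_adjusted_test(
    y,
    lead_dosage,
    opposite_class_alleles: DosageMatrix,
    lead_id: str = "",
    protein: str = "",
) -> AssociationResult:
    """Test the lead adjusting for all two-field alleles of the other class.

    Because a locus's complete two-field dosages sum to 2, one reference
    allele per locus (the lowest-frequency one) is dropped; any further
    aliased columns are dropped with a log message.
    """
    if lead_id and lead_id in opposite_class_alleles.variant_ids:
        raise ValueError(f"lead {lead_id!r} is itself in the adjustment set")
    from .catalog import compute_maf
    from .phenotypes import _aliased_columns

    by_locus: dict[str, list] = {}
    for j, v in enumerate(opposite_class_alleles.variants):
        maf = v.maf if v.maf is not None else compute_maf(opposite_class_alleles.dosage[:, j])
        by_locus.setdefault(v.locus, []).append((maf, v.id, j))
    keep = []
    for locus in sorted(by_locus):
        entries = sorted(by_locus[locus])
        ref = entries[0]
        logger.info("class_adjusted_test: dropping reference allele %s at %s",
                    ref[1], locus)
        keep.extend(j for _m, _i, j in entries[1:])
    cols = opposite_class_alleles.dosage[:, keep]
    names = [opposite_class_alleles.variants[j].id for j in keep]
    if cols.size:
        design = np.column_stack([np.ones(len(cols)), cols])
        aliased = _aliased_columns(design, ["(intercept)"] + names)
        if aliased:
            logger.warning("class_adjusted_test: dropping aliased columns %s", aliased)
            sel = [k for k, nm in enumerate(names) if nm not in set(aliased)]
            cols = cols[:, sel]
            names = [names[k] for k in sel]
    res = single_marker_test(
        y, lead_dosage, extra_covariates=cols if cols.size else None,
        protein=protein, variant=lead_id, conditioning_set=tuple(names),
        model_tag="class_adjusted",
    )
    return res


def combined_model_test(
    y,
    hla_lead,
    external_variant,
    alpha: float = GENOME_WIDE_ALPHA,
    hla_id: str = "hla_lead",
    external_id: str = "external",
    protein: str = "",
) -> CombinedModelResult:
    """Joint model with the HLA lead and an external variant (class III SNP,
    cis-eQTL/pQTL); classifies which signal survives co-adjustment."""
    hla = np.asarray(hla_lead, dtype=float)
    ext = np.asarray(external_variant, dtype=float)
    mask = ~np.isnan(np.asarray(y, dtype=float)) & ~np.isnan(hla) & ~np.isnan(ext)
    r = np.corrcoef(hla[mask], ext[mask])[0, 1]
    if abs(r) > 0.999:
        nan = AssociationResult(protein, hla_id, np.nan, np.nan, 0.0,
                                int(mask.sum()), (), "combined",
                                note="skip: collinear pair")
        nan2 = AssociationResult(protein, external_id, np.nan, np.nan, 0.0,
                                 int(mask.sum()), (), "combined",
                                 note="skip: collinear pair")
        return CombinedModelResult(nan, nan2, "neither", collinear=True)
    res_hla = single_marker_test(
        y, hla, extra_covariates=ext[:, None], protein=protein, variant=hla_id,
        conditioning_set=(external_id,), model_tag="combined",
    )
    res_ext = single_marker_test(
        y, ext, extra_covariates=hla[:, None], protein=protein, variant=external_id,
        conditioning_set=(hla_id,), model_tag="combined",
    )
    thr = -np.log10(alpha)
    sig_h, sig_e = res_hla.log10p > thr, res_ext.log10p > thr
    label = ("both_independent" if sig_h and sig_e
             else "hla_driven" if sig_h
             else "external_driven" if sig_e
             else "neither")
    return CombinedModelResult(res_hla, res_ext, label)


def variance_explained(y, ordered_dosages, protein: str = "") -> VarianceDecomposition:
    """Sequential (Type-I) variance fractions for the ordered variant set.

    fraction_k = (RSS_{k-1} - RSS_k) / TSS for the nested model sequence
    starting from the intercept-only model; the total equals the joint-model
    R^2.  A variant aliased with its predecessors contributes 0 (logged).
    """
    if isinstance(ordered_dosages, DosageMatrix):
        names = ordered_dosages.variant_ids
        D = ordered_dosages.dosage
    elif isinstance(ordered_dosages, pd.DataFrame):
        names = list(ordered_dosages.columns)
        D = ordered_dosages.to_numpy(float)
    else:
        D = np.asarray(ordered_dosages, dtype=float)
        names = [f"v{j}" for j in range(D.shape[1])]
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    Dm = D[mask]
    n = len(yv)
    yc = yv - yv.mean()
    tss = float(yc @ yc)
    X = np.ones((n, 1))
    rss_prev = tss
    fractions = []
    for k, name in enumerate(names):
        col = Dm[:, [k]]
        resid_col = col - X @ np.linalg.lstsq(X, col, rcond=None)[0]
        if float(np.sum(resid_col * resid_col)) < _VAR_TOL * n:
            logger.warning("variance_explained: %s aliased with predecessors; "
                           "contributes 0", name)
            fractions.append(0.0)
            continue
        X = np.hstack([X, col])
        resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        rss = float(resid @ resid)
        fractions.append(max((rss_prev - rss) / tss, 0.0))
        rss_prev = rss
    return VarianceDecomposition(protein, list(names), fractions)


def permutation_null(
    y,
    dosages: DosageMatrix,
    n_perm: int,
    seed,
    covariates=None,
    protein: str = "",
) -> PermutationNull:
    """Permute the prepared phenotype across individuals and retain each
    iteration's lead -log10 p (dosages and covariates fixed)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    yv = y[mask]
    Dm = dosages.dosage[mask]
    n = len(yv)
    C, names = _design(n, covariates if covariates is None else (
        covariates.loc[mask] if isinstance(covariates, pd.DataFrame)
        else np.asarray(covariates)[mask]
    ))
    _check_full_rank(C, names)
    Cpinv = np.linalg.pinv(C)
    proj = lambda M: M - C @ (Cpinv @ M)  # noqa: E731
    Dr = proj(Dm)
    sxx = np.einsum("ij,ij->j", Dr, Dr)
    valid = sxx > _VAR_TOL * n
    dfree = n - C.shape[1] - 1

    def max_abs_t(Y):  # Y: n x b, already permuted raw phenotype columns
        Yr = proj(Y)
        sxy = Dr[:, valid].T @ Yr  # V x b
        syy = np.einsum("ij,ij->j", Yr, Yr)
        b = sxy / sxx[valid, None]
        rss = np.maximum(syy[None, :] - b * b * sxx[valid, None], 1e-300)
        t = b / np.sqrt(rss / dfree / sxx[valid, None])
        return np.abs(t).max(axis=0)

    obs_t = float(max_abs_t(yv[:, None])[0])
    observed = log10p_from_t(obs_t, dfree)
    null = np.empty(n_perm)
    block = 200
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        Y = np.column_stack([yv[rng.permutation(n)] for _ in range(b)])
        tmax = max_abs_t(Y)
        null[start:start + b] = [log10p_from_t(float(t), dfree) for t in tmax]
    return PermutationNull(protein, n_perm, null, observed)


def replication_check(discovery, replication, alpha: float = 0.05) -> dict:
    """Per-pair replication flags and the rank correlation of effect sizes.

    Pairs are matched on (protein, variant).  A pair replicates when its
    replication p < alpha with a concordant effect direction.
    """
    disc = {(r.protein, r.variant): r for r in discovery}
    repl = {(r.protein, r.variant): r for r in replication}
    shared = sorted(set(disc) & set(repl))
    if not shared:
        raise ValueError("replication_check: no shared (protein, variant) pairs")
    thr = -np.log10(alpha)
    rows = []
    for key in shared:
        d, r = disc[key], repl[key]
        sig = r.log10p > thr
        concordant = np.sign(d.beta) == np.sign(r.beta)
        rows.append({
            "protein": key[0], "variant": key[1],
            "discovery_beta": d.beta, "replication_beta": r.beta,
            "replication_significant": bool(sig),
            "direction_concordant": bool(concordant),
            "replicated": bool(sig and concordant),
        })
    table = pd.DataFrame(rows)
    if len(shared) >= 2:
        rho = float(stats.spearmanr(
            table["discovery_beta"], table["replication_beta"]
        ).statistic)
    else:
        rho = np.nan
    return {
        "table": table,
        "n_pairs": len(shared),
        "fraction_replicated": float(table["replicated"].mean()),
        "fraction_concordant": float(table["direction_concordant"].mean()),
        "effect_rank_correlation": rho,
    }
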