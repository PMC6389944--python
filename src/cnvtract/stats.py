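"""Penetrance association statistics with permutation FWER control.

Every imaging variable is tested with an ordinary least-squares GLM of
the variable on the penetrance score (or a binary carrier indicator),
with age and gender as covariates, total brain volume additionally for
volumetric variables and the intra-scan head-motion index additionally
for diffusion-derived variables. Family-wise error across the variables
of one family (one microstructure metric across the 19 bundles, the
shape descriptors as a single family, the tract volumes, …) is
controlled with max-|t| permutation testing under the Freedman–Lane
scheme: residuals of the covariate-only model are permuted, the full
model is refit, and the permutation distribution of the maximum |t|
across the family yields corrected p-values with the +1 estimator
``p_corr = (1 + #{max|t|_b >= |t|_obs}) / (B + 1)`` (never exactly
zero). Corrected p-values are floored at the parametric p so the
``p_corr >= p`` contract holds even for one-feature families.

All permutation draws come from a single seeded generator, so results
are bit-exact reproducible given ``(seed, B)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from cnvtract.tractometry import FeatureMatrix

__all__ = [
    "AssociationResult",
    "GlobalPcaResult",
    "ScoreCorrelation",
    "fit_glm",
    "permutation_correct",
    "binary_model",
    "loo_cnv_sensitivity",
    "global_pca_test",
    "cc_ratio_test",
    "score_correlation",
    "design_matrix",
]

_MIN_P = float(np.finfo(float).tiny)


@dataclass
class AssociationResult:
    """One feature × predictor association from the covariate-adjusted GLM."""

    feature: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    family_id: str = ""
    p_corr: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.p_corr is not None and not 0.0 < self.p_corr <= 1.0:
            raise ValueError("p_corr must lie in (0, 1]")


@dataclass
class ScoreCorrelation:
    """Spearman rank correlation between the two penetrance scores."""

    rho: float
    p: float
    n: int
    method: str          # "exact-permutation" or "t-approximation"
    defined: bool = True


@dataclass
class GlobalPcaResult:
    """Global PCA of the standardised feature matrix plus component tests."""

    loadings: pd.DataFrame            # components x variables
    scores: pd.DataFrame              # subjects x components
    explained_variance_ratio: np.ndarray
    results: dict[str, list[AssociationResult]]  # predictor -> per-component
    imputed_cells: int = 0
    dropped_columns: list[str] = field(default_factory=list)


def design_matrix(cohort: pd.DataFrame, predictor: str,
                  volumetric: bool = False, diffusion_derived: bool = False,
                  ) -> tuple[np.ndarray, list[str]]:
    """Covariate-policy design matrix ``[1, predictor, age, gender(, TBV)(, motion)]``."""
    if predictor not in cohort.columns:
        raise ValueError(f"predictor {predictor!r} not in cohort table")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(cohort)),
        predictor: cohort[predictor].to_numpy(dtype=float),
        "age": cohort["age"].to_numpy(dtype=float),
        "gender": (cohort["gender"] == "M").to_numpy(dtype=float)
        if cohort["gender"].dtype == object else cohort["gender"].to_numpy(float),
    }
    if volumetric:
        cols["total_brain_volume"] = cohort["total_brain_volume"].to_numpy(float)
    if diffusion_derived:
        cols["motion_index"] = cohort["motion_index"].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design matrix (rank {r} < "
                         f"{X.shape[1]}); collinear columns: {bad or names}")


def _ols_t(X: np.ndarray, y: np.ndarray, idx: int
           ) -> tuple[float, float, float, float, bool]:
    """OLS of y on X; returns (beta_idx, se, t, p, degenerate)."""
    n, p = X.shape
    XtXinv = np.linalg.inv(X.T @ X)
    beta = XtXinv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    scale = float(y @ y) or 1.0
    if rss <= 1e-12 * scale:
        # perfect fit: no residual variance; flag and report the smallest
        # representable p rather than dividing by zero
        return float(beta[idx]), 0.0, np.inf * np.sign(beta[idx]), _MIN_P, True
    sigma2 = rss / dof
    se = float(np.sqrt(sigma2 * XtXinv[idx, idx]))
    t = float(beta[idx] / se)
    pval = float(2.0 * sps.t.sf(abs(t), dof))
    return float(beta[idx]), se, t, max(pval, _MIN_P), False


def fit_glm(y: pd.Series | np.ndarray, cohort: pd.DataFrame, predictor: str,
            volumetric: bool = False, diffusion_derived: bool = False,
            feature: str = "", family_id: str = "") -> AssociationResult:
    """Covariate-adjusted OLS association of one feature with a predictor.

    Complete cases only (non-finite values of ``y`` are dropped). The
    reported t is ``beta / SE(beta)`` for the predictor with a two-tailed
    p from the t reference distribution; a perfect (zero-residual) fit is
    flagged degenerate with the minimum representable p.
    """
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != len(cohort):
        raise ValueError("y and cohort length mismatch")
    keep = np.isfinite(yv)
    X, names = design_matrix(cohort[keep], predictor, volumetric,
                             diffusion_derived)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"too few complete rows (n={n}) for {p} regressors")
    _check_rank(X, names)
    beta, se, t, pval, degen = _ols_t(X, yv[keep], idx=1)
    name = feature or (y.name if isinstance(y, pd.Series) and y.name else "y")
    return AssociationResult(feature=str(name), predictor=predictor, beta=beta,
                             se=se, t=t, p=pval, n=n, family_id=family_id,
                             degenerate=degen)


def _t_vector(X: np.ndarray, Y: np.ndarray, idx: int) -> np.ndarray:
    """Vectorised per-column t statistics of Y (n, F) on shared design X."""
    n, p = X.shape
    XtXinv = np.linalg.inv(X.T @ X)
    pinvX = XtXinv @ X.T
    beta = pinvX @ Y
    resid = Y - X @ beta
    rss = np.einsum("nf,nf->f", resid, resid)
    dof = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * XtXinv[idx, idx])
        t = np.where(se > 0, beta[idx] / se,
                     np.inf * np.sign(beta[idx]))
    return t


def permutation_correct(features: pd.DataFrame | np.ndarray,
                        cohort: pd.DataFrame, predictor: str,
                        B: int = 5000, seed: int = 0,
                        volumetric: bool = False,
                        diffusion_derived: bool = False,
                        family_id: str = "",
                        chunk: int = 200) -> list[AssociationResult]:
    """Freedman–Lane max-|t| permutation correction across one family.

    Residuals of the covariate-only (nuisance) model are permuted, added
    back to the nuisance fit, and the full model refit; the null
    distribution of the maximum |t| over the family gives
    ``p_corr = (1 + #{b : max|t|_b >= |t|_obs}) / (B + 1)`` per feature
    (then floored at the parametric p). Rows with any missing value in
    the family are dropped; all-NaN columns are excluded.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a usable null distribution")
    F = pd.DataFrame(features)
    F = F.loc[:, F.notna().any(axis=0)]
    if F.shape[1] == 0:
        raise ValueError("family is empty (all columns missing)")
    keep = np.isfinite(F.to_numpy(dtype=float)).all(axis=1)
    sub = cohort[keep] if keep.ndim == 1 else cohort
    Y = F.to_numpy(dtype=float)[keep]
    X, names = design_matrix(sub, predictor, volumetric, diffusion_derived)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"too few complete rows (n={n}) for permutation "
                         f"inference with {p} regressors")
    _check_rank(X, names)
    t_obs = _t_vector(X, Y, idx=1)

    Z = np.delete(X, 1, axis=1)                      # nuisance-only design
    pinvZ = np.linalg.pinv(Z)
    fitted = Z @ (pinvZ @ Y)
    E = Y - fitted
    rng = np.random.default_rng(seed)
    XtXinv = np.linalg.inv(X.T @ X)
    pinvX = XtXinv @ X.T
    c = XtXinv[1, 1]
    dof = n - p
    max_null = np.empty(B)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perm = np.stack([rng.permutation(n) for _ in range(b)])
        Ystar = fitted[None, :, :] + E[perm]         # (b, n, F)
        beta = np.einsum("pn,bnf->bpf", pinvX, Ystar)
        resid = Ystar - np.einsum("np,bpf->bnf", X, beta)
        rss = np.einsum("bnf,bnf->bf", resid, resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / dof * c)
            tb = np.where(se > 0, beta[:, 1, :] / se, np.inf)
        max_null[done:done + b] = np.max(np.abs(tb), axis=1)
        done += b

    results = []
    for j, col in enumerate(F.columns):
        beta, se, t, pval, degen = _ols_t(X, Y[:, j], idx=1)
        exceed = int(np.sum(max_null >= abs(t_obs[j]) - 1e-12))
        p_corr = (1 + exceed) / (B + 1)
        results.append(AssociationResult(
            feature=str(col), predictor=predictor, beta=beta, se=se, t=t,
            p=pval, n=n, family_id=family_id,
            p_corr=min(max(p_corr, pval), 1.0), degenerate=degen))
    return results


def binary_model(features: pd.DataFrame | np.ndarray, cohort: pd.DataFrame,
                 B: int | None = None, seed: int = 0,
                 volumetric: bool = False, diffusion_derived: bool = False,
                 family_id: str = "") -> list[AssociationResult]:
    """Carrier-vs-control contrast: the same GLM with the binary flag.

    With ``B`` set, family-wise correction is applied exactly as for the
    penetrance models.
    """
    if B is not None:
        return permutation_correct(features, cohort, "carrier", B=B, seed=seed,
                                   volumetric=volumetric,
                                   diffusion_derived=diffusion_derived,
                                   family_id=family_id)
    F = pd.DataFrame(features)
    return [fit_glm(F[c], cohort, "carrier", volumetric, diffusion_derived,
                    feature=str(c), family_id=family_id) for c in F.columns]


def loo_cnv_sensitivity(y: pd.Series | np.ndarray, cohort: pd.DataFrame,
                        predictor: str, volumetric: bool = False,
                        diffusion_derived: bool = False,
                        labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Leave-one-CNV-out sensitivity of one association.

    Refits the GLM with each CNV class's carriers excluded and reports
    the change in effect size (``delta_beta``, ``delta_t``) relative to
    the full fit. Omissions leaving too few rows are marked
    non-estimable. Large |delta_t| for one CNV indicates that variant
    drives the pooled effect.
    """
    full = fit_glm(y, cohort, predictor, volumetric, diffusion_derived)
    if labels is None:
        labels = sorted(set(cohort.loc[cohort["carrier"] == 1, "cnv_label"]))
    if len(set(cohort.loc[cohort["carrier"] == 1, "cnv_label"])) < 2:
        raise ValueError("need >= 2 CNV classes among carriers")
    yv = np.asarray(y, dtype=float)
    rows = []
    for label in labels:
        keep = (cohort["cnv_label"] != label).to_numpy()
        row = {"cnv_label": label, "n_omitted": int((~keep).sum()),
               "n_used": int(keep.sum())}
        try:
            fit = fit_glm(yv[keep], cohort[keep], predictor,
                          volumetric, diffusion_derived)
            row.update(beta=fit.beta, t=fit.t,
                       delta_beta=fit.beta - full.beta, delta_t=fit.t - full.t,
                       estimable=True)
        except ValueError:
            row.update(beta=np.nan, t=np.nan, delta_beta=np.nan,
                       delta_t=np.nan, estimable=False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cnv_label")


def global_pca_test(features: FeatureMatrix | pd.DataFrame,
                    cohort: pd.DataFrame,
                    n_components_tested: int | None = None,
                    predictors: Sequence[str] = ("P_Sz", "P_DD"),
                    B: int = 5000, seed: int = 0) -> GlobalPcaResult:
    """PCA of all (z-scored) imaging variables plus per-component tests.

    Constant columns are dropped (warning); remaining missing cells are
    mean-imputed (counted in ``imputed_cells``) for the decomposition
    only. Component scores are tested with the full covariate set (age,
    gender, TBV, motion — components mix volumetric and diffusion
    variables) and corrected across the tested components by max-|t|
    permutation. Defaults to testing ``min(n_subjects − 2, 34)``
    components.
    """
    X = features.data if isinstance(features, FeatureMatrix) else pd.DataFrame(features)
    def _is_constant(col: pd.Series) -> bool:
        v = col.to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        return v.size == 0 or float(np.std(v)) < 1e-12

    const = [c for c in X.columns if _is_constant(X[c])]
    if const:
        warnings.warn(f"dropping {len(const)} constant/empty columns before "
                      "global PCA", stacklevel=2)
        X = X.drop(columns=const)
    V = X.to_numpy(dtype=float)
    nan = ~np.isfinite(V)
    imputed = int(nan.sum())
    if imputed:
        mu = np.nanmean(V, axis=0)
        V = np.where(nan, mu[None, :], V)
    V = (V - V.mean(axis=0)) / V.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    rank = int(np.sum(S > 1e-10 * S[0]))
    evr = S**2 / np.sum(S**2)
    m_max = min(len(cohort) - 2, rank)
    m = m_max if n_components_tested is None else min(n_components_tested, m_max)
    # fixed sign convention: largest-|loading| element positive
    for j in range(m):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    comp_names = [f"PC{j + 1}" for j in range(m)]
    scores = pd.DataFrame(U[:, :m] * S[:m], index=X.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:m], index=comp_names, columns=X.columns)
    results = {
        pred: permutation_correct(scores, cohort, pred, B=B, seed=seed,
                                  volumetric=True, diffusion_derived=True,
                                  family_id="global_pca")
        for pred in predictors}
    return GlobalPcaResult(loadings=loadings, scores=scores,
                           explained_variance_ratio=evr[:m],
                           results=results, imputed_cells=imputed,
                           dropped_columns=const)


def cc_ratio_test(body_volume: pd.Series | np.ndarray,
                  splenium_volume: pd.Series | np.ndarray,
                  cohort: pd.DataFrame,
                  predictors: Sequence[str] = ("P_Sz", "P_DD"),
                  ) -> dict[str, AssociationResult]:
    """Post-hoc test of the corpus-callosum body / splenium volume ratio.

    The per-subject ratio is regressed on each penetrance score. Being
    dimensionless, the ratio keeps the motion covariate (tract volumes
    are diffusion-derived) but drops total brain volume.
    """
    body = np.asarray(body_volume, dtype=float)
    spl = np.asarray(splenium_volume, dtype=float)
    if np.any(spl[np.isfinite(spl)] <= 0):
        raise ValueError("splenium volume must be positive")
    ratio = body / spl
    return {pred: fit_glm(ratio, cohort, pred, volumetric=False,
                          diffusion_derived=True, feature="cc_body/cc_splenium")
            for pred in predictors}


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = len(rx)
    rx0 = rx - rx.mean()
    ry0 = ry - ry.mean()
    denom = np.sqrt((rx0 @ rx0) * (ry0 @ ry0))
    count = total = 0
    chunk: list[tuple] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = (rx0 @ ry0[np.array(chunk)].T) / denom
            count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = (rx0 @ ry0[np.array(chunk)].T) / denom
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)
    return count / total


def score_correlation(cohort: pd.DataFrame, subset: str = "all",
                      columns: tuple[str, str] = ("P_Sz", "P_DD"),
                      ) -> ScoreCorrelation:
    """Spearman rank correlation between the two penetrance scores.

    Average ranks are used for ties. The two-sided p is exact (full
    permutation enumeration) for n <= 10 and the t-approximation
    otherwise. ``subset`` selects ``"all"`` subjects or ``"carriers"``
    only; both are reported by the pipeline since either choice is
    defensible. A zero-variance score vector yields an undefined
    (flagged) result.
    """
    df = cohort if subset == "all" else cohort[cohort["carrier"] == 1]
    x = df[columns[0]].to_numpy(dtype=float)
    y = df[columns[1]].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        return ScoreCorrelation(rho=np.nan, p=np.nan, n=n,
                                method="undefined", defined=False)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        return ScoreCorrelation(rho=rho, p=_exact_spearman_p(rx, ry, rho),
                                n=n, method="exact-permutation")
    r2 = min(rho * rho, 1.0 - 1e-15)
    t = rho * np.sqrt((n - 2) / (1.0 - r2))
    return ScoreCorrelation(rho=rho, p=float(2.0 * sps.t.sf(abs(t), n - 2)),
                            n=n, method="t-approximation")
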