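"""Interaction linear mixed models for dosage-coded colony data.

Fits the model

    y = X beta + Z mu + epsilon

where ``y`` holds per-colony globin expression measurements, ``X`` contains
an intercept, ordinal edit-dosage variables and their pairwise products,
and ``Z`` holds random-intercept indicators for cell donors and for the
gRNA set delivered to each culture condition.  Variance components are
estimated by restricted maximum likelihood (REML) with the residual
variance profiled out; inference on fixed effects (the interaction
coefficients especially) uses t statistics with Satterthwaite-approximate
degrees of freedom.

The estimator is written for the moderate problem sizes of clonal colony
assays (tens to low thousands of colonies, a handful of variance
components) and uses dense linear algebra throughout, with the Woodbury
identity to keep per-evaluation cost at O(n q^2) for q random-intercept
levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSpec",
    "ModelSpec",
    "DesignMatrices",
    "LMMFit",
    "ConvergenceError",
    "build_design",
    "fit_reml",
    "satterthwaite_test",
    "interaction_profile",
]

#: gamma (variance ratio) below this is treated as a boundary zero.
_BOUNDARY_GAMMA = 1e-8


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class GroupSpec:
    """One random-intercept grouping factor.

    ``reference`` names a level that receives no indicator column (its
    rows are all-zero in this Z block), used for the unedited/control
    condition so that only gRNA-containing conditions carry a random
    intercept.
    """

    column: str
    reference: str | None = None


@dataclass
class ModelSpec:
    """Definition of one interaction mixed model.

    Parameters
    ----------
    response
        Column holding the expression measure to model.
    fixed_terms
        Dosage columns entering as main effects.
    interaction_pairs
        Pairs of fixed terms whose elementwise product enters as an
        interaction fixed effect.  Each member must appear in
        ``fixed_terms``.
    random_groups
        Random-intercept grouping factors (typically donor and
        guide-condition).
    transform
        ``"identity"`` or ``"log"`` applied to the response before
        fitting.
    """

    response: str
    fixed_terms: list[str]
    interaction_pairs: list[tuple[str, str]] = field(default_factory=list)
    random_groups: list[GroupSpec] = field(default_factory=list)
    transform: str = "identity"

    def __post_init__(self):
        for a, b in self.interaction_pairs:
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValueError(
                    f"interaction pair ({a}, {b}) not contained in fixed_terms"
                )
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class DesignMatrices:
    """Aligned response vector, fixed-effect and random-effect matrices."""

    y: np.ndarray                      # (n,)
    X: np.ndarray                      # (n, p)
    x_names: list[str]
    z_blocks: list[np.ndarray]         # one (n, q_g) indicator matrix per factor
    z_names: list[str]                 # grouping factor names
    z_levels: list[list[str]]          # column labels per block
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return sum(Z.shape[1] for Z in self.z_blocks)


@dataclass
class LMMFit:
    """REML fit: coefficients, variance components and inference."""

    beta: np.ndarray
    se: np.ndarray
    x_names: list[str]
    sigma2: dict[str, float]           # variance per grouping factor + "residual"
    reml_loglik: float
    df: np.ndarray                     # Satterthwaite df per coefficient
    pvalues: np.ndarray
    tvalues: np.ndarray
    conf_int: np.ndarray               # (p, 2) 95% CI
    cov_beta: np.ndarray               # (p, p)
    gamma: np.ndarray                  # fitted variance ratios per factor
    boundary: list[str]                # factors estimated at zero variance
    n: int
    n_iter: int
    converged: bool = True
    _dm: DesignMatrices | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "df": self.df,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
            },
            index=self.x_names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "estimate": float(b),
                    "se": float(s),
                    "df": float(d),
                    "t": float(t),
                    "p": float(p),
                    "ci95": [float(lo), float(hi)],
                }
                for name, b, s, d, t, p, (lo, hi) in zip(
                    self.x_names, self.beta, self.se, self.df,
                    self.tvalues, self.pvalues, self.conf_int,
                )
            },
            "variance_components": {k: float(v) for k, v in self.sigma2.items()},
            "reml_loglik": float(self.reml_loglik),
            "n": int(self.n),
            "boundary": list(self.boundary),
        }


def interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble y, X and Z from a merged colony table.

    Rows flagged for exclusion (boolean ``exclude_flag`` column) are
    dropped.  X columns are ordered intercept, main dosages (spec order),
    then interaction products; Z carries one indicator column per level
    of each grouping factor, omitting any declared reference level.
    """
    required = [spec.response, *spec.fixed_terms] + [g.column for g in spec.random_groups]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"colony table is missing required columns: {missing}")

    work = table
    n_dropped = 0
    if "exclude_flag" in work.columns:
        mask = work["exclude_flag"].fillna(False).astype(bool)
        n_dropped = int(mask.sum())
        work = work.loc[~mask]
    work = work.dropna(subset=[spec.response, *spec.fixed_terms])
    if work.empty:
        raise ValueError("no usable rows after exclusions")

    y = work[spec.response].to_numpy(dtype=float)
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response")
        y = np.log(y)

    n = len(work)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in spec.fixed_terms:
        v = work[term].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(
                f"dosage column {term!r} is constant; the design is rank deficient"
            )
        cols.append(v)
        names.append(term)
    for a, b in spec.interaction_pairs:
        cols.append(work[a].to_numpy(float) * work[b].to_numpy(float))
        names.append(interaction_name(a, b))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")

    z_blocks, z_names, z_levels = [], [], []
    for g in spec.random_groups:
        values = work[g.column].astype(str)
        levels = sorted(v for v in values.unique() if v != g.reference)
        Z = np.zeros((n, len(levels)))
        for j, lev in enumerate(levels):
            Z[:, j] = (values == lev).to_numpy(dtype=float)
        z_blocks.append(Z)
        z_names.append(g.column)
        z_levels.append(levels)

    return DesignMatrices(
        y=y, X=X, x_names=names, z_blocks=z_blocks, z_names=z_names,
        z_levels=z_levels, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# REML internals.  Parameterization: gamma_g = sigma_g^2 / sigma_e^2 >= 0,
# optimized on the log scale with the residual variance profiled out.
# With Gamma = blockdiag(gamma_g I_{q_g}) and S = Z Gamma^{1/2}:
#   W      = I + S S'          (V = sigma_e^2 W)
#   W^-1 B = B - S K^-1 S' B,  K = I_q + S'S   (stable as gamma -> 0)
#   log|W| = log|K|
# ---------------------------------------------------------------------------


def _profiled_reml(gamma: np.ndarray, dm: DesignMatrices):
    """Profiled -2 restricted log-likelihood (up to an additive constant).

    Returns (criterion, sigma_e^2, beta, XtWiX) at the given variance
    ratios.
    """
    n, p = dm.n, dm.p
    y, X = dm.y, dm.X
    if dm.q:
        S = np.hstack([
            np.sqrt(g) * Z for g, Z in zip(gamma, dm.z_blocks)
        ])
        K = np.eye(S.shape[1]) + S.T @ S
        cK, low = _chol(K)
        logdet_W = 2.0 * np.sum(np.log(np.diag(cK)))

        def w_inv(B):
            return B - S @ _chol_solve((cK, low), S.T @ B)
    else:
        logdet_W = 0.0

        def w_inv(B):
            return B

    Wi_X = w_inv(X)
    Wi_y = w_inv(y)
    XtWiX = X.T @ Wi_X
    XtWiy = X.T @ Wi_y
    cX, lowX = _chol(XtWiX)
    beta = _chol_solve((cX, lowX), XtWiy)
    logdet_XWX = 2.0 * np.sum(np.log(np.diag(cX)))
    quad = float(y @ Wi_y - XtWiy @ beta)
    quad = max(quad, 1e-300)
    sigma_e2 = quad / (n - p)
    crit = (n - p) * np.log(quad) + logdet_W + logdet_XWX
    return crit, sigma_e2, beta, XtWiX


def _chol(A: np.ndarray):
    from scipy.linalg import cho_factor

    # small jitter ladder for near-singular K / X'WiX
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("matrix not positive definite")


def _chol_solve(cf, b):
    from scipy.linalg import cho_solve

    return cho_solve(cf, b)


def _reml_constant(n: int, p: int) -> float:
    return -0.5 * (n - p) * (1.0 + np.log(2.0 * np.pi / (n - p)))


def fit_reml(dm: DesignMatrices, starts: tuple[float, ...] = (0.1, 1.0)) -> LMMFit:
    """Estimate the mixed model by REML.

    Variance ratios are optimized on the log scale from a fixed set of
    multi-start points; ratios driven below ``1e-8`` are profiled at the
    zero boundary and reported in ``boundary``.  The fit is deterministic
    given the data.
    """
    n, p = dm.n, dm.p
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    G = len(dm.z_blocks)
    trace: list[tuple[np.ndarray, float]] = []

    if G == 0:
        gamma = np.empty(0)
        crit, sigma_e2, beta, XtWiX = _profiled_reml(gamma, dm)
        n_iter = 0
    else:
        def objective(log_gamma):
            # clip to keep a flat/unidentifiable direction from overflowing
            gamma = np.exp(np.clip(log_gamma, -30.0, 30.0))
            val = _profiled_reml(gamma, dm)[0]
            trace.append((gamma, val))
            return val

        best = None
        for s in starts:
            x0 = np.full(G, np.log(s))
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise ConvergenceError("REML optimization failed", trace)
        gamma = np.exp(np.clip(best.x, -30.0, 30.0))
        # profile tiny components exactly at the boundary
        gamma = np.where(gamma < _BOUNDARY_GAMMA, 0.0, gamma)
        crit, sigma_e2, beta, XtWiX = _profiled_reml(gamma, dm)
        n_iter = int(best.nit)
        if not best.success and best.fun > min(v for _, v in trace) + 1e-6:
            raise ConvergenceError(
                f"REML optimizer did not converge: {best.message}", trace
            )

    boundary = [name for name, g in zip(dm.z_names, gamma) if g == 0.0]
    sigma2 = {name: float(g * sigma_e2) for name, g in zip(dm.z_names, gamma)}
    sigma2["residual"] = float(sigma_e2)

    cov_beta = sigma_e2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    reml_ll = -0.5 * (crit + (n - p) * (1.0 + np.log(2.0 * np.pi / (n - p))))

    fit = LMMFit(
        beta=beta, se=se, x_names=list(dm.x_names), sigma2=sigma2,
        reml_loglik=float(reml_ll), df=np.empty(p), pvalues=np.empty(p),
        tvalues=beta / se, conf_int=np.empty((p, 2)), cov_beta=cov_beta,
        gamma=gamma, boundary=boundary, n=n, n_iter=n_iter, _dm=dm,
    )
    _fill_satterthwaite(fit, dm)
    return fit


def _variance_derivative_terms(fit: LMMFit, dm: DesignMatrices):
    """Pieces shared by all Satterthwaite contrasts for one fit.

    Returns (C, dC_list, A) where C = Cov(beta-hat), dC_list holds the
    derivative of C with respect to each free variance component
    (non-boundary group variances first, residual last) and A is the
    asymptotic covariance of those components (inverse expected REML
    information).  Components estimated at the zero boundary are held
    fixed and excluded.
    """
    n = dm.n
    sigma_e2 = fit.sigma2["residual"]
    active = [i for i, g in enumerate(fit.gamma) if g > 0.0]

    # V and V^-1 (dense; n is moderate)
    V = sigma_e2 * np.eye(n)
    for i, Z in enumerate(dm.z_blocks):
        if fit.gamma[i] > 0.0:
            V += fit.sigma2[dm.z_names[i]] * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    X = dm.X
    ViX = Vi @ X
    XtViX_inv = np.linalg.inv(X.T @ ViX)
    P = Vi - ViX @ XtViX_inv @ ViX.T

    C = XtViX_inv  # = Cov(beta-hat)

    derivs: list[np.ndarray] = []   # dV/dsigma2_j as factored forms
    dC_list: list[np.ndarray] = []
    PG: list[np.ndarray] = []       # P @ dV_j  (n x n)
    for i in active:
        Z = dm.z_blocks[i]
        dV = Z @ Z.T
        derivs.append(dV)
        dC_list.append(ViX.T @ dV @ ViX)
        PG.append(P @ dV)
    derivs.append(np.eye(n))
    dC_list.append(ViX.T @ ViX)
    PG.append(P)

    # dC/ds_j = C (X' Vi dV_j Vi X) C
    dC_list = [C @ M @ C for M in dC_list]

    m = len(derivs)
    info = np.empty((m, m))
    for j in range(m):
        for k in range(j, m):
            info[j, k] = info[k, j] = 0.5 * np.sum(PG[j] * PG[k].T)
    try:
        A = np.linalg.inv(info)
        singular = False
    except np.linalg.LinAlgError:
        A = None
        singular = True
    return C, dC_list, A, singular


def satterthwaite_test(fit: LMMFit, dm: DesignMatrices, contrast: np.ndarray):
    """Satterthwaite df and two-sided p-value for the contrast c'beta.

    df = 2 [Var(c'beta-hat)]^2 / (g' A g) with g the gradient of the
    contrast variance in the variance components and A their asymptotic
    covariance.  With no random components this reduces exactly to the
    residual degrees of freedom n - p.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (dm.p,):
        raise ValueError(f"contrast must have length p={dm.p}")
    C, dC_list, A, singular = _variance_derivative_terms(fit, dm)
    var_c = float(c @ C @ c)
    if singular:
        warnings.warn(
            "singular variance-component information; falling back to "
            "residual degrees of freedom", RuntimeWarning,
        )
        df = float(dm.n - dm.p)
    else:
        g = np.array([float(c @ dC @ c) for dC in dC_list])
        denom = float(g @ A @ g)
        df = 2.0 * var_c**2 / denom if denom > 0 else float(dm.n - dm.p)
    t = float(c @ fit.beta) / np.sqrt(var_c)
    pval = 2.0 * stats.t.sf(abs(t), df)
    return df, pval


def _fill_satterthwaite(fit: LMMFit, dm: DesignMatrices) -> None:
    C, dC_list, A, singular = _variance_derivative_terms(fit, dm)
    p = dm.p
    df = np.empty(p)
    for j in range(p):
        var_c = C[j, j]
        if singular:
            df[j] = dm.n - p
        else:
            g = np.array([dC[j, j] for dC in dC_list])
            denom = float(g @ A @ g)
            df[j] = 2.0 * var_c**2 / denom if denom > 0 else dm.n - p
    if singular:
        warnings.warn(
            "singular variance-component information; using residual df",
            RuntimeWarning,
        )
    fit.df = df
    fit.pvalues = 2.0 * stats.t.sf(np.abs(fit.tvalues), df)
    tq = stats.t.ppf(0.975, df)
    fit.conf_int = np.column_stack([fit.beta - tq * fit.se, fit.beta + tq * fit.se])


def interaction_profile(
    fit: LMMFit,
    dm: DesignMatrices,
    grid: dict[str, list[float]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted means with CI bands over a grid of dosage combinations.

    The grid maps fixed-term names to the dosage values to evaluate;
    terms not in the grid are held at zero.  Predictions are
    x0' beta-hat; bands use the fixed-effect covariance with
    Satterthwaite df per point.  Values outside the observed dosage
    range trigger a warning.
    """
    term_cols = {name: j for j, name in enumerate(fit.x_names)}
    for term, values in grid.items():
        if term not in term_cols:
            raise KeyError(f"{term!r} is not a fixed effect of this model")
        j = term_cols[term]
        observed = dm.X[:, j]
        if min(values) < observed.min() or max(values) > observed.max():
            warnings.warn(
                f"grid for {term!r} extends beyond the observed dosage range "
                f"[{observed.min():g}, {observed.max():g}]", UserWarning,
            )

    terms = list(grid)
    meshes = np.meshgrid(*[np.asarray(grid[t], float) for t in terms], indexing="ij")
    combos = np.column_stack([m.ravel() for m in meshes])

    rows = []
    for combo in combos:
        x0 = np.zeros(dm.p)
        x0[0] = 1.0
        setting = dict(zip(terms, combo))
        for term, value in setting.items():
            x0[term_cols[term]] = value
        for name, j in term_cols.items():
            if ":" in name:
                a, b = name.split(":", 1)
                if a in setting and b in setting:
                    x0[j] = setting[a] * setting[b]
        pred = float(x0 @ fit.beta)
        se = float(np.sqrt(x0 @ fit.cov_beta @ x0))
        df, _ = satterthwaite_test(fit, dm, x0)
        tq = stats.t.ppf(0.5 + level / 2.0, df)
        rows.append(
            {**setting, "predicted": pred, "se": se,
             "ci_low": pred - tq * se, "ci_high": pred + tq * se}
        )
    return pd.DataFrame(rows)
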