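"""Per-gene REML variance-component estimation for the hierarchical model.

For one gene, the n-array vector of normalized log-ratios is modelled as

    y = X beta + sum_k Z_k u_k + e,        u_k ~ N(0, sigma2_k I),

with fixed effects X (intercept, sex, LPS) and one random term per
replication level: subject, day (nested in subject), the Subject:LPS and
Day:LPS interactions (acting only on stimulated arrays), stimulation tube,
amplification run and the residual (hybridisation and everything below
amplification).  The marginal covariance is

    V(theta) = sum_k theta_k Z_k Z_k' + theta_resid I,   theta_k >= 0,

and theta is estimated by maximizing the restricted likelihood

    -2 l_R(theta) = log|V| + log|X' V^-1 X| + y' P y   (+ const),

with P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.  The criterion and its
analytic gradient are coded explicitly and maximized by projected
quasi-Newton (L-BFGS-B) over the non-negative orthant, so components whose
optimum lies on the boundary are estimated at exactly zero.  Fixed effects
are the generalized-least-squares solution at the optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .design import COMPONENTS, DesignMatrixBundle
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VarCompFit",
    "RemlProblem",
    "fit_gene",
    "fit_all",
    "fits_frame",
    "subtraction_estimate",
    "lps_response_variance",
    "test_lps_effect",
]

#: Components summed for the biological / technical aggregates.
BIOLOGICAL = ("subject", "day")
TECHNICAL = ("stim", "amp", "residual")

_ZERO_TOL = 1e-8


@dataclass
class VarCompFit:
    """REML fit for one gene: variance components and fixed effects."""

    gene_id: str
    sigma2: dict[str, float]
    beta: dict[str, float]
    beta_se: dict[str, float]
    reml_loglik: float
    converged: bool
    boundary_components: set[str] = field(default_factory=set)
    unidentifiable: set[str] = field(default_factory=set)
    n_iter: int = 0

    def sd(self, component: str) -> float:
        return float(np.sqrt(self.sigma2[component]))


class RemlProblem:
    """Precomputed per-design structures shared by every gene's fit.

    Holds X and the Gram matrices G_k = Z_k Z_k' for the requested
    components (residual implicit as the identity), and evaluates the
    -2 restricted log-likelihood and its gradient at a variance vector.
    """

    def __init__(self, bundle: DesignMatrixBundle, components: Sequence[str] | None = None):
        if components is None:
            components = COMPONENTS
        unknown = set(components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if "residual" not in components:
            components = tuple(components) + ("residual",)
        # keep canonical order; drop unidentifiable (estimated as 0)
        self.components = tuple(c for c in COMPONENTS if c in set(components))
        self.free = tuple(
            c for c in self.components
            if c == "residual" or c not in bundle.unidentifiable
        )
        self.bundle = bundle
        self.X = bundle.X
        self.n, self.p = self.X.shape
        eye = np.eye(self.n)
        self.G = np.stack(
            [
                eye if c == "residual" else bundle.incidence(c) @ bundle.incidence(c).T
                for c in self.free
            ]
        )
        self.resid_idx = self.free.index("residual")

    def neg2reml(self, theta: np.ndarray, y: np.ndarray, *, gradient: bool = True):
        """-2 restricted log-likelihood (up to a constant) and its gradient."""
        theta = np.asarray(theta, dtype=float)
        V = np.tensordot(theta, self.G, axes=1)
        # guard: keep V positive definite even with all-zero theta
        jitter = max(1e-12, 1e-10 * max(theta.max(initial=0.0), 1e-6))
        V[np.diag_indices_from(V)] += jitter
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        XY = np.column_stack([self.X, y])
        S = linalg.cho_solve((c, low), XY, check_finite=False)
        VinvX, Vinvy = S[:, : self.p], S[:, self.p]
        W = self.X.T @ VinvX
        cw, low_w = linalg.cho_factor(W, lower=True, check_finite=False)
        logdet_w = 2.0 * np.sum(np.log(np.diag(cw)))
        Xty = self.X.T @ Vinvy
        beta = linalg.cho_solve((cw, low_w), Xty, check_finite=False)
        Py = Vinvy - VinvX @ beta
        quad = float(y @ Py)
        f = logdet_v + logdet_w + quad
        if not gradient:
            return f
        Vinv = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        B = linalg.cho_solve((cw, low_w), VinvX.T, check_finite=False)
        P = Vinv - VinvX @ B
        g = np.empty(len(theta))
        for k in range(len(theta)):
            Gk = self.G[k]
            g[k] = np.sum(P * Gk) - Py @ (Gk @ Py)
        return f, g

    def gls(self, theta: np.ndarray, y: np.ndarray):
        """GLS fixed effects and standard errors at a variance vector."""
        V = np.tensordot(theta, self.G, axes=1)
        V[np.diag_indices_from(V)] += max(1e-12, 1e-10 * max(theta.max(initial=0.0), 1e-6))
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        VinvX = linalg.cho_solve((c, low), self.X, check_finite=False)
        W = self.X.T @ VinvX
        Winv = np.linalg.inv(W)
        beta = Winv @ (VinvX.T @ y)
        se = np.sqrt(np.diag(Winv))
        return beta, se


def fit_gene(
    y: np.ndarray,
    bundle: DesignMatrixBundle,
    *,
    gene_id: str = "gene",
    components: Sequence[str] | None = None,
    problem: RemlProblem | None = None,
    max_iter: int = 200,
) -> VarCompFit:
    """REML-fit the variance components of one gene.

    Returns the maximizer of the restricted likelihood over the
    non-negative orthant; components the design cannot identify are fixed
    at 0 and flagged.  Convergence follows L-BFGS-B with a relative
    function tolerance of 1e-8 and projected-gradient tolerance 1e-6
    (scaled by the data variance); non-convergence returns best-so-far
    estimates with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    if problem is None:
        problem = RemlProblem(bundle, components)
    if y.shape != (problem.n,):
        raise ValueError(f"y has shape {y.shape}, expected ({problem.n},)")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    vy = float(np.var(y, ddof=1)) if problem.n > 1 else 0.0
    nfree = len(problem.free)
    if vy <= _ZERO_TOL * max(1.0, float(np.abs(y).max(initial=0.0))) ** 2:
        # degenerate: constant response
        beta = np.zeros(problem.p)
        beta[0] = float(y.mean()) if len(y) else 0.0
        sigma2 = {c: 0.0 for c in problem.components}
        return VarCompFit(
            gene_id=gene_id,
            sigma2=sigma2,
            beta=dict(zip(problem.bundle.fixed_names, beta)),
            beta_se={k: 0.0 for k in problem.bundle.fixed_names},
            reml_loglik=np.inf,
            converged=True,
            boundary_components=set(problem.components),
            unidentifiable=set(problem.components) & problem.bundle.unidentifiable,
        )

    x0 = np.full(nfree, vy / (nfree + 1))
    x0[problem.resid_idx] = vy / 2.0
    bounds = [(0.0, None)] * nfree
    scale = vy  # typical magnitude of theta, for tolerance scaling

    res = optimize.minimize(
        lambda t: problem.neg2reml(t, y),
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": max_iter,
            "ftol": 1e-8,
            "gtol": 1e-6 * max(scale, 1e-3),
        },
    )
    theta = np.clip(res.x, 0.0, None)
    snap = _ZERO_TOL * max(scale, 1e-12)
    theta[theta < snap] = 0.0

    beta, se = problem.gls(theta, y)
    sigma2 = {c: 0.0 for c in problem.components}
    for c, t in zip(problem.free, theta):
        sigma2[c] = float(t)
    boundary = {c for c in problem.free if sigma2[c] == 0.0}
    return VarCompFit(
        gene_id=gene_id,
        sigma2=sigma2,
        beta=dict(zip(problem.bundle.fixed_names, beta)),
        beta_se=dict(zip(problem.bundle.fixed_names, se)),
        reml_loglik=-0.5 * float(res.fun),
        converged=bool(res.success),
        boundary_components=boundary,
        unidentifiable=set(problem.components) & problem.bundle.unidentifiable,
        n_iter=int(res.nit),
    )


def fit_all(
    matrix: ExpressionMatrix | pd.DataFrame,
    bundle: DesignMatrixBundle,
    *,
    components: Sequence[str] | None = None,
    progress: bool = False,
) -> list[VarCompFit]:
    """Fit every retained gene independently; per-gene failures are logged.

    Accepts an :class:`ExpressionMatrix` (filtered view used) or a plain
    genes x arrays DataFrame whose columns match the bundle's arrays.
    """
    M = matrix.matrix() if isinstance(matrix, ExpressionMatrix) else matrix
    if list(M.columns) != list(bundle.array_ids):
        M = M.loc[:, bundle.array_ids]
    problem = RemlProblem(bundle, components)
    fits: list[VarCompFit] = []
    values = M.to_numpy()
    for i, gid in enumerate(M.index):
        try:
            fits.append(fit_gene(values[i], bundle, gene_id=str(gid), problem=problem))
        except Exception:  # pragma: no cover - defensive
            logger.exception("fit failed for gene %s", gid)
        if progress and (i + 1) % 500 == 0:
            logger.info("fitted %d/%d genes", i + 1, len(M.index))
    return fits


def fits_frame(fits: Sequence[VarCompFit]) -> pd.DataFrame:
    """Tabulate fits: sigma2/sd per component, fixed effects, convergence."""
    rows = []
    for f in fits:
        row: dict = {"gene_id": f.gene_id}
        for c in COMPONENTS:
            row[f"sigma2_{c}"] = f.sigma2.get(c, np.nan)
            row[f"sd_{c}"] = np.sqrt(f.sigma2.get(c, np.nan))
        for k, v in f.beta.items():
            row[f"beta_{k}"] = v
            row[f"se_{k}"] = f.beta_se.get(k, np.nan)
        row["reml_loglik"] = f.reml_loglik
        row["converged"] = f.converged
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Method-of-moments cross-checks and derived quantities
# ---------------------------------------------------------------------------

def subtraction_estimate(
    replicate_variances: Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """Peel per-level variances from cumulative replicate variances.

    ``replicate_variances`` maps levels, ordered from the innermost
    (hybridisation) outward, to the total variance observed between
    replicates at that level; each level's total is the sum of its own
    component and everything below it, so component_k = total_k -
    total_{k-1} (the innermost component equals its own total).  Negative
    differences are floored at zero; the floored amounts are returned
    alongside as a diagnostic.  This is the method-of-moments cross-check
    on the REML fit.
    """
    if not replicate_variances:
        raise ValueError("no levels supplied")
    levels = list(replicate_variances)
    components: dict[str, float] = {}
    floored: dict[str, float] = {}
    prev = 0.0
    for lvl in levels:
        tot = float(replicate_variances[lvl])
        if tot < 0:
            raise ValueError(f"negative total variance at level {lvl}")
        diff = tot - prev
        if diff < 0:
            floored[lvl] = -diff
            diff = 0.0
        components[lvl] = diff
        prev = tot
    return components, floored


def lps_response_variance(
    fit: VarCompFit, include: Iterable[str] | None = None
) -> float:
    """Variance of the per-gene LPS response: sum of selected components.

    The variance of M_LPS adds the variance of every included component
    (all 7 by default, including the residual).
    """
    if include is None:
        include = COMPONENTS
    include = tuple(include)
    unknown = set(include) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    return float(sum(fit.sigma2.get(c, 0.0) for c in include))


def test_lps_effect(fits: Sequence[VarCompFit], fdr: float = 0.05) -> pd.DataFrame:
    """Wald test of the per-gene LPS fixed effect with BH adjustment.

    Non-converged fits are excluded with a warning.  Returns a frame with
    the effect, its SE, z statistic, p, BH-adjusted p and a significance
    flag at the requested FDR.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    kept = [f for f in fits if f.converged]
    dropped = len(fits) - len(kept)
    if dropped:
        warnings.warn(f"excluding {dropped} non-converged fits from the LPS test")
    if not kept:
        return pd.DataFrame(
            columns=["gene_id", "lps_effect", "se", "z", "p", "p_adj", "significant"]
        )
    eff = np.array([f.beta.get("lps", np.nan) for f in kept])
    se = np.array([f.beta_se.get("lps", np.nan) for f in kept])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, eff / se, np.where(eff == 0, 0.0, np.inf * np.sign(eff)))
    p = 2.0 * stats.norm.sf(np.abs(z))
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in kept],
            "lps_effect": eff,
            "se": se,
            "z": z,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
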