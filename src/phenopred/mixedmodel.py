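"""Restricted maximum likelihood (REML) for linear mixed models.

Fits models of the form

    y = X beta + sum_u Z_u u_u + e,     u_u ~ N(0, sigma_u^2 K_u),
    e ~ N(0, sigma_e^2 I)

where every K_u is either the identity (classical design factors: rows,
columns, environments, G-by-E, ...) or a general covariance supplied through
its factor L_u with K_u = L_u L_u' (kinship / kernel BLUP).  Correlated terms
are whitened internally: Z_u L_u has iid effects, so a single engine covers
both the field-trial adjustment models and GBLUP / NIRS-BLUP.

The restricted likelihood is profiled over the residual variance and
maximised over the log variance ratios lambda_u = sigma_u^2 / sigma_e^2 with
a quasi-Newton method.  Each evaluation solves Henderson's mixed-model
equations; the coefficient matrix is factorised sparse (SuperLU) for large
crossed designs and dense (Cholesky) for small ones, and the restricted
log-likelihood is assembled from the standard determinant identities

    log|V| + log|X'V^-1 X| = (n - p) log sigma_e^2 + log|C|
                             + sum_u q_u log lambda_u

with C the ratio-form mixed-model coefficient matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import optimize

__all__ = ["RandomTerm", "REMLResult", "reml_fit", "indicator_matrix"]

_DENSE_LIMIT = 700  # MME dimension below which dense Cholesky wins
_ABSORB_REMAINDER_LIMIT = 1500  # max dense MME dimension after absorption
_LAMBDA_LOG_BOUNDS = (-23.0, 16.0)  # lambda in [1e-10, ~9e6]
_RESID_FLOOR = 1e-12


def indicator_matrix(labels: pd.Series | np.ndarray) -> tuple[sp.csr_matrix, list]:
    """0/1 incidence matrix of a categorical vector, with its level order."""
    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    n = len(codes)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return Z, list(levels)


@dataclass
class RandomTerm:
    """One random term: incidence ``Z`` and optional covariance factor ``L``."""

    name: str
    Z: sp.spmatrix
    levels: list = field(default_factory=list)
    L: np.ndarray | None = None  # K = L L'

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        Z, levels = indicator_matrix(labels)
        return cls(name, Z, levels)

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def design(self) -> sp.spmatrix:
        if self.L is None:
            return self.Z
        return sp.csr_matrix(self.Z @ self.L)


@dataclass
class REMLResult:
    varcomps: dict[str, float]  # per-term sigma^2 plus "residual"
    loglik: float
    beta: np.ndarray
    fixed_names: list[str]
    fixed_cov: np.ndarray  # sigma_e^2 * C^-1 fixed block
    blups: dict[str, np.ndarray]  # per-term effects on the original (L u) scale
    term_levels: dict[str, list]
    converged: bool
    n_iter: int
    message: str = ""

    def fixed_effect(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])


class _MMEWorkspace:
    """Precomputed cross-products; per-lambda factorisation of the MME.

    One identity-covariance random term may be *absorbed*: its contribution
    is folded into a block-diagonal residual structure
    ``H_R = I + lambda_a Z_a Z_a'`` whose blocks (the term's level groups)
    are inverted in closed form, so the explicit equations only carry the
    remaining terms.  Crossed field-trial models with a large G-by-E factor
    collapse from thousands of equations to a few hundred this way, with the
    restricted likelihood unchanged:

        log|V|/sigma_e^2 = log|H_R| + log|H~|,   H~ from the whitened data,

    and ``log|H_R| = sum_groups log(1 + s_g lambda_a)`` for group sizes s_g.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: sp.spmatrix,
        terms: list[RandomTerm],
        absorb: int | None = None,
    ):
        self.n = y.size
        self.p = X.shape[1]
        self.absorb = absorb
        self.terms = terms
        explicit = [t for u, t in enumerate(terms) if u != absorb]
        designs = [sp.csr_matrix(X)] + [t.design() for t in explicit]
        self.T = sp.hstack(designs, format="csc")
        self.dim = self.T.shape[1]
        self.TtT = (self.T.T @ self.T).tocsc()
        self.Tty = np.asarray(self.T.T @ y).ravel()
        self.yty = float(y @ y)
        self.q = [t.q for t in explicit]
        self.offsets = np.cumsum([self.p] + self.q)
        # dense factorisation also when correlated (whitened) terms make the
        # system dense anyway
        self.dense = (
            self.dim <= _DENSE_LIMIT
            or absorb is not None
            or any(t.L is not None for t in explicit)
        )
        if self.dense:
            self.TtT_dense = self.TtT.toarray()
        if absorb is not None:
            self._prepare_absorption(y, terms[absorb])

    def _prepare_absorption(self, y: np.ndarray, term: RandomTerm) -> None:
        Za = sp.csc_matrix(term.Z)
        sizes = np.asarray(Za.sum(axis=0)).ravel().astype(int)
        # per distinct group size: Gram matrix of group-aggregated rows
        P = np.asarray((Za.T @ self.T).todense())  # (q_a, dim) group sums
        qy = np.asarray(Za.T @ y).ravel()
        self._ab_sizes = sorted(set(sizes[sizes > 0]))
        self._ab_counts = {}
        self._ab_gram = {}
        self._ab_w = {}
        self._ab_qq = {}
        self._ab_groups = {}
        for s in self._ab_sizes:
            mask = sizes == s
            Ps = P[mask]
            self._ab_counts[s] = int(mask.sum())
            self._ab_gram[s] = Ps.T @ Ps
            self._ab_w[s] = Ps.T @ qy[mask]
            self._ab_qq[s] = float(qy[mask] @ qy[mask])
            self._ab_groups[s] = mask
        self._ab_P = P
        self._ab_qy = qy
        self._ab_sizes_vec = sizes

    def _ratio_diag(self, lam_explicit: np.ndarray) -> np.ndarray:
        d = np.zeros(self.dim)
        for u in range(len(self.q)):
            d[self.offsets[u] : self.offsets[u + 1]] = 1.0 / lam_explicit[u]
        return d

    def _split_lambda(self, lam: np.ndarray) -> tuple[np.ndarray, float | None]:
        if self.absorb is None:
            return lam, None
        mask = np.ones(len(lam), dtype=bool)
        mask[self.absorb] = False
        return lam[mask], float(lam[self.absorb])

    def factor(self, lam: np.ndarray):
        lam_explicit, lam_a = self._split_lambda(np.asarray(lam, dtype=float))
        d = self._ratio_diag(lam_explicit)
        logdet_hr = 0.0
        rhs = self.Tty
        ypy_base = self.yty
        if self.dense:
            C = self.TtT_dense + np.diag(d)
            if lam_a is not None:
                rhs = self.Tty.copy()
                for s in self._ab_sizes:
                    coef = lam_a / (1.0 + s * lam_a)
                    C -= coef * self._ab_gram[s]
                    rhs -= coef * self._ab_w[s]
                    ypy_base -= coef * self._ab_qq[s]
                    logdet_hr += self._ab_counts[s] * np.log1p(s * lam_a)
            try:
                from scipy.linalg import cho_factor

                cf = cho_factor(C, lower=True, check_finite=False)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError("singular mixed-model equations") from exc
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return ("dense", cf, logdet, logdet_hr, rhs, ypy_base, lam_a)
        C = self.TtT + sp.diags(d)
        lu = spla.splu(C.tocsc())
        diag_u = lu.U.diagonal()
        if np.any(np.abs(diag_u) < 1e-300):
            raise np.linalg.LinAlgError("singular mixed-model equations")
        logdet = float(np.sum(np.log(np.abs(diag_u))))
        return ("sparse", lu, logdet, logdet_hr, rhs, ypy_base, lam_a)

    def solve(self, factorisation, rhs: np.ndarray) -> np.ndarray:
        kind, fac = factorisation[0], factorisation[1]
        if kind == "dense":
            from scipy.linalg import cho_solve

            return cho_solve(fac, rhs, check_finite=False)
        return fac.solve(rhs)

    def solution(self, factorisation) -> tuple[np.ndarray, float]:
        """MME solution and y'Py at the factorisation's lambda."""
        rhs, ypy_base = factorisation[4], factorisation[5]
        theta = self.solve(factorisation, rhs)
        return theta, max(ypy_base - float(theta @ rhs), 0.0)

    def neg2_restricted_ll(self, log_lam: np.ndarray) -> float:
        fac = self.factor(np.exp(log_lam))
        theta, ypy = self.solution(fac)
        df = self.n - self.p
        sigma_e2 = max(ypy / df, _RESID_FLOOR)
        log_lam_explicit, _ = self._split_lambda(log_lam)
        return (
            df * (np.log(2 * np.pi * sigma_e2) + 1.0)
            + fac[2]
            + fac[3]
            + float(np.sum(np.array(self.q) * log_lam_explicit))
        )

    def absorbed_blup(self, factorisation, y: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """BLUP of the absorbed term: lambda_a * groupsum(resid)/(1+s*lambda_a)."""
        lam_a = factorisation[6]
        resid = y - np.asarray(self.T @ theta).ravel()
        Za = self.terms[self.absorb].Z
        q_hat = np.asarray(Za.T @ resid).ravel()
        return lam_a * q_hat / (1.0 + self._ab_sizes_vec * lam_a)


def _ols_fit(y: np.ndarray, X: sp.spmatrix, fixed_names: list[str]) -> REMLResult:
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X)
    n, p = Xd.shape
    XtX = Xd.T @ Xd
    try:
        cov_unscaled = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular fixed design") from exc
    beta = cov_unscaled @ (Xd.T @ y)
    resid = y - Xd @ beta
    df = max(n - p, 1)
    sigma_e2 = max(float(resid @ resid) / df, _RESID_FLOOR)
    ll = -0.5 * (df * (np.log(2 * np.pi * sigma_e2) + 1.0) + np.linalg.slogdet(XtX)[1])
    return REMLResult(
        varcomps={"residual": sigma_e2},
        loglik=ll,
        beta=beta,
        fixed_names=fixed_names,
        fixed_cov=sigma_e2 * cov_unscaled,
        blups={},
        term_levels={},
        converged=True,
        n_iter=0,
    )


def reml_fit(
    y: np.ndarray,
    X: sp.spmatrix | np.ndarray,
    random_terms: list[RandomTerm] | None = None,
    fixed_names: list[str] | None = None,
    start: dict[str, float] | None = None,
    fixed_ratios: dict[str, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> REMLResult:
    """Fit the mixed model by REML and solve the mixed-model equations.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (must be full column rank).
    random_terms
        Random terms; a term with ``L`` set has covariance ``L L'`` times its
        variance component.
    start
        Optional starting variance ratios (sigma_u^2 / sigma_e^2) per term.
    fixed_ratios
        Variance ratios to hold fixed instead of estimating (used for
        closed-form cross-checks and for fast per-wavelength refits).

    Returns
    -------
    REMLResult with variance components, BLUEs, BLUPs (on the original
    correlated scale for terms with ``L``), the scaled fixed-effect
    covariance, and convergence information.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = sp.csr_matrix(X)
    if X.shape[0] != y.size:
        raise ValueError("design and response not conformable")
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(X.shape[1])]
    random_terms = list(random_terms or [])
    for t in random_terms:
        if t.Z.shape[0] != y.size:
            raise ValueError(f"random term {t.name!r} not conformable with response")
    if not random_terms:
        return _ols_fit(y, X, fixed_names)

    # absorb the largest identity-covariance term when the crossed system is
    # otherwise too large for dense factorisation (typically G-by-E)
    total_dim = X.shape[1] + sum(t.q for t in random_terms)
    absorb = None
    if total_dim > _DENSE_LIMIT:
        candidates = [
            (t.q, u)
            for u, t in enumerate(random_terms)
            if t.L is None and total_dim - t.q <= _ABSORB_REMAINDER_LIMIT
        ]
        if candidates:
            q_a, absorb = max(candidates)
            sizes = np.asarray(sp.csc_matrix(random_terms[absorb].Z).sum(axis=0)).ravel()
            if len(set(sizes[sizes > 0])) > 30:
                absorb = None
    ws = _MMEWorkspace(y, X, random_terms, absorb=absorb)
    fixed_ratios = dict(fixed_ratios or {})
    free_ix = [u for u, t in enumerate(random_terms) if t.name not in fixed_ratios]
    lam_full = np.empty(len(random_terms))
    for u, t in enumerate(random_terms):
        if t.name in fixed_ratios:
            lam_full[u] = fixed_ratios[t.name]
        else:
            lam_full[u] = (start or {}).get(t.name, 0.5)

    converged = True
    n_iter = 0
    message = "all variance ratios fixed"
    if free_ix:
        def objective(x_free: np.ndarray) -> float:
            log_lam = np.log(lam_full)
            log_lam[free_ix] = x_free
            return ws.neg2_restricted_ll(log_lam)

        x0 = np.log(lam_full[free_ix])
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[_LAMBDA_LOG_BOUNDS] * len(free_ix),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        converged = bool(res.success)
        n_iter = int(res.nit)
        message = str(res.message)
        # derivative-free polish on small problems, where the cost is trivial
        # and finite-difference noise limits the quasi-Newton accuracy
        if ws.dim <= 200 and len(free_ix) <= 6:
            lo, hi = _LAMBDA_LOG_BOUNDS

            def clipped(x: np.ndarray) -> float:
                return objective(np.clip(x, lo, hi))

            res2 = optimize.minimize(
                clipped,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 1000},
            )
            if res2.fun <= res.fun:
                res = res2
                res.x = np.clip(res.x, lo, hi)
                converged = converged or bool(res2.success)
                message = str(res2.message) if res2.success else message
        lam_full[free_ix] = np.exp(res.x)
        if not converged:
            warnings.warn(
                f"REML did not converge after {n_iter} iterations: {message}",
                RuntimeWarning,
                stacklevel=2,
            )

    # final solve at the optimum
    fac = ws.factor(lam_full)
    theta, ypy = ws.solution(fac)
    df = ws.n - ws.p
    sigma_e2 = max(ypy / df, _RESID_FLOOR)
    lam_explicit, _ = ws._split_lambda(lam_full)
    loglik = -0.5 * (
        df * (np.log(2 * np.pi * sigma_e2) + 1.0)
        + fac[2]
        + fac[3]
        + float(np.sum(np.array(ws.q) * np.log(lam_explicit)))
    )

    varcomps = {"residual": sigma_e2}
    blups: dict[str, np.ndarray] = {}
    term_levels: dict[str, list] = {}
    lower_lam = np.exp(_LAMBDA_LOG_BOUNDS[0]) * 1.01
    explicit_pos = {u: k for k, u in enumerate(u for u in range(len(random_terms)) if u != absorb)}
    for u, t in enumerate(random_terms):
        sigma_u2 = lam_full[u] * sigma_e2
        if t.name not in fixed_ratios and lam_full[u] <= lower_lam:
            sigma_u2 = 0.0  # boundary estimate
        varcomps[t.name] = sigma_u2
        if u == absorb:
            blups[t.name] = ws.absorbed_blup(fac, y, theta)
        else:
            k = explicit_pos[u]
            u_tilde = theta[ws.offsets[k] : ws.offsets[k + 1]]
            blups[t.name] = t.L @ u_tilde if t.L is not None else u_tilde.copy()
        term_levels[t.name] = list(t.levels)

    # fixed-effect covariance: sigma_e^2 times the fixed block of C^-1
    rhs = np.zeros((ws.dim, ws.p))
    rhs[: ws.p, : ws.p] = np.eye(ws.p)
    cinv_fixed = ws.solve(fac, rhs)[: ws.p, :]
    fixed_cov = sigma_e2 * 0.5 * (cinv_fixed + cinv_fixed.T)

    return REMLResult(
        varcomps=varcomps,
        loglik=float(loglik),
        beta=theta[: ws.p].copy(),
        fixed_names=list(fixed_names),
        fixed_cov=fixed_cov,
        blups=blups,
        term_levels=term_levels,
        converged=converged,
        n_iter=n_iter,
        message=message,
    )
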