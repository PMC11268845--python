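"""Prediction models over SNP, NIRS or combined predictors.

Five model families share a fit/predict contract keyed by individual ids:

* ``fit_blup`` — linear mixed model with one or two correlated random
  effects (GBLUP on the additive genomic relationship matrix, NIRS-BLUP on
  the spectral relationship matrix, or the combined model with both);
* ``fit_bayesian_lasso`` — whole-genome/whole-spectrum regression with
  double-exponential shrinkage priors on the effects, Gibbs-sampled;
* ``fit_rkhs_ka`` — Bayesian multi-kernel regression over Gaussian kernels
  at several bandwidths; kernel averaging emerges from the per-kernel
  variance components;
* ``tune_and_fit_ml`` — random forest or epsilon-support-vector regression
  with model-based hyperparameter optimisation (space-filling initial design
  plus expected-improvement refinement).

Fixed effects are an intercept plus a one-hot indicator of the male-sterile
tester that mothers each hybrid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import KinshipMatrix
from .kinship import ensure_psd
from .mixedmodel import RandomTerm, REMLResult, reml_fit

__all__ = [
    "FixedDesign",
    "tester_design",
    "BlupModel",
    "fit_blup",
    "ChainSettings",
    "BayesianFit",
    "fit_bayesian_lasso",
    "fit_rkhs_ka",
    "MLModelSpec",
    "MLModel",
    "tune_and_fit_ml",
    "predict",
]


# ---------------------------------------------------------------------------
# fixed design


@dataclass
class FixedDesign:
    """Intercept + one-hot tester indicator, indexed by individual id."""

    table: pd.DataFrame  # rows: individuals; columns: intercept, tester dummies

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def rows(self, ids: list[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self.table.index]
        if missing:
            raise KeyError(f"individuals missing from fixed design: {missing[:5]}")
        return self.table.loc[ids].to_numpy(float)


def tester_design(testers: pd.Series) -> FixedDesign:
    """One-hot tester encoding with the first tester level as reference."""
    levels = sorted(testers.unique())
    tab = pd.DataFrame({"intercept": 1.0}, index=testers.index)
    for lev in levels[1:]:
        tab[f"tester:{lev}"] = (testers == lev).astype(float)
    return FixedDesign(tab)


def intercept_design(ids: list[str]) -> FixedDesign:
    return FixedDesign(pd.DataFrame({"intercept": 1.0}, index=list(ids)))


def _psd_factor(K: KinshipMatrix) -> np.ndarray:
    """Symmetric factor L with K = L L', tolerant of rank deficiency."""
    repaired = ensure_psd(K)
    w, V = np.linalg.eigh(repaired.values)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


# ---------------------------------------------------------------------------
# (NIRS-)G(BLUP)


@dataclass
class BlupModel:
    """Fitted kinship BLUP: variance components, BLUEs and per-id effects."""

    result: REMLResult
    fixed: FixedDesign
    ids: list[str]
    effects: pd.DataFrame  # per id, one column per random term
    trait: str = ""

    @property
    def varcomps(self) -> dict[str, float]:
        return self.result.varcomps

    def predict(self, ids: list[str]) -> np.ndarray:
        unknown = [i for i in ids if i not in self.effects.index]
        if unknown:
            raise KeyError(f"unknown individual id(s): {unknown[:5]}")
        Xb = self.fixed.rows(list(ids)) @ self.result.beta
        return Xb + self.effects.loc[list(ids)].sum(axis=1).to_numpy()


def fit_blup(
    y: pd.Series,
    fixed: FixedDesign,
    kinships: list[KinshipMatrix],
    fixed_ratios: dict[str, float] | None = None,
) -> BlupModel:
    """REML fit of the kinship BLUP with 1 (GBLUP / NIRS-BLUP) or 2 kernels.

    ``y`` is indexed by training ids; every kinship must cover the union of
    training and prediction individuals.  Unobserved individuals receive
    predictions through the kinship cross-block (their BLUPs are linear in
    the training BLUPs under the fitted covariance).
    """
    if not kinships:
        raise ValueError("at least one kinship matrix required")
    train_ids = list(y.index)
    all_ids = list(kinships[0].ids)
    for K in kinships:
        missing = set(train_ids) - set(K.ids)
        if missing:
            raise ValueError(f"kinship missing individuals: {sorted(missing)[:5]}")
        if list(K.ids) != all_ids:
            raise ValueError("all kinships must be over the same id set/order")
    pos = {i: k for k, i in enumerate(all_ids)}
    n = len(train_ids)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), [pos[i] for i in train_ids])), shape=(n, len(all_ids))
    )
    terms = []
    for K in kinships:
        name = {"additive-genomic": "additive", "nirs": "nirs"}.get(K.kind, K.kind)
        if any(t.name == name for t in terms):
            name = f"{name}{len(terms)}"
        terms.append(RandomTerm(name, Z, levels=all_ids, L=_psd_factor(K)))
    X = fixed.rows(train_ids)
    result = reml_fit(
        y.to_numpy(float), X, terms, fixed_names=fixed.names, fixed_ratios=fixed_ratios
    )
    effects = pd.DataFrame(
        {t.name: result.blups[t.name] for t in terms}, index=all_ids
    )
    return BlupModel(result=result, fixed=fixed, ids=all_ids, effects=effects, trait=str(y.name))


# ---------------------------------------------------------------------------
# Bayesian LASSO


@dataclass(frozen=True)
class ChainSettings:
    """Gibbs chain controls; defaults follow common whole-genome-regression
    practice (documented package choices)."""

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("chain must be longer than the burn-in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")


@dataclass
class BayesianFit:
    """Posterior summaries of a Gibbs-sampled regression."""

    beta: np.ndarray
    fixed_names: list[str]
    effects: dict[str, np.ndarray]  # block name -> posterior-mean effects
    blocks: dict[str, pd.DataFrame]  # block name -> feature rows per id
    fixed: FixedDesign
    settings: ChainSettings
    diagnostics: dict = field(default_factory=dict)
    trait: str = ""

    def predict(self, ids: list[str]) -> np.ndarray:
        out = self.fixed.rows(list(ids)) @ self.beta
        for name, eff in self.effects.items():
            out = out + self.blocks[name].loc[list(ids)].to_numpy(float) @ eff
        return out


def _sample_inverse_gaussian(rng: np.random.Generator, mu: np.ndarray, lam: float) -> np.ndarray:
    """Inverse-Gaussian draws (Michael-Schucany-Haas transformation)."""
    nu = rng.normal(size=mu.shape)
    y = nu * nu
    x = mu + (mu * mu * y) / (2 * lam) - (mu / (2 * lam)) * np.sqrt(
        4 * lam * mu * y + mu * mu * y * y
    )
    x = np.where(x <= 0, mu * 1e-12 + 1e-300, x)
    z = rng.random(size=mu.shape)
    return np.where(z <= mu / (mu + x), x, mu * mu / x)


def fit_bayesian_lasso(
    y: pd.Series,
    fixed: FixedDesign,
    marker_matrix: pd.DataFrame | None = None,
    spectra_matrix: pd.DataFrame | None = None,
    settings: ChainSettings = ChainSettings(),
    fix_sigma_e2: float | None = None,
    fix_lambda: float | None = None,
    prior: str = "laplace",
    normal_tau2: float = 1.0,
) -> BayesianFit:
    """Gibbs sampler for the Bayesian LASSO over markers and/or spectra.

    Flat priors on the fixed effects; conditionally normal effects with
    exponential mixing variances (the double-exponential / Laplace prior in
    its scale-mixture representation) on each predictor block, each block
    with its own shrinkage parameter lambda.  lambda^2 carries a Gamma
    hyperprior (shape 1.1; rate set from the block's predictor variance so
    the prior mean matches a heritability-0.5 split, a documented package
    default); the residual variance a scaled-inverse-chi-square prior
    (df 5).  ``fix_sigma_e2``/``fix_lambda`` pin those parameters, which is
    useful for closed-form cross-checks.

    ``prior="normal"`` replaces the Laplace prior by a fixed-variance normal
    prior (effect variance ``normal_tau2 * sigma_e^2``), under which the
    sampler targets the ridge/BLUP posterior — a cross-validation device for
    the sampler itself.
    """
    if prior not in ("laplace", "normal"):
        raise ValueError(f"unknown prior {prior!r}")
    rng = np.random.default_rng(settings.seed)
    train_ids = list(y.index)
    yv = y.to_numpy(float)
    n = yv.size
    X = fixed.rows(train_ids)
    XtX_inv = np.linalg.inv(X.T @ X)

    blocks: dict[str, pd.DataFrame] = {}
    if marker_matrix is not None:
        blocks["markers"] = marker_matrix
    if spectra_matrix is not None:
        blocks["spectra"] = spectra_matrix
    if not blocks:
        raise ValueError("supply a marker matrix, a spectra matrix, or both")
    Zs = {k: v.loc[train_ids].to_numpy(float) for k, v in blocks.items()}
    ztz = {k: np.einsum("ij,ij->j", Z, Z) for k, Z in Zs.items()}

    # state
    beta = XtX_inv @ (X.T @ yv)
    eff = {k: np.zeros(Z.shape[1]) for k, Z in Zs.items()}
    tau2 = {
        k: np.full(Z.shape[1], normal_tau2 if prior == "normal" else 1.0)
        for k, Z in Zs.items()
    }
    var_y = max(yv.var(), 1e-12)
    sigma_e2 = fix_sigma_e2 if fix_sigma_e2 is not None else var_y / 2.0
    lam2 = {}
    lam_shape = 1.1
    lam_rate = {}
    for k, Z in Zs.items():
        msx = max(float(np.sum(Z.var(axis=0))), 1e-12)
        lam0_sq = 2.0 * msx  # heritability-0.5 heuristic starting scale
        lam2[k] = fix_lambda**2 if fix_lambda is not None else lam0_sq
        lam_rate[k] = (lam_shape - 1.0) / lam0_sq if lam0_sq > 0 else 1.0
    df0, S0 = 5.0, var_y * 0.5 * (5.0 + 2.0)

    resid = yv - X @ beta
    keep = 0
    beta_sum = np.zeros_like(beta)
    eff_sum = {k: np.zeros_like(v) for k, v in eff.items()}
    lam_trace = []
    for it in range(settings.n_iter):
        # fixed effects (flat prior)
        resid = resid + X @ beta
        bhat = XtX_inv @ (X.T @ resid)
        beta = rng.multivariate_normal(bhat, sigma_e2 * XtX_inv)
        resid = resid - X @ beta
        # effects, one coordinate at a time
        for k, Z in Zs.items():
            a, t2, zz = eff[k], tau2[k], ztz[k]
            for j in range(Z.shape[1]):
                zj = Z[:, j]
                resid = resid + zj * a[j]
                prec = zz[j] + 1.0 / t2[j]
                mean = (zj @ resid) / prec
                a[j] = rng.normal(mean, np.sqrt(sigma_e2 / prec))
                resid = resid - zj * a[j]
            if prior == "normal":
                continue
            # mixing variances
            mu = np.sqrt(lam2[k] * sigma_e2 / np.maximum(a * a, 1e-300))
            inv_tau2 = _sample_inverse_gaussian(rng, mu, lam2[k])
            tau2[k] = 1.0 / np.maximum(inv_tau2, 1e-300)
            if fix_lambda is None:
                lam2[k] = rng.gamma(
                    Z.shape[1] + lam_shape, 1.0 / (np.sum(tau2[k]) / 2.0 + lam_rate[k])
                )
        if fix_sigma_e2 is None:
            sse = float(resid @ resid) + float(
                sum((eff[k] ** 2 / tau2[k]).sum() for k in Zs)
            )
            dof = n + sum(Z.shape[1] for Z in Zs.values()) + df0
            sigma_e2 = (sse + S0) / rng.chisquare(dof)
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep += 1
            beta_sum += beta
            for k in Zs:
                eff_sum[k] += eff[k]
            lam_trace.append({k: float(np.sqrt(lam2[k])) for k in Zs})
    return BayesianFit(
        beta=beta_sum / keep,
        fixed_names=fixed.names,
        effects={k: eff_sum[k] / keep for k in Zs},
        blocks=blocks,
        fixed=fixed,
        settings=settings,
        diagnostics={
            "n_samples": keep,
            "lambda_trace": lam_trace,
            "final_sigma_e2": float(sigma_e2),
        },
        trait=str(y.name),
    )


# ---------------------------------------------------------------------------
# RKHS kernel averaging


@dataclass
class RKHSFit:
    """Posterior summaries of the multi-kernel RKHS regression."""

    beta: np.ndarray
    fixed: FixedDesign
    train_ids: list[str]
    kernels: list[KinshipMatrix]
    u_mean: list[np.ndarray]  # posterior-mean kernel effects on training ids
    varcomps: dict[str, float]
    settings: ChainSettings
    trait: str = ""

    def predict(self, ids: list[str]) -> np.ndarray:
        out = self.fixed.rows(list(ids)) @ self.beta
        for K, u in zip(self.kernels, self.u_mean):
            Ktt = K.block(self.train_ids, self.train_ids)
            Kst = K.block(list(ids), self.train_ids)
            # conditional prior mean carries training effects to new ids;
            # training ids reproduce their own effects exactly
            out = out + Kst @ np.linalg.lstsq(Ktt, u, rcond=1e-10)[0]
        return out


def fit_rkhs_ka(
    y: pd.Series,
    fixed: FixedDesign,
    kernels: list[KinshipMatrix],
    settings: ChainSettings = ChainSettings(),
    fix_ratios: list[float] | None = None,
) -> RKHSFit:
    """Bayesian multi-kernel ("kernel averaging") regression.

    Each kernel contributes an independent random effect
    ``u_l ~ N(0, K_l sigma_l^2)``; the per-kernel variance components weight
    the kernels.  Sampling works in each kernel's eigenbasis, where the
    conditional posterior of the coordinates is independent normal.
    ``fix_ratios`` pins sigma_l^2/sigma_e^2 (closed-form cross-checks).
    """
    if not kernels:
        raise ValueError("empty kernel list")
    rng = np.random.default_rng(settings.seed)
    train_ids = list(y.index)
    yv = y.to_numpy(float)
    n = yv.size
    X = fixed.rows(train_ids)
    XtX_inv = np.linalg.inv(X.T @ X)
    eig = []
    for K in kernels:
        w, V = np.linalg.eigh(K.block(train_ids, train_ids))
        keep = w > max(1e-10, 1e-12 * w.max())
        eig.append((w[keep], V[:, keep]))
    var_y = max(yv.var(), 1e-12)
    L = len(kernels)
    df0 = 5.0
    S0_e = var_y * 0.5 * (df0 + 2.0)
    S0_u = var_y * 0.5 / L * (df0 + 2.0)
    sigma_e2 = var_y / 2.0
    sigma_u2 = [var_y / (2.0 * L)] * L

    beta = XtX_inv @ (X.T @ yv)
    b = [np.zeros(w.size) for w, _ in eig]
    u = [np.zeros(n) for _ in kernels]
    beta_sum = np.zeros_like(beta)
    u_sum = [np.zeros(n) for _ in kernels]
    vc_sum = np.zeros(L + 1)
    keep_count = 0
    for it in range(settings.n_iter):
        resid = yv - X @ beta - sum(u)
        for l, (w, V) in enumerate(eig):
            resid = resid + u[l]
            vt_r = V.T @ resid
            prec = 1.0 / sigma_e2 + 1.0 / (w * sigma_u2[l])
            mean = (vt_r / sigma_e2) / prec
            b[l] = mean + rng.normal(size=w.size) / np.sqrt(prec)
            u[l] = V @ b[l]
            resid = resid - u[l]
            if fix_ratios is None:
                scale = float(np.sum(b[l] ** 2 / w))
                sigma_u2[l] = (scale + S0_u) / rng.chisquare(w.size + df0)
        # fixed effects
        resid = resid + X @ beta
        bhat = XtX_inv @ (X.T @ resid)
        beta = rng.multivariate_normal(bhat, sigma_e2 * XtX_inv)
        resid = resid - X @ beta
        if fix_ratios is None:
            sigma_e2 = (float(resid @ resid) + S0_e) / rng.chisquare(n + df0)
        else:
            sigma_u2 = [r * sigma_e2 for r in fix_ratios]
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep_count += 1
            beta_sum += beta
            for l in range(L):
                u_sum[l] += u[l]
            vc_sum += np.array([sigma_e2, *sigma_u2])
    vc_mean = vc_sum / keep_count
    varcomps = {"residual": float(vc_mean[0])}
    for l, K in enumerate(kernels):
        tag = f"kernel{l + 1}" + (f"_h{K.bandwidth:g}" if K.bandwidth is not None else "")
        varcomps[tag] = float(vc_mean[l + 1])
    return RKHSFit(
        beta=beta_sum / keep_count,
        fixed=fixed,
        train_ids=train_ids,
        kernels=kernels,
        u_mean=[s / keep_count for s in u_sum],
        varcomps=varcomps,
        settings=settings,
        trait=str(y.name),
    )


# ---------------------------------------------------------------------------
# machine learning with model-based optimisation


@dataclass(frozen=True)
class MLModelSpec:
    """Learner + hyperparameter space + tuning budget.

    Random forest: ``mtry`` (features per split) between 100 and one third
    of the feature count (clamped for narrow matrices), ``min.node.size`` in
    [3, 15], 500 trees, out-of-bag MSE objective.  Support-vector
    regression: RBF kernel, ``C`` in (0, 2^10], ``epsilon`` in [0, 0.5],
    cross-validated RMSE objective.
    """

    learner: str = "random-forest"  # | "support-vector-regression"
    n_initial: int = 12
    n_sequential: int = 6
    n_trees: int = 500
    min_node_range: tuple[int, int] = (3, 15)
    c_range: tuple[float, float] = (1e-6, 2.0**10)
    epsilon_range: tuple[float, float] = (0.0, 0.5)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.learner not in ("random-forest", "support-vector-regression"):
            raise ValueError(f"unknown learner {self.learner!r}")

    def mtry_bounds(self, n_features: int) -> tuple[int, int]:
        hi = max(1, n_features // 3)
        lo = min(100, hi)
        return lo, hi


@dataclass
class MLModel:
    """Tuned learner plus the feature table used to address predictions."""

    estimator: object
    features: pd.DataFrame
    best_params: dict
    trace: pd.DataFrame
    spec: MLModelSpec
    trait: str = ""

    def predict(self, ids: list[str]) -> np.ndarray:
        unknown = [i for i in ids if i not in self.features.index]
        if unknown:
            raise KeyError(f"unknown individual id(s): {unknown[:5]}")
        return np.asarray(self.estimator.predict(self.features.loc[list(ids)].to_numpy(float)))


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm

    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def tune_and_fit_ml(
    y: pd.Series,
    features: pd.DataFrame,
    spec: MLModelSpec = MLModelSpec(),
    seed: int = 0,
) -> MLModel:
    """Model-based hyperparameter optimisation, then a final fit on all data.

    A space-filling (Latin hypercube) initial design of ``n_initial``
    configurations is evaluated, a Gaussian-process surrogate is fitted to
    the objective (out-of-bag MSE for the forest, cross-validated RMSE for
    the support-vector machine), and ``n_sequential`` further configurations
    are chosen by expected improvement.  Integer parameters are rounded;
    every evaluated configuration respects the declared bounds.
    """
    from scipy.stats import qmc
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern
    from sklearn.model_selection import KFold
    from sklearn.svm import SVR

    train_ids = list(y.index)
    Xf = features.loc[train_ids].to_numpy(float)
    yv = y.to_numpy(float)
    if yv.size < 30:
        raise ValueError("need at least 30 training observations for tuning")
    rng = np.random.default_rng(seed)

    if spec.learner == "random-forest":
        lo, hi = spec.mtry_bounds(Xf.shape[1])
        bounds = [(lo, hi), spec.min_node_range]

        def make(params):
            mtry = int(round(params[0]))
            node = int(round(params[1]))
            return (
                {"mtry": mtry, "min.node.size": node},
                RandomForestRegressor(
                    n_estimators=spec.n_trees,
                    max_features=min(mtry, Xf.shape[1]),
                    min_samples_leaf=node,
                    oob_score=True,
                    bootstrap=True,
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                ),
            )

        def objective(params) -> tuple[dict, float, object]:
            pd_, est = make(params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xf, yv)
            oob = est.oob_prediction_
            ok = ~np.isnan(oob)
            return pd_, float(np.mean((oob[ok] - yv[ok]) ** 2)), est

    else:
        bounds = [spec.c_range, spec.epsilon_range]
        kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        splits = list(kf.split(Xf))

        def make(params):
            C = float(np.clip(params[0], spec.c_range[0], spec.c_range[1]))
            eps = float(np.clip(params[1], *spec.epsilon_range))
            return {"C": C, "epsilon": eps}, SVR(kernel="rbf", C=C, epsilon=eps)

        def objective(params) -> tuple[dict, float, object]:
            pd_, est = make(params)
            sq = 0.0
            for tr, te in splits:
                est.fit(Xf[tr], yv[tr])
                pred = est.predict(Xf[te])
                sq += float(np.sum((pred - yv[te]) ** 2))
            return pd_, float(np.sqrt(sq / yv.size)), make(params)[1]

    lows = np.array([b[0] for b in bounds], float)
    highs = np.array([b[1] for b in bounds], float)
    sampler = qmc.LatinHypercube(d=len(bounds), seed=int(rng.integers(2**31)))
    design = lows + qmc.LatinHypercube.random(sampler, spec.n_initial) * (highs - lows)

    evaluated, scores, records = [], [], []
    for params in design:
        pd_, score, _ = objective(params)
        evaluated.append(params)
        scores.append(score)
        records.append({**pd_, "objective": score, "phase": "initial"})

    gp_kernel = ConstantKernel(1.0) * Matern(nu=2.5, length_scale=np.ones(len(bounds)))
    for _ in range(spec.n_sequential):
        Xn = (np.array(evaluated) - lows) / np.maximum(highs - lows, 1e-12)
        sc = np.array(scores)
        sc_n = (sc - sc.mean()) / max(sc.std(), 1e-12)
        gp = GaussianProcessRegressor(
            kernel=gp_kernel, normalize_y=False, alpha=1e-6, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xn, sc_n)
        cand = rng.random((256, len(bounds)))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, sc_n.min())
        best_cand = lows + cand[int(np.argmax(ei))] * (highs - lows)
        pd_, score, _ = objective(best_cand)
        evaluated.append(best_cand)
        scores.append(score)
        records.append({**pd_, "objective": score, "phase": "sequential"})

    best_ix = int(np.argmin(scores))
    best_params, _, est = objective(evaluated[best_ix])
    est.fit(Xf, yv)
    return MLModel(
        estimator=est,
        features=features,
        best_params=best_params,
        trace=pd.DataFrame.from_records(records),
        spec=spec,
        trait=str(y.name),
    )


def predict(model, ids: list[str]) -> np.ndarray:
    """Uniform prediction entry point: one value per requested individual."""
    return np.asarray(model.predict(list(ids)), dtype=float)
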