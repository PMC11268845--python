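"""Mixed-model adjustment of field-trial phenotypes and plot-level spectra.

Adjusted entry means (BLUEs, ``mu + g_i``) are computed per trait and per
NIRS wavelength from the plot table, with the genotype fixed and the field
design factors random.  The full adjustment model uses environment, row- and
column-within-environment, year, location and genotype-by-environment random
terms; the reduced model (single-location spectra, parental spectra) drops
environment, location and G-by-E and nests rows/columns within year.

Heritability is estimated on the entry-mean scale from the genotypic
variance of a genotype-random refit and the mean variance of pairwise BLUE
differences (Cullis-style H^2 for unbalanced trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import SpectraMatrix
from .mixedmodel import RandomTerm, REMLResult, _MMEWorkspace, indicator_matrix, reml_fit

__all__ = [
    "ModelSpec",
    "FULL_MODEL",
    "REDUCED_MODEL",
    "AdjustedMeans",
    "adjust_trait",
    "adjust_spectra",
    "fit_genotype_random",
    "estimate_heritability",
]

_KNOWN_TERMS = ("environment", "row", "col", "year", "location", "gxe")


@dataclass(frozen=True)
class ModelSpec:
    """Which design factors enter the adjustment model as random terms.

    ``genotype`` is always fixed when producing BLUEs.  Rows and columns are
    nested in the environment when the environment term is present, else in
    the year (reduced model).
    """

    random: tuple[str, ...] = _KNOWN_TERMS
    name: str = "full"

    def __post_init__(self) -> None:
        unknown = set(self.random) - set(_KNOWN_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")

    @property
    def nesting(self) -> str:
        return "environment" if "environment" in self.random else "year"


#: full adjustment model: environment, row/col within environment, year,
#: location and G-by-E random
FULL_MODEL = ModelSpec(random=_KNOWN_TERMS, name="full")
#: reduced model: no environment, location or G-by-E terms; rows/columns
#: nested within year
REDUCED_MODEL = ModelSpec(random=("row", "col", "year"), name="reduced")


@dataclass
class AdjustedMeans:
    """Adjusted entry means (mu + g_i) with uncertainty bookkeeping."""

    values: pd.Series  # per non-check genotype
    se: pd.Series
    v_delta_blue: float  # mean variance of pairwise BLUE differences
    varcomps: dict[str, float]
    trait: str = ""
    converged: bool = True


def _build_design(
    plots: pd.DataFrame, spec: ModelSpec
) -> tuple[sp.csr_matrix, list[str], list[str], list[RandomTerm]]:
    """Fixed design (intercept + genotype treatment contrasts) and random terms."""
    genos = sorted(plots["genotype"].unique())
    codes = plots["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    n = len(plots)
    # treatment contrasts: first genotype (sorted) is the reference, g = 0
    rows, cols, vals = [np.arange(n)], [np.zeros(n, dtype=int)], [np.ones(n)]
    nonref = codes > 0
    rows.append(np.arange(n)[nonref])
    cols.append(codes[nonref])  # column k holds genotype k (k >= 1)
    vals.append(np.ones(int(nonref.sum())))
    X = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, len(genos)),
    )
    fixed_names = ["intercept"] + [f"g:{g}" for g in genos[1:]]

    nest = plots[spec.nesting].astype(str)
    terms: list[RandomTerm] = []
    for name in spec.random:
        if name == "row":
            labels = nest + ":r" + plots["row"].astype(str)
        elif name == "col":
            labels = nest + ":c" + plots["col"].astype(str)
        elif name == "gxe":
            labels = plots["genotype"].astype(str) + ":" + plots["environment"].astype(str)
        else:
            labels = plots[name].astype(str)
        if labels.nunique() < 2:
            continue  # single-level factor carries no variance information
        terms.append(RandomTerm.from_labels(name, labels))
    return X, fixed_names, genos, terms


def _adjusted_from_result(
    result: REMLResult, genos: list[str], check_set: set[str]
) -> tuple[pd.Series, pd.Series]:
    mu = result.beta[0]
    vals, ses = {}, {}
    cov = result.fixed_cov
    for k, g in enumerate(genos):
        if g in check_set:
            continue
        if k == 0:
            vals[g] = mu
            ses[g] = np.sqrt(max(cov[0, 0], 0.0))
        else:
            vals[g] = mu + result.beta[k]
            v = cov[0, 0] + cov[k, k] + 2 * cov[0, k]
            ses[g] = np.sqrt(max(v, 0.0))
    return pd.Series(vals).sort_index(), pd.Series(ses).sort_index()


def _mean_pairwise_contrast_variance(
    result: REMLResult, genos: list[str], keep: list[str], max_exact: int = 1000
) -> float:
    """Mean of var(g_i^ - g_j^) over genotype pairs, from the BLUE covariance.

    The reference genotype has g = 0 with zero variance and covariance; its
    row/column of the contrast covariance is included.  Exact over all pairs
    up to ``max_exact`` genotypes, otherwise over 10,000 sampled pairs.
    """
    index = {g: k for k, g in enumerate(genos)}
    # covariance of the genotype-effect estimates, reference padded with zeros
    cols = [index[g] for g in keep]
    cov_full = np.zeros((len(genos), len(genos)))
    cov_full[1:, 1:] = result.fixed_cov[1:, 1:]
    C = cov_full[np.ix_(cols, cols)]
    m = len(keep)
    if m < 2:
        raise ValueError("need at least two genotypes for pairwise contrasts")
    d = np.diag(C)
    if m <= max_exact:
        # sum_{i<j}(C_ii + C_jj - 2 C_ij) = (m-1)*sum(d) - (sum(C) - sum(d))
        s = (m - 1) * d.sum() - (C.sum() - d.sum())
        return float(s / (m * (m - 1) / 2))
    rng = np.random.default_rng(12345)
    i = rng.integers(0, m, size=10000)
    j = rng.integers(0, m, size=10000)
    ok = i != j
    i, j = i[ok], j[ok]
    return float(np.mean(d[i] + d[j] - 2 * C[i, j]))


def adjust_trait(
    plots: pd.DataFrame, trait: str, spec: ModelSpec = FULL_MODEL
) -> AdjustedMeans:
    """Adjusted entry means for one trait from plot-level records.

    Check varieties take part in the fit (they sharpen the field-effect
    estimates) but are excluded from the returned mean set.  Plots with a
    missing trait value are dropped, so masked plots (e.g. waterlogged ones)
    are handled transparently as long as every genotype keeps >= 1 plot.
    """
    if trait not in plots.columns:
        raise KeyError(f"trait column {trait!r} not in plot table")
    data = plots.loc[plots[trait].notna()].reset_index(drop=True)
    if data.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    X, fixed_names, genos, terms = _build_design(data, spec)
    result = reml_fit(data[trait].to_numpy(float), X, terms, fixed_names=fixed_names)
    check_set = set(data.loc[data["is_check"], "genotype"]) if "is_check" in data else set()
    values, se = _adjusted_from_result(result, genos, check_set)
    keep = [g for g in genos if g not in check_set]
    vdb = _mean_pairwise_contrast_variance(result, genos, keep)
    return AdjustedMeans(
        values=values,
        se=se,
        v_delta_blue=vdb,
        varcomps=dict(result.varcomps),
        trait=trait,
        converged=result.converged,
    )


def fit_genotype_random(
    plots: pd.DataFrame, trait: str, spec: ModelSpec = FULL_MODEL
) -> REMLResult:
    """Refit the adjustment model with genotype random, for sigma_g^2."""
    data = plots.loc[plots[trait].notna()].reset_index(drop=True)
    _, _, _, terms = _build_design(data, spec)
    terms = [RandomTerm.from_labels("genotype", data["genotype"])] + terms
    X = sp.csr_matrix(np.ones((len(data), 1)))
    return reml_fit(data[trait].to_numpy(float), X, terms, fixed_names=["intercept"])


def estimate_heritability(sigma_g2: float, v_delta_blue: float) -> float:
    """Entry-mean heritability sigma_g^2 / (sigma_g^2 + vDeltaBLUE / 2)."""
    if sigma_g2 < 0 or v_delta_blue < 0:
        raise ValueError("variance inputs must be non-negative")
    if sigma_g2 == 0 and v_delta_blue == 0:
        raise ValueError("heritability undefined when both variances are zero")
    if sigma_g2 == 0:
        return 0.0
    if v_delta_blue == 0:
        return 1.0
    return float(np.clip(sigma_g2 / (sigma_g2 + v_delta_blue / 2.0), 0.0, 1.0))


def heritability_from_trial(plots: pd.DataFrame, trait: str, spec: ModelSpec = FULL_MODEL) -> float:
    """Convenience: Cullis H^2 from one plot table (two REML fits)."""
    am = adjust_trait(plots, trait, spec)
    rr = fit_genotype_random(plots, trait, spec)
    return estimate_heritability(rr.varcomps.get("genotype", 0.0), am.v_delta_blue)


def adjust_spectra(
    plot_spectra: SpectraMatrix,
    plots: pd.DataFrame,
    spec: ModelSpec = FULL_MODEL,
    mode: str = "exact",
    n_subset: int = 50,
) -> SpectraMatrix:
    """Per-wavelength adjusted entry means: one aggregated profile per genotype.

    The trait-adjustment model is fitted independently at every wavelength
    and ``mu + g_i`` extracted, aggregating the multiple plot-level profiles
    of each genotype across environments into a single adjusted profile.

    ``mode="exact"`` re-estimates the variance components at every
    wavelength.  ``mode="fast"`` estimates them on ``n_subset`` evenly spaced
    wavelengths, fixes the variance ratios at their medians, and solves the
    mixed-model equations once per wavelength against a single shared
    factorisation.  Technical replicates must already be averaged (one row
    per plot, ``meta['plot_id']`` unique).
    """
    if plot_spectra.meta is None or "plot_id" not in plot_spectra.meta:
        raise ValueError("plot spectra must carry plot_id metadata")
    if plot_spectra.meta["plot_id"].duplicated().any():
        raise ValueError("technical replicates must be averaged before adjustment")
    data = plots.set_index("plot_id").loc[plot_spectra.meta["plot_id"]].reset_index()
    X, fixed_names, genos, terms = _build_design(data, spec)
    check_set = set(data.loc[data["is_check"], "genotype"]) if "is_check" in data else set()
    keep = [g for g in genos if g not in check_set]
    Y = plot_spectra.values
    const_cols = np.where(Y.std(axis=0) == 0)[0]
    if const_cols.size:
        warnings.warn(
            f"{const_cols.size} constant wavelength column(s) returned as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.empty((len(keep), plot_spectra.n_wavelengths))
    geno_pos = {g: i for i, g in enumerate(genos)}

    if mode == "fast" and terms:
        sub = np.unique(
            np.linspace(0, plot_spectra.n_wavelengths - 1, min(n_subset, Y.shape[1])).astype(int)
        )
        sub = [j for j in sub if j not in const_cols] or [0]
        ratios: dict[str, list[float]] = {t.name: [] for t in terms}
        for j in sub:
            r = reml_fit(Y[:, j], X, terms, fixed_names=fixed_names)
            for t in terms:
                ratios[t.name].append(r.varcomps[t.name] / r.varcomps["residual"])
        fixed_ratios = {k: max(float(np.median(v)), 1e-10) for k, v in ratios.items()}
        ws = _MMEWorkspace(Y[:, 0], sp.csr_matrix(X), terms)
        fac = ws.factor(np.array([fixed_ratios[t.name] for t in terms]))
        Theta = ws.solve(fac, np.asarray(ws.T.T @ Y))
        betas = Theta[: len(genos), :]
        for i, g in enumerate(keep):
            k = geno_pos[g]
            out[i] = betas[0] + (betas[k] if k > 0 else 0.0)
    else:
        for j in range(plot_spectra.n_wavelengths):
            if j in const_cols:
                out[:, j] = Y[0, j]
                continue
            r = reml_fit(Y[:, j], X, terms, fixed_names=fixed_names)
            mu = r.beta[0]
            for i, g in enumerate(keep):
                k = geno_pos[g]
                out[i, j] = mu + (r.beta[k] if k > 0 else 0.0)
    if const_cols.size:
        for j in const_cols:
            out[:, j] = Y[0, j]
    return SpectraMatrix(
        keep,
        plot_spectra.wavelengths.copy(),
        out,
        meta=pd.DataFrame({"genotype": keep}),
    )
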