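"""Relationship and kernel matrices from genotypes and preprocessed spectra.

* marker quality control (missingness, biallelic, expected heterozygosity);
* the VanRaden additive genomic relationship matrix
  ``G = Z Z' / (2 sum p_i (1 - p_i))`` with allele-frequency-centred dosages;
* the spectral analogue ``G_NIRS = W W' / l`` on preprocessed profiles;
* Gaussian kernels ``K_h = exp(-h * D^2 / mean(D^2))`` at several bandwidths
  for RKHS kernel averaging;
* positive-semidefinite repair by escalating diagonal jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import GenotypeMatrix, KinshipMatrix, SpectraMatrix

__all__ = [
    "FilterReport",
    "filter_markers",
    "vanraden_grm",
    "nirs_relationship",
    "gaussian_kernels",
    "ensure_psd",
]

DEFAULT_BANDWIDTHS = (0.1, 0.5, 2.5)


@dataclass
class FilterReport:
    """Which markers each QC rule removed."""

    n_input: int
    removed_missing: list[str] = field(default_factory=list)
    removed_multiallelic: list[str] = field(default_factory=list)
    removed_low_het: list[str] = field(default_factory=list)
    n_imputed_entries: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - len(
            set(self.removed_missing) | set(self.removed_multiallelic) | set(self.removed_low_het)
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_missing": self.removed_missing,
            "removed_multiallelic": self.removed_multiallelic,
            "removed_low_het": self.removed_low_het,
            "n_imputed_entries": self.n_imputed_entries,
        }


def filter_markers(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.10,
    min_expected_het: float = 0.095,
    max_alleles: int = 2,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Marker QC: missingness, allele count and expected heterozygosity.

    Markers with more than ``max_missing`` missing calls, more than
    ``max_alleles`` observed dosage states beyond the biallelic 0/1/2 coding,
    or expected heterozygosity ``2 p (1 - p) < min_expected_het`` (boundary
    inclusive: exactly 0.095 is retained) are removed.  Remaining missing
    entries are imputed by the marker mean dosage.
    """
    D = genotypes.dosages
    n = D.shape[0]
    report = FilterReport(n_input=genotypes.m)
    missing = np.isnan(D)
    miss_rate = missing.mean(axis=0)
    # dosages outside {0,1,2} (beyond rounding tolerance) indicate extra alleles
    with np.errstate(invalid="ignore"):
        bad_code = ~np.isnan(D) & ~np.isclose(D % 1, 0) | (D > 2) | (D < 0)
    multiallelic = bad_code.any(axis=0) if max_alleles <= 2 else np.zeros(genotypes.m, bool)
    p = np.nanmean(np.where(missing, np.nan, D), axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        exp_het = 2.0 * p * (1.0 - p)
    low_het = ~(exp_het >= min_expected_het)  # NaN-frequency markers removed too

    drop_missing = miss_rate > max_missing
    markers = np.array(genotypes.markers)
    report.removed_missing = list(markers[drop_missing])
    report.removed_multiallelic = list(markers[multiallelic & ~drop_missing])
    report.removed_low_het = list(markers[low_het & ~drop_missing & ~multiallelic])
    keep = ~(drop_missing | multiallelic | low_het)
    if not keep.any():
        raise ValueError("all markers removed by quality filters")
    kept = D[:, keep].copy()
    col_mean = np.nanmean(kept, axis=0)
    nan_ix = np.where(np.isnan(kept))
    kept[nan_ix] = col_mean[nan_ix[1]]
    report.n_imputed_entries = int(len(nan_ix[0]))
    return GenotypeMatrix(list(genotypes.ids), list(markers[keep]), kept), report


def vanraden_grm(
    genotypes: GenotypeMatrix, allele_freqs: np.ndarray | None = None
) -> KinshipMatrix:
    """Additive genomic relationship matrix, VanRaden scaling.

    ``Z = dosage - 2 p_i`` per marker and ``G = Z Z' / (2 sum p_i (1-p_i))``.
    By default allele frequencies are computed from the supplied individuals
    (the union of training and test sets when one matrix serves both).
    """
    D = genotypes.dosages
    if np.isnan(D).any():
        raise ValueError("impute or filter missing dosages before building the GRM")
    p = np.asarray(allele_freqs, float) if allele_freqs is not None else D.mean(axis=0) / 2.0
    if p.shape != (genotypes.m,):
        raise ValueError("allele frequency vector does not match marker count")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fixed markers (p in {0,1}) must be filtered before the GRM")
    Z = D - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return KinshipMatrix(list(genotypes.ids), 0.5 * (G + G.T), kind="additive-genomic")


def nirs_relationship(W: SpectraMatrix) -> KinshipMatrix:
    """Spectral relationship matrix ``G_NIRS = W W' / l`` on preprocessed profiles."""
    l = W.n_wavelengths
    if l == 0:
        raise ValueError("no wavelengths in preprocessed spectra")
    G = (W.values @ W.values.T) / l
    return KinshipMatrix(list(W.sample_ids), 0.5 * (G + G.T), kind="nirs")


def gaussian_kernels(
    features: np.ndarray,
    ids: list[str],
    bandwidths: tuple[float, ...] = DEFAULT_BANDWIDTHS,
    normalise: bool = True,
) -> list[KinshipMatrix]:
    """Gaussian kernels over pairwise squared Euclidean distances.

    ``K_h = exp(-h * D^2)`` with ``D^2`` normalised by its mean off-diagonal
    value (so the bandwidth grid is meaningful regardless of feature count);
    set ``normalise=False`` for raw distances.  Diagonal is exactly 1.
    """
    features = np.asarray(features, float)
    if features.shape[0] != len(ids):
        raise ValueError("feature rows must match ids")
    if features.shape[0] < 2:
        raise ValueError("pairwise distances need at least two individuals")
    if any(h <= 0 for h in bandwidths):
        raise ValueError("bandwidths must be positive")
    d2 = squareform(pdist(features, metric="sqeuclidean"))
    if normalise:
        mean_off = d2.sum() / (d2.shape[0] * (d2.shape[0] - 1))
        if mean_off > 0:
            d2 = d2 / mean_off
    kernels = []
    for h in bandwidths:
        K = np.exp(-h * d2)
        np.fill_diagonal(K, 1.0)
        kernels.append(
            KinshipMatrix(list(ids), 0.5 * (K + K.T), kind="gaussian-kernel", bandwidth=float(h))
        )
    return kernels


def ensure_psd(K: KinshipMatrix, jitter: float = 1e-6, max_escalations: int = 6) -> KinshipMatrix:
    """Repair small negative eigenvalues by escalating diagonal jitter.

    Adds ``jitter * I`` and escalates tenfold until the smallest eigenvalue
    is >= -1e-8; raises if the matrix is still indefinite after
    ``max_escalations`` escalations.
    """
    vals = K.values
    w_min = float(np.linalg.eigvalsh(vals)[0])
    if w_min >= -1e-8:
        return K
    total = 0.0
    step = jitter
    for _ in range(max_escalations):
        total += step
        w_min_new = w_min + total
        if w_min_new >= -1e-8:
            return KinshipMatrix(
                list(K.ids),
                vals + total * np.eye(K.n),
                kind=K.kind,
                bandwidth=K.bandwidth,
                jitter_applied=total,
            )
        step *= 10.0
    raise ValueError(f"matrix not PSD after {max_escalations} jitter escalations")
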