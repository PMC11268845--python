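"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of data around: dosage matrices (individuals x
markers), reflectance/derivative spectra (samples x wavelengths), long-format
field-plot tables, and symmetric relationship/kernel matrices.  Each container
is a thin, validated wrapper over a numpy array plus identifier metadata;
heavy tabular work stays in pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SpectraMatrix",
    "KinshipMatrix",
    "EvaluationResult",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix.

    Dosages count copies of the alternate (B) allele: 0, 1, 2.  Missing
    entries are ``np.nan`` (float storage).  Rows are individuals, columns
    markers.
    """

    ids: list[str]
    markers: list[str]
    dosages: np.ndarray  # (n, m) float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.markers)} markers"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def row(self, individual: str) -> np.ndarray:
        return self.dosages[self.ids.index(individual)]

    def subset(self, individuals: list[str]) -> "GenotypeMatrix":
        idx = [self.ids.index(i) for i in individuals]
        return GenotypeMatrix(list(individuals), list(self.markers), self.dosages[idx])

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker B-allele frequency, ignoring missing entries."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def is_homozygous(self) -> bool:
        d = self.dosages[~np.isnan(self.dosages)]
        return bool(np.all((d == 0) | (d == 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.ids, columns=self.markers)


@dataclass
class SpectraMatrix:
    """Samples x wavelengths spectral matrix.

    ``sample_ids`` identify rows (plots, plot x technical replicate, or
    genotypes depending on the processing stage).  ``meta`` optionally carries
    plot / replicate bookkeeping aligned to the rows.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray  # (l,) nm, strictly increasing
    values: np.ndarray  # (n, l)
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError("spectra shape does not match ids x wavelengths")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths.size)

    def subset(self, sample_ids: list[str]) -> "SpectraMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return SpectraMatrix(list(sample_ids), self.wavelengths.copy(), self.values[idx], meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=[f"{w:g}" for w in self.wavelengths]
        )


@dataclass
class KinshipMatrix:
    """Symmetric individuals x individuals relationship or kernel matrix."""

    ids: list[str]
    values: np.ndarray  # (n, n)
    kind: str = "additive-genomic"  # | "nirs" | "gaussian-kernel"
    bandwidth: float | None = None
    jitter_applied: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, individuals: list[str]) -> "KinshipMatrix":
        idx = np.array([self.ids.index(i) for i in individuals])
        return KinshipMatrix(
            list(individuals),
            self.values[np.ix_(idx, idx)],
            kind=self.kind,
            bandwidth=self.bandwidth,
            jitter_applied=self.jitter_applied,
        )

    def block(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = np.array([self.ids.index(i) for i in rows])
        ci = np.array([self.ids.index(i) for i in cols])
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class EvaluationResult:
    """Cross-validation accuracies plus averaged predictions.

    ``accuracies`` is tidy: one row per (run, model, predictor_set, trait)
    with the Pearson r on the masked test split.  ``mean_predictions`` holds
    per-genotype predictions averaged over all runs in which the genotype was
    in the test set, used downstream for selection-accuracy classification.
    """

    accuracies: pd.DataFrame
    mean_predictions: pd.DataFrame
    selection: pd.DataFrame | None = None
    scheme: str = "random"

    def median_accuracy(self) -> pd.DataFrame:
        return (
            self.accuracies.groupby(["model", "predictor_set", "trait"], as_index=False)["r"]
            .median()
            .rename(columns={"r": "median_r"})
        )
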