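"""NIR spectra preprocessing: replicate averaging, Savitzky-Golay first
derivative, and column centring/scaling.

The derivative step removes additive baseline shifts (a constant offset has
zero derivative) and attenuates the smooth drift that instruments add at
higher wavelengths; centring/scaling puts every wavelength on a comparable
footing before relationship matrices or regressions are built on the
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import SpectraMatrix

__all__ = [
    "PreprocessParams",
    "average_technical_replicates",
    "savitzky_golay_derivative",
    "center_scale",
    "preprocess_spectra",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Savitzky-Golay and scaling settings.

    ``window`` is the filter length in data points (odd, default 37);
    ``polyorder`` the local polynomial degree (default 2, the lowest order
    that smooths while admitting a first derivative); the derivative order is
    fixed at 1.  ``scale`` toggles unit-sample-variance scaling after
    centring.
    """

    window: int = 37
    polyorder: int = 2
    scale: bool = True

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed the polynomial order")
        if self.polyorder < 1:
            raise ValueError("polynomial order must admit a first derivative")


def average_technical_replicates(spectra: SpectraMatrix) -> SpectraMatrix:
    """Arithmetic mean of technical replicates: one spectrum per plot.

    Requires ``meta['plot_id']``; the output records the replicate count per
    plot in its metadata.
    """
    if spectra.meta is None or "plot_id" not in spectra.meta:
        raise ValueError("spectra metadata must carry a plot_id column")
    meta = spectra.meta.reset_index(drop=True)
    groups = meta.groupby("plot_id", sort=True)
    plot_ids, values, counts, genos, envs = [], [], [], [], []
    for pid, idx in groups.indices.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"plot {pid} has zero replicates")
        plot_ids.append(str(pid))
        values.append(spectra.values[idx].mean(axis=0))
        counts.append(len(idx))
        genos.append(meta.loc[idx[0], "genotype"] if "genotype" in meta else None)
        envs.append(meta.loc[idx[0], "environment"] if "environment" in meta else None)
    out_meta = pd.DataFrame({"plot_id": plot_ids, "n_tech_reps": counts})
    if "genotype" in meta:
        out_meta["genotype"] = genos
    if "environment" in meta:
        out_meta["environment"] = envs
    return SpectraMatrix(plot_ids, spectra.wavelengths.copy(), np.array(values), out_meta)


def savitzky_golay_derivative(
    spectra: SpectraMatrix, params: PreprocessParams = PreprocessParams()
) -> SpectraMatrix:
    """Row-wise Savitzky-Golay first derivative with edge trimming.

    Each point is replaced by the derivative of a local least-squares
    polynomial of degree ``polyorder`` over a sliding window; the
    ``(window-1)/2`` points at each edge, where the window is incomplete, are
    dropped and the wavelength grid trimmed accordingly.  The derivative is
    per wavelength unit (the grid step).
    """
    w = params.window
    l = spectra.n_wavelengths
    if w > l:
        raise ValueError(f"window ({w}) exceeds wavelength count ({l})")
    step = float(np.diff(spectra.wavelengths).mean())
    if not np.allclose(np.diff(spectra.wavelengths), step):
        raise ValueError("Savitzky-Golay derivative requires a uniform wavelength grid")
    deriv = savgol_filter(
        spectra.values, window_length=w, polyorder=params.polyorder, deriv=1, delta=step, axis=1
    )
    half = (w - 1) // 2
    sl = slice(half, l - half)
    return SpectraMatrix(
        list(spectra.sample_ids),
        spectra.wavelengths[sl].copy(),
        deriv[:, sl],
        meta=spectra.meta.copy() if spectra.meta is not None else None,
    )


def center_scale(
    spectra: SpectraMatrix, scale: bool = True
) -> tuple[SpectraMatrix, list[float]]:
    """Centre every wavelength column to mean 0 and (optionally) sample sd 1.

    Constant columns cannot be scaled; they are dropped with a warning and
    their wavelengths returned for provenance.
    """
    if spectra.n < 2:
        raise ValueError("need at least two samples to centre and scale")
    V = spectra.values
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [float(w) for w in spectra.wavelengths[~keep]]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant wavelength column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    W = V[:, keep] - V[:, keep].mean(axis=0)
    if scale:
        W = W / sd[keep]
    return (
        SpectraMatrix(
            list(spectra.sample_ids),
            spectra.wavelengths[keep].copy(),
            W,
            meta=spectra.meta.copy() if spectra.meta is not None else None,
        ),
        dropped,
    )


def preprocess_spectra(
    adjusted: SpectraMatrix, params: PreprocessParams = PreprocessParams()
) -> tuple[SpectraMatrix, dict]:
    """Derivative + centre/scale; returns (W, provenance record)."""
    deriv = savitzky_golay_derivative(adjusted, params)
    W, dropped = center_scale(deriv, scale=params.scale)
    provenance = {
        "window": params.window,
        "polyorder": params.polyorder,
        "derivative": 1,
        "scaled": params.scale,
        "n_wavelengths_in": adjusted.n_wavelengths,
        "n_wavelengths_out": W.n_wavelengths,
        "dropped_constant_wavelengths": dropped,
    }
    return W, provenance
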