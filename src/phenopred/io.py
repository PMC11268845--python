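"""Readers and writers for the pipeline's file formats.

Plain-text formats throughout: TSV dosage matrices (rows = individuals,
header = marker ids), CSV plot/spectra/pedigree/results tables, TSV kinship
matrices, YAML configuration and JSON provenance.  Optionally reads VCF
(biallelic records; dosage = alternate-allele count) when ``cyvcf2`` is
installed.  Every writer round-trips losslessly with its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, KinshipMatrix, SpectraMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_spectra",
    "write_spectra",
    "read_plots",
    "write_plots",
    "read_pedigree",
    "write_pedigree",
    "read_kinship",
    "write_kinship",
    "read_config",
    "write_config",
    "write_provenance",
]

_MISSING = "NA"


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """TSV dosage matrix: first column ``id``, then one column per marker."""
    df = genotypes.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep=_MISSING, float_format="%.10g")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING])
    if df.index.name != "id":
        raise ValueError(f"malformed genotype header in {path}: first column must be 'id'")
    return GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def _read_genotypes_vcf(path: Path) -> tuple[GenotypeMatrix, int]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 extra") from exc
    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    markers, rows, skipped = [], [], 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1  # non-biallelic records are skipped, not guessed
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        markers.append(name)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (gts012), 3 unknown
        gt = np.array(variant.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    dosages = np.array(rows).T if rows else np.empty((len(ids), 0))
    return GenotypeMatrix(ids, markers, dosages), skipped


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a TSV dosage matrix or a VCF (by extension).

    Missing entries stay flagged as NaN — imputation is an explicit,
    downstream step.  Non-biallelic VCF records are skipped with a count
    recorded on the returned object (``.n_skipped_records``).
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        gm, skipped = _read_genotypes_vcf(path)
        gm.n_skipped_records = skipped  # type: ignore[attr-defined]
        return gm
    return _read_genotypes_tsv(path)


_SPECTRA_META_COLS = ("sample_id", "plot_id", "tech_rep", "genotype", "environment")


def write_spectra(spectra: SpectraMatrix, path: str | Path) -> None:
    """CSV: sample id, optional plot/replicate metadata, one column per wavelength."""
    meta = pd.DataFrame({"sample_id": spectra.sample_ids})
    if spectra.meta is not None:
        for col in _SPECTRA_META_COLS[1:]:
            if col in spectra.meta:
                meta[col] = spectra.meta[col].to_numpy()
    grid = pd.DataFrame(
        spectra.values, columns=[f"{w:g}" for w in spectra.wavelengths], index=meta.index
    )
    pd.concat([meta, grid], axis=1).to_csv(path, index=False, float_format="%.12g")


def read_spectra(path: str | Path, require_uniform_grid: bool = True) -> SpectraMatrix:
    """Read a spectra CSV; wavelength columns are the numeric headers.

    The parsed grid must be strictly increasing; with
    ``require_uniform_grid`` (default) a wavelength column missing mid-grid
    is a hard error.
    """
    df = pd.read_csv(path)
    meta_cols = [c for c in df.columns if c in _SPECTRA_META_COLS]
    wl_cols = [c for c in df.columns if c not in _SPECTRA_META_COLS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column in {path}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength header not strictly increasing")
    if require_uniform_grid and wavelengths.size > 2:
        steps = np.diff(wavelengths)
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength grid has a gap (missing column mid-grid)")
    meta = df[meta_cols].drop(columns=["sample_id"], errors="ignore")
    return SpectraMatrix(
        [str(s) for s in df["sample_id"]],
        wavelengths,
        df[wl_cols].to_numpy(float),
        meta=meta if not meta.empty else None,
    )


def write_plots(plots: pd.DataFrame, path: str | Path) -> None:
    plots.to_csv(path, index=False, float_format="%.12g")


def read_plots(path: str | Path, pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    """Plot table CSV; optionally validates genotypes against a pedigree."""
    plots = pd.read_csv(path)
    required = {"plot_id", "genotype", "environment"}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    if plots["plot_id"].duplicated().any():
        raise ValueError("duplicate plot ids")
    if "year" in plots:
        plots["year"] = plots["year"].astype(str)
    if pedigree is not None:
        known = set(pedigree["hybrid_id"])
        test_mask = ~plots["is_check"] if "is_check" in plots else pd.Series(True, index=plots.index)
        strange = set(plots.loc[test_mask, "genotype"]) - known
        if strange:
            raise ValueError(f"plot genotypes absent from pedigree: {sorted(strange)[:5]}")
    return plots


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    required = {"hybrid_id", "pollinator_id", "tester_id"}
    if required - set(ped.columns):
        raise ValueError("pedigree must have hybrid_id, pollinator_id, tester_id columns")
    if ped["hybrid_id"].duplicated().any():
        raise ValueError("duplicate hybrid ids in pedigree")
    return ped


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    df = K.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_kinship(path: str | Path, kind: str = "additive-genomic") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    return KinshipMatrix([str(i) for i in df.index], 0.5 * (vals + vals.T), kind=kind)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def write_provenance(record: dict, path: str | Path) -> None:
    """JSON provenance: parameters, seeds and library versions."""
    import scipy

    from . import __version__

    payload = {
        "phenopred_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        **record,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
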