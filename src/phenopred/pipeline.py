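"""End-to-end scenario orchestration: simulate -> adjust -> preprocess ->
kinship -> predict -> evaluate, with all intermediate artefacts written out.

Scenarios (the origin of the NIRS predictor data differs):

* ``within-generation`` — hybrid spectra adjusted across all environments;
* ``single-location`` — hybrid spectra from one location only, adjusted with
  the reduced model (no environment/location terms); phenotypes still
  adjusted across all environments;
* ``familywise`` — as within-generation but evaluated leaving one subfamily
  out at a time;
* ``across-generation`` — pollinator seed spectra, linked to the hybrids
  through the pedigree, predict hybrid performance; pollinator spectra are
  adjusted with the reduced model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .adjust import FULL_MODEL, REDUCED_MODEL, adjust_spectra, adjust_trait
from .containers import KinshipMatrix, SpectraMatrix
from .evaluate import CVScheme, run_cv, selection_accuracy
from .kinship import filter_markers, nirs_relationship, vanraden_grm
from .models import fit_blup, predict, tester_design
from .preprocess import PreprocessParams, average_technical_replicates, preprocess_spectra
from .simulate import SimulationConfig, simulate_field_trial, simulate_nirs, simulate_population

__all__ = ["RunConfig", "run_pipeline"]

SCENARIOS = ("within-generation", "single-location", "familywise", "across-generation")


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    scenario: str = "within-generation"
    seed: int = 0
    outdir: str | Path = "phenopred_run"
    simulation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    n_runs: int = 20
    train_fraction: float = 0.8
    trait: str = "seed_yield"
    selection_sizes: tuple[int, ...] = (80, 40)
    spectra_location: str | None = None  # single-location scenario
    spectra_mode: str = "fast"  # per-wavelength variance components: fast|exact

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.selection_sizes, list):
            cfg.selection_sizes = tuple(cfg.selection_sizes)
        return cfg


def _blup_fitters(fixed, kinships: dict[str, KinshipMatrix]):
    """Fit/predict closures for the BLUP family over each predictor set."""
    fitters = {}
    if "snp" in kinships:
        fitters[("GBLUP", "SNP")] = lambda y, test, K=kinships["snp"]: predict(
            fit_blup(y, fixed, [K]), test
        )
    if "nirs" in kinships:
        fitters[("NIRS-BLUP", "NIRS")] = lambda y, test, K=kinships["nirs"]: predict(
            fit_blup(y, fixed, [K]), test
        )
    if "snp" in kinships and "nirs" in kinships:
        fitters[("GBLUP+NIRS-BLUP", "SNP+NIRS")] = lambda y, test: predict(
            fit_blup(y, fixed, [kinships["snp"], kinships["nirs"]]), test
        )
    return fitters


def _pollinator_spectra(pop, config: SimulationConfig) -> SpectraMatrix:
    """Seed spectra of the pollinators grown in a small unreplicated trial."""
    sim = SimulationConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "environments": tuple(config.environments[:1]),
            "replicate_fraction": 0.0,
            "seed": config.seed + 1,
        }
    )
    gvals = pd.DataFrame(
        {t: pd.Series(0.0, index=pop["pollinators"].ids) for t in sorted(config.h2_targets)}
    )
    plots = simulate_field_trial(gvals, sim)
    spectra = simulate_nirs(pop["pollinators"], plots, sim)
    return spectra, plots


def run_pipeline(config: RunConfig) -> dict:
    """Execute one scenario end to end; returns the in-memory result bundle.

    Writes every intermediate artefact (pedigree, genotypes, plot table,
    adjusted means, preprocessed spectra, kinships, accuracies, selection
    outcomes) plus a provenance log into ``config.outdir``.
    """
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_params = dict(config.simulation)
    sim_params.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_params)
    pop = simulate_population(sim)
    pedigree, plots = pop["pedigree"], pop["plots"]
    hybrids = pop["hybrids"]

    pio.write_pedigree(pedigree, out / "pedigree.csv")
    pio.write_genotypes(hybrids, out / "hybrid_genotypes.tsv")
    pio.write_plots(plots, out / "plots.csv")

    # --- phenotype adjustment (always across all environments)
    adjusted = adjust_trait(plots, config.trait, FULL_MODEL)
    adj_df = pd.DataFrame(
        {"genotype": adjusted.values.index, "trait": config.trait, "value": adjusted.values.values,
         "se": adjusted.se.values}
    )
    adj_df.to_csv(out / "adjusted_means.csv", index=False)

    # --- spectra: scenario decides the source and the adjustment model
    if config.scenario == "across-generation":
        raw_spectra, pol_plots = _pollinator_spectra(pop, sim)
        spectra_model = REDUCED_MODEL
        spectra_plots = pol_plots
    elif config.scenario == "single-location":
        loc = config.spectra_location or plots["location"].iloc[0]
        if loc not in set(plots["location"]):
            raise ValueError(f"scenario/data mismatch: location {loc!r} not in trial")
        spectra_plots = plots.loc[plots["location"] == loc].reset_index(drop=True)
        raw_spectra = pop["spectra"]
        keep = raw_spectra.meta["plot_id"].isin(set(spectra_plots["plot_id"])).to_numpy()
        raw_spectra = SpectraMatrix(
            [s for s, k in zip(raw_spectra.sample_ids, keep) if k],
            raw_spectra.wavelengths.copy(),
            raw_spectra.values[keep],
            raw_spectra.meta.loc[keep].reset_index(drop=True),
        )
        spectra_model = REDUCED_MODEL
    else:
        raw_spectra = pop["spectra"]
        spectra_plots = plots
        spectra_model = FULL_MODEL

    averaged = average_technical_replicates(raw_spectra)
    adj_spectra = adjust_spectra(averaged, spectra_plots, spectra_model, mode=config.spectra_mode)
    W, prep_prov = preprocess_spectra(adj_spectra, PreprocessParams(**config.preprocess))
    pio.write_spectra(W, out / "preprocessed_spectra.csv")

    # --- kinships over the hybrid population
    filtered, filter_report = filter_markers(hybrids)
    G_snp = vanraden_grm(filtered)
    if config.scenario == "across-generation":
        # map each pollinator profile to its hybrids through the pedigree
        pol_of = pedigree.set_index("hybrid_id")["pollinator_id"]
        have = [h for h in hybrids.ids if pol_of[h] in W.sample_ids]
        rows = [W.sample_ids.index(pol_of[h]) for h in have]
        W_hyb = SpectraMatrix(have, W.wavelengths.copy(), W.values[rows])
    else:
        have = [h for h in hybrids.ids if h in W.sample_ids]
        rows = [W.sample_ids.index(h) for h in have]
        W_hyb = SpectraMatrix(have, W.wavelengths.copy(), W.values[rows])
    ids = [h for h in have if h in adjusted.values.index]
    G_snp = G_snp.subset(ids)
    G_nirs = nirs_relationship(W_hyb).subset(ids)
    pio.write_kinship(G_snp, out / "kinship_snp.tsv")
    pio.write_kinship(G_nirs, out / "kinship_nirs.tsv")

    # --- cross-validation
    testers = pedigree.set_index("hybrid_id")["tester_id"].loc[ids]
    fixed = tester_design(testers)
    fitters = _blup_fitters(fixed, {"snp": G_snp, "nirs": G_nirs})
    if config.scenario == "familywise":
        fam = pedigree.set_index("hybrid_id")["family_label"].loc[ids]
        scheme = CVScheme(kind="familywise", families=fam, seed=config.seed)
    else:
        scheme = CVScheme(
            kind="random",
            n_runs=config.n_runs,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
    result = run_cv(fitters, adjusted.values.loc[ids].rename(config.trait), scheme)
    result.accuracies.to_csv(out / "accuracies.csv", index=False)
    result.mean_predictions.to_csv(out / "mean_predictions.csv", index=False)

    # --- selection accuracy on run-averaged predictions
    sel_rows = []
    for (model, pset), grp in result.mean_predictions.groupby(["model", "predictor_set"]):
        preds = grp.set_index("genotype")["prediction"]
        for k in config.selection_sizes:
            kk = min(k, len(preds))
            oc = selection_accuracy(adjusted.values.loc[ids], preds, kk)
            sel_rows.append(
                {"model": model, "predictor_set": pset, "k": kk, "a": oc.a, "b": oc.b,
                 "c": oc.c, "d": oc.d, "cz": oc.cz}
            )
    selection = pd.DataFrame(sel_rows)
    selection.to_csv(out / "selection.csv", index=False)
    result.selection = selection

    pio.write_provenance(
        {
            "scenario": config.scenario,
            "seed": config.seed,
            "trait": config.trait,
            "simulation": sim_params,
            "spectra_model": spectra_model.name,
            "preprocess": prep_prov,
            "marker_filter": filter_report.to_dict(),
            "cv": {"kind": scheme.kind, "n_runs": len(result.accuracies["run"].unique())},
            "elapsed_seconds": round(time.time() - t_start, 2),
        },
        out / "provenance.json",
    )
    return {
        "population": pop,
        "adjusted": adjusted,
        "W": W,
        "kinships": {"snp": G_snp, "nirs": G_nirs},
        "evaluation": result,
        "selection": selection,
        "outdir": out,
    }
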