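"""Simulation of a structured test-hybrid breeding population.

Emulates the data-generating process behind a hybrid rapeseed trial series:

* 5 founder lines crossed to one common elite line give 5 subfamilies of
  fully inbred (doubled-haploid-like) pollinators;
* pollinators are crossed to 2 homozygous male-sterile testers, most to both
  testers, some to only one, producing F1 test hybrids;
* hybrids are evaluated in multi-environment, partially replicated field
  trials (p-rep with 1.2 replicates, replicated check varieties, row/column
  field effects, genotype-by-environment interaction);
* harvested seed of every plot is scanned by NIR spectroscopy in two
  technical replicates, with a genotype-driven smooth spectral signal,
  environment-specific smooth effects, baseline drift and noise.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SpectraMatrix

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "simulate_parent_genomes",
    "derive_pollinators",
    "make_crossing_design",
    "synthesize_hybrid_genotypes",
    "simulate_trait_architecture",
    "simulate_field_trial",
    "simulate_nirs",
    "simulate_population",
]

#: default environment labels: (location, year) pairs, 5 locations x 2 years
DEFAULT_ENVIRONMENTS: tuple[tuple[str, str], ...] = tuple(
    (loc, yr) for yr in ("2020", "2021") for loc in ("RHH", "HOH", "MOO", "ROS", "LAU")
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic breeding experiment.

    Defaults mirror the real experiment shape: 251 pollinators in 5
    subfamilies, 159 crossed to both testers and 46 to each single tester
    (410 hybrids), 6,200 markers, 1,820-point reflectance spectra on a 1-nm
    grid from 680 nm, partially replicated trials with 1.2 replicates and 3
    check varieties at 10 replications per environment.
    """

    n_markers: int = 6200
    n_wavelengths: int = 1820
    wavelength_start: float = 680.0
    wavelength_step: float = 1.0
    n_founders: int = 5
    family_sizes: tuple[int, ...] = (50, 50, 50, 50, 51)
    n_both: int = 159
    n_t1_only: int = 46
    n_t2_only: int = 46
    environments: tuple[tuple[str, str], ...] = DEFAULT_ENVIRONMENTS
    replicate_fraction: float = 0.2
    n_checks: int = 3
    check_reps: int = 10
    # trait architecture / trial variance components (per-trait scalars;
    # h2 targets are on the adjusted-entry-mean scale)
    h2_targets: dict = field(default_factory=lambda: {"seed_yield": 0.6})
    n_qtl: int = 200
    var_env: float = 1.0
    var_gxe: float = 0.25
    var_row: float = 0.1
    var_col: float = 0.1
    var_resid: float = 1.0
    # recombination
    n_blocks: int = 20
    # NIR spectra
    spectral_loading_rank: int = 10
    spectral_genetic_scale: float = 1.0
    spectral_env_sd: float = 0.01
    baseline_drift_amplitude: float = 0.01
    spectral_noise_sd: float = 0.002
    n_tech_reps: int = 2
    # optional random plot-drop mask (waterlogging-style exclusions)
    plot_drop_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if len(self.family_sizes) != self.n_founders:
            raise ValueError("family_sizes must have one entry per founder")
        if any(s < 0 for s in self.family_sizes):
            raise ValueError("family sizes must be non-negative")
        for name in ("var_env", "var_gxe", "var_row", "var_col", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for trait, h2 in self.h2_targets.items():
            if not (0 < h2 <= 1):
                raise ValueError(f"h2 target for {trait} must be in (0, 1]")
        if not (0 <= self.replicate_fraction <= 1):
            raise ValueError("replicate_fraction must be in [0, 1]")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength grid must be strictly increasing")
        if self.spectral_loading_rank > self.n_wavelengths:
            raise ValueError("spectral loading rank exceeds wavelength count")

    @property
    def n_pollinators(self) -> int:
        return int(sum(self.family_sizes))

    @property
    def n_hybrids(self) -> int:
        return 2 * self.n_both + self.n_t1_only + self.n_t2_only

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wavelength_start + self.wavelength_step * np.arange(self.n_wavelengths)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STAGES[stage])))


_STAGES = {
    "parents": 0,
    "pollinators": 1,
    "crossing": 2,
    "trait": 3,
    "trial": 4,
    "nirs": 5,
    "checks": 6,
}

def _founder_ids(config: SimulationConfig) -> list[str]:
    return [f"P{k + 1}" for k in range(config.n_founders)]


TESTER_IDS = ("M1", "M2")
ELITE_ID = "L1"


def simulate_parent_genomes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw fully homozygous parental genomes (founders, elite line, testers).

    Per-marker B-allele frequencies are Uniform(0.1, 0.9), bounded away from
    fixation so downstream expected-heterozygosity filtering is
    non-degenerate; each parent is homozygous at every marker (dosage 0 or 2).
    """
    rng = config.rng("parents")
    ids = _founder_ids(config) + [ELITE_ID, *TESTER_IDS]
    freqs = rng.uniform(0.1, 0.9, size=config.n_markers)
    dosages = 2.0 * (rng.random((len(ids), config.n_markers)) < freqs)
    markers = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    return GenotypeMatrix(ids, markers, dosages)


def derive_pollinators(
    parents: GenotypeMatrix, config: SimulationConfig
) -> tuple[GenotypeMatrix, pd.Series]:
    """Create inbred pollinator genomes as founder x elite recombinants.

    Each pollinator is a fully inbred offspring of (founder_k x elite): the
    genome is split into ``n_blocks`` contiguous marker blocks and each block
    is inherited intact from either parent with probability 1/2, mimicking a
    doubled haploid derived from the F1.  Family label = founder index.
    """
    founder_ids = _founder_ids(config)
    for pid in (*founder_ids, ELITE_ID):
        if pid not in parents.ids:
            raise ValueError(f"parent {pid} missing from parent genomes")
    rng = config.rng("pollinators")
    elite = parents.row(ELITE_ID)
    bounds = np.linspace(0, config.n_markers, min(config.n_blocks, config.n_markers) + 1)
    bounds = np.unique(bounds.astype(int))
    ids: list[str] = []
    labels: list[str] = []
    rows = []
    for k, founder_id in enumerate(founder_ids):
        founder = parents.row(founder_id)
        for j in range(config.family_sizes[k]):
            picks = rng.integers(0, 2, size=len(bounds) - 1)
            row = elite.copy()
            for b, pick in enumerate(picks):
                if pick == 1:
                    row[bounds[b] : bounds[b + 1]] = founder[bounds[b] : bounds[b + 1]]
            rows.append(row)
            ids.append(f"F{k + 1}_{j + 1:03d}")
            labels.append(f"FAM{k + 1}")
    geno = GenotypeMatrix(ids, list(parents.markers), np.array(rows))
    return geno, pd.Series(labels, index=ids, name="family")


def make_crossing_design(
    pollinator_ids: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Assign pollinators to testers and enumerate the resulting hybrids.

    ``n_both`` pollinators are crossed to both testers and ``n_t1_only`` /
    ``n_t2_only`` to a single tester, so the hybrid count is
    ``2*n_both + n_t1_only + n_t2_only`` (410 at the defaults).  Returns the
    pedigree: hybrid_id, pollinator_id, tester_id, family_label.
    """
    needed = config.n_both + config.n_t1_only + config.n_t2_only
    if needed > len(pollinator_ids):
        raise ValueError(
            f"crossing design needs {needed} pollinators, only {len(pollinator_ids)} available"
        )
    rng = config.rng("crossing")
    order = list(np.array(pollinator_ids)[rng.permutation(len(pollinator_ids))])
    both = order[: config.n_both]
    t1_only = order[config.n_both : config.n_both + config.n_t1_only]
    t2_only = order[config.n_both + config.n_t1_only : needed]
    records = []
    for pol in both:
        for tester in TESTER_IDS:
            records.append((pol, tester))
    records += [(pol, TESTER_IDS[0]) for pol in t1_only]
    records += [(pol, TESTER_IDS[1]) for pol in t2_only]
    # stable hybrid naming by (pollinator, tester)
    records.sort()
    ped = pd.DataFrame(records, columns=["pollinator_id", "tester_id"])
    ped.insert(0, "hybrid_id", ped["pollinator_id"] + "x" + ped["tester_id"])
    fam = ped["pollinator_id"].str.split("_").str[0].str.replace("F", "FAM", regex=False)
    ped["family_label"] = fam
    if ped["hybrid_id"].duplicated().any():
        raise ValueError("duplicate hybrid ids in pedigree")
    return ped


def synthesize_hybrid_genotypes(
    pollinators: GenotypeMatrix, testers: GenotypeMatrix, pedigree: pd.DataFrame
) -> GenotypeMatrix:
    """F1 genotypes of inbred x inbred crosses: dosage = parental mean.

    A hybrid is heterozygous exactly where its parents carry different
    homozygous dosages.  Raises if a parent is not fully homozygous.
    """
    for gm, role in ((pollinators, "pollinator"), (testers, "tester")):
        if not gm.is_homozygous():
            raise ValueError(f"heterozygous {role} encountered; parents must be inbred")
    pol_index = {i: k for k, i in enumerate(pollinators.ids)}
    tes_index = {i: k for k, i in enumerate(testers.ids)}
    rows = np.empty((len(pedigree), pollinators.m))
    ids = []
    for r, rec in enumerate(pedigree.itertuples(index=False)):
        if rec.pollinator_id not in pol_index or rec.tester_id not in tes_index:
            raise ValueError(f"pedigree parent missing: {rec.pollinator_id}/{rec.tester_id}")
        rows[r] = 0.5 * (
            pollinators.dosages[pol_index[rec.pollinator_id]]
            + testers.dosages[tes_index[rec.tester_id]]
        )
        ids.append(rec.hybrid_id)
    return GenotypeMatrix(ids, list(pollinators.markers), rows)


@dataclass
class TraitArchitecture:
    """Ground truth for one simulated trait."""

    trait: str
    genotypic_values: pd.Series  # per hybrid
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    target_h2: float
    genetic_variance: float


def _entry_mean_error_variance(config: SimulationConfig) -> float:
    """Expected error variance of an adjusted genotype mean under the design.

    Each genotype appears in every environment, replicated in a fraction
    ``replicate_fraction`` of them, so across ``E`` environments it averages
    over E G-by-E draws and ~E*(1+replicate_fraction) plot residuals (row and
    column effects behave like extra plot-level noise before adjustment).
    """
    n_env = len(config.environments)
    plots_per_geno = n_env * (1.0 + config.replicate_fraction)
    return config.var_gxe / n_env + (
        config.var_resid + config.var_row + config.var_col
    ) / plots_per_geno


def simulate_trait_architecture(
    genotypes: GenotypeMatrix, config: SimulationConfig, trait: str
) -> TraitArchitecture:
    """Draw additive QTL effects and scale genotypic values to the h2 target.

    ``n_qtl`` markers receive N(0,1) additive effects; genotypic values are
    centred and rescaled so that the heritability of an adjusted entry mean,
    sigma_g^2 / (sigma_g^2 + V_mean_error), matches ``h2_targets[trait]``
    given the configured trial variance components.
    """
    h2 = config.h2_targets[trait]
    # independent stream per trait
    trait_ix = sorted(config.h2_targets).index(trait)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, _STAGES["trait"], trait_ix))
    )
    n_qtl = min(config.n_qtl, genotypes.m)
    qtl = rng.choice(genotypes.m, size=n_qtl, replace=False)
    effects = rng.normal(size=n_qtl)
    g = genotypes.dosages[:, qtl] @ effects
    g = g - g.mean()
    current = g.var()
    v_err = _entry_mean_error_variance(config)
    if h2 == 1.0:
        # attainable only when the configured non-genetic variances vanish
        if v_err > 1e-12:
            raise ValueError("h2 = 1 is infeasible with non-zero error variances")
    else:
        target_var = h2 / (1.0 - h2) * v_err
        if current <= 0:
            if target_var > 0:
                raise ValueError("all genotypic values equal; cannot reach positive h2")
            scale = 0.0
        else:
            scale = math.sqrt(target_var / current)
        g = g * scale
        effects = effects * scale
    return TraitArchitecture(
        trait=trait,
        genotypic_values=pd.Series(g, index=genotypes.ids, name=trait),
        qtl_indices=qtl,
        qtl_effects=effects,
        target_h2=h2,
        genetic_variance=float(g.var()),
    )


def _check_ids(config: SimulationConfig) -> list[str]:
    return [f"CHK{j + 1}" for j in range(config.n_checks)]


def simulate_field_trial(
    genotypic_values: pd.DataFrame | pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate plot-level records of a partially replicated trial series.

    In every environment a fraction ``replicate_fraction`` of test genotypes
    is grown twice and the rest once; ``n_checks`` check varieties are grown
    ``check_reps`` times each.  Plots are laid out on a near-square row x
    column grid per environment.  Each plot value is the sum of the true
    genotypic value and environment, row, column, G-by-E and residual draws
    with the configured variances.

    Returns a long-format plot table: plot_id, genotype, environment,
    location, year, row, col, is_check, plus one column per trait.
    """
    if not config.environments:
        raise ValueError("environments must be non-empty")
    if isinstance(genotypic_values, pd.Series):
        genotypic_values = genotypic_values.to_frame()
    traits = list(genotypic_values.columns)
    test_ids = list(genotypic_values.index)
    rng = config.rng("trial")
    check_rng = config.rng("checks")
    checks = _check_ids(config)
    # checks carry their own fixed genotypic values, comparable in scale
    check_vals = pd.DataFrame(
        {
            t: check_rng.normal(
                scale=math.sqrt(max(genotypic_values[t].var(), 1e-12)), size=len(checks)
            )
            for t in traits
        },
        index=checks,
    )
    all_vals = pd.concat([genotypic_values, check_vals])

    env_labels = [f"{loc}.{yr}" for loc, yr in config.environments]
    records = []
    for (loc, yr), env in zip(config.environments, env_labels):
        n_rep = int(round(config.replicate_fraction * len(test_ids)))
        replicated = rng.choice(len(test_ids), size=n_rep, replace=False)
        plot_genos = list(test_ids)
        plot_genos += [test_ids[i] for i in replicated]
        for chk in checks:
            plot_genos += [chk] * config.check_reps
        n_plots = len(plot_genos)
        n_col = math.ceil(math.sqrt(n_plots))
        n_row = math.ceil(n_plots / n_col)
        positions = rng.permutation(n_row * n_col)[:n_plots]
        rows_ix = positions // n_col
        cols_ix = positions % n_col
        row_eff = {t: rng.normal(scale=math.sqrt(config.var_row), size=n_row) for t in traits}
        col_eff = {t: rng.normal(scale=math.sqrt(config.var_col), size=n_col) for t in traits}
        env_eff = {t: rng.normal(scale=math.sqrt(config.var_env)) for t in traits}
        gxe = {
            t: {g: rng.normal(scale=math.sqrt(config.var_gxe)) for g in all_vals.index}
            for t in traits
        }
        for p, geno in enumerate(plot_genos):
            rec = {
                "genotype": geno,
                "environment": env,
                "location": loc,
                "year": yr,
                "row": int(rows_ix[p]) + 1,
                "col": int(cols_ix[p]) + 1,
                "is_check": geno in checks,
            }
            for t in traits:
                rec[t] = (
                    all_vals.loc[geno, t]
                    + env_eff[t]
                    + row_eff[t][rows_ix[p]]
                    + col_eff[t][cols_ix[p]]
                    + gxe[t][geno]
                    + rng.normal(scale=math.sqrt(config.var_resid))
                )
            records.append(rec)
    plots = pd.DataFrame.from_records(records)
    plots.insert(0, "plot_id", [f"PL{j + 1:05d}" for j in range(len(plots))])
    if config.plot_drop_fraction > 0:
        keep = rng.random(len(plots)) >= config.plot_drop_fraction
        plots = plots.loc[keep].reset_index(drop=True)
    return plots


def _gaussian_bump_loadings(
    wavelengths: np.ndarray, rank: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth (Gaussian-bump) wavelength profiles, one per latent factor."""
    lo, hi = wavelengths[0], wavelengths[-1]
    span = hi - lo
    centres = rng.uniform(lo, hi, size=rank)
    widths = rng.uniform(0.03 * span, 0.15 * span, size=rank)
    amps = rng.normal(size=rank)
    return amps[:, None] * np.exp(
        -0.5 * ((wavelengths[None, :] - centres[:, None]) / widths[:, None]) ** 2
    )


def simulate_nirs(
    genotypes: GenotypeMatrix,
    plots: pd.DataFrame,
    config: SimulationConfig,
) -> SpectraMatrix:
    """Plot-level seed NIR reflectance spectra with technical replicates.

    Each spectrum is a sum of a shared base curve, a genotype-driven low-rank
    smooth signal (latent genetic factor scores, derived from the markers,
    loaded onto Gaussian-bump wavelength profiles), a smooth
    environment-specific effect, a per-measurement baseline drift increasing
    with wavelength, and independent noise.  Technical replicates of a plot
    share the genotype and environment signal and differ only in drift and
    noise.
    """
    rng = config.rng("nirs")
    wl = config.wavelengths
    rank = config.spectral_loading_rank
    loadings = _gaussian_bump_loadings(wl, rank, rng)  # (rank, l)
    # genetic factor scores: random linear functions of centred dosages
    M = genotypes.dosages - genotypes.dosages.mean(axis=0)
    proj = rng.normal(size=(genotypes.m, rank)) / math.sqrt(max(genotypes.m, 1))
    scores = config.spectral_genetic_scale * (M @ proj)  # (n_geno, rank)
    geno_signal = pd.DataFrame(scores @ loadings, index=genotypes.ids)
    # base curve: gentle reflectance profile common to all samples
    span = wl[-1] - wl[0] if wl.size > 1 else 1.0
    base = 0.4 + 0.1 * np.sin(2 * np.pi * (wl - wl[0]) / span)
    # smooth environment effects
    env_labels = list(dict.fromkeys(plots["environment"]))
    env_eff = {
        env: config.spectral_env_sd * _gaussian_bump_loadings(wl, 3, rng).sum(axis=0)
        for env in env_labels
    }
    # checks and any genotype without markers get a flat genetic signal
    zero = np.zeros(wl.size)
    ramp = (wl - wl[0]) / span

    ids: list[str] = []
    meta_rows = []
    values = np.empty((len(plots) * config.n_tech_reps, wl.size))
    r = 0
    for rec in plots.itertuples(index=False):
        gsig = geno_signal.loc[rec.genotype].to_numpy() if rec.genotype in geno_signal.index else zero
        plot_base = base + gsig + env_eff[rec.environment]
        for rep in range(config.n_tech_reps):
            drift = config.baseline_drift_amplitude * rng.random() * ramp
            noise = (
                rng.normal(scale=config.spectral_noise_sd, size=wl.size)
                if config.spectral_noise_sd > 0
                else 0.0
            )
            values[r] = plot_base + drift + noise
            ids.append(f"{rec.plot_id}.r{rep + 1}")
            meta_rows.append((rec.plot_id, rep + 1, rec.genotype, rec.environment))
            r += 1
    meta = pd.DataFrame(meta_rows, columns=["plot_id", "tech_rep", "genotype", "environment"])
    return SpectraMatrix(ids, wl, values, meta)


def simulate_population(config: SimulationConfig) -> dict:
    """End-to-end convenience wrapper returning every simulated artefact."""
    parents = simulate_parent_genomes(config)
    pollinators, families = derive_pollinators(parents, config)
    pedigree = make_crossing_design(pollinators.ids, config)
    testers = parents.subset(list(TESTER_IDS))
    hybrids = synthesize_hybrid_genotypes(pollinators, testers, pedigree)
    architectures = {
        t: simulate_trait_architecture(hybrids, config, t) for t in sorted(config.h2_targets)
    }
    gvals = pd.DataFrame({t: a.genotypic_values for t, a in architectures.items()})
    plots = simulate_field_trial(gvals, config)
    spectra = simulate_nirs(hybrids, plots, config)
    return {
        "config": config,
        "parents": parents,
        "pollinators": pollinators,
        "families": families,
        "pedigree": pedigree,
        "hybrids": hybrids,
        "architectures": architectures,
        "genotypic_values": gvals,
        "plots": plots,
        "spectra": spectra,
    }
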