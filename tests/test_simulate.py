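"""Generator tests: population structure, crossing design, trials, spectra."""

import numpy as np
import pandas as pd
import pytest

from phenopred.simulate import (
    SimulationConfig,
    derive_pollinators,
    make_crossing_design,
    simulate_field_trial,
    simulate_nirs,
    simulate_parent_genomes,
    simulate_population,
    simulate_trait_architecture,
    synthesize_hybrid_genotypes,
)

from conftest import tiny_config


class TestParentGenomes:
    def test_seeded_reproducibility(self):
        cfg = tiny_config(n_markers=100, seed=1)
        a = simulate_parent_genomes(cfg)
        b = simulate_parent_genomes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.ids == b.ids

    def test_parents_fully_homozygous(self):
        parents = simulate_parent_genomes(tiny_config())
        assert parents.is_homozygous()
        assert not np.any(parents.dosages == 1)

    def test_marker_count_matches_config(self):
        cfg = tiny_config(n_markers=6200)
        assert simulate_parent_genomes(cfg).m == 6200

    def test_rejects_nonpositive_marker_count(self):
        with pytest.raises(ValueError):
            tiny_config(n_markers=0)


class TestPollinators:
    def test_no_segregation_at_monomorphic_loci(self):
        cfg = tiny_config()
        parents = simulate_parent_genomes(cfg)
        pol, fam = derive_pollinators(parents, cfg)
        # loci where every founder equals the elite line: all offspring share it
        elite = parents.row("L1")
        for k in range(cfg.n_founders):
            same = parents.row(f"P{k + 1}") == elite
            fam_rows = pol.dosages[fam.values == f"FAM{k + 1}"]
            assert np.all(fam_rows[:, same] == elite[same])

    def test_family_sizes(self):
        cfg = tiny_config(family_sizes=(50, 50, 50, 50, 51), n_both=159, n_t1_only=46, n_t2_only=46)
        parents = simulate_parent_genomes(cfg)
        pol, fam = derive_pollinators(parents, cfg)
        assert pol.n == 251
        assert fam.value_counts().sort_index().tolist() == [50, 50, 50, 50, 51]

    def test_single_block_offspring_equal_one_parent(self):
        cfg = tiny_config(n_blocks=1)
        parents = simulate_parent_genomes(cfg)
        pol, fam = derive_pollinators(parents, cfg)
        elite = parents.row("L1")
        for i, pid in enumerate(pol.ids):
            founder = parents.row("P" + fam.iloc[i].removeprefix("FAM"))
            row = pol.dosages[i]
            assert np.array_equal(row, founder) or np.array_equal(row, elite)

    def test_pollinators_homozygous(self, tiny_population):
        assert tiny_population["pollinators"].is_homozygous()


class TestCrossingDesign:
    def test_default_counts_give_410_hybrids(self):
        cfg = SimulationConfig()
        ids = [f"F1_{i:03d}" for i in range(cfg.n_pollinators)]
        ped = make_crossing_design(ids, cfg)
        assert len(ped) == 410
        assert ped["hybrid_id"].is_unique

    def test_single_cross(self):
        cfg = tiny_config(n_both=0, n_t1_only=1, n_t2_only=0, family_sizes=(1, 0, 0, 0, 0))
        ped = make_crossing_design(["F1_001"], cfg)
        assert len(ped) == 1

    def test_two_double_crosses(self):
        cfg = tiny_config(n_both=2, n_t1_only=0, n_t2_only=0, family_sizes=(2, 0, 0, 0, 0))
        ped = make_crossing_design(["F1_001", "F1_002"], cfg)
        assert len(ped) == 4
        assert ped["tester_id"].value_counts().tolist() == [2, 2]

    def test_each_pollinator_has_at_most_two_testers(self, tiny_population):
        ped = tiny_population["pedigree"]
        per_pol = ped.groupby("pollinator_id")["tester_id"].nunique()
        assert per_pol.isin([1, 2]).all()

    def test_counts_exceeding_pollinators_raise(self):
        cfg = tiny_config(n_both=5, n_t1_only=0, n_t2_only=0)
        with pytest.raises(ValueError):
            make_crossing_design(["F1_001"], cfg)


class TestHybridGenotypes:
    def test_f1_dosage_rules(self, tiny_population):
        pol = tiny_population["pollinators"]
        parents = tiny_population["parents"]
        ped = tiny_population["pedigree"]
        hyb = tiny_population["hybrids"]
        rec = ped.iloc[0]
        expected = 0.5 * (pol.row(rec.pollinator_id) + parents.row(rec.tester_id))
        np.testing.assert_array_equal(hyb.row(rec.hybrid_id), expected)

    def test_heterozygosity_equals_half_parental_hamming(self, tiny_population):
        pol = tiny_population["pollinators"]
        parents = tiny_population["parents"]
        ped = tiny_population["pedigree"]
        hyb = tiny_population["hybrids"]
        for rec in ped.head(10).itertuples(index=False):
            h = hyb.row(rec.hybrid_id)
            diff = pol.row(rec.pollinator_id) != parents.row(rec.tester_id)
            assert int((h == 1).sum()) == int(diff.sum())

    def test_full_sibs_identical(self):
        cfg = tiny_config(n_both=0, n_t1_only=2, n_t2_only=0, family_sizes=(2, 0, 0, 0, 0))
        parents = simulate_parent_genomes(cfg)
        pol, _ = derive_pollinators(parents, cfg)
        ped = pd.DataFrame(
            {
                "hybrid_id": ["a", "b"],
                "pollinator_id": [pol.ids[0]] * 2,
                "tester_id": ["M1", "M1"],
            }
        )
        hyb = synthesize_hybrid_genotypes(pol, parents.subset(["M1", "M2"]), ped)
        np.testing.assert_array_equal(hyb.dosages[0], hyb.dosages[1])

    def test_heterozygous_parent_rejected(self, tiny_population):
        pol = tiny_population["pollinators"]
        parents = tiny_population["parents"]
        bad = pol.subset(pol.ids[:2])
        bad.dosages[0, 0] = 1.0
        with pytest.raises(ValueError, match="heterozygous"):
            synthesize_hybrid_genotypes(
                bad,
                parents.subset(["M1", "M2"]),
                pd.DataFrame(
                    {"hybrid_id": ["x"], "pollinator_id": [bad.ids[0]], "tester_id": ["M1"]}
                ),
            )


class TestTraitArchitecture:
    def test_h2_one_requires_zero_error_variances(self, tiny_population):
        cfg = tiny_config(
            h2_targets={"t": 1.0}, var_env=0, var_gxe=0, var_row=0, var_col=0, var_resid=0
        )
        arch = simulate_trait_architecture(tiny_population["hybrids"], cfg, "t")
        plots = simulate_field_trial(arch.genotypic_values, cfg)
        merged = plots.loc[~plots["is_check"]]
        np.testing.assert_allclose(
            merged["t"].to_numpy(),
            arch.genotypic_values.loc[merged["genotype"]].to_numpy(),
        )

    def test_zero_qtl_effects_give_equal_values(self, tiny_population):
        cfg = tiny_config(n_qtl=0, h2_targets={"t": 0.5})
        # no QTL drawn -> flat genotypic values are infeasible for h2 > 0
        with pytest.raises(ValueError):
            simulate_trait_architecture(tiny_population["hybrids"], cfg, "t")

    def test_generative_variance_ratio_matches_target(self, tiny_population):
        """Scaled genotypic variance reproduces the entry-mean h2 target."""
        from phenopred.simulate import _entry_mean_error_variance

        cfg = tiny_config(h2_targets={"t": 0.6})
        arch = simulate_trait_architecture(tiny_population["hybrids"], cfg, "t")
        v_err = _entry_mean_error_variance(cfg)
        h2 = arch.genetic_variance / (arch.genetic_variance + v_err)
        assert abs(h2 - 0.6) < 1e-10


class TestFieldTrial:
    def test_prep_design_plot_counts(self):
        """1.2 replicates: 100 genotypes -> 120 test plots, plus 3x10 checks."""
        cfg = tiny_config(
            environments=(("L1", "2020"),), n_checks=3, check_reps=10, replicate_fraction=0.2
        )
        gv = pd.Series(np.zeros(100), index=[f"H{i:03d}" for i in range(100)], name="t")
        plots = simulate_field_trial(gv, cfg)
        assert int((~plots["is_check"]).sum()) == 120
        assert int(plots["is_check"].sum()) == 30

    def test_zero_variances_reproduce_genotypic_values(self):
        cfg = tiny_config(var_env=0, var_gxe=0, var_row=0, var_col=0, var_resid=0)
        gv = pd.Series([1.0, -2.0, 0.5], index=["A", "B", "C"], name="t")
        plots = simulate_field_trial(gv, cfg)
        test = plots.loc[~plots["is_check"]]
        np.testing.assert_allclose(test["t"], gv.loc[test["genotype"]].to_numpy())

    def test_seeded_determinism(self):
        cfg = tiny_config()
        gv = pd.Series(np.arange(5.0), index=list("ABCDE"), name="t")
        pd.testing.assert_frame_equal(simulate_field_trial(gv, cfg), simulate_field_trial(gv, cfg))

    def test_plot_drop_mask(self):
        cfg = tiny_config(plot_drop_fraction=0.3)
        gv = pd.Series(np.arange(40.0), index=[f"G{i}" for i in range(40)], name="t")
        full = simulate_field_trial(gv, tiny_config())
        dropped = simulate_field_trial(gv, cfg)
        assert len(dropped) < len(full)

    def test_realised_variance_decomposition(self):
        """Plot-value variance decomposes into the configured components."""
        cfg = tiny_config(environments=(("L1", "2020"), ("L2", "2020")))
        gv = pd.Series(np.zeros(200), index=[f"H{i}" for i in range(200)], name="t")
        resid_vars, env_vars = [], []
        for seed in range(10):
            c = tiny_config(
                environments=(("L1", "2020"), ("L2", "2020")), seed=seed, var_env=1.0
            )
            plots = simulate_field_trial(gv, c)
            test = plots.loc[~plots["is_check"]]
            env_means = test.groupby("environment")["t"].mean()
            env_vars.append(env_means.var())
            resid_vars.append((test["t"] - env_means[test["environment"]].values).var())
        # residual part: var_gxe + var_row + var_col + var_resid = 1.45
        assert abs(np.mean(resid_vars) - 1.45) / 1.45 < 0.10
        assert np.mean(env_vars) > 0


class TestNIRS:
    def test_noise_and_drift_zero_makes_replicates_identical(self, tiny_population):
        cfg = tiny_config(spectral_noise_sd=0.0, baseline_drift_amplitude=0.0)
        plots = tiny_population["plots"].head(6)
        spectra = simulate_nirs(tiny_population["hybrids"], plots, cfg)
        v = spectra.values.reshape(len(plots), 2, -1)
        np.testing.assert_array_equal(v[:, 0, :], v[:, 1, :])

    def test_full_wavelength_grid_has_1820_points(self):
        cfg = SimulationConfig()
        wl = cfg.wavelengths
        assert wl.size == 1820
        assert wl[0] == 680 and wl[-1] == 2499

    def test_two_tech_reps_per_plot(self, tiny_population):
        spectra = tiny_population["spectra"]
        assert spectra.n == 2 * len(tiny_population["plots"])
        assert spectra.meta.groupby("plot_id").size().eq(2).all()

    def test_zero_genetic_scale_decouples_spectra_from_genotype(self, tiny_population):
        """With no genotype signal, genotype-mean spectra ignore genetic values."""
        hyb = tiny_population["hybrids"]
        gv = tiny_population["genotypic_values"]["seed_yield"]
        cors = []
        for seed in range(8):
            cfg = tiny_config(spectral_genetic_scale=0.0, seed=seed)
            plots = tiny_population["plots"]
            spectra = simulate_nirs(hyb, plots, cfg)
            df = pd.DataFrame(spectra.values)
            df["genotype"] = spectra.meta["genotype"].to_numpy()
            means = df.groupby("genotype").mean()
            means = means.loc[[g for g in gv.index if g in means.index]]
            score = means.to_numpy() @ np.ones(means.shape[1])
            cors.append(np.corrcoef(score, gv.loc[means.index])[0, 1])
        assert abs(np.mean(cors)) < 0.1

    def test_rank_exceeding_wavelengths_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(spectral_loading_rank=500, n_wavelengths=100)


def test_end_to_end_determinism():
    """Identical config + seed gives bit-identical artefacts at every stage."""
    a = simulate_population(tiny_config(seed=5))
    b = simulate_population(tiny_config(seed=5))
    np.testing.assert_array_equal(a["hybrids"].dosages, b["hybrids"].dosages)
    pd.testing.assert_frame_equal(a["plots"], b["plots"])
    np.testing.assert_array_equal(a["spectra"].values, b["spectra"].values)
    pd.testing.assert_frame_equal(a["pedigree"], b["pedigree"])
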