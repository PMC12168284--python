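"""Generator contracts: determinism, limits, planted-effect structure."""

import io

import numpy as np
import pandas as pd
import pytest

import plaquestab as ps


def _tsv_bytes(table):
    buf = io.StringIO()
    table.to_tsv(buf)
    return buf.getvalue()


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=4, seed=11)
        t1, m1, x1, _ = ps.simulate_cohort(cfg)
        t2, m2, x2, _ = ps.simulate_cohort(cfg)
        assert _tsv_bytes(t1) == _tsv_bytes(t2)
        assert m1.data.equals(m2.data)
        assert x1.data.equals(x2.data)

    def test_null_cohort_deterministic(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=3, seed=5)
        t1, *_ = ps.simulate_null_cohort(cfg)
        t2, *_ = ps.simulate_null_cohort(cfg)
        assert _tsv_bytes(t1) == _tsv_bytes(t2)

    def test_different_seeds_differ(self):
        t1, *_ = ps.simulate_cohort(ps.SimulationConfig(n_subjects_per_group=3, seed=1))
        t2, *_ = ps.simulate_cohort(ps.SimulationConfig(n_subjects_per_group=3, seed=2))
        assert _tsv_bytes(t1) != _tsv_bytes(t2)


class TestLimits:
    def test_zero_drift_means_zero_latent_steps(self):
        cfg = ps.SimulationConfig(
            n_subjects_per_group=4,
            drift_sd_per_group={"HI": 0.0, "HEU": 0.0, "HUU": 0.0},
            zero_inflation=0.0,
            seed=3,
        )
        _, meta, _, truth = ps.simulate_cohort(cfg)
        steps = ps.latent_step_norms(truth, meta)
        assert (steps["step_norm"] == 0.0).all()

    def test_zero_spatial_effect_equalizes_position_means(self):
        cfg = ps.SimulationConfig(
            n_subjects_per_group=40,
            spatial_effect_per_group={"HI": 0.0, "HEU": 0.0, "HUU": 0.0},
            seed=4,
        )
        _, meta, _, truth = ps.simulate_cohort(cfg)
        lat = truth.latent
        ant = lat.loc[meta.data.index[meta.data["position"] == "anterior"]]
        post = lat.loc[meta.data.index[meta.data["position"] == "posterior"]]
        # offset taxa show no anterior/posterior mean difference beyond noise
        idx = np.flatnonzero(truth.spatial_offset)
        diff = ant.iloc[:, idx].mean() - post.iloc[:, idx].mean()
        assert np.abs(diff).max() < 0.25

    def test_planted_spatial_effect_shifts_anterior_mean(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=40, seed=4)
        _, meta, _, truth = ps.simulate_cohort(cfg)
        huu = meta.data[meta.data["hiv_status"] == "HUU"]
        lat = truth.latent
        ant = lat.loc[huu.index[huu["position"] == "anterior"]]
        post = lat.loc[huu.index[huu["position"] == "posterior"]]
        idx = np.flatnonzero(truth.spatial_offset)
        observed = (ant.iloc[:, idx].mean() - post.iloc[:, idx].mean()).to_numpy()
        planted = truth.spatial_offset[idx]
        assert np.corrcoef(observed, planted)[0, 1] > 0.9

    def test_single_visit_yields_no_pairs(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=3, n_visits=1, seed=6)
        _, meta, _, _ = ps.simulate_null_cohort(cfg)
        assert ps.match_paired_teeth(meta) == []


class TestCounts:
    def test_counts_are_nonnegative_integers_bounded_by_depth(self):
        table, _, _, truth = ps.simulate_cohort(
            ps.SimulationConfig(n_subjects_per_group=4, seed=8)
        )
        counts = table.counts
        assert counts.min() >= 0
        assert np.issubdtype(counts.dtype, np.integer)
        totals = table.data.sum(axis=1)
        # zeroed mass is not redistributed: totals never exceed drawn depth
        assert (totals <= truth.depths.loc[totals.index]).all()

    def test_totals_equal_depth_without_zero_inflation(self):
        table, _, _, truth = ps.simulate_cohort(
            ps.SimulationConfig(n_subjects_per_group=3, zero_inflation=0.0, seed=9)
        )
        totals = table.data.sum(axis=1)
        assert (totals == truth.depths.loc[totals.index]).all()


class TestPlantedStructure:
    def test_group_drift_ordering_recovered_from_latents(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=30, seed=1)
        _, meta, _, truth = ps.simulate_cohort(cfg)
        steps = ps.latent_step_norms(truth, meta)
        means = steps.groupby("hiv_status")["step_norm"].mean()
        assert means["HUU"] > means["HEU"]
        assert means["HUU"] > means["HI"]

    def test_mean_drift_monotone_in_sigma(self):
        means = []
        for sigma in (0.2, 0.5, 1.0, 1.5):
            cfg = ps.SimulationConfig(
                n_subjects_per_group=10,
                drift_sd_per_group={"HI": sigma, "HEU": sigma, "HUU": sigma},
                drift_caries_coupling=0.0,
                seed=21,
            )
            _, meta, _, truth = ps.simulate_cohort(cfg)
            means.append(ps.latent_step_norms(truth, meta)["step_norm"].mean())
        assert means == sorted(means)

    def test_block_correlation_vanishes_at_zero(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=40, block_corr=0.0, seed=2,
                                  drift_sd_per_group={"HI": 0, "HEU": 0, "HUU": 0})
        _, meta, _, truth = ps.simulate_cohort(cfg)
        first_visit = meta.data.index[meta.data["visit"] == 1]
        lat = truth.latent.loc[first_visit]
        block0 = np.flatnonzero(truth.block_membership == 0)
        corr = np.corrcoef(lat.iloc[:, block0].to_numpy().T)
        off_diag = corr[np.triu_indices_from(corr, 1)]
        assert np.abs(off_diag).mean() < 0.1

    def test_block_correlation_present_when_planted(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=40, block_corr=0.6, seed=2,
                                  drift_sd_per_group={"HI": 0, "HEU": 0, "HUU": 0})
        _, meta, _, truth = ps.simulate_cohort(cfg)
        first_visit = meta.data.index[meta.data["visit"] == 1]
        lat = truth.latent.loc[first_visit]
        block0 = np.flatnonzero(truth.block_membership == 0)
        corr = np.corrcoef(lat.iloc[:, block0].to_numpy().T)
        off_diag = corr[np.triu_indices_from(corr, 1)]
        assert off_diag.mean() > 0.4

    def test_cd4_links_to_cariogenic_balance(self):
        cfg = ps.SimulationConfig(n_subjects_per_group=40, seed=3)
        _, _, _, truth = ps.simulate_cohort(cfg)
        cd4 = truth.cd4_latent
        r = np.corrcoef(cd4["cariogenic_balance"], cd4["cd4"])[0, 1]
        assert r < -0.3  # negative link: more cariogenic load, lower CD4


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_taxa": 0},
            {"n_subjects_per_group": -1},
            {"block_corr": 1.0},
            {"groups": ("HI", "HI", "HUU")},
            {"cariogenic_taxa": (999,)},
            {"drift_sd_per_group": {"HI": -0.1, "HEU": 0.4, "HUU": 1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ps.InvalidConfigError):
            ps.simulate_cohort(ps.SimulationConfig(**kwargs))


class TestGgm:
    def test_support_and_determinism(self):
        d1, support, prec = ps.simulate_ggm(12, 3, 50, seed=1)
        d2, _, _ = ps.simulate_ggm(12, 3, 50, seed=1)
        pd.testing.assert_frame_equal(d1, d2)
        assert len(support) == 9  # chain of 3 edges per 4-node block
        assert (np.linalg.eigvalsh(prec) > 0).all()

    def test_flip_edge_negates_one_partial_correlation(self):
        _, _, prec = ps.simulate_ggm(12, 3, 50, seed=1, flip_edge=(0, 1))
        assert prec[0, 1] > 0
        assert prec[1, 2] < 0


class TestPhaseCohort:
    def test_phases_respect_thresholds(self, phase_cohort):
        table, meta, truth = phase_cohort
        prop = table.data["Streptococcus mutans"] / table.data.sum(axis=1)
        for sid, phase in truth["phase"].items():
            if phase == "during":
                assert prop.loc[sid] >= 0.10
            else:
                assert prop.loc[sid] <= 0.05

    def test_markers_enriched_in_their_phase(self, phase_cohort):
        table, meta, truth = phase_cohort
        rel = table.relative_abundance()
        phase = pd.Series(truth["phase"])
        before = rel.loc[phase[phase == "before"].index, truth["before_marker"]]
        after = rel.loc[phase[phase == "after"].index, truth["before_marker"]]
        assert before.mean() > 3 * after.mean()
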