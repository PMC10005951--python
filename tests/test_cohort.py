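import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hubspin as hs
from hubspin.exceptions import DegeneratePRSError, InvalidArgumentError


class TestConfigValidation:
    def test_proportions_bounded(self):
        with pytest.raises(InvalidArgumentError):
            hs.CohortConfig(proportion_case=1.5)

    def test_duplicate_planted_edges_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hs.CohortConfig(planted_edges=[(0, 1), (1, 0)])

    def test_diagonal_planted_edge_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hs.CohortConfig(planted_edges=[(3, 3)])


class TestTemplateConnectome:
    def test_symmetric_zero_diagonal_nonnegative(self, template):
        w = template.weights
        assert np.max(np.abs(w - w.T)) == 0.0
        assert np.all(np.diagonal(w) == 0.0)
        assert np.all(w >= 0)

    def test_full_density_complete_graph(self, parcellation):
        t = hs.generate_template_connectome(
            parcellation, hs.CohortConfig(seed=1, template_density=1.0)
        )
        off = ~np.eye(t.n_regions, dtype=bool)
        assert np.all(t.weights[off] > 0)

    def test_invalid_density(self, parcellation):
        with pytest.raises(InvalidArgumentError):
            hs.generate_template_connectome(
                parcellation, hs.CohortConfig(seed=1, template_density=0.0)
            )

    def test_hub_degree_exceeds_nonhub_upper_quartile(self, parcellation):
        # planted hubs must be recoverable as high-strength nodes
        for seed in range(50):
            t = hs.generate_template_connectome(parcellation, hs.CohortConfig(seed=seed))
            cen = hs.degree_centrality(t)
            hubs = set(t.metadata["hubs"])
            hub_vals = [v for l, v in zip(cen.labels, cen.values) if l in hubs]
            non_vals = [v for l, v in zip(cen.labels, cen.values) if l not in hubs]
            assert min(hub_vals) > np.percentile(non_vals, 75)


class TestSubjectConnectomes:
    def test_zero_sd_reproduces_template(self, parcellation, template):
        cfg = hs.CohortConfig(seed=2, n_subjects=5, subject_edge_sd=0.0)
        subj = hs.generate_subject_connectomes(template, cfg)
        for m in subj.matrices:
            assert np.array_equal(m.weights, template.weights)

    def test_outputs_valid_connectomes(self, parcellation, template):
        cfg = hs.CohortConfig(seed=3, n_subjects=10)
        subj = hs.generate_subject_connectomes(template, cfg)
        for m in subj.matrices:
            assert np.max(np.abs(m.weights - m.weights.T)) == 0.0
            assert np.all(np.diagonal(m.weights) == 0.0)
            assert np.all(m.weights >= 0)

    def test_planted_edges_more_variable(self, parcellation, template):
        cfg = hs.CohortConfig(seed=4, n_subjects=200)
        subj = hs.generate_subject_connectomes(template, cfg)
        data = hs.simulate_cohort(parcellation, cfg, template=template)
        cols = data.truth["planted_edge_columns"]
        emp_sd = subj.deviations.std(axis=0)
        expected = cfg.subject_edge_sd * cfg.planted_edge_sd_multiplier
        assert np.allclose(emp_sd[cols], expected, rtol=0.25)


class TestPhenotypes:
    def test_noiseless_single_edge_prs_is_that_deviation(self, parcellation, template):
        cfg = hs.CohortConfig(
            seed=5, n_subjects=50, planted_edges=((0, 1),), planted_weights=(1.0,),
            prs_noise_sd=0.0,
        )
        subj = hs.generate_subject_connectomes(template, cfg)
        table = hs.generate_phenotypes(cfg, subj, template)
        col = np.flatnonzero((subj.pairs == [0, 1]).all(axis=1))[0]
        r = np.corrcoef(table["prs"], subj.deviations[:, col])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_prs_standardized(self, parcellation, template):
        cfg = hs.CohortConfig(seed=6, n_subjects=300)
        subj = hs.generate_subject_connectomes(template, cfg)
        table = hs.generate_phenotypes(cfg, subj, template)
        assert table["prs"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table["prs"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_prs_rejected(self, parcellation, template):
        cfg = hs.CohortConfig(seed=7, n_subjects=50, planted_edges=(), prs_noise_sd=0.0)
        subj = hs.generate_subject_connectomes(template, cfg)
        with pytest.raises(DegeneratePRSError):
            hs.generate_phenotypes(cfg, subj, template)

    def test_planted_variance_fraction(self, parcellation, template):
        # default: planted edges explain half of the PRS variance
        r2s = []
        for seed in (8, 9, 10, 11, 12):
            cfg = hs.CohortConfig(seed=seed, n_subjects=1000)
            subj = hs.generate_subject_connectomes(template, cfg)
            table = hs.generate_phenotypes(cfg, subj, template)
            data = hs.simulate_cohort(parcellation, cfg, template=template)
            cols = data.truth["planted_edge_columns"]
            w = np.array(data.truth["planted_weights"])
            signal = subj.deviations[:, cols] @ w
            r2s.append(np.corrcoef(signal, table["prs"])[0, 1] ** 2)
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.05)

    def test_case_fraction_within_binomial_ci(self, parcellation, template):
        cfg = hs.CohortConfig(seed=9, n_subjects=560)
        subj = hs.generate_subject_connectomes(template, cfg)
        table = hs.generate_phenotypes(cfg, subj, template)
        n_case = (table["group"] == "ASD").sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], cfg.n_subjects, cfg.proportion_case)
        assert lo <= n_case <= hi

    def test_ages_within_range(self, parcellation, template):
        cfg = hs.CohortConfig(seed=10, n_subjects=100)
        subj = hs.generate_subject_connectomes(template, cfg)
        table = hs.generate_phenotypes(cfg, subj, template)
        assert table["age"].between(*cfg.age_range).all()


class TestThickness:
    def test_degenerate_config_constant_maps(self, parcellation, template):
        cfg = hs.CohortConfig(
            seed=11, n_subjects=8, noise_sd=0.0, group_effect=0.0, prs_effect=0.0,
            age_slope=0.0, site_offset_sd=0.0,
        )
        data = hs.simulate_cohort(parcellation, cfg, template=template)
        assert np.allclose(data.thickness.to_numpy(), cfg.baseline)

    def test_full_hub_coupling_group_difference_tracks_centrality(self, parcellation, template):
        cfg = hs.CohortConfig(seed=12, n_subjects=200, noise_sd=0.0, hub_coupling=1.0,
                              site_offset_sd=0.0)
        data = hs.simulate_cohort(parcellation, cfg, template=template)
        T = data.thickness.to_numpy()
        asd = (data.subjects["group"] == "ASD").to_numpy()
        diff = T[asd].mean(axis=0) - T[~asd].mean(axis=0)
        c = data.centrality.values
        ctilde = (c - c.min()) / (c.max() - c.min())
        r = np.corrcoef(diff, ctilde)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_entries_finite_positive(self, default_cohort):
        T = default_cohort.thickness.to_numpy()
        assert np.all(np.isfinite(T))
        assert np.all(T > 0)


class TestReproducibilityAndIO:
    def test_bit_identical_replay(self, parcellation):
        cfg = hs.CohortConfig(seed=99, n_subjects=40)
        a = hs.simulate_cohort(parcellation, cfg)
        b = hs.simulate_cohort(parcellation, cfg)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.thickness, b.thickness)
        assert np.array_equal(a.template.weights, b.template.weights)
        for ma, mb in zip(a.connectomes.matrices, b.connectomes.matrices):
            assert np.array_equal(ma.weights, mb.weights)

    def test_write_cohort_files(self, tmp_path, parcellation):
        cfg = hs.CohortConfig(seed=1, n_subjects=3)
        data = hs.simulate_cohort(parcellation, cfg)
        hs.write_cohort(data, tmp_path)
        for name in ("subjects.csv", "thickness.tsv", "template_connectome.tsv",
                     "parcellation.csv", "truth.json"):
            assert (tmp_path / name).exists()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["planted_edges"]) == 6
        sid = data.subjects["subject_id"].iloc[0]
        back = hs.ConnectivityMatrix.from_tsv(tmp_path / f"connectome_{sid}.tsv")
        assert np.allclose(back.weights, data.connectomes.matrices[0].weights)
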