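"""Synthetic study generator: catalogs, expected abundances, counts."""

import numpy as np
import pandas as pd
import pytest

from zgakit import synth
from zgakit.schedule import CycleSchedule, default_schedule
from zgakit.synth import (
    DesignPoint,
    EmbryoDesign,
    GeneSpec,
    design_points,
    expected_abundance,
    expected_matrix,
    generate_catalog,
    make_study,
    sample_counts,
)


class TestGenerateCatalog:
    def test_all_maternal_mix(self):
        cat = generate_catalog(100, class_mix={"maternal_only": 1.0}, seed=0)
        assert len(cat) == 100
        assert all(g.zygotic_rate == 0 for g in cat)

    def test_fixed_seed_reproducible(self):
        assert generate_catalog(50, seed=3) == generate_catalog(50, seed=3)
        assert generate_catalog(50, seed=3) != generate_catalog(50, seed=4)

    def test_class_frequencies_within_binomial_ci(self):
        n = 10_000
        mix = synth.DEFAULT_CLASS_MIX
        cat = generate_catalog(n, seed=12)
        counts = pd.Series([g.gene_class for g in cat]).value_counts()
        for cls, p in mix.items():
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(cls, 0) - n * p) < 4 * se

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_catalog(10, class_mix={"maternal_only": 0.5})

    def test_spec_field_constraints_enforced(self):
        with pytest.raises(ValueError):
            GeneSpec("g", "zygotic_only", maternal_initial=5.0)
        with pytest.raises(ValueError):
            GeneSpec("g", "maternal_only", zygotic_rate=1.0)


class TestExpectedAbundance:
    def test_stable_maternal_gene_constant_everywhere(self, sched):
        gene = GeneSpec("g", "maternal_only", maternal_initial=100.0)
        pts = design_points(EmbryoDesign(), sched)
        vals = [expected_abundance(gene, p, sched) for p in pts]
        assert np.allclose(vals, 100.0)

    def test_long_tu_silent_before_cycle14_in_controls(self, sched):
        # eclipse(20 kb) = 14 min exceeds every pre-14 window (max 11 min)
        gene = GeneSpec("g", "zygotic_only", tu_length_kb=20.0, zygotic_rate=2.0)
        pts = {p.cycle_label: p for p in design_points(EmbryoDesign(), sched)
               if p.condition == "control"}
        assert expected_abundance(gene, pts["C12"], sched) == 0.0
        assert expected_abundance(gene, pts["C13"], sched) == 0.0
        assert expected_abundance(gene, pts["C14L"], sched) > 0.0

    def test_two_cycle_toy_matches_quadrature_oracle(self):
        """Cumulative completed transcripts vs a dense-grid integration of
        the initiation process."""
        s = CycleSchedule(cycles=((12, 10.0, 2.0), (13, 30.0, 2.0)),
                          terminal_cycle=13)
        gene = GeneSpec("g", "zygotic_only", tu_length_kb=2.0, zygotic_rate=1.5)
        point = DesignPoint("control", "C13", 20.0, 13, 2.0)
        got = expected_abundance(gene, point, s, nuclei_base=1.0)

        # oracle: integrate initiations that complete by the sampling time
        grid = np.linspace(0, 20.0, 2_000_001)
        dt = grid[1] - grid[0]
        ecl = 2.0 * 0.7
        rate = np.zeros_like(grid)
        in_c12 = (grid > 4.0) & (grid <= 10.0)  # initiation window cycle 12
        rate[in_c12 & (grid + ecl <= 10.0)] = 1.5 * 1.0  # must finish pre-mitosis
        start13 = 12.0
        in_c13 = grid > start13 + 4.0
        rate[in_c13 & (grid + ecl <= 20.0)] = 1.5 * 2.0  # completed by sampling
        oracle = rate.sum() * dt
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_arrested_accrual_is_continuous(self, sched):
        gene = GeneSpec("g", "zygotic_only", tu_length_kb=1.0, zygotic_rate=2.0)
        p70 = DesignPoint("arrested", "70", 70.0, 12, 1.0)
        assert expected_abundance(gene, p70, sched) == pytest.approx(
            2.0 * (70 - 4 - 0.7)
        )


class TestSampleCounts:
    def _expected(self, n=200, seed=5):
        cat = generate_catalog(n, seed=seed)
        return expected_matrix(cat, EmbryoDesign(seed=seed), default_schedule())

    def test_zero_expectation_gives_zero_counts(self):
        exp = self._expected()
        mat, _ = sample_counts(exp, EmbryoDesign(seed=1))
        zero_rows = exp.index[(exp == 0).all(axis=1)]
        assert len(zero_rows) > 0
        assert (mat.values.loc[zero_rows] == 0).all().all()

    def test_fixed_seed_reproducible(self):
        exp = self._expected()
        a, _ = sample_counts(exp, EmbryoDesign(seed=9))
        b, _ = sample_counts(exp, EmbryoDesign(seed=9))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_zero_dispersion_is_poisson_limit(self):
        """With dispersion 0 the sample variance tracks the mean."""
        mu = 50.0
        exp = pd.DataFrame({"cond:A": [mu]}, index=["g"])
        design = EmbryoDesign(
            replicates=2, nb_dispersion=0.0, library_log_sigma=0.0,
            library_median=mu, seed=2,
        )
        draws = []
        for seed in range(5000):
            d = EmbryoDesign(replicates=2, nb_dispersion=0.0,
                             library_log_sigma=0.0, library_median=mu, seed=seed)
            mat, _ = sample_counts(exp, d)
            draws.extend(mat.values.loc["g"].tolist())
        draws = np.asarray(draws, dtype=float)
        assert draws.mean() == pytest.approx(mu, rel=0.05)
        assert draws.var() == pytest.approx(mu, rel=0.1)

    def test_overdispersed_variance_exceeds_poisson(self):
        mu = 200.0
        exp = pd.DataFrame({"cond:A": [mu]}, index=["g"])
        draws = []
        for seed in range(3000):
            d = EmbryoDesign(replicates=2, nb_dispersion=0.1,
                             library_log_sigma=0.0, library_median=mu, seed=seed)
            mat, _ = sample_counts(exp, d)
            draws.extend(mat.values.loc["g"].tolist())
        draws = np.asarray(draws, dtype=float)
        expected_var = mu + 0.1 * mu**2
        assert draws.var() == pytest.approx(expected_var, rel=0.15)


class TestMakeStudy:
    def test_default_bundle_mirrors_study_layout(self, small_bundle):
        meta = small_bundle.meta
        assert small_bundle.counts.values.shape[1] == len(meta) == 24
        assert set(meta["condition"]) == {"control", "arrested"}
        labels = set(meta["cycle_label"])
        assert {"C12", "C13", "C14E", "C14L", "15", "30", "50", "70"} == labels
        assert meta.groupby(["condition", "cycle_label"]).size().eq(3).all()

    def test_bundle_files_written(self, tmp_path):
        make_study(design=EmbryoDesign(seed=2), n_genes=50, out_dir=tmp_path)
        for name in ("counts.tsv", "meta.tsv", "truth.tsv", "profiles.tsv",
                     "schedule.tsv"):
            assert (tmp_path / name).exists()
        counts = pd.read_csv(tmp_path / "counts.tsv", sep="\t", index_col=0)
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t", index_col=0)
        assert counts.shape == (50, 24)
        assert list(truth.index) == list(counts.index)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            make_study(catalog=[], n_genes=0)

    def test_truth_labels_consistent_with_classes(self, small_bundle):
        truth = small_bundle.truth
        assert (truth.loc[truth.gene_class == "zygotic_only", "planted_group"]
                == "1").all()
        assert (truth.loc[truth.gene_class == "maternal_and_zygotic",
                          "planted_group"] == "2").all()
        assert (truth.loc[truth.planted_group == "3", "gene_class"]
                == "maternal_only").all()
        delay = truth.planted_delay_class != "none"
        assert (truth.loc[delay, "gene_class"] == "zygotic_only").all()
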