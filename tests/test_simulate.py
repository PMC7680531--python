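"""Simulator statistics: Mendelian segregation, Haldane linkage, censored
phenotypes, tail bulks and the binomial read model."""

import math

import numpy as np
import pandas as pd
import pytest

import bsaqtl as b
from bsaqtl.errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# variant map
# ---------------------------------------------------------------------------

class TestVariantMap:
    def test_construction_invariants(self):
        vm = b.build_variant_map(19, 2000, 30_000_000, 100.0, seed=1)
        assert len(vm) == 19 * 2000
        assert list(vm["chromosome"].unique()) == list(b.BNAPUS_CHROMOSOMES)
        for _, block in vm.groupby("chromosome"):
            assert block["position_bp"].is_monotonic_increasing
            assert block["position_cM"].is_monotonic_increasing
            assert block["position_bp"].is_unique
        assert (vm["cab_allele"] != vm["dar_allele"]).all()

    def test_seeded_determinism(self):
        a = b.build_variant_map(1, 5, 1_000_000, 50.0, seed=42)
        c = b.build_variant_map(1, 5, 1_000_000, 50.0, seed=42)
        pd.testing.assert_frame_equal(a, c)

    def test_linear_genetic_map(self):
        vm = b.build_variant_map(1, 100, 10_000_000, 100.0, seed=3)
        np.testing.assert_allclose(vm["position_cM"], vm["position_bp"] * 1e-5)

    @pytest.mark.parametrize("kwargs", [
        {"n_chromosomes": 0}, {"variants_per_chromosome": -1},
        {"chromosome_length_bp": 0}, {"map_length_cM": 0.0},
    ])
    def test_rejects_nonpositive_parameters(self, kwargs):
        with pytest.raises(ConfigError):
            b.build_variant_map(**{"n_chromosomes": 1, "variants_per_chromosome": 10,
                                   "chromosome_length_bp": 1_000_000,
                                   "map_length_cM": 50.0, **kwargs})


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

class TestF2Genotypes:
    def test_mendelian_segregation_1_2_1(self):
        vm = b.build_variant_map(1, 1, 1_000_000, 1.0, seed=5)
        geno = b.simulate_f2_genotypes(vm, 10_000, seed=6)
        n = geno.n_lines
        counts = np.bincount(geno.dosage[:, 0], minlength=3)
        for observed, expected in zip(counts, (0.25, 0.5, 0.25)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed / n - expected) < 3 * se

    @pytest.mark.parametrize("distance_cm", [1.0, 10.0, 50.0])
    def test_haldane_recombination_fraction(self, distance_cm):
        length = 1_000_000
        vm = pd.DataFrame(
            {
                "chromosome": "chr01",
                "position_bp": [1, length],
                "position_cM": [0.0, distance_cm],
                "cab_allele": "A",
                "dar_allele": "G",
            }
        )
        n = 20_000
        gametes = b.simulate_gametes(vm, n, seed=int(distance_cm))
        r_hat = (gametes[:, 0] != gametes[:, 1]).mean()
        r = (1 - math.exp(-2 * distance_cm / 100)) / 2
        assert abs(r_hat - r) < 3 * math.sqrt(r * (1 - r) / n)

    def test_zero_map_distance_perfectly_linked(self):
        vm = pd.DataFrame(
            {
                "chromosome": "chr01",
                "position_bp": [100, 200],
                "position_cM": [5.0, 5.0],
                "cab_allele": "A",
                "dar_allele": "G",
            }
        )
        geno = b.simulate_f2_genotypes(vm, 2000, seed=8)
        assert (geno.dosage[:, 0] == geno.dosage[:, 1]).all()

    def test_dosage_alphabet_and_determinism(self, small_map):
        g1 = b.simulate_f2_genotypes(small_map, 50, seed=9)
        g2 = b.simulate_f2_genotypes(small_map, 50, seed=9)
        assert set(np.unique(g1.dosage)) <= {0, 1, 2}
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_empty_map_rejected(self):
        empty = pd.DataFrame(columns=["chromosome", "position_bp", "position_cM",
                                      "cab_allele", "dar_allele"])
        with pytest.raises(DataError):
            b.simulate_f2_genotypes(empty, 10, seed=0)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def map_with_default_loci():
    vm = b.build_variant_map(19, 100, 30_000_000, 100.0, seed=13)
    model = b.snap_model_to_map(b.default_qtl_model(noise_sd=0.0), vm)
    return vm, model


class TestPhenotypes:
    def _fixed_genotypes(self, vm, dosage_value, n=4):
        dosage = np.full((n, len(vm)), dosage_value, dtype=np.int8)
        return b.F2GenotypeMatrix(dosage=dosage,
                                  line_ids=[f"L{i:04d}" for i in range(n)],
                                  variant_map=vm)

    def test_all_cabriolet_vern_matches_parental_mean(self, map_with_default_loci):
        vm, model = map_with_default_loci
        geno = self._fixed_genotypes(vm, 2)
        ph = b.simulate_phenotypes(geno, model, b.VERN, seed=0)
        np.testing.assert_allclose(ph["flowering_days"], 42.92)
        assert not ph["censored"].any()

    def test_all_darmor_vern_matches_parental_mean(self, map_with_default_loci):
        vm, model = map_with_default_loci
        ph = b.simulate_phenotypes(self._fixed_genotypes(vm, 0), model, b.VERN, seed=0)
        np.testing.assert_allclose(ph["flowering_days"], 71.25)

    def test_all_cabriolet_nvern_matches_parental_mean(self, map_with_default_loci):
        vm, model = map_with_default_loci
        ph = b.simulate_phenotypes(self._fixed_genotypes(vm, 2), model, b.NVERN, seed=0)
        np.testing.assert_allclose(ph["flowering_days"], 78.0)

    def test_all_darmor_nvern_is_censored_dnf(self, map_with_default_loci):
        vm, model = map_with_default_loci
        ph = b.simulate_phenotypes(self._fixed_genotypes(vm, 0), model, b.NVERN, seed=0)
        assert (ph["flowering_days"] == 170).all()
        assert ph["censored"].all()

    def test_censoring_rule(self, map_with_default_loci):
        """No value exceeds the censor bound; the flag is exactly the bound."""
        vm, _ = map_with_default_loci
        model = b.snap_model_to_map(b.default_qtl_model(noise_sd=40.0), vm)
        geno = b.simulate_f2_genotypes(vm, 500, seed=14)
        ph = b.simulate_phenotypes(geno, model, b.NVERN, seed=15)
        assert (ph["flowering_days"] <= 170).all()
        assert (ph["censored"] == (ph["flowering_days"] == 170)).all()
        assert ph["censored"].any()

    def test_missing_causal_locus_rejected(self, small_map, small_genotypes):
        model = b.QTLModel(
            loci=[b.QTLLocus("chr09", 1, additive={b.VERN: 5.0})],
            baseline={b.VERN: 60.0, b.NVERN: 120.0},
        )
        with pytest.raises(DataError):
            b.simulate_phenotypes(small_genotypes, model, b.VERN, seed=0)


# ---------------------------------------------------------------------------
# bulks
# ---------------------------------------------------------------------------

def _phenotable(days, censored=None):
    days = np.asarray(days, dtype=float)
    if censored is None:
        censored = days == 170
    return pd.DataFrame(
        {
            "line_id": [f"L{i:04d}" for i in range(len(days))],
            "treatment": "VERN",
            "flowering_days": days,
            "censored": censored,
        }
    )


class TestSelectBulks:
    def test_five_percent_of_720(self):
        ph = _phenotable(np.linspace(40, 160, 720))
        bulks = b.select_bulks(ph, 0.05, seed=0)
        assert len(bulks.early_lines) == 36
        assert len(bulks.late_lines) == 36
        days = ph.set_index("line_id")["flowering_days"]
        assert days[bulks.early_lines].max() < days[bulks.late_lines].min()

    def test_censored_ties_sampled_for_late_bulk(self):
        """86 DNF lines compete for 36 late slots by seeded sampling."""
        days = np.concatenate([np.linspace(40, 150, 634), np.full(86, 170.0)])
        ph = _phenotable(days)
        bulks1 = b.select_bulks(ph, 0.05, seed=3)
        bulks2 = b.select_bulks(ph, 0.05, seed=3)
        bulks3 = b.select_bulks(ph, 0.05, seed=4)
        censored_ids = set(ph.loc[ph["censored"], "line_id"])
        assert len(bulks1.late_lines) == 36
        assert set(bulks1.late_lines) <= censored_ids
        assert bulks1.late_lines == bulks2.late_lines
        assert set(bulks3.late_lines) != set(bulks1.late_lines)

    def test_censored_lines_never_enter_early_bulk(self):
        days = np.full(100, 170.0)
        days[:4] = [50, 60, 70, 80]
        ph = _phenotable(days)
        bulks = b.select_bulks(ph, 0.05, seed=1)
        assert set(bulks.early_lines) <= {"L0000", "L0001", "L0002", "L0003"}
        assert len(bulks.late_lines) == 5

    def test_degenerate_all_identical_still_disjoint(self):
        ph = _phenotable(np.full(100, 90.0))
        bulks = b.select_bulks(ph, 0.1, seed=2)
        assert len(bulks.early_lines) == 10
        assert len(bulks.late_lines) == 10
        assert not set(bulks.early_lines) & set(bulks.late_lines)

    @pytest.mark.parametrize("fraction", [0.0, 0.5, 1.2, -0.1])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ConfigError):
            b.select_bulks(_phenotable([1.0, 2.0]), fraction, seed=0)


# ---------------------------------------------------------------------------
# read model
# ---------------------------------------------------------------------------

class TestAlleleCounts:
    def test_fixed_cabriolet_no_error_all_reads_cab(self, small_map):
        dosage = np.full((10, len(small_map)), 2, dtype=np.int8)
        geno = b.F2GenotypeMatrix(dosage, [f"L{i}" for i in range(10)], small_map)
        counts = b.simulate_allele_counts(geno, error_rate=0.0, seed=20)
        assert (counts["dar_count"] == 0).all()
        assert (counts["cab_count"] > 0).any()

    def test_binomial_expectation_at_half(self):
        """f = 0.5, e = 0: mean Cabriolet read fraction ~ 0.5 over 1e5 draws."""
        vm = b.build_variant_map(1, 100_000, 50_000_000, 100.0, seed=21)
        dosage = np.ones((2, len(vm)), dtype=np.int8)  # every line heterozygous
        geno = b.F2GenotypeMatrix(dosage, ["L1", "L2"], vm)
        counts = b.simulate_allele_counts(geno, mean_depth=30, error_rate=0.0, seed=22)
        depth = (counts["cab_count"] + counts["dar_count"]).to_numpy()
        frac = counts["cab_count"].sum() / depth.sum()
        se = math.sqrt(0.25 / depth.sum())
        assert abs(frac - 0.5) < 3 * se

    def test_error_rate_shifts_alt_fraction(self):
        """Observed alt fraction converges to f(1-e) + (1-f)e."""
        vm = b.build_variant_map(1, 100_000, 50_000_000, 100.0, seed=23)
        counts = b.simulate_allele_counts("darmor", variant_map=vm, mean_depth=30,
                                          error_rate=0.01, seed=24)
        depth = (counts["cab_count"] + counts["dar_count"]).sum()
        frac = counts["cab_count"].sum() / depth
        se = math.sqrt(0.01 * 0.99 / depth)
        assert abs(frac - 0.01) < 3 * se

    def test_seeded_determinism(self, small_genotypes):
        c1 = b.simulate_allele_counts(small_genotypes, seed=25)
        c2 = b.simulate_allele_counts(small_genotypes, seed=25)
        pd.testing.assert_frame_equal(c1, c2)

    def test_unknown_bulk_line_rejected(self, small_genotypes):
        with pytest.raises(DataError):
            b.simulate_allele_counts(small_genotypes, ["NOPE"], seed=0)

    @pytest.mark.parametrize("kwargs", [{"mean_depth": 0}, {"error_rate": 0.5},
                                        {"error_rate": -0.01}])
    def test_invalid_read_model_parameters(self, small_genotypes, kwargs):
        with pytest.raises(ConfigError):
            b.simulate_allele_counts(small_genotypes, **kwargs, seed=0)
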