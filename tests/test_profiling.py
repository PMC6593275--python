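"""OTU mapping weights, CPM, CPI and prediction error."""

import numpy as np
import pandas as pd
import pytest

from vitaprof.profiling import (
    compute_cpi,
    compute_cpm,
    compute_error,
    map_otus,
    mapped_abundances,
)

from conftest import flat_taxonomy, make_bpm


def assignments_of(**otus):
    frame = pd.DataFrame.from_dict(otus, orient="index", columns=["rank", "taxon"])
    frame.index.name = "otu_id"
    return frame


@pytest.fixture
def reference():
    """Genus G with species A (1 strain) and B (3 strains); genus H with one
    species; a second family with one genus/species."""
    rows = {
        "a1": [1] * 9,
        "b1": [0] * 9, "b2": [0] * 9, "b3": [1] * 9,
        "h1": [1, 0, 1, 0, 1, 0, 1, 0, 1],
        "z1": [0, 1, 0, 1, 0, 1, 0, 1, 0],
    }
    bpm = make_bpm(rows)
    tax = flat_taxonomy({
        "a1": ("Sp a", "G", "F1"),
        "b1": ("Sp b", "G", "F1"),
        "b2": ("Sp b", "G", "F1"),
        "b3": ("Sp b", "G", "F1"),
        "h1": ("Sp h", "H", "F1"),
        "z1": ("Sp z", "Z", "F2"),
    })
    return bpm, tax


class TestMapping:
    def test_species_equal_weights_over_strains(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("species", "Sp b")), tax, bpm)
        assert w["o1"].rank_used == "species"
        assert w["o1"].weights.to_dict() == {
            "b1": pytest.approx(1 / 3),
            "b2": pytest.approx(1 / 3),
            "b3": pytest.approx(1 / 3),
        }

    def test_four_strain_species_quarter_weights(self):
        bpm = make_bpm({f"s{i}": [1] * 9 for i in range(4)})
        tax = flat_taxonomy({g: ("Sp s", "G", "F") for g in bpm.genome_ids})
        w = map_otus(assignments_of(o1=("species", "Sp s")), tax, bpm)
        assert np.allclose(w["o1"].weights, 0.25)

    def test_genus_mean_of_species_means(self, reference):
        """Genus with species of 1 and 3 strains: weights 1/2 and 1/6 each."""
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("genus", "G")), tax, bpm)["o1"].weights
        assert w["a1"] == pytest.approx(0.5)
        for b in ("b1", "b2", "b3"):
            assert w[b] == pytest.approx(1 / 6)

    def test_flat_mode_equal_genome_weights(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("genus", "G")), tax, bpm, mode="flat")
        assert np.allclose(w["o1"].weights, 0.25)

    def test_family_three_level_nesting(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("family", "F1")), tax, bpm)["o1"].weights
        # F1 has genera G (species a, b) and H (species h)
        assert w["a1"] == pytest.approx(1 / 4)
        assert w["b1"] == pytest.approx(1 / 12)
        assert w["h1"] == pytest.approx(1 / 2)
        assert w.sum() == pytest.approx(1.0)

    def test_order_rank_unmapped(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("order", "Clostridiales")), tax, bpm)
        assert w["o1"].unmapped

    def test_unknown_species_falls_back_to_genus(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("species", "G novel")), tax, bpm)["o1"]
        assert w.rank_used == "genus"
        assert w.weights["a1"] == pytest.approx(0.5)

    def test_unknown_taxon_unmapped_not_error(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("genus", "Nonexistent")), tax, bpm)
        assert w["o1"].unmapped


class TestCPM:
    def test_single_genome_binary(self, reference):
        bpm, tax = reference
        w = map_otus(assignments_of(o1=("species", "Sp a")), tax, bpm)
        cpm = compute_cpm(w, bpm)
        assert np.allclose(cpm.loc["o1"], 1.0)

    def test_equal_split_half(self):
        bpm = make_bpm({"x": [1] * 9, "y": [0] * 9})
        tax = flat_taxonomy({g: ("Sp s", "G", "F") for g in bpm.genome_ids})
        w = map_otus(assignments_of(o1=("species", "Sp s")), tax, bpm)
        assert np.allclose(compute_cpm(w, bpm).loc["o1"], 0.5)

    def test_matches_brute_force_dot_product(self, small_reference, small_community):
        bpm = small_reference.bpm()
        w = map_otus(small_community.assignments, small_reference.taxonomy, bpm)
        cpm = compute_cpm(w, bpm)
        rng = np.random.default_rng(0)
        for otu_id in rng.choice(w.mapped_ids, size=10, replace=False):
            weights = w[str(otu_id)].weights
            expected = sum(
                wm * bpm.phenotypes.loc[g].to_numpy(dtype=float)
                for g, wm in weights.items()
            )
            assert np.allclose(cpm.loc[str(otu_id)], expected, atol=1e-12)


def simple_cpm(values: dict[str, float]):
    cpm = pd.DataFrame({v: pd.Series(values) for v in make_bpm({"g": [0] * 9}).phenotypes})
    cpm.index.name = "otu_id"
    return cpm


class TestCPI:
    def test_single_mapped_otu_full_prototroph(self):
        cpm = simple_cpm({"o1": 1.0})
        counts = pd.DataFrame({"s": [123.0]}, index=cpm.index)
        rep = compute_cpi(cpm, counts)
        assert np.allclose(rep.cpi.loc["s"], 100.0)
        assert np.allclose(rep.auxotrophy.loc["s"], 0.0)
        assert np.allclose(rep.sigma.loc["s"], 0.0)

    def test_two_otu_arithmetic(self):
        cpm = simple_cpm({"o1": 1.0, "o2": 0.0})
        counts = pd.DataFrame({"s": [60.0, 40.0]}, index=cpm.index)
        rep = compute_cpi(cpm, counts)
        assert np.allclose(rep.cpi.loc["s"], 60.0)
        assert np.allclose(rep.auxotrophy.loc["s"], 40.0)

    def test_zero_mapped_abundance_gives_nan(self):
        cpm = simple_cpm({"o1": 1.0})
        counts = pd.DataFrame({"s": [0.0], "t": [5.0]}, index=cpm.index)
        rep = compute_cpi(cpm, counts)
        assert rep.cpi.loc["s"].isna().all()
        assert np.allclose(rep.cpi.loc["t"], 100.0)

    def test_complement_identity(self, small_reference, small_community):
        bpm = small_reference.bpm()
        w = map_otus(small_community.assignments, small_reference.taxonomy, bpm)
        cpm = compute_cpm(w, bpm)
        rep = compute_cpi(cpm, small_community.counts, w)
        assert np.allclose((rep.cpi + rep.auxotrophy).to_numpy(), 100.0)

    def test_scale_invariance(self):
        cpm = simple_cpm({"o1": 0.7, "o2": 0.2})
        c1 = pd.DataFrame({"s": [10.0, 30.0]}, index=cpm.index)
        r1, r2 = compute_cpi(cpm, c1), compute_cpi(cpm, c1 * 17.5)
        pd.testing.assert_frame_equal(r1.cpi, r2.cpi)
        pd.testing.assert_frame_equal(r1.sigma, r2.sigma)

    def test_mixture_linearity(self):
        cpm = simple_cpm({"o1": 0.9, "o2": 0.1})
        a = pd.DataFrame({"s": [80.0, 20.0]}, index=cpm.index)
        b = pd.DataFrame({"s": [20.0, 80.0]}, index=cpm.index)
        mix = (a + b) / 2
        cpi_mix = compute_cpi(cpm, mix).cpi
        mean_cpi = (compute_cpi(cpm, a).cpi + compute_cpi(cpm, b).cpi) / 2
        pd.testing.assert_frame_equal(cpi_mix, mean_cpi)

    def test_coverage_fractions_sum_to_one(self, small_reference, small_community):
        bpm = small_reference.bpm()
        w = map_otus(small_community.assignments, small_reference.taxonomy, bpm)
        cpm = compute_cpm(w, bpm)
        rep = compute_cpi(cpm, small_community.counts, w)
        assert np.allclose(rep.coverage.sum(axis=1), 1.0)

    def test_exact_when_species_level_homogeneous(self, reference):
        """Species-mapped, phenotype-pure OTUs: sigma = 0 and CPI equals the
        abundance-weighted prototroph fraction exactly."""
        bpm, tax = reference
        asg = assignments_of(o1=("species", "Sp a"), o2=("species", "Sp h"))
        w = map_otus(asg, tax, bpm)
        cpm = compute_cpm(w, bpm)
        counts = pd.DataFrame({"s": [30.0, 70.0]}, index=asg.index)
        rep = compute_cpi(cpm, counts, w)
        assert np.allclose(rep.sigma.to_numpy(), 0.0)
        assert rep.cpi.loc["s", "B1"] == pytest.approx(100.0)
        assert rep.cpi.loc["s", "B2"] == pytest.approx(30.0)

    def test_negative_counts_rejected(self):
        cpm = simple_cpm({"o1": 1.0})
        counts = pd.DataFrame({"s": [-1.0]}, index=cpm.index)
        with pytest.raises(ValueError, match="negative"):
            compute_cpi(cpm, counts)


class TestError:
    def test_binary_phenotypes_zero_error(self):
        cpm = simple_cpm({"o1": 1.0, "o2": 0.0})
        counts = pd.DataFrame({"s": [1.0, 1.0]}, index=cpm.index)
        assert np.allclose(compute_error(cpm, counts).to_numpy(), 0.0)

    def test_single_otu_half_phenotype(self):
        """A = 1, P = 0.5: sigma is the Bernoulli standard deviation, 50%."""
        cpm = simple_cpm({"o1": 0.5})
        counts = pd.DataFrame({"s": [9.0]}, index=cpm.index)
        assert np.allclose(compute_error(cpm, counts).to_numpy(), 50.0)

    def test_error_vanishes_with_many_small_otus(self):
        for n in (10, 100, 1000):
            cpm = simple_cpm({f"o{i}": 0.5 for i in range(n)})
            counts = pd.DataFrame({"s": np.ones(n)}, index=cpm.index)
            sigma = compute_error(cpm, counts).loc["s"].iloc[0]
            assert sigma == pytest.approx(50.0 / np.sqrt(n))
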