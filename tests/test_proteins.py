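"""Mutation sampling, expression rules and channel rendering."""

import numpy as np
import pytest

from msiplex.proteins import (ConfigurationError, MissingCompartmentError,
                              assign_expression, compartment_profile,
                              lost_proteins, procedural_texture,
                              render_channel, sample_mutation_status)
from msiplex.raster import rasterize_sample


class TestLostProteins:
    @pytest.mark.parametrize("gene,expected", [
        ("MLH1", {"MLH1", "PMS2"}),   # MLH1-PMS2 heterodimer
        ("PMS2", {"PMS2"}),
        ("MSH2", {"MSH2", "MSH6"}),   # MSH2-MSH6 heterodimer
        ("MSH6", {"MSH6"}),
        ("none", set()),
    ])
    def test_epistasis_table(self, gene, expected):
        assert lost_proteins(gene) == expected

    def test_unknown_gene_rejected(self):
        with pytest.raises(ConfigurationError):
            lost_proteins("BRCA1")


class TestSampleMutationStatus:
    def test_override_is_deterministic(self, rng):
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "MSH2"}, rng=rng)
        assert status.mutated_gene == "MSH2"

    def test_unknown_override_gene_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_mutation_status(user_overrides={"mutated_gene": "KRAS"},
                                   rng=rng)

    def test_non_representative_needs_gene(self, rng):
        with pytest.raises(ConfigurationError):
            sample_mutation_status(population_representative=False, rng=rng)

    def test_pten_fraction_bounds(self, rng):
        fracs = [sample_mutation_status(rng=rng).pten_stromal_fraction
                 for _ in range(300)]
        assert min(fracs) >= 0.30 and max(fracs) <= 0.70

    def test_p53_fraction_tracks_overexpression_flag(self, rng):
        for _ in range(300):
            s = sample_mutation_status(rng=rng)
            f = s.epithelial_fraction["P53"]
            if s.p53_overexpressed:
                assert f > 0.5
            else:
                assert f <= 0.5


class TestAssignExpression:
    def test_mutated_gene_silences_epithelium_not_stroma(self, small_scaffold,
                                                         rng):
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "MLH1"}, rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        epi = {c.cell_id for c in small_scaffold.cells
               if c.phenotype in ("epithelial", "goblet")}
        stromal = {c.cell_id for c in small_scaffold.cells
                   if c.phenotype == "stromal"}
        for protein in ("MLH1", "PMS2"):
            assert expr.expressors[protein] & epi == set()
            assert stromal <= expr.expressors[protein]

    def test_full_fractions_express_everywhere(self, small_scaffold, rng):
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "none",
                            "epithelial_fraction": {p: 1.0 for p in
                                                    ("MLH1", "PMS2", "MSH2",
                                                     "MSH6")}},
            rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        all_ids = {c.cell_id for c in small_scaffold.cells}
        for protein in ("MLH1", "PMS2", "MSH2", "MSH6"):
            assert expr.expressors[protein] == all_ids

    def test_heterodimer_subset_rules_always_hold(self, small_scaffold):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            status = sample_mutation_status(rng=rng)
            expr = assign_expression(small_scaffold, status, rng)
            assert expr.expressors["PMS2"] <= expr.expressors["MLH1"]
            assert expr.expressors["MSH6"] <= expr.expressors["MSH2"]

    def test_p53_never_stromal(self, small_scaffold, rng):
        stromal = {c.cell_id for c in small_scaffold.cells
                   if c.phenotype == "stromal"}
        for _ in range(10):
            status = sample_mutation_status(rng=rng)
            expr = assign_expression(small_scaffold, status, rng)
            assert expr.expressors["P53"] & stromal == set()


class TestCompartmentProfile:
    def test_mlh1_nucleolar_dominant(self):
        profile = compartment_profile("MLH1")
        assert profile["nucleoli"] == "strong"
        assert profile["nucleus"] == "weak"

    def test_p53_single_compartment(self):
        assert compartment_profile("P53") == {
            "nucleus_minus_nucleoli": "strong"}

    @pytest.mark.parametrize("protein", ["MLH1", "PMS2", "MSH2", "MSH6",
                                         "P53", "PTEN"])
    def test_every_profile_non_empty(self, protein):
        assert compartment_profile(protein)

    def test_unknown_protein_rejected(self):
        with pytest.raises(ConfigurationError):
            compartment_profile("KI67")


class TestProceduralTexture:
    def test_zero_amplitude_constant(self):
        t = procedural_texture((64, 64), params={"amplitude": 0.0},
                               rng=np.random.default_rng(1))
        assert np.allclose(t, t.flat[0])

    def test_deterministic_under_seed(self):
        a = procedural_texture((128, 128), rng=np.random.default_rng(5))
        b = procedural_texture((128, 128), rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("kind", ["smooth_noise", "chromatin"])
    def test_mean_in_mid_band(self, kind):
        t = procedural_texture((256, 256), kind,
                               rng=np.random.default_rng(2))
        assert 0.3 <= t.mean() <= 0.7
        assert t.min() >= 0.0 and t.max() <= 1.0

    def test_power_spectrum_decays_with_frequency(self):
        t = procedural_texture((256, 256), rng=np.random.default_rng(3))
        spectrum = np.abs(np.fft.fftshift(np.fft.fft2(t - t.mean()))) ** 2
        y, x = np.indices(spectrum.shape)
        r = np.hypot(y - 128, x - 128)
        edges = [1, 4, 8, 16, 32, 64, 110]
        power = [spectrum[(r >= a) & (r < b)].mean()
                 for a, b in zip(edges[:-1], edges[1:])]
        assert all(a > b for a, b in zip(power[:-1], power[1:]))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            procedural_texture((32, 32), kind="perlin",
                               rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def rasters(small_scaffold, small_scaffold_organelles):
    return rasterize_sample(small_scaffold, small_scaffold_organelles)


class TestRenderChannel:
    def test_no_expressors_gives_blank_image(self, small_scaffold,
                                             small_scaffold_organelles,
                                             rasters):
        rng = np.random.default_rng(4)
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "MLH1"}, rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        expr.expressors["MLH1"] = set()  # not even stromal cells
        img = render_channel("MLH1", small_scaffold,
                             small_scaffold_organelles, expr, rng,
                             rasters=rasters)
        assert img.max() == 0.0

    def test_mutated_channel_stromal_only(self, small_scaffold,
                                          small_scaffold_organelles, rasters):
        rng = np.random.default_rng(4)
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "MLH1"}, rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        img = render_channel("MLH1", small_scaffold,
                             small_scaffold_organelles, expr, rng,
                             rasters=rasters)
        epi = [c.cell_id for c in small_scaffold.cells
               if c.phenotype in ("epithelial", "goblet")]
        stromal = [c.cell_id for c in small_scaffold.cells
                   if c.phenotype == "stromal"]
        assert img[np.isin(rasters.cell_labels, epi)].max() == 0.0
        assert img[np.isin(rasters.cell_labels, stromal)].mean() > 0.0

    def test_nucleolar_contrast_in_expressing_cells(self, small_scaffold,
                                                    small_scaffold_organelles,
                                                    rasters):
        rng = np.random.default_rng(6)
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "none",
                            "epithelial_fraction": {"MLH1": 1.0}}, rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        img = render_channel("MLH1", small_scaffold,
                             small_scaffold_organelles, expr, rng,
                             rasters=rasters)
        nucleoli = rasters.organelle_labels["nucleoli"] > 0
        nucleus_rest = (rasters.nucleus_labels > 0) & ~nucleoli
        assert img[nucleoli].mean() > img[nucleus_rest].mean()

    def test_missing_organelle_layer_names_compartment(self, small_scaffold,
                                                       rng):
        bare = rasterize_sample(small_scaffold, organelles=None)
        status = sample_mutation_status(
            user_overrides={"mutated_gene": "none"}, rng=rng)
        expr = assign_expression(small_scaffold, status, rng)
        with pytest.raises(MissingCompartmentError, match="nucleoli"):
            render_channel("MLH1", small_scaffold, {}, expr, rng,
                           rasters=bare)
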