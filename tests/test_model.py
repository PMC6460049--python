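import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from nksig.lattice import build_lattice
from nksig.model import (
    SFK,
    SFK_CL,
    CONSERVED_GROUPS,
    KIR_STATES,
    ClusterScalingRule,
    MissingParameterError,
    ModelVariant,
    PeptideDose,
    Variant,
    build_model,
    cluster_edge_for_dose,
    geometry_from_params,
    initial_state,
    reaction_network,
    rule_from_params,
)


class TestModelVariant:
    def test_model1_features(self):
        v = ModelVariant(Variant.MODEL1)
        assert not v.sfk_coclustered and v.trans_dephos_reaction

    def test_model2_features(self):
        v = ModelVariant(Variant.MODEL2)
        assert v.sfk_coclustered and not v.trans_dephos_reaction

    def test_trans_channel_in_model2_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant(Variant.MODEL2, trans_dephos_reaction=True)

    def test_coclustering_in_model1_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant(Variant.MODEL1, sfk_coclustered=True)


class TestPeptideDose:
    def test_mixed_doses_must_sum_to_total(self):
        with pytest.raises(ValueError):
            PeptideDose(L7R_uM=5.0, L7D_uM=6.0, mode="mixed")  # 11 uM total

    def test_mixed_constructor_balances(self):
        d = PeptideDose.mixed(5.0)
        assert d.L7D_uM == pytest.approx(7.5)

    def test_single_mode_has_no_antagonist(self):
        with pytest.raises(ValueError):
            PeptideDose(L7R_uM=5.0, L7D_uM=1.0, mode="single")


class TestReactionNetwork:
    def test_variants_differ_exactly_by_trans_channel(self, reference_params):
        p = reference_params.values
        rx1 = {r.name for r in reaction_network(Variant.MODEL1, p)}
        rx2 = {r.name for r in reaction_network(Variant.MODEL2, p)}
        extra = rx1 - rx2
        assert rx2 < rx1
        assert all(name.startswith("trans_dephos") for name in extra)

    def test_shared_reactions_identical(self, reference_params):
        p = reference_params.values
        rx1 = {r.name: r for r in reaction_network(Variant.MODEL1, p)}
        rx2 = {r.name: r for r in reaction_network(Variant.MODEL2, p)}
        for name in rx2:
            assert rx1[name] == rx2[name]

    def test_printed_affinities_set_unbinding_rates(self, reference_params):
        rx = {r.name: r for r in reaction_network(Variant.MODEL2, reference_params.values)}
        assert rx["unbind:KIR_L7R"].rate == pytest.approx(0.8)
        assert rx["unbind:KIR_L7D"].rate == pytest.approx(4.4)
        assert rx["unbind:AR_L"].rate == pytest.approx(5.0)

    def test_missing_parameters_named(self, reference_params):
        p = {"geometry": dict(reference_params.values["geometry"])}
        with pytest.raises(MissingParameterError) as err:
            reaction_network(Variant.MODEL1, p)
        assert "binding.L7R.KD_uM" in str(err.value)


class TestClusterScaling:
    RULE = ClusterScalingRule()  # 0.2 -> 1.0 um over 0 -> 12.5 uM

    def test_no_antagonist_keeps_tight_cluster(self):
        assert cluster_edge_for_dose(0.0, self.RULE, 0.02) == pytest.approx(0.2)

    def test_max_dose_reaches_max_edge(self):
        assert cluster_edge_for_dose(12.5, self.RULE, 0.02) == pytest.approx(1.0)

    def test_fixed_rule_is_dose_independent(self):
        rule = ClusterScalingRule.fixed(0.2)
        for dose in (0.0, 5.0, 12.5):
            assert cluster_edge_for_dose(dose, rule, 0.02) == pytest.approx(0.2)

    def test_dose_beyond_grid_rejected(self):
        with pytest.raises(ValueError):
            cluster_edge_for_dose(13.0, self.RULE, 0.02)

    def test_edge_snaps_to_chamber_multiples(self):
        edge = cluster_edge_for_dose(5.0, self.RULE, 0.25)
        assert edge / 0.25 == pytest.approx(round(edge / 0.25))

    @settings(max_examples=100, derandomize=True)
    @given(d1=st.floats(0, 12.5), d2=st.floats(0, 12.5))
    def test_edge_monotone_in_dose(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert cluster_edge_for_dose(lo, self.RULE, 0.02) <= \
            cluster_edge_for_dose(hi, self.RULE, 0.02) + 1e-12

    def test_linear_area_interpolation_monotone(self):
        rule = ClusterScalingRule(interpolation="linear_area")
        edges = [cluster_edge_for_dose(d, rule, 0.02) for d in (0, 4, 8, 12.5)]
        assert edges == sorted(edges)
        assert edges[0] == pytest.approx(0.2) and edges[-1] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def lattice(desk_params):
    return build_lattice(geometry_from_params(desk_params.values))


class TestInitialState:

    def _counts(self, desk_params, lattice, variant, dose, seed=0):
        rule = rule_from_params(desk_params.values)
        counts, conf, edge = initial_state(variant, dose, rule, lattice,
                                           desk_params.values, seed=seed)
        return counts, conf, edge

    def test_kir_confined_to_tight_cluster(self, desk_params, lattice):
        counts, conf, edge = self._counts(desk_params, lattice, Variant.MODEL2,
                                          PeptideDose.single(5.0))
        names = [s for s in CONSERVED_GROUPS["KIR_total"]]
        from nksig.model import species_catalog
        idx = {sp.name: i for i, sp in enumerate(species_catalog(desk_params.values))}
        kir = counts[:, idx["KIR"]]
        inside = conf["KIR"]
        assert kir[~inside].sum() == 0
        assert kir.sum() == desk_params.get("copy_numbers.KIR")

    def test_model1_sfk_is_spatially_uniform(self, desk_params, lattice):
        counts, _, _ = self._counts(desk_params, lattice, Variant.MODEL1,
                                    PeptideDose.single(5.0))
        from nksig.model import species_catalog
        idx = {sp.name: i for i, sp in enumerate(species_catalog(desk_params.values))}
        sfk = counts[:, idx[SFK]]
        assert counts[:, idx[SFK_CL]].sum() == 0
        assert chisquare(sfk + 1e-9).pvalue > 0.01 or sfk.std() <= 1

    def test_model2_splits_sfk_between_cluster_and_bulk(self, desk_params, lattice):
        counts, conf, _ = self._counts(desk_params, lattice, Variant.MODEL2,
                                       PeptideDose.single(0.0))
        from nksig.model import species_catalog
        idx = {sp.name: i for i, sp in enumerate(species_catalog(desk_params.values))}
        n_cl = counts[:, idx[SFK_CL]].sum()
        n_free = counts[:, idx[SFK]].sum()
        frac = desk_params.get("cluster.sfk_cluster_fraction")
        total = desk_params.get("copy_numbers.SFK")
        assert n_cl + n_free == total
        assert n_cl == round(frac * total)
        assert counts[~conf[SFK_CL], idx[SFK_CL]].sum() == 0

    def test_totals_invariant_across_doses(self, desk_params, lattice):
        from nksig.model import species_catalog
        idx = {sp.name: i for i, sp in enumerate(species_catalog(desk_params.values))}
        totals = []
        for dose in (PeptideDose.mixed(0.0), PeptideDose.mixed(5.0),
                     PeptideDose.mixed(12.5)):
            counts, _, _ = self._counts(desk_params, lattice, Variant.MODEL2, dose)
            totals.append((counts[:, idx["KIR"]].sum(),
                           counts[:, idx[SFK]].sum() + counts[:, idx[SFK_CL]].sum()))
        assert len(set(totals)) == 1

    def test_cluster_density_dilutes_with_antagonist(self, desk_params, lattice):
        # same KIR copy number spread over a larger region at higher L7D
        _, conf_lo, edge_lo = self._counts(desk_params, lattice, Variant.MODEL2,
                                           PeptideDose.mixed(12.5))  # L7D = 0
        _, conf_hi, edge_hi = self._counts(desk_params, lattice, Variant.MODEL2,
                                           PeptideDose.mixed(0.0))  # L7D = 12.5
        assert edge_hi > edge_lo
        assert conf_hi["KIR"].sum() > conf_lo["KIR"].sum()

    def test_pvav1_starts_at_zero(self, desk_params, lattice):
        counts, _, _ = self._counts(desk_params, lattice, Variant.MODEL1,
                                    PeptideDose.single(12.5))
        from nksig.model import species_catalog
        idx = {sp.name: i for i, sp in enumerate(species_catalog(desk_params.values))}
        assert counts[:, idx["pVAV1"]].sum() == 0


class TestBuildModel:
    def test_ligand_counts_at_printed_box_volume(self, reference_params):
        m = build_model(Variant.MODEL2, PeptideDose.mixed(5.0),
                        params=reference_params.values)
        names = [sp.name for sp in m.species]
        assert m.initial_counts[:, names.index("HLA_L7R")].sum() == 241
        assert m.initial_counts[:, names.index("HLA_L7D")].sum() == 361

    def test_single_mode_has_no_antagonist_ligand(self, reference_params):
        m = build_model(Variant.MODEL2, PeptideDose.single(5.0),
                        params=reference_params.values)
        names = [sp.name for sp in m.species]
        assert m.initial_counts[:, names.index("HLA_L7R")].sum() == 241
        assert m.initial_counts[:, names.index("HLA_L7D")].sum() == 0

    def test_incomplete_params_raise_named_error(self):
        with pytest.raises(MissingParameterError):
            build_model(Variant.MODEL1, PeptideDose.single(1.0), params={})

    def test_variants_share_everything_but_trans_and_sfk(self, desk_params):
        m1 = build_model(Variant.MODEL1, PeptideDose.mixed(5.0),
                         params=desk_params.values, seed=0)
        m2 = build_model(Variant.MODEL2, PeptideDose.mixed(5.0),
                         params=desk_params.values, seed=0)
        names = [sp.name for sp in m1.species]
        extra = {r.name for r in m1.reactions} - {r.name for r in m2.reactions}
        assert all(n.startswith("trans_dephos") for n in extra)
        differing = [
            n for n in names
            if not np.array_equal(m1.initial_counts[:, names.index(n)],
                                  m2.initial_counts[:, names.index(n)])
        ]
        # only the kinase placement differs (one pool split into two states)
        assert set(differing) <= {SFK, SFK_CL}
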