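import io
import math

import numpy as np
import pandas as pd
import pytest

from flavoscreen import descriptors_2d as d2
from flavoscreen.compound_io import ConfigurationError

from conftest import make_graph, random_graph


class TestBuildGraph:
    def test_propane_distance(self):
        g = d2.build_graph("CCC")
        assert g.dist[0, 2] == 2

    def test_benzene_diameter(self):
        assert d2.build_graph("c1ccccc1").diameter == 3

    def test_quercetin_heavy_atoms(self):
        g = d2.build_graph("O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12")
        assert g.n == 22

    def test_disconnected_fragments_infinite(self):
        g = d2.build_graph("CCO.CC")
        assert not np.isfinite(g.dist[0, 3])

    def test_distance_matrix_metric(self):
        g = d2.build_graph("OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1")
        d = g.dist
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        for i in range(g.n):
            for j in range(g.n):
                for k in range(g.n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestAutocorrelation:
    def test_path3_lag1(self):
        g = make_graph(3, [(0, 1), (1, 2)], weights=[1, 2, 3])
        assert d2.ats(g, 1) == pytest.approx(8.0)  # 1*2 + 2*3

    def test_path3_lag2(self):
        g = make_graph(3, [(0, 1), (1, 2)], weights=[1, 2, 3])
        assert d2.ats(g, 2) == pytest.approx(3.0)  # 1*3

    def test_beyond_diameter_zero(self):
        g = make_graph(3, [(0, 1), (1, 2)], weights=[1, 2, 3])
        assert d2.ats(g, 5) == 0.0

    def test_aats_path3(self):
        g = make_graph(3, [(0, 1), (1, 2)], weights=[1, 2, 3])
        assert d2.aats(g, 1) == pytest.approx(4.0)  # 8 / 2 pairs

    def test_aats_uniform_weights(self):
        g = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)], weights=[3] * 5)
        for k in (1, 2, 3, 4):
            assert d2.aats(g, k) == pytest.approx(9.0)

    def test_aats_missing_beyond_diameter(self):
        g = make_graph(3, [(0, 1), (1, 2)])
        assert math.isnan(d2.aats(g, 7))

    def test_unknown_weight(self):
        g = make_graph(2, [(0, 1)])
        with pytest.raises(ConfigurationError):
            d2.ats(g, 1, weight="charge")

    def test_bruteforce_oracle_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_graph(rng)
            k = int(rng.integers(1, 6))
            # oracle: explicit double loop over the distance matrix
            w = np.array([a.mass for a in g.atoms])
            expected = 0.0
            pairs = 0
            for i in range(g.n):
                for j in range(i + 1, g.n):
                    if g.dist[i, j] == k:
                        expected += w[i] * w[j]
                        pairs += 1
            assert d2.ats(g, k, "mass") == pytest.approx(expected)
            if pairs:
                assert d2.aats(g, k, "mass") == pytest.approx(expected / pairs)
            else:
                assert math.isnan(d2.aats(g, k, "mass"))


class TestNeighborhoodClasses:
    def test_benzene_single_class(self):
        g = d2.build_graph("c1ccccc1")
        for k in (0, 1, 2, 5):
            assert [len(c) for c in d2.neighborhood_classes(g, k)] == [6]

    def test_propane_k1(self):
        g = d2.build_graph("CCC")
        sizes = sorted(len(c) for c in d2.neighborhood_classes(g, 1))
        assert sizes == [1, 2]

    def test_refinement_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            g = random_graph(rng)
            previous = None
            for k in range(0, 5):
                classes = {frozenset(c) for c in d2.neighborhood_classes(g, k)}
                if previous is not None:
                    # every new class is contained in some old class
                    for cls in classes:
                        assert any(cls <= old for old in previous)
                previous = classes


class TestInformationContent:
    def test_two_even_classes(self):
        # 4 atoms in classes {2,2}: IC = 1 bit, CIC = log2(4) - 1 = 1
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)], elements=["C", "C", "C", "C"])
        # path graph P4 at k>=1: ends vs middles -> {2, 2}
        assert d2.ic(g, 1) == pytest.approx(1.0)
        assert d2.cic(g, 1) == pytest.approx(1.0)

    def test_all_equivalent(self):
        g = d2.build_graph("c1ccccc1")
        assert d2.ic(g, 3) == pytest.approx(0.0)
        assert d2.cic(g, 3) == pytest.approx(math.log2(6))

    def test_all_distinct_cic_zero(self):
        g = d2.build_graph("OC=N")  # O, C, N all distinguishable at k>=1
        assert d2.cic(g, 2) == pytest.approx(0.0, abs=1e-12)

    def test_identity_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = random_graph(rng)
            k = int(rng.integers(0, 5))
            assert d2.ic(g, k) + d2.cic(g, k) == pytest.approx(
                math.log2(g.n), abs=1e-12
            )

    def test_mic_refines_ic(self):
        # multiplicity-augmented initial labels can only split classes
        for smiles in ("O=c1cc(-c2ccccc2)oc2ccccc12", "CC(=O)OC", "C=CC#N"):
            g = d2.build_graph(smiles)
            for k in (0, 1, 2, 3):
                assert d2.mic(g, k) >= d2.ic(g, k) - 1e-12
                assert d2.mic(g, k) <= math.log2(g.n) + 1e-12


class TestEState:
    def test_propane_hand_computed(self):
        g = d2.build_graph("CCC")
        S = d2.estate_indices(g)
        # central carbon: I = 1.5; terminals I = 2
        assert S[1] == pytest.approx(1.25)
        assert S[0] == S[2] == pytest.approx(2.125)
        assert d2.min_estate(g, "ssCH2") == pytest.approx(1.25)

    def test_ethane_no_ssch2(self):
        assert math.isnan(d2.min_estate(d2.build_graph("CC"), "ssCH2"))

    def test_symmetric_atoms_equal(self):
        g = d2.build_graph("OCCCCO")
        S = d2.estate_indices(g)
        assert S[0] == pytest.approx(S[5])
        assert S[1] == pytest.approx(S[4])

    def test_perturbation_antisymmetry(self):
        rng = np.random.default_rng(5)
        for smiles in ("CCC", "CCO", "O=c1cc(-c2ccccc2)oc2ccccc12", "CC(C)(C)CO"):
            g = d2.build_graph(smiles)
            S = d2.estate_indices(g)
            I = d2.intrinsic_states(g)
            assert float(np.sum(S - I)) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_atom_error(self):
        with pytest.raises(ValueError):
            d2.estate_indices(d2.build_graph("[Na+].[Cl-]"))

    def test_unknown_atom_type(self):
        with pytest.raises(ConfigurationError):
            d2.min_estate(d2.build_graph("CCC"), "dddC")


class TestDescriptorVector:
    def test_benzene_cic3(self):
        vec_cic = d2.cic(d2.build_graph("c1ccccc1"), 3)
        assert vec_cic == pytest.approx(math.log2(6), abs=1e-3)

    def test_small_molecule_aats7m_missing(self):
        with pytest.warns(UserWarning, match="minssCH2"):
            vec = d2.compute_descriptor_vector("CC")
        assert math.isnan(vec["AATS7m"])

    def test_deterministic(self, reference):
        c = reference.by_cid(5280343)
        assert d2.compute_descriptor_vector(c) == d2.compute_descriptor_vector(c)

    def test_minssch2_imputed_with_warning(self):
        with pytest.warns(UserWarning, match="imputed"):
            vec = d2.compute_descriptor_vector("O=c1cc(-c2ccccc2)oc2ccccc12")
        assert vec["minssCH2"] == 0.0

    def test_table_for_reference(self, reference):
        with pytest.warns(UserWarning):
            table = d2.descriptor_table_for(reference)
        assert table.ids == reference.ids
        assert set(table.names) == set(d2.MODEL_2D_DESCRIPTORS)
        assert not np.isnan(table.values).any()  # all flavonoids span lag 7


class TestIngest:
    def test_well_formed(self):
        t = d2.ingest_descriptor_table("id,a,b\nx,1,2\ny,3,4\nz,5,6\n")
        assert t.ids == ["x", "y", "z"]
        assert t.names == ["a", "b"]

    def test_empty_cell_missing(self):
        t = d2.ingest_descriptor_table("id,a,b\nx,1,\ny,3,4\n")
        assert math.isnan(t.frame.loc["x", "b"])

    def test_duplicate_id(self):
        with pytest.raises(ValueError, match="duplicate"):
            d2.ingest_descriptor_table("id,a\nx,1\nx,2\n")

    def test_non_numeric_cell_named(self):
        with pytest.raises(ValueError, match="'b'"):
            d2.ingest_descriptor_table("id,a,b\nx,1,oops\n")


class TestClean:
    def test_zero_column_dropped(self):
        t = d2.ingest_descriptor_table("id,a,z\nx,1,0\ny,2,0\n")
        cleaned, dropped = d2.clean_descriptors(t)
        assert cleaned.names == ["a"]
        assert dropped["z"] == "all zeros"

    def test_constant_column_dropped(self):
        t = d2.ingest_descriptor_table("id,a,c\nx,1,5.0\ny,2,5.0\n")
        cleaned, dropped = d2.clean_descriptors(t)
        assert cleaned.names == ["a"]
        assert dropped["c"] == "constant column"

    def test_blank_column_dropped(self):
        t = d2.ingest_descriptor_table("id,a,b\nx,1,\ny,2,\n")
        cleaned, dropped = d2.clean_descriptors(t)
        assert dropped["b"] == "blank column"

    def test_varying_table_unchanged(self):
        t = d2.ingest_descriptor_table("id,a,b\nx,1,9\ny,2,4\nz,3,1\n")
        cleaned, dropped = d2.clean_descriptors(t)
        assert cleaned.names == ["a", "b"]
        assert not dropped

    def test_all_dropped_error(self):
        t = d2.ingest_descriptor_table("id,a\nx,0\ny,0\n")
        with pytest.raises(ValueError, match="degenerate"):
            d2.clean_descriptors(t)

    def test_no_missing_after_clean(self):
        t = d2.ingest_descriptor_table("id,a,b\nx,1,\ny,2,4\nz,3,5\n")
        cleaned, _ = d2.clean_descriptors(t)
        assert not np.isnan(cleaned.values).any()


class TestCorrelationFilter:
    def test_identical_columns(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        filtered, dropped = d2.correlation_filter(d2.DescriptorTable(frame))
        assert len(dropped) == 1
        assert dropped[0] in ("a", "b")
        assert "c" in filtered.names

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(100)
        frame = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        filtered, dropped = d2.correlation_filter(d2.DescriptorTable(frame))
        assert not dropped
        corr = filtered.frame.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9

    def test_postcondition_random(self):
        rng = np.random.default_rng(8)
        latent = rng.standard_normal(50)
        frame = pd.DataFrame(
            {f"d{i}": 0.97 * latent + 0.2 * rng.standard_normal(50) for i in range(8)}
        )
        filtered, dropped = d2.correlation_filter(d2.DescriptorTable(frame), 0.9)
        corr = filtered.frame.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.9
        assert dropped  # the latent mix guarantees offending pairs

    def test_threshold_domain(self):
        t = d2.DescriptorTable(pd.DataFrame({"a": [1.0, 2]}))
        with pytest.raises(ValueError):
            d2.correlation_filter(t, 0.0)
        with pytest.raises(ValueError):
            d2.correlation_filter(t, 1.5)
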