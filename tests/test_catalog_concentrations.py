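"""Compound catalog invariants and concentration-matrix I/O."""

import numpy as np
import pandas as pd
import pytest

from soilpah.catalog import Compound, CompoundCatalog, default_catalog, read_catalog_csv
from soilpah.concentrations import ConcentrationMatrix, read_concentration_table, substitute_below_mdl


class TestCatalog:
    def test_structure(self, catalog):
        assert len(catalog) == 16
        assert len(set(catalog.abbreviations)) == 16
        assert all(c.tef > 0 for c in catalog)
        assert all(2 <= c.ring_count <= 6 for c in catalog)
        assert catalog.compounds[catalog.index("BaP")].tef == 1.0
        assert catalog.compounds[catalog.index("DBahA")].tef == 1.0
        assert catalog.compounds[catalog.index("Naph")].tef == 0.001

    def test_lmw_hmw_partition(self, catalog):
        lmw, hmw = catalog.lmw_indices(), catalog.hmw_indices()
        assert sorted(lmw + hmw) == list(range(16))
        assert {catalog.abbreviations[i] for i in lmw} == {"Naph", "Acy", "Ace", "Flu", "Phe", "Ant"}

    def test_invalid_compound_rejected(self):
        with pytest.raises(ValueError):
            Compound("x", "X", ring_count=7, tef=0.1)
        with pytest.raises(ValueError):
            Compound("x", "X", ring_count=4, tef=0.0)

    def test_wrong_size_rejected(self, catalog):
        with pytest.raises(ValueError):
            CompoundCatalog(catalog.compounds[:15])

    def test_overrides(self, catalog):
        c2 = catalog.with_overrides(mdl=2.5, error_fraction={"BaP": 0.2})
        assert all(c.mdl == 2.5 for c in c2)
        assert c2.compounds[c2.index("BaP")].error_fraction == 0.2
        assert c2.compounds[c2.index("Naph")].error_fraction == 0.1

    def test_catalog_csv_roundtrip(self, tmp_path):
        path = tmp_path / "cat.csv"
        pd.DataFrame({"abbreviation": ["BaP"], "mdl": [3.0]}).to_csv(path, index=False)
        cat = read_catalog_csv(path)
        assert cat.compounds[cat.index("BaP")].mdl == 3.0
        pd.DataFrame({"abbreviation": ["Nope"], "mdl": [3.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="Nope"):
            read_catalog_csv(path)


class TestConcentrationIO:
    def _frame(self, catalog, n=3, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(1, 100, size=(n, 16)), columns=catalog.abbreviations)
        df.insert(0, "sample_id", [f"S{i}" for i in range(n)])
        return df

    def test_roundtrip(self, catalog, tmp_path):
        df = self._frame(catalog)
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        m = read_concentration_table(path, catalog)
        assert m.n_samples == 3
        np.testing.assert_allclose(m.values, df[catalog.abbreviations].to_numpy())
        out = tmp_path / "c2.csv"
        m.write_csv(out)
        m2 = read_concentration_table(out, catalog)
        np.testing.assert_allclose(m2.values, m.values)

    def test_column_order_invariance(self, catalog, tmp_path):
        df = self._frame(catalog)
        canonical = tmp_path / "a.csv"
        permuted = tmp_path / "b.csv"
        df.to_csv(canonical, index=False)
        df[["sample_id"] + catalog.abbreviations[::-1]].to_csv(permuted, index=False)
        np.testing.assert_allclose(
            read_concentration_table(canonical, catalog).values,
            read_concentration_table(permuted, catalog).values,
        )

    def test_missing_column_error(self, catalog, tmp_path):
        df = self._frame(catalog).drop(columns=["BaP"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="BaP"):
            read_concentration_table(path, catalog)

    def test_negative_value_error(self, catalog, tmp_path):
        df = self._frame(catalog)
        df.loc[1, "Chr"] = -4.0
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Chr"):
            read_concentration_table(path, catalog)

    def test_non_numeric_error(self, catalog, tmp_path):
        df = self._frame(catalog).astype(object)
        df.loc[0, "Pyr"] = "oops"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Pyr"):
            read_concentration_table(path, catalog)


class TestBelowMdlSubstitution:
    def test_substitution_and_flags(self, catalog):
        values = np.full((2, 16), 5.0)
        values[0, 0] = 0.0  # below the 1.0 ng/g default MDL
        m = ConcentrationMatrix([f"S{i}" for i in range(2)], values, catalog)
        out = substitute_below_mdl(m)
        assert out.values[0, 0] == 0.5
        assert out.below_mdl[0, 0]
        assert not out.below_mdl[1, 0]
        # everything at/above MDL untouched
        np.testing.assert_array_equal(out.values[1], values[1])

    def test_identity_when_all_above(self, catalog):
        values = np.full((3, 16), 50.0)
        m = ConcentrationMatrix([f"S{i}" for i in range(3)], values, catalog)
        out = substitute_below_mdl(m)
        np.testing.assert_array_equal(out.values, values)
        assert not out.below_mdl.any()
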