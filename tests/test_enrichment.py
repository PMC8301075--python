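"""GMT parsing and hypergeometric over-representation arithmetic."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t21meta.enrichment import (
    GeneSet,
    GeneSetCollection,
    directional_enrichment,
    hypergeom_upper_tail,
    ora,
    read_gmt,
    write_gmt,
)
from t21meta.exceptions import ContractError, GMTParseError
from t21meta.simulate import simulate_studies, small_config, write_fixture_set


class TestGMT:
    def test_dedup_members_within_line(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(path)
        assert coll.sets[0].members == ["A", "B"]

    def test_empty_file_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert len(read_gmt(path)) == 0

    def test_trailing_empty_fields_ignored(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\tdesc\tA\tB\t\t\n")
        assert read_gmt(path).sets[0].members == ["A", "B"]

    def test_malformed_line_reports_lineno(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tA\nS2\tonly-desc\n")
        with pytest.raises(GMTParseError, match=":2"):
            read_gmt(path)

    def test_write_read_roundtrip(self, tmp_path):
        coll = GeneSetCollection(
            sets=[GeneSet("a", "da", ["X", "Y"]), GeneSet("b", "db", ["Z"])]
        )
        write_gmt(coll, tmp_path / "c.gmt")
        back = read_gmt(tmp_path / "c.gmt")
        assert [(s.name, s.description, s.members) for s in back.sets] == [
            ("a", "da", ["X", "Y"]),
            ("b", "db", ["Z"]),
        ]

    def test_fixture_gmt_roundtrips(self, tmp_path):
        write_fixture_set(tmp_path / "fx", small_config(seed=2))
        first = (tmp_path / "fx" / "gene_sets.gmt").read_text()
        coll = read_gmt(tmp_path / "fx" / "gene_sets.gmt")
        write_gmt(coll, tmp_path / "again.gmt")
        assert (tmp_path / "again.gmt").read_text() == first


def _enumerate_upper_tail(N, K, n, observed):
    """Exact P(X >= observed) by enumerating all C(N, n) draws (rational)."""
    hits = 0
    universe = range(N)
    in_set = set(range(K))
    for draw in itertools.combinations(universe, n):
        if len(in_set.intersection(draw)) >= observed:
            hits += 1
    return Fraction(hits, math.comb(N, n))


class TestHypergeometric:
    def test_matches_enumeration_small_universes(self):
        """Upper-tail p equals brute-force enumeration for N <= 20."""
        cases = [
            (10, 5, 4, 4),
            (10, 5, 4, 2),
            (12, 3, 6, 1),
            (15, 7, 5, 3),
            (20, 8, 6, 4),
            (20, 10, 10, 8),
            (9, 4, 4, 0),
            (16, 2, 8, 2),
        ]
        for N, K, n, obs in cases:
            exact = _enumerate_upper_tail(N, K, n, obs)
            assert hypergeom_upper_tail(obs, N, K, n) == pytest.approx(
                float(exact), rel=1e-10
            )

    def test_exhaustive_enumeration_example(self):
        # N=10, K=5, n=4, observed=4: C(5,4)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 10, 5, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_observed_is_one(self):
        assert hypergeom_upper_tail(0, 100, 10, 10) == 1.0

    @given(st.integers(2, 14), st.data())
    @settings(max_examples=40, deadline=None)
    def test_enumeration_property(self, N, data):
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(1, N - 1))
        obs = data.draw(st.integers(0, min(K, n)))
        exact = _enumerate_upper_tail(N, K, n, obs)
        assert hypergeom_upper_tail(obs, N, K, n) == pytest.approx(
            float(exact), rel=1e-9, abs=1e-15
        )


# the published enrichment table instance: background and list size implied by
# its own Expected column (Expected = size * n_deg / N)
TABLE_N = 27724
TABLE_NDEG = 2474
TABLE_ROWS = [
    # (size, observed, expected_2dp, ratio_2dp)
    ("microtubule cytoskeleton", 1164, 186, 103.88, 1.79),
    ("chromosome", 1014, 165, 90.49, 1.82),
    ("Golgi apparatus", 1516, 214, 135.29, 1.58),
    ("nucleolus", 939, 143, 83.80, 1.71),
    ("mitochondrion", 1555, 213, 138.77, 1.53),
]


def _table_instance(size, observed):
    """Build a synthetic universe/list/set realizing one published row."""
    universe = [f"u{i}" for i in range(TABLE_N)]
    members = universe[:size]
    # DEG list: `observed` genes inside the set, remainder outside
    degs = members[:observed] + universe[size : size + TABLE_NDEG - observed]
    coll = GeneSetCollection(sets=[GeneSet("s", "", members)])
    return degs, universe, coll


class TestORA:
    @pytest.mark.parametrize("name,size,observed,expected,ratio", TABLE_ROWS)
    def test_published_row_arithmetic(self, name, size, observed, expected, ratio):
        degs, universe, coll = _table_instance(size, observed)
        row = ora(degs, universe, coll).iloc[0]
        assert row["size"] == size
        assert row["observed"] == observed
        assert row["expected"] == pytest.approx(expected, abs=0.01)
        assert round(row["ratio"], 2) == ratio

    def test_zero_observed_row(self):
        universe = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection(sets=[GeneSet("s", "", universe[:10])])
        row = ora(universe[40:45], universe, coll).iloc[0]
        assert row["observed"] == 0
        assert row["p"] == 1.0
        assert row["ratio"] == 0.0

    def test_expected_over_size_constant(self, rng):
        """All rows of one analysis share the background DEG proportion."""
        universe = [f"g{i}" for i in range(500)]
        sets = [
            GeneSet(f"s{j}", "", list(rng.choice(universe, size=30 + 5 * j, replace=False)))
            for j in range(6)
        ]
        degs = list(rng.choice(universe, size=60, replace=False))
        table = ora(degs, universe, GeneSetCollection(sets=sets))
        props = table["expected"] / table["size"]
        np.testing.assert_allclose(props, 60 / 500, rtol=1e-12)

    def test_deg_outside_universe_raises_or_drops(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection(sets=[GeneSet("s", "", universe[:5])])
        with pytest.raises(ContractError):
            ora(["absent"], universe, coll)
        table = ora(["absent", "g0"], universe, coll, on_outside="drop")
        assert table.iloc[0]["observed"] == 1

    def test_adjusted_p_at_least_p_and_sorted(self, rng):
        universe = [f"g{i}" for i in range(300)]
        sets = [
            GeneSet(f"s{j}", "", list(rng.choice(universe, size=25, replace=False)))
            for j in range(8)
        ]
        degs = list(rng.choice(universe, size=40, replace=False))
        table = ora(degs, universe, GeneSetCollection(sets=sets))
        assert (table["adjusted_p"] >= table["p"]).all()
        assert (table["p"].diff().dropna() >= 0).all()


class TestDirectional:
    def _records(self, genes, included, direction):
        return pd.DataFrame({"gene": genes, "included": included, "direction": direction})

    def test_all_up_gives_empty_down(self):
        genes = [f"g{i}" for i in range(40)]
        rec = self._records(genes, [i < 10 for i in range(40)], ["up"] * 40)
        coll = GeneSetCollection(sets=[GeneSet("s", "", genes[:20])])
        out = directional_enrichment(rec, coll)
        assert (out["down"]["observed"] == 0).all()
        assert (out["down"]["p"] == 1.0).all()
        assert out["up"].iloc[0]["observed"] == 10

    def test_split_counts_partition_observed(self):
        genes = [f"g{i}" for i in range(60)]
        included = [i < 30 for i in range(60)]
        direction = ["up" if i % 2 == 0 else "down" for i in range(60)]
        rec = self._records(genes, included, direction)
        coll = GeneSetCollection(
            sets=[GeneSet("a", "", genes[:25]), GeneSet("b", "", genes[20:50])]
        )
        out = directional_enrichment(rec, coll)
        for _, row in out["all"].iterrows():
            assert row["n_up_members"] + row["n_down_members"] == row["observed"]

    def test_positional_set_enriched_in_up(self):
        """Synthetic trisomy run: the all-cis set leads the upregulated ORA."""
        from t21meta.de import run_de
        from t21meta.harmonize import harmonize_study
        from t21meta.meta import run_meta
        from t21meta.simulate import default_gene_sets

        cfg = small_config(seed=8, cis_fraction=0.05)
        studies, maps, truth = simulate_studies(cfg)
        harm = [harmonize_study(s, pm) for s, pm in zip(studies, maps)]
        rec, _ = run_meta([run_de(s) for s in harm])
        coll = GeneSetCollection(
            sets=[GeneSet(n, d, m) for n, d, m in default_gene_sets(truth, seed=8)]
        )
        out = directional_enrichment(rec, coll)
        top = out["up"].iloc[0]
        assert top["set"] == "chr21_positional"
        assert top["p"] < 1e-6
        assert (out["up"].iloc[0]["n_down_members"]) == 0
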