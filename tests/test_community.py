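"""Range estimation, species grouping and the Stevens per-plot statistic."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elevrange import (
    LoadError,
    classify_affinity,
    group_percentages,
    load_occurrences,
    species_ranges,
    stevens_profile,
)
from .conftest import make_occurrences, random_occurrences


def brute_force_mean_range(data, ranges, members=None):
    """Literal per-plot species loop, independent of the implementation."""
    size_of = dict(zip(ranges.species_id, ranges["size"]))
    out = []
    for i, pid in enumerate(data.plots.plot_id):
        sizes = []
        for sp in data.species:
            if data.matrix.loc[pid, sp] == 1 and sp in size_of:
                if members is None or sp in members:
                    sizes.append(size_of[sp])
        out.append(np.mean(sizes) if sizes else np.nan)
    return np.array(out)


class TestClassifyAffinity:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("East Asia", "temperate"),
            ("  central ASIA ", "temperate"),
            ("East Asia & North America", "temperate"),
            ("tropical Asia", "tropical"),
            ("Tropical Asia to Tropical Africa", "tropical"),
            ("Cosmopolitan", "cosmopolitan"),
        ],
    )
    def test_published_labels(self, label, expected):
        assert classify_affinity(label) == expected

    def test_unknown_label_warns_and_returns_unclassified(self):
        with pytest.warns(UserWarning, match="Mars"):
            assert classify_affinity("Mars lowlands") == "unclassified"


class TestSpeciesRanges:
    def test_size_is_max_minus_min_occupied_elevation(self):
        data = make_occurrences([2000, 2600, 3100], [[1], [1], [1]])
        r = species_ranges(data)
        assert r["size"].iloc[0] == 1100

    def test_singleton_species_has_zero_range(self):
        data = make_occurrences([2000, 3000], [[1], [0]])
        assert species_ranges(data)["size"].iloc[0] == 0

    def test_full_gradient_span(self):
        data = make_occurrences([1800, 3600, 5400], [[1], [0], [1]])
        assert species_ranges(data)["size"].iloc[0] == 3600

    def test_unrecorded_species_excluded(self):
        data = make_occurrences([2000, 3000], [[1, 0], [1, 0]])
        r = species_ranges(data)
        assert list(r.species_id) == ["s1"]

    def test_adding_a_plot_never_shrinks_a_range(self, rng):
        base = random_occurrences(rng, 12, 8)
        r0 = species_ranges(base).set_index("species_id")["size"]
        extra = make_occurrences(
            np.append(base.elevations, 7000.0),
            np.vstack([base.matrix.to_numpy(), (rng.random(8) < 0.5).astype(int)]),
        )
        r1 = species_ranges(extra).set_index("species_id")["size"]
        assert (r1.loc[r0.index] >= r0 - 1e-12).all()


class TestStevensProfile:
    def test_mean_of_present_species_sizes(self):
        data = make_occurrences([2500], [[1, 1, 1]])
        ranges = pd.DataFrame(
            {"species_id": ["s1", "s2", "s3"], "min_elev": 0, "max_elev": 0,
             "size": [1000.0, 2000.0, 3000.0]}
        )
        prof = stevens_profile(data, ranges)
        assert prof.mean_range_m.iloc[0] == 2000.0
        assert prof.n_species.iloc[0] == 3

    def test_empty_plot_is_missing_not_zero(self):
        data = make_occurrences([2000, 5000], [[1], [0]])
        ranges = species_ranges(data)
        prof = stevens_profile(data, ranges)
        assert prof.n_species.iloc[1] == 0
        assert np.isnan(prof.mean_range_m.iloc[1])

    def test_unknown_group_rejected(self, rng):
        data = random_occurrences(rng, 4, 3)
        with pytest.raises(ValueError, match="group"):
            stevens_profile(data, species_ranges(data), "alpine")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_species_loop(self, seed):
        rng = np.random.default_rng(seed)
        data = random_occurrences(rng, int(rng.integers(2, 10)), int(rng.integers(1, 12)))
        ranges = species_ranges(data)
        prof = stevens_profile(data, ranges)
        expected = brute_force_mean_range(data, ranges)
        got = prof.mean_range_m.to_numpy()
        assert ((got == expected) | (np.isnan(got) & np.isnan(expected))).all()

    def test_overall_reconstructs_from_life_form_groups(self, rng):
        data = random_occurrences(rng, 10, 14)
        ranges = species_ranges(data)
        traits = pd.DataFrame(
            {
                "species_id": data.species,
                "life_form": rng.choice(["woody", "herbaceous"], size=14),
                "areal_type": "east asia",
                "affinity": "temperate",
            }
        )
        overall = stevens_profile(data, ranges, "overall", traits)
        woody = stevens_profile(data, ranges, "woody", traits)
        herb = stevens_profile(data, ranges, "herbaceous", traits)
        # overall sum = woody sum + herbaceous sum per plot (exact partition)
        tot = np.nansum(
            [woody.n_species * woody.mean_range_m, herb.n_species * herb.mean_range_m],
            axis=0,
        )
        expect = overall.n_species * overall.mean_range_m
        np.testing.assert_allclose(np.nan_to_num(expect), tot, rtol=1e-12)


class TestGroupPercentages:
    def test_printed_survey_counts(self):
        traits = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(545)],
                "life_form": ["woody"] * 158 + ["herbaceous"] * 387,
                "affinity": ["temperate"] * 337 + ["tropical"] * 112 + ["cosmopolitan"] * 96,
                "areal_type": "",
            }
        )
        pct = group_percentages(traits).set_index("group")["percentage"]
        assert pct["woody"] == 28.99
        assert pct["herbaceous"] == 71.01
        assert pct["temperate"] == 61.83
        assert pct["tropical"] == 20.55

    def test_single_species(self):
        traits = pd.DataFrame(
            {"species_id": ["s1"], "life_form": ["woody"], "areal_type": ["East Asia"]}
        )
        pct = group_percentages(traits).set_index("group")["percentage"]
        assert pct["woody"] == 100.00


class TestLoadOccurrences:
    def _write(self, tmp_path, plots, matrix, traits):
        p, m, t = tmp_path / "p.csv", tmp_path / "m.csv", tmp_path / "t.csv"
        p.write_text(plots)
        m.write_text(matrix)
        t.write_text(traits)
        return p, m, t

    def test_roundtrip(self, tmp_path):
        p, m, t = self._write(
            tmp_path,
            "plot_id,elevation_m\na,2000\nb,3000\n",
            "plot_id,s1\na,1\nb,1\n",
            "species_id,life_form,areal_type\ns1,woody,East Asia\n",
        )
        data, traits = load_occurrences(p, m, t)
        assert data.matrix.shape == (2, 1)
        assert data.matrix.to_numpy().sum() == 2
        assert traits.affinity.iloc[0] == "temperate"

    def test_duplicate_plot_id_names_the_id(self, tmp_path):
        p, m, t = self._write(
            tmp_path,
            "plot_id,elevation_m\na,2000\na,3000\n",
            "plot_id,s1\na,1\na,0\n",
            "species_id,life_form,areal_type\ns1,woody,East Asia\n",
        )
        with pytest.raises(LoadError, match="'a'"):
            load_occurrences(p, m, t)

    def test_nonbinary_cell_names_coordinates(self, tmp_path):
        p, m, t = self._write(
            tmp_path,
            "plot_id,elevation_m\na,2000\nb,3000\n",
            "plot_id,s1\na,2\nb,0\n",
            "species_id,life_form,areal_type\ns1,woody,East Asia\n",
        )
        with pytest.raises(LoadError, match="'a'.*'s1'"):
            load_occurrences(p, m, t)

    def test_nonnumeric_elevation_names_row(self, tmp_path):
        p, m, t = self._write(
            tmp_path,
            "plot_id,elevation_m\na,high\nb,3000\n",
            "plot_id,s1\na,1\nb,0\n",
            "species_id,life_form,areal_type\ns1,woody,East Asia\n",
        )
        with pytest.raises(LoadError, match="high"):
            load_occurrences(p, m, t)

    def test_species_without_traits_kept_unclassified(self, tmp_path):
        p, m, t = self._write(
            tmp_path,
            "plot_id,elevation_m\na,2000\nb,3000\n",
            "plot_id,s1,s2\na,1,1\nb,1,0\n",
            "species_id,life_form,areal_type\ns1,woody,East Asia\n",
        )
        _, traits = load_occurrences(p, m, t)
        row = traits.set_index("species_id").loc["s2"]
        assert row.affinity == "unclassified"
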