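"""Mol% normalization and composition statistics against brute-force oracles."""

import math

import numpy as np
import pytest

from memlipid.lipidome import (
    OMEGA3_SET,
    OMEGA6_SET,
    FattyAcidSet,
    LipidomeSample,
    class_composition,
    condition_fold_change,
    exclude_set,
    fraction_containing,
    normalize,
    saturation_profile,
    species_contains,
    unsaturation_index,
)
from memlipid.nomenclature import chains_of, parse_species

from conftest import make_lipidome, random_species_table


def sample_from(table: dict[str, float], scale: float = 1.0) -> LipidomeSample:
    return LipidomeSample(
        "s1", {parse_species(n): v * scale for n, v in table.items()}
    )


class TestNormalize:
    def test_proportionality(self):
        lip = normalize(sample_from({"PC-34:1;0": 30, "PE-36:2;0": 70}), "all")
        vals = {s.name: v for s, v in lip.abundances.items()}
        assert vals == {"PC-34:1;0": 30.0, "PE-36:2;0": 70.0}

    def test_membrane_scope_drops_storage(self):
        lip = normalize(sample_from({"PC-34:1;0": 50, "TAG-52:2;0": 50}), "membrane")
        assert {s.name: v for s, v in lip.abundances.items()} == {"PC-34:1;0": 100.0}

    def test_five_species_membrane_renormalization(self, toy_membrane_table):
        # hand-computed: drop TAG (20 pmol), renormalize remaining 80 pmol
        lip = normalize(sample_from(toy_membrane_table), "membrane")
        vals = {s.name: v for s, v in lip.abundances.items()}
        assert vals["PC-34:1;0"] == pytest.approx(50.0)
        assert vals["PE-36:2;0"] == pytest.approx(25.0)
        assert vals["Chol"] == pytest.approx(18.75)
        assert vals["SM-34:1;1"] == pytest.approx(6.25)

    def test_gpl_scope_keeps_only_glycerophospholipids(self, toy_membrane_table):
        lip = normalize(sample_from(toy_membrane_table), "GPL")
        names = {s.name for s in lip.abundances}
        assert names == {"PC-34:1;0", "PE-36:2;0"}
        assert sum(lip.abundances.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_scope_errors(self):
        with pytest.raises(ValueError, match="scope"):
            normalize(sample_from({"TAG-52:2;0": 10.0}), "membrane")


class TestUnsaturationIndex:
    def test_degenerate_single_species(self):
        lip = make_lipidome({"PC-36:2;0": 100.0})
        assert unsaturation_index(lip).value == pytest.approx(2.0)

    def test_symmetric_mixture(self):
        lip = make_lipidome({"PC-32:0;0": 50.0, "PC-40:6;0": 50.0})
        assert unsaturation_index(lip).value == pytest.approx(3.0)

    def test_weighted_mean(self):
        # 0.5*1 + 0.25*4 + 0.25*0 = 1.5
        lip = make_lipidome({"PC-34:1;0": 50.0, "PC-36:4;0": 25.0, "PC-32:0;0": 25.0})
        assert unsaturation_index(lip).value == pytest.approx(1.5)

    def test_cholesterol_excluded(self):
        lip = make_lipidome({"PC-36:2;0": 50.0, "Chol": 50.0})
        res = unsaturation_index(lip)
        assert res.value == pytest.approx(2.0)
        assert res.n_species == 1

    def test_scale_invariance(self):
        table = {"PC-34:1;0": 40, "PE-36:2;0": 35, "PS-40:6;0": 25}
        a = unsaturation_index(normalize(sample_from(table), "all")).value
        b = unsaturation_index(normalize(sample_from(table, scale=7.3), "all")).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_adding_saturated_species_never_increases_index(self):
        base = {"PC-34:1;0": 60.0, "PE-36:2;0": 40.0}
        before = unsaturation_index(make_lipidome(base)).value
        heavier = normalize(
            sample_from({**base, "PC-32:0;0": 30.0}), "all"
        )
        assert unsaturation_index(heavier).value <= before


class TestExcludeAndFraction:
    def test_dha_set_removal(self):
        lip = make_lipidome({"PC-16:0;0-22:6;0": 15.0, "PC-34:1;0": 85.0})
        out = exclude_set(lip, OMEGA3_SET)
        assert {s.name: v for s, v in out.abundances.items()} == {"PC-34:1;0": 100.0}

    def test_empty_overlap_is_identity(self):
        lip = make_lipidome({"PC-34:1;0": 60.0, "PE-36:2;0": 40.0})
        out = exclude_set(lip, OMEGA3_SET)
        assert {s.name: v for s, v in out.abundances.items()} == {
            s.name: v for s, v in lip.abundances.items()
        }

    def test_renormalization_after_partial_removal(self):
        # two 22:6-containing species at 10 mol% each -> rest scaled by 1/0.8
        table = {
            "PC-16:0;0-22:6;0": 10.0,
            "PE-18:0;0-22:6;0": 10.0,
            "PC-34:1;0": 30.0,
            "PE-36:2;0": 25.0,
            "PS-36:1;0": 15.0,
            "PI-38:4;0": 10.0,
        }
        out = exclude_set(make_lipidome(table), OMEGA3_SET)
        vals = {s.name: v for s, v in out.abundances.items()}
        assert vals["PC-34:1;0"] == pytest.approx(30.0 / 0.8)
        assert sum(vals.values()) == pytest.approx(100.0, abs=1e-9)

    def test_exclusion_emptying_lipidome_errors(self):
        lip = make_lipidome({"PC-16:0;0-22:6;0": 100.0})
        with pytest.raises(ValueError, match="removed every lipid"):
            exclude_set(lip, OMEGA3_SET)

    def test_fraction_after_exclusion_is_zero(self):
        table = {"PC-16:0;0-22:6;0": 20.0, "PC-34:1;0": 80.0}
        out = exclude_set(make_lipidome(table), OMEGA3_SET)
        assert fraction_containing(out, OMEGA3_SET) == 0.0

    def test_fraction_containing_additivity(self):
        lip = make_lipidome(
            {"PC-16:0;0-22:6;0": 12.0, "PE-18:0;0-20:5;0": 3.0, "PC-34:1;0": 85.0}
        )
        assert fraction_containing(lip, OMEGA3_SET) == pytest.approx(15.0)

    def test_fraction_bounds(self):
        allin = make_lipidome({"PC-16:0;0-22:6;0": 100.0})
        assert fraction_containing(allin, OMEGA3_SET) == pytest.approx(100.0)
        none = make_lipidome({"PC-34:1;0": 100.0})
        assert fraction_containing(none, OMEGA3_SET) == 0.0

    def test_sum_only_containment_rule(self):
        # lyso class forces the single chain; diacyl sum stays undetermined
        assert species_contains(parse_species("LPC-22:6;0"), OMEGA3_SET)
        assert not species_contains(parse_species("PC-44:12;0"), OMEGA3_SET)
        assert species_contains(parse_species("PE-18:0;0-20:4;0"), OMEGA6_SET)


class TestSaturationProfile:
    def test_fully_saturated_species(self):
        prof = saturation_profile(make_lipidome({"PC-16:0;0-16:0;0": 100.0}, "GPL"))
        assert prof.fully_saturated_species_pct == pytest.approx(100.0)
        assert prof.saturated_chain_pct == pytest.approx(100.0)

    def test_chain_enumeration(self):
        # chains: 16:0, 22:6, 16:0, 16:0 weighted 50/50 -> 75% saturated, 25% 5-6 db
        prof = saturation_profile(
            make_lipidome(
                {"PC-16:0;0-22:6;0": 50.0, "PC-16:0;0-16:0;0": 50.0}, "GPL"
            )
        )
        assert prof.saturated_chain_pct == pytest.approx(75.0)
        assert prof.high_unsat_chain_pct == pytest.approx(25.0)
        assert prof.fully_saturated_species_pct == pytest.approx(50.0)
        assert prof.unresolved_abundance_pct == pytest.approx(0.0)

    def test_distribution_thirds(self):
        third = 100.0 / 3.0
        prof = saturation_profile(
            make_lipidome(
                {"PC-32:0;0": third, "PC-36:2;0": third, "PE-36:3;0": 100 - 2 * third},
                "GPL",
            )
        )
        assert prof.distribution[0] == pytest.approx(third)
        assert prof.distribution[2] == pytest.approx(third)
        assert prof.distribution[3] == pytest.approx(third)
        assert sum(prof.distribution.values()) == pytest.approx(100.0, abs=1e-9)

    def test_unresolved_abundance_reported(self):
        prof = saturation_profile(
            make_lipidome({"PC-34:1;0": 40.0, "PC-16:0;0-18:1;0": 60.0}, "GPL")
        )
        assert prof.unresolved_abundance_pct == pytest.approx(40.0)


class TestClassCompositionAndFolds:
    def test_single_class(self):
        comp = class_composition(make_lipidome({"PC-34:1;0": 100.0}))
        assert comp == {"PC": pytest.approx(100.0)}

    def test_aggregation_identity(self):
        comp = class_composition(
            make_lipidome(
                {"PC-34:1;0": 40.0, "PE-36:2;0": 25.0, "Chol": 30.0, "SM-34:1;1": 5.0}
            )
        )
        assert comp["Chol"] == pytest.approx(30.0)
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)

    def test_groupby_sum(self):
        comp = class_composition(
            make_lipidome(
                {
                    "PC-34:1;0": 10.0,
                    "PC-36:2;0": 20.0,
                    "PC-32:0;0": 10.0,
                    "PE-36:2;0": 60.0,
                }
            )
        )
        assert comp["PC"] == pytest.approx(40.0)

    @pytest.mark.parametrize(
        "a, b, expected",
        [([15.0], [1.0], 15.0), ([3.0, 3.0], [3.0, 3.0], 1.0), ([14, 16, 18], [0.9, 1.0, 1.1], 16.0)],
    )
    def test_fold_change(self, a, b, expected):
        assert condition_fold_change(a, b).fold == pytest.approx(expected)

    def test_fold_change_zero_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            condition_fold_change([1.0], [0.0])

    def test_fold_change_dispersion_positive_with_noise(self):
        fc = condition_fold_change([14, 16, 18], [0.9, 1.0, 1.1])
        assert fc.sd > 0


class TestBruteForceOracle:
    """Statistics match an independent loop implementation on random tables."""

    @staticmethod
    def _oracle_stats(table: dict[str, float]):
        species = {n: parse_species(n) for n in table}
        total = sum(table.values())
        ui = sum(
            w * species[n].total_double_bonds for n, w in table.items()
        ) / total
        sat = 100.0 * sum(
            w for n, w in table.items() if species[n].total_double_bonds == 0
        ) / total
        frac = 100.0 * sum(
            w
            for n, w in table.items()
            if any(
                (c.carbons, c.double_bonds) in OMEGA3_SET.members
                for c in (chains_of(species[n]) or [])
            )
        ) / total
        return ui, sat, frac

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = random_species_table(rng, 20)
        lip = make_lipidome(table, "GPL")
        ui, sat, frac = self._oracle_stats(table)
        assert unsaturation_index(lip).value == pytest.approx(ui, rel=1e-10)
        assert saturation_profile(lip).fully_saturated_species_pct == pytest.approx(
            sat, rel=1e-10, abs=1e-10
        )
        assert fraction_containing(lip, OMEGA3_SET) == pytest.approx(
            frac, rel=1e-10, abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_exclude_then_sum_is_100(self, seed):
        rng = np.random.default_rng(100 + seed)
        lip = make_lipidome(random_species_table(rng, 20), "GPL")
        out = exclude_set(lip, OMEGA6_SET)
        assert sum(out.abundances.values()) == pytest.approx(100.0, abs=1e-9)
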