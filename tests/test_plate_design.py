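"""Enrichment-plate layout, screen combinatorics, and factorial analysis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import platescreen as ps
from platescreen.errors import InputError, InvariantError, ParameterError
from platescreen.plate_design import MainEffect


class TestEnrichmentLayout:
    def test_d5_is_tb_with_penicillin(self):
        layout = ps.enrichment_layout()
        c = layout.condition("D5")
        assert c.medium == "TB"
        assert c.antibiotic == "penicillinG"

    def test_b1_is_lb_without_antibiotic(self):
        c = ps.enrichment_layout().condition("B1")
        assert c.medium == "LB"
        assert c.antibiotic == "none"
        assert c.pH is None

    def test_a9_is_nb_with_kanamycin(self):
        c = ps.enrichment_layout().condition("A9")
        assert c.medium == "NB"
        assert c.antibiotic == "kanamycin"

    def test_antibiotic_determined_by_column_block(self):
        layout = ps.enrichment_layout()
        for well, cond in layout.wells:
            col = int(well[1:])
            expected = ("none", "penicillinG", "kanamycin")[(col - 1) // 4]
            assert cond.antibiotic == expected

    def test_media_grid_repeats_across_blocks(self):
        layout = ps.enrichment_layout()
        for row in "ABCDEFGH":
            for col in range(1, 5):
                base = layout.condition(f"{row}{col}")
                for block in (4, 8):
                    shifted = layout.condition(f"{row}{col + block}")
                    assert (shifted.medium, shifted.pH) == (base.medium, base.pH)

    def test_96_unique_wells(self):
        layout = ps.enrichment_layout()
        assert len(layout.wells) == 96
        assert len({w for w, _ in layout.wells}) == 96

    def test_buffered_ph_gradients(self):
        layout = ps.enrichment_layout()
        assert [layout.condition(f"{r}2").pH for r in "ABCD"] == [5.8, 6.5, 7.2, 8.0]
        assert [layout.condition(f"{r}4").pH for r in "EFGH"] == [5.8, 6.5, 7.2, 8.0]


class TestExpandScreen:
    def test_published_screen_dimensions(self):
        counts = ps.expand_screen(4, 96, 4)
        assert counts == (384, 16, 1536)

    def test_identity_case(self):
        assert ps.expand_screen(1, 1, 1) == (1, 1, 1)

    def test_agrees_with_explicit_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_e, wells, subs = (int(v) for v in rng.integers(1, 11, size=3))
            # enumerate the plates/cultures explicitly
            enrichment = [(p, w) for p in range(n_e) for w in range(wells)]
            plates = [(p, s) for p in range(n_e) for s in range(subs)]
            conditions = [(p, s, w) for p, s in plates for w in range(wells)]
            got = ps.expand_screen(n_e, wells, subs)
            assert got == (len(enrichment), len(plates), len(conditions))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(n_e=st.integers(1, 10), wells=st.integers(1, 10), subs=st.integers(1, 10))
    def test_multiplicative_property(self, n_e, wells, subs):
        counts = ps.expand_screen(n_e, wells, subs)
        assert counts.enrichment_cultures == n_e * wells
        assert counts.subculture_plates == n_e * subs
        assert counts.total_conditions == counts.subculture_plates * wells

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            ps.expand_screen(0, 96, 4)


class TestFullFactorial:
    def test_tb_design_has_27_formulations_with_reference_tb14(self):
        design = ps.full_factorial(ps.default_tb_factors())
        assert len(design.formulations) == 27
        assert design.reference_id == "TB14"
        assert design.levels("TB14") == {
            "tryptone": 12.0, "yeast_extract": 24.0, "glycerol": 4.0
        }

    def test_balance_each_level_appears_equally(self):
        design = ps.full_factorial(ps.default_tb_factors())
        for name, levels in design.factors:
            for lv in levels:
                count = sum(
                    1 for _, combo in design.formulations if dict(combo)[name] == lv
                )
                assert count == 9

    def test_single_factor_single_level(self):
        design = ps.full_factorial([("x", [1.0])])
        assert len(design.formulations) == 1
        assert design.reference_id == design.formulations[0][0]

    def test_matches_brute_force_enumeration(self):
        factors = [("a", (1.0, 2.0)), ("b", (10.0, 20.0))]
        design = ps.full_factorial(factors)
        expected = [
            (("a", a), ("b", b))
            for a, b in itertools.product((1.0, 2.0), (10.0, 20.0))
        ]
        assert [combo for _, combo in design.formulations] == expected

    def test_last_factor_varies_fastest(self):
        design = ps.full_factorial(ps.default_tb_factors())
        first_three = [dict(c)["glycerol"] for _, c in design.formulations[:3]]
        assert first_three == [1.0, 4.0, 8.0]

    def test_empty_factors_rejected(self):
        with pytest.raises(ParameterError):
            ps.full_factorial([])


def _table(rows, reference="TB14"):
    return ps.ResponseTable(records=tuple(rows), reference_id=reference)


class TestFoldChanges:
    def test_reference_fold_is_one(self):
        t = _table([("TB14", "s1", 1, 5.0), ("TB14", "s1", 2, 7.0)])
        assert ps.fold_changes(t) == {"TB14": 1.0}

    def test_hand_computed_two_fold(self):
        t = _table([
            ("TB14", "s1", 1, 10.0), ("TB14", "s1", 2, 30.0),   # mean 20
            ("TB01", "s1", 1, 35.0), ("TB01", "s1", 2, 45.0),   # mean 40
        ])
        folds = ps.fold_changes(t)
        assert folds["TB01"] == pytest.approx(2.0)
        assert folds["TB14"] == 1.0

    def test_record_order_irrelevant(self):
        rows = [("TB14", "s1", 1, 10.0), ("TB02", "s1", 1, 15.0),
                ("TB02", "s2", 1, 25.0), ("TB14", "s2", 1, 30.0)]
        assert ps.fold_changes(_table(rows)) == ps.fold_changes(_table(rows[::-1]))

    def test_scale_invariance(self):
        rows = [("TB14", "s1", 1, 10.0), ("TB03", "s1", 1, 26.0)]
        base = ps.fold_changes(_table(rows))
        scaled = ps.fold_changes(
            _table([(f, s, r, 13.0 * t) for f, s, r, t in rows])
        )
        for k in base:
            assert scaled[k] == pytest.approx(base[k])

    def test_zero_reference_mean_rejected(self):
        t = _table([("TB14", "s1", 1, 0.0), ("TB05", "s1", 1, 3.0)])
        with pytest.raises(InputError):
            ps.fold_changes(t)

    def test_missing_reference_rejected(self):
        t = _table([("TB05", "s1", 1, 3.0)])
        with pytest.raises(InputError):
            ps.fold_changes(t)

    def test_negative_titer_rejected(self):
        with pytest.raises(InvariantError):
            _table([("TB14", "s1", 1, -1.0)])


class TestMainEffects:
    def test_planted_negative_yeast_extract_effect_recovered(self):
        design = ps.full_factorial(ps.default_tb_factors())
        table = ps.simulate_factorial_response(
            design,
            effect_model={"yeast_extract": (1.0, 0.5, 0.25)},
            noise_sigma=0.05,
            seed=1,
        )
        effects = {e.factor: e for e in ps.main_effects(table, design)}
        assert effects["yeast_extract"].trend == "decreasing"

    def test_planted_positive_tryptone_effect_recovered(self):
        design = ps.full_factorial(ps.default_tb_factors())
        table = ps.simulate_factorial_response(
            design, effect_model={"tryptone": (0.5, 1.0, 2.0)},
            noise_sigma=0.05, seed=2,
        )
        effects = {e.factor: e for e in ps.main_effects(table, design)}
        assert effects["tryptone"].trend == "increasing"

    def test_constant_titers_are_non_monotone(self):
        design = ps.full_factorial(ps.default_tb_factors())
        rows = [(fid, "s1", 1, 5.0) for fid, _ in design.formulations]
        effects = ps.main_effects(_table(rows), design)
        assert all(e.trend == "non-monotone" for e in effects)

    def test_level_means_are_marginal_averages(self):
        design = ps.full_factorial([("a", (1.0, 2.0)), ("b", (1.0, 2.0))])
        # titer = 10*a + b, exactly linear
        rows = [
            (fid, "s1", 1, 10.0 * dict(c)["a"] + dict(c)["b"])
            for fid, c in design.formulations
        ]
        effects = {e.factor: e for e in ps.main_effects(
            _table(rows, reference=design.reference_id), design)}
        assert effects["a"].level_means == ((1.0, 11.5), (2.0, 21.5))
        assert effects["b"].level_means == ((1.0, 16.0), (2.0, 17.0))
        assert effects["a"].trend == "increasing"

    def test_missing_formulation_rejected(self):
        design = ps.full_factorial(ps.default_tb_factors())
        with pytest.raises(InputError):
            ps.main_effects(_table([("TB14", "s1", 1, 5.0)]), design)
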