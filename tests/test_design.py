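"""Design efficiency arithmetic, A-optimal generation and cost accounting."""

import itertools

import numpy as np
import pytest

from tricot import (
    CostSheet,
    Design,
    DesignSpec,
    DisconnectedError,
    ValidationError,
    a_score,
    canonical_efficiency,
    cost_effectiveness,
    cost_saving_percent,
    equivalent_units,
    generate_design,
    order_blocks_sequentially,
    random_balanced_design,
    readings_per_entry,
    relative_efficiency,
)


class TestClosedFormEfficiency:
    @pytest.mark.parametrize(
        "t,k,expected",
        [(11, 3, 11 / 10 * 2 / 3), (2, 2, 1.0), (6, 3, 0.8), (4, 3, 8 / 9)],
    )
    def test_values(self, t, k, expected):
        assert relative_efficiency(t, k) == pytest.approx(expected)

    def test_rounds_to_073_for_eleven_varieties(self):
        assert f"{relative_efficiency(11, 3):.2f}" == "0.73"

    @pytest.mark.parametrize("t,k", [(1, 1), (3, 4), (5, 1)])
    def test_domain_errors(self, t, k):
        with pytest.raises(ValidationError):
            relative_efficiency(t, k)


class TestEquivalentUnits:
    def test_rwanda_potato_case(self):
        assert round(equivalent_units(465, 11, 3)) == 341

    def test_complete_blocks_full_credit(self):
        assert equivalent_units(300, 6, 6) == pytest.approx(300)

    def test_six_items(self):
        assert equivalent_units(100, 6, 3) == pytest.approx(80.0)


class TestCostArithmetic:
    def test_cost_per_eeu(self):
        assert cost_effectiveness(1517.18, 341) == 4.45
        assert cost_effectiveness(1829.07, 300) == 6.10
        assert cost_effectiveness(0.0, 300) == 0.00

    def test_saving_percent(self):
        assert cost_saving_percent(4.45, 6.10) == 27
        assert cost_saving_percent(5.0, 5.0) == 0
        assert cost_saving_percent(3.05, 6.10) == 50
        with pytest.raises(ValidationError):
            cost_saving_percent(1.0, 0.0)

    def test_cost_sheet_total(self, tmp_path):
        path = tmp_path / "costs.csv"
        path.write_text(
            "category,amount\nSeeds,283.04\nFertilizer,25.28\nMaterial,390.58\n"
            "Transport,263.25\nAirtime,78.26\nLabor,476.77\n"
        )
        assert CostSheet.from_csv(path).total == 1517.18


class TestReadingsPerEntry:
    @pytest.mark.parametrize(
        "farms,items,expected", [(150, 12, 37), (12, 12, 3), (155, 11, 42)]
    )
    def test_values(self, farms, items, expected):
        assert readings_per_entry(farms, items, 3) == expected

    def test_fewer_items_than_block_rejected(self):
        with pytest.raises(ValidationError):
            readings_per_entry(10, 2, 3)


class TestGenerateDesign:
    def test_single_possible_triad(self):
        d = generate_design(DesignSpec(t=3, b=1, seed=0))
        assert len(d.blocks) == 1 and set(d.blocks[0]) == set(d.items)

    def test_four_items_four_blocks_is_bibd(self):
        """Brute force over all multisets of four 3-subsets of a 4-set shows
        the four distinct subsets (a BIBD with lambda = 2) minimise the
        A-score; the optimizer must find it."""
        d = generate_design(DesignSpec(t=4, b=4, seed=7))
        lam = d.concurrence().to_numpy()
        off = lam[~np.eye(4, dtype=bool)]
        assert set(off) == {2}
        # independent enumeration oracle
        subsets = list(itertools.combinations(range(4), 3))
        best = min(
            (
                a_score(Design([tuple(map(str, bl)) for bl in combo],
                               items=[str(i) for i in range(4)]))
                for combo in itertools.combinations_with_replacement(subsets, 4)
                if len({i for bl in combo for i in bl}) == 4
            )
        )
        assert a_score(d) == pytest.approx(best, abs=1e-10)

    def test_balanced_replication_t6_b20(self):
        d = generate_design(DesignSpec(t=6, b=20, seed=3, n_restarts=3))
        assert set(d.replication()) == {10}

    def test_reproducible(self):
        spec = DesignSpec(t=6, b=10, seed=42)
        assert generate_design(spec).blocks == generate_design(spec).blocks

    def test_attrition_robustness(self):
        """Dropping any single block leaves the design connected (b >= t)."""
        d = generate_design(DesignSpec(t=6, b=10, seed=5, n_restarts=3))
        for j in range(d.b):
            reduced = Design([bl for i, bl in enumerate(d.blocks) if i != j],
                             items=d.items)
            assert len(reduced.connected_components()) == 1

    def test_no_worse_than_unoptimized(self):
        spec = DesignSpec(t=7, b=10, seed=11, n_restarts=3)
        d = generate_design(spec)
        raw = random_balanced_design(7, 10, seed=11)
        assert a_score(d) <= a_score(raw) + 1e-12

    def test_infeasible_spec(self):
        with pytest.raises(ValidationError):
            DesignSpec(t=2, b=4)


class TestCanonicalEfficiency:
    def test_bibd_4_3_2_matches_closed_form(self):
        d = generate_design(DesignSpec(t=4, b=4, seed=1))
        assert d.is_bibd()
        assert canonical_efficiency(d) == pytest.approx(relative_efficiency(4, 3), abs=1e-10)

    def test_fano_plane_identity_if_bibd(self):
        """At (t,b) = (7,7) the optimum is the Fano plane BIBD; the identity
        with the closed form holds whenever the optimizer reaches a BIBD,
        and the closed form upper-bounds the efficiency regardless."""
        d = generate_design(DesignSpec(t=7, b=7, seed=1))
        e = canonical_efficiency(d)
        assert e <= relative_efficiency(7, 3) + 1e-9
        if d.is_bibd():
            assert e == pytest.approx(relative_efficiency(7, 3), abs=1e-10)

    def test_complete_blocks_efficiency_one(self):
        d = Design([("A", "B", "C", "D")] * 3)
        assert canonical_efficiency(d) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_names_components(self):
        d = Design([("A", "B", "C"), ("D", "E", "F")])
        with pytest.raises(DisconnectedError) as err:
            a_score(d)
        assert ["A", "B", "C"] in err.value.components


class TestSequentialOrdering:
    def test_single_block_unchanged(self):
        d = Design([("A", "B", "C")])
        assert order_blocks_sequentially(d).blocks == d.blocks

    @pytest.mark.parametrize("t,b,max_spread", [(4, 4, 1), (6, 20, 2)])
    def test_prefix_balance(self, t, b, max_spread):
        d = order_blocks_sequentially(generate_design(DesignSpec(t=t, b=b, seed=2, n_restarts=3)))
        counts = dict.fromkeys(d.items, 0)
        for bl in d.blocks:
            for it in bl:
                counts[it] += 1
            vals = list(counts.values())
            assert max(vals) - min(vals) <= max_spread  # greedy keeps prefixes even

    def test_t6_b20_half_prefix(self):
        d = order_blocks_sequentially(generate_design(DesignSpec(t=6, b=20, seed=2, n_restarts=3)))
        counts = dict.fromkeys(d.items, 0)
        for bl in d.blocks[:10]:
            for it in bl:
                counts[it] += 1
        assert all(4 <= c <= 6 for c in counts.values())

    def test_contents_preserved(self):
        d = generate_design(DesignSpec(t=5, b=8, seed=9, n_restarts=2))
        ordered = order_blocks_sequentially(d)
        assert sorted(map(sorted, ordered.blocks)) == sorted(map(sorted, d.blocks))


def test_design_json_round_trip(tmp_path):
    d = generate_design(DesignSpec(t=5, b=6, seed=4, n_restarts=2))
    path = tmp_path / "design.json"
    d.to_json(path)
    assert Design.from_json(path) == d
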