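"""Signed circular gene-order comparison, breakpoint distance against a
brute-force adjacency oracle, and the single-TDRL test against exhaustive
duplication-loss enumeration."""

import itertools
import random

import pytest

from mitochar.gene_order import (
    SignedGeneOrder,
    SymbolSetError,
    breakpoint_distance,
    diff_orders,
    linearize,
    orders_identical,
    read_orders,
    tdrl_derivable,
    write_orders,
)
from mitochar.simulate import GenomeSpec, apply_event, generate_mitogenome


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_breakpoints(a, b):
    """Count adjacencies of ``a`` absent from ``b`` by scanning every
    rotation of ``b`` and of its reverse complement for each pair."""
    genes_b = list(b.genes)
    flipped = [(n, -s) for n, s in reversed(genes_b)]

    def contains(pair, seq):
        doubled = seq + seq
        return any(tuple(doubled[i:i + 2]) == pair for i in range(len(seq)))

    missing = 0
    ga = list(a.genes)
    for i in range(len(ga)):
        pair = (ga[i], ga[(i + 1) % len(ga)])
        if not (contains(pair, genes_b) or contains(pair, flipped)):
            missing += 1
    return missing


def oracle_tdrl_outcomes(window):
    """All window orders reachable by one tandem duplication followed by
    loss of each gene from one of the two copies."""
    outcomes = set()
    for mask in itertools.product((1, 2), repeat=len(window)):
        copy1 = tuple(g for g, m in zip(window, mask) if m == 1)
        copy2 = tuple(g for g, m in zip(window, mask) if m == 2)
        outcomes.add(copy1 + copy2)
    return outcomes


def random_order(rng, n):
    genes = [f"g{i}" for i in range(n)]
    rng.shuffle(genes)
    return SignedGeneOrder(
        "rand", tuple((g, rng.choice([1, -1])) for g in genes)
    )


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

class TestLinearize:
    def test_reference_starts_at_cox1(self, annotation):
        order = linearize(annotation)
        assert order.genes[:6] == (
            ("cox1", 1), ("trnL2", 1), ("cox2", 1),
            ("trnK", 1), ("trnD", 1), ("atp8", 1),
        )

    def test_reference_cr_segment(self, annotation):
        order = linearize(annotation)
        i = order.names.index("CR")
        assert order.genes[i: i + 4] == (
            ("CR", 0), ("trnQ", -1), ("trnI", 1), ("trnM", 1)
        )

    def test_rotation_invariant(self, sinensis_order):
        for k in (1, 7, 20):
            assert linearize(sinensis_order.rotated(k)).genes == \
                   sinensis_order.canonical().genes

    def test_single_gene(self):
        from mitochar.model import CircularGenome, GeneFeature

        g = CircularGenome("g", 9, None, [GeneFeature("cox1", "F", 1, 9)])
        assert linearize(g).genes == (("cox1", 1),)

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SignedGeneOrder("x", (("a", 1), ("a", 1)))


class TestOrdersIdentical:
    def test_rotation_equivalence(self, ground_order):
        assert orders_identical(ground_order, ground_order.rotated(5))

    def test_reference_differs_from_ground_pattern(self, ground_order,
                                                   sinensis_order):
        assert not orders_identical(ground_order, sinensis_order)

    def test_sign_flip_detected(self, ground_order):
        flipped = SignedGeneOrder(
            "flip",
            tuple((n, -s) if n == "trnW" else (n, s)
                  for n, s in ground_order.genes),
        )
        assert not orders_identical(ground_order, flipped)

    def test_symbol_mismatch_error(self):
        a = SignedGeneOrder("a", (("cox1", 1), ("x", 1)))
        b = SignedGeneOrder("b", (("cox1", 1), ("y", 1)))
        with pytest.raises(SymbolSetError, match="x"):
            orders_identical(a, b)


class TestBreakpointDistance:
    def test_identity_is_zero(self, ground_order):
        assert breakpoint_distance(ground_order, ground_order) == 0

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_bruteforce_oracle(self, n):
        rng = random.Random(n)
        for _ in range(30):
            a, b = random_order(rng, n), random_order(rng, n)
            assert breakpoint_distance(a, b) == oracle_breakpoints(a, b)

    def test_metric_properties(self):
        rng = random.Random(99)
        for _ in range(25):
            a, b, c = (random_order(rng, 6) for _ in range(3))
            dab = breakpoint_distance(a, b)
            assert dab == breakpoint_distance(b, a)
            assert dab <= breakpoint_distance(a, c) + breakpoint_distance(c, b)

    def test_iq_swap_distance_matches_oracle(self, ground_order):
        swapped = apply_event(
            ground_order,
            ("tdrl", ["trnI", "trnQ"], {"trnQ": 1, "trnI": 2}),
        )
        assert breakpoint_distance(ground_order, swapped) == \
               oracle_breakpoints(ground_order, swapped)


class TestDiffOrders:
    def test_self_diff_empty(self, sinensis_order):
        assert diff_orders(sinensis_order, sinensis_order).is_empty

    def test_reference_vs_ground_pattern(self, ground_order, sinensis_order):
        diff = diff_orders(ground_order, sinensis_order)
        assert "trnH" in diff.displaced
        old, new = diff.displaced["trnH"]
        assert set(old) == {"nad5", "nad4"}
        assert set(new) == {"trnE", "trnF"}
        others = set(diff.displaced) - {"trnH"}
        assert len(others) == 1 and others <= {"trnI", "trnQ"}

    def test_in_place_inversion_reported(self, sinensis_order):
        inverted = apply_event(sinensis_order, ("invert", ["trnH"]))
        diff = diff_orders(sinensis_order, inverted)
        assert diff.inverted == ("trnH",)
        assert not diff.displaced


class TestTdrl:
    def test_identical_orders_trivially_derivable(self, ground_order):
        result = tdrl_derivable(ground_order, ground_order)
        assert result.derivable
        assert result.copy2 == ()

    def test_iqm_window_witness(self, ground_order):
        rearranged = apply_event(
            ground_order,
            ("tdrl", ["trnI", "trnQ", "trnM"],
             {"trnQ": 1, "trnI": 2, "trnM": 2}),
        )
        result = tdrl_derivable(ground_order, rearranged,
                                ["trnI", "trnQ", "trnM"])
        assert result.derivable
        assert result.copy1 == ("trnQ",)
        assert result.copy2 == ("trnI", "trnM")

    def test_reversed_window_of_four_not_derivable(self):
        a = SignedGeneOrder(
            "a", (("cox1", 1),) + tuple((g, 1) for g in "ABCD")
        )
        b = SignedGeneOrder(
            "b", (("cox1", 1),) + tuple((g, 1) for g in "DCBA")
        )
        assert not tdrl_derivable(a, b, list("ABCD")).derivable

    def test_inversion_inside_window_refused(self, ground_order):
        inverted = apply_event(ground_order, ("invert", ["trnI"]))
        result = tdrl_derivable(ground_order, inverted, ["trnI", "trnQ"])
        assert not result.derivable
        assert "inversion" in result.reason

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_exhaustive_duplication_loss_enumeration(self, k):
        window = [f"w{i}" for i in range(k)]
        base = SignedGeneOrder(
            "base", (("cox1", 1),) + tuple((g, 1) for g in window)
        )
        outcomes = oracle_tdrl_outcomes(tuple(window))
        for perm in itertools.permutations(window):
            b = SignedGeneOrder(
                "b", (("cox1", 1),) + tuple((g, 1) for g in perm)
            )
            assert tdrl_derivable(base, b, window).derivable == \
                   (perm in outcomes), perm


class TestOrderFiles:
    def test_round_trip(self, tmp_path, ground_order, sinensis_order):
        path = tmp_path / "orders.txt"
        write_orders([ground_order, sinensis_order], path)
        again = read_orders(path)
        assert [o.genes for o in again] == [ground_order.genes,
                                            sinensis_order.genes]
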