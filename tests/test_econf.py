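"""Electron-configuration descriptor: ground states, Hund filling, compound
vectors and zero-variance pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from econfqspr.econf import (
    BIT_LABELS,
    COMPONENTS,
    N_BITS,
    SUBSHELLS,
    FeaturizationError,
    compound_vector,
    element_bits,
    featurize_table,
    ground_state_config,
    prune_constant_bits,
)
from econfqspr.elements import BY_Z, ELEMENTS, UnsupportedElementError, parse_formula

IDX = {lab: i for i, lab in enumerate(BIT_LABELS)}


def brute_force_bits(config):
    """Independent electron-by-electron filler used as the oracle.

    Walks the tabulated subshell occupations one electron at a time: all
    spin-up passes over the degenerate components first, then spin-down,
    exactly as Hund's rule dictates.
    """
    bits = np.zeros(N_BITS, dtype=int)
    for n, l, k in config.subshell_occupations:
        comps = COMPONENTS[l]
        placed = 0
        for spin, value in (("+", 1), ("-", -1)):
            for comp in comps:
                if placed == k:
                    break
                stem = f"{n}{l}" if comp == "" else f"{n}{l}_{comp}"
                bits[IDX[stem + spin]] = value
                placed += 1
    return bits


def test_vector_has_118_canonically_ordered_bits():
    assert N_BITS == 118
    assert BIT_LABELS[0] == "1s+" and BIT_LABELS[1] == "1s-"
    assert BIT_LABELS[IDX["2p_x+"] + 1] == "2p_x-"  # + precedes - per component
    # allowed (shell, subshell) pairs only
    assert (7, "d") not in SUBSHELLS and (6, "f") not in SUBSHELLS


@pytest.mark.parametrize(
    "element, expected",
    [
        ("O", "1s2 2s2 2p4"),
        ("H", "1s1"),
        ("Cr", "1s2 2s2 2p6 3s2 3p6 3d5 4s1"),
        ("Cu", "1s2 2s2 2p6 3s2 3p6 3d10 4s1"),
        ("Pd", "1s2 2s2 2p6 3s2 3p6 3d10 4s2 4p6 4d10"),
    ],
)
def test_tabulated_ground_states(element, expected):
    assert str(ground_state_config(element)) == expected


def test_lanthanide_actinide_irregulars():
    def occ(sym):
        return {(n, l): k for n, l, k in ground_state_config(sym).subshell_occupations}

    la = occ("La")
    assert la[(5, "d")] == 1 and (4, "f") not in la
    gd = occ("Gd")
    assert gd[(4, "f")] == 7 and gd[(5, "d")] == 1
    u = occ("U")
    assert u[(5, "f")] == 3 and u[(6, "d")] == 1
    lr = occ("Lr")
    assert lr[(7, "p")] == 1 and (6, "d") not in lr


@pytest.mark.parametrize("bad", [0, 105, 200, "Og"])
def test_out_of_range_elements_rejected(bad):
    with pytest.raises(UnsupportedElementError):
        ground_state_config(bad)


def test_oxygen_element_vector_bit_by_bit():
    bits = element_bits(ground_state_config("O"))
    expected = {
        "1s+": 1, "1s-": -1, "2s+": 1, "2s-": -1,
        "2p_x+": 1, "2p_y+": 1, "2p_z+": 1, "2p_x-": -1,
    }
    for lab, v in expected.items():
        assert bits[IDX[lab]] == v
    assert np.count_nonzero(bits) == len(expected)


def test_closed_shell_and_half_filled_cases():
    he = element_bits(ground_state_config("He"))
    assert he[IDX["1s+"]] == 1 and he[IDX["1s-"]] == -1
    assert np.count_nonzero(he) == 2
    n = element_bits(ground_state_config("N"))  # 2p3: three up, no down
    assert all(n[IDX[f"2p_{c}+"]] == 1 for c in "xyz")
    assert all(n[IDX[f"2p_{c}-"]] == 0 for c in "xyz")


def test_element_bits_match_brute_force_filler_for_all_elements():
    for z in range(1, 105):
        cfg = ground_state_config(z)
        np.testing.assert_array_equal(
            element_bits(cfg), brute_force_bits(cfg), err_msg=BY_Z[z].symbol
        )


def test_electron_conservation_and_hund_ordering_all_elements():
    for z in range(1, 105):
        bits = element_bits(ground_state_config(z))
        assert int(np.abs(bits).sum()) == z
        assert np.all(bits[0::2] >= 0) and np.all(bits[1::2] <= 0)
        # spin-down occupied only if every spin-up of the subshell is
        for n, l in SUBSHELLS:
            comps = COMPONENTS[l]
            stems = [f"{n}{l}" if c == "" else f"{n}{l}_{c}" for c in comps]
            if any(bits[IDX[s + "-"]] != 0 for s in stems):
                assert all(bits[IDX[s + "+"]] != 0 for s in stems)


def test_unpaired_electron_counts():
    for sym, unpaired in [("O", 2), ("N", 3), ("Ne", 0), ("Cr", 6), ("Ar", 0)]:
        assert element_bits(ground_state_config(sym)).sum() == unpaired


def test_compound_vector_worked_example():
    counts = parse_formula("Al2(MoO4)3")
    vec = compound_vector(counts)
    assert vec[IDX["1s+"]] == 17  # 2 Al + 3 Mo + 12 O
    assert int(np.abs(vec).sum()) == 2 * 13 + 3 * 42 + 12 * 8  # 248 electrons
    # the x12 oxygen sub-contribution
    o12 = 12 * element_bits(ground_state_config("O"))
    assert o12[IDX["1s+"]] == 12 and o12[IDX["1s-"]] == -12
    assert o12[IDX["2p_x-"]] == -12 and o12[IDX["2p_y-"]] == 0


def test_single_element_compound_equals_element_bits():
    for sym in ("Fe", "H", "U"):
        np.testing.assert_array_equal(
            compound_vector({sym: 1}), element_bits(ground_state_config(sym))
        )


@given(
    st.dictionaries(st.sampled_from(sorted(ELEMENTS)), st.integers(1, 9),
                    min_size=1, max_size=4)
)
def test_compound_electron_conservation(counts):
    vec = compound_vector(counts)
    expected = sum(c * ELEMENTS[s].atomic_number for s, c in counts.items())
    assert int(np.abs(vec).sum()) == expected


def test_compound_vector_linearity_over_disjoint_parts():
    a, b = {"Na": 2, "S": 1}, {"Fe": 1, "Cl": 3}
    np.testing.assert_array_equal(
        compound_vector({**a, **b}), compound_vector(a) + compound_vector(b)
    )


def test_featurize_table_rows_and_labels():
    df = featurize_table(["H2", "He"])
    assert list(df.columns) == BIT_LABELS
    assert df.loc[0, "1s+"] == 2 and df.loc[0, "1s-"] == 0
    assert df.loc[1, "1s+"] == 1 and df.loc[1, "1s-"] == -1

    empty = featurize_table([])
    assert empty.shape == (0, 118)


def test_featurize_table_collects_all_failures():
    with pytest.raises(FeaturizationError) as err:
        featurize_table(["H2O", "Xx", "NaCl", "(K"])
    assert len(err.value.failures) == 2
    assert {i for i, _, _ in err.value.failures} == {1, 3}


def test_prune_drops_exactly_the_constant_columns():
    df = featurize_table(["H2O", "H2O2", "NaCl"])
    pruned, kept = prune_constant_bits(df)
    assert set(kept) == {c for c in df.columns if df[c].nunique() > 1}
    assert pruned.shape[1] < 118


def test_prune_idempotent():
    df = featurize_table(["H2O", "NaCl", "Fe2O3"])
    once, kept1 = prune_constant_bits(df)
    twice, kept2 = prune_constant_bits(once)
    assert kept1 == kept2
    pd.testing.assert_frame_equal(once, twice)


def test_prune_edge_cases():
    with pytest.raises(ValueError):
        prune_constant_bits(featurize_table([]))
    same = featurize_table(["H2O", "H2O"])
    with pytest.warns(UserWarning):
        all_dropped, kept = prune_constant_bits(same)
    assert kept == [] and all_dropped.shape == (2, 0)
    # two rows differing in exactly one descriptor bit -> one kept column
    h = featurize_table(["H", "H2"])
    _, kept = prune_constant_bits(h)
    assert kept == ["1s+"]


def test_prune_alignment_with_keep_columns():
    df = featurize_table(["H2O", "NaCl", "Fe2O3"])
    _, kept = prune_constant_bits(df)
    new = featurize_table(["KBr"])
    aligned, _ = prune_constant_bits(new, keep_columns=kept)
    assert list(aligned.columns) == kept
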