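"""Contact energies, Monte Carlo design, classification, mutation reports."""

import itertools

import numpy as np
import pytest

from modetrap.design import (
    AA_ORDER,
    ContactDefinition,
    ContactEnergyModel,
    ContactMap,
    DesignConfig,
    DesignError,
    Sequence,
    build_rank2_contact_model,
    classify_landscape,
    contact_energy,
    contact_energy_from_map,
    load_energy_matrix,
    mc_design,
    mutation_report,
    switching_weight,
)
from modetrap.structure import structure_from_arrays


def ca_model(pair=None, ref=None, cutoff=6.5, width=1.0):
    return ContactEnergyModel(
        pair_matrix=np.zeros((20, 20)) if pair is None else pair,
        reference_energies=np.zeros(20) if ref is None else ref,
        contact_definition=ContactDefinition(
            representative="CA", cutoff=cutoff, switch_width=width
        ),
    )


def line_structure(n, spacing=4.0):
    return structure_from_arrays(np.c_[np.arange(n) * spacing, np.zeros(n), np.zeros(n)])


# ---------------------------------------------------------------- energies

def test_single_residue_energy_is_reference_term():
    s = line_structure(1)
    ref = np.arange(20, dtype=float)
    model = ca_model(ref=ref)
    for letter in "AWKV":
        e = contact_energy(s, Sequence(letters=letter), model)
        assert e == pytest.approx(ref[AA_ORDER.index(letter)])


def test_all_zero_model_gives_zero(helix12):
    seq = Sequence(letters="A" * 12)
    assert contact_energy(helix12, seq, ca_model()) == 0.0


def test_hand_summed_pair_energies():
    # four CA beads: contacts (0,1), (1,2), (2,3) at 4.0 Å, full weight
    s = line_structure(4)
    rng = np.random.default_rng(5)
    pair = rng.normal(size=(20, 20))
    pair = (pair + pair.T) / 2
    ref = rng.normal(size=20)
    model = ca_model(pair=pair, ref=ref)
    seq = Sequence(letters="ACDE")
    idx = [AA_ORDER.index(a) for a in "ACDE"]
    expected = (
        pair[idx[0], idx[1]] + pair[idx[1], idx[2]] + pair[idx[2], idx[3]]
        + sum(ref[i] for i in idx)
    )
    assert contact_energy(s, seq, model) == pytest.approx(expected, abs=1e-12)


def test_switching_weight_shape():
    cd = ContactDefinition(representative="CA", cutoff=6.5, switch_width=1.0)
    d = np.array([5.0, 5.5, 6.0, 6.5, 7.0])
    w = switching_weight(d, cd)
    assert w[0] == 1.0 and w[1] == 1.0
    assert 0 < w[2] < 1
    assert w[3] == 0.0 and w[4] == 0.0
    assert w[2] == pytest.approx(0.5)  # midpoint of the cosine ramp


def test_shipped_matrix_loads_symmetric():
    model = load_energy_matrix()
    assert model.pair_matrix.shape == (20, 20)
    np.testing.assert_allclose(model.pair_matrix, model.pair_matrix.T)
    assert np.all(np.isfinite(model.pair_matrix))
    # salt bridges attract, like charges repel, hydrophobics attract
    i, r, d = AA_ORDER.index("I"), AA_ORDER.index("R"), AA_ORDER.index("D")
    assert model.pair_matrix[i, i] < 0
    assert model.pair_matrix[r, d] < 0
    assert model.pair_matrix[r, r] > 0


def test_custom_matrix_file_roundtrip(tmp_path):
    model = build_rank2_contact_model(scale=0.5)
    lines = ["  " + " ".join(AA_ORDER)]
    for i, a in enumerate(AA_ORDER):
        lines.append(a + " " + " ".join(f"{v:.6f}" for v in model.pair_matrix[i]))
    lines.append("REF " + " ".join(f"{v:.6f}" for v in model.reference_energies))
    p = tmp_path / "matrix.txt"
    p.write_text("\n".join(lines) + "\n")
    back = load_energy_matrix(p)
    np.testing.assert_allclose(back.pair_matrix, model.pair_matrix, atol=1e-6)
    np.testing.assert_allclose(
        back.reference_energies, model.reference_energies, atol=1e-6
    )


# ---------------------------------------------------------------- MC design

def test_zero_pair_matrix_design_hits_reference_argmin(helix12):
    ref = np.ones(20)
    ref[AA_ORDER.index("G")] = -2.0
    model = ca_model(ref=ref)
    res = mc_design(
        helix12,
        Sequence(letters="A" * 12),
        model,
        DesignConfig(seed=1, schedule=((1.0, 200),)),
    )
    assert res.best_sequence.letters == "G" * 12


def test_all_zero_model_ties_break_lexicographically(helix12):
    res = mc_design(
        helix12,
        Sequence(letters="V" * 12),
        ca_model(),
        DesignConfig(seed=2, schedule=((1.0, 100),)),
    )
    assert res.best_sequence.letters == "A" * 12


def test_two_position_design_matches_brute_force():
    s = line_structure(4)
    rng = np.random.default_rng(17)
    pair = rng.normal(size=(20, 20))
    pair = (pair + pair.T) / 2
    ref = rng.normal(size=20)
    model = ca_model(pair=pair, ref=ref)
    frozen = Sequence(letters="WYWY")
    cfg = DesignConfig(seed=3, schedule=((1.0, 2000),), designable_positions=(3, 4))
    res = mc_design(s, frozen, model, cfg)
    best = min(
        (
            contact_energy(s, Sequence(letters="WY" + a + b), model)
            for a, b in itertools.product(AA_ORDER, repeat=2)
        )
    )
    assert res.best_energy == pytest.approx(best, abs=1e-12)


def test_incremental_delta_matches_full_recomputation(two_domain):
    s = two_domain.structure
    model = build_rank2_contact_model(
        contact_definition=ContactDefinition(representative="CA", cutoff=6.5)
    )
    cmap = ContactMap.from_structure(s, model.contact_definition, neighbor_radius=10.0)
    rng = np.random.default_rng(9)
    seq = Sequence(letters="".join(rng.choice(list(AA_ORDER), size=s.n_residues)))
    from modetrap.design import _delta_u

    u = contact_energy_from_map(cmap, seq, model)
    idx = seq.as_indices()
    for _ in range(50):
        pos = int(rng.integers(s.n_residues))
        new_aa = int(rng.integers(20))
        du = _delta_u(cmap, model, idx, pos, new_aa)
        idx[pos] = new_aa
        seq = Sequence(letters="".join(AA_ORDER[a] for a in idx))
        u_full = contact_energy_from_map(cmap, seq, model)
        assert du == pytest.approx(u_full - u, abs=1e-9)
        u = u_full


def test_greedy_limit_never_accepts_uphill(two_domain):
    model = build_rank2_contact_model(
        contact_definition=ContactDefinition(representative="CA", cutoff=6.5)
    )
    from modetrap.structure import sequence_of

    wt = sequence_of(two_domain.structure)
    res = mc_design(
        two_domain.structure, wt, model,
        DesignConfig(seed=4, schedule=((1e-9, 2000),), final_quench=False),
    )
    assert np.all(np.diff(res.energy_trace) <= 1e-9)


def test_design_deterministic_under_seed(two_domain):
    from modetrap.structure import sequence_of

    model = build_rank2_contact_model(
        contact_definition=ContactDefinition(representative="CA", cutoff=6.5)
    )
    wt = sequence_of(two_domain.structure)
    cfg = DesignConfig(seed=123, schedule=((0.5, 500),))
    a = mc_design(two_domain.structure, wt, model, cfg)
    b = mc_design(two_domain.structure, wt, model, cfg)
    assert a.best_sequence.letters == b.best_sequence.letters
    assert a.mutations == b.mutations
    np.testing.assert_array_equal(a.energy_trace, b.energy_trace)


def test_best_energy_never_above_initial(two_domain):
    from modetrap.structure import sequence_of

    model = build_rank2_contact_model(
        contact_definition=ContactDefinition(representative="CA", cutoff=6.5)
    )
    wt = sequence_of(two_domain.structure)
    for seed in range(5):
        res = mc_design(
            two_domain.structure, wt, model, DesignConfig(seed=seed, schedule=((1.0, 300),))
        )
        assert res.best_energy <= res.initial_energy + 1e-12


def test_absent_designable_position_errors(helix12):
    with pytest.raises(DesignError):
        mc_design(
            helix12,
            Sequence(letters="A" * 12),
            ca_model(),
            DesignConfig(seed=1, designable_positions=(99,)),
        )


# ---------------------------------------------------------------- classification

@pytest.mark.parametrize(
    "energies, expected",
    [
        ((5.0, 1.0, 0.0, 3.0), "trap"),
        ((5.0, 1.0, 0.0, 1.2), "smoothing"),
        ((5.0, 6.0, 0.0, 3.0), "neither"),
    ],
)
def test_classify_landscape_cases(energies, expected):
    assert classify_landscape(*energies, tol=0.5) == expected


def test_classify_rejects_nonfinite():
    with pytest.raises(ValueError):
        classify_landscape(np.nan, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------- reporting

def test_mutation_report_group_specific_and_global():
    wt = Sequence(letters="TSR")
    designs = {
        "OP1": Sequence(letters="DER"),
        "OP2": Sequence(letters="DER"),
        "CL1": Sequence(letters="KER"),
        "CL2": Sequence(letters="KER"),
    }
    table = mutation_report(wt, designs)
    row0 = table.iloc[0]  # T -> D (OP) / K (CL): design-specific convergence
    assert row0["group_specific"] and not row0["global_convergence"]
    row1 = table.iloc[1]  # S -> E in all four designs: global convergence
    assert row1["global_convergence"]
    row2 = table.iloc[2]  # unchanged position
    assert not row2["mutated"]


def test_mutation_report_identical_sequences_empty():
    wt = Sequence(letters="ACDE")
    table = mutation_report(wt, {"D1": wt, "D2": wt})
    assert not table["mutated"].any()


def test_mutation_report_length_mismatch():
    with pytest.raises(DesignError):
        mutation_report(Sequence(letters="AC"), {"D1": Sequence(letters="ACD")})
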