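from fractions import Fraction
from itertools import product

import numpy as np
import pytest

import segjoint as sj
from segjoint.genmodels import MODEL_REGISTRY, build_structure

# free-parameter counts implied by the published likelihood/AIC table
EXPECTED_K = {
    "1MG-AD": 4, "1MG-A": 3, "1MG-EAD": 3, "1MG-NCD": 3,
    "2MG-ADI": 10, "2MG-AD": 6, "2MG-A": 4, "2MG-EA": 3, "2MG-CD": 4,
    "2MG-EAD": 3,
    "PG-ADI": 10, "PG-AD": 7,
    "MX1-AD-ADI": 12, "MX1-AD-AD": 9, "MX1-A-AD": 8, "MX1-EAD-AD": 8,
    "MX1-NCD-AD": 8,
    "MX2-ADI-ADI": 18, "MX2-ADI-AD": 15, "MX2-AD-AD": 11, "MX2-A-AD": 9,
    "MX2-EA-AD": 8, "MX2-CD-AD": 9, "MX2-EAD-AD": 8,
}

LOCUS_FREQ = {
    "P1": {+1: Fraction(1)},
    "P2": {-1: Fraction(1)},
    "F1": {0: Fraction(1)},
    "F2": {+1: Fraction(1, 4), 0: Fraction(1, 2), -1: Fraction(1, 4)},
    "BC1P1": {+1: Fraction(1, 2), 0: Fraction(1, 2)},
    "BC1P2": {0: Fraction(1, 2), -1: Fraction(1, 2)},
}
POLY_SHIFT = {  # (coefficient of [d], coefficient of [h])
    "P1": (1, 0), "P2": (-1, 0), "F1": (0, 1),
    "F2": (0, Fraction(1, 2)),
    "BC1P1": (Fraction(1, 2), Fraction(1, 2)),
    "BC1P2": (Fraction(-1, 2), Fraction(1, 2)),
}


def brute_force_mx2_a_ad(generation):
    """Independent enumeration of the two-additive-locus + polygene mixture.

    Walks all two-locus genotype classes with per-locus Mendelian
    frequencies and accumulates the weight of each distinct mean
    expression (coefficients on m, d_a, d_b, [d], [h])."""
    freq = LOCUS_FREQ[generation]
    a, b = POLY_SHIFT[generation]
    table = {}
    for (u, fu), (v, fv) in product(freq.items(), freq.items()):
        coeffs = (1, u, v, a, b)  # m, d_a, d_b, poly_d, poly_h
        table[coeffs] = table.get(coeffs, Fraction(0)) + fu * fv
    return table


@pytest.mark.parametrize("generation,n_components", [
    ("F2", 9), ("BC1P1", 4), ("BC1P2", 4), ("P1", 1), ("P2", 1), ("F1", 1),
])
def test_mx2_a_ad_matches_brute_force(generation, n_components):
    gm = build_structure("MX2-A-AD").generations[generation]
    expected = brute_force_mx2_a_ad(generation)
    assert gm.n_components == n_components == len(expected)
    got = {tuple(row): w for row, w in zip(gm.design, gm.weights)}
    assert got == {tuple(Fraction(c) for c in k): v
                   for k, v in expected.items()}


def test_mx2_a_ad_f2_mendelian_weights():
    gm = build_structure("MX2-A-AD").generations["F2"]
    assert sorted(gm.weights) == sorted(
        Fraction(w, 16) for w in (1, 2, 1, 2, 4, 2, 1, 2, 1))


def test_1mg_a_parental_means():
    st = build_structure("1MG-A")
    p1 = st.generations["P1"]
    assert p1.n_components == 1 and p1.weights == (Fraction(1),)
    assert p1.design[0] == (Fraction(1), Fraction(1))  # mean = m + d_a


@pytest.mark.parametrize("name", sj.MODEL_NAMES)
def test_weights_are_mendelian_probabilities(name):
    st = build_structure(name)
    for g in sj.GENERATIONS:
        gm = st.generations[g]
        assert sum(gm.weights) == 1
        assert all(w > 0 for w in gm.weights)
        if g in ("P1", "P2", "F1"):
            assert gm.n_components == 1


@pytest.mark.parametrize("name,k", sorted(EXPECTED_K.items()))
def test_free_parameter_counts(name, k):
    assert sj.count_free_parameters(name) == k


@pytest.mark.parametrize("name,n_f2", [
    ("1MG-AD", 3), ("2MG-EA", 5), ("2MG-EAD", 3), ("2MG-CD", 4),
    ("1MG-EAD", 2), ("PG-AD", 1),
])
def test_component_merging(name, n_f2):
    # classes with identical exact mean expressions collapse
    assert build_structure(name).generations["F2"].n_components == n_f2


def test_nesting_2mg_ad_reproduces_2mg_a():
    theta_a = np.array([100.0, 20.0, -5.0])  # m, d_a, d_b
    means_a = sj.build_structure("2MG-A").component_means(theta_a)
    theta_ad = np.array([100.0, 20.0, 0.0, -5.0, 0.0])  # h_a = h_b = 0
    means_ad = sj.build_structure("2MG-AD").component_means(theta_ad)
    for g in sj.GENERATIONS:
        assert np.allclose(sorted(means_a[g]), sorted(means_ad[g]))


def test_nesting_mx2_collapses_to_2mg_a(tiny_dataset):
    st_mx = sj.build_structure("MX2-A-AD")
    st_mg = sj.build_structure("2MG-A")
    p = sj.EffectParams(m=100.0, d_a=20.0, d_b=-5.0, sigma2_e=25.0)
    ll_mg = sj.joint_loglik(tiny_dataset, st_mg, p)
    ll_mx = sj.joint_loglik(tiny_dataset, st_mx, p)  # [d]=[h]=0, s2pg=0
    assert ll_mx == pytest.approx(ll_mg, abs=1e-9)


def test_ea_structure_symmetric_under_locus_swap():
    # with tied additive effects the two loci are exchangeable by design
    gm = build_structure("2MG-EA").generations["F2"]
    assert [str(w) for w in gm.weights] == ["1/16", "1/4", "3/8", "1/4", "1/16"]
    coeffs = [row[1] for row in gm.design]
    assert coeffs == [Fraction(c) for c in (2, 1, 0, -1, -2)]


def test_unknown_model_lists_codes():
    with pytest.raises(KeyError, match="MX2-A-AD"):
        sj.get_model("NOT-A-MODEL")


def test_effect_params_constraint_validation():
    spec = sj.get_model("1MG-A")
    with pytest.raises(ValueError, match="h_a"):
        sj.EffectParams(m=1.0, d_a=2.0, h_a=3.0, sigma2_e=1.0).validate(spec)
    sj.EffectParams(m=1.0, d_a=2.0, sigma2_e=1.0).validate(spec)


def test_registry_json_export(tmp_path):
    import json
    path = tmp_path / "registry.json"
    sj.registry_to_json(path)
    payload = json.loads(path.read_text())
    assert set(payload) == set(sj.MODEL_NAMES)
    assert payload["MX2-A-AD"]["k"] == 9
    f2 = payload["MX2-A-AD"]["generations"]["F2"]
    assert len(f2["weights"]) == 9


def test_registry_has_24_models():
    assert len(MODEL_REGISTRY) == 24
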