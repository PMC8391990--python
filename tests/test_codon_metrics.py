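import math
from collections import Counter

import pytest
from pytest import approx

from codonusage.codon_metrics import (
    MISSING,
    OVER,
    RANDOM,
    ReferenceWeights,
    UNDER,
    build_reference_weights,
    cai,
    enc,
    rscu,
)
from codonusage.genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    DEGENERATE_CODONS,
)
from codonusage.sequence_io import CodingSequence

from conftest import random_cds


def cds_from_codons(codons, gene_id="g"):
    return CodingSequence(gene_id, "".join(codons))


# ---------------------------------------------------------------------------
# RSCU


def test_sole_codon_of_sixfold_family_scores_six():
    table = rscu(cds_from_codons(["CTG"] * 4))
    assert table["CTG"] == approx(6.0)
    assert table.classification["CTG"] == OVER
    assert table["CTT"] == 0.0
    assert table.classification["CTT"] == UNDER
    assert math.isnan(table["AAA"])  # Lys absent
    assert table.classification["AAA"] == MISSING


def test_uniform_family_usage_is_random():
    table = rscu(cds_from_codons(list(AA_TO_CODONS["L"])))
    for codon in AA_TO_CODONS["L"]:
        assert table[codon] == approx(1.0)
        assert table.classification[codon] == RANDOM


def test_hand_evaluated_leucine_mixture():
    table = rscu(cds_from_codons(["CTG", "CTG", "CTT"]))
    assert table["CTG"] == approx(4.0)  # 2 / (3/6)
    assert table["CTT"] == approx(2.0)
    for codon in ("CTA", "CTC", "TTA", "TTG"):
        assert table[codon] == 0.0
        assert table.classification[codon] == UNDER


def test_family_sums_equal_degeneracy_on_random_genes(rng):
    for _ in range(200):
        table = rscu(random_cds(rng, int(rng.integers(20, 150))))
        for aa in DEGENERATE_AAS:
            values = [table[c] for c in AA_TO_CODONS[aa]]
            if any(math.isnan(v) for v in values):
                assert all(math.isnan(v) for v in values)
            else:
                assert sum(values) == approx(DEGENERACY[aa], abs=1e-9)


def test_terminal_stop_and_nondegenerate_codons_excluded():
    with_stop = rscu(cds_from_codons(["CTG", "ATG", "TGG", "TAA"]))
    without = rscu(cds_from_codons(["CTG"]))
    assert dict(with_stop.values) == approx(dict(without.values), nan_ok=True)


# ---------------------------------------------------------------------------
# ENc


def one_codon_per_family_gene(repeats=3):
    return cds_from_codons(
        [AA_TO_CODONS[aa][0] for aa in DEGENERATE_AAS for _ in range(repeats)]
    )


def test_enc_is_20_at_maximal_bias():
    value = enc(one_codon_per_family_gene())
    assert value.enc == approx(20.0)
    assert all(f == approx(1.0) for f in value.family_means.values())


def test_enc_is_61_at_uniform_usage():
    codons = [c for c in DEGENERATE_CODONS for _ in range(30)]
    assert enc(cds_from_codons(codons)).enc == approx(61.0)


def test_enc_bounds_on_random_genes(rng):
    for _ in range(50):
        value = enc(random_cds(rng, int(rng.integers(60, 400))))
        if value.enc is not None:
            assert 20.0 <= value.enc <= 61.0


def brute_force_enc(cds):
    """Independent re-implementation of Wright's estimator."""
    counts = Counter(cds.coding_codons)
    f_values = {}
    for aa in DEGENERATE_AAS:
        n = sum(counts[c] for c in AA_TO_CODONS[aa])
        if n < 2:
            continue
        s = sum((counts[c] / n) ** 2 for c in AA_TO_CODONS[aa])
        f_values[aa] = (n * s - 1) / (n - 1)
    means = {}
    for k in (2, 3, 4, 6):
        fs = [f for aa, f in f_values.items() if DEGENERACY[aa] == k]
        if fs:
            means[k] = sum(fs) / len(fs)
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if sorted(means) != [2, 3, 4, 6]:
        return None
    raw = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(61.0, max(20.0, raw))


def test_enc_matches_brute_force_oracle(rng):
    for _ in range(30):
        cds = random_cds(rng, 300)
        expected = brute_force_enc(cds)
        got = enc(cds).enc
        assert got == approx(expected, abs=1e-6)


def test_enc_imputes_isoleucine_class():
    # all degenerate families except Ile
    codons = [
        AA_TO_CODONS[aa][0]
        for aa in DEGENERATE_AAS
        if aa != "I"
        for _ in range(3)
    ]
    value = enc(cds_from_codons(codons))
    assert value.enc == approx(20.0)
    assert value.family_means[3] == approx(
        (value.family_means[2] + value.family_means[4]) / 2
    )


def test_enc_undefined_when_class_empty():
    # only Lys (2-fold): classes 4 and 6 cannot be estimated
    assert enc(cds_from_codons(["AAA", "AAG"] * 3)).enc is None


# ---------------------------------------------------------------------------
# CAI


def all_ones_weights(overrides=None):
    w = {c: 1.0 for c in DEGENERATE_CODONS}
    w.update(overrides or {})
    return ReferenceWeights(w, "toy")


def test_cai_is_one_on_all_optimal_gene(rng):
    ref = all_ones_weights({"CTT": 0.5, "AAA": 0.2})
    optimal = [c for c in DEGENERATE_CODONS if ref.w[c] == 1.0]
    cds = cds_from_codons(list(rng.choice(optimal, size=100)))
    result = cai(cds, ref)
    assert result.cai59 == approx(1.0)
    assert result.cai18 == approx(1.0)


def test_cai_two_term_geometric_mean():
    ref = all_ones_weights({"CTT": 0.5})
    result = cai(cds_from_codons(["CTG", "CTT"]), ref)
    assert result.cai59 == approx(math.sqrt(0.5))
    assert result.cai18 == approx(math.sqrt(0.5))  # single family present


def test_cai18_averages_per_family_not_per_codon():
    # Leu (w=0.5 used twice) and Lys (w=1.0 used once):
    # cai59 = (0.5^2 * 1)^(1/3); cai18 = (0.5 + 1)/2
    ref = all_ones_weights({"CTT": 0.5})
    result = cai(cds_from_codons(["CTT", "CTT", "AAA"]), ref)
    assert result.cai59 == approx(0.25 ** (1 / 3))
    assert result.cai18 == approx(0.75)


def test_cai_monotone_in_weight_substitution(rng):
    ref = build_reference_weights(
        [random_cds(rng, 200, f"r{i}") for i in range(5)]
    )
    cds = random_cds(rng, 120)
    base = cai(cds, ref).cai59
    codons = cds.coding_codons
    for i, codon in enumerate(codons):
        aa = CODON_TO_AA.get(codon)
        if aa is None or DEGENERACY[aa] < 2:
            continue
        best = max(AA_TO_CODONS[aa], key=lambda c: ref.w[c])
        if best != codon:
            swapped = codons.copy()
            swapped[i] = best
            assert cai(cds_from_codons(swapped), ref).cai59 >= base - 1e-12
            break


def test_cai_undefined_for_met_trp_only_gene():
    ref = all_ones_weights()
    with pytest.raises(ValueError, match="CAI undefined"):
        cai(cds_from_codons(["ATG", "TGG"]), ref)


# ---------------------------------------------------------------------------
# reference weights


def test_uniform_pooled_counts_give_unit_weights():
    counts = {c: 7.0 for c in DEGENERATE_CODONS}
    ref = build_reference_weights(counts, "uniform")
    assert all(w == approx(1.0) for w in ref.w.values())


def test_weights_equal_hand_computed_rscu_ratios():
    # two genes pooling to Leu counts CTG=3, CTT=1 -> RSCU 4.5 and 1.5
    panel = [
        cds_from_codons(["CTG", "CTG"], "a"),
        cds_from_codons(["CTG", "CTT"], "b"),
    ]
    ref = build_reference_weights(panel)
    assert ref.w["CTG"] == approx(1.0)
    assert ref.w["CTT"] == approx(1.5 / 4.5)
    # unseen codons of the family get the small positive pseudo-weight
    assert ref.w["CTA"] == approx(0.5 / 4)
    # families absent from the reference are uninformative
    assert ref.w["GGA"] == 1.0


def test_every_family_has_a_unit_weight_codon(rng):
    ref = build_reference_weights([random_cds(rng, 300, f"r{i}") for i in range(4)])
    for aa in DEGENERATE_AAS:
        assert max(ref.w[c] for c in AA_TO_CODONS[aa]) == approx(1.0)


def test_empty_reference_panel_is_error():
    with pytest.raises(ValueError, match="empty"):
        build_reference_weights([])


def test_weights_tsv_roundtrip(tmp_path, rng):
    ref = build_reference_weights([random_cds(rng, 200)])
    path = tmp_path / "w.tsv"
    ref.to_tsv(path)
    back = ReferenceWeights.from_tsv(path)
    for c in DEGENERATE_CODONS:
        assert back.w[c] == approx(ref.w[c], rel=1e-4)
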