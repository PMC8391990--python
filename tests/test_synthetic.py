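import io

import numpy as np
import pytest

from codonusage.codon_metrics import rscu
from codonusage.dinucleotide import dinucleotide_odds
from codonusage.sequence_io import load_panel, write_panel
from codonusage.synthetic_data import (
    SyntheticPanelSpec,
    default_preferred_codons,
    generate_panel,
    generate_panel_with_truth,
)


def test_generated_genes_pass_inclusion_filters():
    spec = SyntheticPanelSpec(n_genes=15, length_codons_range=(150, 400), seed=1)
    panel = generate_panel(spec)
    buf = io.StringIO()
    write_panel(panel, buf)
    buf.seek(0)
    accepted, report = load_panel(buf)
    assert len(accepted) == 15
    assert len(report) == 0


def test_seed_determinism():
    spec = SyntheticPanelSpec(n_genes=4, length_codons_range=(150, 250), seed=11)
    a = generate_panel(spec)
    b = generate_panel(spec)
    assert [(c.gene_id, c.seq) for c in a] == [(c.gene_id, c.seq) for c in b]
    other = generate_panel(
        SyntheticPanelSpec(n_genes=4, length_codons_range=(150, 250), seed=12)
    )
    assert [c.seq for c in other] != [c.seq for c in a]


def test_gc3_targets_are_realized():
    spec = SyntheticPanelSpec(
        n_genes=25, length_codons_range=(3000, 3000), seed=2
    )
    _, truth = generate_panel_with_truth(spec)
    errors = [
        abs(g["realized_gc3"] - 100 * g["gc3_target"]) for g in truth["genes"]
    ]
    assert max(errors) < 3.0
    assert np.mean(errors) < 1.5
    # binomial sampling noise shrinks with length: shorter genes still track
    spec_short = SyntheticPanelSpec(
        n_genes=25, length_codons_range=(1000, 1000), seed=2
    )
    _, truth_short = generate_panel_with_truth(spec_short)
    short_errors = [
        abs(g["realized_gc3"] - 100 * g["gc3_target"])
        for g in truth_short["genes"]
    ]
    assert np.mean(short_errors) < 2.0


def test_preferred_codon_becomes_overrepresented():
    spec = SyntheticPanelSpec(
        n_genes=40,
        length_codons_range=(400, 800),
        gc3_targets=0.5,
        neutrality_slope=None,
        bias_strength=4.0,
        preferred_codons={"L": "CTG"},
        seed=3,
    )
    panel = generate_panel(spec)
    over = np.mean([rscu(c).classification["CTG"] == "OVER" for c in panel])
    assert over >= 0.95


def test_cpg_odds_track_suppression_factor():
    means = []
    for s in (1.0, 0.6, 0.3):
        spec = SyntheticPanelSpec(
            n_genes=3,
            length_codons_range=(2000, 2000),
            gc3_targets=0.5,
            neutrality_slope=None,
            cpg_suppression=s,
            seed=4,
        )
        panel = generate_panel(spec)
        means.append(np.mean([dinucleotide_odds(c).rho["CG"] for c in panel]))
    # realized rho falls as the suppression deepens (factor decreases)
    assert means[0] > means[1] > means[2]
    assert abs(means[1] - 0.6) < 0.1
    assert abs(means[2] - 0.3) < 0.1


def test_suppression_preserves_the_protein():
    from codonusage.protein_props import translate

    base = SyntheticPanelSpec(
        n_genes=3, length_codons_range=(300, 300), gc3_targets=0.5,
        neutrality_slope=None, cpg_suppression=1.0, seed=5,
    )
    suppressed = SyntheticPanelSpec(
        n_genes=3, length_codons_range=(300, 300), gc3_targets=0.5,
        neutrality_slope=None, cpg_suppression=0.4, seed=5,
    )
    for a, b in zip(generate_panel(base), generate_panel(suppressed)):
        assert translate(a) == translate(b)
        assert a.seq != b.seq


def test_infeasible_gc3_target_error_names_parameters():
    spec = SyntheticPanelSpec(
        n_genes=2, length_codons_range=(100, 100), gc3_targets=0.02, seed=6
    )
    with pytest.raises(ValueError, match="infeasible"):
        generate_panel(spec)


def test_invalid_spec_parameters_rejected():
    with pytest.raises(ValueError, match="cpg_suppression"):
        SyntheticPanelSpec(cpg_suppression=0.0)
    with pytest.raises(ValueError, match="encode"):
        SyntheticPanelSpec(preferred_codons={"L": "AAA"})
    with pytest.raises(ValueError, match="length"):
        SyntheticPanelSpec(length_codons_range=(10, 5))


def test_default_preferences_are_valid_synonyms():
    from codonusage.genetic_code import CODON_TO_AA, DEGENERATE_AAS

    prefs = default_preferred_codons()
    assert sorted(prefs) == sorted(DEGENERATE_AAS)
    assert prefs["L"] == "CTG"
    for aa, codon in prefs.items():
        assert CODON_TO_AA[codon] == aa


def test_truth_record_matches_panel():
    spec = SyntheticPanelSpec(n_genes=6, length_codons_range=(150, 300), seed=7)
    panel, truth = generate_panel_with_truth(spec)
    assert [g["gene_id"] for g in truth["genes"]] == [c.gene_id for c in panel]
    for cds, g in zip(panel, truth["genes"]):
        assert cds.codon_count == g["length_codons"] + 1  # terminal stop
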