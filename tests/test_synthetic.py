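from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from etscan.ingest import apply_eligibility
from etscan.lexicon import detect_ets
from etscan.synthetic import (
    Archetype,
    GroupSpec,
    MarketConfig,
    generate_market,
    render_ingredient_text,
    sample_ets_sets,
)

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")


def _one_group_config(archetypes, n, seed=0, name="Premade Food & Dinner Kits"):
    return MarketConfig(
        groups={name: GroupSpec(n=n, archetypes=archetypes)},
        style_probs={"enumber": 0.4, "name": 0.3, "misspelling": 0.15,
                     "subclass": 0.15},
        defect_rates={},
        seed=seed,
    )


def test_same_seed_identical_output():
    cfg = MarketConfig.default(seed=42, scale=0.1)
    rec1, truth1 = generate_market(cfg)
    rec2, truth2 = generate_market(MarketConfig.default(seed=42, scale=0.1))
    pd.testing.assert_frame_equal(rec1, rec2)
    assert truth1.ets_sets == truth2.ets_sets
    rec3, _ = generate_market(MarketConfig.default(seed=43, scale=0.1))
    assert not rec1.equals(rec3)


def test_defect_tallies_match_ground_truth():
    cfg = MarketConfig.default(seed=9, scale=0.5)
    records, truth = generate_market(cfg)
    _, report = apply_eligibility(records)
    assert report.tallies == truth.expected_tallies
    assert report.n_eligible == len(records) - sum(truth.expected_tallies.values())


def test_zero_defect_config_excludes_nothing():
    cfg = MarketConfig.default(seed=2, scale=0.2)
    cfg.defect_rates = {k: 0.0 for k in cfg.defect_rates}
    records, truth = generate_market(cfg)
    _, report = apply_eligibility(records)
    assert sum(report.tallies.values()) == 0
    assert report.n_eligible == len(records)


def test_two_archetype_analytic_fold_enrichment():
    """w=(0.5,0.5), p=(0.8,0.8)/(0.1,0.1) gives pair FE ≈ 1.605 analytically,
    and the empirical estimate approaches it at large n."""
    arch = [
        Archetype(0.5, {"E412": 0.8, "E415": 0.8}),
        Archetype(0.5, {"E412": 0.1, "E415": 0.1}),
    ]
    cfg = _one_group_config(arch, n=20_000, seed=7)
    _, truth = generate_market(cfg)
    group = next(iter(cfg.groups))
    fe = truth.fold_enrichment(group, ["E412", "E415"])
    want = (0.5 * 0.64 + 0.5 * 0.01) / 0.45**2
    assert fe == pytest.approx(want)
    assert fe == pytest.approx(1.6049, abs=1e-3)

    sets = truth.ets_sets
    n = len(sets)
    both = sum(1 for s in sets if {"E412", "E415"} <= s)
    p1 = sum(1 for s in sets if "E412" in s) / n
    p2 = sum(1 for s in sets if "E415" in s) / n
    fe_hat = (both / n) / (p1 * p2)
    assert fe_hat == pytest.approx(fe, rel=0.1)


def test_single_archetype_is_independent():
    """With one archetype the analytic FE is exactly 1 for every combo."""
    arch = [Archetype(1.0, {"E450": 0.3, "E451": 0.2, "E412": 0.1})]
    cfg = _one_group_config(arch, n=10)
    _, truth = generate_market(cfg)
    group = next(iter(cfg.groups))
    for combo in (["E450", "E451"], ["E450", "E412"],
                  ["E450", "E451", "E412"]):
        assert truth.fold_enrichment(group, combo) == pytest.approx(1.0)


def test_empirical_marginals_converge(lexicon):
    """Per-code prevalence at n=5000 sits inside a 5-sigma binomial band."""
    probs = {"E412": 0.25, "E415": 0.10, "E450": 0.05}
    arch = [Archetype(1.0, probs)]
    rng = np.random.default_rng(123)
    spec = GroupSpec(n=5000, archetypes=arch)
    sets = sample_ets_sets(spec, 5000, rng)
    for code, p in probs.items():
        phat = sum(1 for s in sets if code in s) / 5000
        tol = 5 * np.sqrt(p * (1 - p) / 5000)
        assert abs(phat - p) < tol, code


@pytest.mark.parametrize("style,needle", [
    ("enumber", ("e407", "e 407", "e-407")),
    ("subclass", ("e472a", "e472b", "e472c", "e472d", "e472e", "e472f")),
])
def test_render_styles(lexicon, style, needle):
    rng = np.random.default_rng(0)
    code = "E407" if style == "enumber" else "E472"
    text = render_ingredient_text({code}, lexicon, rng, style=style).lower()
    assert any(tok in text for tok in needle)
    assert detect_ets(text, lexicon) == {code}


def test_render_empty_set_is_filler_only(lexicon):
    rng = np.random.default_rng(1)
    text = render_ingredient_text(frozenset(), lexicon, rng)
    assert text
    assert detect_ets(text, lexicon) == set()


def test_config_validation():
    bad_weight = [Archetype(0.6, {"E412": 0.5})]
    with pytest.raises(ValueError, match="weights"):
        _one_group_config(bad_weight, n=10).validate()
    bad_prob = [Archetype(1.0, {"E412": 1.5})]
    with pytest.raises(ValueError, match="outside"):
        _one_group_config(bad_prob, n=10).validate()
    cfg = _one_group_config([Archetype(1.0, {})], n=10)
    cfg.style_probs = {"enumber": 0.9}
    with pytest.raises(ValueError, match="style"):
        cfg.validate()
    cfg2 = _one_group_config([Archetype(1.0, {})], n=10)
    cfg2.defect_rates = {"duplicate": 1.0}
    with pytest.raises(ValueError, match="rate"):
        cfg2.validate()
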