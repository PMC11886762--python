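import numpy as np
import pytest
from scipy import stats

from ditchflux.data_model import to_frame, validate
from ditchflux.synthetic_data import (
    GeneratorConfig,
    generate,
    generate_three_gas_subset,
    latent_correlation_matrix,
    lognormal_params,
    write_dataset,
)


def test_default_config_matches_study_counts(default_records):
    frame = to_frame(default_records)
    assert len(frame) == 119
    assert frame.co2_flux.notna().sum() == 99
    assert frame.n2o_flux.notna().sum() == 56
    assert frame.ch4_diffusive.notna().sum() == 94
    assert frame.ch4_ebullitive.notna().sum() == 20
    assert (frame.co2_flux.dropna() < 0).sum() == 5
    assert (frame.n2o_flux.dropna() < 0).sum() == 6


def test_generated_data_validates_cleanly(default_records):
    assert validate(default_records).ok


def test_same_seed_gives_byte_identical_csv(tmp_path, default_config):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_dataset(generate(default_config, seed=7), p1, default_config, 7)
    write_dataset(generate(default_config, seed=7), p2, default_config, 7)
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.params.json").exists()


def test_different_seeds_differ(default_config):
    a = generate(default_config, seed=1)
    b = generate(default_config, seed=2)
    assert a != b


def test_lognormal_moment_matching_closed_form():
    mu, sigma = lognormal_params(2060.0, 2620.0)
    assert np.exp(mu + sigma**2 / 2) == pytest.approx(2060.0)
    var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
    assert np.sqrt(var) == pytest.approx(2620.0)


def test_source_flux_means_match_published_moments(default_config):
    """Mean CO2 and N2O source fluxes over 10 seeds land near the published
    2060 and 0.892 g gas m-2 yr-1 (within 15%; single seeds vary ~13%)."""
    co2_means, n2o_means = [], []
    for seed in range(1, 11):
        frame = to_frame(generate(default_config, seed=seed))
        co2 = frame.co2_flux.dropna()
        n2o = frame.n2o_flux.dropna()
        co2_means.append(co2[co2 > 0].mean())
        n2o_means.append(n2o[n2o > 0].mean())
    assert np.mean(co2_means) == pytest.approx(2060.0, rel=0.15)
    assert np.mean(n2o_means) == pytest.approx(0.892, rel=0.15)


def test_latent_matrix_is_psd_and_reproduces_targets(default_config):
    corr = latent_correlation_matrix(default_config)
    assert np.linalg.eigvalsh(corr).min() >= -1e-10
    np.testing.assert_allclose(np.diag(corr), 1.0)
    # without effects, the (co2, do) latent entry is exactly 2 sin(pi rho/6)
    plain = latent_correlation_matrix(GeneratorConfig(effects_enabled=False))
    assert plain[0, 3] == pytest.approx(2 * np.sin(np.pi * -0.74 / 6))


def test_infeasible_target_raises_naming_pair():
    cfg = GeneratorConfig(
        spearman_targets={("co2", "do"): 0.999},
    )
    with pytest.raises(ValueError, match="co2.*do"):
        latent_correlation_matrix(cfg)


def test_copula_recovers_spearman_structure(default_config):
    """Empirical pairwise-complete Spearman rho (mean over 10 seeds) lands
    within +/-0.15 of every injected target."""
    targets = {
        ("co2_flux", "do"): -0.74,
        ("co2_flux", "tp"): 0.55,
        ("n2o_flux", "ch4_diffusive"): 0.58,
        ("n2o_flux", "tn"): 0.53,
        ("co2_flux", "n2o_flux"): 0.50,
    }
    acc = {pair: [] for pair in targets}
    for seed in range(1, 11):
        frame = to_frame(generate(default_config, seed=seed))
        for (a, b) in targets:
            sub = frame[[a, b]].dropna()
            acc[(a, b)].append(stats.spearmanr(sub[a], sub[b])[0])
    for pair, target in targets.items():
        assert np.mean(acc[pair]) == pytest.approx(target, abs=0.15), pair


def test_effects_disabled_removes_group_structure():
    cfg = GeneratorConfig(effects_enabled=False)
    corr_on = latent_correlation_matrix(GeneratorConfig())
    corr_off = latent_correlation_matrix(cfg)
    # compensation inflates the n2o row only when effects are on
    assert abs(corr_on[1, 7]) > abs(corr_off[1, 7])


def test_ebullition_only_at_diffusive_sites(default_records):
    for rec in default_records:
        if rec.ch4_ebullitive is not None:
            assert rec.ch4_diffusive is not None
            assert rec.ch4_ebullitive >= 0


def test_daily_metadata_is_consistent_with_annual_flux(default_records):
    """Raw daily rates carried for harmonization re-derive the annual flux."""
    from ditchflux.harmonize import harmonize_record_flux

    n_meta = 0
    for rec in default_records:
        if rec.daily_flux_value is None:
            continue
        n_meta += 1
        annual = harmonize_record_flux(
            rec.daily_flux_value, rec.daily_flux_unit, rec.daily_flux_gas,
            season_length_days=rec.season_length_days,
        )
        assert annual == pytest.approx(rec.co2_flux, rel=1e-9)
    assert n_meta > 20


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_co2=200)
    with pytest.raises(ValueError):
        GeneratorConfig(n_ch4_ebullitive=100)
    with pytest.raises(ValueError):
        GeneratorConfig(co2_sd=-1.0)
    with pytest.raises(ValueError):
        GeneratorConfig(
            category_probs={**GeneratorConfig().category_probs,
                            "climate": {"temperate": 0.5, "continental": 0.4}}
        )


class TestThreeGasSubset:
    def test_shape_and_ebullition_count(self):
        recs = generate_three_gas_subset(seed=1)
        assert len(recs) == 22
        assert sum(r.ch4_ebullitive is not None for r in recs) == 2
        for rec in recs:
            assert rec.co2_flux is not None
            assert rec.n2o_flux is not None
            assert rec.ch4_diffusive is not None

    def test_deterministic_given_seed(self):
        assert generate_three_gas_subset(seed=3) == generate_three_gas_subset(seed=3)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_three_gas_subset(n=0)
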