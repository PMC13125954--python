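import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from hybridotype.ploidy_gmm import (
    denoise,
    fit_ploidy_models,
    fit_sample,
    ploidy_report,
    select_sites,
    write_fits,
)

from .util import make_record, make_table


def single_sample_table(ads, gqs=None):
    records = [
        make_record(f"m{j}", 10, "A", ("G",), [(0, 1)], ads=[ad],
                    gqs=None if gqs is None else [gqs[j - 1]])
        for j, ad in enumerate(ads, 1)
    ]
    return make_table(["x"], records)


def test_site_selection_rules():
    table = single_sample_table(
        [(30, 30),   # balance 0.5, depth 60 -> kept
         (58, 2),    # balance 0.033 -> outside bounds
         (12, 6),    # depth 18 < 20 -> excluded
         (2, 58),    # balance 0.967 -> outside bounds
         (25, 30)],  # kept
    )
    vals = select_sites(table, "x", min_sites=1)
    assert vals == pytest.approx([0.5, 30 / 55])


def test_site_selection_respects_gq_and_min_sites():
    table = single_sample_table([(30, 30)] * 5, gqs=[99, 99, 10, 99, 10])
    assert len(select_sites(table, "x", min_sites=1)) == 3
    with pytest.raises(ValueError, match="need >= 100"):
        select_sites(table, "x")


def truncated_normal(rng, mean, sd, n):
    x = rng.normal(mean, sd, size=3 * n)
    x = x[(x > 0.01) & (x < 0.99)]
    return x[:n]


def test_denoise_on_clean_and_half_uniform_data():
    rng = np.random.default_rng(100)
    clean = truncated_normal(rng, 0.5, 0.05, 600)
    _, noise = denoise(clean)
    assert noise < 0.05
    mixed = np.concatenate([truncated_normal(rng, 0.5, 0.05, 300),
                            rng.uniform(0, 1, 300)])
    weights, noise = denoise(mixed)
    assert noise == pytest.approx(0.5, abs=0.1)
    # signal weights favor the points near the mode
    near = np.abs(mixed - 0.5) < 0.05
    assert weights[near].mean() > weights[~near].mean()
    with pytest.raises(ValueError, match="denoise needs"):
        denoise(np.array([0.5, 0.5]))


def test_unimodal_half_balance_selects_diploid():
    rng = np.random.default_rng(7)
    x = truncated_normal(rng, 0.5, 0.05, 500)
    fit = fit_ploidy_models(x)
    assert fit.best_ploidy == 2


def test_bimodal_third_balances_select_triploid():
    rng = np.random.default_rng(8)
    x = np.concatenate([truncated_normal(rng, 1 / 3, 0.05, 250),
                        truncated_normal(rng, 2 / 3, 0.05, 250)])
    fit = fit_ploidy_models(x)
    assert fit.best_ploidy == 3


def test_trimodal_quarter_balances_select_tetraploid():
    rng = np.random.default_rng(9)
    x = np.concatenate([truncated_normal(rng, 0.25, 0.04, 170),
                        truncated_normal(rng, 0.5, 0.04, 170),
                        truncated_normal(rng, 0.75, 0.04, 170)])
    fit = fit_ploidy_models(x)
    assert fit.best_ploidy == 4


def test_degenerate_constant_values_fall_back_to_diploid():
    x = np.full(300, 0.5)
    with pytest.warns(UserWarning, match="variance"):
        fit = fit_ploidy_models(x)
    assert fit.best_ploidy == 2
    assert fit.delta[2] == pytest.approx(0.0, abs=1e-6)


def test_free_model_dominates_fixed_models(noiseless_cohort):
    table, _, _ = noiseless_cohort
    for s in ["E2_01", "E3_LLR_01"]:
        fit = fit_sample(table, s, seed=1, min_sites=60)
        for p, ll in fit.loglik_fixed.items():
            assert fit.loglik_free >= ll - 1e-6
            assert fit.delta[p] >= -1e-6


def test_reported_loglik_matches_brute_force_recomputation():
    rng = np.random.default_rng(12)
    x = np.concatenate([truncated_normal(rng, 1 / 3, 0.05, 200),
                        truncated_normal(rng, 2 / 3, 0.05, 200)])
    w = rng.uniform(0.5, 1.0, size=len(x))
    fit = fit_ploidy_models(x, weights=w)
    for key, model in fit.models.items():
        logp = np.log(model.weights)[None, :] + norm.logpdf(
            x[:, None], model.means[None, :], np.sqrt(model.var)
        )
        brute = float(np.dot(w, logsumexp(logp, axis=1)))
        assert model.loglik == pytest.approx(brute, abs=1e-8), key


def test_r_squared_is_high_for_well_separated_modes():
    rng = np.random.default_rng(13)
    x = truncated_normal(rng, 0.5, 0.03, 2000)
    fit = fit_ploidy_models(x)
    assert 0.0 <= fit.r_squared <= 1.0
    assert fit.r_squared > 0.6


def test_parental_sample_with_few_het_sites_still_fits(sim_cohort):
    table, _, _ = sim_cohort
    # parentals carry far fewer heterozygous-like sites than hybrids
    n_parental = len(select_sites(table, "L_01", min_sites=1))
    n_hybrid = len(select_sites(table, "E2_01", min_sites=1))
    assert n_parental < n_hybrid / 2
    fit = fit_sample(table, "L_01", min_sites=min(n_parental, 30), seed=4)
    assert fit.best_ploidy in (2, 3, 4)


def test_report_and_table_outputs(tmp_path):
    rng = np.random.default_rng(14)
    fits = [
        fit_ploidy_models(truncated_normal(rng, 0.5, 0.05, 300), sample_id="a"),
        fit_ploidy_models(
            np.concatenate([truncated_normal(rng, 1 / 3, 0.05, 150),
                            truncated_normal(rng, 2 / 3, 0.05, 150)]),
            sample_id="b",
        ),
    ]
    plot = tmp_path / "ploidy.png"
    tsv = tmp_path / "ploidy.tsv"
    ploidy_report(fits, plot, tsv)
    assert plot.stat().st_size > 0
    lines = tsv.read_text().splitlines()
    assert len(lines) == 3
    assert lines[1].split("\t")[6] == "2" and lines[2].split("\t")[6] == "3"
    with pytest.raises(ValueError):
        ploidy_report([], tmp_path / "x.png")
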