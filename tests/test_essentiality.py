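"""Gamma-mixture essentiality: valley finding, component fits, labels."""

import numpy as np
import pytest

from pytradis.core import GeneInsertionStats
from pytradis.essentiality import (
    call_essentiality,
    classify,
    find_pivot,
    fit_components,
    replace_zeros,
)
from pytradis.simulate import SimulationConfig, simulate


def _mixture(rng, n_ess=400, n_non=1600, ess=(0.5, 0.002), non=(6.0, 0.05)):
    """shape/mean parameterization, matching how library densities arise."""
    a1, m1 = ess
    a2, m2 = non
    return np.concatenate(
        [rng.gamma(a1, m1 / a1, size=n_ess), rng.gamma(a2, m2 / a2, size=n_non)]
    )


# ---------------------------------------------------------------------------
# find_pivot


def test_pivot_falls_between_the_component_means(rng):
    idx = _mixture(rng)
    pivot = find_pivot(idx)
    assert 0.002 < pivot < 0.05


def test_pivot_identical_indices_is_hard_error():
    with pytest.raises(ValueError, match="identical|valley|unimodal"):
        find_pivot(np.full(500, 0.05))


def test_pivot_unimodal_input_is_hard_error(rng):
    with pytest.raises(ValueError, match="unimodal|valley"):
        find_pivot(rng.gamma(6.0, 0.05 / 6.0, size=1000))


def test_pivot_requires_enough_genes(rng):
    with pytest.raises(ValueError, match="100"):
        find_pivot(_mixture(rng, 10, 30))


def test_pivot_stable_under_dataset_duplication(rng):
    idx = _mixture(rng)
    p1 = find_pivot(idx)
    p2 = find_pivot(np.concatenate([idx, idx]))
    # scale-free in n up to the bandwidth's weak n-dependence
    assert abs(np.log10(p2) - np.log10(p1)) < 0.15


def test_zero_replacement_is_half_min_positive():
    replaced, pseudo = replace_zeros(np.array([0.0, 0.01, 0.02]))
    assert pseudo == 0.005 and replaced[0] == 0.005


# ---------------------------------------------------------------------------
# fit_components


def test_parameter_recovery_on_two_gamma_data():
    """n=2000 per side: shapes and rates recovered within 15%."""
    rng = np.random.default_rng(42)
    idx = np.concatenate(
        [rng.gamma(0.4, 1 / 200, size=2000), rng.gamma(6.0, 1 / 120, size=2000)]
    )
    fit = fit_components(idx)
    assert abs(fit.shape_ess - 0.4) / 0.4 < 0.15
    assert abs(fit.rate_ess - 200) / 200 < 0.15
    assert abs(fit.shape_non - 6.0) / 6.0 < 0.15
    assert abs(fit.rate_non - 120) / 120 < 0.15


def test_changepoints_sit_exactly_on_the_threshold(rng):
    fit = fit_components(_mixture(rng))
    assert fit.log2_ratio(fit.changepoint_lo) == pytest.approx(fit.loglik_threshold, abs=1e-6)
    assert fit.log2_ratio(fit.changepoint_hi) == pytest.approx(-fit.loglik_threshold, abs=1e-6)
    assert fit.changepoint_lo <= fit.changepoint_hi


def test_higher_threshold_widens_ambiguous_band(rng):
    idx = _mixture(rng)
    pivot = find_pivot(idx)
    f2 = fit_components(idx, pivot, loglik_threshold=2)
    f3 = fit_components(idx, pivot, loglik_threshold=3)
    assert f3.changepoint_lo <= f2.changepoint_lo
    assert f3.changepoint_hi >= f2.changepoint_hi


def test_too_few_observations_per_side_is_error(rng):
    idx = np.concatenate([np.full(5, 1e-4), rng.gamma(6, 0.05 / 6, 200)])
    with pytest.raises(ValueError, match=">= 10"):
        fit_components(idx, pivot=0.01)


# ---------------------------------------------------------------------------
# classify


def _stats_from_indices(indices, length=1000):
    return [
        GeneInsertionStats(
            gene_id=f"g{i}", replicon="chr", start=1, end=length, strand="+",
            read_count=int(round(v * length) * 2), insertion_count=int(round(v * length)),
            gene_length=length,
        )
        for i, v in enumerate(indices)
    ]


def test_zero_index_is_always_essential(rng):
    fit = fit_components(_mixture(rng))
    [call] = classify(_stats_from_indices([0.0]), fit)
    assert call.label == "essential" and call.log2_ratio >= fit.loglik_threshold


def test_high_index_is_non_essential(rng):
    fit = fit_components(_mixture(rng))
    [call] = classify(_stats_from_indices([0.12]), fit)
    assert call.label == "non_essential"


def test_labels_partition_and_match_interval_rule(rng):
    """Each gene gets exactly one label, and the density-ratio rule equals
    the changepoint-interval rule on a grid of indices."""
    fit = fit_components(_mixture(rng))
    grid = np.geomspace(1e-5, 0.2, 200)
    calls = classify(_stats_from_indices(grid), fit)
    for x, call in zip(grid, calls):
        x_eval = max(x, fit.zero_replacement)
        if x_eval < fit.changepoint_lo:
            expected = "essential"
        elif x_eval > fit.changepoint_hi:
            expected = "non_essential"
        else:
            expected = "ambiguous"
        assert call.label == expected, x
        assert call.label in ("essential", "ambiguous", "non_essential")


def test_simulated_library_recovery():
    """Planted essentials (zero insertions) recovered with high sensitivity
    and few false essential calls."""
    cfg = SimulationConfig(
        seed=21, n_replicons=1, replicon_lengths=(600_000,), n_genes=500,
        n_insertions=30_000, reads_per_insertion=2.0,
    )
    lib = simulate(cfg)
    calls, fit = call_essentiality(lib.truth_stats)
    assert len(calls) == 500
    called = {c.gene_id for c in calls if c.label == "essential"}
    n_ess = len(lib.essential_ids)
    sens = len(called & lib.essential_ids) / n_ess
    fpr = len(called - lib.essential_ids) / (500 - n_ess)
    assert sens >= 0.95
    assert fpr <= 0.02


def test_write_calls_and_metadata(tmp_path, rng):
    fit = fit_components(_mixture(rng))
    stats = _stats_from_indices([0.0, 0.05, 0.002])
    calls = classify(stats, fit)
    from pytradis.essentiality import write_calls, write_fit_metadata

    out = tmp_path / "calls.tsv"
    write_calls(stats, calls, str(out))
    lines = out.read_text().splitlines()
    assert lines[0].endswith("log2_ratio\tlabel") and len(lines) == 4
    meta = tmp_path / "fit.txt"
    write_fit_metadata(fit, str(meta))
    assert "pivot" in meta.read_text()
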