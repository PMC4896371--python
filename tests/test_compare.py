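"""Comparative analysis: TMM, common dispersion, exact test, BH."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pytradis.compare import (
    ComparisonRow,
    CountMatrix,
    _exact_pvalue,
    estimate_dispersion,
    exact_test,
    tmm_normalize,
)


def _cm(counts, n1=3, n2=3):
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    df = pd.DataFrame(np.asarray(counts), columns=cols)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(len(df))],
        conditions={"A": cols[:n1], "B": cols[n1:]},
        counts=df,
    )


def _nb(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


# ---------------------------------------------------------------------------
# TMM


def test_identical_columns_give_unit_factors(rng):
    col = rng.integers(1, 500, size=300)
    f = tmm_normalize(pd.DataFrame({"a": col, "b": col}))
    assert np.allclose(f, 1.0)


def test_pure_depth_doubling_is_compensated(rng):
    col = rng.integers(1, 500, size=300)
    f = tmm_normalize(pd.DataFrame({"a": col, "b": 2 * col}))
    # normalized counts match: (count / (libsize * factor)) equal per gene
    eff = np.array([col.sum() * f.iloc[0], 2 * col.sum() * f.iloc[1]])
    assert np.allclose(col / eff[0], 2 * col / eff[1])
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


def test_all_zero_sample_is_hard_error():
    with pytest.raises(ValueError, match="all-zero"):
        tmm_normalize(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


def test_tmm_matches_edger(rng, tmp_path):
    """Independent oracle: edgeR's calcNormFactors on random matrices."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.05, size=(400, 5)), columns=list("abcde")
    )
    counts["b"] *= 3
    counts["e"] = (counts["e"] * 0.4).astype(int) + 1
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{path}"));'
        'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")'
    )
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"edgeR unavailable: {proc.stderr.strip()[:120]}")
    reference = np.array([float(v) for v in proc.stdout.split()])
    mine = tmm_normalize(counts).to_numpy()
    assert np.allclose(mine, reference, atol=1e-6)


# ---------------------------------------------------------------------------
# dispersion


def test_poisson_data_gives_near_zero_dispersion(rng):
    mu = rng.gamma(2, 100, size=2000)
    cm = _cm(rng.poisson(mu[:, None], size=(2000, 6)))
    assert estimate_dispersion(cm) < 0.01


def test_nb_dispersion_recovered(rng):
    mu = rng.gamma(2, 100, size=2000)
    cm = _cm(_nb(rng, mu[:, None], 0.2, (2000, 6)))
    assert 0.15 <= estimate_dispersion(cm) <= 0.25


def test_dispersion_invariant_to_gene_order(rng):
    mu = rng.gamma(2, 100, size=500)
    counts = _nb(rng, mu[:, None], 0.15, (500, 6))
    a = estimate_dispersion(_cm(counts))
    b = estimate_dispersion(_cm(counts[::-1]))
    assert a == pytest.approx(b, rel=1e-6)


def test_no_replication_is_hard_error(rng):
    cm = _cm(rng.poisson(100, size=(100, 2)), n1=1, n2=1)
    with pytest.raises(ValueError, match="replicate"):
        estimate_dispersion(cm)


# ---------------------------------------------------------------------------
# exact test


def test_identical_counts_give_p_one():
    cm = _cm(np.full((20, 6), 50))
    rows = exact_test(cm, "A", "B", dispersion=0.1)
    assert all(r.p_value == pytest.approx(1.0) for r in rows)


def test_condition_swap_negates_logfc_keeps_p(rng):
    mu = rng.gamma(2, 100, size=300)
    cm = _cm(_nb(rng, mu[:, None], 0.1, (300, 6)))
    ab = exact_test(cm, "A", "B", dispersion=0.1)
    ba = exact_test(cm, "B", "A", dispersion=0.1)
    for x, y in zip(ab, ba):
        assert x.p_value == pytest.approx(y.p_value, rel=1e-9)
        assert x.log2_fold_change == pytest.approx(-y.log2_fold_change, rel=1e-9)


def test_all_zero_genes_reported_with_nan(rng):
    counts = _nb(rng, 100, 0.1, (50, 6))
    counts[7] = 0
    rows = exact_test(_cm(counts), "A", "B", dispersion=0.1)
    assert np.isnan(rows[7].p_value) and np.isnan(rows[7].q_value)
    assert not np.isnan(rows[6].p_value)


def test_bh_matches_bruteforce(rng):
    mu = rng.gamma(2, 100, size=200)
    cm = _cm(_nb(rng, mu[:, None], 0.1, (200, 6)))
    rows = exact_test(cm, "A", "B", dispersion=0.1)
    p = np.array([r.p_value for r in rows])
    q = np.array([r.q_value for r in rows])
    order = np.argsort(p)
    n = len(p)
    brute = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        brute[i] = running
    assert np.allclose(q, brute)


def test_poisson_limit_agrees_with_conditional_binomial():
    """phi=0: the conditional law of one group's sum is binomial; check a
    hand-checkable pair against scipy's two-sided binomial test."""
    from scipy.stats import binomtest

    for z1, z2, n1, n2 in [(8, 2, 1, 1), (10, 30, 2, 2), (5, 5, 3, 1)]:
        p = _exact_pvalue(z1, z2, n1, n2, phi=0.0)
        ref = binomtest(z1, z1 + z2, n1 / (n1 + n2)).pvalue
        assert p == pytest.approx(ref, rel=1e-9), (z1, z2, n1, n2)


def test_null_calibration_and_power(rng):
    """phi=0.1, 3v3: null p-values are calibrated; strong depletions are
    detected at q < 0.05."""
    mu = np.full(2000, 200.0)
    cm = _cm(_nb(rng, mu[:, None], 0.1, (2000, 6)))
    rows = exact_test(cm, "A", "B")
    p = np.array([r.p_value for r in rows])
    assert 0.025 <= (p < 0.05).mean() <= 0.075

    mu2 = mu.copy()
    mu2[:100] /= 8
    y1 = _nb(rng, mu[:, None], 0.1, (2000, 3))
    y2 = _nb(rng, mu2[:, None], 0.1, (2000, 3))
    rows = exact_test(_cm(np.hstack([y1, y2])), "A", "B")
    q = np.array([r.q_value for r in rows])
    assert (q[:100] < 0.05).mean() >= 0.90
    lfc = np.array([r.log2_fold_change for r in rows])
    assert lfc[:100].mean() == pytest.approx(-3.0, abs=0.5)


def test_count_matrix_from_gene_stats_files(small_lib, tmp_path):
    from pytradis.io import write_gene_stats

    paths = {}
    for cond in ("ctrl", "sel"):
        ps = []
        for i in range(2):
            p = tmp_path / f"{cond}{i}.tsv"
            write_gene_stats(small_lib.truth_stats, str(p))
            ps.append(str(p))
        paths[cond] = ps
    cm = CountMatrix.from_gene_stats_files(paths)
    assert cm.counts.shape == (len(small_lib.truth_stats), 4)
    assert (cm.counts.iloc[:, 0] == [s.read_count for s in small_lib.truth_stats]).all()
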