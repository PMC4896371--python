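"""Between-condition fitness comparison of mutant read counts.

Read counts per gene proxy the abundance of the corresponding insertion
mutants, so a gene whose counts drop between an input and a selected
condition harbours insertions that are deleterious under selection. The
analysis follows the classic count-testing recipe for two-group designs:

* TMM (trimmed mean of M-values) library-size normalization,
* a single common negative-binomial dispersion estimated by conditional
  maximum likelihood on counts scaled to a common library size,
* a per-gene two-sided exact NB test on the group-summed scaled counts
  conditioned on their total, and
* Benjamini–Hochberg FDR adjustment across tested genes.

The computation is self-contained (no runtime dependency on external
count-testing packages); the TMM factors are cross-checked against an
independent reference implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

_POISSON_PHI = 1e-8  # below this the NB conditional reduces to binomial


@dataclass
class CountMatrix:
    """Genes x samples count matrix with a condition -> samples design."""

    gene_ids: List[str]
    conditions: Dict[str, List[str]]
    counts: pd.DataFrame  # index: gene_ids, columns: sample names

    def __post_init__(self) -> None:
        samples = [s for ss in self.conditions.values() for s in ss]
        if sorted(samples) != sorted(self.counts.columns):
            raise ValueError("condition design does not match count matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_gene_stats_files(
        cls,
        condition_files: Dict[str, Sequence[str]],
        value: str = "read_count",
    ) -> "CountMatrix":
        """Build a count matrix from per-sample gene-statistics TSVs.

        ``value`` selects the counted quantity: 'read_count' (default) or
        'ins_count' (unique insertion sites).
        """
        from .io import read_gene_stats

        column = {"read_count": "read_count", "ins_count": "insertion_count"}[value]
        series = {}
        conditions: Dict[str, List[str]] = {}
        gene_ids: Optional[List[str]] = None
        for cond, paths in condition_files.items():
            conditions[cond] = []
            for path in paths:
                stats = read_gene_stats(path)
                ids = [s.gene_id for s in stats]
                if gene_ids is None:
                    gene_ids = ids
                elif ids != gene_ids:
                    raise ValueError(f"{path}: gene order differs between sample tables")
                name = f"{cond}:{path}"
                conditions[cond].append(name)
                series[name] = [getattr(s, column) for s in stats]
        counts = pd.DataFrame(series, index=gene_ids)
        return cls(gene_ids=list(gene_ids), conditions=conditions, counts=counts)


@dataclass
class ComparisonRow:
    gene_id: str
    log2_fold_change: float
    mean_log_cpm: float
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.abs(log_r).max() < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    r_rank = rankdata(log_r)
    e_rank = rankdata(abs_e)
    kept = (r_rank >= lo_l) & (r_rank <= hi_l) & (e_rank >= lo_s) & (e_rank <= hi_s)
    if not kept.any():
        return 1.0
    f = np.sum(log_r[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return float(2.0 ** f)


def tmm_normalize(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample is the column whose 75th count percentile (scaled
    by library size) is closest to the mean across samples. 30% of M-values
    and 5% of A-values are trimmed from each tail; the trimmed mean is
    precision-weighted. A sample with zero total count is a hard error.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    f75 = np.array([np.percentile(mat[:, j], 75) / lib[j] for j in range(mat.shape[1])])
    ref_col = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_col], lib[j], lib[ref_col])
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Common dispersion (conditional maximum likelihood on scaled counts)


def _scaled_pseudo(counts: pd.DataFrame, factors: pd.Series) -> Tuple[pd.DataFrame, float]:
    """Scale every sample to the geometric-mean effective library size."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * factors.loc[counts.columns].to_numpy(dtype=float)
    geo = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.to_numpy(dtype=float) * (geo / eff)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), geo


def _conditional_loglik(phi: float, group_mats: Sequence[np.ndarray]) -> float:
    """NB conditional log-likelihood given per-group totals, equal library
    sizes, summed over genes and groups."""
    r = 1.0 / phi
    total = 0.0
    for y in group_mats:
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size * gammaln(r)
            + len(z) * gammaln(n * r) - np.sum(gammaln(z + n * r))
        )
    return total


def estimate_dispersion(counts: "CountMatrix", factors: Optional[pd.Series] = None) -> float:
    """Single common NB dispersion phi maximizing the conditional likelihood.

    Counts are first scaled to the geometric-mean effective library size so
    replicates are exchangeable, then the conditional likelihood of each
    gene's replicate counts given their group sum is maximized over phi.
    Requires at least one condition with >= 2 replicates. phi ~ 0 is the
    Poisson limit.
    """
    if factors is None:
        factors = tmm_normalize(counts.counts)
    replicated = {c: s for c, s in counts.conditions.items() if len(s) >= 2}
    if not replicated:
        raise ValueError(
            "no condition has replicates: common dispersion cannot be estimated; "
            "supply a dispersion value explicitly"
        )
    pseudo, _ = _scaled_pseudo(counts.counts, factors)
    group_mats = []
    for samples in replicated.values():
        y = pseudo[samples].to_numpy(dtype=float)
        y = y[y.sum(axis=1) > 0]  # all-zero genes carry no information
        group_mats.append(y)

    res = minimize_scalar(
        lambda t: -_conditional_loglik(float(np.exp(t)), group_mats),
        bounds=(np.log(1e-6), np.log(10.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


# ---------------------------------------------------------------------------
# Exact test


def _exact_pvalue(z1: float, z2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional p-value for group sums z1 vs z2.

    Under the null the per-replicate means are equal, so conditioned on
    z = z1 + z2 the first group's sum follows a beta-binomial-type weight
    w(k) ∝ Γ(k+r1)/k! · Γ(z-k+r2)/(z-k)! with r_i = n_i/phi (binomial with
    p = n1/(n1+n2) in the Poisson limit). The p-value sums the weights of
    all outcomes no more probable than the observed one.
    """
    # round each group sum (scaled counts are non-integer) so the test is
    # exactly symmetric under condition swap
    obs = int(round(z1))
    z = obs + int(round(z2))
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi <= _POISSON_PHI:
        p = n1 / (n1 + n2)
        logw = (
            gammaln(z + 1) - gammaln(k + 1) - gammaln(z - k + 1)
            + k * np.log(p) + (z - k) * np.log1p(-p)
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logw = gammaln(k + r1) - gammaln(k + 1) + gammaln(z - k + r2) - gammaln(z - k + 1)
    logw -= logw.max()
    w = np.exp(logw)
    pv = w[w <= w[obs] * (1.0 + 1e-10)].sum() / w.sum()
    return float(min(pv, 1.0))


def exact_test(
    counts: "CountMatrix",
    cond1: str,
    cond2: str,
    factors: Optional[pd.Series] = None,
    dispersion: Optional[float] = None,
) -> List[ComparisonRow]:
    """Per-gene two-sided exact NB test of ``cond2`` versus ``cond1``.

    Counts are scaled to the geometric-mean effective library size, summed
    within each condition, and tested conditioned on the gene's total.
    Fold changes are cond2 over cond1 with a half-count prior per group
    mean. Genes with zero counts in both conditions are excluded from
    testing and reported with NaN p/q. q-values are Benjamini–Hochberg
    over the tested genes.
    """
    for cond in (cond1, cond2):
        if cond not in counts.conditions:
            raise ValueError(f"unknown condition {cond!r}")
    if factors is None:
        factors = tmm_normalize(counts.counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors)
    s1, s2 = counts.conditions[cond1], counts.conditions[cond2]
    pseudo, geo = _scaled_pseudo(counts.counts[s1 + s2], factors.loc[s1 + s2])
    n1, n2 = len(s1), len(s2)
    z1 = pseudo[s1].sum(axis=1).to_numpy()
    z2 = pseudo[s2].sum(axis=1).to_numpy()

    logfc = np.log2((z2 / n2 + 0.5) / (z1 / n1 + 0.5))
    logcpm = np.log2(((z1 + z2) / (n1 + n2) + 0.5) / geo * 1e6)

    pvals = np.full(len(z1), np.nan)
    tested = (z1 + z2) > 0
    for i in np.nonzero(tested)[0]:
        pvals[i] = _exact_pvalue(z1[i], z2[i], n1, n2, dispersion)
    qvals = np.full_like(pvals, np.nan)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    return [
        ComparisonRow(
            gene_id=g,
            log2_fold_change=float(logfc[i]),
            mean_log_cpm=float(logcpm[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
        )
        for i, g in enumerate(counts.gene_ids)
    ]


def compare_conditions(
    condition_files: Dict[str, Sequence[str]],
    cond1: str,
    cond2: str,
    dispersion: Optional[float] = None,
    value: str = "read_count",
) -> List[ComparisonRow]:
    """End-to-end comparison from per-sample gene-statistics TSVs."""
    cm = CountMatrix.from_gene_stats_files(condition_files, value=value)
    return exact_test(cm, cond1, cond2, dispersion=dispersion)


def write_comparison(rows: Sequence[ComparisonRow], path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tlog2FC\tlogCPM\tPValue\tQValue\n")
        for r in rows:
            p = "" if np.isnan(r.p_value) else f"{r.p_value:.6g}"
            q = "" if np.isnan(r.q_value) else f"{r.q_value:.6g}"
            fh.write(f"{r.gene_id}\t{r.log2_fold_change:.6g}\t{r.mean_log_cpm:.6g}\t{p}\t{q}\n")
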