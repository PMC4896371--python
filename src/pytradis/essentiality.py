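"""Gene essentiality calls from the bimodal insertion-index distribution.

In a dense transposon library the per-gene insertion index (unique
insertion sites / gene length) is bimodal: essential genes cluster at or
near zero, non-essential genes form a broad positive mode. The classifier

1. locates the valley (``pivot``) between the two modes on a smoothed
   density of the indices,
2. fits a gamma distribution by maximum likelihood to each side of the
   pivot (the "essential" and "non-essential" components), and
3. labels each gene by the log2 ratio of the two component densities at
   its index: ``>= loglik_threshold`` → essential, ``<= -loglik_threshold``
   → non_essential, otherwise ambiguous. The default threshold of 2
   corresponds to 4:1 odds.

A gamma likelihood is undefined at zero, so zero indices are replaced by
half the smallest positive index for valley finding, fitting and
evaluation alike. This is a likelihood-ratio classification, not
hypothesis testing: no multiple-testing correction applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import digamma

from .core import GeneInsertionStats

DEFAULT_LOGLIK_THRESHOLD = 2.0
MIN_FIT_GENE_LENGTH = 100  # nt; shorter genes have too-granular indices to fit


@dataclass(frozen=True)
class GammaMixtureFit:
    """Fitted essential / non-essential gamma components and changepoints."""

    shape_ess: float
    rate_ess: float
    shape_non: float
    rate_non: float
    pivot: float
    changepoint_lo: float
    changepoint_hi: float
    loglik_threshold: float
    zero_replacement: float

    def log2_ratio(self, index: float | np.ndarray) -> float | np.ndarray:
        """log2 of essential-component density over non-essential density."""
        x = np.where(np.asarray(index, dtype=float) <= 0, self.zero_replacement, index)
        num = sps.gamma.logpdf(x, a=self.shape_ess, scale=1.0 / self.rate_ess)
        den = sps.gamma.logpdf(x, a=self.shape_non, scale=1.0 / self.rate_non)
        return (num - den) / np.log(2)


@dataclass(frozen=True)
class EssentialityCall:
    gene_id: str
    insertion_index: float
    log2_ratio: float
    label: str  # essential | ambiguous | non_essential


def replace_zeros(indices: np.ndarray) -> Tuple[np.ndarray, float]:
    """Replace zero indices with half the smallest positive index."""
    indices = np.asarray(indices, dtype=float)
    positive = indices[indices > 0]
    if positive.size == 0:
        raise ValueError("all insertion indices are zero; library has no insertions")
    pseudo = positive.min() / 2.0
    return np.where(indices <= 0, pseudo, indices), pseudo


def find_pivot(indices: Sequence[float], grid_points: int = 512) -> float:
    """Insertion-index value at the density valley between the two modes.

    Zero indices are mapped to the half-min-positive pseudo-value, then a
    Gaussian KDE with Silverman bandwidth is evaluated on log10(index) —
    the two modes of a dense library are separated multiplicatively, so the
    valley is much better resolved on the log scale. The pivot is the
    argmin of the smoothed density between the two largest local maxima.

    Raises if the smoothed density is unimodal (no interior valley): the
    library is not dense enough for a bimodal fit.
    """
    indices = np.asarray(indices, dtype=float)
    if indices.size < 100:
        raise ValueError(f"need >= 100 gene indices to locate the valley, got {indices.size}")
    replaced, _ = replace_zeros(indices)
    logx = np.log10(replaced)
    if np.ptp(logx) == 0:
        raise ValueError("all insertion indices identical: no valley (library not dense enough?)")
    kde = sps.gaussian_kde(logx, bw_method="silverman")
    bw = kde.factor * logx.std(ddof=1)
    grid = np.linspace(logx.min() - 3 * bw, logx.max() + 3 * bw, grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if maxima.size < 2:
        raise ValueError(
            "insertion-index density is unimodal: no valley between an "
            "essential and a non-essential mode (library not dense enough?)"
        )
    top_two = maxima[np.argsort(dens[maxima])][-2:]
    lo, hi = int(top_two.min()), int(top_two.max())
    valley = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    return float(10 ** grid[valley])


def _gamma_mle(x: np.ndarray, w: Optional[np.ndarray] = None) -> Optional[Tuple[float, float]]:
    """(Weighted) gamma MLE with location fixed at zero; (shape, rate).

    Solves log(a) - digamma(a) = log(mean) - mean(log) by bisection.
    Returns None for a (near-)constant sample, where the Jensen gap
    vanishes and the shape MLE diverges.
    """
    if w is None:
        w = np.ones_like(x)
    total = w.sum()
    if total <= 0:
        return None
    mean = float((w * x).sum() / total)
    s = float(np.log(mean) - (w * np.log(x)).sum() / total)
    if not np.isfinite(s) or s <= 1e-8:
        return None
    try:
        shape = brentq(lambda a: np.log(a) - digamma(a) - s, 1e-3, 1e7)
    except ValueError:
        return None
    return float(shape), float(shape / mean)


def _fit_gamma(data: np.ndarray, atom: Optional[float] = None) -> Tuple[float, float]:
    """Gamma MLE for one component; returns (shape, rate).

    Two degeneracies fall back to the exponential sub-family (shape 1,
    rate 1/mean — the ML solution with the shape pinned): a (near-)
    constant sample, where the shape MLE diverges, and a sample dominated
    by the zero-replacement ``atom`` (more than half its observations),
    where the continuous likelihood is driven by a point mass and the
    "fit" would be an arbitrarily tight spike. Both arise when planted or
    real essential genes all sit at insertion index zero; the exponential
    component still decays fast enough that the pseudo-value region is
    decisively essential.
    """
    data = np.asarray(data, dtype=float)
    if atom is not None and (data == atom).mean() > 0.5:
        return 1.0, float(1.0 / data.mean())
    est = _gamma_mle(data)
    if est is None:
        return 1.0, float(1.0 / data.mean())
    return est


def _em_refine(
    x: np.ndarray,
    ess: Tuple[float, float],
    non: Tuple[float, float],
    weight_ess: float,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> Optional[Tuple[float, float, float, float]]:
    """EM maximum-likelihood refinement of the two-gamma mixture.

    The split fit only initializes: hard assignment at the pivot truncates
    both components and misassigns overlap-region observations, biasing
    the parameters. EM removes that bias. Returns None — caller keeps the
    split fit — when a component collapses (degenerate spike, vanishing
    weight), as happens when essential genes all sit on the pseudo-value.
    """
    (a1, r1), (a2, r2), pi = ess, non, weight_ess
    prev = -np.inf
    for _ in range(max_iter):
        l1 = np.log(pi) + sps.gamma.logpdf(x, a=a1, scale=1.0 / r1)
        l2 = np.log1p(-pi) + sps.gamma.logpdf(x, a=a2, scale=1.0 / r2)
        hi = np.maximum(l1, l2)
        loglik = float((hi + np.log(np.exp(l1 - hi) + np.exp(l2 - hi))).sum())
        with np.errstate(over="ignore"):
            resp = 1.0 / (1.0 + np.exp(l2 - l1))
        g1 = _gamma_mle(x, resp)
        g2 = _gamma_mle(x, 1.0 - resp)
        if g1 is None or g2 is None:
            return None
        (a1, r1), (a2, r2) = g1, g2
        pi = float(resp.mean())
        if a1 > 1e3 or a2 > 1e3 or min(pi, 1.0 - pi) < 1e-3:
            return None
        if abs(loglik - prev) < tol * (1.0 + abs(loglik)):
            break
        prev = loglik
    if a1 / r1 > a2 / r2:  # keep "essential" the low-mean component
        (a1, r1), (a2, r2) = (a2, r2), (a1, r1)
    return a1, r1, a2, r2


def fit_components(
    indices: Sequence[float],
    pivot: Optional[float] = None,
    loglik_threshold: float = DEFAULT_LOGLIK_THRESHOLD,
) -> GammaMixtureFit:
    """Fit the two gamma components and solve the log-odds changepoints.

    The essential component is fit by maximum likelihood to indices below
    the pivot (zeros replaced by the pseudo-value), the non-essential
    component to indices at or above it; an EM pass over the two-gamma
    mixture then refines both fits, removing the truncation bias of the
    hard split (the EM result is kept only when it converges to two proper
    components — a degenerate spike of identical pseudo-values reverts to
    the split fit). Changepoints are the index values where
    ``|log2(dens_ess/dens_non)|`` equals ``loglik_threshold``; because
    shape_ess < shape_non and rate_ess > rate_non in any well-separated
    library, the log ratio is strictly decreasing and each crossing is
    unique.
    """
    indices = np.asarray(indices, dtype=float)
    replaced, pseudo = replace_zeros(indices)
    if pivot is None:
        pivot = find_pivot(indices)
    ess = replaced[replaced < pivot]
    non = replaced[replaced >= pivot]
    if ess.size < 10 or non.size < 10:
        raise ValueError(
            f"need >= 10 observations on each side of pivot {pivot:g} "
            f"(got {ess.size} below, {non.size} at/above)"
        )
    shape_ess, rate_ess = _fit_gamma(ess, atom=pseudo)
    shape_non, rate_non = _fit_gamma(non)
    refined = _em_refine(
        replaced, (shape_ess, rate_ess), (shape_non, rate_non), ess.size / replaced.size
    )
    if refined is not None:
        shape_ess, rate_ess, shape_non, rate_non = refined

    def log2_ratio(x: float) -> float:
        return (
            sps.gamma.logpdf(x, a=shape_ess, scale=1.0 / rate_ess)
            - sps.gamma.logpdf(x, a=shape_non, scale=1.0 / rate_non)
        ) / np.log(2)

    lo = _solve_crossing(log2_ratio, loglik_threshold, pseudo, replaced.max())
    hi = _solve_crossing(log2_ratio, -loglik_threshold, pseudo, replaced.max())
    if lo > hi:
        raise RuntimeError("changepoints crossed; components not separated")
    return GammaMixtureFit(
        shape_ess=shape_ess,
        rate_ess=rate_ess,
        shape_non=shape_non,
        rate_non=rate_non,
        pivot=float(pivot),
        changepoint_lo=lo,
        changepoint_hi=hi,
        loglik_threshold=float(loglik_threshold),
        zero_replacement=pseudo,
    )


def _solve_crossing(log2_ratio, target: float, xmin: float, xmax: float) -> float:
    """Smallest x in [xmin/10, 10*xmax] with log2_ratio(x) == target."""
    grid = np.geomspace(xmin / 10, xmax * 10, 2048)
    vals = np.array([log2_ratio(x) - target for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError(
            f"log2 density ratio never crosses {target:+g}; components overlap too much"
        )
    i = int(sign_change[0])
    return float(brentq(lambda x: log2_ratio(x) - target, grid[i], grid[i + 1], xtol=1e-12))


def classify(stats: Sequence[GeneInsertionStats], fit: GammaMixtureFit) -> List[EssentialityCall]:
    """One essentiality call per gene, in input order.

    Genes with insertion index 0 are evaluated at the zero-replacement
    pseudo-value, whose density ratio is asserted to clear the essential
    threshold — a zero-index gene is always called essential.
    """
    zero_ratio = float(fit.log2_ratio(0.0))
    if zero_ratio < fit.loglik_threshold:
        raise RuntimeError(
            "density ratio at the zero-replacement value does not clear the "
            "essential threshold; the fitted components are not separated"
        )
    calls: List[EssentialityCall] = []
    for s in stats:
        idx = s.insertion_index
        ratio = float(fit.log2_ratio(idx))
        if ratio >= fit.loglik_threshold:
            label = "essential"
        elif ratio <= -fit.loglik_threshold:
            label = "non_essential"
        else:
            label = "ambiguous"
        calls.append(EssentialityCall(s.gene_id, idx, ratio, label))
    return calls


def call_essentiality(
    stats: Sequence[GeneInsertionStats],
    loglik_threshold: float = DEFAULT_LOGLIK_THRESHOLD,
) -> Tuple[List[EssentialityCall], GammaMixtureFit]:
    """End-to-end: pivot, component fit and per-gene calls from gene stats.

    Genes shorter than 100 nt are excluded from pivot finding and fitting
    (their indices are too granular) but are still classified.
    """
    fit_indices = np.array(
        [s.insertion_index for s in stats if s.gene_length >= MIN_FIT_GENE_LENGTH]
    )
    fit = fit_components(fit_indices, loglik_threshold=loglik_threshold)
    return classify(stats, fit), fit


def write_calls(
    stats: Sequence[GeneInsertionStats],
    calls: Sequence[EssentialityCall],
    path: str,
) -> None:
    """Gene-stats table plus log2_ratio and label columns."""
    from .io import GENE_STATS_COLUMNS

    by_id = {c.gene_id: c for c in calls}
    with open(path, "wt") as fh:
        fh.write("\t".join(GENE_STATS_COLUMNS + ("log2_ratio", "label")) + "\n")
        for s in stats:
            c = by_id[s.gene_id]
            fh.write(
                "\t".join(
                    [
                        s.gene_id,
                        s.gene_name or "-",
                        "0" if s.feature_type == "CDS" else "1",
                        str(s.start),
                        str(s.end),
                        s.strand,
                        str(s.read_count),
                        repr(s.insertion_index),
                        str(s.gene_length),
                        str(s.insertion_count),
                        s.product or "-",
                        f"{c.log2_ratio:.6g}",
                        c.label,
                    ]
                )
                + "\n"
            )


def write_fit_metadata(fit: GammaMixtureFit, path: str) -> None:
    """Sidecar text file recording the fit; the procedure is deterministic
    (no random seed is involved)."""
    with open(path, "wt") as fh:
        fh.write("# gamma-mixture essentiality fit (deterministic; no RNG)\n")
        for key in (
            "shape_ess",
            "rate_ess",
            "shape_non",
            "rate_non",
            "pivot",
            "changepoint_lo",
            "changepoint_hi",
            "loglik_threshold",
            "zero_replacement",
        ):
            fh.write(f"{key}\t{getattr(fit, key)!r}\n")
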