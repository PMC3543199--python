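"""Simplified negative-binomial differential-expression test.

An original, deliberately small reimplementation of the classic NB count
model for two-condition, replicated RNA-seq comparisons:

* per-sample size factors by median-of-ratios against the per-gene
  geometric mean;
* per-gene dispersion alpha (Var = mu + alpha mu^2) by method of moments on
  size-factor-normalised counts within conditions, conservatively shared
  with a fitted mean-dispersion trend via alpha = max(gene, trend);
* a conditional test of equal per-condition means given the pooled total:
  exact enumeration of the NB joint probabilities for small totals, a
  moment-matched normal approximation above a configurable switchover.

Genes are called differentially expressed at a raw p-value cutoff combined
with a fold-change cutoff (default: fold >= 2, p < 1e-3) — no
multiple-testing correction, matching common practice for this style of
screen. This is not a port of any published package; p-values are validated
by calibration and power properties, not by value matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Condition-total above which the exact enumeration switches to the
#: normal approximation (enumeration cost bound).
EXACT_SWITCHOVER = 1024

FOLD_CUTOFF = 2.0
P_CUTOFF = 1e-3


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalisation factors.

    factor_j = median over genes (nonzero in every sample) of
    count_gj / geometric_mean_g. Raises when no gene is nonzero in all
    samples; adding a pseudocount to the matrix is the usual remedy.
    """
    counts = matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("count matrix must be nonnegative")
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider adding a "
            "pseudocount before computing size factors"
        )
    logc = np.log(counts[all_nonzero])
    geo = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - geo, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def estimate_dispersion(
    matrix: pd.DataFrame, factors: pd.Series, conditions
) -> pd.Series:
    """Per-gene NB dispersion alpha >= 0 (Var = mu + alpha mu^2).

    Method of moments within each replicated condition on normalised
    counts, pooled across conditions with (n-1) weights, clamped at 0;
    then a 1/mu + const trend is fitted over genes and each gene takes
    max(own estimate, trend at its mean) — noisy per-gene estimates are
    never allowed below the trend, a conservative sharing rule.
    """
    conditions = pd.Series(list(conditions), index=matrix.columns)
    norm = matrix.to_numpy(dtype=float) / factors.to_numpy()
    reps = {c: np.flatnonzero((conditions == c).to_numpy()) for c in conditions.unique()}
    replicated = {c: ix for c, ix in reps.items() if len(ix) >= 2}
    if not replicated:
        logger.warning(
            "estimate_dispersion: no condition has replicates; pooling all "
            "samples as one group (blind fallback)"
        )
        replicated = {"__all__": np.arange(matrix.shape[1])}

    num = np.zeros(matrix.shape[0])
    wsum = 0.0
    mu_parts = []
    for ix in replicated.values():
        sub = norm[:, ix]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(ix) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / m**2, 0.0)
        num += w * a
        wsum += w
        mu_parts.append(m)
    alpha_gene = np.maximum(num / wsum, 0.0)
    mu = np.mean(mu_parts, axis=0)

    alpha_trend = _fit_trend(mu, alpha_gene)
    alpha = np.maximum(alpha_gene, alpha_trend)
    return pd.Series(alpha, index=matrix.index, name="dispersion")


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a1/mu + a0 over all expressed genes.

    Zero (clamped) gene-wise estimates are kept in the fit: excluding them
    would bias the trend upward, since clamping is how sampling noise below
    the mean-variance line manifests.
    """
    use = mu > 0
    if use.sum() < 10:
        return np.zeros_like(mu)
    X = np.column_stack([1.0 / mu[use], np.ones(int(use.sum()))])
    coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
    a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(mu > 0, a1 / mu + a0, 0.0)
    return trend


def _count_dist(mean: float, var: float):
    """Poisson when var <= mean, else NB with matching moments."""
    if var <= mean or mean <= 0:
        return stats.poisson(mean if mean > 0 else 1e-12)
    r = mean * mean / (var - mean)
    return stats.nbinom(r, r / (r + mean))


@dataclass
class DEResult:
    """Per-gene DE results for one two-condition comparison."""

    table: pd.DataFrame  # mean_a, mean_b, fold, pvalue, significant
    cond_a: str
    cond_b: str


def nb_test(
    matrix: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    cond_a,
    cond_b,
    conditions=None,
    fold_cutoff: float = FOLD_CUTOFF,
    p_cutoff: float = P_CUTOFF,
) -> DEResult:
    """Two-sided conditional test of equal NB means between two conditions.

    Per gene, given the pooled total K = kA + kB, the probability of each
    split (a, K-a) under the null common rate is computed from the NB laws
    of the two condition sums; the p-value is the total probability of
    splits no more likely than the observed one. Totals above
    ``EXACT_SWITCHOVER`` use a moment-matched normal approximation with
    continuity correction. Fold change is the ratio of normalised condition
    means, with a 0.5 pseudocount on both means when either is zero.
    """
    if conditions is None:
        raise ValueError("pass conditions= (one label per sample column)")
    conditions = pd.Series(list(conditions), index=matrix.columns)
    ia = np.flatnonzero((conditions == cond_a).to_numpy())
    ib = np.flatnonzero((conditions == cond_b).to_numpy())
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"conditions {cond_a!r} and {cond_b!r} must both be present")

    counts = matrix.to_numpy(dtype=float)
    f = factors.to_numpy(dtype=float)
    alpha = dispersions.reindex(matrix.index).to_numpy(dtype=float)

    fa, fb = f[ia], f[ib]
    sa, sb = fa.sum(), fb.sum()
    ka = counts[:, ia].sum(axis=1)
    kb = counts[:, ib].sum(axis=1)
    mean_a = (counts[:, ia] / fa).mean(axis=1)
    mean_b = (counts[:, ib] / fb).mean(axis=1)

    n_genes = len(matrix)
    pvals = np.ones(n_genes)
    folds = np.full(n_genes, np.nan)

    for g in range(n_genes):
        A, B = ka[g], kb[g]
        K = A + B
        ma, mb = mean_a[g], mean_b[g]
        if ma == 0 and mb == 0:
            continue
        folds[g] = (mb + 0.5) / (ma + 0.5) if (ma == 0 or mb == 0) else mb / ma
        q = K / (sa + sb)
        mu_a, mu_b = q * sa, q * sb
        var_a = mu_a + alpha[g] * np.sum((q * fa) ** 2)
        var_b = mu_b + alpha[g] * np.sum((q * fb) ** 2)
        if K <= EXACT_SWITCHOVER:
            da, db = _count_dist(mu_a, var_a), _count_dist(mu_b, var_b)
            a_vals = np.arange(int(K) + 1)
            joint = da.pmf(a_vals) * db.pmf(int(K) - a_vals)
            denom = joint.sum()
            if denom <= 0:
                continue
            obs = joint[int(A)]
            pvals[g] = min(joint[joint <= obs * (1 + 1e-10)].sum() / denom, 1.0)
        else:
            # Conditional on K, kA is approximately normal around mu_a with
            # variance var_a*var_b/(var_a+var_b) (mu_a + mu_b = K exactly).
            sd = np.sqrt(var_a * var_b / (var_a + var_b))
            z = (abs(A - mu_a) - 0.5) / sd
            pvals[g] = min(2.0 * stats.norm.sf(max(z, 0.0)), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        abs_fold = np.where(np.isnan(folds), np.nan, np.maximum(folds, 1.0 / folds))
    significant = (pvals < p_cutoff) & (abs_fold >= fold_cutoff)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold": folds,
            "pvalue": pvals,
            "significant": np.where(np.isnan(abs_fold), False, significant),
        },
        index=matrix.index,
    )
    return DEResult(table=table, cond_a=str(cond_a), cond_b=str(cond_b))


def run_de(matrix: pd.DataFrame, conditions, cond_a, cond_b, **kwargs) -> DEResult:
    """Full stack: size factors -> dispersions -> NB test."""
    factors = size_factors(matrix)
    disp = estimate_dispersion(matrix, factors, conditions)
    return nb_test(matrix, factors, disp, cond_a, cond_b, conditions=conditions, **kwargs)


#: Fold-change strata used when reporting depth effects.
FOLD_BINS = ((2.0, 5.0), (5.0, 10.0), (10.0, np.inf))
_BIN_LABELS = ("2-5", "5-10", ">10")


def _bin_label(abs_fold: float) -> str | None:
    for (lo, hi), lab in zip(FOLD_BINS, _BIN_LABELS):
        if lo <= abs_fold < hi:
            return lab
    return None


def de_depth_experiment(
    matrix: pd.DataFrame,
    conditions,
    cond_a,
    cond_b,
    scale_fractions=(1.0, 0.5, 0.1),
    mode: str = "proportional",
    seed: int = 0,
    true_fold: pd.Series | None = None,
) -> pd.DataFrame:
    """Significant-gene counts vs depth, stratified by fold-change bins.

    For each depth fraction f the count matrix is scaled (proportional
    rounding preserves relative expression; binomial mode thins
    stochastically), the full DE stack is re-run, and significant genes
    are tallied within fold bins 2-5, 5-10 and >10. Bins come from
    ``true_fold`` (planted truth) when given, else from the observed fold
    at full depth.
    """
    if mode not in ("proportional", "binomial"):
        raise ValueError("mode must be 'proportional' or 'binomial'")
    conditions = list(conditions)
    full = run_de(matrix, conditions, cond_a, cond_b)
    ref_fold = true_fold.reindex(matrix.index) if true_fold is not None else full.table["fold"]
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_ref = np.maximum(ref_fold, 1.0 / ref_fold)
    bins = pd.Series([None if not np.isfinite(v) else _bin_label(v) for v in abs_ref],
                     index=matrix.index)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(83,)))
    rows = []
    for f in scale_fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"scale fraction must be in (0, 1], got {f}")
        if f == 1.0:
            res = full
        else:
            if mode == "proportional":
                scaled = np.round(matrix.to_numpy(dtype=float) * f)
            else:
                scaled = rng.binomial(
                    np.round(matrix.to_numpy(dtype=float)).astype(np.int64), f
                ).astype(float)
            sm = pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
            try:
                res = run_de(sm, conditions, cond_a, cond_b)
            except ValueError:
                # every gene hit a zero somewhere: nothing testable left
                rows.append((f, "all", 0))
                for lab in _BIN_LABELS:
                    rows.append((f, lab, 0))
                continue
        sig = res.table["significant"]
        rows.append((f, "all", int(sig.sum())))
        for lab in _BIN_LABELS:
            rows.append((f, lab, int((sig & (bins == lab)).sum())))
    return pd.DataFrame(rows, columns=["scale_fraction", "fold_bin", "n_significant"])
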