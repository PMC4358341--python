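"""Negative-binomial differential expression for two-group count contrasts.

Implements the classic count-based RNA-seq testing scheme: median-of-ratios
size factors, pooled method-of-moments gene dispersions with a parametric
mean-dispersion trend and a conservative max rule, and a conditioned
NB exact-style test on the per-condition count sums, followed by
Benjamini-Hochberg FDR control and the study's >=2-fold & FDR < 0.01
gene-selection filter.

The NB variance is parameterised as ``var = mu + alpha * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class DesignError(ValueError):
    """Raised for contrasts or designs the estimators cannot handle."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus per-sample design metadata.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``design`` is indexed by sample id with columns ``genotype``,
    ``treatment`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            if set(self.counts.columns) != set(self.design.index):
                raise DesignError("counts columns and design rows disagree")
            self.design = self.design.loc[self.counts.columns]
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DesignError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise DesignError("counts must be integral")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, genotype: str | None = None,
                    treatment: str | None = None) -> list[str]:
        """Sample ids matching the given genotype and/or treatment."""
        mask = pd.Series(True, index=self.design.index)
        if genotype is not None:
            mask &= self.design["genotype"] == genotype
        if treatment is not None:
            mask &= self.design["treatment"] == treatment
        out = list(self.design.index[mask])
        if not out:
            raise DesignError(
                f"no samples for genotype={genotype!r} treatment={treatment!r}"
            )
        return out


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j the factor is the median over genes (restricted to
    genes whose counts are positive in every sample, i.e. positive
    geometric mean) of ``count_gj / geometric_mean_g``.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise DesignError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    log_geomean = logs.mean(axis=1)
    ok = np.isfinite(log_geomean)
    if not ok.any():
        raise DesignError("no gene has positive counts in every sample")
    ratios = logs[ok] - log_geomean[ok, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def _condition_groups(design: pd.DataFrame) -> list[list[str]]:
    groups = design.groupby(["genotype", "treatment"], sort=False).groups
    return [list(idx) for idx in groups.values()]


def estimate_dispersions(
    counts: CountMatrix,
    factors: pd.Series,
    conditions: list[list[str]] | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersion alpha with a fitted trend and max rule.

    Gene-wise estimates come from the pooled method of moments on
    normalized counts: with pooled within-condition variance ``w`` and
    shot-noise term ``z = qbar * mean(1/s_j)``, the raw estimate is
    ``max(0, (w - z) / qbar**2)`` (variance at or below the mean gives 0).
    A parametric trend ``alpha(q) = a0 + a1/q`` is fitted to the positive
    raw estimates and the final dispersion is the elementwise max of the
    gene-wise value and the trend, the conservative convention.

    Returns a DataFrame with columns ``dispersion_gene``,
    ``dispersion_trend`` and ``dispersion``.
    """
    if conditions is None:
        conditions = _condition_groups(counts.design)
    conditions = [g for g in conditions if len(g) >= 2]
    if not conditions:
        raise DesignError(
            "no condition has >=2 replicates; pool conditions to estimate dispersion"
        )
    used = [s for grp in conditions for s in grp]
    norm = counts.counts[used].to_numpy(dtype=float) / factors[used].to_numpy()

    qbar = norm.mean(axis=1)
    # pooled within-condition variance (df = n - #conditions)
    ss = np.zeros(norm.shape[0])
    pos = 0
    df = 0
    for grp in conditions:
        k = len(grp)
        block = norm[:, pos:pos + k]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        pos += k
        df += k - 1
    w = ss / df
    z = qbar * np.mean(1.0 / factors[used].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - z) / qbar**2
    raw = np.where(qbar > 0, np.maximum(raw, 0.0), 0.0)

    trend = _fit_dispersion_trend(qbar, raw)
    final = np.maximum(raw, trend)
    return pd.DataFrame(
        {"base_mean": qbar, "dispersion_gene": raw,
         "dispersion_trend": trend, "dispersion": final},
        index=counts.gene_ids,
    )


def _fit_dispersion_trend(qbar: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(q) = a0 + a1/q on positive raw estimates."""
    ok = (raw > 0) & (qbar > 0)
    if ok.sum() < 10:
        return np.zeros_like(qbar)
    x, y = qbar[ok], raw[ok]

    def model(q, a0, a1):
        return a0 + a1 / q

    try:
        (a0, a1), _ = optimize.curve_fit(
            model, x, y, p0=(np.median(y), 1.0), maxfev=2000
        )
    except RuntimeError:
        return np.zeros_like(qbar)
    a0, a1 = max(a0, 0.0), max(a1, 0.0)
    with np.errstate(divide="ignore"):
        t = np.where(qbar > 0, a0 + a1 / np.maximum(qbar, 1e-300), 0.0)
    return t


def _nb_logpmf_window(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """NB (or Poisson limit) log-pmf with moment-matched parameters."""
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(k, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_pvalue(
    k_a: int, k_b: int, mu_a: float, mu_b: float, var_a: float, var_b: float,
    window_sd: float = 12.0,
) -> float:
    """Conditioned NB exact-style two-sided p-value for two count sums.

    Conditions on the total ``k_a + k_b`` and sums the probabilities of all
    splits no more likely than the observed one, with split probabilities
    taken from moment-matched NB distributions of the two sums. Splits with
    negligible mass outside a ``window_sd``-sigma window are truncated.
    """
    ks = k_a + k_b
    if ks == 0:
        return 1.0
    sd = np.sqrt(var_a + var_b)
    centre = ks * mu_a / (mu_a + mu_b)
    lo = int(max(0, np.floor(min(centre, k_a) - window_sd * sd)))
    hi = int(min(ks, np.ceil(max(centre, k_a) + window_sd * sd)))
    a = np.arange(lo, hi + 1)
    logp = _nb_logpmf_window(a, mu_a, var_a) + _nb_logpmf_window(ks - a, mu_b, var_b)
    log_obs = (_nb_logpmf_window(np.array([k_a]), mu_a, var_a)
               + _nb_logpmf_window(np.array([ks - k_a]), mu_b, var_b))[0]
    m = logp.max()
    total = np.exp(logp - m).sum()
    num = np.exp(logp[logp <= log_obs + 1e-10] - m).sum()
    return float(min(1.0, num / total))


def nb_test(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: pd.DataFrame | pd.Series,
    samples_a: list[str],
    samples_b: list[str],
) -> pd.DataFrame:
    """Per-gene NB test of condition B against condition A.

    Returns a DataFrame with normalized means, fold change (B over A, with
    ``inf`` for zero-baseline induction and ``NaN`` when both means are
    zero), raw and BH-adjusted p-values.
    """
    missing = [s for s in list(samples_a) + list(samples_b)
               if s not in counts.sample_ids]
    if missing:
        raise DesignError(f"unknown samples: {missing}")
    if len(samples_a) + len(samples_b) < 3:
        raise DesignError("need >=2 replicates in total per contrast side pair")
    alpha = (dispersions["dispersion"] if isinstance(dispersions, pd.DataFrame)
             else dispersions).reindex(counts.gene_ids).to_numpy()

    ca = counts.counts[samples_a].to_numpy(dtype=float)
    cb = counts.counts[samples_b].to_numpy(dtype=float)
    sa = factors[samples_a].to_numpy()
    sb = factors[samples_b].to_numpy()

    mean_a = (ca / sa).mean(axis=1)
    mean_b = (cb / sb).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_b / mean_a
    fc = np.where((mean_a == 0) & (mean_b == 0), np.nan, fc)

    # pooled mean under the null, per gene
    q0 = np.concatenate([ca / sa, cb / sb], axis=1).mean(axis=1)
    k_a = ca.sum(axis=1)
    k_b = cb.sum(axis=1)
    mu_a = q0 * sa.sum()
    mu_b = q0 * sb.sum()
    var_a = q0 * sa.sum() + alpha * q0**2 * (sa**2).sum()
    var_b = q0 * sb.sum() + alpha * q0**2 * (sb**2).sum()

    pvals = np.ones(len(q0))
    for i in range(len(q0)):
        if k_a[i] + k_b[i] == 0:
            continue
        pvals[i] = nb_exact_pvalue(
            int(k_a[i]), int(k_b[i]), mu_a[i], mu_b[i], var_a[i], var_b[i]
        )

    padj = bh_adjust(pvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(fc)
    return pd.DataFrame(
        {"base_mean_a": mean_a, "base_mean_b": mean_b, "fold_change": fc,
         "log2_fold_change": l2fc, "pval": pvals, "padj": padj},
        index=counts.gene_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_de_genes(
    results: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Apply the >=2-fold (either direction) & FDR filter.

    A gene is significant when ``padj < fdr_threshold`` and its fold change
    is >= ``fc_threshold``, <= ``1/fc_threshold`` or infinite (zero
    baseline with expression after treatment). Adds ``significant`` and
    ``direction`` ('induced' / 'repressed' / '') columns.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    fc = results["fold_change"].to_numpy()
    padj = results["padj"].to_numpy()
    with np.errstate(invalid="ignore"):
        big = (fc >= fc_threshold) | np.isposinf(fc)
        small = fc <= 1.0 / fc_threshold
    sig = (padj < fdr_threshold) & (big | small) & ~np.isnan(fc)
    out = results.copy()
    out["significant"] = sig
    direction = np.where(sig & big, "induced", np.where(sig & small, "repressed", ""))
    out["direction"] = direction
    return out


def de_contrast(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: pd.DataFrame | pd.Series,
    *,
    genotype: str | None = None,
    treatment_a: str | None = None,
    treatment_b: str | None = None,
    samples_a: list[str] | None = None,
    samples_b: list[str] | None = None,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """One full contrast: test + BH + selection filter.

    Either give ``genotype`` with the two treatments (B vs A within that
    genotype) or explicit sample lists.
    """
    if samples_a is None or samples_b is None:
        if genotype is None or treatment_a is None or treatment_b is None:
            raise DesignError("give either sample lists or genotype + treatments")
        samples_a = counts.samples_for(genotype=genotype, treatment=treatment_a)
        samples_b = counts.samples_for(genotype=genotype, treatment=treatment_b)
    res = nb_test(counts, factors, dispersions, samples_a, samples_b)
    return select_de_genes(res, fc_threshold, fdr_threshold)
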