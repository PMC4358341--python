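"""Category over-representation via the Wallenius noncentral hypergeometric.

Tests whether a gene category is over-represented among differentially
expressed genes, allowing a per-gene bias weight (the biased-urn model):
drawing DE genes from the universe without replacement, genes inside the
category are picked with odds ``w`` relative to genes outside it. With
``w = 1`` this reduces to the one-sided Fisher / central hypergeometric
test.

The pmf is computed by numerical integration of the Wallenius density

    P(X = x) = C(m1, x) C(m2, n - x) *
               integral_0^1 (1 - t^(w/D))^x (1 - t^(1/D))^(n-x) dt,

with ``D = w (m1 - x) + (m2 - (n - x))``, then normalized over the
support.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gammaln


def _log_binom(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def wallenius_pmf_vector(
    n_cat: int, n_universe: int, n_de: int, weight_ratio: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized pmf over the full support of the Wallenius distribution.

    Returns ``(support, pmf, raw_mass)`` where ``raw_mass`` is the
    unnormalized total (a self-check: it should be 1 within ~1e-6).
    """
    m1, m2, n, w = n_cat, n_universe - n_cat, n_de, weight_ratio
    lo = max(0, n - m2)
    hi = min(n, m1)
    support = np.arange(lo, hi + 1)
    logpmf = np.full(support.size, -np.inf)
    for i, x in enumerate(support):
        d = w * (m1 - x) + (m2 - (n - x))
        lc = _log_binom(m1, x) + _log_binom(m2, n - x)
        if d <= 0:  # boundary: every remaining item is drawn
            logpmf[i] = lc if x == hi else -np.inf
            continue
        # substitute t = s**d: the integral over t in (0,1) of
        # (1-t^(w/d))^x (1-t^(1/d))^(n-x) dt becomes
        # d * s^(d-1) (1-s^w)^x (1-s)^(n-x) ds, numerically benign.
        logd = np.log(d)

        def log_g(s, x=x, d=d, logd=logd):
            with np.errstate(divide="ignore", invalid="ignore"):
                out = (logd + (d - 1.0) * np.log(s)
                       + x * np.log1p(-(s ** w))
                       + (n - x) * np.log1p(-s))
            return np.where((s <= 0.0) | (s >= 1.0), -np.inf, out)

        grid = 1.0 - np.geomspace(1e-12, 1.0, 512)
        lg = log_g(grid)
        peak = float(grid[np.argmax(lg)])
        m = float(np.max(lg))
        if not np.isfinite(m):
            continue

        def integrand(s, m=m):
            v = log_g(np.asarray(s, dtype=float))
            return np.exp(v - m)

        val, _ = integrate.quad(
            integrand, 0.0, 1.0, points=[peak], limit=400
        )
        if val > 0:
            logpmf[i] = lc + m + np.log(val)
    mmax = logpmf.max()
    pmf = np.exp(logpmf - mmax)
    raw = pmf.sum() * np.exp(mmax)
    return support, pmf / pmf.sum(), raw


def wallenius_tail(
    x: int, n_cat: int, n_universe: int, n_de: int, weight_ratio: float = 1.0
) -> float:
    """Upper tail P[X >= x] of the Wallenius noncentral hypergeometric.

    ``x`` DE genes observed in a category of ``n_cat`` genes, with ``n_de``
    genes drawn from a universe of ``n_universe`` at odds ``weight_ratio``
    for in-category genes.
    """
    if weight_ratio <= 0:
        raise ValueError("weight_ratio must be positive")
    if not (0 <= n_cat <= n_universe and 0 <= n_de <= n_universe):
        raise ValueError("infeasible category/universe/draw sizes")
    lo = max(0, n_de - (n_universe - n_cat))
    hi = min(n_de, n_cat)
    if x < 0 or x > hi:
        raise ValueError(f"x={x} outside the feasible range [0, {hi}]")
    if x <= lo:
        return 1.0
    support, pmf, _ = wallenius_pmf_vector(n_cat, n_universe, n_de, weight_ratio)
    return float(min(1.0, pmf[support >= x].sum()))


def enrich(
    de_genes: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    weights: pd.Series | dict | None = None,
    alpha: float = 0.001,
    direction: str = "over",
) -> pd.DataFrame:
    """Category over-representation among DE genes.

    ``annotation`` is a two-column frame (``gene_id``, ``category_id``).
    With per-gene ``weights`` the odds ratio for a category is the mean
    weight of in-category universe genes over the mean weight of the rest;
    without weights the test is central (Fisher-style). Categories are
    reported sorted by p-value; ``significant`` flags raw p < ``alpha``
    (no multiple-testing adjustment, matching the conventional raw
    p < 0.001 reporting threshold; a BH column is provided alongside).
    """
    from .de import bh_adjust

    if not universe:
        raise ValueError("empty universe")
    extra = set(de_genes) - set(universe)
    if extra:
        raise ValueError(f"DE genes not in universe: {sorted(extra)[:5]}...")
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    ann = annotation[annotation["gene_id"].isin(universe)]
    n_universe, n_de = len(universe), len(de_genes)

    if weights is not None:
        wser = pd.Series(weights, dtype=float)
        wser = wser.reindex(list(universe)).fillna(1.0)
    else:
        wser = None

    rows = []
    for cat, sub in ann.groupby("category_id", sort=False):
        cat_genes = set(sub["gene_id"])
        n_cat = len(cat_genes)
        x = len(cat_genes & de_genes)
        if wser is not None:
            w_in = wser[list(cat_genes)].mean()
            out_genes = list(universe - cat_genes)
            w_out = wser[out_genes].mean() if out_genes else 1.0
            ratio = float(w_in / w_out) if w_out > 0 else 1.0
        else:
            ratio = 1.0
        if direction == "over":
            p = wallenius_tail(x, n_cat, n_universe, n_de, ratio)
        else:
            support, pmf, _ = wallenius_pmf_vector(n_cat, n_universe, n_de, ratio)
            p = float(min(1.0, pmf[support <= x].sum()))
        rows.append({
            "category_id": cat, "n_universe": n_universe, "n_category": n_cat,
            "n_de": n_de, "n_de_in_category": x, "weight_ratio": ratio,
            "p_over": p,
        })
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["significant"] = res["p_over"] < alpha
    res["p_adj"] = bh_adjust(res["p_over"].to_numpy())
    return res.sort_values("p_over", kind="stable").reset_index(drop=True)
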