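"""Group comparisons: Mann-Whitney U, chi-square, and the bootstrap
size-correction used when carrier groups are far smaller than the
non-carrier pool.

``mann_whitney_u`` uses the exact null distribution of U (dynamic-programming
enumeration) whenever ``n_x * n_y <= 400`` and the data are tie-free, and a
tie-corrected, continuity-corrected normal approximation otherwise.  All
tests are two-sided.

``bootstrap_compare`` implements the size-correction: each iteration draws
``n_controls`` non-carriers from the pool without replacement, computes the
two-sided Mann-Whitney p against the carrier values, and the median p over
all iterations is the corrected p value.  The routine is vectorised over
iterations and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm, rankdata

EXACT_MAX_PRODUCT = 400


@lru_cache(maxsize=128)
def _u_counts(n: int, m: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, for sizes (n, m).

    Recurrence: N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1).
    Returned array has length n*m + 1, summing to C(n+m, n).
    """
    if n == 0 or m == 0:
        return np.ones(1)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    out = np.zeros(n * m + 1)
    out[m:m + a.size] += a
    out[:b.size] += b
    return out


def _exact_two_sided(u: float, n: int, m: int) -> float:
    counts = _u_counts(n, m)
    total = comb(n + m, n)
    u_hi = int(round(max(u, n * m - u)))
    return min(1.0, 2.0 * counts[u_hi:].sum() / total)


def _tie_term(values: np.ndarray) -> float:
    _, t = np.unique(values, return_counts=True)
    return float((t ** 3 - t).sum())


def _asymptotic_two_sided(u: float, n: int, m: int, combined: np.ndarray) -> float:
    big_n = n + m
    mu = n * m / 2.0
    tie = _tie_term(combined)
    var = n * m / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    return min(1.0, 2.0 * norm.sf(max(z, 0.0)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty input")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    if n * m <= EXACT_MAX_PRODUCT and not has_ties:
        return u, _exact_two_sided(u, n, m)
    return u, _asymptotic_two_sided(u, n, m, combined)


def chi_square_test(table) -> tuple[float, float, int]:
    """Pearson chi-square without continuity correction; (stat, p, df)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi_square_test: zero marginal total")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


@dataclass
class BootstrapResult:
    p_corrected: float
    p_iterations: np.ndarray


def bootstrap_compare(
    carrier_vals: Sequence[float],
    noncarrier_pool: Sequence[float],
    n_controls: int = 30,
    iters: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Median of per-iteration Mann-Whitney p values over resampled controls."""
    x = np.asarray(carrier_vals, dtype=float)
    pool = np.asarray(noncarrier_pool, dtype=float)
    if x.size == 0:
        raise ValueError("bootstrap_compare: empty carrier values")
    if pool.size < n_controls:
        raise ValueError(
            f"bootstrap_compare: pool of {pool.size} smaller than n_controls={n_controls}"
        )
    if rng is None:
        if seed is None:
            raise ValueError("bootstrap_compare: a seed or rng is mandatory")
        rng = np.random.default_rng(seed)

    n = x.size
    # without-replacement sampling per iteration, vectorised
    keys = rng.random((iters, pool.size))
    idx = np.argpartition(keys, n_controls - 1, axis=1)[:, :n_controls]
    controls = pool[idx]

    combined = np.concatenate(
        [np.broadcast_to(x, (iters, n)), controls], axis=1
    )
    ranks = rankdata(combined, axis=1)
    u = ranks[:, :n].sum(axis=1) - n * (n + 1) / 2.0

    sorted_rows = np.sort(combined, axis=1)
    tied = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)

    p = np.empty(iters)
    exact_ok = n * n_controls <= EXACT_MAX_PRODUCT
    if exact_ok:
        counts = _u_counts(n, n_controls)
        sf = np.concatenate([np.cumsum(counts[::-1])[::-1], [0.0]]) / comb(n + n_controls, n)
        free = ~tied
        u_hi = np.rint(np.maximum(u[free], n * n_controls - u[free])).astype(int)
        p[free] = np.minimum(1.0, 2.0 * sf[u_hi])
        tie_rows = np.where(tied)[0]
    else:
        tie_rows = np.arange(iters)
    for i in tie_rows:
        p[i] = _asymptotic_two_sided(u[i], n, n_controls, combined[i])

    return BootstrapResult(float(np.median(p)), p)


@dataclass
class GroupComparison:
    metric: str
    stratum: str
    n_group: int
    n_reference: int
    group_summary: float
    reference_summary: float
    p_raw: float
    p_bootstrap: float | None
    test: str = "mann_whitney"


def summarize_groups(
    values: Mapping[str, float] | pd.Series,
    labels: pd.DataFrame,
    metric: str,
    summary: str = "median",
    n_controls: int = 30,
    iters: int = 1000,
    seed: int | None = None,
) -> list[GroupComparison]:
    """Per-stratum comparison of a metric against non-carriers.

    ``labels`` needs columns ``sample_id``, ``carrier_group`` and
    ``allelic_status``.  Strata are gene x allelic-status (e.g.
    ``PALB2_biallelic``); the reference is every non-carrier sample.  Samples
    without a value for the metric are dropped.  Both the raw Mann-Whitney p
    and the bootstrap size-corrected p are reported.
    """
    import logging

    log = logging.getLogger("hrdscape")
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    values = pd.Series(values).dropna()
    lab = labels.set_index("sample_id")
    common = values.index.intersection(lab.index)
    values, lab = values.loc[common], lab.loc[common]

    ref_vals = values[lab["carrier_group"] == "non_carrier"].to_numpy()
    summarise = np.median if summary == "median" else np.mean
    comparisons: list[GroupComparison] = []
    gene_of = lab["carrier_group"].str.split("_").str[0]
    carriers = lab["carrier_group"].str.contains("germline|somatic", regex=True)
    rng = np.random.default_rng(seed) if seed is not None else None
    for gene in ("PALB2", "BRCA1", "BRCA2"):
        for status in ("biallelic", "monoallelic"):
            mask = carriers & (gene_of == gene) & (lab["allelic_status"] == status)
            vals = values[mask].to_numpy()
            stratum = f"{gene}_{status}"
            if vals.size == 0:
                log.info("summarize_groups: empty stratum %s omitted", stratum)
                continue
            _, p_raw = mann_whitney_u(vals, ref_vals)
            p_boot = None
            if rng is not None and ref_vals.size >= n_controls:
                p_boot = bootstrap_compare(
                    vals, ref_vals, n_controls=n_controls, iters=iters, rng=rng
                ).p_corrected
            comparisons.append(GroupComparison(
                metric=metric,
                stratum=stratum,
                n_group=int(vals.size),
                n_reference=int(ref_vals.size),
                group_summary=float(summarise(vals)),
                reference_summary=float(summarise(ref_vals)),
                p_raw=float(p_raw),
                p_bootstrap=p_boot,
            ))
    return comparisons


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": c.metric, "stratum": c.stratum, "n_group": c.n_group,
        "n_reference": c.n_reference, "group_summary": c.group_summary,
        "reference_summary": c.reference_summary, "p_raw": c.p_raw,
        "p_bootstrap": np.nan if c.p_bootstrap is None else c.p_bootstrap,
        "test": c.test,
    } for c in comparisons])
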