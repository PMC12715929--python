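"""Over-representation statistics for Pfam occurrence tables.

Three complementary views of enrichment are provided:

* :func:`permutation_null` — compares each Pfam's gene-level occurrence
  count against a null built by redrawing, for every region, the same number
  of Pfam identifiers with replacement from the occurrence pool.  Because
  draws are i.i.d. across regions, the per-Pfam null total over all regions
  is multinomial with the pool frequencies, which is how the null is
  simulated.  Empirical p-values use the (b+1)/(B+1) estimator and are
  Benjamini–Hochberg adjusted.
* :func:`fisher_enrichment` — region-presence 2×2 Fisher exact tests of a
  test group against a control group, Bonferroni-adjusted, flagging Pfams
  with adjusted p below ``alpha``, positive proportion difference and sample
  odds ratio above ``min_or``.
* :func:`zscore_table` — the closed-form observed-vs-expected score: with
  pool frequency f_l = n_l / N and group total ``total_i``, the expected
  count is m' = total_i·f_l, its standard deviation s' = sqrt(total_i·f_l·
  (1-f_l)), Z = (obs - m')/s', and log1p(Z) is reported for non-negative Z
  to damp the heavy upper tail of domain counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from locus_colocal.count_model import PfamCountTable
from locus_colocal.errors import ValidationError

logger = logging.getLogger(__name__)

_PERM_CHUNK = 500  # iterations simulated per multinomial block


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m·p) elementwise.  ``bh``: Benjamini–Hochberg
    step-up with monotone enforcement from the largest rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown adjustment method {method!r}")


def odds_ratio_ci(a: float, b: float, c: float, d: float,
                  level: float = 0.95) -> tuple[float, float, float]:
    """Sample (cross-product) odds ratio with a Wald interval on ln OR.

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
    cells) so the ratio and its interval stay finite.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("2x2 cell counts must be non-negative")
    if a + b <= 0 or c + d <= 0:
        raise ValidationError("each row of the 2x2 table needs a positive margin")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = scipy.stats.norm.ppf(0.5 + level / 2)
    log_or = math.log(or_)
    return or_, math.exp(log_or - zq * se), math.exp(log_or + zq * se)


@dataclass
class PermutationNullSummary:
    """Null distribution summary from :func:`permutation_null`.

    ``table`` columns: pfam, obs, null_mean, null_sd, b (exceedance count),
    p_emp, p_bh.
    """

    B: int
    seed: int
    total_draws: int
    table: pd.DataFrame


def _pool_frequencies(pool: PfamCountTable, weighting: str) -> pd.Series:
    if weighting == "occurrence":
        n_l = pool.n_l
        return n_l / n_l.sum()
    if weighting == "uniform":
        pfams = pool.n_l.index
        return pd.Series(1.0 / len(pfams), index=pfams)
    raise ValidationError(f"unknown pool weighting {weighting!r}")


def permutation_null(table: PfamCountTable, B: int = 10_000, seed: int = 0,
                     pool: PfamCountTable | None = None,
                     weighting: str = "occurrence") -> PermutationNullSummary:
    """Empirical enrichment p-values from a resampling null.

    Each of the ``B`` iterations redraws, for every region, as many Pfam
    identifiers as the region actually carries, with replacement from the
    occurrence pool (``pool`` defaults to ``table`` itself; pass the combined
    or control table to score a group against an external frequency law).
    The per-Pfam null count is the total across regions; the empirical
    p-value is (b_l + 1)/(B + 1) with b_l the number of iterations whose null
    count reaches the observed count.
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    if table.N == 0:
        raise ValidationError("cannot permute an empty count table")
    if pool is None:
        pool = table
    f = _pool_frequencies(pool, weighting)
    pfams = f.index.to_numpy()
    obs = table.n_l.reindex(pfams, fill_value=0).to_numpy()
    total_draws = int(table.N)

    rng = np.random.default_rng(seed)
    probs = f.to_numpy()
    b = np.zeros(len(pfams), dtype=np.int64)
    s1 = np.zeros(len(pfams))
    s2 = np.zeros(len(pfams))
    done = 0
    while done < B:
        chunk = min(_PERM_CHUNK, B - done)
        counts = rng.multinomial(total_draws, probs, size=chunk)
        b += (counts >= obs).sum(axis=0)
        s1 += counts.sum(axis=0)
        s2 += (counts.astype(np.float64) ** 2).sum(axis=0)
        done += chunk
    null_mean = s1 / B
    null_var = np.maximum(0.0, s2 / B - null_mean**2)
    p_emp = (b + 1) / (B + 1)
    out = pd.DataFrame({
        "pfam": pfams,
        "obs": obs,
        "null_mean": null_mean,
        "null_sd": np.sqrt(null_var),
        "b": b,
        "p_emp": p_emp,
        "p_bh": adjust_pvalues(p_emp, "bh"),
    })
    return PermutationNullSummary(B=B, seed=seed, total_draws=total_draws, table=out)


def zscore_table(table: PfamCountTable, pool: PfamCountTable | None = None) -> pd.DataFrame:
    """Observed-vs-expected Z-scores for every scoreable Pfam.

    Pfams whose pool frequency is 0 or 1 have zero null variance and are
    skipped with a warning.  Columns: pfam, obs, f_l, m_prime, s_prime, z,
    log1p_z (NaN for negative Z), enrichment_ratio (obs/m').
    """
    if pool is None:
        pool = table
    f = _pool_frequencies(pool, "occurrence")
    total_i = table.N
    obs = table.n_l.reindex(f.index, fill_value=0)

    degenerate = (f <= 0) | (f >= 1)
    if degenerate.any():
        for pfam in f.index[degenerate]:
            logger.warning("skipping %s: pool frequency %g gives zero variance",
                           pfam, f[pfam])
    f = f[~degenerate]
    obs = obs[~degenerate]

    m_prime = total_i * f
    s_prime = np.sqrt(total_i * f * (1 - f))
    z = (obs - m_prime) / s_prime
    log1p_z = pd.Series(np.nan, index=z.index)
    log1p_z[z >= 0] = np.log1p(z[z >= 0])
    return pd.DataFrame({
        "pfam": f.index,
        "obs": obs.to_numpy(),
        "f_l": f.to_numpy(),
        "m_prime": m_prime.to_numpy(),
        "s_prime": s_prime.to_numpy(),
        "z": z.to_numpy(),
        "log1p_z": log1p_z.to_numpy(),
        "enrichment_ratio": (obs / m_prime).to_numpy(),
    }).reset_index(drop=True)


def fisher_enrichment(test: PfamCountTable, control: PfamCountTable,
                      alpha: float = 0.05, min_or: float = 2.0,
                      m: int | None = None,
                      or_estimator: str = "sample") -> pd.DataFrame:
    """Region-presence Fisher exact tests of a test group against a control.

    For each Pfam in the union of both tables the 2×2 table is
    ``[[r_test, n_test - r_test], [r_ctrl, n_ctrl - r_ctrl]]`` where r is the
    number of regions containing the Pfam.  Two-sided exact p-values are
    Bonferroni-adjusted over ``m`` tests (default: the number of Pfams
    tested).  A Pfam is flagged ``enriched`` iff p_bonf < ``alpha``, the
    proportion difference is positive and the odds ratio exceeds ``min_or``.

    ``or_estimator`` selects the reported odds ratio: ``"sample"`` is the
    Haldane-corrected cross-product ratio, ``"conditional"`` the exact-test
    conditional maximum-likelihood estimate.
    """
    if test.n_regions == 0 or control.n_regions == 0:
        raise ValidationError("both groups need at least one region")
    if or_estimator not in ("sample", "conditional"):
        raise ValidationError(f"unknown odds-ratio estimator {or_estimator!r}")

    r_test = test.r_l
    r_ctrl = control.r_l
    pfams = sorted(set(r_test.index) | set(r_ctrl.index))
    n_t, n_c = test.n_regions, control.n_regions

    rows = []
    for pfam in pfams:
        a = int(r_test.get(pfam, 0))
        c = int(r_ctrl.get(pfam, 0))
        if a == 0 and c == 0:
            logger.warning("skipping %s: absent from every region of both groups", pfam)
            continue
        b_, d = n_t - a, n_c - c
        p = float(scipy.stats.fisher_exact([[a, b_], [c, d]], alternative="two-sided")[1])
        if or_estimator == "sample":
            or_, lo, hi = odds_ratio_ci(a, b_, c, d)
        else:
            res = scipy.stats.contingency.odds_ratio([[a, b_], [c, d]], kind="conditional")
            or_ = float(res.statistic)
            ci = res.confidence_interval(0.95)
            lo, hi = float(ci.low), float(ci.high)
        prop_t, prop_c = a / n_t, c / n_c
        rows.append({
            "pfam": pfam,
            "r_test": a,
            "r_control": c,
            "fisher_p": p,
            "odds_ratio": or_,
            "ci_low": lo,
            "ci_high": hi,
            "prop_test": prop_t,
            "prop_control": prop_c,
            "prop_diff": prop_t - prop_c,
        })
    out = pd.DataFrame(rows)
    m_tests = m if m is not None else len(out)
    out["p_bonf"] = np.minimum(1.0, out["fisher_p"] * m_tests)
    out["enriched"] = (
        (out["p_bonf"] < alpha) & (out["prop_diff"] > 0) & (out["odds_ratio"] > min_or)
    )
    return out.reset_index(drop=True)
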