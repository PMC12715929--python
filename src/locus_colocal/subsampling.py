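"""Sampling-size vs Pfam-count trend analysis.

As more anchored regions are sampled, the cumulative occurrence count of a
genuinely co-localised Pfam should rise steadily, giving a Spearman rank
correlation near 1 between sample size and cumulative count; incidental
Pfams plateau early and correlate weakly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from locus_colocal.count_model import PfamCountTable
from locus_colocal.errors import ValidationError


@dataclass
class TrendResult:
    """Cumulative occurrence trajectory of one Pfam with its Spearman rho."""

    pfam: str
    sizes: list[int]
    counts: list[int]
    rho: float | None
    p: float | None
    seed: int
    flag: str = ""  # "constant input" when rho is undefined


def spearman_rho(x, y) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average-rank tie handling.

    Returns (rho, p); both are None when either vector is constant, since
    ranks carry no information then.  p uses the t-distribution
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def subsample_trend(table: PfamCountTable, target_pfams: set[str],
                    n_max: int = 100, seed: int = 0) -> list[TrendResult]:
    """Cumulative Pfam counts along one random ordering of regions.

    Draws a single seeded permutation of the table's regions and, for each
    target Pfam, accumulates its occurrence count over the first s regions
    for s = 1..n_max, then correlates size with cumulative count.
    """
    if n_max > table.n_regions:
        raise ValidationError(
            f"n_max={n_max} exceeds the {table.n_regions} available regions")
    rng = np.random.default_rng(seed)
    order = [table.region_ids[i] for i in rng.permutation(table.n_regions)[:n_max]]

    rec = table.records
    per_region = {
        pfam: rec[rec["pfam"] == pfam].groupby("region_id").size()
        for pfam in sorted(target_pfams)
    }
    sizes = list(range(1, n_max + 1))
    results = []
    for pfam, counts_by_region in per_region.items():
        increments = np.array([counts_by_region.get(r, 0) for r in order])
        cumulative = np.cumsum(increments)
        rho, p = spearman_rho(sizes, cumulative)
        results.append(TrendResult(
            pfam=pfam,
            sizes=sizes,
            counts=[int(c) for c in cumulative],
            rho=rho,
            p=p,
            seed=seed,
            flag="" if rho is not None else "constant input",
        ))
    return results
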