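"""Relative abundance, rare-taxon grouping, rarefaction and correlations.

Marker-gene (SSU/LSU) profiles are analysed as relative abundances
without rarefying; rarefaction (subsampling without replacement to a
common depth) is available for single-copy-gene analyses where library
size comparability matters, with the depth chosen as the smallest
library that contains the marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import TaxonProfile

RARE_LABEL = "rare"
DEFAULT_RARE_THRESHOLD = 0.01  # mean relative abundance below this is pooled


def relative_abundance(profile: TaxonProfile) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample fractions of assigned reads.

    Returns the fraction table (empty samples dropped) and the list of
    samples with zero assigned reads, reported rather than NaN-filled.
    """
    totals = profile.totals()
    empty = list(totals.index[totals == 0])
    kept = profile.counts.loc[totals > 0]
    rel = kept.div(totals[totals > 0], axis=0)
    return rel, empty


def group_rare(
    rel_abund: pd.DataFrame, threshold: float = DEFAULT_RARE_THRESHOLD
) -> pd.DataFrame:
    """Pool taxa rarer than ``threshold`` mean relative abundance.

    The mean is the unweighted average of per-sample fractions; taxa at
    exactly the threshold are kept separate. The pooled column is
    labelled 'rare'; per-sample sums are preserved.
    """
    means = rel_abund.mean(axis=0)
    rare = [t for t in rel_abund.columns if means[t] < threshold]
    kept = rel_abund.drop(columns=rare)
    if rare:
        kept[RARE_LABEL] = rel_abund[rare].sum(axis=1)
    return kept


def choose_depth(
    library_sizes: Mapping[str, int], marker_presence: Iterable[str]
) -> int:
    """Subsampling depth: the smallest library that contains the marker."""
    present = [s for s in marker_presence if s in library_sizes]
    if not present:
        raise ValueError("no library contains the marker")
    return int(min(library_sizes[s] for s in present))


def rarefy(profile: TaxonProfile, depth: int, seed: int) -> TaxonProfile:
    """Subsample each library to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` assigned reads are excluded with a
    warning. Deterministic given the seed (samples processed in index
    order); the per-sample draw is multivariate hypergeometric.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = profile.totals()
    excluded = list(totals.index[totals < depth])
    if excluded:
        warnings.warn(f"samples below depth {depth} excluded: {excluded}")
    kept = profile.counts.loc[totals >= depth]
    rng = np.random.default_rng(seed)
    rows = np.vstack(
        [
            rng.multivariate_hypergeometric(kept.loc[s].to_numpy(), depth)
            for s in kept.index
        ]
    ) if len(kept) else np.zeros((0, len(kept.columns)), dtype=int)
    out = pd.DataFrame(rows, index=kept.index, columns=kept.columns)
    return TaxonProfile(out, rank=profile.rank, unclassified=profile.unclassified)


@dataclass(frozen=True)
class CorrelationResult:
    var1: str
    var2: str
    r: float
    n: int
    r_squared: float | None = None  # set for regression pairs


def pearson_matrix(
    x_table: pd.DataFrame,
    y_table: pd.DataFrame,
    method: str = "pearson",
) -> list[CorrelationResult]:
    """Correlations for every (x column, y column) pair.

    Missing values are handled pairwise-complete; pairs with fewer than
    three complete observations, or with a constant column, are skipped
    with a warning. ``method`` may be 'pearson' (default) or 'spearman'
    for rank-based analysis of skewed covariates.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    results = []
    for xcol in x_table.columns:
        for ycol in y_table.columns:
            x = x_table[xcol]
            y = y_table[ycol].reindex(x.index)
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            if n < 3:
                warnings.warn(f"pair ({xcol}, {ycol}): fewer than 3 complete pairs")
                continue
            xv = x[mask].to_numpy(dtype=float)
            yv = y[mask].to_numpy(dtype=float)
            if xv.std() == 0 or yv.std() == 0:
                warnings.warn(f"pair ({xcol}, {ycol}): constant column, skipped")
                continue
            if method == "pearson":
                r = float(sps.pearsonr(xv, yv).statistic)
            else:
                r = float(sps.spearmanr(xv, yv).statistic)
            results.append(CorrelationResult(str(xcol), str(ycol), r, n))
    return results


def regress_between_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> CorrelationResult:
    """Simple linear regression of mean relative abundances, A on B.

    Each table is sample × taxon; taxon means across samples are paired
    on the shared taxon index (>= 3 shared taxa required) and R² = r² is
    reported.
    """
    shared = [t for t in table_a.columns if t in set(table_b.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared taxa for regression")
    a = table_a[shared].mean(axis=0).to_numpy(dtype=float)
    b = table_b[shared].mean(axis=0).to_numpy(dtype=float)
    fit = sps.linregress(b, a)
    return CorrelationResult(
        "mean_A", "mean_B", float(fit.rvalue), len(shared), float(fit.rvalue**2)
    )


def fisher_z_interval(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a sample correlation around ``rho``.

    Fisher z-transform with SE 1/sqrt(n-3); used to check recovery of a
    configured correlation target.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    z = np.arctanh(rho)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlations_to_tsv(results: Sequence[CorrelationResult], path) -> None:
    pd.DataFrame(
        [(r.var1, r.var2, r.r, r.n, "" if r.r_squared is None else r.r_squared) for r in results],
        columns=["var1", "var2", "r", "n", "R2"],
    ).to_csv(path, sep="\t", index=False)
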