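"""Family-level shape-diversity estimation from morphospace scores.

For every family and every retained PC the sample variance of scores is
computed and families are ranked from most (rank 1) to least variable, ties
averaged.  The median rank across PCs summarizes a family's overall shape
diversity, but abundant families look spuriously diverse; since
-median_rank is close to linear in log10(count), the residuals of the OLS
fit -median_rank ~ log10(count) serve as size-corrected diversity estimates
(higher residual = more diverse than expected for its sample count).
Whether a named group of families (e.g. a phylogenetic clade) is
systematically more or less diverse than expected is tested by a two-sided
Wilcoxon signed-rank test of its residuals against zero.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DiversityTable",
    "family_variance_ranks",
    "median_rank",
    "diversity_residuals",
    "group_bias_test",
]


@dataclasses.dataclass
class DiversityTable:
    """Per-family variance/rank tables over the retained PCs.

    Attributes
    ----------
    counts : Series (family -> int)
    variances : DataFrame (families x PCs), per-family score variance.
    ranks : DataFrame (families x PCs), 1 = most variable, ties averaged;
        every column sums to F(F+1)/2.
    """

    counts: pd.Series
    variances: pd.DataFrame
    ranks: pd.DataFrame


def family_variance_ranks(
    scores: np.ndarray, families, ddof: int = 1
) -> DiversityTable:
    """Per-PC score variance of each family, ranked most-to-least variable.

    Sample variance (denominator n - ``ddof``) per family per PC; families
    of size <= ddof are kept with variance 0 and a warning rather than
    dropped.  Ranks are descending with average ties.

    Raises
    ------
    ValidationError
        On fewer than 2 families.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    fam = pd.Series(np.asarray(families), name="family")
    if fam.shape[0] != scores.shape[0]:
        raise ValidationError("families and scores must have equal sample counts")
    names = pd.unique(fam)
    if names.size < 2:
        raise ValidationError("need at least 2 families")
    counts = fam.value_counts().reindex(names)
    if (counts <= ddof).any():
        warnings.warn(
            "families with too few samples for a variance estimate get variance 0",
            RuntimeWarning,
            stacklevel=2,
        )
    k = scores.shape[1]
    variances = np.zeros((names.size, k))
    for row, name in enumerate(names):
        block = scores[fam.to_numpy() == name]
        if block.shape[0] > ddof:
            variances[row] = block.var(axis=0, ddof=ddof)
    var_df = pd.DataFrame(
        variances, index=pd.Index(names, name="family"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    # descending: most variable family gets rank 1; ties averaged
    ranks = var_df.apply(lambda col: stats.rankdata(-col.to_numpy(), method="average"))
    return DiversityTable(counts=counts, variances=var_df, ranks=ranks)


def median_rank(t: DiversityTable) -> pd.Series:
    """Per-family median of its variance ranks across PCs."""
    return t.ranks.median(axis=1).rename("median_rank")


def diversity_residuals(t: DiversityTable, on_singular: str = "raise") -> pd.Series:
    """Size-corrected diversity: residuals of -median_rank ~ log10(count).

    OLS with intercept; residuals sum to zero and higher values mean more
    shape diversity than expected for the family's sample count.

    Parameters
    ----------
    on_singular : {'raise', 'center'}
        What to do when every family has the same count (the size regressor
        is constant): raise, or fall back to the intercept-only fit, i.e.
        centered -median_rank (no size correction is needed in a balanced
        design).

    Raises
    ------
    ValidationError
        On fewer than 3 families, or a constant regressor with
        ``on_singular='raise'``.
    """
    if t.counts.size < 3:
        raise ValidationError("need at least 3 families for the size correction")
    x = np.log10(t.counts.to_numpy(dtype=float))
    y = -median_rank(t).to_numpy()
    if np.ptp(x) == 0.0:
        if on_singular != "center":
            raise ValidationError(
                "all family counts equal: size regressor is singular"
            )
        residuals = y - y.mean()
    else:
        fit = stats.linregress(x, y)
        residuals = y - (fit.intercept + fit.slope * x)
    return pd.Series(residuals, index=t.counts.index, name="residual")


def group_bias_test(residuals: pd.Series, group_members) -> float:
    """Two-sided Wilcoxon signed-rank p-value that a group's residuals center on 0.

    Exact distribution for n <= 25 members, normal approximation above.
    Residuals exactly 0 are dropped (standard signed-rank convention) with
    a warning.

    Raises
    ------
    ValidationError
        If the group is empty, has no members in the table, or only zero
        residuals.
    """
    members = [m for m in group_members if m in residuals.index]
    if not members:
        raise ValidationError("no group members found among the families")
    values = residuals.loc[members].to_numpy(dtype=float)
    n_zero = int(np.count_nonzero(values == 0.0))
    if n_zero:
        warnings.warn(
            f"dropping {n_zero} zero residual(s) from the signed-rank test",
            RuntimeWarning,
            stacklevel=2,
        )
        values = values[values != 0.0]
    if values.size == 0:
        raise ValidationError("group empty after dropping zero residuals")
    method = "exact" if values.size <= 25 else "approx"
    result = stats.wilcoxon(
        values, alternative="two-sided", method=method, zero_method="wilcox"
    )
    return float(result.pvalue)
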