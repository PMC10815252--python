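"""Chi-square goodness-of-fit test of phenotype segregation.

A monogenic dominant trait segregates 3 mutant : 1 wild type in an F2.
Both the plain Pearson statistic and the Yates continuity-corrected
statistic are reported (df = 1 for two phenotype classes); p-values come
from the chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

__all__ = ["SegregationResult", "chi_square_segregation"]


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]  # (n_wt, n_mut)
    expected: tuple[float, float]
    ratio: tuple[float, float]
    chi2_pearson: float
    chi2_yates: float
    df: int
    p_pearson: float
    p_yates: float


def chi_square_segregation(
    n_wt: int, n_mut: int, ratio: tuple[float, float] = (1, 3)
) -> SegregationResult:
    """Test observed (wild-type, mutant) counts against a Mendelian ratio.

    Expected counts are ``N * r_i / sum(r)``; Pearson chi-square is
    ``sum((o-e)^2 / e)`` and the Yates version ``sum((|o-e| - 0.5)^2 / e)``,
    each on 1 degree of freedom.
    """
    n = n_wt + n_mut
    if n <= 0:
        raise ValueError("total count must be positive")
    if min(ratio) <= 0:
        raise ValueError("ratio components must be positive")
    r_total = ratio[0] + ratio[1]
    expected = (n * ratio[0] / r_total, n * ratio[1] / r_total)
    observed = (n_wt, n_mut)
    chi2_p = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    chi2_y = sum((abs(o - e) - 0.5) ** 2 / e for o, e in zip(observed, expected))
    return SegregationResult(
        observed=observed,
        expected=expected,
        ratio=ratio,
        chi2_pearson=chi2_p,
        chi2_yates=chi2_y,
        df=1,
        p_pearson=float(_chi2_dist.sf(chi2_p, 1)),
        p_yates=float(_chi2_dist.sf(chi2_y, 1)),
    )
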