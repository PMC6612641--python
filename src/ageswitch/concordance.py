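"""Cross-tissue direction concordance of an age signature."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError


@dataclass(frozen=True)
class ConcordanceReport:
    n_tested: int
    n_consistent: int
    fraction: float  # NaN when n_tested == 0
    p_value: float  # NaN when n_tested == 0

    def as_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_consistent": self.n_consistent,
            "fraction": self.fraction,
            "p_value": self.p_value,
        }


def direction_concordance(
    signature: pd.DataFrame,
    other_tissue: pd.DataFrame,
    min_abs_rho: float = 0.0,
) -> ConcordanceReport:
    """Fraction of signature transcripts moving the same way in another tissue.

    A transcript is consistent iff the sign of its rho in the other tissue
    equals the signature direction and |rho| >= min_abs_rho. Transcripts
    absent from the other tissue are excluded from n_tested. The p-value is
    a two-sided exact binomial test of n_consistent out of n_tested at 0.5.
    """
    if min_abs_rho < 0:
        raise InvalidInputError("min_abs_rho must be non-negative")
    other = other_tissue.groupby("transcript_id")["rho"].mean()
    sig = signature.set_index("transcript_id")["direction"]
    shared = sig.index.intersection(other.index)
    if len(shared) == 0:
        warnings.warn("no shared transcripts between tissues", stacklevel=2)
        return ConcordanceReport(0, 0, float("nan"), float("nan"))
    rho = other.loc[shared].to_numpy(dtype=float)
    direction = sig.loc[shared].to_numpy(dtype=float)
    consistent = (np.sign(rho) == direction) & (np.abs(rho) >= min_abs_rho)
    k, n = int(consistent.sum()), len(shared)
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return ConcordanceReport(n, k, k / n, float(p))
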