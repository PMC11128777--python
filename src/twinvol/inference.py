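"""Multiple-testing control shared by all pipeline stages.

P-values are corrected within exactly four families — covariate effects,
assumption tests, univariate model fits, bivariate covariances — and a
test belongs to its family from creation, so no p-value can be corrected
twice. The step-up Benjamini-Hochberg procedure is delegated to
statsmodels behind this surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

FAMILY_LABELS = (
    "covariates",
    "assumptions",
    "univariate_model_fits",
    "bivariate_covariances",
)


@dataclass
class TestFamily:
    """A named family of tests corrected together."""

    label: str
    test_ids: list[str] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.label not in FAMILY_LABELS:
            raise ValidationError(
                f"family label {self.label!r} not in {FAMILY_LABELS}")
        if len(self.test_ids) != len(self.p_values):
            raise ValidationError("test_ids and p_values must align")

    def add(self, test_id: str, p: float) -> None:
        self.test_ids.append(test_id)
        self.p_values.append(float(p))


def benjamini_hochberg(family: TestFamily) -> pd.DataFrame:
    """Step-up FDR control at ``family.alpha``.

    Returns a frame (test_id, p, p_adjusted, reject) where ``reject`` is
    exactly ``p_adjusted <= alpha`` and adjusted p-values are monotone
    non-decreasing in the raw-p rank.
    """
    if not family.test_ids:
        raise ValidationError(f"family {family.label!r} is empty")
    p = np.asarray(family.p_values, dtype=float)
    bad = [tid for tid, pi in zip(family.test_ids, p)
           if not (0.0 <= pi <= 1.0) or not np.isfinite(pi)]
    if bad:
        raise ValidationError(f"p-values outside [0, 1] for tests: {bad}")
    reject, p_adj, _, _ = multipletests(p, alpha=family.alpha, method="fdr_bh")
    # align the flag definition with the adjusted values exactly
    reject = p_adj <= family.alpha
    return pd.DataFrame({
        "test_id": family.test_ids,
        "p": p,
        "p_adjusted": p_adj,
        "reject": reject,
    })
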