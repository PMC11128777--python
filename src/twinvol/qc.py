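"""Quantitative outlier exclusion.

Volumes farther than a z-threshold (default 3.29 SD, the two-sided 0.001
normal quantile) from the per-dataset, per-region mean are set to missing
in a single pass: means and SDs are computed once on whatever enters this
stage and are not recomputed after removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ValidationError

DEFAULT_Z_THRESHOLD = 3.29


@dataclass
class QCReport:
    """Outlier-screen outcome: flagged cells and the statistics used."""

    z_threshold: float
    counts: pd.DataFrame                      # dataset, region, n_flagged, n_checked
    flagged: list[tuple[str, str]]            # (individual_id, region)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def flag_outliers(
    cohort: Cohort,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[Cohort, QCReport]:
    """Single-pass outlier screen per region within each dataset.

    Cells with ``|value - mean| > z_threshold * SD`` (SD with the n-1
    denominator) are set to missing. A region with zero SD yields zero
    flags; a region entirely missing within a dataset is skipped with a
    warning in the report. The flag decision is invariant to affine
    rescaling of a region's unit.
    """
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")
    out = cohort.copy()
    table = out.table
    rows = []
    flagged: list[tuple[str, str]] = []
    warnings: list[str] = []
    for ds in sorted(table["dataset"].unique()):
        ds_idx = table.index[table["dataset"] == ds]
        for reg in out.region_names:
            vals = table.loc[ds_idx, reg].to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            n_obs = int(obs.sum())
            if n_obs == 0:
                warnings.append(f"region {reg!r} entirely missing in dataset {ds!r}; skipped")
                continue
            if n_obs < 3:
                warnings.append(f"region {reg!r} has {n_obs} values in dataset {ds!r}; skipped")
                continue
            m = vals[obs].mean()
            s = vals[obs].std(ddof=1)
            if s == 0:
                hit = np.zeros(len(vals), dtype=bool)
            else:
                hit = obs & (np.abs(vals - m) > z_threshold * s)
            if hit.any():
                vals[hit] = np.nan
                table.loc[ds_idx, reg] = vals
                flagged += [(str(table.loc[j, "individual_id"]), reg)
                            for j, h in zip(ds_idx, hit) if h]
            rows.append({"dataset": ds, "region": reg,
                         "n_flagged": int(hit.sum()), "n_checked": n_obs,
                         "mean": m, "sd": s})
    counts = pd.DataFrame(rows, columns=["dataset", "region", "n_flagged",
                                         "n_checked", "mean", "sd"])
    report = QCReport(z_threshold=float(z_threshold), counts=counts,
                      flagged=flagged, warnings=warnings)
    return out, report
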