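"""Normalization, low-count filtering, duplicate collapse and batch centering.

The raw count matrices are converted to log2 counts-per-million, features
with negligible expression are dropped, duplicated feature ids are collapsed
to the most highly expressed row, and a location-only batch adjustment is
applied per feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .errors import PreprocessingError

LOG2_OFFSET = 1.0


def normalize_log2(raw: ExpressionCohort) -> ExpressionCohort:
    """Scale each sample to counts-per-million, then log2(x + 1).

    CPM normalization removes library-size differences; the +1 offset keeps
    zeros finite.  A sample with library size 0 is unusable and raises
    :class:`PreprocessingError`.
    """
    counts = raw.values.to_numpy(dtype=float)
    if (counts < 0).any():
        raise PreprocessingError("negative counts in raw matrix")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = [s for s, l in zip(raw.sample_ids, libsize) if l == 0]
        raise PreprocessingError(f"zero library size for sample(s): {bad}")
    cpm = counts / libsize * 1e6
    logged = np.log2(cpm + LOG2_OFFSET)
    out = pd.DataFrame(logged, index=raw.values.index, columns=raw.values.columns)
    return ExpressionCohort(out, raw.annotations.copy(), is_log=True)


def filter_low_counts(
    raw: ExpressionCohort, min_cpm: float = 1.0, min_frac: float = 0.2
) -> ExpressionCohort:
    """Keep features with CPM >= ``min_cpm`` in at least ``min_frac`` of samples.

    Operates on raw counts (CPM computed internally); row order is preserved
    and the filter is idempotent.
    """
    if not 0 <= min_frac <= 1:
        raise PreprocessingError("min_frac must be in [0, 1]")
    counts = raw.values.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise PreprocessingError("zero library size; cannot compute CPM")
    cpm = counts / libsize * 1e6
    frac_ok = (cpm >= min_cpm).mean(axis=1)
    keep = frac_ok >= min_frac
    if not keep.any():
        raise PreprocessingError("low-count filter removed every feature")
    return ExpressionCohort(
        raw.values.loc[keep].copy(), raw.annotations.copy(), is_log=raw.is_log
    )


def collapse_duplicates(
    cohort: ExpressionCohort, policy: str = "max_mean"
) -> tuple[ExpressionCohort, int]:
    """Collapse duplicated feature ids; returns (cohort, n_rows_dropped).

    ``max_mean`` (default) keeps, for each duplicated id, the row with the
    highest mean expression.  ``mean`` averages the duplicated rows instead.
    """
    idx = cohort.values.index
    if idx.is_unique:
        return cohort, 0
    n_before = len(idx)
    if policy == "max_mean":
        means = cohort.values.mean(axis=1).to_numpy()
        order = np.arange(len(idx))
        # stable: among equal means the first occurrence wins
        df = pd.DataFrame({"id": idx, "mean": means, "pos": order})
        best = df.sort_values(["id", "mean", "pos"], ascending=[True, False, True])
        best = best.drop_duplicates("id", keep="first").sort_values("pos")
        values = cohort.values.iloc[best["pos"].to_numpy()]
    elif policy == "mean":
        values = cohort.values.groupby(level=0, sort=False).mean()
    else:
        raise PreprocessingError(f"unknown duplicate policy '{policy}'")
    out = ExpressionCohort(values.copy(), cohort.annotations.copy(), is_log=cohort.is_log)
    return out, n_before - len(values)


def batch_center(cohort: ExpressionCohort) -> ExpressionCohort:
    """Per-feature location-only batch adjustment.

    For every feature, each batch's mean is subtracted and the grand mean
    added back, so a pure additive batch shift is removed exactly while the
    feature's overall level is preserved.  A single batch is the identity.
    Empty batch labels cannot occur (labels come from the annotation table).
    """
    batches = cohort.batch
    if batches.nunique() <= 1:
        return cohort.copy()
    vals = cohort.values
    grand = vals.mean(axis=1)
    adjusted = vals.copy()
    for b in sorted(batches.unique()):
        cols = list(batches.index[batches == b])
        batch_mean = vals[cols].mean(axis=1)
        adjusted[cols] = vals[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    return ExpressionCohort(adjusted, cohort.annotations.copy(), is_log=cohort.is_log)
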