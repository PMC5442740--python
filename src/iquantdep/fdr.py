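"""Target-decoy FDR estimation and filtering for peptide-spectrum matches.

The FDR at a score threshold s is the concatenated-search decoy/target
count ratio

    FDR(s) = #{decoy PSMs with score >= s} / max(1, #{target PSMs with score >= s})

capped at 1 (a ``plus_one`` switch adds the conservative +1 to the decoy
count).  The q-value of a PSM is the minimum FDR over all thresholds at or
below its score, which makes q monotone nonincreasing in score.  Tied
scores share a single threshold, so decoys at a tied score count against
targets at that same score (the conservative tie policy).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DECOY_PREFIX = "REV_"


def compute_fdr(psms: pd.DataFrame, plus_one: bool = False) -> pd.DataFrame:
    """Annotate a PSM table with threshold FDR and q-values.

    Parameters
    ----------
    psms
        PSM table with at least ``score`` (finite, higher = better) and
        ``is_decoy`` (bool) columns.
    plus_one
        If True, use (#decoys + 1) in the numerator.

    Returns
    -------
    Copy of ``psms`` with ``fdr_at_score`` (the FDR of the threshold equal
    to the PSM's own score) and ``q_value`` columns appended.
    """
    scores = np.asarray(psms["score"], dtype=float)
    if len(scores) == 0:
        raise ValueError("empty PSM table")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite PSM scores")
    is_decoy = np.asarray(psms["is_decoy"], dtype=bool)
    n_targets_total = int((~is_decoy).sum())
    if n_targets_total == 0:
        raise ValueError("PSM table contains no target PSMs; FDR is undefined")

    # distinct thresholds, descending; ties share one threshold
    thresholds = np.unique(scores)[::-1]
    order = np.sort(scores)
    target_sorted = np.sort(scores[~is_decoy])
    decoy_sorted = np.sort(scores[is_decoy])
    # counts with score >= threshold
    n_ge = len(order) - np.searchsorted(order, thresholds, side="left")
    t_ge = len(target_sorted) - np.searchsorted(target_sorted, thresholds, side="left")
    d_ge = n_ge - t_ge

    numer = d_ge + (1 if plus_one else 0)
    fdr = np.minimum(1.0, numer / np.maximum(1, t_ge))
    # q(threshold i) = min FDR over this and every lower threshold
    q = np.minimum.accumulate(fdr[::-1])[::-1]

    # map each PSM to its own score's threshold (thresholds are descending)
    idx = np.searchsorted(-thresholds, -scores, side="left")
    out = psms.copy()
    out["fdr_at_score"] = fdr[idx]
    out["q_value"] = q[idx]
    return out


def filter_fdr(
    psms: pd.DataFrame, threshold: float = 0.01, use_q: bool = True
) -> pd.DataFrame:
    """Retain target PSMs passing the FDR threshold; decoys never pass.

    ``use_q`` selects the monotone q-value (default) or the raw threshold
    FDR as the filtered statistic; the strict inequality ``< threshold``
    is applied either way.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for col in ("q_value", "fdr_at_score"):
        if col not in psms.columns:
            raise ValueError("PSM table is not FDR-annotated; run compute_fdr first")
    stat = psms["q_value"] if use_q else psms["fdr_at_score"]
    keep = (~psms["is_decoy"].astype(bool)) & (stat < threshold)
    return psms.loc[keep].reset_index(drop=True)
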