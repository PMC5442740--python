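"""Differentially expressed protein (DEP) selection.

Three DEP classes are called from the protein-level relative abundances:

* **1 day DEPs** and **2 month DEPs** — one-sample Student's t test of the
  replicate log2 abundances against 0, jointly with a peptide-support
  floor (at least two nonredundant peptides) and an adaptive fold-change
  cutoff: the 90th nearest-rank percentile of the fold-change magnitude
  distribution over ALL quantified proteins at that timepoint.
* **2 month / 1 day DEPs** — among the 2 month DEPs, those whose change at
  2 months significantly exceeds the change at 1 day: an unpaired pooled
  two-sample Student's t test of the per-replicate log2 fold-changes, plus
  a 90th-percentile cutoff on the normalized fold-change (the 2-month
  fold-change divided by the 1-day fold-change, folded to magnitude scale).

Fold-change magnitudes are max(FC, 1/FC) = 2^|log2 FC| so up and down
regulation are treated symmetrically.  Raw p-values are compared to the
significance level directly; no multiple-testing correction is applied at
this stage — callers needing FDR-controlled lists should treat the output
as a ranked candidate list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SelectionThresholds:
    """Joint DEP filter settings.

    p_cut : significance level for the raw t-test p (default 0.1)
    min_peptides : minimum nonredundant peptide support (default 2)
    fc_percentile : percentile rank of the per-timepoint fold-change
        magnitude distribution used as the adaptive cutoff (default 90)
    norm_fc_percentile : same, for the normalized (2 month / 1 day)
        fold-change distribution (default 90)
    """

    p_cut: float = 0.1
    min_peptides: int = 2
    fc_percentile: float = 90.0
    norm_fc_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError(f"p_cut must be in (0, 1), got {self.p_cut}")
        for name in ("fc_percentile", "norm_fc_percentile"):
            q = getattr(self, name)
            if not (0.0 < q < 100.0):
                raise ValueError(f"{name} must be in (0, 100), got {q}")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


def one_sample_t(values, null_mean: float = 0.0) -> float:
    """Two-sided one-sample Student's t-test p-value.

    t = (mean - null_mean) / (sd / sqrt(n)) with n - 1 degrees of freedom.
    Zero sample variance is degenerate: p is reported as 1.0 when the mean
    equals the null and 0.0 otherwise, with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero sample variance: degenerate one-sample t-test p-value")
        return 1.0 if math.isclose(x.mean(), null_mean, abs_tol=0.0) else 0.0
    t = (x.mean() - null_mean) / (sd / math.sqrt(x.size))
    return float(2.0 * stats.t.sf(abs(t), df=x.size - 1))


def two_sample_t(group_a, group_b) -> float:
    """Two-sided pooled-variance two-sample Student's t-test p-value.

    df = n_a + n_b - 2; zero pooled variance follows the same degenerate
    policy as :func:`one_sample_t`.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs at least 2 values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        warnings.warn("zero pooled variance: degenerate two-sample t-test p-value")
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / math.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    return float(2.0 * stats.t.sf(abs(t), df=df))


def percentile_cutoff(values, q: float) -> float:
    """Nearest-rank percentile: the k-th smallest value, k = ceil(q/100 * n)."""
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        raise ValueError("empty value list")
    if not (0.0 < q <= 100.0):
        raise ValueError(f"percentile rank must be in (0, 100], got {q}")
    k = math.ceil(q / 100.0 * x.size)
    return float(x[max(k, 1) - 1])


def _timepoint_stats(pivot: pd.DataFrame, p_cut_warnings: list) -> pd.DataFrame:
    """Per-protein mean log2fc, one-sample p, and fold-change magnitude."""
    arr = pivot.to_numpy(dtype=float)
    n = arr.shape[1]
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0.0
    if degenerate.any():
        p_cut_warnings.append(int(degenerate.sum()))
        p[degenerate] = np.where(mean[degenerate] == 0.0, 1.0, 0.0)
    return pd.DataFrame(
        {"mean_log2fc": mean, "p": p, "fc_mag": np.exp2(np.abs(mean))},
        index=pivot.index,
    )


def select_deps(
    proteins: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> pd.DataFrame:
    """Call the three DEP classes from a protein ratio table.

    ``proteins`` is the output of :func:`iquantdep.quantify.aggregate_proteins`:
    one row per (protein, replicate) with log2 abundances at both timepoints
    and the nonredundant peptide count.  Every protein must be quantified in
    the same replicates at both timepoints, and at least 10 proteins are
    required for the percentile cutoffs to be meaningful.

    Returns one row per protein with the test statistics, fold-changes,
    directions, and the three boolean DEP flags.  The containment
    ``is_dep_2m_over_1d => is_dep_2month`` holds by construction: the
    third class is selected among the 2 month DEPs.
    """
    if thresholds is None:
        thresholds = SelectionThresholds()
    required = {
        "protein",
        "replicate",
        "log2_abundance_1day",
        "log2_abundance_2month",
        "n_nonredundant_peptides",
    }
    missing = required - set(proteins.columns)
    if missing:
        raise ValueError(f"protein ratio table missing columns: {sorted(missing)}")

    piv_1d = proteins.pivot(
        index="protein", columns="replicate", values="log2_abundance_1day"
    )
    piv_2m = proteins.pivot(
        index="protein", columns="replicate", values="log2_abundance_2month"
    )
    if piv_1d.isna().any().any() or piv_2m.isna().any().any():
        raise ValueError("replicate mismatch: not every protein has every replicate")
    if len(piv_1d) < 10:
        raise ValueError(
            f"only {len(piv_1d)} proteins quantified; percentile cutoffs need >= 10"
        )

    degenerate_counts: list = []
    s1 = _timepoint_stats(piv_1d, degenerate_counts)
    s2 = _timepoint_stats(piv_2m, degenerate_counts)
    if degenerate_counts:
        warnings.warn(
            f"{sum(degenerate_counts)} zero-variance protein/timepoint tests "
            "received degenerate p-values"
        )

    n_pep = proteins.groupby("protein")["n_nonredundant_peptides"].first()
    out = pd.DataFrame(
        {
            "protein": piv_1d.index,
            "mean_log2fc_1day": s1["mean_log2fc"].to_numpy(),
            "mean_log2fc_2month": s2["mean_log2fc"].to_numpy(),
            "p_1day": s1["p"].to_numpy(),
            "p_2month": s2["p"].to_numpy(),
            "fc_mag_1day": s1["fc_mag"].to_numpy(),
            "fc_mag_2month": s2["fc_mag"].to_numpy(),
            "n_nonredundant_peptides": n_pep.loc[piv_1d.index].to_numpy(),
        }
    ).reset_index(drop=True)

    cut_1d = percentile_cutoff(out["fc_mag_1day"], thresholds.fc_percentile)
    cut_2m = percentile_cutoff(out["fc_mag_2month"], thresholds.fc_percentile)
    support = out["n_nonredundant_peptides"] >= thresholds.min_peptides
    out["is_dep_1day"] = (
        (out["p_1day"] < thresholds.p_cut) & support & (out["fc_mag_1day"] > cut_1d)
    )
    out["is_dep_2month"] = (
        (out["p_2month"] < thresholds.p_cut) & support & (out["fc_mag_2month"] > cut_2m)
    )

    # normalized fold-change: 2-month FC divided by 1-day FC, magnitude scale
    norm_log2 = out["mean_log2fc_2month"] - out["mean_log2fc_1day"]
    out["norm_fc"] = np.exp2(norm_log2)
    norm_fc_mag = np.exp2(np.abs(norm_log2))
    cut_norm = percentile_cutoff(norm_fc_mag, thresholds.norm_fc_percentile)

    p_2v1 = np.array(
        [
            two_sample_t(piv_1d.loc[prot], piv_2m.loc[prot])
            for prot in piv_1d.index
        ]
    )
    out["p_2m_vs_1d"] = p_2v1
    out["is_dep_2m_over_1d"] = (
        out["is_dep_2month"]
        & (out["p_2m_vs_1d"] < thresholds.p_cut)
        & (norm_fc_mag > cut_norm)
    )
    out["direction_1day"] = np.where(out["mean_log2fc_1day"] >= 0, "up", "down")
    out["direction_2month"] = np.where(out["mean_log2fc_2month"] >= 0, "up", "down")
    out.attrs["fc_cutoff_1day"] = cut_1d
    out.attrs["fc_cutoff_2month"] = cut_2m
    out.attrs["norm_fc_cutoff"] = cut_norm
    return out
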