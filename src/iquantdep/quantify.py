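"""Reporter-ion normalization, peptide ratios, and L1 protein rollup.

The quantitation path is:

1. collapse retained PSMs to one row per (peptide, replicate) by summing
   raw reporter intensities per channel, drop peptides shared between
   proteins, drop rows with zero/missing intensities, and log2-transform
   (:func:`build_reporter_matrix`);
2. quantile-normalize the resulting peptide x (4 channels x R replicates)
   log2 matrix so every column shares one reference distribution
   (:func:`quantile_normalize`);
3. form per-peptide treated/control log2 ratios, 116:114 at 1 day and
   117:115 at 2 months, within each replicate (:func:`peptide_ratios`);
4. aggregate peptide ratios to one protein-level log2 relative abundance
   per (protein, replicate, timepoint) by minimizing the L1 objective
   sum_i |r_i - rho| (:func:`lp_protein_ratio`, :func:`aggregate_proteins`).

The L1 minimizer has the order-statistic closed form (median for odd n,
midpoint of the two central order statistics for even n); an explicit
linear-program route is kept as a cross-checked alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CHANNELS = ("i114", "i115", "i116", "i117")


def build_reporter_matrix(psms: pd.DataFrame) -> pd.DataFrame:
    """Collapse filtered target PSMs into a peptide-level log2 intensity matrix.

    Returns a DataFrame indexed by (protein, peptide) with a (replicate,
    channel) column MultiIndex.  Multiple PSMs of one peptide in one
    replicate are summed per channel on the raw intensity scale before the
    log transform.  Peptides mapping to more than one protein are excluded
    (unique-peptide parsimony), as are peptides with any zero or missing
    intensity in any observed (replicate, channel) cell — the documented
    no-imputation missing-data policy.
    """
    if psms.empty:
        raise ValueError("no PSMs to quantify")
    if psms["is_decoy"].astype(bool).any():
        raise ValueError("decoy PSMs must be filtered out before quantitation")
    shared = psms.groupby("peptide")["protein"].nunique()
    shared_peptides = set(shared.index[shared > 1])
    df = psms[~psms["peptide"].isin(shared_peptides)]
    if df.empty:
        raise ValueError("no uniquely mapped peptides to quantify")
    collapsed = (
        df.groupby(["protein", "peptide", "replicate"], sort=True)[list(CHANNELS)]
        .sum()
        .reset_index()
    )
    wide = collapsed.pivot_table(
        index=["protein", "peptide"],
        columns="replicate",
        values=list(CHANNELS),
        aggfunc="first",
    )
    # columns come out as (channel, replicate); flip to (replicate, channel)
    wide.columns = pd.MultiIndex.from_tuples(
        [(rep, ch) for ch, rep in wide.columns], names=["replicate", "channel"]
    )
    wide = wide.sort_index(axis=1)
    ok = np.isfinite(wide.to_numpy(dtype=float)) & (wide.to_numpy(dtype=float) > 0)
    complete = ok.all(axis=1)
    wide = wide.loc[complete]
    if wide.empty:
        raise ValueError("every peptide was dropped by the missing-data policy")
    return np.log2(wide.astype(float))


def quantile_normalize(matrix: pd.DataFrame, mode: str = "joint") -> pd.DataFrame:
    """Quantile-normalize the columns of a matrix.

    Every column is mapped onto the reference distribution formed by the
    row-wise means of the column-sorted matrix; within-column ranks are
    preserved and tied values receive the mean of the reference values
    their ranks span.

    ``mode="joint"`` normalizes all columns together (the default: one
    normalization across all 4 channels x R replicates); ``"per_replicate"``
    normalizes each replicate's 4 channel columns separately (requires a
    (replicate, channel) column MultiIndex); ``"none"`` returns the input
    unchanged, for noise-free validation runs where rank remapping is
    unnecessary.
    """
    if mode == "none":
        return matrix.copy()
    if mode == "per_replicate":
        if matrix.columns.nlevels != 2:
            raise ValueError(
                "per-replicate normalization needs (replicate, channel) columns"
            )
        parts = [
            quantile_normalize(matrix[[c for c in matrix.columns if c[0] == rep]])
            for rep in matrix.columns.get_level_values(0).unique()
        ]
        return pd.concat(parts, axis=1)[matrix.columns]
    if mode != "joint":
        raise ValueError(f"unknown normalization mode {mode!r}")

    arr = matrix.to_numpy(dtype=float)
    if arr.shape[0] < 1:
        raise ValueError("empty matrix")
    if not np.isfinite(arr).all():
        raise ValueError(
            "non-finite entries; apply the missing-data policy before normalizing"
        )
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties get the mean of the reference values their ranks span
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def peptide_ratios(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide, per-replicate treated/control log2 ratios.

    From a normalized (protein, peptide) x (replicate, channel) log2
    matrix, emits one row per (peptide, replicate) with
    ``log2_ratio_1day = log2 i116 - log2 i114`` and
    ``log2_ratio_2month = log2 i117 - log2 i115``.  A (peptide, replicate)
    missing one member of a channel pair is dropped from that ratio only.
    """
    if matrix.columns.nlevels != 2:
        raise ValueError("expected (replicate, channel) column MultiIndex")
    reps = matrix.columns.get_level_values(0).unique()
    rows = []
    for rep in reps:
        sub = matrix.xs(rep, axis=1, level=0)
        r1d = sub["i116"] - sub["i114"]
        r2m = sub["i117"] - sub["i115"]
        block = pd.DataFrame(
            {
                "replicate": rep,
                "log2_ratio_1day": r1d,
                "log2_ratio_2month": r2m,
            }
        )
        rows.append(block.reset_index())
    out = pd.concat(rows, ignore_index=True)
    out = out.dropna(subset=["log2_ratio_1day", "log2_ratio_2month"], how="all")
    return out[
        [
            "protein",
            "peptide",
            "replicate",
            "log2_ratio_1day",
            "log2_ratio_2month",
        ]
    ]


def lp_protein_ratio(ratios, method: str = "closed_form") -> float:
    """L1-optimal protein log2 ratio from its peptide log2 ratios.

    Returns the rho minimizing sum_i |r_i - rho|.  ``closed_form`` uses the
    order-statistic solution: the sample median for odd n, the midpoint of
    the two central order statistics for even n (the documented tie policy
    on the flat segment of the objective).  ``lp`` solves the equivalent
    linear program min sum t_i s.t. t_i >= r_i - rho, t_i >= rho - r_i,
    kept as an independent cross-check route.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("no ratios to aggregate")
    if not np.isfinite(r).all():
        raise ValueError("non-finite ratios")
    if method == "closed_form":
        return float(np.median(r))
    if method == "lp":
        from scipy.optimize import linprog

        n = r.size
        # variables: [rho, t_1..t_n]; minimize sum t_i
        c = np.concatenate([[0.0], np.ones(n)])
        a_ub = np.zeros((2 * n, n + 1))
        b_ub = np.zeros(2 * n)
        a_ub[:n, 0] = -1.0  # r_i - rho <= t_i
        a_ub[:n, 1:] = -np.eye(n)
        b_ub[:n] = -r
        a_ub[n:, 0] = 1.0  # rho - r_i <= t_i
        a_ub[n:, 1:] = -np.eye(n)
        b_ub[n:] = r
        res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=[(None, None)] * (n + 1))
        if not res.success:
            raise RuntimeError(f"LP solve failed: {res.message}")
        return float(res.x[0])
    raise ValueError(f"unknown method {method!r}")


def aggregate_proteins(ratios: pd.DataFrame, method: str = "closed_form") -> pd.DataFrame:
    """Roll peptide ratios up to protein relative abundances.

    For each (protein, replicate, timepoint), applies
    :func:`lp_protein_ratio` to the protein's peptide log2 ratios.
    Peptides mapping to multiple proteins are excluded before rollup.
    ``n_nonredundant_peptides`` is the number of distinct peptide sequences
    supporting the protein (maximum over replicates); modifications and
    charge states are not distinguished.
    """
    if ratios.empty:
        raise ValueError("empty peptide ratio table")
    shared = ratios.groupby("peptide")["protein"].nunique()
    df = ratios[~ratios["peptide"].isin(set(shared.index[shared > 1]))]
    if df.empty:
        raise ValueError("no uniquely mapped peptides after shared-peptide exclusion")

    rows = []
    for (protein, rep), grp in df.groupby(["protein", "replicate"], sort=True):
        r1 = grp["log2_ratio_1day"].dropna()
        r2 = grp["log2_ratio_2month"].dropna()
        if r1.empty and r2.empty:
            continue
        rows.append(
            {
                "protein": protein,
                "replicate": rep,
                "log2_abundance_1day": (
                    lp_protein_ratio(r1, method) if not r1.empty else np.nan
                ),
                "log2_abundance_2month": (
                    lp_protein_ratio(r2, method) if not r2.empty else np.nan
                ),
                "_n_peptides_rep": grp["peptide"].nunique(),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no proteins with usable peptides")
    n_pep = out.groupby("protein")["_n_peptides_rep"].max().rename(
        "n_nonredundant_peptides"
    )
    out = out.drop(columns="_n_peptides_rep").merge(n_pep, on="protein")
    return out.sort_values(["protein", "replicate"]).reset_index(drop=True)
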