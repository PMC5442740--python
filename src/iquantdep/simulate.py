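"""Seeded synthetic iTRAQ 4-plex PSM datasets with planted ground truth.

The generator emulates a two-timepoint transplantation study design:
channel 114 = vehicle at 1 day, 115 = vehicle at 2 months, 116 = treated
at 1 day, 117 = treated at 2 months, with triplicate experiments.  Each
protein draws a baseline log2 intensity; each of its peptides, in each
replicate, receives four channel intensities

    2^(baseline + peptide offset + channel log2 bias + condition effect
       + Normal(0, peptide_noise_sd))

where the condition effect adds the planted 1-day log2 fold-change to
channel 116 and the 2-month log2 fold-change to channel 117 (vehicle
channels carry no effect).  Effects are planted on a designated fraction
of proteins as sign-symmetric magnitudes drawn from
Normal(log2_effect_mean, log2_effect_sd); the rest are null.  Decoy PSM
rows (protein ids prefixed ``REV_``) carry search scores from a separate,
lower-scoring distribution so the target-decoy FDR filter has something to
do.  Planted up-regulated 2-month proteins are assigned to the
oligodendrocyte marker set with elevated odds, planting the cell-type
enrichment signal the downstream profile should recover.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
consumed in a fixed documented order (baselines, peptide structure,
effects, cell types, intensities, scores, decoys, gene sets), so a given
config is byte-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .fdr import DECOY_PREFIX

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for one synthetic dataset.

    Defaults encode the benchmark condition exercised throughout the test
    suite: 1,000 proteins in triplicate, 10% planted DEPs per timepoint at
    |log2 FC| = 1, 5-10 peptides per protein, peptide-level log2 noise of
    0.2, and 5-fold oligodendrocyte enrichment odds for up-regulated
    2-month DEPs.  Marker set sizes are a 1/10 scale of the 1,441 / 1,489 /
    1,371-gene neuron / astrocyte / oligodendrocyte marker panels typical
    of brain cell-type catalogs.
    """

    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (5, 10)
    n_replicates: int = 3
    frac_dep_1day: float = 0.1
    frac_dep_2month: float = 0.1
    log2_effect_mean: float = 1.0
    log2_effect_sd: float = 0.0
    peptide_noise_sd: float = 0.2
    peptide_offset_sd: float = 1.0
    channel_bias: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    baseline_log_intensity_mean: float = 16.0
    baseline_log_intensity_sd: float = 2.0
    decoy_fraction: float = 0.15
    target_score_mean: float = 8.0
    target_score_sd: float = 2.0
    decoy_score_mean: float = 2.0
    decoy_score_sd: float = 1.0
    marker_set_sizes: tuple[int, int, int] = (144, 149, 137)  # neuron, astro, oligo
    oligo_enrichment_factor: float = 5.0
    n_function_sets: int = 10
    function_set_size: tuple[int, int] = (20, 60)
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dep_1day", "frac_dep_2month", "decoy_fraction",
                     "dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.peptides_per_protein[0] < 1 or (
            self.peptides_per_protein[0] > self.peptides_per_protein[1]
        ):
            raise ValueError("peptides_per_protein must be a valid (min, max) range")
        if any(b <= 0 for b in self.channel_bias) or len(self.channel_bias) != 4:
            raise ValueError("channel_bias must be 4 strictly positive factors")
        for name in ("peptide_noise_sd", "peptide_offset_sd",
                     "baseline_log_intensity_sd", "log2_effect_sd",
                     "target_score_sd", "decoy_score_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if sum(self.marker_set_sizes) > self.n_proteins:
            raise ValueError(
                f"marker_set_sizes sum to {sum(self.marker_set_sizes)} "
                f"> n_proteins = {self.n_proteins}"
            )
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def _plant_effects(rng: np.random.Generator, cfg: SimulationConfig,
                   frac: float) -> np.ndarray:
    """Sign-symmetric planted log2 effects for a random protein fraction."""
    effects = np.zeros(cfg.n_proteins)
    n_dep = int(round(frac * cfg.n_proteins))
    if n_dep == 0:
        return effects
    idx = rng.choice(cfg.n_proteins, size=n_dep, replace=False)
    magnitudes = np.abs(rng.normal(cfg.log2_effect_mean, cfg.log2_effect_sd, n_dep))
    signs = np.where(rng.random(n_dep) < 0.5, 1.0, -1.0)
    effects[idx] = signs * magnitudes
    return effects


def _assign_cell_types(rng: np.random.Generator, cfg: SimulationConfig,
                       fc_2month: np.ndarray) -> np.ndarray:
    """Fill marker sets to size, biasing up-regulated 2-month DEPs to oligo."""
    n_neuron, n_astro, n_oligo = cfg.marker_set_sizes
    remaining = {
        "neuron": n_neuron,
        "astrocyte": n_astro,
        "oligodendrocyte": n_oligo,
        "none": cfg.n_proteins - n_neuron - n_astro - n_oligo,
    }
    membership = np.array(["unassigned"] * cfg.n_proteins, dtype=object)
    cats = ("neuron", "astrocyte", "oligodendrocyte", "none")

    up_2m = np.flatnonzero(fc_2month > 0)
    for i in up_2m:
        weights = np.array(
            [
                remaining["neuron"],
                remaining["astrocyte"],
                cfg.oligo_enrichment_factor * remaining["oligodendrocyte"],
                remaining["none"],
            ],
            dtype=float,
        )
        if weights.sum() == 0:
            break
        choice = cats[rng.choice(4, p=weights / weights.sum())]
        membership[i] = choice
        remaining[choice] -= 1

    rest = np.flatnonzero(membership == "unassigned")
    rest = rest[rng.permutation(len(rest))]
    pool = np.concatenate(
        [np.repeat(cat, remaining[cat]) for cat in cats]
    )
    membership[rest] = pool[: len(rest)]
    return membership


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 18))
        s = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection]:
    """Generate one synthetic PSM dataset with planted ground truth.

    Returns
    -------
    psms
        PSM table (``psm_id, peptide, protein, is_decoy, score, replicate,
        i114, i115, i116, i117``), targets first, then decoys.
    truth
        One row per protein: planted log2 fold-changes at both timepoints,
        DEP flags (true iff the planted effect is nonzero), and cell-type
        membership (gene symbol = protein id in synthetic data).
    collection
        Gene sets over the protein-id universe: the three cell-type marker
        sets sized per config, plus ``n_function_sets`` random
        functional-category sets for exercising set enrichment.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    protein_ids = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])
    # draw order is fixed: baselines, peptide counts, offsets, effects(1d, 2m),
    # cell types, peptide sequences, intensity noise, scores, decoys, gene sets
    baselines = rng.normal(
        cfg.baseline_log_intensity_mean,
        cfg.baseline_log_intensity_sd,
        cfg.n_proteins,
    )
    pep_lo, pep_hi = cfg.peptides_per_protein
    pep_counts = rng.integers(pep_lo, pep_hi + 1, cfg.n_proteins)
    offsets = [
        rng.normal(0.0, cfg.peptide_offset_sd, int(k)) for k in pep_counts
    ]
    fc_1day = _plant_effects(rng, cfg, cfg.frac_dep_1day)
    fc_2month = _plant_effects(rng, cfg, cfg.frac_dep_2month)
    membership = _assign_cell_types(rng, cfg, fc_2month)
    peptides = _random_peptides(rng, int(pep_counts.sum()))

    log_bias = np.log2(np.asarray(cfg.channel_bias, dtype=float))
    effect_per_channel = np.zeros((cfg.n_proteins, 4))
    effect_per_channel[:, 2] = fc_1day   # 116: treated, 1 day
    effect_per_channel[:, 3] = fc_2month  # 117: treated, 2 months

    rows_protein = []
    rows_peptide = []
    rows_replicate = []
    mu_rows = []
    pep_cursor = 0
    for i in range(cfg.n_proteins):
        for j in range(int(pep_counts[i])):
            pep = peptides[pep_cursor]
            pep_cursor += 1
            base = baselines[i] + offsets[i][j]
            for rep in range(1, cfg.n_replicates + 1):
                rows_protein.append(protein_ids[i])
                rows_peptide.append(pep)
                rows_replicate.append(rep)
                mu_rows.append(base + log_bias + effect_per_channel[i])
    mu = np.asarray(mu_rows)
    noise = rng.normal(0.0, cfg.peptide_noise_sd, mu.shape)
    intensities = np.exp2(mu + noise)
    if cfg.dropout_rate > 0:
        drop = rng.random(mu.shape) < cfg.dropout_rate
        intensities[drop] = 0.0

    n_target = len(rows_protein)
    target_scores = rng.normal(cfg.target_score_mean, cfg.target_score_sd, n_target)

    psms = pd.DataFrame(
        {
            "psm_id": [f"PSM{k:07d}" for k in range(n_target)],
            "peptide": rows_peptide,
            "protein": rows_protein,
            "is_decoy": False,
            "score": target_scores,
            "replicate": rows_replicate,
            "i114": intensities[:, 0],
            "i115": intensities[:, 1],
            "i116": intensities[:, 2],
            "i117": intensities[:, 3],
        }
    )

    if cfg.decoy_fraction > 0:
        n_decoy = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_target))
        decoy_scores = rng.normal(cfg.decoy_score_mean, cfg.decoy_score_sd, n_decoy)
        decoy_proteins = DECOY_PREFIX + rng.choice(protein_ids, n_decoy)
        decoy_peptides = _random_peptides(rng, n_decoy)
        decoy_reps = rng.integers(1, cfg.n_replicates + 1, n_decoy)
        decoy_mu = rng.normal(
            cfg.baseline_log_intensity_mean,
            cfg.baseline_log_intensity_sd,
            (n_decoy, 4),
        )
        decoys = pd.DataFrame(
            {
                "psm_id": [f"PSM{k:07d}" for k in range(n_target, n_target + n_decoy)],
                "peptide": decoy_peptides,
                "protein": decoy_proteins,
                "is_decoy": True,
                "score": decoy_scores,
                "replicate": decoy_reps,
                "i114": np.exp2(decoy_mu[:, 0]),
                "i115": np.exp2(decoy_mu[:, 1]),
                "i116": np.exp2(decoy_mu[:, 2]),
                "i117": np.exp2(decoy_mu[:, 3]),
            }
        )
        psms = pd.concat([psms, decoys], ignore_index=True)

    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_log2fc_1day": fc_1day,
            "true_log2fc_2month": fc_2month,
            "is_dep_1day": fc_1day != 0.0,
            "is_dep_2month": fc_2month != 0.0,
            "cell_type_membership": membership,
        }
    )

    sets: dict[str, set[str]] = {
        cell: set(protein_ids[membership == cell])
        for cell in ("neuron", "astrocyte", "oligodendrocyte")
    }
    lo, hi = cfg.function_set_size
    for s in range(cfg.n_function_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, cfg.n_proteins)
        members = rng.choice(protein_ids, size=size, replace=False)
        sets[f"FUNC_SET_{s:02d}"] = set(members)
    collection = GeneSetCollection(sets=sets, universe=set(protein_ids))
    return psms, truth, collection


def simulate_score_mixture(
    n_psms: int,
    frac_incorrect: float = 0.3,
    correct_mean: float = 5.0,
    null_mean: float = 0.0,
    score_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled target/decoy score mixture for FDR calibration studies.

    Emulates the concatenated-search setting the decoy/target estimator
    assumes: of ``n_psms`` target PSMs, a fraction ``frac_incorrect`` are
    incorrect matches whose scores come from the null distribution, and
    the decoy set is the same size as the incorrect-target set, drawn from
    that same null.  The returned table carries ``is_correct`` ground-truth
    labels so the realized false-discovery proportion after filtering can
    be compared with the nominal level.
    """
    if not (0.0 < frac_incorrect < 1.0):
        raise ValueError("frac_incorrect must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_incorrect = int(round(frac_incorrect * n_psms))
    n_correct = n_psms - n_incorrect
    scores = np.concatenate(
        [
            rng.normal(correct_mean, score_sd, n_correct),
            rng.normal(null_mean, score_sd, n_incorrect),
            rng.normal(null_mean, score_sd, n_incorrect),  # decoys
        ]
    )
    n_total = n_correct + 2 * n_incorrect
    return pd.DataFrame(
        {
            "psm_id": [f"PSM{k:07d}" for k in range(n_total)],
            "peptide": "PEPTIDEK",
            "protein": (
                ["P1"] * n_psms + [DECOY_PREFIX + "P1"] * n_incorrect
            ),
            "is_decoy": [False] * n_psms + [True] * n_incorrect,
            "score": scores,
            "replicate": 1,
            "i114": 1.0,
            "i115": 1.0,
            "i116": 1.0,
            "i117": 1.0,
            "is_correct": (
                [True] * n_correct + [False] * (n_incorrect * 2)
            ),
        }
    )
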