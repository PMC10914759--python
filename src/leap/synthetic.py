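"""Synthetic cohort and plate-read generation.

Emulates the study design end to end: a 450-donor cohort (132 lung cancer)
with exact quota-sampled demographics, a 150-donor triplicate subset mirroring
the site x diagnosis mix, and 384-well plate reads for the 18-sensor panel at
10-60 min with a per-plate BM19 standard-curve dilution series.

Demographic margins are quota-sampled (largest-remainder apportionment, then
a seeded shuffle) rather than drawn independently, so configured integer
counts are hit exactly and fixture tests are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, SignalModel
from .panel import (
    SENSORS,
    STD_SENSOR,
    STANDARD_LEVELS,
    WELLS_384,
    ASSAYS_PER_PLATE,
)

READS_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "assay_id",
    "donor_id",
    "sensor_id",
    "time_min",
    "fluorescence",
]

DONOR_COLUMNS = [
    "donor_id",
    "site",
    "sex",
    "age_band",
    "smoking",
    "diagnosis",
    "stage",
    "histology",
    "n_assays",
]

CANCER = "lung cancer"
NON_CANCER = "non-lung cancer"


class ReadsParseError(ValueError):
    """Raised when a reads/donors CSV violates the expected schema."""


def _quota_counts(probs: dict, n: int) -> dict:
    """Integer apportionment of n among categories by largest remainder."""
    cats = list(probs)
    raw = np.array([probs[c] for c in cats], dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    # ties in fractional part resolved by category order (deterministic)
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(cats, base))


def _quota_column(probs: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    counts = _quota_counts(probs, n)
    col = np.concatenate([np.full(c, cat, dtype=object) for cat, c in counts.items()])
    rng.shuffle(col)
    return col


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the donor table.

    Exactly ``cancer_count`` donors carry a lung-cancer diagnosis (with stage
    and histology); exactly ``triplicate_count`` donors are assigned 3 assays,
    chosen to mirror the cohort's site x diagnosis distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_donors

    donors = pd.DataFrame(
        {
            "donor_id": [f"D{i + 1:04d}" for i in range(n)],
            "site": _quota_column(config.site_probs, n, rng),
            "sex": _quota_column(config.sex_probs, n, rng),
            "age_band": _quota_column(config.age_band_probs, n, rng),
            "smoking": _quota_column(config.smoking_probs, n, rng),
        }
    )
    diagnosis = np.concatenate(
        [
            np.full(config.cancer_count, CANCER, dtype=object),
            np.full(n - config.cancer_count, NON_CANCER, dtype=object),
        ]
    )
    rng.shuffle(diagnosis)
    donors["diagnosis"] = diagnosis

    donors["stage"] = ""
    donors["histology"] = ""
    is_cancer = donors["diagnosis"] == CANCER
    k = int(is_cancer.sum())
    if k:
        donors.loc[is_cancer, "stage"] = _quota_column(config.stage_probs, k, rng)
        donors.loc[is_cancer, "histology"] = _quota_column(config.histology_probs, k, rng)

    donors["n_assays"] = 1
    if config.triplicate_count:
        cells = donors.groupby(["site", "diagnosis"], sort=True).indices
        sizes = {c: len(ix) for c, ix in cells.items()}
        total = sum(sizes.values())
        quotas = _quota_counts(
            {c: s / total for c, s in sizes.items()}, config.triplicate_count
        )
        chosen = []
        for cell, ix in cells.items():
            take = min(quotas[cell], len(ix))
            chosen.append(rng.choice(ix, size=take, replace=False))
        chosen = np.concatenate(chosen)
        donors.loc[chosen, "n_assays"] = 3
    return donors


def true_concentration(
    donor, sensor: str, time_min: float, model: SignalModel, donor_effect: float = 0.0
) -> float:
    """Noise-free released peptide-TCPP concentration in ng/ml.

    Saturating kinetics ``A_s * t/(t + K_s)``, multiplied by
    ``(1 - delta_s)`` for cancer donors and by ``exp(donor_effect)``. The
    donor effect is shared across sensors; draw it once per donor (see
    :func:`draw_donor_effects`).
    """
    if time_min <= 0:
        raise ValueError("time_min must be > 0")
    a = model.amplitude[sensor]
    k = model.half_time[sensor]
    delta = model.effect_fraction(sensor)
    cancer = donor["diagnosis"] == CANCER
    return a * time_min / (time_min + k) * (1.0 - delta * cancer) * np.exp(donor_effect)


def draw_donor_effects(donors: pd.DataFrame, model: SignalModel, rng) -> pd.Series:
    """One lognormal (log-scale Gaussian) effect per donor, indexed by donor_id."""
    u = rng.normal(0.0, model.donor_sd, size=len(donors))
    return pd.Series(u, index=donors["donor_id"].to_numpy())


def generate_plate_reads(
    donors: pd.DataFrame, model: SignalModel, seed: int
) -> pd.DataFrame:
    """Generate well-level fluorescence reads for every assay of every donor.

    Each assay occupies an 18-well block (one well per sensor) read at every
    timepoint; 21 assays fill a 384-well plate whose last six wells hold the
    two-fold standard dilution series (800 -> 25 ng/ml, ``role='standard'``).
    Sample fluorescence is ``intercept + slope*C*(1+cv_noise) + read_noise``
    floored at 0 RFU.
    """
    if len(donors) == 0:
        raise ValueError("donor table is empty")
    model.validate()
    rng = np.random.default_rng(seed)
    effects = draw_donor_effects(donors, model, rng)

    # assay table: one row per assay, plate position assigned sequentially
    rep = donors["n_assays"].to_numpy()
    a_donor = np.repeat(donors["donor_id"].to_numpy(), rep)
    a_cancer = np.repeat((donors["diagnosis"] == CANCER).to_numpy(), rep)
    a_rep_no = np.concatenate([np.arange(1, r + 1) for r in rep])
    assay_ids = np.array(
        [f"{d}-A{r}" for d, r in zip(a_donor, a_rep_no)], dtype=object
    )
    n_assays = len(assay_ids)
    plate_no = np.arange(n_assays) // ASSAYS_PER_PLATE
    block = np.arange(n_assays) % ASSAYS_PER_PLATE

    tps = np.asarray(model.timepoints, dtype=float)
    n_t, n_s = len(tps), len(SENSORS)
    per_assay = n_s * n_t

    # expand to assay x sensor x time (assay-major, then sensor, then time)
    idx_a = np.repeat(np.arange(n_assays), per_assay)
    idx_s = np.tile(np.repeat(np.arange(n_s), n_t), n_assays)
    t = np.tile(tps, n_assays * n_s)

    amp = np.array([model.amplitude[s] for s in SENSORS])
    half = np.array([model.half_time[s] for s in SENSORS])
    delta = np.array([model.effect_fraction(s) for s in SENSORS])
    u = effects.loc[a_donor].to_numpy()

    conc = (
        amp[idx_s]
        * t
        / (t + half[idx_s])
        * (1.0 - delta[idx_s] * a_cancer[idx_a])
        * np.exp(u[idx_a])
    )
    fluor = (
        model.curve_intercept
        + model.curve_slope
        * conc
        * (1.0 + rng.normal(0.0, model.replicate_cv, size=conc.size))
        + rng.normal(0.0, model.read_noise_sd, size=conc.size)
    )
    np.maximum(fluor, 0.0, out=fluor)

    wells = np.array(WELLS_384, dtype=object)
    sample = pd.DataFrame(
        {
            "plate_id": np.array(
                [f"P{p + 1:03d}" for p in plate_no], dtype=object
            )[idx_a],
            "well": wells[block[idx_a] * n_s + idx_s],
            "role": "sample",
            "assay_id": assay_ids[idx_a],
            "donor_id": a_donor[idx_a],
            "sensor_id": np.array(SENSORS, dtype=object)[idx_s],
            "time_min": t.astype(int),
            "fluorescence": fluor,
        }
    )

    n_plates = int(plate_no.max()) + 1
    levels = np.tile(np.asarray(STANDARD_LEVELS), n_plates)
    std_fluor = (
        model.curve_intercept
        + model.curve_slope * levels
        + rng.normal(0.0, model.read_noise_sd, size=levels.size)
    )
    np.maximum(std_fluor, 0.0, out=std_fluor)
    std = pd.DataFrame(
        {
            "plate_id": np.repeat(
                np.array([f"P{p + 1:03d}" for p in range(n_plates)], dtype=object),
                len(STANDARD_LEVELS),
            ),
            "well": np.tile(
                wells[ASSAYS_PER_PLATE * n_s :][: len(STANDARD_LEVELS)], n_plates
            ),
            "role": "standard",
            "assay_id": np.array(
                [f"STD-{int(c)}" for c in levels], dtype=object
            ),
            "donor_id": "",
            "sensor_id": STD_SENSOR,
            "time_min": int(tps[-1]),
            "fluorescence": std_fluor,
        }
    )
    return pd.concat([sample, std], ignore_index=True)[READS_COLUMNS]


def standard_level_of(assay_id: str) -> float:
    """Nominal ng/ml of a standard well, encoded as ``STD-<ng/ml>``."""
    try:
        return float(assay_id.split("-", 1)[1])
    except (IndexError, ValueError) as exc:
        raise ReadsParseError(f"malformed standard assay_id {assay_id!r}") from exc


def write_reads_csv(reads: pd.DataFrame, path) -> None:
    reads[READS_COLUMNS].to_csv(path, index=False)


def read_reads_csv(path) -> pd.DataFrame:
    reads = pd.read_csv(path, dtype={"donor_id": object}, keep_default_na=False)
    missing = [c for c in READS_COLUMNS if c not in reads.columns]
    if missing:
        raise ReadsParseError(f"{path}: missing columns {missing}")
    valid = set(SENSORS) | {STD_SENSOR}
    bad = ~reads["sensor_id"].isin(valid)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ReadsParseError(
            f"{path}, line {line}: unknown sensor_id "
            f"{reads.loc[bad].iloc[0]['sensor_id']!r}"
        )
    fluor = pd.to_numeric(reads["fluorescence"], errors="coerce")
    nonfinite = ~np.isfinite(fluor.to_numpy(dtype=float, na_value=np.nan))
    if nonfinite.any():
        line = int(np.flatnonzero(nonfinite)[0]) + 2
        raise ReadsParseError(f"{path}, line {line}: non-finite fluorescence")
    reads["fluorescence"] = fluor
    reads["time_min"] = reads["time_min"].astype(int)
    return reads[READS_COLUMNS]


def write_donors_csv(donors: pd.DataFrame, path) -> None:
    donors[DONOR_COLUMNS].to_csv(path, index=False)


def read_donors_csv(path) -> pd.DataFrame:
    donors = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in DONOR_COLUMNS if c not in donors.columns]
    if missing:
        raise ReadsParseError(f"{path}: missing columns {missing}")
    donors["n_assays"] = donors["n_assays"].astype(int)
    bad = ~donors["n_assays"].isin([1, 3])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ReadsParseError(f"{path}, line {line}: n_assays must be 1 or 3")
    return donors[DONOR_COLUMNS]
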