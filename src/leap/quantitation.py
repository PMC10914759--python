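"""Fluorescence quantitation and feature-matrix assembly.

Raw plate-reader fluorescence is converted to released peptide-TCPP
concentration (ng/ml) through the per-plate BM19 standard curve (ordinary
least squares of fluorescence on concentration), censored to zero strictly
below the lower limit of quantitation, and pivoted into the assay x
sensor_time feature matrix used by every downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DEFAULT_LLOQ, feature_name, sensor_of_feature  # noqa: F401
from .synthetic import CANCER, standard_level_of

#: metadata columns preceding the feature block in features.csv
META_COLS = [
    "assay_id",
    "donor_id",
    "label",
    "site",
    "sex",
    "age_band",
    "smoking",
    "stage",
    "histology",
]

LABEL_CANCER = "LC"
LABEL_CONTROL = "non-LC"


class CurveFitError(ValueError):
    """Standard-curve fit is impossible (too few levels / no variance)."""


class CompletenessError(ValueError):
    """An assay is missing one or more sensor x time reads."""


@dataclass
class StandardCurve:
    """Per-plate calibration line: fluorescence = intercept + slope * ng/ml."""

    plate_id: str
    slope: float
    intercept: float
    r_squared: float
    lloq: float = DEFAULT_LLOQ
    qc_pass: bool = True


def fit_standard_curve(
    concentrations,
    fluorescences,
    plate_id: str = "",
    lloq: float = DEFAULT_LLOQ,
    qc_threshold: float = 0.999,
) -> StandardCurve:
    """OLS line of fluorescence on concentration for one plate's standards.

    ``r_squared`` is the squared Pearson correlation. Curves with r-squared
    below ``qc_threshold`` are flagged (``qc_pass=False``) with a warning,
    not rejected; the observed regime is r-squared > 0.9999.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fluorescences, dtype=float)
    if len(np.unique(x)) < 3:
        raise CurveFitError(
            f"plate {plate_id!r}: need >=3 distinct concentration levels"
        )
    if np.ptp(x) == 0:
        raise CurveFitError(f"plate {plate_id!r}: zero concentration variance")
    if np.ptp(y) == 0:
        # degenerate flat response: slope 0 would be unusable; keep the OLS
        # line (slope 0) but report r^2 = 0 and fail QC
        curve = StandardCurve(plate_id, 0.0, float(y.mean()), 0.0, lloq, False)
        warnings.warn(
            f"plate {plate_id!r}: flat standard responses, r^2 = 0 (QC fail)"
        )
        return curve
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    qc = r2 >= qc_threshold
    if not qc:
        warnings.warn(
            f"plate {plate_id!r}: standard curve r^2 = {r2:.6f} "
            f"below QC threshold {qc_threshold}"
        )
    return StandardCurve(plate_id, float(fit.slope), float(fit.intercept), r2, lloq, qc)


def fluor_to_conc(curve: StandardCurve, fluorescence):
    """Invert the calibration line; negative concentrations floor at 0."""
    if curve.slope <= 0:
        raise CurveFitError(f"plate {curve.plate_id!r}: non-positive slope")
    conc = (np.asarray(fluorescence, dtype=float) - curve.intercept) / curve.slope
    out = np.maximum(conc, 0.0)
    return float(out) if np.isscalar(fluorescence) else out


def apply_lloq(conc, lloq: float = DEFAULT_LLOQ):
    """Censor concentrations strictly below the LLOQ to exactly zero.

    Values exactly at the LLOQ are retained ('below' is read strictly).
    Idempotent.
    """
    arr = np.asarray(conc, dtype=float)
    out = np.where(arr < lloq, 0.0, arr)
    return float(out) if np.isscalar(conc) else out


def fit_plate_curves(
    reads: pd.DataFrame,
    lloq: float = DEFAULT_LLOQ,
    qc_threshold: float = 0.999,
) -> dict[str, StandardCurve]:
    """Fit one standard curve per plate; plates without standards fall back
    to the study-wide pooled curve with a warning."""
    std = reads[reads["role"] == "standard"]
    if std.empty:
        raise CurveFitError("no standard reads present in dataset")
    conc_all = std["assay_id"].map(standard_level_of).to_numpy()
    curves: dict[str, StandardCurve] = {}
    pooled = fit_standard_curve(
        conc_all, std["fluorescence"], "pooled", lloq, qc_threshold
    )
    for plate in reads["plate_id"].unique():
        mask = (std["plate_id"] == plate).to_numpy()
        if mask.sum() >= 3:
            curves[plate] = fit_standard_curve(
                conc_all[mask],
                std["fluorescence"].to_numpy()[mask],
                plate,
                lloq,
                qc_threshold,
            )
        else:
            warnings.warn(
                f"plate {plate!r}: no standard series, using pooled curve"
            )
            curves[plate] = StandardCurve(
                plate, pooled.slope, pooled.intercept, pooled.r_squared, lloq,
                pooled.qc_pass,
            )
    return curves


def build_feature_matrix(
    reads: pd.DataFrame,
    donors: pd.DataFrame,
    curves: dict[str, StandardCurve] | None = None,
    lloq: float | None = None,
    qc_threshold: float = 0.999,
) -> pd.DataFrame:
    """One row per assay, one column per sensor_time feature (ng/ml).

    Duplicate wells of the same sensor x time within an assay are averaged on
    the concentration scale *before* LLOQ censoring (censor-then-average
    would bias near-LLOQ means downward). Columns are ordered sensor-major
    then time. Raises :class:`CompletenessError` naming every missing
    assay x feature cell.
    """
    sample = reads[reads["role"] == "sample"].copy()
    if sample.empty:
        raise ValueError("no sample reads present")
    if curves is None:
        curves = fit_plate_curves(reads, lloq or DEFAULT_LLOQ, qc_threshold)
    if lloq is None:
        lloq = next(iter(curves.values())).lloq

    slopes = sample["plate_id"].map({p: c.slope for p, c in curves.items()})
    intercepts = sample["plate_id"].map({p: c.intercept for p, c in curves.items()})
    if slopes.isna().any():
        missing = sorted(sample.loc[slopes.isna(), "plate_id"].unique())
        raise CurveFitError(f"no fitted curve for plates {missing}")
    if (slopes <= 0).any():
        bad = sorted(sample.loc[slopes <= 0, "plate_id"].unique())
        raise CurveFitError(f"non-positive slope for plates {bad}")
    sample["conc"] = np.maximum(
        (sample["fluorescence"] - intercepts) / slopes, 0.0
    )

    sample["feature"] = sample["sensor_id"] + "_" + sample["time_min"].astype(str)
    avg = (
        sample.groupby(["assay_id", "donor_id", "feature"], sort=False)["conc"]
        .mean()
        .reset_index()
    )
    avg["conc"] = apply_lloq(avg["conc"].to_numpy(), lloq)

    wide = avg.pivot(index=["assay_id", "donor_id"], columns="feature", values="conc")
    timepoints = sorted(sample["time_min"].unique())
    sensors = list(dict.fromkeys(sample["sensor_id"]))
    ordered = [
        feature_name(s, t)
        for s in sorted(sensors, key=list(sample["sensor_id"].unique()).index)
        for t in timepoints
    ]
    ordered = [f for f in ordered if f in wide.columns] + [
        f for f in wide.columns if f not in ordered
    ]
    wide = wide.reindex(columns=ordered)

    if wide.isna().any().any():
        gaps = [
            f"{assay}:{feat}"
            for (assay, _), row in wide.iterrows()
            for feat in wide.columns[row.isna()]
        ]
        raise CompletenessError(
            f"{len(gaps)} missing sensor x time reads: {gaps[:20]}"
            + ("..." if len(gaps) > 20 else "")
        )

    wide = wide.reset_index()
    wide.columns.name = None
    meta = donors.set_index("donor_id")
    wide.insert(
        2,
        "label",
        np.where(
            meta.loc[wide["donor_id"], "diagnosis"].to_numpy() == CANCER,
            LABEL_CANCER,
            LABEL_CONTROL,
        ),
    )
    for i, col in enumerate(["site", "sex", "age_band", "smoking", "stage", "histology"]):
        wide.insert(3 + i, col, meta.loc[wide["donor_id"], col].to_numpy())
    return wide


def feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in META_COLS]


def intra_assay_cv(features: pd.DataFrame) -> float:
    """Average intra-assay coefficient of variation over replicate assays, %.

    Per donor with >=2 replicate rows: CV = sample SD / mean for every
    feature whose replicate mean is positive, averaged over features; the
    result is the mean over donors, as a percent.
    """
    cols = feature_columns(features)
    groups = features.groupby("donor_id")
    donor_cvs = []
    for _, grp in groups:
        if len(grp) < 2:
            continue
        vals = grp[cols].to_numpy(dtype=float)
        means = vals.mean(axis=0)
        ok = means > 0
        if not ok.any():
            continue
        sds = vals[:, ok].std(axis=0, ddof=1)
        donor_cvs.append(float(np.mean(sds / means[ok])))
    if not donor_cvs:
        raise ValueError("no donors with replicate assays")
    return 100.0 * float(np.mean(donor_cvs))


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    features = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in META_COLS if c not in features.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    for c in feature_columns(features):
        features[c] = pd.to_numeric(features[c])
    return features
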