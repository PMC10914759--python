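"""Data splitting, final model selection, the voting ensemble, and
sensor relative-impact ranking.

Donors (never individual assays) are dealt into Training / Selection / Test
thirds stratified jointly on disease status, stage, site, sex, age band,
smoking and histology, so replicate assays of one donor can never straddle
subsets. Candidate programs surviving evolution are re-scored on the
Selection subset by ``accuracy x reliability`` (reliability penalises
train/selection inconsistency); the top programs form a vote-counting
ensemble whose positive-vote fraction is thresholded at five operating
points from specificity-maximising to sensitivity-maximising.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..panel import sensor_of_feature
from ..quantitation import META_COLS, LABEL_CANCER, feature_columns
from .palette import PALETTE_VERSION
from .program import Program, execute
from .evolution import EvolutionConfig, evolve, program_fitness

SUBSETS = ("Training", "Selection", "Test")

DEFAULT_STRATA = ["label", "stage", "site", "sex", "age_band", "smoking", "histology"]

#: vote-fraction thresholds; strictly decreasing from Spec Max to Sens Max
OPERATING_POINTS = {
    "spec_max": 0.7,
    "spec_bias": 0.6,
    "ensemble": 0.5,
    "sens_bias": 0.4,
    "sens_max": 0.3,
}


def split_data(
    features: pd.DataFrame,
    strata: list[str] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Assign each donor to Training / Selection / Test, stratified thirds.

    Donors are grouped by the joint stratum, shuffled within it, and dealt
    round-robin with a pointer that carries across strata, so subset sizes
    and per-stratum cell counts differ by at most one. Returns a Series
    mapping donor_id -> subset name. Strata smaller than 3 donors are dealt
    the same way (round-robin) with a warning.
    """
    strata = DEFAULT_STRATA if strata is None else strata
    missing = [c for c in strata if c not in features.columns]
    if missing:
        raise ValueError(f"strata columns missing from features: {missing}")
    donors = features.drop_duplicates("donor_id").set_index("donor_id")
    rng = np.random.default_rng(seed)

    keys = donors[strata].astype(str).agg("|".join, axis=1)
    assignment: dict[str, str] = {}
    pointer = 0
    small = 0
    for key in sorted(keys.unique()):
        ids = sorted(keys.index[keys == key])
        if len(ids) < 3:
            small += 1
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for d in ids:
            assignment[d] = SUBSETS[pointer % 3]
            pointer += 1
    if small:
        warnings.warn(
            f"{small} strata have fewer than 3 donors and were dealt round-robin"
        )
    out = pd.Series(assignment, name="subset")
    out.index.name = "donor_id"
    return out


def subset_rows(features: pd.DataFrame, split: pd.Series, subset: str) -> pd.DataFrame:
    mask = features["donor_id"].map(split) == subset
    return features[mask]


def assert_no_leakage(split: pd.Series) -> None:
    sets = {s: set(split.index[split == s]) for s in SUBSETS}
    for a in SUBSETS:
        for b in SUBSETS:
            if a < b and sets[a] & sets[b]:
                raise AssertionError(f"donor leakage between {a} and {b}")


@dataclass
class ScoredProgram:
    program: Program
    acc_train: float
    acc_select: float
    reliability: float
    score: float


def select_final(
    pool,
    X_select,
    y_select,
    X_train,
    y_train,
    fitness_kind: str = "balanced",
    deduplicate: bool = True,
) -> list[ScoredProgram]:
    """Rank the surviving pool on the Selection subset.

    accuracy = (sensitivity + specificity)/2 on Selection; reliability =
    1 - |train accuracy - selection accuracy|; score = accuracy x
    reliability, ranked descending. The top entry is "the single algorithm";
    a top slice forms the ensemble. Exact duplicate programs (common because
    parents persist across generations) are collapsed before ranking.
    """
    if not pool:
        raise ValueError("empty candidate pool")
    seen = set()
    scored = []
    for m in pool:
        if deduplicate:
            fp = m.program.fingerprint()
            if fp in seen:
                continue
            seen.add(fp)
        acc_sel = program_fitness(m.program, X_select, y_select, fitness_kind)
        acc_tr = (
            m.fitness
            if m.fitness is not None
            else program_fitness(m.program, X_train, y_train, fitness_kind)
        )
        rel = 1.0 - abs(acc_tr - acc_sel)
        scored.append(
            ScoredProgram(m.program, acc_tr, acc_sel, rel, acc_sel * rel)
        )
    scored.sort(key=lambda s: (-s.score, -s.acc_select, len(s.program)))
    return scored


class EnsembleModel:
    """A fitted voting ensemble with standardisation and operating points."""

    def __init__(
        self,
        members: list[ScoredProgram],
        feature_names: list[str],
        means: np.ndarray,
        stds: np.ndarray,
        thresholds: dict | None = None,
        split: pd.Series | None = None,
        seed: int | None = None,
        log_transform: bool = True,
    ):
        if not members:
            raise ValueError("ensemble needs at least one member")
        thresholds = dict(OPERATING_POINTS if thresholds is None else thresholds)
        tvals = list(thresholds.values())
        if any(nxt >= prev for nxt, prev in zip(tvals[1:], tvals)):
            raise ValueError("thresholds must strictly decrease Spec Max -> Sens Max")
        self.members = members
        self.feature_names = list(feature_names)
        self.means = np.asarray(means, dtype=float)
        self.stds = np.asarray(stds, dtype=float)
        self.thresholds = thresholds
        self.split = split
        self.seed = seed
        self.log_transform = log_transform

    # -- prediction -------------------------------------------------------
    def _standardise(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.log_transform:
            X = np.log1p(np.maximum(X, 0.0))
        return (X - self.means) / self.stds

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of member programs voting positive per row."""
        Z = self._standardise(X)
        votes = np.zeros(Z.shape[0])
        for sp in self.members:
            votes += execute(sp.program, Z) > 0
        return votes / len(self.members)

    def predict(self, X, operating_point: str = "ensemble") -> np.ndarray:
        if operating_point not in self.thresholds:
            raise KeyError(
                f"unknown operating point {operating_point!r}; "
                f"expected one of {list(self.thresholds)}"
            )
        return self.vote_fraction(X) >= self.thresholds[operating_point]

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "palette_version": PALETTE_VERSION,
            "log_transform": self.log_transform,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "thresholds": [[k, v] for k, v in self.thresholds.items()],
            "seed": self.seed,
            "split": None if self.split is None else self.split.to_dict(),
            "members": [
                {
                    "acc_train": sp.acc_train,
                    "acc_select": sp.acc_select,
                    "reliability": sp.reliability,
                    "score": sp.score,
                    "program": sp.program.to_dict(),
                }
                for sp in self.members
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "EnsembleModel":
        if data["palette_version"] != PALETTE_VERSION:
            raise ValueError(
                f"model palette version {data['palette_version']} != "
                f"runtime palette version {PALETTE_VERSION}"
            )
        members = [
            ScoredProgram(
                Program.from_dict(m["program"]),
                m["acc_train"],
                m["acc_select"],
                m["reliability"],
                m["score"],
            )
            for m in data["members"]
        ]
        split = None if data.get("split") is None else pd.Series(data["split"])
        thresholds = data["thresholds"]
        if not isinstance(thresholds, dict):  # stored as ordered pairs
            thresholds = dict(thresholds)
        return cls(
            members,
            data["feature_names"],
            np.asarray(data["means"]),
            np.asarray(data["stds"]),
            thresholds,
            split,
            data.get("seed"),
            data.get("log_transform", True),
        )

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ensemble_predict(model: EnsembleModel, X, operating_point: str = "ensemble"):
    """Class calls at one operating point (thin functional wrapper)."""
    return model.predict(X, operating_point)


def train_model(
    features: pd.DataFrame,
    cfg: EvolutionConfig | None = None,
    seed: int = 0,
    strata: list[str] | None = None,
    log_transform: bool = True,
) -> EnsembleModel:
    """Full chain: stratified split -> evolve on Training -> select on
    Selection -> ensemble of the top-scoring programs."""
    cfg = (cfg or EvolutionConfig()).validate()
    split = split_data(features, strata, seed)
    assert_no_leakage(split)
    cols = feature_columns(features)

    train = subset_rows(features, split, "Training")
    select = subset_rows(features, split, "Selection")
    X_train = train[cols].to_numpy(dtype=float)
    y_train = (train["label"] == LABEL_CANCER).to_numpy()
    X_select = select[cols].to_numpy(dtype=float)
    y_select = (select["label"] == LABEL_CANCER).to_numpy()

    # programs see z-scored log concentrations: the assay noise model is
    # multiplicative (shared donor effect, replicate CV), so log features
    # make nuisance variation additive and cancellable by differences
    if log_transform:
        X_train = np.log1p(np.maximum(X_train, 0.0))
        X_select = np.log1p(np.maximum(X_select, 0.0))
    means = X_train.mean(axis=0)
    stds = X_train.std(axis=0)
    stds[stds == 0] = 1.0
    Zt = (X_train - means) / stds
    Zs = (X_select - means) / stds

    pool = []
    for restart in range(max(1, cfg.n_restarts)):
        result = evolve(Zt, y_train, cfg, seed=seed + 1_000_003 * restart)
        pool.extend(result.pool)
    ranked = select_final(pool, Zs, y_select, Zt, y_train, cfg.fitness_kind)
    members = _distinct_members(ranked, Zs, cfg.ensemble_size)
    return EnsembleModel(
        members, cols, means, stds, split=split, seed=seed,
        log_transform=log_transform,
    )


def _distinct_members(ranked, Z_select, size: int):
    """Top-ranked programs with pairwise-distinct Selection-set call vectors.

    Evolution floods the pool with behavioural clones of the best program;
    voting over clones degenerates to the single top model, so members are
    taken in rank order but skipped when their calls duplicate an already
    chosen member's.
    """
    from .program import execute

    members, seen = [], set()
    for sp in ranked:
        key = (execute(sp.program, Z_select) > 0).tobytes()
        if key in seen:
            continue
        seen.add(key)
        members.append(sp)
        if len(members) == size:
            break
    return members if members else ranked[:1]


def relative_impact(
    model: EnsembleModel, features: pd.DataFrame, labels=None
) -> pd.DataFrame:
    """Per-sensor relative impact, normalised so the panel mean is 100%.

    Combines (i) the fraction of ensemble members referencing any feature of
    the sensor and (ii) the drop in ensemble balanced accuracy when the
    sensor's features are replaced by the training mean, each normalised to
    its panel average:  impact = 100 * (f/mean(f) + a/mean(a)) / 2.
    Sensors are binned at >200%, 100-200% and <100%.
    """
    from ..stats import balanced_accuracy

    cols = model.feature_names
    if labels is None:
        labels = features["label"] == LABEL_CANCER
    y = np.asarray(labels, dtype=bool)
    sensors = list(dict.fromkeys(sensor_of_feature(c) for c in cols))
    col_idx = {s: [i for i, c in enumerate(cols) if sensor_of_feature(c) == s]
               for s in sensors}

    Z = model._standardise(features)
    base_calls = np.zeros(Z.shape[0])
    for sp in model.members:
        base_calls += execute(sp.program, Z) > 0
    base = balanced_accuracy(y, base_calls / len(model.members) >= model.thresholds["ensemble"])

    usage = np.array(
        [
            np.mean(
                [
                    bool(sp.program.referenced_features() & set(col_idx[s]))
                    for sp in model.members
                ]
            )
            for s in sensors
        ]
    )
    drops = np.zeros(len(sensors))
    for k, s in enumerate(sensors):
        Za = Z.copy()
        Za[:, col_idx[s]] = 0.0  # training mean in standardised space
        votes = np.zeros(Za.shape[0])
        for sp in model.members:
            votes += execute(sp.program, Za) > 0
        acc = balanced_accuracy(y, votes / len(model.members) >= model.thresholds["ensemble"])
        drops[k] = max(0.0, base - acc)

    terms = []
    if usage.mean() > 0:
        terms.append(usage / usage.mean())
    if drops.mean() > 0:
        terms.append(drops / drops.mean())
    else:
        warnings.warn("all ablation drops are zero; impact uses selection term only")
    if not terms:
        raise ValueError("degenerate ensemble: no feature usage and no ablation signal")
    impact = 100.0 * np.mean(terms, axis=0)

    tier = np.where(impact > 200, ">200%", np.where(impact >= 100, "100-200%", "<100%"))
    return pd.DataFrame(
        {
            "sensor": sensors,
            "usage_fraction": usage,
            "ablation_drop": drops,
            "impact_pct": impact,
            "tier": tier,
        }
    )
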