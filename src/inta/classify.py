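"""Random-forest discrimination of EVs from large lipoproteins.

EVs and large LPs overlap in size but differ in effective refractive index
(vesicles ~1.37, lipoproteins ~1.45-1.57).  A random forest over the three
per-particle observables (diameter, scattering cross-section, RI) returns
P(EV); particles are labelled EV when P(EV) >= threshold, LP when
P(EV) <= 1 - threshold, and left unclassified in between.  The default
threshold is 0.80, at which the large majority of particles receive a
confident label.  Ties at the boundary go to the labelled side
(p_ev = 0.80 -> EV).

Features enter as (diameter, log10 sigma, ri); the log stabilizes the
decades-spanning cross-section for inspection tools (tree splits themselves
are scale-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import ClassifierConfig

__all__ = [
    "ClassifierModel",
    "train_classifier",
    "classify",
    "relative_ev_concentration",
    "misclassification_report",
]

FEATURES = ["diameter_nm", "sigma_nm2", "ri"]
EV_LABEL = "EV"
LP_LABEL = "LP"
UNCLASSIFIED = "unclassified"

_SIGMA_FLOOR = 1e-6  # nm^2, keeps log10 finite for sigma = 0 records


def _feature_matrix(records: pd.DataFrame) -> np.ndarray:
    missing = [f for f in FEATURES if f not in records.columns]
    if missing:
        raise ValueError(f"records are missing classifier features: {missing}")
    bad = records[FEATURES].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            "records with missing feature values: particle_ids "
            f"{records.loc[bad, 'particle_id'].tolist()[:10]}"
        )
    X = records[FEATURES].to_numpy(dtype=float).copy()
    X[:, 1] = np.log10(np.clip(X[:, 1], _SIGMA_FLOOR, None))
    return X


@dataclass
class ClassifierModel:
    """Trained forest plus threshold and training metadata."""

    forest: RandomForestClassifier
    confidence_threshold: float = 0.8
    training_meta: dict = field(default_factory=dict)

    @property
    def oob_accuracy(self) -> float:
        return float(self.forest.oob_score_)

    def p_ev(self, records: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(records)
        ev_col = list(self.forest.classes_).index(EV_LABEL)
        return self.forest.predict_proba(X)[:, ev_col]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a ClassifierModel")
        return model


def train_classifier(
    ev_records: pd.DataFrame,
    lp_records: pd.DataFrame,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train the EV/LP forest on labelled pure-sample record tables.

    Requires at least 100 records per class.  Uses class-balanced bootstrap
    so unequal pure-sample sizes do not bias P(EV); out-of-bag accuracy is
    stored as the training report.
    """
    config = config or ClassifierConfig()
    for name, rec in (("EV", ev_records), ("LP", lp_records)):
        if len(rec) < 100:
            raise ValueError(f"need >= 100 {name} records, got {len(rec)}")
    X = np.vstack([_feature_matrix(ev_records), _feature_matrix(lp_records)])
    y = np.array([EV_LABEL] * len(ev_records) + [LP_LABEL] * len(lp_records))
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        class_weight="balanced_subsample",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    meta = {
        "n_ev": int(len(ev_records)),
        "n_lp": int(len(lp_records)),
        "oob_accuracy": float(forest.oob_score_),
        "seed": int(seed),
        "features": ["diameter_nm", "log10_sigma_nm2", "ri"],
    }
    return ClassifierModel(forest, config.confidence_threshold, meta)


def classify(records: pd.DataFrame, model: ClassifierModel) -> pd.DataFrame:
    """Attach P(EV) and the three-way confidence-thresholded label.

    label = EV if p_ev >= t, LP if p_ev <= 1 - t, else unclassified.
    The returned frame carries ``fraction_classified`` in its attrs.
    """
    out = records.copy()
    p = model.p_ev(records)
    t = model.confidence_threshold
    # compare P(LP) >= t rather than p <= 1 - t: avoids the floating-point
    # asymmetry of 1 - t at the documented boundary (ties go to the label)
    label = np.where(
        p >= t, EV_LABEL, np.where(1.0 - p >= t, LP_LABEL, UNCLASSIFIED)
    )
    out["p_ev"] = p
    out["label"] = label
    out.attrs["fraction_classified"] = (
        float(np.mean(label != UNCLASSIFIED)) if len(out) else float("nan")
    )
    return out


def relative_ev_concentration(classified: pd.DataFrame) -> float:
    """Count-based relative EV concentration n_EV / (n_EV + n_LP).

    Unclassified records are excluded.  With per-count calibration factors
    identical for both classes this equals C_EV / (C_EV + C_LP).
    """
    n_ev = int((classified["label"] == EV_LABEL).sum())
    n_lp = int((classified["label"] == LP_LABEL).sum())
    if n_ev + n_lp == 0:
        raise ValueError("no confidently classified records; ratio undefined")
    return n_ev / (n_ev + n_lp)


def expected_relative_concentration(
    mix_fraction: float, kept_rate_ev: float, kept_rate_lp: float
) -> float:
    """Expected measured EV fraction for a nominal mixing fraction.

    Mirrors how expectations are formed from measurements of the pure
    samples: a mixture combining EV and LP number fractions ``f`` and
    ``1 - f`` yields kept-trajectory counts proportional to ``f * k_EV``
    and ``(1 - f) * k_LP``, where the ``k`` are the pure samples' kept
    (filter-passing) trajectory rates, so the expected measured fraction is
    ``f k_EV / (f k_EV + (1 - f) k_LP)``.
    """
    if not 0 <= mix_fraction <= 1:
        raise ValueError("mix_fraction must lie in [0, 1]")
    num = mix_fraction * kept_rate_ev
    den = num + (1.0 - mix_fraction) * kept_rate_lp
    return num / den if den > 0 else float("nan")


def misclassification_report(pure_samples: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """False-label rates on pure samples with ground truth.

    ``pure_samples`` maps the true class ("EV" or "LP") to a classified
    record table.  Rates are computed among confidently classified records;
    the unclassified fraction is reported alongside.
    """
    rows = []
    for true_label, sample in pure_samples.items():
        if true_label not in (EV_LABEL, LP_LABEL):
            raise ValueError(f"true label must be EV or LP, got {true_label!r}")
        labels = sample["label"]
        n_classified = int((labels != UNCLASSIFIED).sum())
        wrong = EV_LABEL if true_label == LP_LABEL else LP_LABEL
        n_wrong = int((labels == wrong).sum())
        rows.append(
            {
                "true_class": true_label,
                "n_records": len(sample),
                "n_classified": n_classified,
                "mislabel_rate": n_wrong / n_classified if n_classified else np.nan,
                "unclassified_fraction": 1 - n_classified / len(sample)
                if len(sample)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
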