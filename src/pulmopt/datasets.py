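"""Synthetic cohort and planted-feature generators.

:func:`generate_cohort` emulates the structure of a small tabular
respiratory cohort of the Exasens kind: four diagnosis groups (asthma,
COPD, infected, healthy), four saliva-permittivity-style numeric
features whose class means are separated by a configurable effect size
(in units of the within-class standard deviation), categorical
demographics, and numeric cells missing completely at random.  All
distributional parameters are synthetic inventions; they are recorded in
the table's metadata so downstream tests are self-describing.

:func:`generate_separable` builds plain feature matrices with a known
set of informative columns, used as ground truth for feature-selection
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .optim.core import as_generator

__all__ = ["CohortSpec", "generate_cohort", "generate_separable", "save_cohort"]

#: Fixed diagnosis order used everywhere (labels, one-vs-rest reports).
DIAGNOSES = ("asthma", "copd", "infected", "healthy")

#: Saliva-permittivity-style numeric feature columns.
NUMERIC_FEATURES = ("im_min", "im_avg", "re_min", "re_avg")

GENDERS = ("M", "F")
SMOKING = ("non", "ex", "active")

_GENDER_P = (0.5, 0.5)
_SMOKING_P = (0.4, 0.3, 0.3)


@dataclass
class CohortSpec:
    """Generation settings for a synthetic cohort.

    ``effect_size`` separates the class means of the numeric features in
    units of the (unit) within-class standard deviation: diagnosis group
    ``c`` has mean ``effect_size`` on numeric feature ``c`` and 0 on the
    others, so groups are pairwise separated by ``effect_size * sqrt(2)``.
    """

    n: int = 400
    class_weights: dict[str, float] = field(
        default_factory=lambda: {d: 0.25 for d in DIAGNOSES}
    )
    effect_size: float = 3.0
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("configuration error: n must be >= 1")
        if set(self.class_weights) != set(DIAGNOSES):
            raise ValueError(
                f"configuration error: class_weights must cover {DIAGNOSES}"
            )
        w = np.array([self.class_weights[d] for d in DIAGNOSES], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                "configuration error: class weights must be non-negative and sum to 1"
            )
        if self.effect_size < 0:
            raise ValueError("configuration error: effect_size must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("configuration error: missing_rate must lie in [0, 1)")

    def class_means(self) -> dict[str, list[float]]:
        means = {}
        for c, diag in enumerate(DIAGNOSES):
            mu = [0.0] * len(NUMERIC_FEATURES)
            mu[c] = float(self.effect_size)
            means[diag] = mu
        return means


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns: patient_id, diagnosis, age, gender, smoking, then the four
    numeric features.  Each numeric cell is independently blanked (NaN)
    with probability ``spec.missing_rate``.  Generation metadata
    (including the class means actually used) is attached under
    ``df.attrs["generation"]``.
    """
    rng = as_generator(spec.seed)
    weights = np.array([spec.class_weights[d] for d in DIAGNOSES])
    diag_idx = rng.choice(len(DIAGNOSES), size=spec.n, p=weights)
    means = spec.class_means()

    numeric = rng.normal(size=(spec.n, len(NUMERIC_FEATURES)))
    mean_matrix = np.array([means[DIAGNOSES[c]] for c in diag_idx])
    numeric = numeric + mean_matrix

    if spec.missing_rate > 0:
        blank = rng.random(numeric.shape) < spec.missing_rate
        numeric[blank] = np.nan

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(spec.n)],
            "diagnosis": [DIAGNOSES[c] for c in diag_idx],
            "age": rng.integers(20, 81, size=spec.n),
            "gender": rng.choice(GENDERS, size=spec.n, p=_GENDER_P),
            "smoking": rng.choice(SMOKING, size=spec.n, p=_SMOKING_P),
        }
    )
    for k, name in enumerate(NUMERIC_FEATURES):
        df[name] = numeric[:, k]

    df.attrs["generation"] = {
        "n": spec.n,
        "class_weights": dict(spec.class_weights),
        "effect_size": spec.effect_size,
        "missing_rate": spec.missing_rate,
        "seed": spec.seed,
        "class_means": means,
        "gender_p": list(_GENDER_P),
        "smoking_p": list(_SMOKING_P),
        "age_range": [20, 80],
    }
    return df


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort CSV plus a sidecar ``.meta.json`` with the
    generation metadata (when present)."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = df.attrs.get("generation")
    if meta is not None:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, default=str))


def generate_separable(
    n: int,
    d: int,
    d_informative: int,
    n_classes: int = 4,
    separation: float = 4.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Feature matrix with a planted informative column subset.

    Informative column ``i`` carries a mean shift of ``separation``
    (in sd units) for class ``i mod n_classes``; all other columns are
    pure standard-normal noise.  Returns ``(X, y, informative_indices)``.
    """
    if d_informative > d:
        raise ValueError("configuration error: d_informative must be <= d")
    if n < 10 * n_classes:
        raise ValueError("configuration error: need n >= 10 * n_classes")
    rng = as_generator(seed)
    y = rng.integers(n_classes, size=n)
    X = rng.normal(size=(n, d))
    for i in range(d_informative):
        X[y == (i % n_classes), i] += separation
    return X, y, set(range(d_informative))
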