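"""Stage 1 screening: standardized Euclidean distances and ROC/AUC.

Candidate attribute scenarios combine image bands and pretreated NIR spectra:

========  =======================================================
Scenario  Attributes
========  =======================================================
RGB       per-image mean R, G, B band intensities (3 features)
R         mean R band only (1 feature)
NIR       pretreated absorbances, one feature per wavelength
RGB+NIR   concatenation (3 + n_wavelengths features)
R+NIR     concatenation (1 + n_wavelengths features)
========  =======================================================

All features are standardized (mean 0, sd 1, n−1 denominator) over the full
sample table before distances are computed.  Discrimination of same-individual
pairs (class C1) from the rest is scored by the ROC built on the rule
"smaller distance ⇒ same individual"; the AUC equals the Mann–Whitney
probability P(D_C1 < D_other) + ½·P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .design import PairClass, PairRecord

__all__ = [
    "ScreeningError",
    "Scenario",
    "RocResult",
    "standardize_columns",
    "euclidean_distance",
    "scenario_features",
    "compute_pair_distances",
    "roc_auc",
]

_SCENARIO_KINDS = ("RGB", "R", "NIR", "RGB+NIR", "R+NIR")


class ScreeningError(ValueError):
    """Invalid feature table, scenario, or ROC input."""


@dataclass(frozen=True)
class Scenario:
    """One Table-of-scenarios entry: which attributes enter the distance."""

    kind: str
    pipeline: str | None = None  # pretreatment signature for the NIR part

    def __post_init__(self) -> None:
        if self.kind not in _SCENARIO_KINDS:
            raise ScreeningError(
                f"unknown scenario {self.kind!r}; expected one of {_SCENARIO_KINDS}"
            )
        if "NIR" in self.kind and self.pipeline is None:
            raise ScreeningError(f"scenario {self.kind} requires a pipeline signature")

    def label(self) -> str:
        if "NIR" in self.kind:
            return f"{self.kind}[{self.pipeline}]"
        return self.kind


def standardize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to mean 0, sd 1 (sd with n−1 denominator)."""
    if table.shape[0] < 2:
        raise ScreeningError("standardization needs at least 2 samples")
    sd = table.std(axis=0, ddof=1)
    dead = sd[sd == 0.0].index.tolist()
    if dead:
        raise ScreeningError(f"zero-variance column(s): {dead[:5]}")
    out = (table - table.mean(axis=0)) / sd
    out.attrs["standardized"] = True
    return out


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ScreeningError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def scenario_features(
    rgb: pd.DataFrame | None,
    nir: pd.DataFrame | None,
    scenario: Scenario,
) -> pd.DataFrame:
    """Assemble and standardize the feature table for one scenario.

    ``rgb`` has columns R, G, B (sample ids as index); ``nir`` is the
    pretreated spectra matrix.  Sample ids must agree where both are used.
    """
    parts: list[pd.DataFrame] = []
    if "RGB" in scenario.kind.split("+") or scenario.kind == "RGB":
        _need(rgb, "RGB")
        parts.append(rgb[["R", "G", "B"]])
    elif scenario.kind.startswith("R"):
        _need(rgb, "R")
        parts.append(rgb[["R"]])
    if "NIR" in scenario.kind:
        _need(nir, "NIR")
        parts.append(nir)
    if len(parts) == 2:
        a, b = parts
        if not a.index.equals(b.index):
            if set(a.index) != set(b.index):
                raise ScreeningError("RGB and NIR tables cover different samples")
            b = b.loc[a.index]
        parts = [a, b]
    table = pd.concat(parts, axis=1)
    table.columns = [str(c) for c in table.columns]
    return standardize_columns(table)


def _need(part: pd.DataFrame | None, name: str) -> None:
    if part is None:
        raise ScreeningError(f"scenario requires the {name} feature table")


def compute_pair_distances(
    features: pd.DataFrame,
    pairs: Sequence[PairRecord],
    scenario: Scenario | None = None,
) -> pd.DataFrame:
    """Euclidean distance for every pair; columns sample_a, sample_b,
    pair_class, scenario, distance."""
    if not features.attrs.get("standardized"):
        raise ScreeningError("features must be standardized first")
    ids = set(features.index)
    for p in pairs:
        for s in (p.sample_a, p.sample_b):
            if s.sample_id not in ids:
                raise ScreeningError(f"unknown sample id {s.sample_id!r}")
    x = features.to_numpy(dtype=float)
    pos = {sid: i for i, sid in enumerate(features.index)}
    ia = np.array([pos[p.sample_a.sample_id] for p in pairs])
    ib = np.array([pos[p.sample_b.sample_id] for p in pairs])
    d = np.linalg.norm(x[ia] - x[ib], axis=1)
    return pd.DataFrame(
        {
            "sample_a": [p.sample_a.sample_id for p in pairs],
            "sample_b": [p.sample_b.sample_id for p in pairs],
            "pair_class": [p.pair_class.value for p in pairs],
            "scenario": scenario.label() if scenario else "",
            "distance": d,
        }
    )


@dataclass(frozen=True)
class RocResult:
    """ROC curve and area for "low distance ⇒ positive" classification."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(
    distances: pd.DataFrame,
    positive: str | PairClass = PairClass.C1,
    versus: str = "rest",
) -> RocResult:
    """ROC/AUC for discriminating the positive class by small distances.

    ``versus="rest"`` contrasts C1 with C2∪C3 (the default); ``versus="C2"``
    restricts the negatives to same-family different-individual pairs.  Ties
    are handled by midranks, so the AUC is the Mann–Whitney statistic
    U / (n₊·n₋).
    """
    positive = PairClass(positive)
    cls = distances["pair_class"].astype(str)
    d = distances["distance"].to_numpy(dtype=float)
    pos = d[(cls == positive.value).to_numpy()]
    if versus == "rest":
        neg = d[(cls != positive.value).to_numpy()]
    else:
        neg = d[(cls == PairClass(versus).value).to_numpy()]
    if len(pos) == 0 or len(neg) == 0:
        raise ScreeningError("need at least one pair in each class for ROC")
    # AUC = P(d_pos < d_neg) + 0.5 P(tie): Mann-Whitney U of neg over pos.
    u = mannwhitneyu(neg, pos, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))
    thresholds = np.concatenate(([-np.inf], np.unique(np.concatenate([pos, neg]))))
    tpr = (pos[None, :] <= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
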