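"""DMR-based sperm age predictor.

Workflow: Spearman-correlate each panel region's donor-wise mean
methylation with age, keep the regions most significantly associated
(p < 0.001, at most six), fit ordinary least squares of chronological age
on the selected methylation levels, and evaluate by leave-one-out
cross-validation (and, optionally, on an independent cohort).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .agestats import spearman
from .core import DonorRecord
from .simulate import DbsMeasurement

__all__ = [
    "RegionAgeCorrelation",
    "ClockModel",
    "ClockEvaluation",
    "correlate_regions_with_age",
    "select_clock_regions",
    "fit_clock",
    "loocv_evaluate",
    "predict_ages",
]


@dataclass(frozen=True)
class RegionAgeCorrelation:
    region_id: str
    rho: float
    p_value: float
    n: int
    undefined: bool = False


@dataclass(frozen=True)
class ClockModel:
    """Linear age predictor: age = intercept + sum(coef * mean_meth)."""

    region_ids: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]  # years per methylation fraction
    training_n: int

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.coefficients):
            raise ValueError("one coefficient per region required")

    def to_dict(self) -> dict:
        return {
            "region_ids": list(self.region_ids),
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "training_n": self.training_n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClockModel":
        return cls(
            region_ids=tuple(d["region_ids"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            training_n=int(d["training_n"]),
        )


@dataclass(frozen=True)
class ClockEvaluation:
    donor_ids: tuple[str, ...]
    predicted: tuple[float, ...]
    actual: Optional[tuple[float, ...]] = None
    mae: Optional[float] = None  # mean absolute error, years
    pearson_r: Optional[float] = None


def _meth_matrix(
    region_ids: Sequence[str],
    measurements: Sequence[DbsMeasurement],
    donor_ids: Sequence[str],
) -> np.ndarray:
    """Donor x region matrix of mean methylation; missing cells are errors."""
    lut = {(m.donor_id, m.region_id): m.mean_meth for m in measurements}
    X = np.empty((len(donor_ids), len(region_ids)))
    missing = []
    for i, did in enumerate(donor_ids):
        for j, rid in enumerate(region_ids):
            v = lut.get((did, rid))
            if v is None:
                missing.append((did, rid))
            else:
                X[i, j] = v
    if missing:
        raise ValueError(f"missing measurements for (donor, region): {missing[:10]}")
    return X


def correlate_regions_with_age(
    measurements: Sequence[DbsMeasurement],
    donors: Sequence[DonorRecord],
) -> list[RegionAgeCorrelation]:
    """Spearman correlation of each region's methylation with donor age.

    Regions measured in fewer than 4 donors are excluded with a warning;
    zero-variance methylation flags the region's rho as undefined.
    """
    ages = {d.donor_id: d.age for d in donors}
    per_region: dict[str, list[tuple[float, float]]] = {}
    for m in measurements:
        if m.donor_id in ages:
            per_region.setdefault(m.region_id, []).append(
                (ages[m.donor_id], m.mean_meth)
            )
    out = []
    for region_id in sorted(per_region):
        pairs = per_region[region_id]
        if len(pairs) < 4:
            warnings.warn(
                f"region {region_id}: only {len(pairs)} donors; excluded"
            )
            continue
        a, v = map(np.asarray, zip(*pairs))
        res = spearman(a, v, method="t")  # t approximation, as in the study
        out.append(
            RegionAgeCorrelation(
                region_id, res.rho, res.p_value, res.n, undefined=res.undefined
            )
        )
    return out


def select_clock_regions(
    correlations: Sequence[RegionAgeCorrelation],
    alpha: float = 0.001,
    k: int = 6,
) -> list[str]:
    """Pick the clock regions: p < alpha, at most the k smallest p-values.

    Ties in p are broken by larger |rho|, then region id. Raises when no
    region passes, suggesting a more permissive alpha.
    """
    if not correlations:
        raise ValueError("empty correlation list")
    passing = [c for c in correlations if not c.undefined and c.p_value < alpha]
    if not passing:
        raise ValueError(
            f"no region reaches p < {alpha}; consider relaxing the threshold"
        )
    passing.sort(key=lambda c: (c.p_value, -abs(c.rho), c.region_id))
    return [c.region_id for c in passing[:k]]


def _check_design(X1: np.ndarray, region_ids: Sequence[str]) -> None:
    """Raise on singular designs, naming constant or duplicated regions."""
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        offenders = []
        X = X1[:, 1:]
        for j, rid in enumerate(region_ids):
            if np.allclose(X[:, j], X[0, j]):
                offenders.append(f"{rid} (constant)")
        for j in range(len(region_ids)):
            for k2 in range(j + 1, len(region_ids)):
                if np.allclose(X[:, j], X[:, k2]):
                    offenders.append(f"{region_ids[j]} == {region_ids[k2]}")
        detail = f": {offenders}" if offenders else ""
        raise np.linalg.LinAlgError(f"singular clock design{detail}")


def fit_clock(
    region_ids: Sequence[str],
    measurements: Sequence[DbsMeasurement],
    donors: Sequence[DonorRecord],
) -> ClockModel:
    """Ordinary least squares of chronological age on region methylation.

    No regularization: with k regions much smaller than the cohort, a
    singular design signals a real data problem (constant or duplicated
    regions) and raises rather than being silently repaired.
    """
    region_ids = list(region_ids)
    donor_ids = [d.donor_id for d in donors]
    if len(donors) <= len(region_ids) + 1:
        raise ValueError("need training_n > number of regions + 1")
    X = _meth_matrix(region_ids, measurements, donor_ids)
    y = np.array([d.age for d in donors], dtype=float)
    X1 = np.column_stack([np.ones(len(donor_ids)), X])
    _check_design(X1, region_ids)
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return ClockModel(
        region_ids=tuple(region_ids),
        intercept=float(coef[0]),
        coefficients=tuple(float(c) for c in coef[1:]),
        training_n=len(donors),
    )


def predict_ages(
    model: ClockModel,
    measurements: Sequence[DbsMeasurement],
    donors: Optional[Sequence[DonorRecord]] = None,
    donor_ids: Optional[Sequence[str]] = None,
) -> ClockEvaluation:
    """Apply a fitted clock to new donors.

    Predictions are not clamped to the study age range: extrapolation is
    left visible. When donor records (with ages) are supplied, MAE and the
    Pearson correlation between predicted and chronological age are
    reported.
    """
    if donors is not None:
        donor_ids = [d.donor_id for d in donors]
    elif donor_ids is None:
        donor_ids = sorted({m.donor_id for m in measurements})
    X = _meth_matrix(model.region_ids, measurements, donor_ids)
    pred = model.intercept + X @ np.asarray(model.coefficients)
    if donors is None:
        return ClockEvaluation(tuple(donor_ids), tuple(map(float, pred)))
    actual = np.array([d.age for d in donors], dtype=float)
    mae = float(np.mean(np.abs(pred - actual)))
    r = float(stats.pearsonr(pred, actual).statistic) if len(donors) > 2 else None
    return ClockEvaluation(
        tuple(donor_ids),
        tuple(map(float, pred)),
        tuple(map(float, actual)),
        mae,
        r,
    )


def loocv_evaluate(
    region_ids: Sequence[str],
    measurements: Sequence[DbsMeasurement],
    donors: Sequence[DonorRecord],
) -> ClockEvaluation:
    """Leave-one-out cross-validation of the clock.

    Each donor's age is predicted by a model fitted on everyone else.
    Reports the per-donor predictions, the mean absolute error in years
    and the Pearson correlation between predicted and chronological ages.
    """
    region_ids = list(region_ids)
    if len(donors) <= len(region_ids) + 2:
        raise ValueError("need training_n > number of regions + 2")
    donor_ids = [d.donor_id for d in donors]
    X = _meth_matrix(region_ids, measurements, donor_ids)
    y = np.array([d.age for d in donors], dtype=float)
    n = len(donors)
    pred = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        X1 = np.column_stack([np.ones(n - 1), X[keep]])
        try:
            _check_design(X1, region_ids)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"fold leaving out {donor_ids[i]}: {exc}"
            ) from None
        coef, *_ = np.linalg.lstsq(X1, y[keep], rcond=None)
        pred[i] = coef[0] + X[i] @ coef[1:]
    mae = float(np.mean(np.abs(pred - y)))
    r = float(stats.pearsonr(pred, y).statistic)
    return ClockEvaluation(
        tuple(donor_ids),
        tuple(map(float, pred)),
        tuple(map(float, y)),
        mae,
        r,
    )
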