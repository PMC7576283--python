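"""Clinical and molecular ageing statistics.

Spearman rank correlations with age (the study's summary statistic for
clinical parameters and DFI), partial rank correlations for confounder
checks, per-age-group mean/SD summaries, qPCR relative telomere length,
OLS linear trends, and the DFI pathology-rate computation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import DonorRecord, age_group_for

__all__ = [
    "SpearmanResult",
    "TrendFit",
    "GroupSummary",
    "spearman",
    "spearman_with_age",
    "partial_spearman",
    "group_summaries",
    "relative_telomere_length",
    "fit_linear_trend",
    "dfi_pathological_fraction",
]

# Exact permutation p-values are enumerated up to this sample size (8! =
# 40320 permutations); beyond it the t approximation is used.
EXACT_PERMUTATION_MAX_N = 8


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    undefined: bool = False  # zero-variance input: rho has no meaning


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupSummary:
    group: int
    n: int
    mean: float
    sd: float  # NaN when n == 1


def _t_approx_p(rho: float, n: int, df: Optional[int] = None) -> float:
    """Two-sided p for Spearman rho via t = rho*sqrt((n-2)/(1-rho^2))."""
    df = n - 2 if df is None else df
    if df < 1:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df))


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return float("nan")
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling.

    p-value: exact enumeration of all n! permutations for n <= 8
    (``method='auto'`` or ``'exact'``), otherwise the two-sided t
    approximation. Zero variance in either variable flags the result as
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    rho = _rank_rho(x, y)
    if math.isnan(rho):
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    exact = method == "exact" or (method == "auto" and n <= EXACT_PERMUTATION_MAX_N)
    if exact and n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(x, y, rho)
    else:
        p = _t_approx_p(rho, n)
    return SpearmanResult(rho, p, n)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(x.size)):
        r = _rank_rho(x, ry[list(perm)])
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def _paired(
    values: Union[Mapping[str, float], Sequence[float]],
    donors: Sequence[DonorRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Align a value vector (or donor_id map) with donor ages, dropping
    missing pairs."""
    if isinstance(values, Mapping):
        pairs = [
            (donor.age, values[donor.donor_id])
            for donor in donors
            if donor.donor_id in values and values[donor.donor_id] is not None
        ]
    else:
        if len(values) != len(donors):
            raise ValueError("values and donors length mismatch")
        pairs = [
            (donor.age, v) for donor, v in zip(donors, values) if v is not None
        ]
    pairs = [(a, v) for a, v in pairs if not math.isnan(v)]
    if not pairs:
        return np.empty(0), np.empty(0)
    ages, vals = map(np.asarray, zip(*pairs))
    return ages.astype(float), vals.astype(float)


def spearman_with_age(
    values: Union[Mapping[str, float], Sequence[float]],
    donors: Sequence[DonorRecord],
    method: str = "auto",
) -> SpearmanResult:
    """Spearman correlation of a per-donor value with chronological age."""
    ages, vals = _paired(values, donors)
    if ages.size < 4:
        raise ValueError(f"need at least 4 paired observations, got {ages.size}")
    return spearman(ages, vals, method=method)


def partial_spearman(
    values: Union[Mapping[str, float], Sequence[float]],
    confounders: Mapping[str, Union[Mapping[str, float], Sequence[float]]],
    donors: Sequence[DonorRecord],
) -> SpearmanResult:
    """Partial Spearman correlation with age, adjusted for confounders.

    All variables are rank-transformed; value ranks and age ranks are
    residualized on the confounder ranks by least squares (with intercept)
    and the residuals are correlated. Constant confounders are dropped with
    a warning. With no confounders this reduces to ``spearman_with_age``.
    """
    ages, vals = _paired(values, donors)
    n = ages.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    conf_cols = []
    if isinstance(values, Mapping):
        kept_ids = [
            d.donor_id
            for d in donors
            if d.donor_id in values
            and values[d.donor_id] is not None
            and not math.isnan(values[d.donor_id])
        ]
    else:
        kept_ids = [
            d.donor_id
            for d, v in zip(donors, values)
            if v is not None and not math.isnan(v)
        ]
    for name, cvals in confounders.items():
        if isinstance(cvals, Mapping):
            col = np.array([float(cvals[i]) for i in kept_ids])
        else:
            if len(cvals) != len(donors):
                raise ValueError(f"confounder {name!r} length mismatch")
            keep = set(kept_ids)
            col = np.array(
                [float(v) for d, v in zip(donors, cvals) if d.donor_id in keep]
            )
        if np.all(col == col[0]):
            warnings.warn(f"constant confounder {name!r} dropped")
            continue
        conf_cols.append(stats.rankdata(col))
    if not conf_cols:
        return spearman(ages, vals)
    ra = stats.rankdata(ages)
    rv = stats.rankdata(vals)
    design = np.column_stack([np.ones(n)] + conf_cols)
    res_a = ra - design @ np.linalg.lstsq(design, ra, rcond=None)[0]
    res_v = rv - design @ np.linalg.lstsq(design, rv, rcond=None)[0]
    da = res_a - res_a.mean()
    dv = res_v - res_v.mean()
    denom = math.sqrt(float(da @ da) * float(dv @ dv))
    if denom == 0.0:
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    rho = float(da @ dv) / denom
    return SpearmanResult(rho, _t_approx_p(rho, n, df=n - 2 - len(conf_cols)), n)


def group_summaries(
    donors: Sequence[DonorRecord], parameter: str
) -> list[GroupSummary]:
    """Per-age-group sample mean and SD (n-1 denominator) of one parameter.

    ``parameter`` may be a clinical key or one of the direct attributes
    (age, dfi_percent, rtl_blood, rtl_sperm). Empty groups are omitted with
    a warning; single-donor groups report SD as NaN.
    """
    per_group: dict[int, list[float]] = {}
    for d in donors:
        if parameter in d.clinical:
            v = d.clinical[parameter]
        else:
            v = getattr(d, parameter, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        per_group.setdefault(d.age_group, []).append(float(v))
    out = []
    for g in range(1, 7):
        vals = per_group.get(g)
        if not vals:
            warnings.warn(f"group {g}: no donors with {parameter!r}; omitted")
            continue
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        out.append(GroupSummary(g, arr.size, float(arr.mean()), sd))
    return out


def relative_telomere_length(
    ct_telomere, ct_reference, calibrator_delta: float = 0.0
):
    """qPCR relative telomere length by the 2^-ddCt method.

    rTL = 2^-((Ct_telomere - Ct_reference) - calibrator_delta): the
    telomere-to-single-copy-gene ratio normalized to a calibrator sample.
    Accepts scalars or arrays; Ct values must be finite and positive.
    """
    ct_t = np.asarray(ct_telomere, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise ValueError("non-finite Ct value")
    if np.any(ct_t <= 0) or np.any(ct_r <= 0):
        raise ValueError("Ct values must be positive")
    rtl = 2.0 ** -((ct_t - ct_r) - calibrator_delta)
    return float(rtl) if rtl.ndim == 0 else rtl


def fit_linear_trend(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS linear trend of y on x with Pearson r and its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("zero variance in x: trend undefined")
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def dfi_pathological_fraction(
    donors: Sequence[DonorRecord], threshold: float = 25.0
) -> dict[Union[int, str], float]:
    """Fraction of donors per age group with DFI strictly above threshold.

    The 25% clinical cut-off marks the maximum normal DNA fragmentation;
    values above it (strict inequality) are pathological. Returns one
    fraction per non-empty group plus an 'overall' entry.
    """
    per_group: dict[int, list[bool]] = {}
    flags_all = []
    for d in donors:
        if d.dfi_percent is None:
            continue
        flag = d.dfi_percent > threshold
        per_group.setdefault(d.age_group, []).append(flag)
        flags_all.append(flag)
    out: dict[Union[int, str], float] = {
        g: float(np.mean(v)) for g, v in sorted(per_group.items())
    }
    if flags_all:
        out["overall"] = float(np.mean(flags_all))
    return out
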