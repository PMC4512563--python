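"""Observer-concordance statistics: LCM, Kendall's tau-b, bootstrap CIs.

The localization concordance measure (LCM) compares two field-of-
quantification selections on the same slide:

    LCM = Σ_i w_i · sigm( min_j dist((x_j, y_j), (x_i, y_i)) / (4·FOV_size) )

where i runs over the reference (expert) fields, j over the test fields,
``sigm(x) = 2/(1+e^(−x)) − 1`` (0 at 0, saturating to 1), and the weights
``w_i = L_E,i / mean(L_E)`` emphasize reference fields with a high Ki-67
index while averaging to 1. Identical selections give LCM = 0; selections
from different slide areas give an LCM near the number of reference fields.

Rank agreement between per-slide Ki-67 scores of two methods uses Kendall's
tau-b (tie-corrected, in [−1, 1]) with percentile bootstrap confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Marker for agreement values that cannot be computed (constant variable,
#: too few shared slides).
NOT_COMPUTABLE = float("nan")


@dataclass
class ObserverFieldSet:
    """One observer's fields on one slide: (row, col, ki67_pct) triples.

    Centers are in working-resolution pixels.
    """

    fields: list[tuple[float, float, float]]
    observer_id: str = ""
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("field set must contain at least one field")
        for _, _, k in self.fields:
            if not 0 <= k <= 100:
                raise ValueError(f"ki67_pct {k} outside [0, 100]")

    def centers(self) -> np.ndarray:
        return np.array([(r, c) for r, c, _ in self.fields], dtype=float)

    def levels(self) -> np.ndarray:
        return np.array([k for _, _, k in self.fields], dtype=float)


@dataclass(frozen=True)
class LCMParams:
    """FOV width in working pixels; distances scale by 4·fov_size."""

    fov_size: float

    def __post_init__(self) -> None:
        if self.fov_size <= 0:
            raise ValueError("fov_size must be positive")


def sigm(x: np.ndarray) -> np.ndarray:
    """Scaled logistic 2/(1+e^(−x)) − 1: 0 at 0, →1 as x→∞, monotone."""
    return 2.0 / (1.0 + np.exp(-np.asarray(x, dtype=float))) - 1.0


def lcm(reference: ObserverFieldSet, test: ObserverFieldSet,
        params: LCMParams) -> float:
    """Localization concordance measure between two field sets (low = alike).

    Weights are the reference Ki-67 levels normalized by their mean; if all
    reference levels are zero, uniform weights are used.
    """
    ref_c = reference.centers()
    test_c = test.centers()
    d = np.hypot(ref_c[:, None, 0] - test_c[None, :, 0],
                 ref_c[:, None, 1] - test_c[None, :, 1]).min(axis=1)
    levels = reference.levels()
    mean_level = levels.mean()
    w = levels / mean_level if mean_level > 0 else np.ones_like(levels)
    return float((w * sigm(d / (4.0 * params.fov_size))).sum())


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b rank correlation with the standard tie correction.

    Returns NaN (not computable) when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return NOT_COMPUTABLE
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def bootstrap_ci(x, y, B: int = 100, level: float = 0.95,
                 seed: "int | np.random.Generator" = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for tau-b over paired resamples.

    Pairs are resampled with replacement ``B`` times; resamples where either
    variable comes out constant (tau undefined) are skipped. Deterministic
    under a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three pairs for a bootstrap interval")
    rng = np.random.default_rng(seed)
    taus = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            continue
        taus.append(kendall_tau_b(x[idx], y[idx]))
    if not taus:
        return NOT_COMPUTABLE, NOT_COMPUTABLE
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(taus, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class AgreementTable:
    """Pairwise tau-b (+CI) between scoring methods, optionally per grade."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def agreement_table(scores: pd.DataFrame, grouping: "pd.Series | dict | None" = None,
                    B: int = 100, level: float = 0.95, seed: int = 0
                    ) -> AgreementTable:
    """All pairwise tau-b with bootstrap CIs between scoring methods.

    ``scores`` is a wide table: index = slide ids, one column per method
    (per-slide Ki-67 percentages; NaN = missing). ``grouping`` optionally
    maps slide id → grade label, adding one row block per grade. Pairs with
    fewer than 3 shared slides are marked not computable (NaN).
    """
    scores = pd.DataFrame(scores)
    if scores.shape[1] < 2:
        raise ValueError("need at least two methods")
    if grouping is None:
        groups = {"all": scores.index}
    else:
        grouping = pd.Series(grouping)
        groups = {
            str(g): grouping.index[grouping == g] for g in sorted(grouping.unique())
        }
    records = []
    methods = list(scores.columns)
    for gname, slide_ids in groups.items():
        sub = scores.loc[scores.index.intersection(slide_ids)]
        for i, a in enumerate(methods):
            for b in methods[i + 1:]:
                paired = sub[[a, b]].dropna()
                n = len(paired)
                if n < 3:
                    tau = lo = hi = NOT_COMPUTABLE
                else:
                    tau = kendall_tau_b(paired[a], paired[b])
                    lo, hi = bootstrap_ci(paired[a], paired[b], B=B,
                                          level=level, seed=seed)
                records.append({
                    "group": gname, "method_a": a, "method_b": b,
                    "tau_b": tau, "ci_low": lo, "ci_high": hi,
                    "n_slides": n,
                })
    return AgreementTable(pd.DataFrame.from_records(records))
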