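"""Akaike-weight variable importance over all predictor subsets.

Every subset of the candidate predictors is fit by ordinary least squares and
scored with the least-squares AIC convention

    AIC = n * ln(RSS / n) + 2 * (k + 2)

(k slopes, one intercept, one error variance), which is held fixed across all
models so that AIC differences are meaningful.  Akaike weights
``w = exp(-delta/2) / sum(exp(-delta/2))`` rank the models; the best subset is
the shortest top-ranked prefix whose cumulative weight exceeds 0.95, and each
variable's relative importance (RVI) is the sum of weights over best-subset
models containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from rwlr.errors import FitError, ParameterError

__all__ = [
    "LmFit",
    "ModelRanking",
    "CollinearityReport",
    "aic_least_squares",
    "fit_lm",
    "all_subsets_rank",
    "collinearity_screen",
]

MAX_CANDIDATES = 12


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """n*ln(RSS/n) + 2*(k+2); k = number of slope parameters."""
    rss = max(float(rss), 1e-300)  # exact fits: keep the value finite-ordered
    return n * np.log(rss / n) + 2.0 * (k + 2)


@dataclass
class LmFit:
    """OLS summary for one model."""

    variables: tuple[str, ...]
    params: pd.Series
    pvalues: pd.Series
    r2: float
    rss: float
    n: int
    aic: float


def fit_lm(response: np.ndarray | pd.Series,
           predictors: pd.DataFrame | None) -> LmFit:
    """Ordinary least squares with an intercept; ``None`` fits the null model."""
    y = np.asarray(response, dtype=float)
    n = y.size
    if predictors is None or predictors.shape[1] == 0:
        X = pd.DataFrame(index=np.arange(n))
        names: tuple[str, ...] = ()
    else:
        X = predictors.reset_index(drop=True)
        names = tuple(X.columns)
    k = len(names)
    if n <= k + 2:
        raise FitError(f"n={n} too small for {k} predictors")
    if not np.all(np.isfinite(y)) or (k and not np.isfinite(X.to_numpy()).all()):
        raise FitError("missing or non-finite values in model frame")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise FitError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    return LmFit(variables=names, params=res.params, pvalues=res.pvalues,
                 r2=float(res.rsquared) if k else 0.0, rss=rss, n=n,
                 aic=aic_least_squares(rss, n, k))


@dataclass
class ModelRanking:
    """All-subsets table with weights, best subset and per-variable RVI.

    ``models`` is sorted by AIC (ties: fewer parameters, then variable
    names) and has columns model_id, variables, k, aic, delta, weight,
    cum_weight, in_best_subset.
    """

    models: pd.DataFrame
    best_subset: list[int]          # positional indices into ``models``
    rvi: dict[str, float]
    candidates: list[str]

    @property
    def best_subset_weight(self) -> float:
        return float(self.models["weight"].iloc[self.best_subset].sum())


def all_subsets_rank(
    response: np.ndarray | pd.Series,
    candidates: pd.DataFrame,
    include_null: bool = True,
    cumulative_weight: float = 0.95,
) -> ModelRanking:
    """Enumerate, score and weight every subset of the candidate predictors."""
    names = list(candidates.columns)
    if len(names) > MAX_CANDIDATES:
        raise ParameterError(
            f"{len(names)} candidates exceed the {MAX_CANDIDATES}-variable "
            "enumeration limit"
        )
    if len(names) == 0:
        raise ParameterError("need at least one candidate")
    subsets: list[tuple[str, ...]] = []
    for r in range(0 if include_null else 1, len(names) + 1):
        subsets.extend(combinations(names, r))

    y = np.asarray(response, dtype=float)
    n = y.size
    if n <= len(names) + 2:
        raise FitError(f"n={n} too small for {len(names)} candidates")
    x_all = candidates.to_numpy(dtype=float)
    if not (np.all(np.isfinite(y)) and np.isfinite(x_all).all()):
        raise FitError("missing or non-finite values in model frame")
    col = {name: j for j, name in enumerate(names)}
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for sub in subsets:
        design = np.column_stack(
            [np.ones(n)] + [x_all[:, col[v]] for v in sub])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise FitError(f"rank-deficient design for subset {sub}")
        rss = float(np.sum((y - design @ beta) ** 2))
        rows.append({"variables": sub, "k": len(sub),
                     "aic": aic_least_squares(rss, n, len(sub)),
                     "r2": 0.0 if ss_tot == 0 else 1.0 - rss / ss_tot})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["aic", "k", "variables"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta"] = table["aic"] - table["aic"].iloc[0]
    w = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = w / w.sum()
    table["cum_weight"] = table["weight"].cumsum()
    table.insert(0, "model_id", np.arange(len(table)))

    # first prefix whose cumulative weight exceeds the threshold
    crossing = int(np.argmax(table["cum_weight"].to_numpy() > cumulative_weight))
    best = list(range(crossing + 1))
    table["in_best_subset"] = False
    table.loc[best, "in_best_subset"] = True

    rvi = {
        name: float(table.loc[table["in_best_subset"]
                              & table["variables"].map(lambda v: name in v),
                              "weight"].sum())
        for name in names
    }
    return ModelRanking(models=table, best_subset=best, rvi=rvi,
                        candidates=names)


@dataclass
class CollinearityReport:
    """Outcome of the pairwise |r| screen."""

    pairwise_r: pd.DataFrame
    excluded: dict[str, dict]       # variable -> {reason, partner, aic pair}
    subsets: list[list[str]]


def collinearity_screen(
    candidates: pd.DataFrame,
    response: np.ndarray | pd.Series,
    threshold: float = 0.70,
    keep_both: tuple[str, str] | None = None,
) -> CollinearityReport:
    """Drop the weaker member of every strongly collinear pair.

    For each pair with Pearson |r| above ``threshold`` the member whose
    single-variable model has the greater AIC against the response is
    excluded.  If the pair equals ``keep_both`` neither is dropped; instead
    two candidate subsets are emitted, each containing one member, to be
    ranked separately.
    """
    names = list(candidates.columns)
    corr = candidates.corr(method="pearson")
    single_aic = {
        name: fit_lm(response, candidates[[name]]).aic for name in names
    }
    flagged = [
        (abs(corr.loc[a, b]), a, b)
        for a, b in combinations(names, 2)
        if abs(corr.loc[a, b]) > threshold
    ]
    flagged.sort(reverse=True)

    excluded: dict[str, dict] = {}
    split_pair: tuple[str, str] | None = None
    for _, a, b in flagged:
        if a in excluded or b in excluded:
            continue
        if keep_both and {a, b} == set(keep_both):
            split_pair = (a, b)
            continue
        weak, strong = (a, b) if single_aic[a] > single_aic[b] else (b, a)
        excluded[weak] = {
            "reason": "collinear", "partner": strong,
            "r": float(corr.loc[a, b]),
            "aic_excluded": single_aic[weak], "aic_retained": single_aic[strong],
        }

    retained = [n for n in names if n not in excluded]
    if split_pair is not None:
        a, b = split_pair
        subsets = [[n for n in retained if n != b],
                   [n for n in retained if n != a]]
    else:
        subsets = [retained]
    return CollinearityReport(pairwise_r=corr, excluded=excluded,
                              subsets=subsets)
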