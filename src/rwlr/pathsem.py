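"""Recursive path models on observed variables with SEM fit indices.

Models are systems of linear equations among measured variables with an
acyclic path diagram and uncorrelated residuals.  For such systems,
equation-wise ordinary least squares gives the maximum-likelihood path
coefficients; the model-implied covariance matrix then yields the usual
covariance-structure test statistic

    chi2 = (n - 1) * [ln|Sigma| - ln|S| + tr(S Sigma^-1) - p]

together with CFI (against the independence baseline) and RMSEA with its
90% confidence interval from the noncentral chi-square inversion.  The
standardized solution is obtained by fitting on z-scored data, so indirect
effects are products of standardized path coefficients along directed chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from rwlr.errors import GraphError, IdentificationError, ParameterError

__all__ = [
    "PathSpec",
    "PathFit",
    "fit_path_model",
    "total_effects",
    "accept_model",
]

_FORBIDDEN_TOGETHER = ("br_si", "br_ca")


@dataclass(frozen=True)
class PathSpec:
    """Recursive system: one (endogenous, predictors) entry per equation."""

    equations: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_equations(cls, equations) -> "PathSpec":
        eqs = tuple((lhs, tuple(rhs)) for lhs, rhs in equations)
        spec = cls(equations=eqs)
        spec.topological_order()  # raises on cycles
        return spec

    @classmethod
    def from_text(cls, text: str) -> "PathSpec":
        """Parse lines like ``npp ~ rwlr + mat``."""
        eqs = []
        for line in text.strip().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "~" not in line:
                raise GraphError(f"cannot parse equation {line!r}")
            lhs, rhs = line.split("~", 1)
            preds = tuple(p.strip() for p in rhs.split("+") if p.strip())
            eqs.append((lhs.strip(), preds))
        return cls.from_equations(eqs)

    @property
    def endogenous(self) -> list[str]:
        return [lhs for lhs, _ in self.equations]

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for lhs, rhs in self.equations:
            for v in (lhs, *rhs):
                if v not in seen:
                    seen.append(v)
        return seen

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    @property
    def paths(self) -> list[tuple[str, str]]:
        """(source, target) pairs, one per free coefficient."""
        return [(p, lhs) for lhs, rhs in self.equations for p in rhs]

    def topological_order(self) -> list[str]:
        """Kahn's algorithm over the path diagram; raises on cycles."""
        if len(set(self.endogenous)) != len(self.endogenous):
            raise GraphError("a variable appears on the left twice")
        nodes = self.variables
        incoming = {v: set() for v in nodes}
        for src, dst in self.paths:
            incoming[dst].add(src)
        order, ready = [], [v for v in nodes if not incoming[v]]
        while ready:
            v = ready.pop()
            order.append(v)
            for w in nodes:
                if v in incoming[w]:
                    incoming[w].discard(v)
                    if not incoming[w]:
                        ready.append(w)
        if len(order) != len(nodes):
            raise GraphError("path specification contains a cycle")
        return order


@dataclass
class PathFit:
    """Fitted recursive path model (standardized solution)."""

    spec: PathSpec
    variables: list[str]
    coef: pd.DataFrame            # columns: source, target, estimate, pvalue
    b_matrix: pd.DataFrame        # standardized paths, target rows x source cols
    r2: dict[str, float]
    n: int
    chisq: float
    df: int
    chisq_p: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    total: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coef.to_dict(orient="records"),
            "r2": self.r2,
            "n": self.n,
            "chisq": self.chisq, "df": self.df, "chisq_p": self.chisq_p,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90),
            "accepted": self.accepted, "reasons": self.reasons,
            "warnings": self.warnings,
            "total_effects": self.total,
        }


def _rmsea_ci(chisq: float, df: int, n: int,
              level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square for the RMSEA interval."""
    if df <= 0 or n <= 1:
        return (0.0, 0.0)
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # 0.95, 0.05
    lam_max = max(10.0 * chisq + 100.0, 100.0)

    def bound(q: float) -> float:
        # find lambda with P(X_{df,lambda} <= chisq) = q
        if stats.ncx2.cdf(chisq, df, 1e-10) < q:
            return 0.0
        f = lambda lam: stats.ncx2.cdf(chisq, df, lam) - q
        if f(lam_max) > 0:
            return lam_max
        return brentq(f, 1e-10, lam_max, xtol=1e-10)

    lam_lo, lam_hi = bound(lo_q), bound(hi_q)
    scale = df * (n - 1)
    return (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))


def fit_path_model(
    data: pd.DataFrame,
    spec: PathSpec,
    standardize: bool = True,
    accept: bool = True,
) -> PathFit:
    """ML fit of a recursive path model on the sample covariance matrix.

    Coefficients come from per-equation OLS (the ML estimator for recursive
    systems with uncorrelated errors); fit statistics compare the implied and
    sample covariance structures.  With ``standardize`` (default) the
    reported solution is on the correlation scale.
    """
    varnames = spec.variables
    lowered = {v.lower() for v in varnames}
    if set(_FORBIDDEN_TOGETHER) <= lowered:
        raise ParameterError(
            "br_si and br_ca are strongly collinear and must not enter one "
            "model; fit the two single-element variants instead"
        )
    missing = [v for v in varnames if v not in data.columns]
    if missing:
        raise GraphError(f"variables not in data: {missing}")
    frame = data[varnames].astype(float)
    if frame.isna().any().any():
        raise IdentificationError("complete data required (NaNs present)")
    n, p = len(frame), len(varnames)

    exog = spec.exogenous
    endo = spec.endogenous
    n_free = (len(spec.paths) + len(endo)
              + len(exog) * (len(exog) + 1) // 2)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise IdentificationError(
            f"model has {n_free} free parameters for {p*(p+1)//2} moments"
        )
    max_k = max(len(rhs) for _, rhs in spec.equations)
    if n <= max_k + 2:
        raise IdentificationError("sample too small for the largest equation")

    z = frame.copy()
    if standardize:
        z = (frame - frame.mean()) / frame.std(ddof=1)
    s_mat = z.cov(ddof=1).to_numpy()  # correlation matrix when standardized

    b = pd.DataFrame(0.0, index=varnames, columns=varnames)
    rows, r2, psi = [], {}, {}
    for lhs, rhs in spec.equations:
        design = sm.add_constant(z[list(rhs)], has_constant="add")
        res = sm.OLS(z[lhs].to_numpy(), design).fit()
        for src in rhs:
            b.loc[lhs, src] = float(res.params[src])
            rows.append({"source": src, "target": lhs,
                         "estimate": float(res.params[src]),
                         "pvalue": float(res.pvalues[src])})
        r2[lhs] = float(res.rsquared)
        psi[lhs] = float(res.ssr) / (n - 1)

    # implied covariance: v = B v + u,  Sigma = (I-B)^-1 Omega (I-B)^-T
    i_b = np.eye(p) - b.to_numpy()
    omega = np.zeros((p, p))
    ex_idx = [varnames.index(v) for v in exog]
    omega[np.ix_(ex_idx, ex_idx)] = s_mat[np.ix_(ex_idx, ex_idx)]
    for lhs in endo:
        j = varnames.index(lhs)
        omega[j, j] = psi[lhs]
    inv_ib = np.linalg.inv(i_b)
    sigma = inv_ib @ omega @ inv_ib.T

    sign_s, logdet_s = np.linalg.slogdet(s_mat)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    warn: list[str] = []
    singular = sign_s <= 0 or sign_m <= 0
    if singular:
        # deterministic relations make S rank-deficient; coefficients and
        # effect decompositions remain valid, covariance tests do not
        warn.append("singular covariance matrix: fit indices unavailable")
        chisq = float("nan")
    else:
        f_ml = logdet_m - logdet_s + float(np.trace(
            s_mat @ np.linalg.inv(sigma))) - p
        chisq = max((n - 1) * f_ml, 0.0)

    if singular:
        chisq_p, cfi, rmsea, ci = (float("nan"),) * 3 + ((float("nan"),) * 2,)
    elif df == 0:
        chisq_p, cfi, rmsea, ci = 1.0, 1.0, 0.0, (0.0, 0.0)
        warn.append("zero df: saturated model, fit indices uninformative")
    else:
        chisq_p = float(stats.chi2.sf(chisq, df))
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        chisq_b = (n - 1) * float(-np.linalg.slogdet(corr)[1])
        df_b = p * (p - 1) // 2
        num = max(chisq - df, 0.0)
        den = max(chisq_b - df_b, chisq - df, 0.0)
        cfi = 1.0 if den == 0 else 1.0 - num / den
        rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * (n - 1))))
        ci = _rmsea_ci(chisq, df, n)

    fit = PathFit(
        spec=spec, variables=varnames,
        coef=pd.DataFrame(rows), b_matrix=b, r2=r2, n=n,
        chisq=float(chisq), df=df, chisq_p=chisq_p, cfi=float(cfi),
        rmsea=rmsea, rmsea_ci90=ci, warnings=warn,
    )
    fit.total = total_effects(fit, target=endo[-1])
    if accept:
        fit.accepted, fit.reasons = accept_model(fit)
    return fit


def total_effects(fit: PathFit, target: str) -> dict[str, dict[str, float]]:
    """Direct/indirect/total standardized effects of every variable on target.

    The total-effects matrix of an acyclic system is
    ``(I - B)^-1 - I = B + B^2 + ...``; the indirect part sums products of
    path coefficients along every directed chain of length >= 2.
    """
    if target not in fit.variables:
        raise GraphError(f"unknown target {target!r}")
    b = fit.b_matrix.to_numpy()
    p = len(fit.variables)
    total_mat = np.linalg.inv(np.eye(p) - b) - np.eye(p)
    ti = fit.variables.index(target)
    out: dict[str, dict[str, float]] = {}
    for j, src in enumerate(fit.variables):
        if src == target:
            continue
        direct = float(b[ti, j])
        tot = float(total_mat[ti, j])
        out[src] = {"direct": direct, "indirect": tot - direct, "total": tot}
    return out


def accept_model(
    fit: PathFit,
    p_min: float = 0.05,
    cfi_min: float = 0.9,
    rmsea_lower_max: float = 0.05,
) -> tuple[bool, list[str]]:
    """Acceptance rule: chi2 p > 0.05, CFI > 0.9, RMSEA lower 90% CI < 0.05."""
    reasons: list[str] = []
    if fit.df == 0:
        return True, ["zero df: accepted with uninformative indices"]
    if not fit.chisq_p > p_min:
        reasons.append("chisq_p")
    if not fit.cfi > cfi_min:
        reasons.append("CFI")
    if not fit.rmsea_ci90[0] < rmsea_lower_max:
        reasons.append("RMSEA_lower_CI")
    return (len(reasons) == 0), reasons
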