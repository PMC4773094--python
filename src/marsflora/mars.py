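"""Multi-response MARS with a per-species binomial GLM refit.

The model at the center of this package: a single set of piecewise-linear
hinge basis functions max(0, +/-(x - knot)) is selected greedily on the
pooled 0/1 response columns of *all* species at once (each survey point is a
presence for its own species and an inventory pseudo-absence for every other
species), pruned back by generalized cross-validation, and then each species
gets its own logistic-regression coefficients over the shared basis.  This is
the classical multi-response ("community") MARS formulation adapted for
binomial errors: the basis search is least squares on the indicator matrix,
only the per-species refit is a binomial GLM.

Pooling the signal across species is what lets species with as few as two
records be mapped at all: the shared basis is informed by the common species,
and the rare species only need a handful of coefficients on top of it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import PredictorStack, Raster
from .survey import SurveyTable

__all__ = [
    "HingeBasis",
    "BasisTerm",
    "MarsModel",
    "evaluate_basis",
    "build_response_matrix",
    "design_matrix",
    "fit_forward",
    "prune_backward_gcv",
    "refit_binomial_glm",
    "fit_mars",
    "predict_probability",
    "deviance_diagnostics",
]

_PROB_CLIP = 1e-6


@dataclass(frozen=True)
class HingeBasis:
    """One hinge function b(x) = max(0, sign * (x - knot))."""

    variable: str
    knot: float
    sign: int  # +1 or -1

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def __call__(self, x):
        return evaluate_basis(self, x)


def evaluate_basis(basis: HingeBasis, x):
    """Evaluate a hinge at scalar or array ``x``."""
    return np.maximum(0.0, basis.sign * (np.asarray(x, dtype=float) - basis.knot))


@dataclass(frozen=True)
class BasisTerm:
    """A product of hinge functions (degree = number of factors).

    Degree 1 is a plain hinge; degree 2 is a pairwise interaction.
    """

    hinges: tuple[HingeBasis, ...]

    @property
    def degree(self) -> int:
        return len(self.hinges)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(h.variable for h in self.hinges)

    def evaluate(self, data) -> np.ndarray:
        """Column for this term from a mapping of variable name -> array."""
        out = None
        for h in self.hinges:
            col = evaluate_basis(h, data[h.variable])
            out = col if out is None else out * col
        return out


def build_response_matrix(table: SurveyTable, min_records: int = 2) -> pd.DataFrame:
    """Indicator matrix: rows = retained occurrence points, columns = species.

    Species with fewer than ``min_records`` points are dropped together with
    their points.  Every row has exactly one 1 (a survey point records one
    species); every other species reads that point as a pseudo-absence.
    """
    if min_records < 1:
        raise ValueError("min_records must be >= 1")
    counts = table.record_counts()
    kept = sorted(counts.index[counts >= min_records])
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} species with >= {min_records} records; "
            "multi-response fitting needs at least two"
        )
    frame = table.frame[table.frame["species_id"].isin(kept)]
    Y = pd.get_dummies(frame["species_id"]).astype(float)
    return Y[kept]


def design_matrix(X: pd.DataFrame, terms: list[BasisTerm]) -> np.ndarray:
    """Model matrix with an intercept column followed by one column per term."""
    n = len(X)
    B = np.empty((n, 1 + len(terms)))
    B[:, 0] = 1.0
    for j, term in enumerate(terms):
        B[:, j + 1] = term.evaluate(X)
    return B


# ---------------------------------------------------------------------------
# Forward pass

def _candidate_knots(x: np.ndarray, max_candidates: int, min_span: int) -> np.ndarray:
    """Candidate knot values for one predictor.

    Uses the unique observed values, drops knots with fewer than ``min_span``
    observations strictly on either side (the standard guard against hinges
    pivoting on data edges), and thins to at most ``max_candidates``
    quantile-spaced values.
    """
    xs = np.sort(x)
    uniq = np.unique(xs)
    if len(uniq) < 2:
        return np.empty(0)
    n = len(xs)
    below = np.searchsorted(xs, uniq, side="left")
    above = n - np.searchsorted(xs, uniq, side="right")
    uniq = uniq[(below >= min_span) & (above >= min_span)]
    if len(uniq) > max_candidates:
        idx = np.unique(np.round(np.linspace(0, len(uniq) - 1, max_candidates)).astype(int))
        uniq = uniq[idx]
    return uniq


def _qr_append(Q: np.ndarray, col: np.ndarray, tol: float = 1e-10) -> np.ndarray | None:
    """Orthonormalize ``col`` against the columns of ``Q``; None if dependent."""
    v = col - Q @ (Q.T @ col)
    v = v - Q @ (Q.T @ v)  # re-orthogonalize for stability
    nrm = np.linalg.norm(v)
    if nrm <= tol * max(1.0, np.linalg.norm(col)):
        return None
    return v / nrm


def fit_forward(
    X: pd.DataFrame,
    Y: pd.DataFrame | np.ndarray,
    max_terms: int | None = None,
    degree: int = 1,
    tol: float = 1e-4,
    max_candidates: int = 50,
    min_span: int = 3,
) -> list[BasisTerm]:
    """Greedy forward selection of reflected hinge pairs.

    At each step every (parent term, variable, knot) candidate is scored by
    the total least-squares residual over *all* response columns when the
    reflected pair parent*max(0, x-k), parent*max(0, k-x) is added; the best
    candidate wins (ties: smallest RSS, then lowest variable index, then
    smallest knot).  Stops at ``max_terms`` basis functions (counting the
    intercept) or when the relative RSS improvement falls below ``tol``.

    With ``degree=1`` the only parent is the intercept (additive model);
    higher degrees also consider products with existing terms that do not
    already involve the candidate variable.
    """
    Yv = np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, n_pred = len(X), X.shape[1]
    if n_pred < 1:
        raise ValueError("need at least one predictor column")
    if max_terms is None:
        max_terms = min(21, 2 * n_pred + 1)
    if max_terms < 3:
        raise ValueError("max_terms must be >= 3 (intercept + one hinge pair)")

    Xv = {name: X[name].to_numpy(dtype=float) for name in X.columns}
    knots = {name: _candidate_knots(Xv[name], max_candidates, min_span)
             for name in X.columns}

    terms: list[BasisTerm] = []
    term_cols: list[np.ndarray] = []
    Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of the model space
    resid = Yv - Q @ (Q.T @ Yv)
    rss = float((resid ** 2).sum())

    while 1 + len(terms) + 2 <= max_terms:
        best = None  # (rss_new, parent_idx, var_idx, knot, cols)
        parents: list[tuple[int, np.ndarray, BasisTerm | None]] = [(-1, np.ones(n), None)]
        if degree > 1:
            for ti, t in enumerate(terms):
                if t.degree < degree:
                    parents.append((ti, term_cols[ti], t))
        for p_idx, p_col, p_term in parents:
            for v_idx, name in enumerate(X.columns):
                if p_term is not None and name in p_term.variables:
                    continue
                xcol = Xv[name]
                for knot in knots[name]:
                    u = p_col * np.maximum(0.0, xcol - knot)
                    v = p_col * np.maximum(0.0, knot - xcol)
                    qu = _qr_append(Q, u)
                    drop = 0.0
                    if qu is not None:
                        drop += float(((qu @ resid) ** 2).sum())
                        Q2 = np.column_stack([Q, qu])
                    else:
                        Q2 = Q
                    qv = _qr_append(Q2, v)
                    if qv is not None:
                        drop += float(((qv @ resid) ** 2).sum())
                    if drop <= 0.0:
                        continue
                    rss_new = rss - drop
                    if best is None or rss_new < best[0] - 1e-9 * max(rss, 1.0):
                        best = (rss_new, p_idx, v_idx, float(knot), (u, v))
        if best is None:
            break
        rss_new, p_idx, v_idx, knot, (u, v) = best
        if rss > 0 and (rss - rss_new) / rss < tol:
            break
        name = X.columns[v_idx]
        parent_hinges = () if p_idx < 0 else terms[p_idx].hinges
        for sign, col in ((1, u), (-1, v)):
            term = BasisTerm(parent_hinges + (HingeBasis(name, knot, sign),))
            qcol = _qr_append(Q, col)
            if qcol is None:
                continue  # linearly dependent half of the pair
            terms.append(term)
            term_cols.append(col)
            Q = np.column_stack([Q, qcol])
        resid = Yv - Q @ (Q.T @ Yv)
        rss = float((resid ** 2).sum())
    return terms


# ---------------------------------------------------------------------------
# Backward pass

def _gcv(rss_total: float, n: int, n_responses: int, m: int, penalty: float) -> float:
    c = m + penalty * (m - 1) / 2.0
    if c >= n:
        return np.inf
    return (rss_total / (n * n_responses)) / (1.0 - c / n) ** 2


def _rss_of(B: np.ndarray, Yv: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(B, Yv, rcond=None)
    r = Yv - B @ coef
    return float((r ** 2).sum())


def prune_backward_gcv(
    terms: list[BasisTerm],
    X: pd.DataFrame,
    Y: pd.DataFrame | np.ndarray,
    penalty: float = 2.0,
) -> list[BasisTerm]:
    """Backward deletion pruned by generalized cross-validation.

    Repeatedly removes the term whose deletion least increases the pooled
    RSS, scoring every model on the deletion path with
    GCV(M) = (RSS / (n*S)) / (1 - C(M)/n)^2, C(M) = M + penalty*(M-1)/2
    (M = basis size including the intercept, S = number of responses), and
    returns the subset with minimum GCV.  The intercept is never deleted.
    """
    Yv = np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, S = Yv.shape
    if not terms:
        return []
    cols = {t: t.evaluate(X) for t in terms}

    def rss_for(subset: list[BasisTerm]) -> float:
        B = np.column_stack([np.ones(n)] + [cols[t] for t in subset]) \
            if subset else np.ones((n, 1))
        return _rss_of(B, Yv)

    current = list(terms)
    best_subset = list(current)
    best_gcv = _gcv(rss_for(current), n, S, 1 + len(current), penalty)
    while current:
        # delete the term whose removal least increases RSS
        scores = []
        for i in range(len(current)):
            sub = current[:i] + current[i + 1:]
            scores.append((rss_for(sub), i))
        rss_sub, i_del = min(scores, key=lambda t: (t[0], t[1]))
        current = current[:i_del] + current[i_del + 1:]
        g = _gcv(rss_sub, n, S, 1 + len(current), penalty)
        if g <= best_gcv:
            best_gcv = g
            best_subset = list(current)
    return best_subset


# ---------------------------------------------------------------------------
# Binomial GLM refit (IRLS)

def refit_binomial_glm(
    B: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, dict]:
    """Logistic-regression ML fit of one species on the shared basis matrix.

    Iteratively reweighted least squares; fitted probabilities are clipped to
    [1e-6, 1 - 1e-6] inside the iteration for stability.  On completely
    separated (or one-class) data the coefficients drift to the boundary; the
    result is returned with ``info['boundary'] = True`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    n, k = B.shape
    beta = np.zeros(k)
    p_bar = min(max(y.mean(), _PROB_CLIP), 1 - _PROB_CLIP)
    beta[0] = np.log(p_bar / (1 - p_bar))
    converged = False
    for _ in range(max_iter):
        eta = B @ beta
        p = np.clip(expit(eta), _PROB_CLIP, 1 - _PROB_CLIP)
        w = p * (1 - p)
        sw = np.sqrt(w)
        z = eta + (y - p) / w
        beta_new, *_ = np.linalg.lstsq(B * sw[:, None], z * sw, rcond=None)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = B @ beta
    p = expit(eta)
    boundary = bool((p <= _PROB_CLIP).all() or (p >= 1 - _PROB_CLIP).all()
                    or np.max(np.abs(beta)) > 1e3)
    if boundary and not converged:
        warnings.warn("binomial refit reached the probability boundary "
                      "(separated or one-class response)", stacklevel=2)
    return beta, {"converged": converged, "boundary": boundary}


# ---------------------------------------------------------------------------
# Fitted model container

@dataclass
class MarsModel:
    """Shared hinge basis + per-species binomial GLM coefficients."""

    terms: list[BasisTerm]
    species_ids: list[str]
    coef: np.ndarray  # (n_species, 1 + n_terms)
    predictor_names: list[str]
    glm_flags: pd.DataFrame | None = None  # converged / boundary per species

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.species_ids), 1 + len(self.terms)):
            raise ValueError("coefficient matrix shape does not match basis")

    @property
    def used_variables(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for v in t.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"species {species_id!r} not in model") from None

    def linear_predictor(self, X: pd.DataFrame, species_id: str) -> np.ndarray:
        B = design_matrix(X, self.terms)
        return B @ self.coef[self.species_index(species_id)]

    def predict_proba_points(self, X: pd.DataFrame, species_id: str) -> np.ndarray:
        eta = self.linear_predictor(X, species_id)
        return np.clip(expit(eta), 0.0, 1.0)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "terms": [
                [{"variable": h.variable, "knot": h.knot, "sign": h.sign}
                 for h in t.hinges]
                for t in self.terms
            ],
            "species_ids": list(self.species_ids),
            "coefficients": self.coef.tolist(),
            "predictor_names": list(self.predictor_names),
            "glm_flags": (self.glm_flags.to_dict(orient="index")
                          if self.glm_flags is not None else None),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MarsModel":
        terms = [
            BasisTerm(tuple(HingeBasis(h["variable"], float(h["knot"]), int(h["sign"]))
                            for h in hs))
            for hs in d["terms"]
        ]
        flags = None
        if d.get("glm_flags"):
            flags = pd.DataFrame.from_dict(d["glm_flags"], orient="index")
        return cls(terms, list(d["species_ids"]), np.asarray(d["coefficients"]),
                   list(d["predictor_names"]), flags)

    @classmethod
    def from_json(cls, path: str | Path) -> "MarsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_mars(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    max_terms: int | None = None,
    degree: int = 1,
    penalty: float = 2.0,
    tol: float = 1e-4,
    max_candidates: int = 50,
    min_span: int = 3,
) -> MarsModel:
    """Full fit: forward selection, GCV pruning, per-species binomial refit."""
    terms = fit_forward(X, Y, max_terms=max_terms, degree=degree, tol=tol,
                        max_candidates=max_candidates, min_span=min_span)
    terms = prune_backward_gcv(terms, X, Y, penalty=penalty)
    B = design_matrix(X, terms)
    species = list(Y.columns)
    coef = np.empty((len(species), B.shape[1]))
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, sp in enumerate(species):
            beta, info = refit_binomial_glm(B, Y[sp].to_numpy())
            coef[i] = beta
            flags.append(info)
    return MarsModel(terms, species, coef, list(X.columns),
                     pd.DataFrame(flags, index=species))


def predict_probability(model: MarsModel, stack: PredictorStack, species_id: str) -> Raster:
    """Per-cell occurrence probability surface for one species.

    Inverse logit of the species' linear predictor over the shared basis,
    clamped to [0, 1]; cells with nodata in any used layer stay nodata.
    """
    for var in model.used_variables:
        if var not in stack:
            raise KeyError(f"predictor stack is missing layer {var!r}")
    spec = stack.spec
    data = {name: stack[name].values.ravel() for name in model.used_variables}
    beta = model.coef[model.species_index(species_id)]
    eta = np.full(spec.n_rows * spec.n_cols, beta[0], dtype=float)
    for j, term in enumerate(model.terms):
        eta = eta + beta[j + 1] * term.evaluate(data)
    p = np.clip(expit(eta), 0.0, 1.0)
    if model.used_variables:
        invalid = ~np.isfinite(
            np.column_stack([data[v] for v in model.used_variables])
        ).all(axis=1)
        p[invalid] = np.nan
    return Raster(spec, p.reshape(spec.shape))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def deviance_diagnostics(model: MarsModel, X: pd.DataFrame, Y: pd.DataFrame) -> dict:
    """Per-species deviance/pseudo-R2 and per-predictor drop-deviance ranking.

    ``per_species``: null deviance (intercept-only), residual deviance of the
    fitted model, and pseudo R^2 = 1 - residual/null.  ``per_variable``: for
    every predictor, the mean increase in deviance across species when the
    variable's basis terms are removed and each species' GLM refitted
    (variables with no terms in the final model score 0.00), ranked
    descending.
    """
    B = design_matrix(X, model.terms)
    per_species = []
    resid_dev = np.empty(len(model.species_ids))
    for i, sp in enumerate(model.species_ids):
        y = Y[sp].to_numpy(dtype=float)
        p_hat = expit(B @ model.coef[i])
        d_res = _binomial_deviance(y, p_hat)
        p_null = min(max(y.mean(), _PROB_CLIP), 1 - _PROB_CLIP)
        d_null = _binomial_deviance(y, np.full_like(y, p_null))
        resid_dev[i] = d_res
        per_species.append({
            "species_id": sp,
            "null_deviance": d_null,
            "residual_deviance": d_res,
            "pseudo_r2": 1.0 - d_res / d_null if d_null > 0 else 0.0,
        })
    per_species = pd.DataFrame(per_species).set_index("species_id")

    deltas = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for var in model.predictor_names:
            reduced = [t for t in model.terms if var not in t.variables]
            if len(reduced) == len(model.terms):
                deltas[var] = 0.0
                continue
            B_red = design_matrix(X, reduced)
            inc = np.empty(len(model.species_ids))
            for i, sp in enumerate(model.species_ids):
                y = Y[sp].to_numpy(dtype=float)
                beta, _ = refit_binomial_glm(B_red, y)
                p_red = expit(B_red @ beta)
                inc[i] = _binomial_deviance(y, p_red) - resid_dev[i]
            deltas[var] = float(np.mean(np.maximum(inc, 0.0)))
    per_variable = pd.DataFrame({
        "delta_deviance": pd.Series(deltas),
    })
    per_variable["rank"] = per_variable["delta_deviance"].rank(
        ascending=False, method="first").astype(int)
    per_variable = per_variable.sort_values("rank")
    return {"per_species": per_species, "per_variable": per_variable}
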