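"""Matrix regression of genetic distance on resistance, with AIC averaging.

Distance matrices are unfolded to site-pair vectors in a fixed order, all
variable subsets are fit by OLS on z-scored predictors, and models are
compared by AIC, Akaike weights and per-variable relative importance (RI,
the summed weight of models containing the variable).  Variables with
RI >= 0.60 seed multivariate resistance surfaces; the flat IBR baseline is
added to every multivariate candidate.  Because matrix pairs are not
independent observations, permutation p-values (joint row/column
permutation of the dependent matrix) are offered alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import PairwiseMatrix


@dataclass
class DistanceVector:
    """Lower-triangle unfold of a symmetric matrix in fixed pair order."""

    name: str
    pairs: list          # (id_i, id_j) with i before j in the id order
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pairs) != self.values.size:
            raise ValueError("pair labels and values differ in length")


def unfold(matrix: PairwiseMatrix, name=None) -> DistanceVector:
    """Row-major lower-triangle (i < j) unfold with pair labels."""
    v = np.asarray(matrix.values, dtype=float)
    if not np.allclose(v, v.T, atol=1e-9):
        raise ValueError("matrix is asymmetric beyond 1e-9")
    ids = matrix.ids
    pairs, vals = [], []
    for i in range(1, len(ids)):
        for j in range(i):
            pairs.append((ids[j], ids[i]))
            vals.append(v[i, j])
    return DistanceVector(name or matrix.kind, pairs, np.array(vals))


def fold(vector: DistanceVector, kind="") -> PairwiseMatrix:
    """Inverse of :func:`unfold`."""
    ids = []
    for a, b in vector.pairs:
        for x in (a, b):
            if x not in ids:
                ids.append(x)
    P = len(ids)
    m = np.zeros((P, P))
    for (a, b), val in zip(vector.pairs, vector.values):
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = val
    return PairwiseMatrix(ids, m, kind)


def _check_alignment(y: DistanceVector, X):
    for x in X:
        if x.pairs != y.pairs:
            raise ValueError(
                f"predictor {x.name!r} has a different pair order"
            )


@dataclass
class ModelRecord:
    variables: tuple
    coefficients: dict
    r_squared: float
    aic: float
    delta_aic: float = np.nan
    weight: float = np.nan
    p_permutation: float = np.nan


def fit_model(y: DistanceVector, X, standardize=True,
              use_aicc=False) -> ModelRecord:
    """OLS of a distance vector on predictor distance vectors.

    Predictors (and the response, when ``standardize``) are z-scored so
    coefficients are comparable across resistance scales.
    ``AIC = n ln(RSS/n) + 2 (k + 2)`` with ``n`` site pairs and ``k``
    predictors (parameters: slopes, intercept, residual variance); with
    ``use_aicc`` the small-sample correction ``2p(p+1)/(n-p-1)`` is added.
    Perfectly collinear predictors raise an error naming the pair.
    """
    X = list(X)
    _check_alignment(y, X)
    n = y.values.size
    k = len(X)
    if n <= k + 2:
        raise ValueError(f"{n} pairs cannot support {k} predictors")
    yv = y.values.astype(float)
    if standardize and yv.std() > 0:
        yv = (yv - yv.mean()) / yv.std()
    cols = []
    for x in X:
        v = x.values.astype(float)
        sd = v.std()
        if standardize:
            if sd == 0:
                raise ValueError(f"predictor {x.name!r} is constant")
            v = (v - v.mean()) / sd
        cols.append(v)
    for (i, a), (j, b) in itertools.combinations(enumerate(cols), 2):
        r = np.corrcoef(a, b)[0, 1]
        if abs(r) > 1 - 1e-12:
            raise ValueError(
                f"predictors {X[i].name!r} and {X[j].name!r} are perfectly "
                "collinear"
            )
    design = np.column_stack([np.ones(n)] + cols) if cols else \
        np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    rss = float(resid @ resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * (k + 2)
    if use_aicc:
        p = k + 2
        aic += 2 * p * (p + 1) / max(n - p - 1, 1)
    coefs = {x.name: float(b) for x, b in zip(X, beta[1:])}
    return ModelRecord(tuple(x.name for x in X), coefs, max(r2, 0.0),
                       float(aic))


@dataclass
class ModelTable:
    records: list
    support: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec, sup in zip(self.records, self.support or
                            [""] * len(self.records)):
            rows.append({
                "model": "+".join(rec.variables) or "(intercept)",
                "R2": rec.r_squared, "AIC": rec.aic,
                "dAIC": rec.delta_aic, "weight": rec.weight,
                "support": sup,
            })
        return pd.DataFrame(rows)


def all_subsets(y: DistanceVector, candidates: dict, max_size=None,
                standardize=True, use_aicc=False,
                skip_collinear=True) -> ModelTable:
    """Fit every candidate subset up to ``max_size`` and weight by AIC.

    ``candidates`` maps names to DistanceVectors (duplicate names are a
    caller bug upstream of the dict).  Returns records sorted by AIC with
    ``dAIC = AIC - min(AIC)`` and Akaike weights
    ``w = exp(-dAIC/2) / sum exp(-dAIC/2)``.
    """
    names = list(candidates)
    if not names:
        raise ValueError("no candidate variables")
    max_size = max_size or len(names)
    records = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(names, size):
            vectors = [candidates[c] for c in combo]
            try:
                records.append(fit_model(y, vectors, standardize=standardize,
                                         use_aicc=use_aicc))
            except ValueError:
                if not skip_collinear:
                    raise
    if not records:
        raise ValueError("no fittable models")
    return _weight_and_sort(records)


def _weight_and_sort(records) -> ModelTable:
    aics = np.array([r.aic for r in records])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for rec, d, wi in zip(records, delta, w):
        rec.delta_aic = float(d)
        rec.weight = float(wi)
    order = np.argsort(aics, kind="stable")
    table = ModelTable([records[i] for i in order])
    table.support = support_classes(table)
    return table


@dataclass
class RIScores:
    scores: dict

    def passing(self, threshold=0.60):
        return [v for v, s in self.scores.items() if s >= threshold]


def relative_importance(table: ModelTable) -> RIScores:
    """RI(v) = summed Akaike weight of models containing variable v."""
    scores = {}
    for rec in table.records:
        for v in rec.variables:
            scores[v] = scores.get(v, 0.0) + rec.weight
    return RIScores(scores)


def support_classes(table: ModelTable):
    """Interchangeable (dAIC <= 2), marginal (<= 10), else unsupported.

    Both boundaries inclusive.
    """
    labels = []
    for rec in table.records:
        if rec.delta_aic <= 2.0:
            labels.append("top/interchangeable")
        elif rec.delta_aic <= 10.0:
            labels.append("marginal")
        else:
            labels.append("unsupported")
    return labels


def select_for_multivariate(ri: RIScores, threshold=0.60,
                            always_include="IBR", max_combo_size=None):
    """Variable combinations for multivariate resistance surfaces.

    Variables with RI >= threshold (other than ``always_include``) are
    enumerated as singles, pairs, ... up to ``max_combo_size``; every
    combination is prefixed with ``always_include``, and the
    ``always_include``-only baseline model is emitted first.
    """
    chosen = sorted(
        v for v, s in ri.scores.items()
        if s >= threshold and v != always_include
    )
    max_combo_size = max_combo_size or len(chosen)
    combos = [(always_include,)]
    for size in range(1, max_combo_size + 1):
        for combo in itertools.combinations(chosen, size):
            combos.append((always_include,) + combo)
    return combos


def predictor_correlation(candidates: dict, flag_threshold=0.8):
    """Pearson correlations among candidate distance vectors.

    Pairs with |r| >= threshold are flagged; correlations with a
    zero-variance vector are reported missing.
    """
    names = list(candidates)
    if len(names) < 2:
        raise ValueError("need at least 2 candidates")
    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = candidates[a].values, candidates[b].values
        if va.std() == 0 or vb.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(va, vb)[0, 1])
        rows.append((a, b, r, bool(abs(r) >= flag_threshold)
                     if np.isfinite(r) else False))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "flagged"])


def permutation_significance(y_matrix: PairwiseMatrix, X, n_perm=999,
                             seed=None) -> float:
    """Permutation p-value for a matrix regression.

    Rows and columns of the dependent matrix are permuted jointly
    (preserving its internal structure), the model refit, and
    ``p = (1 + #{permuted R2 >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = unfold(y_matrix)
    obs = fit_model(y, X).r_squared
    rng = np.random.default_rng(seed)
    P = len(y_matrix.ids)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(P)
        vm = y_matrix.values[np.ix_(perm, perm)]
        yp = unfold(PairwiseMatrix(y_matrix.ids, vm, y_matrix.kind))
        if fit_model(yp, X).r_squared >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
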