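"""Group-level Ising network estimation (eLasso).

Each node j of the binary symptom matrix is regressed on all other nodes
with l1-penalized logistic regression over a descending 100-point lambda
path (from the smallest lambda giving the empty model down to 1% of it).
The path point minimizing the extended BIC

    EBIC_gamma = -2 loglik + df ln n + 2 gamma df ln(p_candidates)

is selected per node (ties toward larger lambda, i.e. the sparser model).
The node intercept becomes the threshold tau_j; directed coefficients are
symmetrized into undirected edge weights by the AND rule (edge present
only if selected in both nodewise regressions, weight = mean of the two
coefficients) or the OR rule (present if selected in either, the absent
coefficient counted as 0). gamma defaults to 0.25, the convention of the
eLasso literature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _fast
from .panel import BinarySymptomMatrix

#: coefficients larger than this trigger a (quasi-)separation warning
_SEPARATION_CAP = 15.0


class DegenerateNodeError(ValueError):
    """A symptom column is constant, so its regression is undefined."""


@dataclass
class IsingNetwork:
    """Symmetric Ising network: thresholds tau and edge weights W."""

    labels: tuple[str, ...]
    W: np.ndarray
    tau: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        K = len(self.labels)
        if self.W.shape != (K, K):
            raise ValueError("W must be K x K")
        if self.tau.shape != (K,):
            raise ValueError("tau must have length K")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal")
        if not np.all(np.isfinite(self.tau)) or not np.all(np.isfinite(self.W)):
            raise ValueError("parameters must be finite")

    @property
    def K(self) -> int:
        return len(self.labels)

    def to_json(self, path=None) -> str:
        payload = {
            "labels": list(self.labels),
            "tau": self.tau.tolist(),
            "W": self.W.ravel().tolist(),  # row-major
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "IsingNetwork":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        K = len(payload["labels"])
        return cls(labels=tuple(payload["labels"]),
                   W=np.array(payload["W"], dtype=float).reshape(K, K),
                   tau=np.array(payload["tau"], dtype=float),
                   meta=payload.get("meta", {}))

    def edge_list(self):
        """Edges as (label_i, label_j, weight) for i < j with nonzero weight."""
        out = []
        for i in range(self.K):
            for j in range(i + 1, self.K):
                if self.W[i, j] != 0.0:
                    out.append((self.labels[i], self.labels[j], float(self.W[i, j])))
        return out


def symmetrize_directed(D: np.ndarray, rule: str = "AND") -> np.ndarray:
    """Undirected edge weights from the directed nodewise coefficients.

    ``D[j, k]`` is the coefficient of node k in the regression of node j.
    AND: an edge exists only if both directed coefficients were selected;
    OR: if either was (the absent one counted as 0). The weight is the
    mean of the two directed coefficients in both cases.
    """
    D = np.asarray(D, dtype=float)
    K = D.shape[0]
    W = np.zeros((K, K))
    for j in range(K):
        for k in range(j + 1, K):
            a, b = D[j, k], D[k, j]
            if rule == "AND":
                present = a != 0.0 and b != 0.0
            elif rule == "OR":
                present = a != 0.0 or b != 0.0
            else:
                raise ValueError("rule must be 'AND' or 'OR'")
            if present:
                W[j, k] = W[k, j] = 0.5 * (a + b)
    return W


def ebic(loglik: float, df: int, n: int, p_candidates: int, gamma: float) -> float:
    """Extended BIC; lower is better. Reduces to BIC at gamma = 0."""
    if n < 1 or df < 0:
        raise ValueError("require n >= 1 and df >= 0")
    penalty = df * np.log(n) if df else 0.0
    if df and p_candidates > 1:
        penalty += 2.0 * gamma * df * np.log(p_candidates)
    return float(-2.0 * loglik + penalty)


def fit_elasso(X, gamma: float = 0.25, rule: str = "AND",
               nlambda: int = 100, lambda_min_ratio: float = 0.01,
               labels: Sequence[str] | None = None,
               tol: float = 1e-7, maxiter: int = 50) -> IsingNetwork:
    """Estimate an Ising network from binary data by eLasso.

    Parameters
    ----------
    X : BinarySymptomMatrix or (n, K) binary array.
    gamma : EBIC hyperparameter (0 = plain BIC; larger = sparser).
    rule : "AND" or "OR" edge symmetrization.

    Raises
    ------
    DegenerateNodeError
        if any column is constant (both response levels are required).
    """
    if isinstance(X, BinarySymptomMatrix):
        labels = labels or X.labels
        mat = X.X
        meta_extra = {"year": X.year}
    else:
        mat = np.asarray(X)
        meta_extra = {}
    n, K = mat.shape
    labels = tuple(labels) if labels else tuple(f"x{i + 1}" for i in range(K))
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    col_sums = mat.sum(axis=0)
    for j, s in enumerate(col_sums):
        if s == 0 or s == n:
            raise DegenerateNodeError(
                f"node {labels[j]!r} is constant ({'never' if s == 0 else 'always'} active)")
    counts = _fast.counts_from_matrix(mat)
    tau, _, D, lambdas = _fast.fit_elasso_counts(
        counts, K, float(gamma), rule == "AND", int(nlambda),
        float(lambda_min_ratio), float(tol), int(maxiter))
    W = symmetrize_directed(D, rule)
    if np.abs(W).max(initial=0.0) > _SEPARATION_CAP or np.abs(tau).max() > _SEPARATION_CAP:
        warnings.warn("very large coefficients: possible (quasi-)separation; "
                      "estimates are capped by the finite lambda path",
                      RuntimeWarning, stacklevel=2)
    meta = {
        "gamma": float(gamma),
        "rule": rule,
        "n": int(n),
        "lambda_selected": lambdas.tolist(),
        "nlambda": int(nlambda),
        "lambda_min_ratio": float(lambda_min_ratio),
        **meta_extra,
    }
    return IsingNetwork(labels=labels, W=W, tau=tau, meta=meta)


def connectivity(net: IsingNetwork) -> float:
    """Sum of all edge weights (each unordered pair counted once, signed)."""
    return float(np.triu(net.W, k=1).sum())


def threshold_summary(net: IsingNetwork) -> tuple[float, float, float]:
    """(total, mean, sample SD) of the node thresholds tau."""
    tau = net.tau
    sd = float(tau.std(ddof=1)) if tau.size > 1 else 0.0
    return float(tau.sum()), float(tau.mean()), sd


def write_edge_list_csv(net: IsingNetwork, path, header_lines=()) -> None:
    """Edge-list CSV (node_i, node_j, weight) for graph interoperability."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("node_i,node_j,weight\n")
        for a, b, w in net.edge_list():
            fh.write(f"{a},{b},{w!r}\n")
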