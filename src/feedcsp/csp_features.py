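"""Common Spatial Patterns on subject-level windowed band data.

CSP finds channel weightings w maximising the variance ratio
w' C1 w / w' (C1 + C2) w between two classes of multichannel signals.  Here
each observation is one subject's band-filtered, 200-300 ms windowed ERP
(roughly 26 samples x 64 channels), so per-subject covariances are badly
rank-deficient and shrinkage towards the scaled identity is mandatory.

Per-subject covariances are trace-normalised before averaging, removing
inter-subject amplitude scale; the generalized eigenproblem
``C1 w = mu (C1 + C2) w`` is solved by whitening ``C1 + C2``, eigenvalues mu
lie in [0, 1] and equal the share of class-1 variance captured by the
component; filters are ranked by discriminability |mu - 1/2|.  The spatial
*patterns* A (the forward model, what to plot on a scalp map) follow from the
filter-pattern duality A = (C1+C2) W (W'(C1+C2)W)^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import ChannelMontage

MIN_LAMBDA = 1e-3  # lower end of the regularization grid; keeps C1+C2 PD


class CSPError(ValueError):
    pass


def subject_covariance(window_matrix: np.ndarray,
                       lam: float = MIN_LAMBDA,
                       trace_norm: bool = True) -> np.ndarray:
    """Shrunk spatial covariance of one window matrix.

    C = X X' / tr(X X') (or plain X X' with ``trace_norm=False``), then
    (1 - lam) C + lam * (tr(C)/d) I.  With lam > 0 the result is strictly
    positive definite even for rank-1 input.

    Trace normalisation removes each subject's overall amplitude scale,
    keeping only the spatial *distribution* of variance; the classification
    pipeline disables it because between-group differences in absolute band
    power are exactly what the models are meant to detect.
    """
    X = np.asarray(window_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise CSPError("window matrix must be channels x samples, >= 2 samples")
    if not 0.0 <= lam <= 1.0:
        raise CSPError(f"shrinkage lambda {lam} outside [0, 1]")
    C = X @ X.T
    tr = np.trace(C)
    d = X.shape[0]
    if tr <= 0:
        if lam == 0:
            raise CSPError("zero-variance input needs lambda > 0")
        return lam * np.eye(d) / d
    if trace_norm:
        C = C / tr
    return (1.0 - lam) * C + lam * np.trace(C) / d * np.eye(d)


@dataclass
class CSPModel:
    """Fitted spatial filters W (m x d), eigenvalues mu, patterns A (d x m)."""

    filters: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray
    lam: float
    n_components: int
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "patterns": self.patterns.tolist(),
            "lambda": self.lam,
            "n_components": self.n_components,
            "meta": self.meta,
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CSPModel":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(filters=np.array(d["filters"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   patterns=np.array(d["patterns"]),
                   lam=d["lambda"], n_components=d["n_components"],
                   meta=d.get("meta", {}))


def _rank_components(mu: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m most discriminative eigenvalues.

    Sorted by |mu - 1/2| descending; ties broken towards the larger mu so the
    class-1-dominant end of the spectrum comes first.
    """
    order = np.lexsort((-mu, -np.abs(mu - 0.5)))
    return order[:m]


def csp_fit_from_means(C1: np.ndarray, C2: np.ndarray, m: int,
                       lam: float = 0.0,
                       meta: dict | None = None) -> CSPModel:
    """Fit CSP from two class-mean covariance matrices.

    Solves ``C1 w = mu (C1 + C2) w`` via the symmetric whitening of
    ``C1 + C2``; eigenvalues mu in [0, 1] are the share of class-1 variance
    per component.  The matrices are used as given; callers are responsible
    for regularisation.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if not (np.isfinite(C1).all() and np.isfinite(C2).all()):
        raise CSPError("non-finite class covariance")
    d = C1.shape[0]
    if not 1 <= m <= d:
        raise CSPError(f"n_components {m} outside 1..{d}")

    Ct = C1 + C2
    # whiten Ct: P Ct P' = I with P = Lambda^(-1/2) U'
    evals, U = scipy.linalg.eigh(Ct)
    if evals.min() <= 0:
        raise CSPError("C1 + C2 not positive definite; increase lambda")
    P = (U / np.sqrt(evals)).T
    mu_all, V = scipy.linalg.eigh(P @ C1 @ P.T)
    mu_all = np.clip(mu_all, 0.0, 1.0)
    W_all = V.T @ P  # rows: filters, normalised so W Ct W' = I

    sel = _rank_components(mu_all, m)
    W = W_all[sel]
    mu = mu_all[sel]
    A = Ct @ W.T @ np.linalg.inv(W @ Ct @ W.T)  # d x m patterns
    return CSPModel(filters=W, eigenvalues=mu, patterns=A, lam=lam,
                    n_components=m, meta=meta or {})


def csp_fit(class1: Sequence[np.ndarray],
            class2: Sequence[np.ndarray],
            lam: float = MIN_LAMBDA, m: int = 2,
            meta: dict | None = None) -> CSPModel:
    """Fit CSP from two classes of window matrices.

    Per-subject covariances are shrunk (:func:`subject_covariance`) and
    averaged per class before the generalized eigendecomposition.
    """
    covs1 = np.stack([subject_covariance(X, lam) for X in class1])
    covs2 = np.stack([subject_covariance(X, lam) for X in class2])
    if len(covs1) < 2 or len(covs2) < 2:
        raise CSPError("each class needs >= 2 observations")
    return csp_fit_from_means(covs1.mean(axis=0), covs2.mean(axis=0), m,
                              lam=lam, meta=meta)


def csp_fit_loaded(covs1: np.ndarray, covs2: np.ndarray,
                   lam: float = MIN_LAMBDA, m: int = 2,
                   meta: dict | None = None) -> CSPModel:
    """CSP on raw covariance stacks with pooled diagonal loading.

    The class-mean covariances are regularised towards a *shared* target,
    ``(1 - lam) Ck + lam sigma2 I`` with ``sigma2`` the mean per-channel
    variance pooled over both classes.  A class-dependent loading (e.g. each
    subject's own trace) would inject overall-amplitude differences into
    every spatial direction and swamp the eigenvalue ranking; the pooled
    target leaves directions without genuine spatial structure at exactly
    mu = 1/2.
    """
    covs1 = np.asarray(covs1, dtype=float)
    covs2 = np.asarray(covs2, dtype=float)
    if len(covs1) < 2 or len(covs2) < 2:
        raise CSPError("each class needs >= 2 observations")
    d = covs1.shape[1]
    sigma2 = np.trace(np.concatenate([covs1, covs2]).mean(axis=0)) / d
    load = lam * sigma2 * np.eye(d)
    C1 = (1.0 - lam) * covs1.mean(axis=0) + load
    C2 = (1.0 - lam) * covs2.mean(axis=0) + load
    return csp_fit_from_means(C1, C2, m, lam=lam, meta=meta)


def csp_transform(model: CSPModel, window_matrix: np.ndarray,
                  normalize: bool = True) -> np.ndarray:
    """Log-variance features of one window matrix.

    feature_j = log( var(w_j' X) / sum_k var(w_k' X) ), or plain
    log var(w_j' X) with ``normalize=False``.  The classification pipeline
    uses the unnormalised form so absolute band-power differences between
    groups survive into the features.

    "var" is the *uncentered* second moment mean((w' X)^2), matching the
    uncentered covariance C = X X' the filters were fitted on: a slow
    (delta-band) component is nearly constant across a 100 ms window, so
    subtracting the window mean would erase exactly the amplitude
    information the filter was selected for.
    """
    X = np.asarray(window_matrix, dtype=float)
    if X.shape[0] != model.n_channels:
        raise CSPError(
            f"window has {X.shape[0]} channels, model expects "
            f"{model.n_channels}"
        )
    proj = model.filters @ X
    var = (proj ** 2).mean(axis=1)
    total = var.sum()
    if total <= 0 or not np.isfinite(total):
        raise CSPError("zero projected variance; check input and lambda")
    return np.log(var / total) if normalize else np.log(var)


def csp_transform_many(model: CSPModel, windows: np.ndarray,
                       normalize: bool = True) -> np.ndarray:
    """Feature matrix (n_subjects x m) for a stack of window matrices."""
    return np.stack([csp_transform(model, X, normalize) for X in windows])


def export_patterns(model: CSPModel, montage: ChannelMontage,
                    path: str | Path | None = None) -> pd.DataFrame:
    """Channel x component table of spatial-pattern weights (for topomaps)."""
    cols = {f"component_{j + 1}": model.patterns[:, j]
            for j in range(model.n_components)}
    df = pd.DataFrame({"channel": list(montage.labels), **cols})
    if path is not None:
        df.to_csv(path, index=False)
    return df
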