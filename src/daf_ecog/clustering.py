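"""Rank-2 NMF clustering of electrode response profiles.

The electrode-by-time matrix A concatenates each selected electrode's
trial-resolved percent-change time courses (word task, all delay
conditions); negatives are clipped to zero. A is factorized as A ~ W H with
k = 2 by multiplicative updates minimizing the Frobenius (RMS) residual,
best of several seeded restarts. Each electrode joins the cluster of its
largest W coefficient (after normalizing the H components to unit energy),
and clusters are semantically labeled by their centroid onset: the
component rising before speech onset is "motor-like", the other
"auditory-like".
"""

from __future__ import annotations

import numpy as np

from .containers import HighGammaResponse, ResponseMatrix
from .exceptions import AssemblyError

__all__ = ["build_matrix", "ResponseProfileNMF", "nmf", "assign_clusters",
           "label_clusters"]


def build_matrix(hg_list, selected) -> ResponseMatrix:
    """Assemble the electrode-by-time matrix from per-participant responses.

    Time bins that are missing (NaN, multitaper edges) in any input are
    dropped from every trial so rows stay aligned; each row then concatenates
    that electrode's trials. All participants must contribute the same
    number of trials and the same time grid.
    """
    if isinstance(hg_list, HighGammaResponse):
        hg_list = [hg_list]
    selected = list(selected)
    if not selected:
        raise AssemblyError("no selected electrodes")
    ref = hg_list[0]
    valid_bins = np.ones(ref.times.size, dtype=bool)
    for hg in hg_list:
        if hg.times.size != ref.times.size or not np.allclose(hg.times, ref.times):
            raise AssemblyError("mismatched time axes across participants")
        if hg.n_trials != ref.n_trials:
            raise AssemblyError("mismatched trial counts across participants")
        valid_bins &= ~np.isnan(hg.values).any(axis=(0, 1))
    rows, row_index = [], []
    for hg in hg_list:
        for e, eid in enumerate(hg.electrode_ids):
            if eid in selected:
                rows.append(hg.values[:, e, :][:, valid_bins].ravel())
                row_index.append(eid)
    missing = set(selected) - set(row_index)
    if missing:
        raise AssemblyError(f"selected electrodes absent from inputs: {sorted(missing)}")
    A = np.vstack(rows)
    if not np.all(np.isfinite(A)):
        raise AssemblyError("non-finite entries in the response matrix")
    n_clipped = int(np.sum(A < 0))
    A = np.maximum(A, 0.0)
    n_bins = int(valid_bins.sum())
    col_index = [(int(t), float(tt)) for t in range(ref.n_trials)
                 for tt in ref.times[valid_bins]]
    return ResponseMatrix(A=A, row_index=row_index, col_index=col_index,
                          n_trials=ref.n_trials, n_bins=n_bins,
                          times=ref.times[valid_bins], n_clipped=n_clipped)


class ResponseProfileNMF:
    """Nonnegative matrix factorization A ~ W H (sklearn-style estimator).

    Multiplicative updates on the Frobenius objective, which make the RMS
    residual non-increasing across iterations; the best of ``n_restarts``
    seeded initializations (by final residual) is kept. Convergence is
    declared when the relative residual change drops below ``tol``.

    Attributes (after :meth:`fit`)
    ------------------------------
    W_ : (n_rows, k) nonnegative loadings (H normalized to unit energy).
    H_ : (k, n_cols) nonnegative components, rows unit-L2.
    residual_ : float, RMS of A - W H.
    residual_trace_ : per-iteration RMS residuals of the winning restart.
    labels_ : per-row cluster index (argmax of W_, ties to the lower index).
    converged_ : bool.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 10,
                 max_iter: int = 500, tol: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "n_restarts": self.n_restarts,
                "max_iter": self.max_iter, "tol": self.tol,
                "random_state": self.random_state}

    def set_params(self, **params) -> "ResponseProfileNMF":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _run_once(self, A: np.ndarray, rng: np.random.Generator):
        eps = 1e-12
        n, m = A.shape
        k = self.n_components
        scale = np.sqrt(max(A.mean(), eps) / k)
        W = scale * rng.uniform(0.1, 1.0, size=(n, k))
        H = scale * rng.uniform(0.1, 1.0, size=(k, m))
        norm = np.sqrt(A.size)
        trace = [np.linalg.norm(A - W @ H) / norm]
        converged = False
        for _ in range(self.max_iter):
            W *= (A @ H.T) / np.maximum(W @ (H @ H.T), eps)
            H *= (W.T @ A) / np.maximum((W.T @ W) @ H, eps)
            trace.append(np.linalg.norm(A - W @ H) / norm)
            if abs(trace[-2] - trace[-1]) <= self.tol * max(trace[-2], eps):
                converged = True
                break
        return W, H, np.asarray(trace), converged

    def fit(self, A) -> "ResponseProfileNMF":
        if isinstance(A, ResponseMatrix):
            self.matrix_ = A
            A = A.A
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise AssemblyError("A must be a 2-D matrix")
        if np.any(A < 0):
            raise AssemblyError("A must be nonnegative")
        if self.n_components > min(A.shape):
            raise AssemblyError("n_components exceeds matrix rank bound")
        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng([int(self.random_state), r])
            W, H, trace, conv = self._run_once(A, rng)
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace, conv)
        W, H, trace, conv = best
        # normalize H rows to unit energy; move scale into W
        norms = np.linalg.norm(H, axis=1)
        norms[norms == 0] = 1.0
        self.H_ = H / norms[:, None]
        self.W_ = W * norms[None, :]
        self.residual_trace_ = trace
        self.residual_ = float(trace[-1])
        self.converged_ = bool(conv)
        self.labels_ = assign_clusters(self.W_)
        return self

    def transform(self, A=None) -> np.ndarray:
        return self.W_

    def fit_predict(self, A) -> np.ndarray:
        return self.fit(A).labels_


def nmf(A, k: int = 2, n_restarts: int = 10, seed: int = 0,
        tol: float = 1e-6, max_iter: int = 500) -> ResponseProfileNMF:
    """Functional wrapper: fitted :class:`ResponseProfileNMF`."""
    return ResponseProfileNMF(n_components=k, n_restarts=n_restarts,
                              max_iter=max_iter, tol=tol, random_state=seed).fit(A)


def assign_clusters(W: np.ndarray) -> np.ndarray:
    """Cluster of each row: argmax over components; ties to the lower index."""
    W = np.asarray(W, dtype=float)
    return np.argmax(W, axis=1)


def label_clusters(H: np.ndarray, times: np.ndarray, n_trials: int) -> dict:
    """Semantic labels from component onsets.

    Each component's trial-averaged time course is computed by folding H's
    concatenated (trial, bin) columns; its onset is the first crossing of 25%
    of its own peak. The earlier-onset component (rising before the other,
    i.e. pre-speech activity) is "motor-like", the other "auditory-like".
    Returns {"labels": {cluster: label}, "onsets": {cluster: s},
    "centroids": (k, n_bins)}.
    """
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    n_bins = H.shape[1] // n_trials
    cent = H.reshape(k, n_trials, n_bins).mean(axis=1)
    times = np.asarray(times)[:n_bins]
    onsets = {}
    for c in range(k):
        y = cent[c]
        peak = y.max()
        if peak <= 0:
            onsets[c] = float("nan")
            continue
        above = np.flatnonzero(y >= 0.25 * peak)
        onsets[c] = float(times[above[0]]) if above.size else float("nan")
    order = sorted(onsets, key=lambda c: (np.isnan(onsets[c]), onsets[c]))
    labels = {c: "auditory-like" for c in range(k)}
    labels[order[0]] = "motor-like"
    return {"labels": labels, "onsets": onsets, "centroids": cent}
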