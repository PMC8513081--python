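"""Multiclass common spatial patterns via joint approximate diagonalization.

Classical CSP finds spatial filters whose projected variance is maximally
class-discriminative; it is intrinsically two-class.  The multiclass
extension used here whitens by the prior-weighted average class covariance
and then jointly (approximately) diagonalizes the whitened class
covariances with an orthogonal matrix found by Jacobi-style rotations
(Cardoso–Souloumiac sweeps).  The composed filters ``W`` act as
``Z = W E`` on a trial ``E`` (channels × samples).  Filters are ranked by
an approximation to the mutual information between the class label and the
filter output, computed from the whitened per-class variances
``v_ji = w_j^T R_ci w_j``:

    I(c, w_j) ≈ − Σ_i P(c_i) log v_ji − (3/16) (Σ_i P(c_i)(v_ji² − 1))²

A variant with ``log sqrt(v_ji)`` (halving the first term) is available via
``log_sqrt=True``; the default follows the plain-log form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DomainTensor, EpochSet


@dataclass
class CspModel:
    """Fitted multiclass CSP projection.

    ``W`` has filters in rows (``Z = W @ E``).  ``order`` sorts filters by
    descending mutual-information score; ``apply`` uses the first ``L`` of
    that ordering.
    """

    W: np.ndarray                      # (N, N) filters in rows
    class_covs: list[np.ndarray]       # M trace-normalized (N, N) SPD matrices
    priors: np.ndarray                 # (M,), sums to 1
    mi_scores: np.ndarray              # (N,)
    order: np.ndarray                  # permutation of range(N)
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def estimate_class_covs(epochs: EpochSet) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-class mean of trace-normalized trial covariances, plus priors.

    Each trial contributes ``X X^T / trace(X X^T)``; classes with fewer than
    two trials are rejected.
    """
    covs, priors = [], []
    n = epochs.n_trials
    for ci in range(epochs.n_classes):
        idx = np.nonzero(epochs.labels == ci)[0]
        if idx.size < 2:
            raise ValueError(
                f"class {ci} ({epochs.class_names[ci]!r}) has {idx.size} trial(s); need >= 2"
            )
        acc = np.zeros((epochs.n_channels, epochs.n_channels))
        for t in idx:
            x = epochs.data[t]
            c = x @ x.T
            acc += c / np.trace(c)
        covs.append(acc / idx.size)
        priors.append(idx.size / n)
    return covs, np.asarray(priors)


def joint_diagonalize(matrices: np.ndarray, tol: float = 1e-12, max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal V approximately diagonalizing all symmetric ``matrices``.

    Jacobi sweeps over index pairs; each rotation angle minimizes the summed
    off-diagonal energy of the pair across all matrices (Cardoso–Souloumiac).
    ``matrices`` is (M, N, N) and is not modified; returns V with
    ``V.T @ A_i @ V`` near-diagonal.
    """
    A = np.array(matrices, dtype=np.float64, copy=True)
    m, n, _ = A.shape
    V = np.eye(n)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                # 2x2 subproblem over all matrices
                h = np.stack([A[:, p, p] - A[:, q, q], A[:, p, q] + A[:, q, p]])  # (2, M)
                G = h @ h.T
                ton, toff = G[0, 0] - G[1, 1], G[0, 1] + G[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tol:
                    continue
                rotated = True
                rot_p = c * A[:, :, p] + s * A[:, :, q]
                rot_q = -s * A[:, :, p] + c * A[:, :, q]
                A[:, :, p], A[:, :, q] = rot_p, rot_q
                rot_p = c * A[:, p, :] + s * A[:, q, :]
                rot_q = -s * A[:, p, :] + c * A[:, q, :]
                A[:, p, :], A[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if not rotated:
            break
    return V


def mutual_information_scores(
    whitened_vars: np.ndarray, priors: np.ndarray, log_sqrt: bool = False
) -> np.ndarray:
    """Per-filter approximate mutual information from whitened class variances.

    ``whitened_vars`` is (N filters, M classes) with entries
    ``v_ji = w_j^T R_ci w_j`` in whitened space, so Σ_i P_i v_ji = 1.
    """
    v = np.clip(whitened_vars, 1e-300, None)
    logv = 0.5 * np.log(v) if log_sqrt else np.log(v)
    first = -(logv @ priors)
    second = (3.0 / 16.0) * ((v**2 - 1.0) @ priors) ** 2
    return first - second


def fit_jad(
    class_covs: list[np.ndarray],
    priors: np.ndarray,
    ridge: float = 0.0,
    log_sqrt: bool = False,
) -> CspModel:
    """Fit multiclass CSP: whiten, jointly diagonalize, rank filters.

    ``ridge`` adds ``ridge * mean(diag)`` to the average covariance diagonal
    before whitening when the estimate is ill-conditioned.
    """
    priors = np.asarray(priors, dtype=np.float64)
    m = len(class_covs)
    if m < 2:
        raise ValueError("need at least two classes")
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    n = class_covs[0].shape[0]
    rbar = sum(p * r for p, r in zip(priors, class_covs))
    if ridge > 0:
        rbar = rbar + ridge * np.mean(np.diag(rbar)) * np.eye(n)
    evals, evecs = np.linalg.eigh(rbar)
    if evals[0] <= 1e-12 * evals[-1]:
        raise np.linalg.LinAlgError(
            "average class covariance is singular; add a ridge (fit_jad(..., ridge=1e-6)) "
            "or drop flat channels"
        )
    whitener = (evecs / np.sqrt(evals)).T  # rows: whitening filters
    whitened = np.stack([whitener @ r @ whitener.T for r in class_covs])
    V = joint_diagonalize(whitened)
    W = V.T @ whitener  # filters in rows
    v_ji = np.einsum("jn,inm,jm->ji", W, np.stack(class_covs), W)  # (N, M)
    mi = mutual_information_scores(v_ji, priors, log_sqrt=log_sqrt)
    order = np.argsort(-mi, kind="stable")
    return CspModel(W=W, class_covs=[r.copy() for r in class_covs], priors=priors,
                    mi_scores=mi, order=order, meta={"ridge": ridge, "log_sqrt": log_sqrt})


def fit_csp(epochs: EpochSet, ridge: float = 0.0, log_sqrt: bool = False) -> CspModel:
    """Convenience: covariance estimation + JAD fit on one training set."""
    covs, priors = estimate_class_covs(epochs)
    return fit_jad(covs, priors, ridge=ridge, log_sqrt=log_sqrt)


def save_csp(model: CspModel, path) -> None:
    """Serialize a fitted projection (with provenance metadata) as ``.npz``."""
    import json

    np.savez_compressed(
        path,
        W=model.W,
        class_covs=np.stack(model.class_covs),
        priors=model.priors,
        mi_scores=model.mi_scores,
        order=model.order,
        meta=np.frombuffer(json.dumps(model.meta).encode(), dtype=np.uint8),
    )


def load_csp(path) -> CspModel:
    import json

    with np.load(path) as npz:
        return CspModel(
            W=npz["W"].copy(),
            class_covs=[c.copy() for c in npz["class_covs"]],
            priors=npz["priors"].copy(),
            mi_scores=npz["mi_scores"].copy(),
            order=npz["order"].copy(),
            meta=json.loads(bytes(npz["meta"])),
        )


def apply_csp(model: CspModel, epochs: EpochSet, L: int | None = None) -> DomainTensor:
    """Project trials through the top-``L`` filters (MI order): ``Z = W_L E``.

    ``L`` defaults to all channels, so the spatial-domain tensor keeps the
    shape of its source and no dimension reduction occurs.
    """
    n = model.n_channels
    if epochs.n_channels != n:
        raise ValueError(f"epochs have {epochs.n_channels} channels; model was fitted on {n}")
    if L is None:
        L = n
    if not 1 <= L <= n:
        raise ValueError(f"L must be in [1, {n}], got {L}")
    w_l = model.W[model.order[:L]]
    z = np.einsum("ln,tns->tls", w_l, epochs.data)
    return DomainTensor(z, "spatial", epochs.fs)
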