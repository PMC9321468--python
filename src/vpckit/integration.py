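"""Gaussian integrated information (Phi*) and the minimum information partition.

The system state X(t) collects the (decorrelated, normalized) bipolar LFP
channels of the recorded areas.  Under a multivariate-Gaussian assumption the
entropy and the lagged mutual information have closed forms,

    H(X)            = 1/2 log|Sigma(X)| + N/2 log(2 pi e)
    I(X_t; X_{t-tau}) = H(X_t) - H(X_t | X_{t-tau}),
    Sigma(X_t|X_{t-tau}) = Sigma_t - Sigma_cross Sigma_lag^{-1} Sigma_cross^T,

and integrated information is the part of I that cannot be accounted for by a
partitioned ("disconnected") model of the dynamics:

    Phi* = I - I*,

where I* is the *mismatched information*: the information recoverable when
decoding the past from the present with a model q that is block-diagonal
across the parts of a partition.  For jointly Gaussian states I* has a closed
form up to a scalar inverse-temperature beta that is optimized numerically
(see :func:`mismatched_information`).  The minimum information partition
(MIP) is the bipartition minimizing Phi*_P / N_P with the normalization
N_P = (m - 1) min_k H(M_k); parts (e.g. cortical layers) are atomic and are
never split across the cut.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.covariance import ledoit_wolf

LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


# ---------------------------------------------------------------------------
# Covariance estimation

def shrinkage_cov(x: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance of a channels x samples matrix.

    The estimate is a convex combination of the sample covariance and a
    scaled identity, with intensity chosen from the data; it is positive
    definite even when channels outnumber samples.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std(axis=1)
    dead = np.nonzero(sd < 1e-14)[0]
    if len(dead):
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    cov, _ = ledoit_wolf(x.T, assume_centered=False)
    return cov


def lagged_covariances(x: np.ndarray, tau: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrinkage (Sigma_t, Sigma_cross, Sigma_lag) at integer lag ``tau``.

    The joint vector [X_t, X_{t-tau}] is shrunk as a whole so the three blocks
    are mutually consistent and the joint covariance is positive definite.
    ``Sigma_cross[i, j] = cov(X_t[i], X_{t-tau}[j])``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if tau <= 0 or tau >= x.shape[1]:
        raise ValueError("lag must be in (0, n_samples)")
    joint = np.vstack([x[:, tau:], x[:, :-tau]])
    cov = shrinkage_cov(joint)
    return cov[:n, :n], cov[:n, n:], cov[n:, n:]


# ---------------------------------------------------------------------------
# Entropies and information

def _logdet(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise ValueError("matrix is not positive definite")
    return float(ld)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Closed-form Gaussian differential entropy in nats."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = cov.shape[0]
    return 0.5 * _logdet(cov) + 0.5 * n * LOG_2PIE


def mutual_information(cov_t: np.ndarray, cov_cross: np.ndarray,
                       cov_lag: np.ndarray) -> float:
    """Lagged Gaussian mutual information I(X_t; X_{t-tau}) in nats."""
    cov_t = np.atleast_2d(cov_t)
    cov_cross = np.atleast_2d(cov_cross)
    cov_lag = np.atleast_2d(cov_lag)
    cond = cov_t - cov_cross @ np.linalg.solve(cov_lag, cov_cross.T)
    return 0.5 * (_logdet(cov_t) - _logdet(cond))


def _partition_indices(partition, n: int) -> list[np.ndarray]:
    parts = [np.asarray(p, dtype=int) for p in partition]
    flat = np.concatenate(parts) if parts else np.array([], dtype=int)
    if sorted(flat.tolist()) != list(range(n)):
        raise ValueError("partition must cover all channels with disjoint parts")
    return parts


def _mismatched_objective(beta: float, A: np.ndarray, Dinv: np.ndarray,
                          S: np.ndarray, cov_t: np.ndarray, cov_lag: np.ndarray,
                          lag_inv: np.ndarray) -> float:
    """The Gaussian mismatched-decoding information at inverse temperature beta.

    Derived by Gaussian integration of the mismatched-decoding functional with
    the block-diagonal model q(X_t | X_{t-tau}) = prod_k q_k; concave in beta
    with value 0 at beta = 0 and maximum I when the model is exact.
    """
    R = beta * Dinv
    M = lag_inv + A.T @ R @ A
    Minv_At_R = np.linalg.solve(M, A.T @ R)
    Q = R - R @ A @ Minv_At_R
    term1 = -0.5 * beta * np.trace(Dinv @ S)
    term2 = 0.5 * _logdet(cov_lag @ M)
    term3 = 0.5 * np.trace(Q @ cov_t)
    return term1 + term2 + term3


def mismatched_information(cov_t: np.ndarray, cov_cross: np.ndarray,
                           cov_lag: np.ndarray, partition,
                           beta_max: float = 10.0,
                           return_curve: bool = False):
    """Mismatched information I* for one partition; returns (I*, beta_hat).

    The disconnected model regresses each part's present on that part's own
    past (block-diagonal regression A_D and conditional covariance D), and
    the decoding exponent beta is optimized by bounded scalar maximization.
    ``0 <= I* <= I`` always; I* = I for the single-part (trivial) partition.
    """
    cov_t = np.atleast_2d(np.asarray(cov_t, dtype=float))
    cov_cross = np.atleast_2d(np.asarray(cov_cross, dtype=float))
    cov_lag = np.atleast_2d(np.asarray(cov_lag, dtype=float))
    n = cov_t.shape[0]
    parts = _partition_indices(partition, n)

    A = np.zeros((n, n))
    Dinv = np.zeros((n, n))
    for p in parts:
        ix = np.ix_(p, p)
        a_k = cov_cross[ix] @ np.linalg.inv(cov_lag[ix])
        d_k = cov_t[ix] - a_k @ cov_cross[ix].T
        A[ix] = a_k
        Dinv[ix] = np.linalg.inv(d_k)
    # residual covariance of the *true* process under the model's predictor
    S = (cov_t - A @ cov_cross.T - cov_cross @ A.T + A @ cov_lag @ A.T)
    lag_inv = np.linalg.inv(cov_lag)

    def neg(beta: float) -> float:
        return -_mismatched_objective(beta, A, Dinv, S, cov_t, cov_lag, lag_inv)

    res = minimize_scalar(neg, bounds=(0.0, beta_max), method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    if not res.success:
        raise RuntimeError(f"beta optimization failed: {res.message}")
    i_star = -res.fun
    i_full = mutual_information(cov_t, cov_cross, cov_lag)
    i_star = float(np.clip(i_star, 0.0, i_full))
    if return_curve:
        grid = np.linspace(0, beta_max, 201)
        return i_star, float(res.x), [( b, _mismatched_objective(
            b, A, Dinv, S, cov_t, cov_lag, lag_inv)) for b in grid]
    return i_star, float(res.x)


# ---------------------------------------------------------------------------
# MIP search

@dataclass
class PhiResult:
    """Phi* at the minimum information partition, with all candidates."""

    entropy: float
    mutual_info: float
    phi_star: float                          # unnormalized Phi* at the MIP
    mip: tuple                               # (side_a labels, side_b labels)
    i_star_mip: float
    beta_mip: float
    normalization: float                     # N_P at the MIP
    candidates: list = field(default_factory=list)  # (partition, phi, norm, ratio)
    part_labels: dict = field(default_factory=dict)


def bipartitions(labels: list) -> list[tuple[tuple, tuple]]:
    """All unordered bipartitions of a label set (lexicographic order)."""
    labels = sorted(labels)
    first, rest = labels[0], labels[1:]
    out = []
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            side_a = tuple(sorted([first, *combo]))
            side_b = tuple(sorted(set(labels) - set(side_a)))
            if side_b:
                out.append((side_a, side_b))
    return sorted(out)


def find_mip(cov_t: np.ndarray, cov_cross: np.ndarray, cov_lag: np.ndarray,
             parts: dict) -> PhiResult:
    """Exhaustive bipartition search for the minimum information partition.

    ``parts`` maps part labels (e.g. "CN", "F_s") to channel-index lists;
    parts are atomic.  The MIP minimizes Phi*_P / N_P with
    N_P = min(H(side A), H(side B)) for bipartitions; ties break on the
    lexicographically smallest partition.  Phi* is reported unnormalized.
    """
    labels = sorted(parts)
    if not 2 <= len(labels) <= 8:
        raise ValueError("need between 2 and 8 parts")
    parts = {k: np.asarray(v, dtype=int) for k, v in parts.items()}
    empty = [k for k, v in parts.items() if len(v) == 0]
    if empty:
        import warnings
        warnings.warn(f"dropping empty part(s): {empty}")
        parts = {k: v for k, v in parts.items() if len(v)}
        labels = sorted(parts)

    h = gaussian_entropy(cov_t)
    i_full = mutual_information(cov_t, cov_cross, cov_lag)

    candidates = []
    best = None
    for side_a, side_b in bipartitions(labels):
        ch_a = np.concatenate([parts[l] for l in side_a])
        ch_b = np.concatenate([parts[l] for l in side_b])
        i_star, beta = mismatched_information(cov_t, cov_cross, cov_lag,
                                              [ch_a, ch_b])
        phi_p = max(0.0, i_full - i_star)
        h_a = gaussian_entropy(cov_t[np.ix_(ch_a, ch_a)])
        h_b = gaussian_entropy(cov_t[np.ix_(ch_b, ch_b)])
        norm = min(h_a, h_b)
        if norm <= 0:
            raise ValueError("non-positive part entropy; normalization undefined")
        ratio = phi_p / norm
        candidates.append(((side_a, side_b), phi_p, norm, ratio, i_star, beta))
        if best is None or ratio < best[3] - 1e-15:
            best = candidates[-1]
    part, phi_p, norm, ratio, i_star, beta = best
    return PhiResult(entropy=h, mutual_info=i_full, phi_star=phi_p, mip=part,
                     i_star_mip=i_star, beta_mip=beta, normalization=norm,
                     candidates=[c[:4] for c in candidates],
                     part_labels={k: v.tolist() for k, v in parts.items()})


def phi_from_data(x: np.ndarray, parts: dict, tau: int = 15) -> PhiResult:
    """Convenience: shrinkage covariances at lag ``tau`` (samples) + MIP search."""
    cov_t, cov_cross, cov_lag = lagged_covariances(x, tau)
    return find_mip(cov_t, cov_cross, cov_lag, parts)


# ---------------------------------------------------------------------------
# Time courses and MIP association

def phi_timecourse(event_arrays: list, fs: float, parts: dict, tau: int = 15,
                   window: float = 1.0, stride: float = 0.1,
                   t_range: tuple[float, float] = (-10.5, 4.5)):
    """Sliding-window Phi* aligned to event onset, z-scored per event.

    ``event_arrays`` holds one channels x samples array per event, spanning
    ``t_range`` (seconds relative to onset) at rate ``fs``.  Events whose
    array does not cover the range are dropped.  Returns (times, mean z-scored
    Phi*, MIP label per window per event).
    """
    w = int(window * fs)
    need = int(round((t_range[1] - t_range[0]) * fs))
    starts = np.arange(0, need - w + 1, int(stride * fs))
    times = t_range[0] + (starts + w / 2) / fs
    per_event = []
    mips = []
    for arr in event_arrays:
        if arr.shape[1] < need:
            import warnings
            warnings.warn("event array does not cover the alignment range; dropped")
            continue
        vals = np.empty(len(starts))
        ev_mips = []
        ok = True
        for j, s in enumerate(starts):
            seg = arr[:, s:s + w]
            if np.any(seg.std(axis=1) < 1e-12):
                ok = False
                break
            res = phi_from_data(seg, parts, tau)
            vals[j] = res.phi_star
            ev_mips.append(res.mip)
        if not ok:
            continue
        sd = vals.std()
        per_event.append((vals - vals.mean()) / sd if sd > 0 else vals * 0.0)
        mips.append(ev_mips)
    if not per_event:
        raise ValueError("no usable events")
    return times, np.mean(per_event, axis=0), mips


def mip_type_code(mip: tuple, labels: list) -> int:
    """Fixed integer coding of bipartition types (index in lexicographic list)."""
    table = bipartitions(sorted(labels))
    key = tuple(sorted((tuple(sorted(mip[0])), tuple(sorted(mip[1])))))
    for i, (a, b) in enumerate(table):
        if tuple(sorted((a, b))) == key:
            return i
    raise ValueError("partition not found for the given label set")


def mip_association(mips_by_state: dict) -> dict:
    """Same-side probability of each area pair, per state.

    ``mips_by_state`` maps state name to a list of bipartitions
    ``(side_a, side_b)``.  Returns ``{state: DataFrame}`` of probabilities;
    the diagonal is 1 by construction.
    """
    import pandas as pd
    out = {}
    for state, mips in mips_by_state.items():
        if not mips:
            raise ValueError(f"state {state} has no MIP samples")
        labels = sorted(set(mips[0][0]) | set(mips[0][1]))
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for a, b in mips:
            for side in (a, b):
                for i in side:
                    for j in side:
                        mat.loc[i, j] += 1.0
        out[state] = mat / len(mips)
    return out
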