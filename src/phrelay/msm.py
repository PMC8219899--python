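"""Core-set Markov models with milestoning assignment.

States are core sets confined to the free-energy minima of a projected
space.  Frames between cores are assigned to the last core visited
(milestoning, a committor-function surrogate); frames before the first
core visit are discarded, keeping the assignment causal.  Transition
counts use a sliding window at lag tau and never cross replica
boundaries.  The reversible estimator symmetrizes the count matrix,
``C' = (C + C^T)/2``, and row-normalizes; its spectrum is real, and
implied timescales follow ``t_i = -tau / ln(lambda_{i+1})``.  The
lag-time convergence test flags processes whose timescales drift with
tau, the standard check that the state definition resolves the slow
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

UNASSIGNED = -1


def milestone_assign(core_labels: list[np.ndarray]) -> list[np.ndarray]:
    """Fill non-core frames with the last visited core (per replica).

    Input arrays hold a core id per frame or -1 outside all cores.
    Frames before the first core visit stay -1 (excluded from counting).
    A replica that never enters any core is dropped with a warning.
    """
    out = []
    for rep, lab in enumerate(core_labels):
        lab = np.asarray(lab, dtype=int)
        if (lab < 0).all():
            warn(f"replica {rep} never visits a core; excluded")
            continue
        filled = lab.copy()
        last = UNASSIGNED
        for t in range(len(filled)):
            if filled[t] >= 0:
                last = filled[t]
            else:
                filled[t] = last
        out.append(filled)
    return out


def count_transitions(core_trajs: list[np.ndarray], lag_frames: int,
                      n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts C_ij at the given lag (frames).

    Pairs involving an unassigned frame (-1) are skipped; counts are
    summed over replicas, never across replica boundaries.
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    if n_states is None:
        n_states = int(max((t.max() for t in core_trajs if len(t)), default=-1)) + 1
    if all(len(t) <= lag_frames for t in core_trajs):
        raise ValueError(f"lag {lag_frames} frames is not shorter than any "
                         "trajectory")
    counts = np.zeros((n_states, n_states), dtype=float)
    for lab in core_trajs:
        lab = np.asarray(lab, dtype=int)
        if len(lab) <= lag_frames:
            continue
        a, b = lab[:-lag_frames], lab[lag_frames:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


@dataclass
class CoreSetModel:
    """Estimated transition matrix on the active (connected) core set."""

    lag_ns: float
    counts: np.ndarray              # full count matrix, cores x cores
    transition_matrix: np.ndarray   # row-stochastic, on active set
    stationary: np.ndarray          # pi on active set
    eigenvalues: np.ndarray         # sorted descending, lambda_1 = 1
    active_set: np.ndarray          # core ids in the active set
    reversible: bool = True

    @property
    def implied_timescales_ns(self) -> np.ndarray:
        """t_i = -tau/ln(lambda_{i+1}); NaN where lambda is outside (0, 1)."""
        lam = np.asarray(self.eigenvalues)[1:]
        real = lam.real
        out = np.full(real.shape, np.nan)
        ok = (np.abs(lam.imag) < 1e-10 if np.iscomplexobj(lam)
              else np.ones(real.shape, bool)) & (real > 0) & (real < 1)
        out[ok] = -self.lag_ns / np.log(real[ok])
        return out


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    graph = csr_matrix((counts > 0).astype(int))
    n_comp, comp = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(comp, minlength=n_comp)
    # among largest components prefer the one with most counts
    best = None
    for c in np.flatnonzero(sizes == sizes.max()):
        idx = np.flatnonzero(comp == c)
        w = counts[np.ix_(idx, idx)].sum()
        if best is None or w > best[1]:
            best = (idx, w)
    return best[0]


def estimate_T(counts: np.ndarray, lag_ns: float, reversible: bool = True
               ) -> CoreSetModel:
    """Estimate a row-stochastic transition matrix from transition counts.

    The model is restricted to the largest strongly connected component
    of the directed count graph.  In reversible mode the counts are
    symmetrized before normalization, which guarantees a real spectrum
    and detailed balance with respect to the stationary distribution.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    active = _largest_scc(counts)
    sub = counts[np.ix_(active, active)]
    if sub.sum() == 0:
        raise ValueError("empty active set: no transitions observed")
    c_eff = 0.5 * (sub + sub.T) if reversible else sub
    rows = c_eff.sum(axis=1)
    if (rows == 0).any():
        raise ValueError("state with no outgoing counts in active set")
    t_mat = c_eff / rows[:, None]
    if reversible:
        # detailed balance: pi_i proportional to symmetrized row sums
        pi = rows / rows.sum()
        # real spectrum via the symmetric similarity transform
        sqrt_pi = np.sqrt(pi)
        sym = (sqrt_pi[:, None] * t_mat) / sqrt_pi[None, :]
        evals = np.linalg.eigvalsh(0.5 * (sym + sym.T))
    else:
        evals = np.linalg.eigvals(t_mat)
        vals, vecs = np.linalg.eig(t_mat.T)
        lead = np.argmax(vals.real)
        pi = np.abs(vecs[:, lead].real)
        pi = pi / pi.sum()
    order = np.argsort(np.asarray(evals).real)[::-1]
    evals = np.asarray(evals)[order]
    if reversible:
        evals = evals.real
    return CoreSetModel(lag_ns, counts, t_mat, pi, evals, active, reversible)


def implied_timescales(core_trajs: list[np.ndarray], lags_frames: list[int],
                       frame_interval_ns: float, n_processes: int | None = None,
                       reversible: bool = True, tolerance: float = 0.20
                       ) -> pd.DataFrame:
    """Implied-timescale table over a lag ladder, with convergence flags.

    For each process i the flag is True when the relative spread of
    t_i(tau) over the upper half of the lag ladder stays within
    ``tolerance`` (default 20%) — the practical Markovianity criterion:
    implied timescales of a well-discretized model are lag-independent.
    """
    if len(lags_frames) < 2:
        raise ValueError("need at least 2 lags for a convergence test")
    lags_frames = sorted(lags_frames)
    rows = {}
    for lag in lags_frames:
        counts = count_transitions(core_trajs, lag)
        model = estimate_T(counts, lag * frame_interval_ns, reversible)
        rows[lag] = model.implied_timescales_ns
    n_avail = min(len(v) for v in rows.values())
    if n_processes is None:
        n_processes = n_avail
    n_processes = min(n_processes, n_avail)
    table = pd.DataFrame(
        {f"t{i + 1}_ns": [rows[lag][i] for lag in lags_frames]
         for i in range(n_processes)},
        index=pd.Index([lag * frame_interval_ns for lag in lags_frames],
                       name="lag_ns"))
    upper = table.iloc[len(lags_frames) // 2:]
    flags = {}
    for col in table.columns:
        vals = upper[col].to_numpy()
        if np.isnan(vals).any() or (vals <= 0).any():
            flags[col] = False
        else:
            flags[col] = bool((vals.max() - vals.min()) / vals.mean() <= tolerance)
    table.attrs["converged"] = flags
    return table


def assign_interval_cores(positions: np.ndarray,
                          centers: list[float] | np.ndarray,
                          half_width: float) -> np.ndarray:
    """Core labels for a 1D coordinate: inside |x - center| <= half_width.

    Convenience for 1D model systems where cores sit at known well
    bottoms; overlapping intervals are resolved toward the nearest
    center.
    """
    x = np.asarray(positions, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float)
    dist = np.abs(x[:, None] - centers[None, :])
    nearest = dist.argmin(axis=1)
    labels = np.where(dist[np.arange(len(x)), nearest] <= half_width,
                      nearest, UNASSIGNED)
    return labels.astype(int)
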