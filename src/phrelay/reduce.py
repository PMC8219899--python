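"""Linear dimensionality reduction and free-energy surfaces.

Two projections are provided.  PCA diagonalizes the pooled covariance of
mean-centered features and is fitted jointly across ensembles so that
both protonation states live in one comparable space.  tICA solves the
generalized eigenproblem ``C(tau) v = lambda C(0) v`` with a symmetrized
time-lagged covariance, yielding the slowly varying coordinates; the
implied relaxation time of component i is ``-tau / ln(lambda_i)``.

Free-energy surfaces are 2D histograms of projected frames converted to
``F = -kT ln p`` with the minimum shifted to zero; empty bins are masked
(+inf), never interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from phrelay.containers import FeatureTrajectory, stack_values


@dataclass
class LinearProjection:
    """A fitted linear map from feature space to component space."""

    kind: str                      # "pca" | "tica"
    mean: np.ndarray               # (n_features,)
    components: np.ndarray         # (n_features, n_components), columns are modes
    eigenvalues: np.ndarray        # sorted descending
    feature_names: list[str]
    lag_ns: float | None = None    # tica only
    total_variance: float | None = None  # pca only: trace of covariance

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.kind != "pca" or self.total_variance is None:
            raise ValueError("explained variance defined for PCA only")
        return self.eigenvalues / self.total_variance

    def timescales(self, clip: float = 1e-12) -> np.ndarray:
        """Relaxation timescales -tau/ln(lambda) in ns (tICA only)."""
        if self.kind != "tica" or self.lag_ns is None:
            raise ValueError("timescales defined for tICA only")
        lam = np.clip(self.eigenvalues, clip, 1.0 - clip)
        return -self.lag_ns / np.log(lam)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"kind": self.kind, "feature_names": self.feature_names,
                "lag_ns": self.lag_ns, "total_variance": self.total_variance}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        np.savetxt(path.with_suffix(".mean.csv"), self.mean[None, :], delimiter=",")
        np.savetxt(path.with_suffix(".components.csv"), self.components, delimiter=",")
        np.savetxt(path.with_suffix(".eigenvalues.csv"), self.eigenvalues[None, :],
                   delimiter=",")


def fit_pca(trajs: list[FeatureTrajectory]) -> LinearProjection:
    """PCA on the pooled, mean-centered frames of all given replicas.

    Trajectories from all ensembles should be passed together to obtain
    a joint component space.  Eigenpairs with numerically zero variance
    (rank deficiency) are dropped.
    """
    x = stack_values(trajs)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames for PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(np.trace(cov))
    keep = evals > max(1e-12 * max(total, 1.0), 0.0)
    if not keep.all():
        import warnings
        warnings.warn(f"covariance rank-deficient: keeping {int(keep.sum())} of "
                      f"{len(evals)} components")
        evals, evecs = evals[keep], evecs[:, keep]
    return LinearProjection("pca", mean, evecs, evals,
                            trajs[0].feature_names, total_variance=total)


def _lagged_covariances(trajs: list[FeatureTrajectory], lag_frames: int,
                        mean: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    dim = len(mean)
    c0 = np.zeros((dim, dim))
    ct = np.zeros((dim, dim))
    n = 0
    for t in trajs:
        x = t.values - mean
        a, b = x[:-lag_frames], x[lag_frames:]
        # symmetrized (forward + backward) estimator -> real spectrum
        c0 += 0.5 * (a.T @ a + b.T @ b)
        ct += 0.5 * (a.T @ b + b.T @ a)
        n += a.shape[0]
    return c0 / n, ct / n, n


def fit_tica(trajs: list[FeatureTrajectory], lag_ns: float,
             epsilon_scale: float = 1e-6) -> LinearProjection:
    """tICA at lag ``lag_ns`` on mean-centered features.

    The instantaneous covariance is regularized with ``eps * I`` where
    ``eps = epsilon_scale * trace(C0) / dim``, so perfectly collinear
    features remain well posed.  Eigenvalues are sorted descending; for
    a reversible process they estimate autocorrelations exp(-tau/t_i).
    """
    interval = trajs[0].frame_interval_ns
    lag_frames = int(round(lag_ns / interval))
    if lag_frames < 1 or abs(lag_frames * interval - lag_ns) > 1e-9 * max(lag_ns, 1):
        raise ValueError(f"lag {lag_ns} ns is not a positive multiple of the "
                         f"frame interval {interval} ns")
    too_short = [t.replica_id for t in trajs if t.n_frames <= lag_frames]
    if too_short:
        raise ValueError(f"lag {lag_ns} ns not shorter than replicas: {too_short}")
    x = stack_values(trajs)
    mean = x.mean(axis=0)
    c0, ct, _ = _lagged_covariances(trajs, lag_frames, mean)
    dim = c0.shape[0]
    eps = epsilon_scale * np.trace(c0) / dim
    c0reg = c0 + eps * np.eye(dim)
    evals, evecs = scipy.linalg.eigh(ct, c0reg)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return LinearProjection("tica", mean, evecs, evals,
                            trajs[0].feature_names, lag_ns=lag_ns)


def project(model: LinearProjection, traj: FeatureTrajectory,
            n_components: int | None = None) -> FeatureTrajectory:
    """Project a FeatureTrajectory into component space, preserving frame order."""
    if traj.feature_names != model.feature_names:
        missing = [n for n in model.feature_names if n not in traj.feature_names]
        raise ValueError(f"feature mismatch; model features absent from input: "
                         f"{missing or traj.feature_names}")
    comp = model.components if n_components is None else model.components[:, :n_components]
    y = (traj.values - model.mean) @ comp
    prefix = "pc" if model.kind == "pca" else "tic"
    cols = [f"{prefix}{i + 1}" for i in range(y.shape[1])]
    return FeatureTrajectory(pd.DataFrame(y, columns=cols),
                             traj.frame_interval_ns, traj.replica_id, traj.ensemble)


@dataclass
class EnergySurface2D:
    """Free energy (kT units) on a 2D grid of projected coordinates."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    population: np.ndarray        # sums to 1
    free_energy: np.ndarray       # -kT ln p, min 0; empty bins +inf
    ensemble: str | None = None

    def to_frame(self) -> pd.DataFrame:
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return pd.DataFrame({
            "bin_x": gx.ravel(), "bin_y": gy.ravel(),
            "population": self.population.ravel(),
            "free_energy": self.free_energy.ravel(),
        })


def energy_surface(projected: list[FeatureTrajectory], bins: int = 50,
                   kT: float = 1.0, components: tuple[str, str] | None = None,
                   ranges=None, ensemble: str | None = None) -> EnergySurface2D:
    """2D population histogram and free-energy surface of pooled frames.

    ``components`` selects the two columns (defaults to the first two).
    """
    x = stack_values(projected)
    names = projected[0].feature_names
    if components is None:
        if x.shape[1] < 2:
            raise ValueError("need 2 components for a 2D surface")
        ci, cj = 0, 1
    else:
        ci, cj = names.index(components[0]), names.index(components[1])
    h, ex, ey = np.histogram2d(x[:, ci], x[:, cj], bins=bins, range=ranges)
    pop = h / h.sum()
    with np.errstate(divide="ignore"):
        f = -kT * np.log(pop)
    f -= f[np.isfinite(f)].min()
    return EnergySurface2D(ex, ey, pop, f, ensemble)


def difference_density(surf_a: EnergySurface2D, surf_b: EnergySurface2D
                       ) -> np.ndarray:
    """Difference of the underlying probability densities, pA - pB.

    Requires the two surfaces to share bin edges; rebin upstream if not.
    """
    if (surf_a.population.shape != surf_b.population.shape
            or not np.allclose(surf_a.edges_x, surf_b.edges_x)
            or not np.allclose(surf_a.edges_y, surf_b.edges_y)):
        raise ValueError("surfaces are on different grids; use "
                         "compare_ensembles to histogram on a shared support")
    return surf_a.population - surf_b.population


def compare_ensembles(projected_a: list[FeatureTrajectory],
                      projected_b: list[FeatureTrajectory], bins: int = 50,
                      kT: float = 1.0,
                      labels: tuple[str | None, str | None] = (None, None)
                      ) -> tuple[EnergySurface2D, EnergySurface2D, np.ndarray]:
    """Surfaces for two ensembles on the union support, plus pA - pB."""
    xa = stack_values(projected_a)[:, :2]
    xb = stack_values(projected_b)[:, :2]
    both = np.vstack([xa, xb])
    ranges = [(both[:, 0].min(), both[:, 0].max()),
              (both[:, 1].min(), both[:, 1].max())]
    sa = energy_surface(projected_a, bins, kT, ranges=ranges, ensemble=labels[0])
    sb = energy_surface(projected_b, bins, kT, ranges=ranges, ensemble=labels[1])
    return sa, sb, difference_density(sa, sb)
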