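"""Per-frame structural features from coordinate trajectories.

Reads standard MD formats through :mod:`mdtraj` and computes the scalar
observables the downstream analyses consume: atom-pair and group-minimum
distances, geometric hydrogen bonds with per-ensemble occupancies,
C-alpha RMSF, fitted RMSD time series, and replica-bootstrap histogram
bands.

Conventions
-----------
All distances are in nm (mdtraj native).  Hydrogen bonds use the common
geometric criterion: donor-acceptor distance <= ``d_cut`` (default
0.35 nm) and hydrogen-donor-acceptor angle <= ``angle_cut`` (default
30 degrees); both cutoffs are configurable and echoed in outputs.
Occupancies and population fractions pool frames with equal weight
across replicas; histograms are computed per replica first and the
confidence band resamples replicas (not frames) to respect
within-trajectory correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import mdtraj as md
import numpy as np
import pandas as pd

from phrelay.containers import FeatureTrajectory

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_BACKBONE_NAMES = {"N", "H", "C", "O", "CA", "HA", "OXT"}


@dataclass(frozen=True)
class HBondSpec:
    """One candidate hydrogen bond, named by its donor/acceptor atoms.

    Selectors are mdtraj atom-selection expressions that must resolve to
    exactly one atom each.  ``label`` follows the residue + s/m
    convention for side-/main-chain participation, e.g. ``"K257s-D308s"``.
    """

    donor: str
    hydrogen: str
    acceptor: str
    label: str


def load_trajectory(topology: str | Path, frames: str | Path | list | None = None
                    ) -> md.Trajectory:
    """Load a coordinate trajectory; positions are returned in nm.

    ``topology`` may be a PDB/GRO file; ``frames`` an XTC/DCD/multi-model
    PDB file (or list of files) sharing the topology's atom set.  mdtraj
    applies the Angstrom -> nm conversion for PDB input.
    """
    topology = str(topology)
    if frames is None:
        return md.load(topology)
    if not isinstance(frames, (list, tuple)):
        frames = [frames]
    top = md.load_topology(topology)
    try:
        return md.load([str(f) for f in frames], top=top)
    except ValueError as err:
        # re-raise with both atom counts visible for quick diagnosis
        n_top = top.n_atoms
        raise ValueError(
            f"topology ({n_top} atoms) incompatible with frame files "
            f"{[str(f) for f in frames]}: {err}") from err


def _resolve_one(traj: md.Trajectory, selector: str) -> int:
    idx = traj.topology.select(selector)
    if len(idx) != 1:
        raise ValueError(
            f"selector {selector!r} resolves to {len(idx)} atoms, expected 1")
    return int(idx[0])


def residue_selection(traj_or_top, token: str) -> np.ndarray:
    """Map a compact residue token like ``"K257s"`` to atom indices.

    The trailing letter selects the side chain (``s``: non-backbone heavy
    atoms plus hydrogens bonded to side-chain N/O/S) or the main chain
    (``m``: N, H, C, O).  The one-letter residue code is checked against
    the topology.
    """
    top = getattr(traj_or_top, "topology", traj_or_top)
    if len(token) < 3 or token[-1] not in "sm":
        raise ValueError(f"bad residue token {token!r}; expected e.g. 'K257s'")
    code, resseq, part = token[0].upper(), int(token[1:-1]), token[-1]
    residues = [r for r in top.residues if r.resSeq == resseq]
    if not residues:
        raise ValueError(f"residue {resseq} not found in topology")
    res = residues[0]
    actual = _THREE_TO_ONE.get(res.name.upper(), "X")
    if actual != code:
        raise ValueError(
            f"residue {resseq} is {res.name} ({actual}), token says {code}")
    if part == "m":
        atoms = [a for a in res.atoms if a.name in ("N", "H", "C", "O")]
    else:
        heavy = [a for a in res.atoms
                 if a.name not in _BACKBONE_NAMES and a.element.symbol != "H"]
        polar = {a.index for a in heavy if a.element.symbol in ("N", "O", "S")}
        hyd = [a for b in top.bonds for a in (b[0], b[1])
               if a.element.symbol == "H"
               and (b[0].index in polar or b[1].index in polar)
               and a.residue == res]
        atoms = heavy + hyd
    if not atoms:
        raise ValueError(f"token {token!r} selects no atoms")
    return np.array(sorted(a.index for a in atoms), dtype=int)


def superpose(traj: md.Trajectory, reference: md.Trajectory | None = None,
              ref_frame: int = 0, selection: str = "name CA") -> md.Trajectory:
    """Least-squares rigid-body fit of every frame onto a reference.

    Returns a fitted copy; the input is not modified.  The fit uses the
    Kabsch algorithm over ``selection``, which must contain at least
    three atoms.
    """
    ref = reference if reference is not None else traj
    idx = traj.topology.select(selection)
    if len(idx) < 3:
        raise ValueError(
            f"selection {selection!r} yields {len(idx)} atoms; "
            "need >= 3 for a rigid-body fit")
    out = md.Trajectory(traj.xyz.copy(), traj.topology,
                        time=traj.time.copy() if traj.time is not None else None)
    out.superpose(ref, frame=ref_frame, atom_indices=idx)
    return out


def compute_distances(traj: md.Trajectory,
                      pairs: dict[str, tuple[str, str]],
                      frame_interval_ns: float = 1.0,
                      replica_id: str = "0",
                      ensemble: str | None = None) -> FeatureTrajectory:
    """Euclidean atom-pair distances in nm.

    ``pairs`` maps feature name -> (selector_a, selector_b); each selector
    must resolve to exactly one atom.
    """
    cols = {}
    for name, (sa, sb) in pairs.items():
        ia, ib = _resolve_one(traj, sa), _resolve_one(traj, sb)
        d = traj.xyz[:, ia, :] - traj.xyz[:, ib, :]
        cols[name] = np.sqrt((d * d).sum(axis=1))
    return FeatureTrajectory(pd.DataFrame(cols), frame_interval_ns,
                             replica_id, ensemble)


def compute_min_distances(traj: md.Trajectory,
                          groups: dict[str, tuple[str, str]],
                          frame_interval_ns: float = 1.0,
                          replica_id: str = "0",
                          ensemble: str | None = None) -> FeatureTrajectory:
    """Per-frame minimum distance between two atom groups.

    ``groups`` maps feature name -> (selection_a, selection_b); each
    selection may match several atoms (e.g. the two side-chain N atoms of
    a histidine against the ion).
    """
    cols = {}
    for name, (sa, sb) in groups.items():
        ia = traj.topology.select(sa)
        ib = traj.topology.select(sb)
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"group selector for {name!r} matched no atoms "
                             f"({sa!r}: {len(ia)}, {sb!r}: {len(ib)})")
        diff = traj.xyz[:, ia, None, :] - traj.xyz[:, None, ib, :]
        dist = np.sqrt((diff * diff).sum(axis=-1))
        cols[name] = dist.reshape(traj.n_frames, -1).min(axis=1)
    return FeatureTrajectory(pd.DataFrame(cols), frame_interval_ns,
                             replica_id, ensemble)


def detect_hbonds(traj: md.Trajectory, specs: list[HBondSpec],
                  d_cut: float = 0.35, angle_cut: float = 30.0,
                  frame_interval_ns: float = 1.0, replica_id: str = "0",
                  ensemble: str | None = None
                  ) -> tuple[FeatureTrajectory, dict[str, float]]:
    """Geometric hydrogen-bond detection.

    A bond is present in a frame iff the donor-acceptor distance is
    <= ``d_cut`` (nm) and the hydrogen-donor-acceptor angle (vertex at
    the donor) is <= ``angle_cut`` (degrees).  Returns per-frame 0/1
    features plus the occupancy (fraction of frames present) per label.
    """
    if d_cut <= 0:
        raise ValueError("d_cut must be > 0")
    if not (0 < angle_cut <= 90):
        raise ValueError("angle_cut must be in (0, 90] degrees")
    cols = {}
    occupancy = {}
    for spec in specs:
        i_d = _resolve_one(traj, spec.donor)
        i_a = _resolve_one(traj, spec.acceptor)
        try:
            i_h = _resolve_one(traj, spec.hydrogen)
        except ValueError as err:
            raise ValueError(
                f"hydrogen atom missing for donor of {spec.label!r}: {err}"
            ) from err
        da = traj.xyz[:, i_a, :] - traj.xyz[:, i_d, :]
        dh = traj.xyz[:, i_h, :] - traj.xyz[:, i_d, :]
        dist = np.sqrt((da * da).sum(axis=1))
        cosang = (da * dh).sum(axis=1) / np.maximum(
            dist * np.sqrt((dh * dh).sum(axis=1)), 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        present = (dist <= d_cut) & (ang <= angle_cut)
        cols[spec.label] = present.astype(int)
        occupancy[spec.label] = float(present.mean())
    feats = FeatureTrajectory(pd.DataFrame(cols), frame_interval_ns,
                              replica_id, ensemble)
    return feats, occupancy


def pooled_occupancy(per_replica: list[FeatureTrajectory]) -> dict[str, float]:
    """Bond occupancy pooled over replicas with equal weight per frame."""
    names = per_replica[0].feature_names
    stacked = np.vstack([t.values for t in per_replica])
    return {n: float(stacked[:, i].mean()) for i, n in enumerate(names)}


def rmsf(traj: md.Trajectory, selection: str = "name CA") -> pd.DataFrame:
    """Per-atom root-mean-square fluctuation about the mean structure, nm.

    The trajectory must already be superposed.  Returns a table with
    residue number, atom name and RMSF.  A single-frame input has no
    defined fluctuation and is rejected.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single-frame trajectory")
    idx = traj.topology.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    xyz = traj.xyz[:, idx, :]
    mean = xyz.mean(axis=0)
    val = np.sqrt(((xyz - mean) ** 2).sum(axis=2).mean(axis=0))
    atoms = [traj.topology.atom(i) for i in idx]
    return pd.DataFrame({
        "resSeq": [a.residue.resSeq for a in atoms],
        "atom": [a.name for a in atoms],
        "rmsf_nm": val,
    })


def rmsd_timeseries(traj: md.Trajectory, reference: md.Trajectory,
                    selection: str = "name CA", ref_frame: int = 0,
                    frame_interval_ns: float = 1.0, replica_id: str = "0",
                    ensemble: str | None = None,
                    name: str = "rmsd") -> FeatureTrajectory:
    """Per-frame least-squares-fitted RMSD over ``selection``, nm."""
    idx = traj.topology.select(selection)
    if len(idx) < 3:
        raise ValueError(
            f"selection {selection!r} yields {len(idx)} atoms; need >= 3")
    val = md.rmsd(traj, reference, frame=ref_frame, atom_indices=idx)
    return FeatureTrajectory(pd.DataFrame({name: val.astype(float)}),
                             frame_interval_ns, replica_id, ensemble)


@dataclass
class HistogramWithCI:
    """Mean-of-replicas histogram with a percentile bootstrap band."""

    bin_edges: np.ndarray
    mean_density: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    n_bootstrap: int
    ci_level: float

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None


def histogram_with_bootstrap(samples_per_replica: list[np.ndarray],
                             bins: int | np.ndarray = 50,
                             n_boot: int = 1000, ci: float = 95.0,
                             seed: int | None = None) -> HistogramWithCI:
    """Replica-mean density histogram with a bootstrap confidence band.

    Each replica is histogrammed on common bin edges and normalized to
    unit integral; the band is the percentile interval of the replica
    mean under resampling replicas with replacement (``n_boot`` samples).
    With a single replica the mean is returned and the band flagged
    unavailable.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in samples_per_replica]
    if not samples:
        raise ValueError("no replicas given")
    pooled = np.concatenate(samples)
    edges = np.histogram_bin_edges(pooled, bins=bins)
    dens = np.vstack([np.histogram(s, bins=edges, density=True)[0]
                      for s in samples])
    mean = dens.mean(axis=0)
    if len(samples) < 2:
        return HistogramWithCI(edges, mean, None, None, 0, ci)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(samples), size=(n_boot, len(samples)))
    boot_means = dens[pick].mean(axis=1)
    alpha = (100.0 - ci) / 2.0
    lo = np.percentile(boot_means, alpha, axis=0)
    hi = np.percentile(boot_means, 100.0 - alpha, axis=0)
    # the band quantifies bootstrap spread; it must bracket the point estimate
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    return HistogramWithCI(edges, mean, lo, hi, n_boot, ci)


def population_fraction(values_per_replica: list[np.ndarray], threshold: float,
                        side: str = "below") -> float:
    """Fraction of frames below (or above) a threshold, pooled over replicas."""
    if side not in ("below", "above"):
        raise ValueError("side must be 'below' or 'above'")
    pooled = np.concatenate([np.asarray(v, dtype=float).ravel()
                             for v in values_per_replica])
    if pooled.size == 0:
        raise ValueError("no frames given")
    if side == "below":
        return float((pooled < threshold).mean())
    return float((pooled > threshold).mean())
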