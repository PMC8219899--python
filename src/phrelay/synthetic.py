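"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's data —
metastable conformational dynamics, constant-velocity pulling traces
with planted rupture events, right-censored exponential unfolding times,
one-site titration heats, per-frame pKa records with planted
carboxyl-carboxyl coupling, and a toy coordinate trajectory with a
scheduled hydrogen-bond occupancy per hidden state.  None of them aims
at force-field realism; they provide controllable truth so the analysis
code can be validated quantitatively.

Every generator is fully determined by its seed and records its planted
values in a :class:`GroundTruth` sidecar; no generated artifact exists
without recorded truth.  Units: nm, ns, K, kJ/mol, kJ/(mol nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import exp, log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from phrelay.containers import FeatureTrajectory
from phrelay.kinetics import SurvivalData
from phrelay.pka import PkaRecord
from phrelay.rupture import ForceTrace
from phrelay.thermo import LOW_C_THRESHOLD, one_site_heats

#: Boltzmann constant in kJ/(mol K) (gas constant / 1000).
KB_KJ_MOL_K = 0.008314


@dataclass
class GroundTruth:
    """Planted values of one generated artifact, with the seed that made it."""

    generator: str
    seed: int
    values: dict

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")
        Path(path).write_text(json.dumps(
            {"generator": self.generator, "seed": self.seed,
             "values": self.values}, indent=1, default=_default))


# --- overdamped Langevin dynamics -----------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """1D/2D model potential plus thermostat parameters.

    kinds: ``harmonic`` (stiffness kJ/(mol nm^2), center nm),
    ``double_well_1d`` (barrier kJ/mol at x=0, minima at +/-half_distance),
    ``triple_well_2d`` (three Gaussian wells on a harmonic background).
    ``friction`` is the overdamped drag in kJ ns/(mol nm^2).
    """

    kind: str
    parameters: dict
    temperature_k: float = 300.0
    friction: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.kind == "double_well_1d" and self.parameters.get("barrier", 1.0) <= 0:
            raise ValueError("barrier height must be > 0")

    @property
    def kT(self) -> float:
        return KB_KJ_MOL_K * self.temperature_k

    @property
    def ndim(self) -> int:
        return 2 if self.kind == "triple_well_2d" else 1

    def potential(self, x: np.ndarray) -> np.ndarray:
        p = self.parameters
        if self.kind == "harmonic":
            return 0.5 * p["stiffness"] * (x - p.get("center", 0.0)) ** 2
        if self.kind == "double_well_1d":
            a = p.get("half_distance", 1.0)
            return p["barrier"] * ((x / a) ** 2 - 1.0) ** 2
        if self.kind == "triple_well_2d":
            x = np.atleast_2d(x)
            u = 0.5 * p.get("confinement", 2.0) * (x ** 2).sum(axis=-1)
            for cx, cy, depth, width in p["wells"]:
                r2 = (x[..., 0] - cx) ** 2 + (x[..., 1] - cy) ** 2
                u = u - depth * np.exp(-r2 / (2 * width ** 2))
            return u
        raise ValueError(f"unknown potential kind {self.kind!r}")

    def gradient(self, x):
        p = self.parameters
        if self.kind == "harmonic":
            return p["stiffness"] * (x - p.get("center", 0.0))
        if self.kind == "double_well_1d":
            a = p.get("half_distance", 1.0)
            return 4.0 * p["barrier"] / a ** 2 * x * ((x / a) ** 2 - 1.0)
        if self.kind == "triple_well_2d":
            g = p.get("confinement", 2.0) * np.asarray(x, dtype=float)
            for cx, cy, depth, width in p["wells"]:
                dx = np.asarray(x, dtype=float) - np.array([cx, cy])
                r2 = (dx ** 2).sum(axis=-1)
                g = g + depth / width ** 2 * dx * np.exp(-r2 / (2 * width ** 2))[..., None]
            return g
        raise ValueError(f"unknown potential kind {self.kind!r}")

    def max_stiffness(self) -> float:
        """Upper bound on |U''| used for the integrator stability check."""
        p = self.parameters
        if self.kind == "harmonic":
            return p["stiffness"]
        if self.kind == "double_well_1d":
            a = p.get("half_distance", 1.0)
            return 8.0 * p["barrier"] / a ** 2     # curvature at the minima
        if self.kind == "triple_well_2d":
            return p.get("confinement", 2.0) + max(
                d / w ** 2 for _, _, d, w in p["wells"])
        raise ValueError(self.kind)


def generate_langevin(spec: PotentialSpec, n_steps: int, dt_ns: float,
                      seed: int, x0=None, save_every: int = 1,
                      ) -> tuple[FeatureTrajectory, GroundTruth]:
    """Euler-Maruyama overdamped Langevin trajectory.

    dx = -grad U / gamma dt + sqrt(2 kT dt / gamma) xi.  The stationary
    density is proportional to exp(-U/kT).  An unstable step size
    (dt * max|U''| / gamma >= 0.1) is rejected up front rather than
    allowed to diverge silently.  The ground truth carries the slowest
    relaxation timescale from the fine-grid propagator oracle for 1D
    potentials.
    """
    stability = dt_ns * spec.max_stiffness() / spec.friction
    if stability >= 0.1:
        raise ValueError(
            f"unstable step: dt*stiffness/friction = {stability:.3g} >= 0.1; "
            "reduce dt")
    rng = np.random.default_rng(seed)
    ndim = spec.ndim
    kT = spec.kT
    drift = dt_ns / spec.friction
    sigma = sqrt(2.0 * kT * dt_ns / spec.friction)
    if x0 is None:
        if spec.kind == "harmonic":
            x0 = spec.parameters.get("center", 0.0)
        elif spec.kind == "double_well_1d":
            x0 = -spec.parameters.get("half_distance", 1.0)
        else:
            w = spec.parameters["wells"][0]
            x0 = np.array([w[0], w[1]])
    n_out = n_steps // save_every
    if ndim == 1:
        out = _langevin_1d(spec, float(x0), n_steps, drift, sigma, rng,
                           save_every)
        df = pd.DataFrame({"x": out})
    else:
        x = np.asarray(x0, dtype=float).copy()
        out = np.empty((n_out, 2))
        chunk = 65536
        pos = 0
        saved = 0
        noise = None
        for step in range(n_steps):
            if noise is None or pos >= chunk:
                noise = rng.standard_normal((chunk, 2))
                pos = 0
            x = x - spec.gradient(x) * drift + sigma * noise[pos]
            pos += 1
            if (step + 1) % save_every == 0:
                out[saved] = x
                saved += 1
        df = pd.DataFrame(out, columns=["x", "y"])
    truth_vals: dict = {"kind": spec.kind, "dt_ns": dt_ns, "n_steps": n_steps,
                        "temperature_k": spec.temperature_k,
                        "friction": spec.friction,
                        "parameters": spec.parameters}
    if spec.kind == "harmonic":
        truth_vals["position_variance_nm2"] = kT / spec.parameters["stiffness"]
    if spec.kind == "double_well_1d":
        truth_vals["slowest_timescale_ns"] = grid_relaxation_timescale(
            spec, dt_ns)
    traj = FeatureTrajectory(df, frame_interval_ns=dt_ns * save_every,
                             replica_id=str(seed))
    return traj, GroundTruth("generate_langevin", seed, truth_vals)


def _langevin_1d(spec: PotentialSpec, x0: float, n_steps: int, drift: float,
                 sigma: float, rng: np.random.Generator, save_every: int
                 ) -> np.ndarray:
    p = spec.parameters
    out = np.empty(n_steps // save_every)
    x = x0
    saved = 0
    chunk = 262144
    done = 0
    if spec.kind == "double_well_1d":
        a = p.get("half_distance", 1.0)
        coef = 4.0 * p["barrier"] / a ** 2
        inv_a2 = 1.0 / (a * a)
        while done < n_steps:
            noise = rng.standard_normal(min(chunk, n_steps - done))
            for z in noise:
                x = x - coef * x * (x * x * inv_a2 - 1.0) * drift + sigma * z
                done += 1
                if done % save_every == 0:
                    out[saved] = x
                    saved += 1
    else:  # harmonic
        k = p["stiffness"]
        c = p.get("center", 0.0)
        while done < n_steps:
            noise = rng.standard_normal(min(chunk, n_steps - done))
            for z in noise:
                x = x - k * (x - c) * drift + sigma * z
                done += 1
                if done % save_every == 0:
                    out[saved] = x
                    saved += 1
    return out


def grid_relaxation_timescale(spec: PotentialSpec, dt_ns: float,
                              n_bins: int = 500, span: float = 2.2) -> float:
    """Slowest relaxation timescale of the discretized 1D dynamics.

    Independent oracle for the Markov-model stages: the one-step
    Euler-Maruyama transition density (a Gaussian centered on the drift
    update) is integrated over a uniform bin grid, the row-normalized
    propagator diagonalized, and the timescale read off the second
    eigenvalue as -dt / ln(lambda_2).
    """
    if spec.ndim != 1:
        raise ValueError("grid oracle implemented for 1D potentials")
    a = spec.parameters.get("half_distance", 1.0)
    lo, hi = -span * a, span * a
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    drift = dt_ns / spec.friction
    sigma = sqrt(2.0 * spec.kT * dt_ns / spec.friction)
    mean_next = centers - spec.gradient(centers) * drift
    from scipy.stats import norm
    cdf = norm.cdf((edges[None, :] - mean_next[:, None]) / sigma)
    p = np.diff(cdf, axis=1)
    p /= p.sum(axis=1, keepdims=True)
    evals = np.linalg.eigvals(p)
    lam2 = np.sort(evals.real)[-2]
    return float(-dt_ns / log(lam2))


# --- steered-MD force traces ----------------------------------------------

def generate_rupture_traces(loading_rate: float, f_rupture_mean: float,
                            f_rupture_sd: float, noise_sd: float, n: int,
                            seed: int, dt_ns: float = 0.01,
                            condition: str = "", plateau: float = 0.0,
                            relax_ns: float = 0.5
                            ) -> tuple[list[ForceTrace], GroundTruth]:
    """Linear force ramps with planted rupture events.

    Each trace rises as ``loading_rate * t`` with additive Gaussian
    noise until its planted rupture force (drawn from
    ``N(f_rupture_mean, f_rupture_sd)``), then relaxes exponentially to
    a low plateau.  Planted forces and times are recorded in the ground
    truth.
    """
    if loading_rate <= 0:
        raise ValueError("loading rate must be > 0")
    if n < 1:
        raise ValueError("need n >= 1 traces")
    rng = np.random.default_rng(seed)
    planted = f_rupture_mean + f_rupture_sd * rng.standard_normal(n)
    planted = np.maximum(planted, 0.05 * f_rupture_mean)
    traces = []
    for i in range(n):
        t_rup = planted[i] / loading_rate
        t_end = t_rup + max(6.0 * relax_ns, 2.0)
        t = np.arange(dt_ns, t_end, dt_ns)
        f = np.where(t <= t_rup, loading_rate * t,
                     plateau + (planted[i] - plateau)
                     * np.exp(-(t - t_rup) / relax_ns * 5.0))
        if noise_sd > 0:
            f = f + noise_sd * rng.standard_normal(len(t))
        traces.append(ForceTrace(t, f, condition))
    truth = GroundTruth("generate_rupture_traces", seed, {
        "condition": condition, "loading_rate": loading_rate,
        "rupture_forces": planted,
        "rupture_times_ns": planted / loading_rate,
        "noise_sd": noise_sd})
    return traces, truth


# --- unfolding survival times ---------------------------------------------

def generate_unfolding_times(k_per_ns: float, t_max_ns: float, n: int,
                             seed: int, condition: str = "",
                             criterion: str = "rmsd"
                             ) -> tuple[SurvivalData, GroundTruth]:
    """Exponential event times right-censored at ``t_max_ns``.

    ``k = 0`` yields an all-censored batch (no unfolding on the
    simulated horizon).
    """
    if k_per_ns < 0:
        raise ValueError("rate must be >= 0")
    if t_max_ns <= 0:
        raise ValueError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    if k_per_ns == 0:
        times = np.full(n, t_max_ns)
        cens = np.ones(n, dtype=bool)
    else:
        draws = rng.exponential(1.0 / k_per_ns, size=n)
        cens = draws > t_max_ns
        times = np.where(cens, t_max_ns, draws)
    data = SurvivalData(times, cens, criterion, condition)
    truth = GroundTruth("generate_unfolding_times", seed, {
        "k_per_ns": k_per_ns, "t_max_ns": t_max_ns, "n": n,
        "half_life_ns": (log(2) / k_per_ns) if k_per_ns > 0 else float("inf"),
        "expected_censored_fraction": exp(-k_per_ns * t_max_ns)})
    return data, truth


# --- ITC thermograms ------------------------------------------------------

def generate_itc_thermogram(kd_molar: float, dh_kj_mol: float, n_sites: float,
                            cell_conc_molar: float, syringe_conc_molar: float,
                            volumes_ul: np.ndarray, noise_sd_ucal: float,
                            seed: int, cell_volume_ul: float = 200.0
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-injection heats of a one-set-of-sites titration, plus noise.

    Returns a table (injection, volume_ul, heat_ucal) and ground truth
    carrying the planted Kd, dH, n and the Wiseman c-value with its
    low-c flag (c < 5).
    """
    if cell_conc_molar <= 0 or syringe_conc_molar <= 0 or kd_molar <= 0:
        raise ValueError("concentrations and Kd must be > 0")
    volumes_ul = np.asarray(volumes_ul, dtype=float)
    heats = one_site_heats(kd_molar, dh_kj_mol, n_sites, cell_conc_molar,
                           syringe_conc_molar, volumes_ul, cell_volume_ul)
    rng = np.random.default_rng(seed)
    if noise_sd_ucal > 0:
        heats = heats + noise_sd_ucal * rng.standard_normal(len(heats))
    table = pd.DataFrame({"injection": np.arange(1, len(heats) + 1),
                          "volume_ul": volumes_ul, "heat_ucal": heats})
    c = n_sites * cell_conc_molar / kd_molar
    truth = GroundTruth("generate_itc_thermogram", seed, {
        "kd_molar": kd_molar, "dh_kj_mol": dh_kj_mol, "n_sites": n_sites,
        "cell_conc_molar": cell_conc_molar,
        "syringe_conc_molar": syringe_conc_molar,
        "cell_volume_ul": cell_volume_ul,
        "c_value": c, "low_c": c < LOW_C_THRESHOLD,
        "noise_sd_ucal": noise_sd_ucal})
    return table, truth


# --- hydrogen-bond toy trajectory -----------------------------------------

def _toy_topology(bond_names: list[str]):
    """Topology with one donor/hydrogen/acceptor triplet per bond plus a
    reporter atom whose position encodes the hidden state."""
    import mdtraj as md
    top = md.Topology()
    chain = top.add_chain()
    for i, name in enumerate(bond_names):
        res_d = top.add_residue("LYS", chain, resSeq=100 + 2 * i)
        top.add_atom("NZ", md.element.nitrogen, res_d)
        top.add_atom("HZ1", md.element.hydrogen, res_d)
        res_a = top.add_residue("ASP", chain, resSeq=101 + 2 * i)
        top.add_atom("OD1", md.element.oxygen, res_a)
    res_r = top.add_residue("CA", chain, resSeq=999)
    top.add_atom("CA", md.element.calcium, res_r)
    return top


def generate_hbond_toy_trajectory(schedule: dict[int, dict[str, float]],
                                  n_frames: int, seed: int,
                                  stay_prob: float = 0.98,
                                  frame_interval_ns: float = 0.1,
                                  state_centers: np.ndarray | None = None,
                                  reporter_noise_nm: float = 0.05):
    """Toy coordinate trajectory with per-state hydrogen-bond occupancy.

    A hidden Markov chain over ``len(schedule)`` states (uniform switch
    probabilities, self-transition ``stay_prob``) emits, per frame and
    per scheduled bond, a donor/H/acceptor triplet that satisfies the
    geometric bond criterion with the state's occupancy probability:
    satisfied frames place the acceptor 0.28 nm from the donor on the
    D-H axis, broken frames at 0.60 nm.  A reporter atom is emitted
    around a state-specific center so coordinate clustering can recover
    the hidden labels.  Returns (mdtraj.Trajectory, GroundTruth) with
    true labels and occupancies.
    """
    import mdtraj as md
    states = sorted(schedule)
    bonds = sorted({b for st in schedule.values() for b in st})
    for st in schedule.values():
        for occ in st.values():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} outside [0, 1]")
    n_states = len(states)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=int)
    s = 0
    for t in range(n_frames):
        labels[t] = s
        if rng.random() > stay_prob and n_states > 1:
            s = (s + rng.integers(1, n_states)) % n_states
    if state_centers is None:
        state_centers = np.array([[3.0 * i, 0.0, 0.0] for i in range(n_states)])
    top = _toy_topology(bonds)
    xyz = np.zeros((n_frames, top.n_atoms, 3), dtype=np.float32)
    occ_draws = {}
    for bi, bond in enumerate(bonds):
        probs = np.array([schedule[states[labels[t]]].get(bond, 0.0)
                          for t in range(n_frames)])
        present = rng.random(n_frames) < probs
        occ_draws[bond] = present
        base = np.array([0.0, 1.0 * bi, 0.0])
        xyz[:, 3 * bi, :] = base                        # donor N
        xyz[:, 3 * bi + 1, :] = base + [0.1, 0.0, 0.0]  # hydrogen on the axis
        dist = np.where(present, 0.28, 0.60)
        xyz[:, 3 * bi + 2, :] = base
        xyz[:, 3 * bi + 2, 0] += dist
    rep = top.n_atoms - 1
    xyz[:, rep, :] = (state_centers[labels]
                      + reporter_noise_nm * rng.standard_normal((n_frames, 3)))
    traj = md.Trajectory(xyz, top,
                         time=np.arange(n_frames) * frame_interval_ns)
    truth = GroundTruth("generate_hbond_toy_trajectory", seed, {
        "labels": labels, "schedule": {str(k): v for k, v in schedule.items()},
        "bonds": bonds, "stay_prob": stay_prob,
        "detected_occupancy_truth": {b: float(v.mean())
                                     for b, v in occ_draws.items()},
        "state_centers": state_centers})
    return traj, truth


def toy_hbond_specs(truth: GroundTruth) -> list:
    """HBondSpec list matching the toy topology of the generator."""
    from phrelay.features import HBondSpec
    specs = []
    for i, bond in enumerate(truth.values["bonds"]):
        rd, ra = 100 + 2 * i, 101 + 2 * i
        specs.append(HBondSpec(f"resSeq {rd} and name NZ",
                               f"resSeq {rd} and name HZ1",
                               f"resSeq {ra} and name OD1", bond))
    return specs


# --- per-frame pKa records ------------------------------------------------

def generate_pka_records(n_frames: int, mean_pka: float, sd: float,
                         coupling_fraction: float, seed: int,
                         residue: str = "D308", partner: str = "E285",
                         coupling_mean: float | None = None,
                         coupling_sd: float | None = None,
                         alt_split: float = 1.0
                         ) -> tuple[list[PkaRecord], GroundTruth]:
    """Per-frame pKa draws with a planted coupling fraction.

    Uncoupled frames draw pKa ~ N(mean_pka, sd).  A Bernoulli
    (``coupling_fraction``) flag marks coupled frames, which draw from
    N(coupling_mean, coupling_sd) (defaulting to the base distribution)
    and carry the two alternative values a = pKa + alt_split and
    b = pKa - alt_split for the residue (reversed for the partner).
    """
    if not 0.0 <= coupling_fraction <= 1.0:
        raise ValueError("coupling_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    coupling_mean = mean_pka if coupling_mean is None else coupling_mean
    coupling_sd = sd if coupling_sd is None else coupling_sd
    records = []
    coupled_flags = rng.random(n_frames) < coupling_fraction
    for t in range(n_frames):
        if coupled_flags[t]:
            val = coupling_mean + coupling_sd * rng.standard_normal()
            pa, pb = val + alt_split, val - alt_split
            records.append(PkaRecord(t, residue, val, True, partner, pa, pb))
            pval = mean_pka + sd * rng.standard_normal()
            records.append(PkaRecord(t, partner, pval, True, residue, pb, pa))
        else:
            val = mean_pka + sd * rng.standard_normal()
            records.append(PkaRecord(t, residue, val))
            records.append(PkaRecord(t, partner,
                                     mean_pka + sd * rng.standard_normal()))
    truth = GroundTruth("generate_pka_records", seed, {
        "n_frames": n_frames, "mean_pka": mean_pka, "sd": sd,
        "coupling_fraction": coupling_fraction,
        "coupled_frames": int(coupled_flags.sum()),
        "residue": residue, "partner": partner})
    return records, truth
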