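"""ITC binding thermodynamics: free energies, pH sensitivities, and the
one-set-of-sites isotherm fit.

Free energies follow the standard-state convention with the dissociation
constant in mol/l against a 1 M reference: a Kd of 105 uM at 300 K maps
to a binding free energy of -22.9 kJ/mol, and the pH sensitivity is the
difference ddG = dG(pH 6) - dG(pH 7).  Displayed values are rounded to
one decimal (half away from zero); full precision is kept internally.

The titration model is the single-site (Hill coefficient 1) binding
isotherm with the exact ligand-conservation quadratic per injection and
the well-mixed cell-displacement correction.  The dimensionless Wiseman
parameter ``c = n * [cell] / Kd`` controls identifiability: below c ~ 5
the enthalpy of the fit is poorly determined, which the fit flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_J_PER_K_MOL = 8.314
CAL_TO_J = 4.184
LOW_C_THRESHOLD = 5.0


@dataclass(frozen=True)
class BindingMeasurement:
    """One ITC-derived dissociation constant."""

    variant: str
    ph: float
    kd_molar: float
    kd_err_molar: float = 0.0
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        if self.kd_molar <= 0:
            raise ValueError(f"Kd must be > 0, got {self.kd_molar}")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class FreeEnergyResult:
    """Binding free energy (and, for pairs, the pH sensitivity) in kJ/mol."""

    dg_kj_mol: float
    dg_err_kj_mol: float = 0.0
    ddg_kj_mol: float | None = None
    ddg_err_kj_mol: float | None = None


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the display convention for dG tables)."""
    factor = 10 ** decimals
    scaled = x * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def delta_g(kd_molar: float, temperature_k: float = 300.0) -> float:
    """Binding free energy in kJ/mol from a dissociation constant in mol/l.

    dG = RT ln(Kd / 1 M) with R = 8.314 J/(K mol); negative for
    sub-molar Kd, e.g. Kd = 105e-6 at 300 K -> -22.851 (prints -22.9).
    """
    if kd_molar <= 0:
        raise ValueError(f"Kd must be > 0, got {kd_molar}")
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0")
    return R_J_PER_K_MOL * temperature_k * log(kd_molar) / 1000.0


def delta_g_error(kd_molar: float, kd_err_molar: float,
                  temperature_k: float = 300.0) -> float:
    """First-order propagated dG error: RT * sigma_Kd / Kd, kJ/mol."""
    return R_J_PER_K_MOL * temperature_k * kd_err_molar / kd_molar / 1000.0


def free_energy(m: BindingMeasurement) -> FreeEnergyResult:
    return FreeEnergyResult(delta_g(m.kd_molar, m.temperature_k),
                            delta_g_error(m.kd_molar, m.kd_err_molar,
                                          m.temperature_k))


def delta_delta_g(at_ph6: BindingMeasurement, at_ph7: BindingMeasurement
                  ) -> FreeEnergyResult:
    """pH sensitivity ddG = dG(pH 6) - dG(pH 7) for one variant.

    Errors combine in quadrature from the propagated Kd errors.  The
    result is antisymmetric under swapping the two measurements.
    """
    if at_ph6.variant != at_ph7.variant:
        raise ValueError(f"variant mismatch: {at_ph6.variant!r} vs "
                         f"{at_ph7.variant!r}")
    if abs(at_ph6.temperature_k - at_ph7.temperature_k) > 1e-9:
        raise ValueError("temperature mismatch between the pair")
    g6 = free_energy(at_ph6)
    g7 = free_energy(at_ph7)
    err = sqrt(g6.dg_err_kj_mol ** 2 + g7.dg_err_kj_mol ** 2)
    return FreeEnergyResult(g6.dg_kj_mol, g6.dg_err_kj_mol,
                            g6.dg_kj_mol - g7.dg_kj_mol, err)


#: Published Ca2+ dissociation constants for the langerin carbohydrate
#: recognition domain and point mutants (ITC, T = 300 K; Kd in uM).
#: "WT-remeasured" is the independent repeat of the wildtype series.
LANGERIN_KD_TABLE = pd.DataFrame([
    {"variant": "WT", "ph": 7.0, "kd_um": 105.0, "kd_err_um": 15.0},
    {"variant": "WT", "ph": 6.0, "kd_um": 800.0, "kd_err_um": 150.0},
    {"variant": "H294A", "ph": 7.0, "kd_um": 35.0, "kd_err_um": 15.0},
    {"variant": "H294A", "ph": 6.0, "kd_um": 125.0, "kd_err_um": 5.0},
    {"variant": "E261D", "ph": 7.0, "kd_um": 108.0, "kd_err_um": 11.0},
    {"variant": "E261D", "ph": 6.0, "kd_um": 742.0, "kd_err_um": 141.0},
    {"variant": "WT-remeasured", "ph": 7.0, "kd_um": 113.0, "kd_err_um": 14.0},
    {"variant": "WT-remeasured", "ph": 6.0, "kd_um": 802.0, "kd_err_um": 150.0},
])


def free_energy_table(measurements: pd.DataFrame | None = None,
                      temperature_k: float = 300.0) -> pd.DataFrame:
    """dG / ddG table (one-decimal display columns) per variant and pH.

    ``measurements`` needs columns variant, ph, kd_um, kd_err_um;
    defaults to the bundled langerin table.
    """
    df = LANGERIN_KD_TABLE if measurements is None else measurements
    rows = []
    for variant, group in df.groupby("variant", sort=False):
        ms = {float(r.ph): BindingMeasurement(variant, float(r.ph),
                                              r.kd_um * 1e-6, r.kd_err_um * 1e-6,
                                              temperature_k)
              for r in group.itertuples()}
        ddg = None
        if 6.0 in ms and 7.0 in ms:
            ddg = delta_delta_g(ms[6.0], ms[7.0]).ddg_kj_mol
        for ph, m in sorted(ms.items()):
            g = free_energy(m)
            rows.append({
                "variant": variant, "ph": ph, "kd_um": m.kd_molar * 1e6,
                "dg_kj_mol": round_half_away(g.dg_kj_mol),
                "dg_err_kj_mol": g.dg_err_kj_mol,
                "ddg_kj_mol": round_half_away(ddg) if ddg is not None else np.nan,
            })
    return pd.DataFrame(rows)


# --- one-set-of-sites titration model -------------------------------------

def one_site_heats(kd_molar: float, dh_kj_mol: float, n_sites: float,
                   cell_conc_molar: float, syringe_conc_molar: float,
                   volumes_ul: np.ndarray, cell_volume_ul: float = 200.0
                   ) -> np.ndarray:
    """Per-injection heats (ucal) of a single-site titration.

    Tracks total macromolecule and ligand in the cell through the exact
    well-mixed displacement bookkeeping (each injection of volume v
    dilutes the cell contents by 1 - v/V0), solves the ligand-
    conservation quadratic for the bound concentration after every
    injection, and differences the bound amounts to get the heat.
    """
    if cell_volume_ul <= 0:
        raise ValueError("cell volume must be > 0")
    if cell_conc_molar <= 0 or syringe_conc_molar <= 0:
        raise ValueError("concentrations must be > 0")
    volumes_ul = np.asarray(volumes_ul, dtype=float)
    v0 = cell_volume_ul
    m_tot = cell_conc_molar      # total macromolecule in cell, mol/l
    x_tot = 0.0                  # total ligand in cell, mol/l
    bound_prev = 0.0
    heats = np.empty(len(volumes_ul))
    for i, v in enumerate(volumes_ul):
        dil = 1.0 - v / v0
        m_tot *= dil
        x_tot = x_tot * dil + syringe_conc_molar * v / v0
        sites = n_sites * m_tot
        b = sites + x_tot + kd_molar
        bound = 0.5 * (b - sqrt(b * b - 4.0 * sites * x_tot))
        # heat from newly bound ligand, correcting for complex displaced
        dq_kj = dh_kj_mol * (bound - bound_prev * dil) * v0 * 1e-6
        heats[i] = dq_kj * 1000.0 / CAL_TO_J * 1e6  # kJ -> J -> cal -> ucal
        bound_prev = bound
    return heats


@dataclass
class OneSiteFit:
    kd_molar: float
    dh_kj_mol: float
    n_sites: float
    c_value: float
    low_c: bool
    residuals: np.ndarray
    dh_reliable: bool

    @property
    def note(self) -> str:
        if not self.dh_reliable:
            return ("low c-value (c < 5): the fitted enthalpy is not "
                    "reliably determined")
        return ""


def fit_one_site(heats_ucal: np.ndarray, cell_conc_molar: float,
                 syringe_conc_molar: float, volumes_ul: np.ndarray,
                 cell_volume_ul: float = 200.0, fix_n: float | None = 1.0,
                 ) -> OneSiteFit:
    """Nonlinear least-squares fit of the one-set-of-sites model.

    ``fix_n`` pins the stoichiometry (default 1, i.e. a Hill coefficient
    of 1); pass ``None`` to float it.  Raises on non-convergence with
    the residual report in the message.
    """
    heats = np.asarray(heats_ucal, dtype=float)
    volumes_ul = np.asarray(volumes_ul, dtype=float)
    if len(heats) < 5:
        raise ValueError("need at least 5 injections")

    def model(params):
        log_kd, dh = params[0], params[1]
        n = fix_n if fix_n is not None else params[2]
        return one_site_heats(np.exp(log_kd), dh, n, cell_conc_molar,
                              syringe_conc_molar, volumes_ul, cell_volume_ul)

    scale = np.abs(heats).max()
    dh0 = -10.0 if scale > 0 else 0.0
    x0 = [np.log(cell_conc_molar), dh0] + ([] if fix_n is not None else [1.0])
    res = least_squares(lambda p: model(p) - heats, x0, method="lm",
                        max_nfev=20000)
    if not res.success:
        raise RuntimeError(f"one-site fit did not converge: {res.message}; "
                           f"residual norm {np.linalg.norm(res.fun):.3g}")
    kd = float(np.exp(res.x[0]))
    dh = float(res.x[1])
    n = float(fix_n if fix_n is not None else res.x[2])
    c = n * cell_conc_molar / kd
    flat = scale == 0 or np.abs(model(res.x)).max() < 1e-12 * max(scale, 1.0)
    return OneSiteFit(kd, dh, n, c, c < LOW_C_THRESHOLD, res.fun,
                      dh_reliable=(c >= LOW_C_THRESHOLD) and not flat)
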