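"""Equivalent-circuit models and complex nonlinear least-squares EIS fitting.

The microsystem's impedance spectrum is described by a simplified equivalent
circuit: the overall series resistance of the microelectrodes (R_elec), in
series with the parallel combination of the bacteria-electrode interface
capacitance (C_belec) and a faradaic branch made of the charge-transfer
resistance of the bacteria (R_b) in series with a constant phase element

    Z_CPE(w) = 1 / (Q_i * (j*w)**n_i),

which models the non-uniform accumulation of adsorbed species at the
microelectrode surface.  A full two-Randles-cell topology is also provided
for documentation and limit checks; all quantitative fitting uses the
simplified model.

Fitting minimizes the modulus-weighted complex residual

    sum_f |Z_model(f) - Z_data(f)|^2 / |Z_data(f)|^2

with all positive parameters optimized in log space and the CPE exponent
through a logit transform onto (0, 1], so the parameter constraints hold by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .changestats import (
    ChangepointResult,
    SampleSeries,
    VarianceSeries,
    variance_pipeline,
)

__all__ = [
    "ImpedanceSample",
    "EISSession",
    "CircuitParams",
    "FullCircuitParams",
    "FitResult",
    "cpe_impedance",
    "simplified_circuit_impedance",
    "full_circuit_impedance",
    "fit_circuit",
    "parameter_trajectory",
    "eis_variance_series",
    "max_change_frequency",
    "scale_impedance",
]

log = logging.getLogger(__name__)


@dataclass
class ImpedanceSample:
    """One EIS spectrum: frequencies in Hz, complex impedance in ohms."""

    frequencies: np.ndarray
    impedance: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.shape != self.impedance.shape:
            raise ValueError("frequency and impedance grids differ in shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.impedance)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in degrees (Bode convention)."""
        return np.degrees(np.angle(self.impedance))


@dataclass
class EISSession:
    """Ordered impedance spectra sharing one frequency grid."""

    spectra: list[ImpedanceSample]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty session")
        f0 = self.spectra[0].frequencies
        for s in self.spectra[1:]:
            if not np.allclose(s.frequencies, f0):
                raise ValueError("spectra use different frequency grids")
        ts = self.timestamps
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.spectra])

    @property
    def frequencies(self) -> np.ndarray:
        return self.spectra[0].frequencies


@dataclass
class CircuitParams:
    """Simplified equivalent circuit parameters.

    R_elec : ohm, microsystem overall series resistance
    C_belec : farad, bacteria-electrode interface double-layer capacitance
    R_b : ohm, charge-transfer resistance of the bacteria
    Q_i : S*s^n, CPE magnitude
    n_i : dimensionless CPE exponent in (0, 1]
    """

    R_elec: float
    C_belec: float
    R_b: float
    Q_i: float
    n_i: float

    def __post_init__(self) -> None:
        for name in ("R_elec", "C_belec", "R_b", "Q_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.n_i <= 1:
            raise ValueError("n_i must lie in (0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.R_elec, self.C_belec, self.R_b, self.Q_i, self.n_i])


@dataclass
class FullCircuitParams:
    """Two-Randles-cell topology with a capacitive inter-electrode bridge."""

    R_ELEC_a: float
    R_ELEC_c: float
    R_act: float
    R_cct: float
    C_adl: float
    C_cdl: float
    C_elec: float
    C_b: float
    R_b: float
    Q_i: float
    n_i: float

    def __post_init__(self) -> None:
        for name in ("R_ELEC_a", "R_ELEC_c", "C_elec", "C_b", "R_b", "Q_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.n_i <= 1:
            raise ValueError("n_i must lie in (0, 1]")


@dataclass
class FitResult:
    params: CircuitParams
    rel_errors: dict[str, float]
    residual_norm: float
    converged: bool


def cpe_impedance(Q_i: float, n_i: float, omega) -> np.ndarray:
    """Impedance of a constant phase element, 1/(Q*(j*w)^n)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    if Q_i <= 0 or not 0 < n_i <= 1:
        raise ValueError("require Q_i > 0 and 0 < n_i <= 1")
    return 1.0 / (Q_i * (1j * omega) ** n_i)


def simplified_circuit_impedance(params: CircuitParams, omega) -> np.ndarray:
    """Z(w) = R_elec + [ jwC_belec + 1/(R_b + Z_CPE(w)) ]^-1."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    z_far = params.R_b + cpe_impedance(params.Q_i, params.n_i, omega)
    y = 1j * omega * params.C_belec + 1.0 / z_far
    return params.R_elec + 1.0 / y


def full_circuit_impedance(params: FullCircuitParams, omega) -> np.ndarray:
    """Documented full topology.

    Inner branch: the anodic and cathodic interface cells (R_ct || C_dl)
    in series with the bacterial cell (R_b + Z_CPE) || C_b; the capacitive
    bridge C_elec sits in parallel across that whole inner branch, between
    the two series electrode resistances.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    jw = 1j * omega

    def rc_parallel(r: float, c: float) -> np.ndarray:
        if r <= 0:
            return np.zeros_like(jw)
        if c <= 0:
            return np.full_like(jw, r)
        return r / (1.0 + jw * r * c)

    z_bact_branch = params.R_b + cpe_impedance(params.Q_i, params.n_i, omega)
    z_bact = 1.0 / (1.0 / z_bact_branch + jw * params.C_b)
    inner = (
        rc_parallel(params.R_act, params.C_adl)
        + rc_parallel(params.R_cct, params.C_cdl)
        + z_bact
    )
    z_mid = 1.0 / (1.0 / inner + jw * params.C_elec)
    return params.R_ELEC_a + params.R_ELEC_c + z_mid


def scale_impedance(params: CircuitParams, c: float) -> CircuitParams:
    """Return parameters whose spectrum is ``c`` times the input spectrum.

    Impedances scale linearly when resistances are multiplied by c and
    capacitive/CPE admittance magnitudes divided by c; n_i is unchanged.
    """
    if c <= 0:
        raise ValueError("scale must be positive")
    return CircuitParams(
        R_elec=params.R_elec * c,
        C_belec=params.C_belec / c,
        R_b=params.R_b * c,
        Q_i=params.Q_i / c,
        n_i=params.n_i,
    )


# --- fitting ---------------------------------------------------------------

_PARAM_NAMES = ("R_elec", "C_belec", "R_b", "Q_i", "n_i")


def _pack(p: CircuitParams) -> np.ndarray:
    # log for positive parameters, logit for n_i on (0, 1]
    n = min(p.n_i, 1.0 - 1e-9)
    return np.array([
        np.log(p.R_elec), np.log(p.C_belec), np.log(p.R_b), np.log(p.Q_i),
        np.log(n / (1.0 - n)),
    ])


def _unpack(x: np.ndarray) -> CircuitParams:
    # clip so solver excursions cannot overflow/underflow out of the domain
    x = np.clip(x, -690.0, 690.0)
    n = float(np.clip(1.0 / (1.0 + np.exp(-x[4])), 1e-9, 1.0))
    e = lambda v: float(max(np.exp(v), 1e-290))
    return CircuitParams(R_elec=e(x[0]), C_belec=e(x[1]),
                         R_b=e(x[2]), Q_i=e(x[3]), n_i=n)


def auto_initial_params(spectrum: ImpedanceSample) -> CircuitParams:
    """Heuristic starting point derived from the spectrum itself.

    R_elec from Re(Z) at the highest frequency, R_b from the low-frequency
    real-axis extent, C_belec from the frequency of the imaginary-part apex,
    and the CPE exponent from the mid-band phase of the interfacial part.
    """
    f = spectrum.frequencies
    z = spectrum.impedance
    r_elec = max(float(z[-1].real), 1e-3)
    r_b = max(float(np.abs(z[0])) - r_elec, 10 * r_elec * 1e-3, 1e-3)
    # apex of -Im(Z) marks w ~ 1/(R_b * C) for a Randles-like loop
    i_apex = int(np.argmax(-z.imag))
    w_apex = 2 * np.pi * f[i_apex]
    c = max(1.0 / (w_apex * r_b), 1e-15)
    # interfacial phase at mid band, mapped to a CPE exponent
    zin = z - r_elec
    mid = len(f) // 2
    phi = abs(float(np.angle(zin[mid], deg=True)))
    n = float(np.clip(phi / 90.0, 0.3, 0.99))
    q = max(c ** n, 1e-15)
    return CircuitParams(R_elec=r_elec, C_belec=c, R_b=r_b, Q_i=q, n_i=n)


def _init_candidates(spectrum: ImpedanceSample,
                     init: CircuitParams | None) -> list[CircuitParams]:
    """Starting points for the fit.

    The auto-init under-estimates R_b on blocking-type spectra where the
    interface capacitance shunts the faradaic branch over the whole band,
    so the grid also spans larger R_b and a range of CPE exponents.
    """
    cands: list[CircuitParams] = []
    if init is not None:
        cands.append(init)
    base = auto_initial_params(spectrum)
    cands.append(base)
    w_mid = 2 * np.pi * spectrum.frequencies[len(spectrum.frequencies) // 2]
    z_mid = float(np.abs(spectrum.impedance[len(spectrum.frequencies) // 2]))
    for rb_scale in (1.0, 10.0, 100.0):
        for n in (0.6, 0.8, 0.95):
            q = 1.0 / (z_mid * w_mid ** n)
            cands.append(replace(base, R_b=base.R_b * rb_scale, n_i=n, Q_i=q))
    return cands


def fit_circuit(
    spectrum: ImpedanceSample,
    init: CircuitParams | None = None,
    max_nfev: int = 2000,
    multistart: bool = True,
) -> FitResult:
    """Fit the simplified circuit to one spectrum.

    Modulus-weighted complex least squares over a small grid of starting
    points (the lowest-residual solution wins); per-parameter relative
    errors are estimated from the Jacobian at the solution.  Never raises
    on non-convergence: the result carries ``converged=False`` instead.
    """
    if spectrum.frequencies.size < 5:
        raise ValueError("need at least 5 frequency points")
    omega = 2 * np.pi * spectrum.frequencies
    z_data = spectrum.impedance
    w = 1.0 / np.abs(z_data)

    def residuals(x: np.ndarray) -> np.ndarray:
        z = simplified_circuit_impedance(_unpack(x), omega)
        d = (z - z_data) * w
        return np.concatenate([d.real, d.imag])

    starts = (_init_candidates(spectrum, init) if multistart
              else [init if init is not None else auto_initial_params(spectrum)])
    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, _pack(p0), method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - solver pathologies
            log.warning("circuit fit failed from one start: %s", exc)
            continue
        if best is None or np.linalg.norm(sol.fun) < np.linalg.norm(best.fun):
            best = sol
        if np.linalg.norm(best.fun) < 1e-12:
            break
    if best is None:
        params = init if init is not None else auto_initial_params(spectrum)
        return FitResult(params=params,
                         rel_errors={k: float("inf") for k in _PARAM_NAMES},
                         residual_norm=float("inf"), converged=False)
    return FitResult(params=_unpack(best.x),
                     rel_errors=_relative_errors(best.jac, best.fun, best.x),
                     residual_norm=float(np.linalg.norm(best.fun)),
                     converged=bool(best.success))


def _relative_errors(jac, fun, x) -> dict[str, float]:
    # covariance of the transformed parameters; in log space the standard
    # error of log(p) is already a relative error of p
    m, n = jac.shape
    dof = max(m - n, 1)
    s2 = float(fun @ fun) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    out = dict(zip(_PARAM_NAMES, se))
    # n_i was logit-transformed: scale back to a relative error of n_i
    nv = 1.0 / (1.0 + np.exp(-x[4]))
    out["n_i"] = float(out["n_i"] * (1.0 - nv))
    return out


def parameter_trajectory(
    session: EISSession, event_time_s: float | None = None
) -> dict:
    """Per-spectrum fits, warm-started from the previous converged fit.

    Returns the list of fits plus before/after epoch summaries (medians,
    robust to the occasional degenerate single-spectrum fit) for every
    circuit element when an event time is given.
    """
    fits: list[FitResult] = []
    prev: CircuitParams | None = None
    for spec in session.spectra:
        res = fit_circuit(spec, init=prev)
        if not res.converged:
            log.warning("fit did not converge at t=%s s", spec.timestamp)
            res2 = fit_circuit(spec, init=None)
            if res2.converged:
                res = res2
        fits.append(res)
        if res.converged:
            prev = res.params
    out: dict = {"fits": fits, "timestamps": session.timestamps}
    if event_time_s is not None:
        ts = session.timestamps
        for label, mask in (("before", ts < event_time_s),
                            ("after", ts >= event_time_s)):
            sel = [f.params for f, m in zip(fits, mask) if m and f.converged]
            if sel:
                out[label] = {
                    name: float(np.median([getattr(p, name) for p in sel]))
                    for name in _PARAM_NAMES
                }
    return out


def eis_variance_series(
    session: EISSession, *, ratio_on: str = "raw"
) -> tuple[tuple[VarianceSeries, ChangepointResult],
           tuple[VarianceSeries, ChangepointResult]]:
    """Variance pipelines over |Z| and over phase (degrees) per spectrum."""
    if len(session.spectra) < 2:
        raise ValueError("need at least 2 spectra")
    ts = session.timestamps
    mag = SampleSeries([s.magnitude for s in session.spectra], ts)
    ph = SampleSeries([s.phase_deg for s in session.spectra], ts)
    return (variance_pipeline(mag, ratio_on=ratio_on),
            variance_pipeline(ph, ratio_on=ratio_on))


def max_change_frequency(session: EISSession, event_time_s: float) -> dict:
    """Frequency of the largest epoch-mean change in |Z| and in phase."""
    ts = session.timestamps
    before = [s for s in session.spectra if s.timestamp < event_time_s]
    after = [s for s in session.spectra if s.timestamp >= event_time_s]
    if not before or not after:
        raise ValueError("both epochs must be non-empty")
    f = session.frequencies
    mag_b = np.mean([s.magnitude for s in before], axis=0)
    mag_a = np.mean([s.magnitude for s in after], axis=0)
    ph_b = np.mean([s.phase_deg for s in before], axis=0)
    ph_a = np.mean([s.phase_deg for s in after], axis=0)
    dmag = np.abs(mag_a - mag_b)
    dph = np.abs(ph_a - ph_b)
    degenerate = bool(np.allclose(dmag, 0) and np.allclose(dph, 0))
    return {
        "impedance_hz": float(f[int(np.argmax(dmag))]),
        "phase_hz": float(f[int(np.argmax(dph))]),
        "degenerate": degenerate,
    }
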