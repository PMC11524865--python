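"""Voltage-clamp analysis: electromotility and nonlinear capacitance (NLC).

Outer hair cells change somatic length with membrane potential (prestin-based
electromotility).  The length change follows a two-state Boltzmann function of
voltage, and the associated gating-charge movement appears as a bell-shaped,
voltage-dependent component of membrane capacitance — the first derivative of
the Boltzmann charge-voltage relation:

    L(V)  = Lmax / (1 + exp(-alpha (V - Vhalf)))
    Cm(V) = Qmax alpha / (4 cosh^2(alpha (V - Vhalf) / 2)) + Clin

with alpha the voltage sensitivity in 1/mV, Vhalf the half-maximal voltage in
mV, Qmax the maximal nonlinear charge in fC and Clin the linear (voltage
independent) capacitance in pF.  With Qmax in fC and V in mV the bell term is
directly in pF (fC/mV = pF); the peak sits at Vhalf with height
Qmax*alpha/4 + Clin and the bell integrates to Qmax.

Capacitance itself is estimated from raw currents with the dual-sine
technique: two superimposed voltage sinusoids (390.6 and 781.2 Hz, 10 mV)
ride on a 4 mV voltage staircase; the complex admittance extracted by FFT at
exactly those two frequencies determines the three elements of the minimal
patch circuit (series resistance Rs, membrane resistance Rm, membrane
capacitance Cm).

Some instruments report the voltage sensitivity as a slope factor in mV
(the reciprocal of alpha); :func:`alpha_from_slope_factor` converts
explicitly — no silent unit guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


def alpha_from_slope_factor(slope_mV: float) -> float:
    """Convert a slope factor in mV to the voltage sensitivity alpha in 1/mV."""
    if slope_mV <= 0:
        raise ValueError("slope factor must be positive")
    return 1.0 / slope_mV


def slope_factor_from_alpha(alpha: float) -> float:
    """Convert alpha (1/mV) to the slope factor in mV."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 / alpha


@dataclass(frozen=True)
class NLCParams:
    """Derivative-of-Boltzmann NLC parameters.

    qmax : maximal nonlinear charge, fC.  alpha : voltage sensitivity, 1/mV.
    vhalf : voltage of peak NLC, mV.  clin : linear capacitance, pF.
    """

    qmax: float
    alpha: float
    vhalf: float
    clin: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.qmax < 0 or self.clin < 0:
            raise ValueError("qmax and clin must be non-negative")

    @property
    def peak_nlc(self) -> float:
        """Bell height above Clin at V = vhalf, in pF."""
        return self.qmax * self.alpha / 4.0


@dataclass(frozen=True)
class MotilityParams:
    """Two-state Boltzmann motility parameters.

    lmax : maximal length change, um.  alpha : 1/mV.  vhalf : mV.
    """

    lmax: float
    alpha: float
    vhalf: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.lmax < 0:
            raise ValueError("lmax must be non-negative")


@dataclass
class Recording:
    """A voltage-clamp sweep: voltage staircase with measured traces.

    voltage is in mV and strictly monotone within the sweep; capacitance (pF)
    and displacement (um) are sampled at the same voltages.  metadata carries
    stimulus details (sampling interval, sine frequencies, ...).
    """

    voltage: np.ndarray
    capacitance: np.ndarray | None = None
    displacement: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        for name in ("capacitance", "displacement"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.voltage.shape:
                    raise ValueError(f"{name} length differs from voltage")
                setattr(self, name, arr)
        dv = np.diff(self.voltage)
        if len(dv) and not ((dv > 0).all() or (dv < 0).all()):
            raise ValueError("voltage must be strictly monotone within a sweep")


def boltzmann_length(v, params: MotilityParams):
    """Two-state Boltzmann length change: Lmax / (1 + exp(-alpha (V - Vhalf)))."""
    v = np.asarray(v, dtype=float)
    out = params.lmax * _expit(params.alpha * (v - params.vhalf))
    return float(out) if out.ndim == 0 else out


def boltzmann_slope(v, params: MotilityParams):
    """Analytic derivative dL/dV of the fitted Boltzmann, in um/mV."""
    v = np.asarray(v, dtype=float)
    s = _expit(params.alpha * (v - params.vhalf))
    out = params.lmax * params.alpha * s * (1.0 - s)
    return float(out) if out.ndim == 0 else out


def _expit(x):
    # logistic, stable for large |x|
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _sech2(x):
    # 1/cosh(x)^2 without overflow for large |x|
    e = np.exp(-2.0 * np.abs(np.asarray(x, dtype=float)))
    return 4.0 * e / (1.0 + e) ** 2


def nlc_curve(v, params: NLCParams):
    """Derivative-of-Boltzmann membrane capacitance in pF.

    Symmetric bell about vhalf; peak qmax*alpha/4 + clin; tends to clin far
    from vhalf; the bell integrates to qmax over voltage.
    """
    v = np.asarray(v, dtype=float)
    x = params.alpha * (v - params.vhalf) / 2.0
    out = params.qmax * params.alpha / 4.0 * _sech2(x) + params.clin
    return float(out) if out.ndim == 0 else out


@dataclass
class FitResult:
    """Least-squares fit outcome with diagnostics."""

    params: object
    stderr: dict
    rss: float
    residual_sd: float
    converged: bool
    flat: bool
    message: str = ""


def _lsq(model, x0, bounds, v, y):
    def resid(theta):
        return model(theta) - y

    res = optimize.least_squares(
        resid, x0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    n, p = len(y), len(x0)
    rss = float(2.0 * res.cost)
    dof = max(n - p, 1)
    s2 = rss / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        perr = np.full(p, np.nan)
    return res, rss, np.sqrt(s2), perr


def fit_nlc(rec: Recording) -> FitResult:
    """Fit the derivative-of-Boltzmann NLC model to a capacitance sweep.

    Initialization: clin from the trace minimum, vhalf from the voltage of the
    maximum, alpha0 = 2 / voltage span, qmax0 = 4 (peak - clin0) / alpha0.
    Non-convergence is reported in the result flags, never silently defaulted.
    A fit whose bell height does not exceed 3x the residual SD is flagged
    flat ("no voltage dependence").
    """
    if rec.capacitance is None:
        raise ValueError("recording has no capacitance trace")
    v, c = rec.voltage, rec.capacitance
    if len(v) < 8 or (v.max() - v.min()) < 60.0:
        raise ValueError("need >= 8 voltage points spanning >= 60 mV")
    span = v.max() - v.min()
    clin0 = float(c.min())
    vhalf0 = float(v[np.argmax(c)])
    alpha0 = 2.0 / span
    qmax0 = max(4.0 * (float(c.max()) - clin0) / alpha0, 1e-6)

    def model(theta):
        qmax, alpha, vhalf, clin = theta
        x = alpha * (v - vhalf) / 2.0
        return qmax * alpha / 4.0 * _sech2(x) + clin

    x0 = [qmax0, alpha0, vhalf0, clin0]
    bounds = ([0.0, 1e-6, v.min() - 10 * span, 0.0],
              [np.inf, 10.0, v.max() + 10 * span, np.inf])
    res, rss, sd, perr = _lsq(model, x0, bounds, v, c)
    qmax, alpha, vhalf, clin = res.x
    params = NLCParams(qmax=qmax, alpha=alpha, vhalf=vhalf, clin=clin)
    flat = params.peak_nlc <= max(3.0 * sd, 1e-9 + 1e-6 * clin)
    return FitResult(
        params=params,
        stderr=dict(zip(("qmax", "alpha", "vhalf", "clin"), perr)),
        rss=rss, residual_sd=sd, converged=bool(res.success), flat=flat,
        message=res.message,
    )


def fit_motility(rec: Recording) -> FitResult:
    """Fit the two-state Boltzmann to a displacement sweep.

    The slope function (dL/dV) of the fitted curve is available through
    :func:`boltzmann_slope` on the returned parameters.  A fit whose maximal
    length change does not exceed 3x the residual SD is flagged non-motile.
    """
    if rec.displacement is None:
        raise ValueError("recording has no displacement trace")
    v, d = rec.voltage, rec.displacement
    if len(v) < 8 or (v.max() - v.min()) < 60.0:
        raise ValueError("need >= 8 voltage points spanning >= 60 mV")
    span = v.max() - v.min()
    lmax0 = max(float(d.max() - d.min()), 1e-9)
    vhalf0 = float(np.median(v))
    alpha0 = 2.0 / span

    def model(theta):
        lmax, alpha, vhalf = theta
        return lmax * _expit(alpha * (v - vhalf))

    x0 = [lmax0, alpha0, vhalf0]
    bounds = ([0.0, 1e-6, v.min() - 10 * span], [np.inf, 10.0, v.max() + 10 * span])
    res, rss, sd, perr = _lsq(model, x0, bounds, v, d)
    lmax, alpha, vhalf = res.x
    params = MotilityParams(lmax=lmax, alpha=alpha, vhalf=vhalf)
    flat = lmax <= max(3.0 * sd, 1e-9)
    return FitResult(
        params=params,
        stderr=dict(zip(("lmax", "alpha", "vhalf"), perr)),
        rss=rss, residual_sd=sd, converged=bool(res.success), flat=flat,
        message=res.message,
    )


# ---------------------------------------------------------------------------
# dual-sine FFT admittance capacitance estimation
# ---------------------------------------------------------------------------

F1_HZ = 390.625   # printed as 390.6 Hz; 100 kHz / 256
F2_HZ = 781.25    # printed as 781.2 Hz; 100 kHz / 128
SINE_AMPLITUDE_MV = 10.0
SAMPLE_RATE_HZ = 100_000.0


@dataclass(frozen=True)
class PatchCircuit:
    """Minimal 3-element patch model: series Rs into (Rm parallel Cm).

    rs_mohm, rm_mohm in megaohm; cm_pf in picofarad.  Pipette capacitance is
    assumed neutralized.
    """

    rs_mohm: float
    rm_mohm: float
    cm_pf: float

    def admittance(self, f_hz):
        """Complex admittance in siemens at frequency f (Hz)."""
        w = 2.0 * np.pi * np.asarray(f_hz, dtype=float)
        rs = self.rs_mohm * 1e6
        rm = self.rm_mohm * 1e6
        cm = self.cm_pf * 1e-12
        zm = rm / (1.0 + 1j * w * rm * cm)
        return 1.0 / (rs + zm)


def _bin_index(f_hz: float, n: int, fs_hz: float) -> int:
    k = f_hz * n / fs_hz
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"frequency {f_hz} Hz is not bin-aligned for {n} samples at "
            f"{fs_hz} Hz; adjust the record length to an integer number of "
            f"periods of both stimulus frequencies"
        )
    return int(round(k))


def two_sine_voltage(n: int, fs_hz: float = SAMPLE_RATE_HZ,
                     f1_hz: float = F1_HZ, f2_hz: float = F2_HZ,
                     amplitude_mv: float = SINE_AMPLITUDE_MV,
                     v_dc_mv: float = 0.0) -> np.ndarray:
    """Dual-sine command voltage (mV): DC step plus two sinusoids."""
    _bin_index(f1_hz, n, fs_hz)
    _bin_index(f2_hz, n, fs_hz)
    t = np.arange(n) / fs_hz
    return (v_dc_mv
            + amplitude_mv * np.sin(2 * np.pi * f1_hz * t)
            + amplitude_mv * np.sin(2 * np.pi * f2_hz * t))


def simulate_two_sine_current(circuit: PatchCircuit, n: int,
                              fs_hz: float = SAMPLE_RATE_HZ,
                              f1_hz: float = F1_HZ, f2_hz: float = F2_HZ,
                              amplitude_mv: float = SINE_AMPLITUDE_MV,
                              v_dc_mv: float = 0.0,
                              noise_sd_na: float = 0.0,
                              rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state current response (nA) of the patch circuit to the
    dual-sine command; returns (voltage_mv, current_na)."""
    t = np.arange(n) / fs_hz
    v = two_sine_voltage(n, fs_hz, f1_hz, f2_hz, amplitude_mv, v_dc_mv)
    i_na = np.full(n, v_dc_mv * 1e-3 / ((circuit.rs_mohm + circuit.rm_mohm) * 1e6) * 1e9)
    for f in (f1_hz, f2_hz):
        y = complex(circuit.admittance(f))
        # response to A sin(wt): A |Y| sin(wt + arg Y), converted V*S -> nA
        amp = amplitude_mv * 1e-3 * abs(y) * 1e9
        i_na = i_na + amp * np.sin(2 * np.pi * f * t + np.angle(y))
    if noise_sd_na:
        if rng is None:
            raise ValueError("noise requested without an rng")
        i_na = i_na + rng.normal(0.0, noise_sd_na, n)
    return v, i_na


@dataclass
class TwoSineResult:
    cm_pf: float
    rm_mohm: float
    rs_mohm: float
    ok: bool
    condition: float
    message: str = ""


def two_sine_capacitance(current_na, voltage_mv, fs_hz: float = SAMPLE_RATE_HZ,
                         f1_hz: float = F1_HZ, f2_hz: float = F2_HZ,
                         min_separation: float = 1e-12) -> TwoSineResult:
    """Solve (Rs, Rm, Cm) from the complex admittances at the two stimulus
    frequencies.

    The DFT of current and voltage is taken at exactly the two stimulus bins
    (the record must hold an integer number of periods of both frequencies);
    Y(f) = I(f)/V(f).  With Z = 1/Y and W(Rs) = 1/(Z - Rs) = 1/Rm + j w Cm,
    the real parts of W at the two frequencies must agree, which pins Rs by a
    1-D root solve; Rm and Cm then follow in closed form.  Deterministic.
    """
    i = np.asarray(current_na, dtype=float)
    v = np.asarray(voltage_mv, dtype=float)
    if i.shape != v.shape:
        raise ValueError("current and voltage traces differ in length")
    n = len(i)
    k1 = _bin_index(f1_hz, n, fs_hz)
    k2 = _bin_index(f2_hz, n, fs_hz)
    if fs_hz < 10.0 * f2_hz:
        raise ValueError("sampling rate must be >= 10x the higher frequency")
    iv = np.fft.rfft(i)
    vv = np.fft.rfft(v)
    # nA / mV = uS -> SI siemens
    y1 = iv[k1] / vv[k1] * 1e-6
    y2 = iv[k2] / vv[k2] * 1e-6
    if abs(y1 - y2) < min_separation:
        return TwoSineResult(np.nan, np.nan, np.nan, False, 0.0,
                             "admittances at the two frequencies coincide; "
                             "solve is ill-conditioned")
    z1, z2 = 1.0 / y1, 1.0 / y2
    w1_hz, w2_hz = 2 * np.pi * f1_hz, 2 * np.pi * f2_hz

    def gap(rs_ohm):
        return (1.0 / (z1 - rs_ohm)).real - (1.0 / (z2 - rs_ohm)).real

    rs_hi = min(z1.real, z2.real)
    try:
        # the lower bound dips slightly negative so a true Rs of exactly zero
        # (pure RC) still brackets; the solution is clamped at zero below
        lo, hi = -0.01 * rs_hi, rs_hi * (1.0 - 1e-9)
        g_lo, g_hi = gap(lo), gap(hi)
        if g_lo == 0.0:
            rs = lo
        elif np.sign(g_lo) != np.sign(g_hi):
            rs = optimize.brentq(gap, lo, hi, xtol=1e-6, rtol=8.9e-16,
                                 maxiter=200)
        else:
            raise ValueError("no bracket")
    except ValueError:
        return TwoSineResult(np.nan, np.nan, np.nan, False,
                             float(abs(y1 - y2)),
                             "series-resistance solve failed to bracket a root")
    rs = max(rs, 0.0)
    w1 = 1.0 / (z1 - rs)
    w2 = 1.0 / (z2 - rs)
    gm = 0.5 * (w1.real + w2.real)
    cm = 0.5 * (w1.imag / w1_hz + w2.imag / w2_hz)
    if gm <= 0 or cm <= 0:
        return TwoSineResult(np.nan, np.nan, np.nan, False,
                             float(abs(y1 - y2)),
                             "non-physical solution (Rm or Cm <= 0)")
    return TwoSineResult(
        cm_pf=cm * 1e12, rm_mohm=(1.0 / gm) * 1e-6, rs_mohm=rs * 1e-6,
        ok=True, condition=float(abs(y1 - y2)),
    )


def correct_series_resistance(v_command_mv, i_na, rs_mohm: float) -> np.ndarray:
    """Off-line series-resistance voltage correction:
    V_membrane = V_command - I * Rs (mV, with I in nA and Rs in megaohm)."""
    return np.asarray(v_command_mv, dtype=float) - np.asarray(i_na, dtype=float) * rs_mohm


# ---------------------------------------------------------------------------
# voltage-dependence classification
# ---------------------------------------------------------------------------

@dataclass
class DependenceResult:
    voltage_dependent: bool
    f_stat: float
    p: float
    peak_minus_clin: float
    residual_sd: float
    fit: FitResult


def detect_voltage_dependence(rec: Recording, alpha_level: float = 0.05) -> DependenceResult:
    """Classify a capacitance sweep as voltage-dependent or flat.

    Nested-model F-test of the constant-capacitance fit against the
    derivative-of-Boltzmann fit; the sweep is voltage-dependent only when the
    F-test rejects at ``alpha_level`` AND the fitted bell height exceeds 3x
    the residual SD (a practical-significance guard against tiny but
    statistically detectable ripples).  Zebrafish hair cells and mouse IHCs
    produce flat sweeps under this test; OHCs produce strong rejections.
    """
    if rec.capacitance is None:
        raise ValueError("recording has no capacitance trace")
    c = rec.capacitance
    n = len(c)
    if n < 8:
        raise ValueError("need >= 8 points")
    fit = fit_nlc(rec)
    rss0 = float(((c - c.mean()) ** 2).sum())
    rss1 = fit.rss
    p_full, p_null = 4, 1
    dof = n - p_full
    if rss1 <= 0:
        # perfect full-model fit: any improvement over the constant model is
        # infinitely significant, none means a perfectly flat trace
        if rss0 <= 1e-30:
            return DependenceResult(False, 0.0, 1.0, fit.params.peak_nlc,
                                    fit.residual_sd, fit)
        return DependenceResult(not fit.flat, np.inf, 0.0, fit.params.peak_nlc,
                                fit.residual_sd, fit)
    f_stat = ((rss0 - rss1) / (p_full - p_null)) / (rss1 / dof)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, p_full - p_null, dof))
    amplitude_ok = fit.params.peak_nlc > 3.0 * fit.residual_sd
    return DependenceResult(
        voltage_dependent=bool(p < alpha_level and amplitude_ok),
        f_stat=float(f_stat), p=p, peak_minus_clin=fit.params.peak_nlc,
        residual_sd=fit.residual_sd, fit=fit,
    )
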