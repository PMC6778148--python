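"""Binding-model mathematics: SPR single-cycle kinetics, ITC, FP, competition.

All models are 1:1 (Langmuir for SPR, one set of identical sites for ITC,
single-site depletion-corrected binding for fluorescence polarization) —
the regime in which a unique 1:1 complex is formed.  Fits are trust-region
nonlinear least squares with a deterministic, seeded multi-start schedule
around method-of-moments initial guesses.  Concentrations are SI molar
internally; RU, microcalories and millipolarization appear only at the
I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

CAL_PER_KCAL = 1000.0


class FitError(RuntimeError):
    pass


def _multistart(residual_fn, x0: np.ndarray, n_starts: int, seed: int,
                spread: float = 1.0, bounds=(-np.inf, np.inf)):
    """Deterministic multi-start trust-region least squares in log space.

    The first start is the method-of-moments guess itself; the remaining
    ``n_starts - 1`` are log-spaced perturbations drawn from a seeded
    generator so repeated fits are bit-identical.
    """
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(x0 + rng.uniform(-spread, spread, size=len(x0)))
    best = None
    for s in starts:
        s = np.clip(s, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            res = least_squares(residual_fn, s, method="trf", bounds=bounds,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all fit starts failed")
    return best


# ---------------------------------------------------------------------------
# SPR single-cycle kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    phase: str  # "association" | "dissociation"
    concentration: float  # analyte M; 0 for dissociation
    times: np.ndarray  # seconds, absolute, strictly increasing
    response: np.ndarray  # RU

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("segment times must be strictly increasing")
        if self.phase == "association" and self.concentration <= 0:
            raise ValueError("association phase needs a positive concentration")


@dataclass
class Sensorgram:
    segments: list[Segment]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KineticFit:
    """1:1 Langmuir kinetic parameters; RI fixed at 0, tc fixed at 1e8."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # RU
    residual_norm: float
    biphasic: bool = False
    ri: float = 0.0
    tc: float = 1e8

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def single_cycle_plan(
    top_concentration: float,
    n_injections: int = 5,
    dilution: float = 2.0,
    contact_time: float = 120.0,
    dissociation_time: float = 70.0,
    final_dissociation: float = 600.0,
    dt: float = 1.0,
) -> list[tuple[float, float, float]]:
    """Default single-cycle injection plan.

    Five two-fold ascending analyte injections, 120 s contact and 70 s
    inter-injection dissociation, with a 600 s final dissociation.
    Returns (concentration, contact, dissociation) triples; ``dt`` is
    carried by the simulator.
    """
    concs = [top_concentration / dilution ** (n_injections - 1 - i)
             for i in range(n_injections)]
    plan = []
    for i, c in enumerate(concs):
        diss = final_dissociation if i == n_injections - 1 else dissociation_time
        plan.append((c, contact_time, diss))
    return plan


def simulate_sck(
    kon: float,
    koff: float,
    rmax: float,
    plan: list[tuple[float, float, float]],
    dt: float = 1.0,
) -> Sensorgram:
    """Closed-form piecewise 1:1 Langmuir single-cycle sensorgram.

    Association: R(t) = Req + (R0 - Req) exp(-(kon C + koff) t) with
    Req = kon C Rmax / (kon C + koff); dissociation: R(t) = R0 exp(-koff t).
    The response is continuous across segment boundaries.
    """
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff and rmax must be positive")
    segments = []
    r0, t0 = 0.0, 0.0
    for conc, contact, diss in plan:
        t = np.arange(0.0, contact + dt / 2, dt)
        kobs = kon * conc + koff
        req = kon * conc * rmax / kobs
        resp = req + (r0 - req) * np.exp(-kobs * t)
        segments.append(Segment("association", conc, t0 + t, resp))
        r0, t0 = float(resp[-1]), t0 + contact
        t = np.arange(dt, diss + dt / 2, dt)
        resp = r0 * np.exp(-koff * t)
        segments.append(Segment("dissociation", 0.0, t0 + t, resp))
        r0, t0 = float(resp[-1]), t0 + t[-1]
    return Sensorgram(segments)


def _predict_sck(kon: float, koff: float, rmax: float, sensorgram: Sensorgram) -> np.ndarray:
    """Model response at every sampled time of an observed sensorgram."""
    out = []
    r0, t0 = 0.0, 0.0
    for seg in sensorgram.segments:
        rel = seg.times - t0
        if seg.phase == "association":
            kobs = kon * seg.concentration + koff
            req = kon * seg.concentration * rmax / kobs
            resp = req + (r0 - req) * np.exp(-kobs * rel)
        else:
            resp = r0 * np.exp(-koff * rel)
        out.append(resp)
        r0, t0 = float(resp[-1]), float(seg.times[-1])
    return np.concatenate(out)


def _runs_test_z(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs-test z statistic on residual signs."""
    signs = residuals >= 0
    n1 = int(signs.sum())
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int((signs[1:] != signs[:-1]).sum())
    mu = 2 * n1 * n2 / (n1 + n2) + 1
    var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    return (runs - mu) / math.sqrt(var) if var > 0 else 0.0


def fit_sck(sensorgram: Sensorgram, seed: int = 0, n_starts: int = 8) -> KineticFit:
    """Global 1:1 Langmuir fit of a single-cycle sensorgram.

    Fits kon, koff and Rmax in log space over every segment jointly with
    bulk refractive index fixed at 0 and the mass-transfer constant fixed
    at 1e8 (transport ignored).  Initial guesses: koff from the log-slope
    of the final dissociation, Rmax from the peak response, kon from an
    assumed mid-series KD.  A residual runs test flags biphasic behaviour
    that a 1:1 model cannot describe.
    """
    assoc = [s for s in sensorgram.segments if s.phase == "association"]
    if len(assoc) < 2:
        raise ValueError("need at least 2 association segments")
    obs = np.concatenate([s.response for s in sensorgram.segments])
    scale = float(np.max(np.abs(obs))) or 1.0

    diss = [s for s in sensorgram.segments if s.phase == "dissociation"][-1]
    pos = diss.response > 1e-3 * scale
    if pos.sum() >= 3:
        slope = np.polyfit(diss.times[pos], np.log(diss.response[pos]), 1)[0]
        koff0 = max(1e-6, -slope)
    else:
        koff0 = 1e-2
    rmax0 = 1.5 * scale
    kd0 = float(np.median([s.concentration for s in assoc]))
    kon0 = koff0 / kd0

    def residual(x):
        kon, koff, rmax = np.exp(x)
        return (_predict_sck(kon, koff, rmax, sensorgram) - obs) / scale

    x0 = np.log([kon0, koff0, rmax0])
    lb = np.log([1e-1, 1e-7, 1e-4 * scale])
    ub = np.log([1e10, 1e3, 1e4 * scale])
    best = _multistart(residual, x0, n_starts, seed, spread=2.0, bounds=(lb, ub))
    kon, koff, rmax = np.exp(best.x)
    resid = residual(best.x)
    norm = float(np.linalg.norm(resid) / math.sqrt(len(resid)))
    biphasic = norm > 1e-4 and abs(_runs_test_z(resid)) > 3.0
    return KineticFit(kon=float(kon), koff=float(koff), rmax=float(rmax),
                      residual_norm=norm, biphasic=biphasic)


def fit_steady_state(
    concentrations: np.ndarray, responses: np.ndarray, seed: int = 0
) -> tuple[float, float]:
    """One-site hyperbola fit of equilibrium responses: Req = Rmax C/(KD + C).

    Returns (KD, Rmax).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations")
    if np.ptp(r) == 0:
        raise FitError("degenerate steady-state data: all responses equal")
    rmax0 = 1.2 * r.max()
    half = rmax0 / 2
    kd0 = float(c[np.argmin(np.abs(r - half))]) or float(np.median(c))

    def residual(x):
        kd, rmax = np.exp(x)
        return rmax * c / (kd + c) - r

    best = _multistart(residual, np.log([kd0, rmax0]), 8, seed, spread=2.0)
    kd, rmax = np.exp(best.x)
    return float(kd), float(rmax)


def theoretical_rmax(
    ligand_density_ru: float, mw_ligand: float, mw_analyte: float, valence: int = 1
) -> float:
    """Maximum analyte-binding capacity of an SPR surface in RU.

    Rmax = ligand density x (analyte mass / ligand mass) x valence.
    """
    if ligand_density_ru <= 0 or mw_ligand <= 0 or mw_analyte <= 0 or valence <= 0:
        raise ValueError("all inputs must be positive")
    return ligand_density_ru * (mw_analyte / mw_ligand) * valence


# ---------------------------------------------------------------------------
# Isothermal titration calorimetry (one set of identical sites)
# ---------------------------------------------------------------------------

@dataclass
class ItcExperiment:
    """Injection geometry plus measured (or simulated) per-injection heats.

    ``injection_volumes`` are litres, ``heats_ucal`` microcalories; the
    first injection is the small pre-injection that is discarded in fits.
    """

    cell_concentration: float  # Mt, M (binder in the cell)
    syringe_concentration: float  # Xt0, M (titrant)
    cell_volume: float  # V0, L
    injection_volumes: np.ndarray  # L
    heats_ucal: np.ndarray | None = None
    temperature_c: float = 25.0
    pre_injection: bool = True  # first listed injection is discarded

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")


def standard_injection_scheme(
    pre_volume: float = 0.5e-6, n_injections: int = 29, volume: float = 1.0e-6
) -> np.ndarray:
    """A single 0.5 uL pre-injection followed by 29 injections of 1 uL."""
    return np.array([pre_volume] + [volume] * n_injections)


def _wiseman_cumulative_heat(
    n: float, kd: float, dh_kcal: float, mt: np.ndarray, xt: np.ndarray, v0: float
) -> np.ndarray:
    """Cumulative heat (cal) after each injection, one-set-of-sites model.

    The bound-site fraction theta solves the quadratic mass balance
    theta^2 - theta (1 + Xr + Kr) + Xr = 0 with Xr = Xt/(N Mt) and
    Kr = KD/(N Mt); Q = N theta Mt V0 dH.
    """
    xr = xt / (n * mt)
    kr = kd / (n * mt)
    b = 1.0 + xr + kr
    theta = (b - np.sqrt(b * b - 4.0 * xr)) / 2.0
    return n * theta * mt * v0 * dh_kcal * CAL_PER_KCAL


def itc_isotherm(
    n: float,
    kd: float,
    dh_kcal: float,
    experiment: ItcExperiment,
    volume_correction: str = "midpoint",
) -> np.ndarray:
    """Per-injection heats (ucal) of the one-set-of-sites (Wiseman) isotherm.

    Cell and syringe species are diluted by the cumulative displaced volume;
    the heat of injection i is the difference of cumulative heats plus, with
    the standard ``midpoint`` correction, the heat carried by the displaced
    half-volumes.  ``volume_correction="none"`` disables both displacement
    terms (ideal infinitesimal-injection geometry).
    """
    if n <= 0 or kd <= 0:
        raise ValueError("N and KD must be positive")
    v0 = experiment.cell_volume
    dv = experiment.injection_volumes
    vcum = np.cumsum(dv)
    if volume_correction == "midpoint":
        d = vcum / v0
        mt = experiment.cell_concentration * (1 - d / 2) / (1 + d / 2)
        xt = experiment.syringe_concentration * d / (1 + d / 2)
    elif volume_correction == "none":
        mt = np.full_like(vcum, experiment.cell_concentration)
        xt = experiment.syringe_concentration * vcum / v0
    else:
        raise ValueError(f"unknown volume_correction {volume_correction!r}")
    q = _wiseman_cumulative_heat(n, kd, dh_kcal, mt, xt, v0)
    qprev = np.concatenate([[0.0], q[:-1]])
    heats = q - qprev
    if volume_correction == "midpoint":
        heats = heats + (dv / v0) * (q + qprev) / 2.0
    return heats * 1e6  # cal -> ucal


def bound_fraction_root(n: float, kd: float, mt: float, xt: float) -> float:
    """Numerically solved bound-site fraction for one titration point.

    Independent route for the quadratic mass balance (bisection on the
    binding polynomial), used as a cross-check of the closed form.
    """
    from scipy.optimize import brentq

    def f(theta: float) -> float:
        free = xt - theta * n * mt
        return theta * kd - (1.0 - theta) * free

    return float(brentq(f, 0.0, min(1.0, xt / (n * mt)) if xt < n * mt else 1.0,
                        xtol=1e-15, rtol=1e-15))


def normalized_heats(experiment: ItcExperiment, heats_ucal: np.ndarray) -> np.ndarray:
    """kcal per mole of injectant for each injection."""
    moles = experiment.syringe_concentration * experiment.injection_volumes
    return (heats_ucal * 1e-6) / moles / CAL_PER_KCAL


@dataclass(frozen=True)
class ItcFit:
    n: float
    kd: float  # M
    dh_kcal: float  # kcal/mol
    c_value: float  # N Mt / KD
    unreliable_c: bool
    residual_norm: float


def fit_itc(
    experiment: ItcExperiment, seed: int = 0, n_starts: int = 8
) -> ItcFit:
    """Least-squares one-set-of-sites fit returning N, KD and dH.

    The pre-injection is excluded; heats are fitted in normalized form
    (kcal/mol of injectant).  A Wiseman c value (N Mt/KD) outside
    [0.1, 1e4] raises a reliability warning without failing the fit.
    """
    if experiment.heats_ucal is None:
        raise ValueError("experiment carries no measured heats")
    usable = slice(1, None) if experiment.pre_injection else slice(None)
    if len(experiment.injection_volumes[usable]) < 10:
        raise ValueError("need at least 10 usable injections")
    obs = normalized_heats(experiment, experiment.heats_ucal)[usable]
    dh0 = float(obs[0]) if obs[0] != 0 else -10.0
    kd0 = experiment.cell_concentration / 10.0

    def residual(x):
        n, kd = np.exp(x[0]), np.exp(x[1])
        dh = x[2]
        model = itc_isotherm(n, kd, dh, experiment)
        return normalized_heats(experiment, model)[usable] - obs

    x0 = np.array([0.0, math.log(kd0), dh0])
    lb = np.array([math.log(1e-3), math.log(1e-15), -1e4])
    ub = np.array([math.log(1e3), math.log(1e0), 1e4])
    best = _multistart(residual, x0, n_starts, seed, spread=1.5, bounds=(lb, ub))
    n, kd, dh = math.exp(best.x[0]), math.exp(best.x[1]), float(best.x[2])
    c = n * experiment.cell_concentration / kd
    unreliable = not (0.1 <= c <= 1e4)
    if unreliable:
        warnings.warn(f"Wiseman c value {c:.3g} outside [0.1, 1e4]: "
                      "KD poorly constrained", stacklevel=2)
    resid = residual(best.x)
    return ItcFit(n=n, kd=kd, dh_kcal=dh, c_value=c, unreliable_c=unreliable,
                  residual_norm=float(np.linalg.norm(resid) / math.sqrt(len(resid))))


# ---------------------------------------------------------------------------
# Fluorescence polarization
# ---------------------------------------------------------------------------

@dataclass
class FpTitration:
    """Direct FP titration of a fixed tracer with increasing receptor."""

    receptor_concentrations: np.ndarray  # M
    polarization_mp: np.ndarray
    tracer_concentration: float  # Lt, M
    p_free: float | None = None  # floor, mP
    p_bound: float | None = None  # ceiling, mP

    def __post_init__(self) -> None:
        self.receptor_concentrations = np.asarray(self.receptor_concentrations, float)
        self.polarization_mp = np.asarray(self.polarization_mp, float)
        if np.any(self.receptor_concentrations < 0) or self.tracer_concentration <= 0:
            raise ValueError("concentrations must be non-negative, tracer positive")


def fp_bound_fraction(kd: float, rt: np.ndarray, lt: float) -> np.ndarray:
    """Depletion-corrected bound fraction of the tracer.

    FB = ((KD + Lt + Rt) - sqrt((KD + Lt + Rt)^2 - 4 Lt Rt)) / (2 Lt),
    the exact single-site solution accounting for tracer depletion.
    """
    rt = np.asarray(rt, dtype=float)
    s = kd + lt + rt
    return (s - np.sqrt(s * s - 4.0 * lt * rt)) / (2.0 * lt)


@dataclass(frozen=True)
class FpFit:
    kd: float
    p_free: float
    p_bound: float
    residual_norm: float


def fp_direct_fit(titration: FpTitration, seed: int = 0) -> FpFit:
    """Apparent KD from a direct FP titration (depletion-corrected model)."""
    rt = titration.receptor_concentrations
    mp = titration.polarization_mp
    if len(rt) < 4:
        raise ValueError("need at least 4 receptor concentrations")
    order = np.argsort(rt)
    if np.corrcoef(rt[order], mp[order])[0, 1] < 0:
        warnings.warn("polarization decreases with receptor: gross non-monotonicity",
                      stacklevel=2)
    lt = titration.tracer_concentration
    fix_plateaus = titration.p_free is not None and titration.p_bound is not None
    pf0 = titration.p_free if titration.p_free is not None else float(mp.min())
    pb0 = titration.p_bound if titration.p_bound is not None else float(mp.max())
    half = (pf0 + pb0) / 2
    kd0 = float(rt[np.argmin(np.abs(mp - half))]) or float(np.median(rt[rt > 0]))

    if fix_plateaus:
        def residual(x):
            fb = fp_bound_fraction(math.exp(x[0]), rt, lt)
            return pf0 + (pb0 - pf0) * fb - mp
        best = _multistart(residual, np.array([math.log(kd0)]), 8, seed, spread=2.0)
        kd = math.exp(best.x[0])
        pf, pb = pf0, pb0
    else:
        def residual(x):
            fb = fp_bound_fraction(math.exp(x[0]), rt, lt)
            return x[1] + (x[2] - x[1]) * fb - mp
        best = _multistart(residual, np.array([math.log(kd0), pf0, pb0]), 8, seed,
                           spread=1.0)
        kd, pf, pb = math.exp(best.x[0]), float(best.x[1]), float(best.x[2])
    resid = residual(best.x)
    return FpFit(kd=float(kd), p_free=pf, p_bound=pb,
                 residual_norm=float(np.linalg.norm(resid) / math.sqrt(len(resid))))


# ---------------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------------

@dataclass
class CompetitionCurve:
    """Competitor titration against a preformed receptor-tracer complex."""

    competitor_concentrations: np.ndarray  # M
    signal: np.ndarray  # mP or % bound
    receptor_total: float  # Rt, M
    tracer_total: float  # Lt, M
    tracer_kd: float  # KD of the labelled tracer, M

    def __post_init__(self) -> None:
        self.competitor_concentrations = np.asarray(self.competitor_concentrations, float)
        self.signal = np.asarray(self.signal, float)
        if min(self.receptor_total, self.tracer_total, self.tracer_kd) <= 0:
            raise ValueError("Rt, Lt and tracer KD must be positive")


def free_receptor_ternary(
    rt: float, lt: float, it: float, kd_tracer: float, ki: float
) -> float:
    """Free receptor in the R/L/I competitive equilibrium (cubic root).

    Solves R^3 + a R^2 + b R + c = 0 with
    a = KdL + Ki + Lt + It - Rt,
    b = KdL Ki + Ki (Lt - Rt) + KdL (It - Rt),
    c = -Rt KdL Ki,
    taking the unique physical root in [0, Rt].
    """
    if it == 0:
        # binary reduction
        s = kd_tracer + lt - rt
        return float((-s + math.sqrt(s * s + 4 * kd_tracer * rt)) / 2.0)
    a = kd_tracer + ki + lt + it - rt
    b = kd_tracer * ki + ki * (lt - rt) + kd_tracer * (it - rt)
    c = -rt * kd_tracer * ki
    roots = np.roots([1.0, a, b, c])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    phys = real[(real >= -1e-15) & (real <= rt * (1 + 1e-12))]
    if len(phys) == 0:
        raise ArithmeticError("no physical root of the competition cubic")
    r = float(np.clip(phys.min(), 0.0, rt))
    # one Newton polish for extra accuracy
    f = ((r ** 3) + a * r * r + b * r + c)
    df = 3 * r * r + 2 * a * r + b
    if df != 0:
        r = float(np.clip(r - f / df, 0.0, rt))
    return r


def tracer_bound_fraction_competition(
    rt: float, lt: float, it: np.ndarray, kd_tracer: float, ki: float
) -> np.ndarray:
    """Fraction of tracer bound at each competitor concentration."""
    out = np.empty(len(it))
    for k, i in enumerate(np.asarray(it, dtype=float)):
        r = free_receptor_ternary(rt, lt, float(i), kd_tracer, ki)
        out[k] = r / (kd_tracer + r)
    return out


@dataclass(frozen=True)
class CompetitionFit:
    ki: float
    p_free: float
    p_bound: float
    residual_norm: float
    lower_bound_only: bool = False


def fp_competition_ki(curve: CompetitionCurve, seed: int = 0) -> CompetitionFit:
    """Inhibition constant from an FP competition curve.

    The tracer bound fraction at each competitor level comes from the exact
    ternary equilibrium (cubic in free receptor) with the tracer KD and
    concentrations held at their independently measured values; only KI and
    the signal plateaus are fitted.  A curve too flat to constrain KI is
    returned flagged ``lower_bound_only``.
    """
    it = curve.competitor_concentrations
    sig = curve.signal
    pb0, pf0 = float(sig.max()), float(sig.min())
    mid = (pb0 + pf0) / 2
    nz = it[it > 0]
    ki0 = float(nz[np.argmin(np.abs(sig[it > 0] - mid))]) if len(nz) else 1e-6

    def residual(x):
        fb = tracer_bound_fraction_competition(
            curve.receptor_total, curve.tracer_total, it, curve.tracer_kd,
            math.exp(x[0]))
        return x[1] + (x[2] - x[1]) * fb - sig

    lb = np.array([math.log(1e-15), -1e5, -1e5])
    ub = np.array([math.log(1e3), 1e5, 1e5])
    best = _multistart(residual, np.array([math.log(ki0), pf0, pb0]), 8, seed,
                       spread=2.0, bounds=(lb, ub))
    ki = math.exp(best.x[0])
    resid = residual(best.x)
    span = np.ptp(sig)
    noise = float(np.linalg.norm(resid) / math.sqrt(len(resid)))
    flat = span < 5 * noise or ki > 0.5 * float(np.exp(ub[0]))
    return CompetitionFit(ki=float(ki), p_free=float(best.x[1]), p_bound=float(best.x[2]),
                          residual_norm=noise, lower_bound_only=bool(flat))


def pulldown_ki(curve: CompetitionCurve, seed: int = 0) -> CompetitionFit:
    """One-site competition ("fit Ki") on normalized pull-down densitometry.

    A four-parameter logistic in log competitor concentration whose
    midpoint is tied to KI through the Cheng-Prusoff relation
    IC50 = KI (1 + [tracer]/KD_tracer); top and bottom are fitted, the
    tracer concentration and KD enter as fixed constants.  Signals are
    normalized so the 0-competitor lane reads 100%.
    """
    it = curve.competitor_concentrations
    if np.count_nonzero(it > 0) < 4:
        raise ValueError("need at least 4 competitor levels")
    ref_mask = it == 0
    ref = float(curve.signal[ref_mask].mean()) if ref_mask.any() else float(curve.signal.max())
    sig = 100.0 * curve.signal / ref
    shift = 1.0 + curve.tracer_total / curve.tracer_kd
    pos = it > 0
    logc = np.log10(it[pos])
    y = sig[pos]
    mid = (y.max() + y.min()) / 2
    ic50_guess = 10 ** float(logc[np.argmin(np.abs(y - mid))])
    ki0 = ic50_guess / shift

    def residual(x):
        log_ic50 = x[0] + math.log10(shift)
        top, bottom = x[1], x[2]
        return bottom + (top - bottom) / (1 + 10 ** (logc - log_ic50)) - y

    best = _multistart(residual, np.array([math.log10(ki0), 100.0, 0.0]), 8, seed,
                       spread=1.5)
    ki = 10 ** best.x[0]
    resid = residual(best.x)
    return CompetitionFit(ki=float(ki), p_free=float(best.x[2]), p_bound=float(best.x[1]),
                          residual_norm=float(np.linalg.norm(resid) / math.sqrt(len(resid))))


def effective_concentration(kd_module_a: float, kd_module_b: float, kd_fusion: float) -> float:
    """Effective concentration of a tethered binding element.

    C_eff = KD(A) x KD(B) / KD(A-B fusion): the local concentration one
    module experiences of the other when both are joined by a linker, a
    quantitative indicator of the avidity gain of the fusion.
    """
    if min(kd_module_a, kd_module_b, kd_fusion) <= 0:
        raise ValueError("all KD values must be positive")
    return kd_module_a * kd_module_b / kd_fusion
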