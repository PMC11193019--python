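"""Estimators for presteady-state transporter currents.

Covers the analysis chain of a rapid solution-exchange experiment:

* mono-exponential recovery fits, I = Imax (1 - exp(-t/tau));
* bi-exponential presteady-state fits, I = I1 exp(-t/tau_rise) +
  I2 exp(-t/tau_decay), with a nested F-test fallback to a single
  component;
* Michaelis-Menten and two-site dose-response fits,
  I = Imax c/(Km + c) and I = I1 c/(Km1 + c) + I2 c/(Km2 + c);
* the ln(k) versus voltage linear fit whose slope times 2RT/F is the
  apparent valence z_Q of the rate-limiting transition;
* paired-pulse recovery assembly (second-pulse peak recovery versus
  interpulse interval fitted with the mono-exponential form).

All nonlinear fits are trust-region least squares with deterministic
multi-start grids over the time-constant or Km decades, so results do
not depend on a lucky initial guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .constants import thermal_voltage_mV
from .kinetics import CurrentTrace

__all__ = [
    "DegenerateFitError",
    "ExpFit",
    "BiExpFit",
    "MMFit",
    "TwoSiteMMFit",
    "VoltageFit",
    "fit_mono_exponential",
    "fit_bi_exponential",
    "fit_mm",
    "fit_two_site_mm",
    "fit_voltage_dependence",
    "assemble_recovery",
    "fit_displacement_rise",
]

_TAU_GRID_MS = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)


class DegenerateFitError(ValueError):
    """Data cannot constrain the model (flat, empty, or unidentifiable)."""


@dataclass
class ExpFit:
    Imax: float
    tau_ms: float
    sse: float
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class BiExpFit:
    I1: float
    I2: float
    tau_rise_ms: float
    tau_decay_ms: float
    sse: float
    mono_fallback: bool = False
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class MMFit:
    Imax: float
    Km_mM: float
    sse: float
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class TwoSiteMMFit:
    I1: float
    Km1_mM: float
    I2: float
    Km2_mM: float
    sse: float
    sites_indistinct: bool = False
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class VoltageFit:
    slope_per_mV: float
    ln_k0: float
    zQ: float
    temperature_K: float


def _stderr(res, names: Sequence[str]) -> dict[str, float]:
    """Local-curvature parameter uncertainties from the Jacobian."""
    m, n = res.jac.shape
    if m <= n:
        return {}
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (2 * res.cost / (m - n))
        return {name: float(np.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate(names)}
    except np.linalg.LinAlgError:
        return {}


def _check_xy(times, values, min_points: int):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1D arrays of equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, y


def fit_mono_exponential(times_ms, values, fix_imax: float | None = None) -> ExpFit:
    """Least-squares fit of I = Imax (1 - exp(-t/tau)).

    Multi-start over a log-spaced tau grid; flat data raises
    :class:`DegenerateFitError`. ``fix_imax`` pins the amplitude (used for
    normalized recovery curves where Imax = 1 is a modelling choice).
    """
    t, y = _check_xy(times_ms, values, 4)
    if np.std(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateFitError("flat data: exponential fit is unidentifiable")
    t = t - t[0]

    best = None
    taus = [g for g in _TAU_GRID_MS] + [max(t[-1] / 3.0, 1e-3)]
    for tau0 in taus:
        g = 1.0 - np.exp(-t / tau0)
        if fix_imax is None:
            denom = float(g @ g)
            imax0 = float(g @ y) / denom if denom > 0 else y[-1]
            x0, names = [imax0, tau0], ["Imax", "tau_ms"]

            def resid(x):
                return x[0] * (1.0 - np.exp(-t / x[1])) - y

            bounds = ([-np.inf, 1e-9], [np.inf, np.inf])
        else:
            x0, names = [tau0], ["tau_ms"]

            def resid(x):
                return fix_imax * (1.0 - np.exp(-t / x[0])) - y

            bounds = ([1e-9], [np.inf])
        try:
            res = least_squares(resid, x0, bounds=bounds, method="trf")
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("mono-exponential fit failed to converge from every start")
    if fix_imax is None:
        imax, tau = best.x
    else:
        imax, tau = fix_imax, best.x[0]
    return ExpFit(Imax=float(imax), tau_ms=float(tau), sse=float(2 * best.cost),
                  stderr=_stderr(best, ["Imax", "tau_ms"] if fix_imax is None else ["tau_ms"]))


def _fit_single_decay(t, y):
    """Best single-component fit I1 exp(-t/tau), multi-start."""
    best = None
    for tau0 in _TAU_GRID_MS:
        g = np.exp(-t / tau0)
        a0 = float(g @ y) / float(g @ g)

        def resid(x):
            return x[0] * np.exp(-t / x[1]) - y

        try:
            res = least_squares(resid, [a0, tau0], bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                                method="trf")
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def fit_bi_exponential(times_ms, values, alpha: float = 0.05) -> BiExpFit:
    """Fit I = I1 exp(-t/tau_rise) + I2 exp(-t/tau_decay).

    Components are ordered so tau_rise <= tau_decay. When an F-test on
    the nested single-component fit does not support the second
    component at level ``alpha``, the single-component parameters are
    returned with ``mono_fallback=True``.
    """
    t, y = _check_xy(times_ms, values, 8)
    if np.std(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateFitError("flat data: exponential fit is unidentifiable")
    t = t - t[0]

    single = _fit_single_decay(t, y)
    if single is None:
        raise RuntimeError("exponential fit failed to converge")

    best = None
    grid = [g for g in _TAU_GRID_MS if g < 10 * t[-1]] or list(_TAU_GRID_MS)
    for i, tau1 in enumerate(grid):
        for tau2 in grid[i + 1:]:
            G = np.column_stack([np.exp(-t / tau1), np.exp(-t / tau2)])
            amp, *_ = np.linalg.lstsq(G, y, rcond=None)

            def resid(x):
                return x[0] * np.exp(-t / x[2]) + x[1] * np.exp(-t / x[3]) - y

            try:
                res = least_squares(
                    resid, [amp[0], amp[1], tau1, tau2],
                    bounds=([-np.inf, -np.inf, 1e-9, 1e-9], [np.inf] * 4),
                    method="trf",
                )
            except ValueError:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge from every start")

    sse_full = float(2 * best.cost)
    sse_single = float(2 * single.cost)
    n = t.size
    use_single = False
    if sse_full <= 0:
        use_single = False
    elif sse_single <= sse_full * (1 + 1e-12):
        use_single = True
    else:
        F = ((sse_single - sse_full) / 2.0) / (sse_full / max(n - 4, 1))
        p = float(f_dist.sf(F, 2, max(n - 4, 1)))
        use_single = p > alpha

    if use_single:
        a, tau = single.x
        return BiExpFit(I1=float(a), I2=0.0, tau_rise_ms=float(tau),
                        tau_decay_ms=float(tau), sse=sse_single, mono_fallback=True,
                        stderr=_stderr(single, ["I1", "tau_rise_ms"]))
    a1, a2, tau1, tau2 = best.x
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    return BiExpFit(I1=float(a1), I2=float(a2), tau_rise_ms=float(tau1),
                    tau_decay_ms=float(tau2), sse=sse_full,
                    stderr=_stderr(best, ["I1", "I2", "tau_rise_ms", "tau_decay_ms"]))


def fit_mm(concs_mM, values) -> MMFit:
    """Hyperbolic dose-response fit I = Imax c / (Km + c).

    The amplitude sign is free (block as well as activation data fit
    without preprocessing). Saturation-only or all-zero data raise
    :class:`DegenerateFitError`.
    """
    c = np.asarray(concs_mM, dtype=float)
    y = np.asarray(values, dtype=float)
    if c.size != y.size or np.unique(c).size < 3:
        raise ValueError("need values at >= 3 distinct concentrations")
    if np.all(np.abs(y) <= 1e-12 * max(1.0, np.abs(y).max())) or np.abs(y).max() == 0:
        raise DegenerateFitError("all-zero dose-response data")
    if np.std(y) <= 1e-9 * np.abs(y).max():
        raise DegenerateFitError("saturating-only data: Km unidentifiable")

    pos = c[c > 0]
    km0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    best = None
    for km_start in {km0, *(km0 * 10.0 ** k for k in (-1, 1))}:

        def resid(x):
            return x[0] * c / (x[1] + c) - y

        try:
            res = least_squares(resid, [y[np.argmax(c)], km_start],
                                bounds=([-np.inf, 1e-12], [np.inf, np.inf]), method="trf")
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("Michaelis-Menten fit failed to converge")
    return MMFit(Imax=float(best.x[0]), Km_mM=float(best.x[1]), sse=float(2 * best.cost),
                 stderr=_stderr(best, ["Imax", "Km_mM"]))


def fit_two_site_mm(concs_mM, values) -> TwoSiteMMFit:
    """Two-site dose-response fit I = I1 c/(Km1+c) + I2 c/(Km2+c).

    The two amplitudes may differ in sign (leak block at one site,
    activation at the other, producing a biphasic curve). Multi-start
    over ordered (Km1, Km2) log-grid pairs spanning the sampled decades;
    canonical ordering Km1 < Km2. Requires >= 5 distinct levels; a Km
    ratio below 3 at the optimum sets ``sites_indistinct``.
    """
    c = np.asarray(concs_mM, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(c).size < 5:
        raise ValueError("need values at >= 5 distinct concentrations")
    pos = c[c > 0]
    lo, hi = np.log10(pos.min()) - 1, np.log10(pos.max()) + 1
    km_grid = 10.0 ** np.arange(math.floor(lo), math.ceil(hi) + 1)

    best = None
    for i, km1 in enumerate(km_grid):
        for km2 in km_grid[i + 1:]:
            G = np.column_stack([c / (km1 + c), c / (km2 + c)])
            amp, *_ = np.linalg.lstsq(G, y, rcond=None)

            def resid(x):
                return x[0] * c / (x[1] + c) + x[2] * c / (x[3] + c) - y

            try:
                res = least_squares(
                    resid, [amp[0], km1, amp[1], km2],
                    bounds=([-np.inf, 1e-12, -np.inf, 1e-12], [np.inf] * 4),
                    method="trf",
                )
            except ValueError:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise RuntimeError("two-site fit failed to converge from every start")
    i1, km1, i2, km2 = best.x
    if km1 > km2:
        i1, km1, i2, km2 = i2, km2, i1, km1
    return TwoSiteMMFit(
        I1=float(i1), Km1_mM=float(km1), I2=float(i2), Km2_mM=float(km2),
        sse=float(2 * best.cost),
        sites_indistinct=bool(km2 < 3 * km1),
        stderr=_stderr(best, ["I1", "Km1_mM", "I2", "Km2_mM"]),
    )


def fit_voltage_dependence(voltages_mV, rate_constants, temperature_K: float = 297.0) -> VoltageFit:
    """Apparent valence from the ln(k) versus V linear fit.

    Ordinary least squares of ln k on V; z_Q = slope * 2 RT/F (RT/F in
    mV at the supplied temperature). Pure algebra beyond the line fit —
    no iterative optimizer is involved.
    """
    v = np.asarray(voltages_mV, dtype=float)
    k = np.asarray(rate_constants, dtype=float)
    if v.size < 3:
        raise ValueError("need rate constants at >= 3 voltages")
    if np.any(k <= 0):
        raise ValueError("all rate constants must be > 0 to take ln(k)")
    slope, intercept = np.polyfit(v, np.log(k), 1)
    zq = slope * 2.0 * thermal_voltage_mV(temperature_K)
    return VoltageFit(slope_per_mV=float(slope), ln_k0=float(intercept),
                      zQ=float(zq), temperature_K=temperature_K)


# --- trace-level assembly ---------------------------------------------------


def _post_jump_deviation(trace: CurrentTrace, start_ms: float, component: str,
                         baseline_ms: float, window_ms: float,
                         baseline_at_ms: float | None = None,
                         smooth_ms: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """(latency, deviation-from-baseline) in the post-jump window.

    ``baseline_at_ms`` moves the baseline window before a different time
    point (e.g. the first pulse), keeping it clear of washout
    transients; ``smooth_ms`` applies a moving-average filter before
    measurement to suppress extreme-value bias of noisy extrema.
    """
    t = trace.times_ms
    y = np.asarray(getattr(trace, component), dtype=float)
    if smooth_ms > 0 and t.size > 1:
        n = max(1, int(round(smooth_ms / (t[1] - t[0]))))
        if n > 1:
            y = np.convolve(y, np.ones(n) / n, mode="same")
    b_at = start_ms if baseline_at_ms is None else baseline_at_ms
    base_sel = (t >= b_at - baseline_ms) & (t < b_at)
    baseline = float(np.mean(y[base_sel])) if np.any(base_sel) else float(y[0])
    win = (t >= start_ms) & (t <= start_ms + window_ms)
    if not np.any(win):
        raise ValueError(f"no samples in the peak window after {start_ms} ms")
    return t[win] - start_ms, y[win] - baseline


def _pulse_peak(trace: CurrentTrace, start_ms: float, component: str,
                baseline_ms: float, window_ms: float,
                baseline_at_ms: float | None = None,
                sign: float | None = None,
                smooth_ms: float = 0.0) -> float:
    """Extremum relative to a pre-jump baseline (optionally sign-restricted)."""
    _, dev = _post_jump_deviation(trace, start_ms, component, baseline_ms,
                                  window_ms, baseline_at_ms, smooth_ms)
    if sign is None:
        return float(dev[np.argmax(np.abs(dev))])
    return float(sign * np.max(sign * dev))


def assemble_recovery(
    traces: Sequence[CurrentTrace],
    intervals_ms: Sequence[float] | None = None,
    component: str = "current_pA",
    baseline_ms: float = 50.0,
    window_ms: float = 100.0,
    fix_imax: bool = False,
    deadtime_ms: float = 0.0,
    smooth_ms: float = 2.0,
) -> ExpFit:
    """Paired-pulse recovery time constant from a set of traces.

    Each trace must carry (in ``meta`` or via ``intervals_ms``) its
    interpulse interval and the two pulse start times. The second-pulse
    peak (extremum of the first-pulse polarity in a 100 ms window after
    the jump, relative to the 50 ms baseline preceding the first pulse)
    is normalized to the first-pulse peak, and normalized recovery
    versus interval is fitted with I = Imax (1 - exp(-t/tau))
    (optionally with Imax pinned to 1).

    ``deadtime_ms`` shifts the interval axis by the command-to-removal
    latency of the solution exchange, so intervals count ligand-free
    time: with a piezo exchanger the ligand is actually removed about
    one exchange time after the washout command, and reapplied the same
    latency after the second command.
    """
    if intervals_ms is not None and len(intervals_ms) != len(traces):
        raise ValueError("one interval per trace required")
    rows = []
    for i, tr in enumerate(traces):
        meta = tr.meta
        interval = intervals_ms[i] if intervals_ms is not None else meta.get("interval_ms")
        if interval is None:
            raise ValueError(f"trace {i} has no interpulse interval tag")
        p1 = meta.get("pulse1_start_ms")
        p2 = meta.get("pulse2_start_ms")
        if p1 is None or p2 is None:
            raise ValueError(f"trace {i} lacks pulse timing metadata")
        lat1, dev1 = _post_jump_deviation(tr, p1, component, baseline_ms,
                                          window_ms, smooth_ms=smooth_ms)
        lat2, dev2 = _post_jump_deviation(tr, p2, component, baseline_ms,
                                          window_ms, baseline_at_ms=p1,
                                          smooth_ms=smooth_ms)
        rows.append((float(interval), lat1, dev1, lat2, dev2))

    # the first pulses of a family are identical stimuli: locate the peak on
    # the family-averaged first-pulse response, then read every amplitude at
    # that latency — immune to the extreme-value bias of searching noisy
    # windows trace by trace
    n_min = min(r[2].size for r in rows)
    dev1_mean = np.mean([r[2][:n_min] for r in rows], axis=0)
    i_pk = int(np.argmax(np.abs(dev1_mean)))
    latency = rows[0][1][i_pk]

    pairs = []
    for interval, lat1, dev1, lat2, dev2 in rows:
        peak1 = float(np.interp(latency, lat1, dev1))
        peak2 = float(np.interp(latency, lat2, dev2))
        if peak1 == 0:
            raise DegenerateFitError("first-pulse peak is zero; cannot normalize")
        pairs.append((interval, peak2 / peak1))
    pairs.sort()
    if len(pairs) < 3:
        raise ValueError("need >= 3 interpulse intervals")
    intervals = np.array([p[0] for p in pairs]) - deadtime_ms
    ratios = np.array([p[1] for p in pairs])
    keep = intervals > 0
    intervals, ratios = intervals[keep], ratios[keep]
    if intervals.size < 3:
        raise ValueError("fewer than 3 intervals exceed the exchange deadtime")
    return fit_mono_exponential(
        np.concatenate([[0.0], intervals]),
        np.concatenate([[0.0], ratios]),
        fix_imax=1.0 if fix_imax else None,
    )


def fit_displacement_rise(
    trace: CurrentTrace,
    switch_ms: float | None = None,
    component: str = "current_pA",
    plateau_fraction: float = 0.15,
    alpha: float = 0.05,
    deadtime_ms: float = 0.0,
) -> BiExpFit:
    """Bi-exponential fit of the substrate-evoked current rise.

    The approach to the post-switch plateau, plateau - I(t), is fitted
    with the two-component exponential sum; the fast component reports
    substrate activation of the unbound transporter fraction and the
    slow component inhibitor dissociation. Falls back to one component
    (flag set) when the data do not support two, e.g. at zero or
    saturating preincubation.

    ``deadtime_ms`` starts the fit clock at actual solution arrival
    (one exchange time after the switch command); exponential tails are
    preserved under the symmetric exchange blur, so this removes the
    early-sample bias on the fast time constant.
    """
    if switch_ms is None:
        switch_ms = trace.meta.get("switch_ms")
        if switch_ms is None:
            raise ValueError("switch time not given and absent from trace metadata")
    t = trace.times_ms
    y = getattr(trace, component)
    sel = t >= switch_ms + deadtime_ms
    ts, ys = t[sel] - (switch_ms + deadtime_ms), y[sel]
    n_tail = max(4, int(plateau_fraction * ts.size))
    plateau = float(np.mean(ys[-n_tail:]))
    return fit_bi_exponential(ts, plateau - ys, alpha=alpha)
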