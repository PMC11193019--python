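"""Stimulation protocols and seeded synthetic whole-cell traces.

Protocols are piecewise-constant command waveforms: solution protocols
hold per-species concentrations (mM) over contiguous time segments, and
voltage protocols hold the command potential (mV). Real solution
exchange is not instantaneous — a piezo-driven exchanger resolves 5 to
10 ms — so the commanded concentration is filtered by a single-
exponential relaxation with time constant ``exchange_tau_ms`` before it
reaches the kinetic model.

The synthetic generator closes the loop for every fitting stage: it
integrates a kinetic scheme under a protocol, computes the currents,
adds seeded white Gaussian noise (optionally low-pass filtered), and
records the ground truth in a machine-readable manifest, so estimator
accuracy can be measured against known parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kinetics import (
    CurrentTrace,
    KineticScheme,
    compute_currents,
    integrate_protocol,
)

__all__ = [
    "SolutionProtocol",
    "VoltageProtocol",
    "NoiseModel",
    "SyntheticDataset",
    "paired_pulse_protocol",
    "displacement_protocol",
    "dose_response_protocol",
    "generate_synthetic_traces",
    "noise_sd_for_snr",
]


@dataclass(frozen=True)
class SolutionProtocol:
    """Piecewise-constant command concentrations with exchange filtering.

    ``segments`` is a sequence of (start_ms, end_ms, {species: mM})
    entries that must be contiguous and non-overlapping from 0.
    """

    segments: tuple[tuple[float, float, dict[str, float]], ...]
    exchange_tau_ms: float = 5.0
    exchange_profile: str = "exponential"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exchange_tau_ms < 0:
            raise ValueError("exchange_tau_ms must be >= 0")
        if self.exchange_profile not in ("exponential", "erf"):
            raise ValueError("exchange_profile must be 'exponential' or 'erf'")
        prev_end = 0.0
        for start, end, conc in self.segments:
            if abs(start - prev_end) > 1e-9 or end <= start:
                raise ValueError("segments must be contiguous, non-overlapping, from 0")
            if any(c < 0 for c in conc.values()):
                raise ValueError("concentrations must be >= 0")
            prev_end = end

    @property
    def species(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, _, conc in self.segments:
            for s in conc:
                if s not in seen:
                    seen.append(s)
        return tuple(seen)

    @property
    def end_ms(self) -> float:
        return self.segments[-1][1]

    def segment_edges(self) -> list[float]:
        return [s[0] for s in self.segments] + [self.end_ms]

    def command_at(self, t_ms: float) -> dict[str, float]:
        """Commanded (unfiltered) concentrations at time t."""
        for start, end, conc in self.segments:
            if start - 1e-9 <= t_ms < end:
                return dict(conc)
        return dict(self.segments[-1][2])

    def filter_fraction(self, dt_ms: float) -> float:
        """Completed fraction of a solution transition, dt after the command.

        ``exponential``: 1 - exp(-dt/tau), the simplest relaxation model.
        Its slow tail keeps a washed-out ligand above binding-competitive
        levels for roughly 3 tau, which delays washout-clocked observables.
        ``erf``: a sigmoidal interface passage centred at tau with 10-90%
        width comparable to tau, emulating a piezo-stepped laminar
        interface; the on- and off-delays then cancel in interval-timed
        protocols.
        """
        tau = self.exchange_tau_ms
        if tau <= 0:
            return 1.0
        if self.exchange_profile == "exponential":
            return 1.0 - math.exp(-dt_ms / tau)
        return 0.5 * (1.0 + math.erf((dt_ms - tau) / (tau / 2.0)))


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant command potential around a holding level."""

    holding_mV: float = 0.0
    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for start, end, v in self.segments:
            if end <= start:
                raise ValueError("voltage segment end must exceed start")
            if not -100.0 - 1e-9 <= v <= 60.0 + 1e-9:
                raise ValueError(f"voltage {v} mV outside the supported -100..+60 mV range")

    def segment_edges(self) -> list[float]:
        out: list[float] = []
        for start, end, _ in self.segments:
            out.extend((start, end))
        return out

    def value_at(self, t_ms) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        v = np.full_like(t, self.holding_mV)
        for start, end, val in self.segments:
            v[(t >= start) & (t < end)] = val
        return v


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise in pA; same seed, same trace."""

    sd_pA: float
    seed: int = 0
    lowpass_cutoff_kHz: float | None = None

    def apply(self, trace: CurrentTrace, stream: int = 0) -> CurrentTrace:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, stream]))
        noise = rng.normal(0.0, self.sd_pA, size=trace.times_ms.size)
        if self.lowpass_cutoff_kHz is not None:
            from scipy.signal import lfilter

            dt_s = (trace.times_ms[1] - trace.times_ms[0]) / 1000.0
            alpha = 1.0 - np.exp(-2.0 * np.pi * self.lowpass_cutoff_kHz * 1e3 * dt_s)
            noise = lfilter([alpha], [1.0, alpha - 1.0], noise)
        return CurrentTrace(
            times_ms=trace.times_ms,
            current_pA=trace.current_pA + noise,
            transport_pA=trace.transport_pA,
            anion_pA=trace.anion_pA,
            meta={**trace.meta, "noise_sd_pA": self.sd_pA,
                  "noise_seed": [self.seed, stream]},
        )


@dataclass
class SyntheticDataset:
    """Generated traces plus the ground truth that produced them."""

    traces: list[CurrentTrace]
    manifest: dict

    def write(self, directory: str | Path) -> None:
        """One CSV per trace plus a JSON manifest with the ground truth."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, tr in enumerate(self.traces):
            name = f"trace_{i:03d}.csv"
            tr.to_frame().to_csv(directory / name, index=False)
            names.append({"file": name, "meta": _jsonable(tr.meta)})
        with (directory / "manifest.json").open("w") as out:
            json.dump({**_jsonable(self.manifest), "traces": names}, out, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# --- protocol builders ------------------------------------------------------


def paired_pulse_protocol(
    ligand: str,
    conc_mM: float,
    intervals_ms: Sequence[float],
    pulse_ms: float = 200.0,
    background: Mapping[str, float] | None = None,
    pre_ms: float = 50.0,
    post_ms: float = 200.0,
    exchange_tau_ms: float = 5.0,
) -> list[SolutionProtocol]:
    """Two identical ligand pulses separated by a variable washout interval.

    Returns one protocol per interpulse interval. Background species
    (e.g. 140 mM Na+) are present throughout; the ligand is applied for
    ``pulse_ms`` (200 ms by default), washed out for the interval, and
    applied again identically. The recovery of the second-pulse transient
    versus interval reports the slowest washout relaxation (turnover or
    inhibitor dissociation).
    """
    bg = dict(background or {})
    if any(i <= 0 for i in intervals_ms):
        raise ValueError("interpulse intervals must be > 0")
    out = []
    for interval in intervals_ms:
        t0 = pre_ms
        t1 = t0 + pulse_ms
        t2 = t1 + interval
        t3 = t2 + pulse_ms
        t4 = t3 + post_ms
        seg = (
            (0.0, t0, {**bg, ligand: 0.0}),
            (t0, t1, {**bg, ligand: conc_mM}),
            (t1, t2, {**bg, ligand: 0.0}),
            (t2, t3, {**bg, ligand: conc_mM}),
            (t3, t4, {**bg, ligand: 0.0}),
        )
        out.append(
            SolutionProtocol(
                segments=seg,
                exchange_tau_ms=exchange_tau_ms,
                meta={
                    "kind": "paired_pulse", "ligand": ligand, "conc_mM": conc_mM,
                    "interval_ms": float(interval), "pulse_ms": pulse_ms,
                    "pulse1_start_ms": t0, "pulse2_start_ms": t2,
                    "exchange_tau_ms": exchange_tau_ms,
                },
            )
        )
    return out


def displacement_protocol(
    inhibitor_conc_uM: float,
    preincubation_ms: float = 300.0,
    substrate_conc_mM: float = 2.0,
    na_mM: float = 140.0,
    observe_ms: float = 1000.0,
    exchange_tau_ms: float = 5.0,
    inhibitor: str = "I",
    substrate: str = "S",
) -> SolutionProtocol:
    """Inhibitor preincubation followed by rapid substrate replacement.

    The inhibitor is present from t = 0 through the preincubation, then
    replaced (never co-applied) by the substrate, with solution-exchange
    filtering. The slow phase of the subsequent current rise reports
    inhibitor dissociation; with 0 inhibitor the protocol degenerates to
    a plain substrate jump.
    """
    c_inh = inhibitor_conc_uM / 1000.0  # uM -> mM
    seg = (
        (0.0, preincubation_ms, {"Na": na_mM, inhibitor: c_inh, substrate: 0.0}),
        (preincubation_ms, preincubation_ms + observe_ms,
         {"Na": na_mM, inhibitor: 0.0, substrate: substrate_conc_mM}),
    )
    return SolutionProtocol(
        segments=seg,
        exchange_tau_ms=exchange_tau_ms,
        meta={
            "kind": "displacement", "inhibitor_conc_uM": inhibitor_conc_uM,
            "substrate_conc_mM": substrate_conc_mM,
            "switch_ms": preincubation_ms,
        },
    )


def dose_response_protocol(
    varied: str,
    levels_mM: Sequence[float],
    background: Mapping[str, float] | None = None,
    application_ms: float = 500.0,
    pre_ms: float = 100.0,
    exchange_tau_ms: float = 5.0,
) -> list[SolutionProtocol]:
    """Steady-application family: one protocol per concentration level.

    The steady-state current at the end of each application is the
    dose-response observable.
    """
    levels = [float(x) for x in levels_mM]
    if len(set(levels)) != len(levels) or any(x < 0 for x in levels):
        raise ValueError("levels must be distinct and >= 0")
    bg = dict(background or {})
    out = []
    for level in levels:
        seg = (
            (0.0, pre_ms, {**bg, varied: 0.0}),
            (pre_ms, pre_ms + application_ms, {**bg, varied: level}),
        )
        out.append(
            SolutionProtocol(
                segments=seg, exchange_tau_ms=exchange_tau_ms,
                meta={"kind": "dose_response", "varied": varied,
                      "level_mM": level, "application_start_ms": pre_ms},
            )
        )
    return out


# --- synthetic trace generation --------------------------------------------


def noise_sd_for_snr(trace: CurrentTrace, snr: float,
                     component: str = "current_pA") -> float:
    """Noise SD giving the requested peak signal-to-noise ratio."""
    signal = getattr(trace, component)
    peak = float(np.max(np.abs(signal - signal[0])))
    if peak == 0:
        raise ValueError("flat trace: SNR-based noise level undefined")
    return peak / snr


def generate_synthetic_traces(
    scheme: KineticScheme,
    protocols: Sequence[SolutionProtocol],
    voltage: VoltageProtocol | float = 0.0,
    noise: NoiseModel | None = None,
    anion_driving_mV: float = 60.0,
    dt_ms: float = 0.1,
    initial: str | np.ndarray = "equilibrate",
    ground_truth: Mapping[str, float] | None = None,
) -> SyntheticDataset:
    """Simulate each protocol, add seeded noise, record the ground truth.

    With ``noise=None`` (or sd 0) the traces equal the deterministic
    model output; the (seed, scheme, protocol) triple fully determines
    every output sample.
    """
    traces: list[CurrentTrace] = []
    for i, protocol in enumerate(protocols):
        traj = integrate_protocol(scheme, protocol, voltage=voltage,
                                  initial=initial, dt_ms=dt_ms)
        trace = compute_currents(traj, scheme, anion_driving_mV=anion_driving_mV)
        trace.meta.update(protocol.meta)
        if noise is not None and noise.sd_pA > 0:
            trace = noise.apply(trace, stream=i)
        traces.append(trace)
    manifest = {
        "ground_truth": dict(ground_truth or {}),
        "noise_sd_pA": noise.sd_pA if noise else 0.0,
        "noise_seed": noise.seed if noise else None,
        "anion_driving_mV": anion_driving_mV,
        "dt_ms": dt_ms,
        "n_traces": len(traces),
    }
    return SyntheticDataset(traces=traces, manifest=manifest)
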