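"""Flash-photolysis rebinding kinetics of a hexacoordinate globin.

After photolysis the heme is transiently pentacoordinate (P) and two
ligands compete for it: external CO (pseudo-first-order rate
a = k_on_CO * [CO]) and the internal distal histidine (unimolecular
k_on_His).  The His-bound state (H) relaxes back through P into the CO
state (C), producing the characteristic biphasic rebinding trace: a fast
competitive phase of amplitude a/(a + k_on_His) and a slow phase governed
by His dissociation.  With CO dissociation neglected on the observed
timescale (k_off_CO = 0), C is absorbing and the (P, H) subsystem is
linear two-state, so the trace is an exact biexponential with rates

    lambda_pm = [(a + k_on_His + k_off_His)
                 +- sqrt((a + k_on_His + k_off_His)^2 - 4 a k_off_His)] / 2.

The observable deltaA_N = P + H (fraction not yet CO-bound), normalized
to 1 at t = 0.

Equilibrium oxygen affinity of the hexacoordinate scheme:
[O2]_50 = (k_off_O2 / k_on_O2) * (1 + K_His) with K_His = k_on_His /
k_off_His; conversion to Torr uses the O2 solubility in water at 25 C,
1.82 uM/Torr.  Hexacoordination thus lowers apparent affinity by the
factor (1 + K_His) relative to the intrinsic heme affinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .genemodels import ValidationError

#: O2 solubility in water at 25 C, uM per Torr
O2_SOLUBILITY_25C = 1.82

#: half-saturation oxygen pressure the default parameter set is pinned to (Torr)
_DEFAULT_P50_TORR = 3.0


@dataclass
class KineticParams:
    """Six rate constants of the Fe/His/CO/O2 scheme.

    Units: bimolecular rates per uM per s; unimolecular rates per s.
    """

    k_on_CO: float
    k_off_CO: float
    k_on_O2: float
    k_off_O2: float
    k_on_His: float
    k_off_His: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def K_His(self) -> float:
        if self.k_off_His <= 0:
            raise ValidationError("K_His undefined: k_off_His = 0")
        return self.k_on_His / self.k_off_His

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParams":
        return cls(**json.loads(Path(path).read_text()))


def default_bflgb4_params() -> KineticParams:
    """Default parameter set for the amphioxus neuroglobin-like globin.

    k_on_His = 4000/s and k_off_His = 2/s are the measured internal-ligand
    rates; k_on_CO = 50 /uM/s and k_on_O2 = 200 /uM/s are plausible
    neuroglobin-class defaults; k_off_O2 is pinned so the equilibrium
    half-saturation pressure equals 3 Torr at 25 C.
    """
    k_on_His, k_off_His = 4000.0, 2.0
    k_on_O2 = 200.0
    k_his = k_on_His / k_off_His
    k_off_O2 = _DEFAULT_P50_TORR * O2_SOLUBILITY_25C * k_on_O2 / (1.0 + k_his)
    return KineticParams(
        k_on_CO=50.0, k_off_CO=0.0, k_on_O2=k_on_O2, k_off_O2=k_off_O2,
        k_on_His=k_on_His, k_off_His=k_off_His,
    )


@dataclass
class Trace:
    """Normalized rebinding time course at one CO concentration."""

    time: np.ndarray
    deltaA_N: np.ndarray
    co_conc: float
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.deltaA_N = np.asarray(self.deltaA_N, dtype=float)
        if self.time[0] != 0.0 or np.any(np.diff(self.time) <= 0):
            raise ValidationError("time grid must be strictly increasing and start at 0")
        if self.time.shape != self.deltaA_N.shape:
            raise ValidationError("time and signal shapes differ")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.time, "deltaA_N": self.deltaA_N, "co_uM": self.co_conc}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["deltaA_N"].to_numpy(), float(df["co_uM"].iloc[0]))


def simulate_rebinding(
    params: KineticParams,
    co_conc: float,
    time_grid,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    return_states: bool = False,
):
    """Integrate the three-state scheme from full photolysis (P = 1 at t = 0).

    Uses a stiff-safe implicit integrator (Radau, atol 1e-10 / rtol 1e-8);
    optional Gaussian noise is added to the normalized signal.
    """
    if co_conc <= 0:
        raise ValidationError("co_conc must be positive")
    t = np.asarray(time_grid, dtype=float)
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be strictly increasing and start at 0")
    a = params.k_on_CO * co_conc
    A = np.array(
        [
            [-(a + params.k_on_His), params.k_off_His, params.k_off_CO],
            [params.k_on_His, -params.k_off_His, 0.0],
            [a, 0.0, -params.k_off_CO],
        ]
    )
    sol = solve_ivp(
        lambda _t, y: A @ y,
        (0.0, float(t[-1])),
        np.array([1.0, 0.0, 0.0]),
        method="Radau",
        t_eval=t,
        jac=lambda _t, y: A,
        atol=1e-10,
        rtol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    signal = sol.y[0] + sol.y[1]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=signal.shape)
    trace = Trace(t, signal, co_conc, noise_sigma=noise_sigma, seed=seed)
    if return_states:
        return trace, sol.y  # rows: P, H, C
    return trace


def _biexp_terms(params: KineticParams, co_conc: float):
    """Rates and amplitudes of the exact two-state solution (k_off_CO = 0)."""
    a = params.k_on_CO * co_conc
    g, l = params.k_on_His, params.k_off_His
    # d(P,H)/dt = -M (P,H); deltaA = P + H, P(0) = 1, H(0) = 0
    M = np.array([[a + g, -l], [-g, l]])
    w, V = np.linalg.eig(M)
    order = np.argsort(-w.real)  # fast eigenvalue first
    w = w[order].real
    V = V[:, order].real
    coef = np.linalg.solve(V, np.array([1.0, 0.0]))
    amps = V.sum(axis=0) * coef
    return w, amps


def closed_form_rebinding(params: KineticParams, co_conc: float, t) -> np.ndarray:
    """Exact biexponential deltaA_N(t) for the absorbing-CO scheme.

    Valid only for k_off_CO = 0 (CO state absorbing); otherwise the full
    ODE path must be used.
    """
    if params.k_off_CO != 0:
        raise ValidationError("closed form requires k_off_CO = 0; use ODE path")
    t = np.asarray(t, dtype=float)
    rates, amps = _biexp_terms(params, co_conc)
    return amps[0] * np.exp(-rates[0] * t) + amps[1] * np.exp(-rates[1] * t)


def rebinding_eigenvalues(params: KineticParams, co_conc: float) -> tuple[float, float]:
    """(fast, slow) eigenvalues of the two-state subsystem."""
    rates, _ = _biexp_terms(params, co_conc)
    return float(rates[0]), float(rates[1])


@dataclass
class BiphasicFit:
    amplitude_fast: float
    rate_fast: float
    amplitude_slow: float
    rate_slow: float
    baseline: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.rate_fast <= self.rate_slow or self.rate_slow <= 0:
            raise ValidationError("rates must satisfy rate_fast > rate_slow > 0")
        if self.amplitude_fast < 0 or self.amplitude_slow < 0:
            raise ValidationError("amplitudes must be non-negative")


def fit_biphasic(trace: Trace, n_starts: int = 8) -> BiphasicFit:
    """Least-squares biexponential fit with multi-start rate initialization.

    Model: A_f exp(-r_f t) + A_s exp(-r_s t) + b.  Starting rates are
    log-spaced between 1/t_max and 1/dt_min; the best residual wins.
    """
    t, y = trace.time, trace.deltaA_N
    if len(t) < 20:
        raise ValidationError("need at least 20 points spanning both phases")
    dt_min = np.min(np.diff(t))
    r_lo, r_hi = 0.1 / t[-1], 2.0 / dt_min
    grid = np.geomspace(max(r_lo, 1e-6), r_hi, n_starts)

    def resid(p):
        af, rf, as_, rs, b = p
        return af * np.exp(-np.clip(rf * t, None, 700)) + as_ * np.exp(-np.clip(rs * t, None, 700)) + b - y

    best = None
    for i, rf0 in enumerate(grid):
        for rs0 in grid[:i]:
            p0 = np.array([0.5, rf0, 0.5, rs0, 0.0])
            try:
                res = least_squares(resid, p0, method="trf",
                                    bounds=([0, 1e-9, 0, 1e-9, -0.5], [2, np.inf, 2, np.inf, 0.5]))
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("biphasic fit failed to converge from any start")
    af, rf, as_, rs, b = best.x
    if rf < rs:
        af, rf, as_, rs = as_, rs, af, rf
    if rf == rs:
        rf *= 1.0 + 1e-9
    return BiphasicFit(af, rf, as_, rs, b, float(np.sqrt(2 * best.cost)))


@dataclass
class MechanismFit:
    params: KineticParams
    residual_norm: float
    identifiable: dict


def fit_mechanism(traces: list[Trace], n_starts: int = 4) -> MechanismFit:
    """Global least-squares fit of (k_on_CO, k_on_His, k_off_His) across traces.

    All traces must share the underlying parameters and differ in CO
    concentration; k_off_CO is fixed at 0 and the closed-form solution is
    the model.  Measurements at several concentrations decouple the CO
    association rate from the internal-ligand rates.
    """
    if len(traces) < 3:
        raise ValidationError("need traces at >= 3 CO concentrations")
    concs = {tr.co_conc for tr in traces}
    if len(concs) < 3:
        raise ValidationError("need >= 3 distinct CO concentrations")

    def model(log_p, tr):
        kco, kh_on, kh_off = np.exp(np.clip(log_p, -40.0, 40.0))
        p = KineticParams(kco, 0.0, 1.0, 1.0, kh_on, kh_off)
        return closed_form_rebinding(p, tr.co_conc, tr.time)

    def resid(log_p):
        return np.concatenate([model(log_p, tr) - tr.deltaA_N for tr in traces])

    starts = []
    for kco0 in (10.0, 100.0):
        for kh0 in (1000.0, 10000.0):
            starts.append(np.log([kco0, kh0, 1.0]))
    starts = starts[:n_starts] if n_starts < len(starts) else starts
    best = None
    for p0 in starts:
        try:
            res = least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("mechanistic fit failed to converge")
    kco, kh_on, kh_off = np.exp(np.clip(best.x, -40.0, 40.0))
    fitted = KineticParams(kco, 0.0, 0.0, 0.0, kh_on, kh_off)
    # His rates are unidentifiable when the hexacoordinate branch is silent:
    # the trace is then effectively monoexponential, i.e. one of the two
    # eigenmodes carries no amplitude at every concentration
    probe = KineticParams(kco, 0.0, 1.0, 1.0, kh_on, kh_off)
    biphasic_amp = max(min(abs(a) for a in _biexp_terms(probe, tr.co_conc)[1]) for tr in traces)
    identifiable = {"k_on_CO": True, "k_on_His": bool(biphasic_amp > 1e-3), "k_off_His": bool(biphasic_amp > 1e-3)}
    return MechanismFit(fitted, float(np.sqrt(2 * best.cost)), identifiable)


def oxygen_p50(params: KineticParams, temperature_label: str = "25C", solubility_uM_per_torr: float | None = None) -> float:
    """Equilibrium oxygen half-saturation pressure (Torr).

    [O2]_50 = Kd_O2 * (1 + K_His); hexacoordination competes with oxygen
    binding and raises the half-saturation concentration by (1 + K_His).
    """
    if params.k_on_O2 <= 0 or params.k_off_O2 <= 0:
        raise ValidationError("oxygen rates must be positive")
    if temperature_label not in ("25C",) and solubility_uM_per_torr is None:
        raise ValidationError(f"no O2 solubility constant for {temperature_label!r}; pass solubility_uM_per_torr")
    s = solubility_uM_per_torr if solubility_uM_per_torr is not None else O2_SOLUBILITY_25C
    k_his = params.k_on_His / params.k_off_His if params.k_off_His > 0 else 0.0
    if params.k_on_His == 0:
        k_his = 0.0
    o2_50_uM = (params.k_off_O2 / params.k_on_O2) * (1.0 + k_his)
    return o2_50_uM / s
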