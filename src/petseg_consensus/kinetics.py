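"""Two-tissue compartment FDG kinetics and arterial input functions.

The irreversible/reversible two-tissue compartment model describes FDG
uptake by a free (interstitial + cytosolic) pool ``C_f`` and a
phosphorylated pool ``C_b``::

    dC_f/dt = K1*Cp(t) - (k2 + k3)*C_f + k4*C_b
    dC_b/dt = k3*C_f - k4*C_b

with plasma input ``Cp``.  The measured tissue activity mixes in a blood
volume fraction ``VB``::

    C_T(t) = (1 - VB)*(C_f + C_b) + VB*C_blood(t),   C_blood := Cp.

``solve_2tc`` evaluates the model analytically when the input function is a
sum of exponential terms (the Feng population curve is), by convolving the
bi-exponential impulse response of the linear system with each input term;
arbitrary callables fall back to a stiff ODE integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "FengInput",
    "TAC",
    "TISSUE_PARAMS",
    "solve_2tc",
    "tissue_activity",
    "compute_uptake_ratios",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of one tissue's two-tissue compartment model.

    K1 in ml/(min*g); k2, k3, k4 in 1/min; VB dimensionless (ml blood / ml
    tissue).  k4 = 0 models irreversible trapping; VB = 0 ignores the blood
    signal.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    VB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "VB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.VB < 1:
            raise ValueError("VB must lie in [0, 1)")


#: Published kinetic parameters for the simulated tissue classes.  The three
#: lesion levels model intratumoral heterogeneity; normal lung is the
#: background the phantom normalizes to.
TISSUE_PARAMS: dict[str, KineticParams] = {
    "lesion_level_1": KineticParams(K1=0.180, k2=0.990, k3=0.190, k4=0.0, VB=0.036),
    "lesion_level_2": KineticParams(K1=0.150, k2=0.550, k3=0.120, k4=0.0, VB=0.071),
    "lesion_level_3": KineticParams(K1=0.110, k2=0.400, k3=0.073, k4=0.0, VB=0.095),
    "lung": KineticParams(K1=0.108, k2=0.735, k3=0.016, k4=0.013, VB=0.017),
    "liver": KineticParams(K1=0.864, k2=0.981, k3=0.005, k4=0.016, VB=0.0),
    "myocardium": KineticParams(K1=0.600, k2=1.200, k3=0.100, k4=0.001, VB=0.0),
    "bone_marrow": KineticParams(K1=0.200, k2=0.680, k3=0.050, k4=0.020, VB=0.010),
}


@dataclass(frozen=True)
class FengInput:
    """Feng (model 2) population FDG plasma input function.

    Cp(t) = (A1*t - A2 - A3)*exp(l1*t) + A2*exp(l2*t) + A3*exp(l3*t)

    with Cp(0) = 0 by construction.  Default amplitudes are the published
    population values; the absolute activity scale cancels in every ratio
    this package reports, so the units are arbitrary concentration.
    """

    A1: float = 851.1225
    A2: float = 21.8798
    A3: float = 20.8113
    l1: float = -4.133859
    l2: float = -0.01043449
    l3: float = -0.1190996

    def __call__(self, t):
        """Plasma activity at time ``t`` (minutes, >= 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = (
            (self.A1 * t - self.A2 - self.A3) * np.exp(self.l1 * t)
            + self.A2 * np.exp(self.l2 * t)
            + self.A3 * np.exp(self.l3 * t)
        )
        return out if out.ndim else float(out)

    def exp_terms(self) -> list[tuple[float, int, float]]:
        """Decomposition as ``coef * t**power * exp(rate*t)`` terms."""
        return [
            (self.A1, 1, self.l1),
            (-(self.A2 + self.A3), 0, self.l1),
            (self.A2, 0, self.l2),
            (self.A3, 0, self.l3),
        ]


@dataclass
class TAC:
    """A time-activity curve: sampling times (min) and activities."""

    times: np.ndarray
    activities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape:
            raise ValueError("times and activities must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activities < -1e-9):
            raise ValueError("activities must be non-negative")


def _conv_exp(alpha: float, lam: float, t: np.ndarray) -> np.ndarray:
    # ∫_0^t exp(alpha*(t-s)) * exp(lam*s) ds
    if abs(lam - alpha) < 1e-12:
        return t * np.exp(lam * t)
    return (np.exp(lam * t) - np.exp(alpha * t)) / (lam - alpha)


def _conv_t_exp(alpha: float, lam: float, t: np.ndarray) -> np.ndarray:
    # ∫_0^t exp(alpha*(t-s)) * s * exp(lam*s) ds
    if abs(lam - alpha) < 1e-12:
        return 0.5 * t**2 * np.exp(lam * t)
    d = lam - alpha
    return t * np.exp(lam * t) / d - (np.exp(lam * t) - np.exp(alpha * t)) / d**2


def _solve_analytic(p: KineticParams, input_fn, t: np.ndarray) -> np.ndarray:
    A = np.array([[-(p.k2 + p.k3), p.k4], [p.k3, -p.k4]])
    b = np.array([p.K1, 0.0])
    alphas, V = np.linalg.eig(A)
    if abs(alphas[0] - alphas[1]) < 1e-10 and np.linalg.cond(V) > 1e8:
        raise np.linalg.LinAlgError("near-defective rate matrix")
    w = np.linalg.solve(V, b)  # modal weights of the input column
    y = np.zeros((2, t.size))
    for j in range(2):
        conv = np.zeros_like(t)
        for coef, power, rate in input_fn.exp_terms():
            fn = _conv_t_exp if power == 1 else _conv_exp
            conv += coef * fn(alphas[j].real, rate, t)
        y += np.real(np.outer(V[:, j] * w[j], conv))
    return y  # rows: C_f, C_b


def _solve_numeric(p: KineticParams, input_fn, t: np.ndarray) -> np.ndarray:
    def rhs(tt, y):
        cp = input_fn(tt)
        return [p.K1 * cp - (p.k2 + p.k3) * y[0] + p.k4 * y[1],
                p.k3 * y[0] - p.k4 * y[1]]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [0.0, 0.0], t_eval=t,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"compartment ODE integration failed: {sol.message}")
    return sol.y


def solve_2tc(params: KineticParams, input_fn, times) -> TAC:
    """Solve the two-tissue compartment model on a time grid.

    Parameters
    ----------
    params : KineticParams
    input_fn : callable
        Plasma input ``Cp(t)``.  If it exposes ``exp_terms()`` the solution
        is evaluated in closed form; otherwise the ODEs are integrated.
    times : array-like, minutes
        Strictly increasing, all >= 0.

    Returns
    -------
    TAC
        Total tissue activity ``(1-VB)*(C_f+C_b) + VB*Cp`` at ``times``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    if hasattr(input_fn, "exp_terms"):
        try:
            y = _solve_analytic(params, input_fn, t)
        except np.linalg.LinAlgError:
            y = _solve_numeric(params, input_fn, t)
    else:
        y = _solve_numeric(params, input_fn, t)

    cp = np.asarray(input_fn(t), dtype=float)
    total = (1.0 - params.VB) * (y[0] + y[1]) + params.VB * cp
    return TAC(t, np.clip(total, 0.0, None))


def tissue_activity(params: KineticParams, input_fn, t: float) -> float:
    """Total tissue activity of one tissue at a single time point (minutes)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return 0.0
    return float(solve_2tc(params, input_fn, np.array([t])).activities[0])


def compute_uptake_ratios(
    lesion_params: tuple[KineticParams, KineticParams, KineticParams]
    | list[KineticParams]
    | None = None,
    background_params: KineticParams | None = None,
    input_fn=None,
    t: float = 70.0,
) -> tuple[float, ...]:
    """Lesion-to-background activity ratios at time ``t`` (default 70 min).

    Defaults to the three lesion heterogeneity levels against normal lung
    with the Feng population input.  The background activity must be
    positive at ``t``.
    """
    if lesion_params is None:
        lesion_params = [TISSUE_PARAMS[f"lesion_level_{i}"] for i in (1, 2, 3)]
    if background_params is None:
        background_params = TISSUE_PARAMS["lung"]
    if input_fn is None:
        input_fn = FengInput()
    if t <= 0:
        raise ValueError("t must be positive")
    bg = tissue_activity(background_params, input_fn, t)
    if bg <= 0:
        raise ValueError("background activity is zero; ratios undefined")
    return tuple(tissue_activity(p, input_fn, t) / bg for p in lesion_params)
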