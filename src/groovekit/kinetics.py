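"""Dithionite scrambling-assay kinetics: closed-form fluorescence model,
trace simulation, rate-constant fitting, leak estimation and flux-assay
quantification.

Model: liposomes split into a protein-free fraction f0 (only the outer
leaflet, fraction 1 - L_i_PF of the label, is quenched at rate gamma) and a
protein-containing fraction where label flips between leaflets at forward
rate alpha (inner -> outer) and backward rate beta while the outer leaflet
is quenched at gamma.  The total normalized fluorescence is

    F(t) = f0 (L + (1 - L) e^{-g t})
         + (1-f0)/(D (a+b)) { a (l2+g)(l1+a+b) e^{l1 t}
                              + l1 b (l2+a+b+g) e^{l2 t} }

with l1, l2 the (negative) eigenvalues and D the composite denominator;
l1 l2 = a g and l1 + l2 = -(a+b+g).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ScramblingParams",
    "EigenstructureE1",
    "FluorescenceTrace",
    "FitResult",
    "FluxRecord",
    "eigenstructure",
    "ftot",
    "simulate_trace",
    "fit_scrambling",
    "fit_leak",
    "flux_active_fraction",
    "fold_change",
]

# Below this rate the alpha -> 0 (or beta -> 0) analytic limit replaces the
# closed form.  The cancellation-free eigenstructure keeps the closed form
# accurate down to this scale, and the fast-mode amplitude dropped by the
# limit is O(alpha) ~ 1e-10 here, so the switch is continuous to < 1e-6.
EPS_DEGENERATE = 1e-12  # 1/s


@dataclass(frozen=True)
class ScramblingParams:
    f0: float                     # protein-free liposome fraction
    alpha: float                  # forward (inner -> outer) flip rate, 1/s
    beta: float                   # backward (outer -> inner) flip rate, 1/s
    gamma: float | None = None    # effective dithionite rate, 1/s
    gamma_prime: float | None = None  # second-order rate, 1/(M s)
    dithionite_conc: float | None = None  # M
    L_i_PF: float = 0.5           # inner-leaflet label fraction, protein-free

    def __post_init__(self) -> None:
        g = self.effective_gamma(strict=False)
        if self.alpha < 0 or self.beta < 0 or (g is not None and g < 0):
            raise ValueError("rates must be >= 0")
        if not (0 <= self.f0 <= 1 and 0 <= self.L_i_PF <= 1):
            raise ValueError("f0 and L_i_PF must lie in [0, 1]")
        if (
            self.gamma is not None
            and self.gamma_prime is not None
            and self.dithionite_conc is not None
        ):
            if not np.isclose(self.gamma, self.gamma_prime * self.dithionite_conc):
                raise ValueError("gamma != gamma_prime * dithionite_conc")

    def effective_gamma(self, strict: bool = True) -> float | None:
        if self.gamma is not None:
            return self.gamma
        if self.gamma_prime is not None and self.dithionite_conc is not None:
            return self.gamma_prime * self.dithionite_conc
        if strict:
            raise ValueError("gamma (or gamma_prime and dithionite_conc) required")
        return None


@dataclass(frozen=True)
class EigenstructureE1:
    lambda1: float
    lambda2: float
    D: float


def eigenstructure(alpha: float, beta: float, gamma: float) -> EigenstructureE1:
    """Eigenvalues and composite denominator of the two-leaflet system.

    lambda1 = -((a+b+g) - sqrt((a+b+g)^2 - 4 a g)) / 2 (the slow root),
    lambda2 the fast root, D = (l1+a)(l2+b+g) - a b.

    Evaluated through cancellation-free identities (l1 = -2ag/(s+root),
    l2+b+g = -(l1+a), hence D = -(l1+a)^2 - ab) so that small-alpha and
    small-beta regimes keep full precision.
    """
    l1, l2, l1pa = _stable_eigen(alpha, beta, gamma)
    return EigenstructureE1(
        lambda1=l1, lambda2=l2, D=-(l1pa * l1pa) - alpha * beta
    )


def _stable_eigen(a: float, b: float, g: float) -> tuple[float, float, float]:
    """(lambda1, lambda2, lambda1 + alpha) without subtractive cancellation."""
    s = a + b + g
    root = np.sqrt(max(s * s - 4.0 * a * g, 0.0))
    sr = s + root
    l1 = -2.0 * a * g / sr if sr > 0 else 0.0
    l2 = -sr / 2.0
    # l1 + a = a (a + b - g + root) / sr; when a + b < g the parenthesis is a
    # difference of near-equal terms, so use (root^2 - (g-b-a)^2) = 4 b g
    if a + b >= g:
        q = a + b - g + root
    else:
        denom = root + (g - b - a)
        q = 4.0 * b * g / denom if denom > 0 else 0.0
    l1pa = a * q / sr if sr > 0 else 0.0
    return float(l1), float(l2), float(l1pa)


def ftot(t: np.ndarray | float, params: ScramblingParams) -> np.ndarray:
    """Normalized total fluorescence at time(s) t (seconds).

    For alpha below the degeneracy threshold the analytic alpha -> 0 limit
    of the closed form is used (the protein-containing pool decays only
    through the slow eigenmode), since D(alpha+beta) vanishes there and the
    closed form becomes numerically singular.  An exactly repeated root
    ((a+b+g)^2 = 4 a g) with alpha above the threshold is surfaced as an
    error.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    g = params.effective_gamma()
    if g <= 0:
        raise ValueError("gamma must be > 0")
    L = params.L_i_PF
    pf = L + (1.0 - L) * np.exp(-g * t)
    a, b, f0 = params.alpha, params.beta, params.f0
    if a < EPS_DEGENERATE or b < EPS_DEGENERATE:
        # Vanishing-rate limit of the closed form.  The protein pool starts
        # at flip equilibrium (inner fraction b/(a+b)); the inner part
        # decays through the slow eigenmode, the outer part at gamma.
        # Reproduces both the alpha->0 (all inner, F -> e^{l1 t}) and
        # beta->0 (all outer, F -> e^{-g t}) limits continuously.
        l1, _, _ = _stable_eigen(a, b, g)
        pi_in = b / (a + b) if a + b > 0 else 1.0
        prot = pi_in * np.exp(l1 * t) + (1.0 - pi_in) * np.exp(-g * t)
        return f0 * pf + (1.0 - f0) * prot
    l1, l2, l1pa = _stable_eigen(a, b, g)
    denom = (-(l1pa * l1pa) - a * b) * (a + b)
    if denom == 0.0:  # unreachable for a, b > 0; defensive
        raise ValueError(
            "degenerate eigenstructure (D (alpha+beta) = 0) with alpha >= "
            f"{EPS_DEGENERATE}"
        )
    # l2 + g = -(l1+a) - b; l1 + a + b = l1pa + b; l2 + a + b + g = -l1
    bracket = (
        a * (-l1pa - b) * (l1pa + b) * np.exp(l1 * t)
        - l1 * l1 * b * np.exp(l2 * t)
    )
    return f0 * pf + (1.0 - f0) / denom * bracket


@dataclass(frozen=True)
class FluorescenceTrace:
    times: np.ndarray
    values: np.ndarray
    sampling_rate: float | None = None     # Hz
    dithionite_time: float | None = None   # s, addition time in the raw trace
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0) or not np.all(np.isfinite(v)):
            raise ValueError("invalid times or values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fluorescence trace {self.label}\n")
            fh.write("time_s,fluorescence\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.4f},{v:.8f}\n")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "FluorescenceTrace":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(times=df["time_s"].to_numpy(),
                   values=df["fluorescence"].to_numpy(), label=label)


def simulate_trace(
    params: ScramblingParams,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """ftot(times) plus seeded Gaussian noise."""
    times = np.asarray(times, dtype=float)
    values = ftot(times, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.standard_normal(len(times)) * noise_sd
    return FluorescenceTrace(times=times, values=values)


@dataclass(frozen=True)
class FitResult:
    f0: float
    alpha: float
    beta: float
    L_i_PF: float
    gamma: float
    sse: float
    converged: bool
    identifiability_warning: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "f0": self.f0, "alpha": self.alpha, "beta": self.beta,
            "L_i_PF": self.L_i_PF, "gamma": self.gamma, "sse": self.sse,
            "converged": self.converged,
            "identifiability_warning": self.identifiability_warning,
            "message": self.message,
        }


def fit_scrambling(
    trace: FluorescenceTrace,
    L_i_PF: float,
    gamma: float,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Bounded multi-start least-squares fit of (f0, alpha, beta).

    L_i_PF and gamma are fixed (experimentally determined).  An
    identifiability warning is raised when alpha saturates near gamma scale
    (the fast-scrambling regime where the fit cannot pin the rates).
    """
    b = {"f0": (0.0, 1.0), "alpha": (1e-6, 10.0), "beta": (1e-6, 10.0)}
    if bounds:
        b.update(bounds)
    t, y = trace.times, trace.values
    if t[-1] - t[0] < 5.0 / gamma:
        warnings.warn(
            "trace covers less than 5/gamma of post-dithionite time: "
            "slow-fit warning", stacklevel=2,
        )

    def residuals(theta):
        f0, log_a, log_b = theta
        p = ScramblingParams(
            f0=f0, alpha=np.exp(log_a), beta=np.exp(log_b),
            gamma=gamma, L_i_PF=L_i_PF,
        )
        return ftot(t, p) - y

    lo = np.array([b["f0"][0], np.log(b["alpha"][0]), np.log(b["beta"][0])])
    hi = np.array([b["f0"][1], np.log(b["alpha"][1]), np.log(b["beta"][1])])
    rng = np.random.default_rng(seed)
    best = None
    diagnostics = []
    for k in range(n_starts):
        if k == 0:
            x0 = np.array([0.3, np.log(0.01), np.log(0.01)])
        else:
            x0 = lo + rng.random(3) * (hi - lo)
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            diagnostics.append(f"start {k}: {exc}")
            continue
        diagnostics.append(f"start {k}: cost={res.cost:.6e} status={res.status}")
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            "scrambling fit failed from all starts:\n" + "\n".join(diagnostics)
        )
    f0, alpha, beta = best.x[0], float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    sse = float(2 * best.cost)
    ident = alpha >= 5.0 * gamma or alpha >= 0.99 * b["alpha"][1]
    if ident:
        logger.warning(
            "alpha = %.3g 1/s is in the saturating regime (>= 5 gamma): "
            "rate constants are not identifiable from this trace", alpha,
        )
    return FitResult(
        f0=float(f0), alpha=alpha, beta=beta, L_i_PF=L_i_PF, gamma=gamma,
        sse=sse, converged=True, identifiability_warning=bool(ident),
        message="; ".join(diagnostics[-1:]),
    )


def fit_leak(
    trace: FluorescenceTrace,
    tail_start: float | None = None,
) -> float:
    """Leak rate from the linear tail of a protein-free trace (1/s, >= 0
    for decaying tails).

    The tail (default: the final two thirds of the trace) is fit by least
    squares; the negated slope is returned.
    """
    t, y = trace.times, trace.values
    if tail_start is None:
        tail_start = t[0] + (t[-1] - t[0]) / 3.0
    mask = t >= tail_start
    if mask.sum() < 100:
        raise ValueError(
            f"leak tail has only {int(mask.sum())} samples (< 100)"
        )
    slope, _ = np.polyfit(t[mask], y[mask], 1)
    return float(-slope)


@dataclass(frozen=True)
class FluxRecord:
    delta_cl: float
    delta_cl_pf: float
    active_percent: float


def flux_active_fraction(delta_cl: float, delta_cl_pf: float) -> FluxRecord:
    """Percent of liposomes with at least one active channel:
    A = 100 (1 - delta_cl / delta_cl_pf), clipped to [0, 100]."""
    if delta_cl_pf <= 0:
        raise ValueError("delta_cl_pf must be > 0")
    if delta_cl < 0:
        raise ValueError("delta_cl must be >= 0")
    A = 100.0 * (1.0 - delta_cl / delta_cl_pf)
    if A < 0.0 or A > 100.0:
        warnings.warn(f"active fraction {A:.1f}% outside [0, 100]: clipped",
                      stacklevel=2)
        A = float(np.clip(A, 0.0, 100.0))
    return FluxRecord(delta_cl=delta_cl, delta_cl_pf=delta_cl_pf,
                      active_percent=A)


_FOLD_BANDS = (1000.0, 100.0, 10.0)


def fold_change(rate_reference: float, rate_test: float) -> tuple[float, str]:
    """Reduction ratio reference/test with a qualitative band label.

    Band edges are inclusive: a ratio of exactly 100 reports ">=100-fold".
    """
    if rate_reference <= 0 or rate_test <= 0:
        raise ValueError("rates must be > 0")
    ratio = rate_reference / rate_test
    for edge in _FOLD_BANDS:
        if ratio >= edge:
            return ratio, f">={edge:.0f}-fold"
    return ratio, ""
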