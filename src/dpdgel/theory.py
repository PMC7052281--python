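"""Langevin-chain constitutive model and the bond-stretch fracture criterion.

A freely jointed (Langevin) chain of N Kuhn segments with initial length
ratio l0 = L0/(N_b r0) stores free energy

    W_chain = kT N (x beta + ln(beta / sinh beta)),  beta = L^-1(x),

with x the fractional extension.  Because the entropic chain tension also
stretches the harmonic backbone bonds (stiffness C), the fractional
extension at mean bond stretch lambda_b is x = L^-1 argument obtained from
the force balance

    sqrt(I1/3) = (lambda_b / l0) * L( (N_b / 2N) (C r0^2 / kT)
                                      lambda_b (lambda_b - 1) ),

where sqrt(I1/3) is the mean chain stretch under bulk first invariant
I1 = lambda^2 + 2/lambda (incompressible uniaxial tension at stretch
lambda).  This removes the inverse-Langevin singularity: as the chain
straightens, further extension is carried by bond stretching.

Fracture: a chain breaks when one backbone bond reaches the critical
single-bond stretch lambda_b^cr; equating the chain's critical elastic
energy to the one-bond fracture energy spread over N_b bonds gives the
critical *mean* bond stretch

    lambda_bar_b^cr = 1 + (lambda_b^cr - 1) / sqrt(N_b).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import FiniteExtensibilityError, SolverError

#: critical mean bond stretch of the two-monomer chain (fracture strain
#: 0.225 of the atomistic reference tension test) and its bond count
REFERENCE_MEAN_CRITICAL = 1.225
REFERENCE_N_BONDS = 2


@dataclass
class TheoryParams:
    """Parameters of the chain model (reduced units).

    N defaults to N_b: one Kuhn segment per backbone bond, appropriate for
    the nearly freely jointed coarse-grained chains.
    """

    N_b: float
    l0: float
    C_over_kT: float = 116_000.0
    r0: float = 1.0
    N: float | None = None
    n_density: float = 1.0

    def __post_init__(self):
        if self.N is None:
            self.N = self.N_b
        if min(self.N_b, self.l0, self.C_over_kT, self.r0, self.N) <= 0:
            raise ValueError("all chain parameters must be positive")
        if not 0.0 < self.l0 < 1.0:
            raise ValueError("initial length ratio l0 must lie in (0, 1)")


@dataclass
class FractureCriterion:
    """Critical single-bond stretch and derived chain-level thresholds."""

    lambda_bond_cr: float
    C_over_kT: float = 116_000.0
    r0: float = 1.0

    @classmethod
    def from_reference_chain(cls, mean_critical: float = REFERENCE_MEAN_CRITICAL,
                             n_bonds: float = REFERENCE_N_BONDS,
                             **kwargs) -> "FractureCriterion":
        """Invert the criterion at the atomistic reference chain (N_b = 2)."""
        return cls(lambda_bond_cr=invert_to_bond_critical(mean_critical,
                                                          n_bonds), **kwargs)

    @property
    def W_cr(self) -> float:
        """Critical chain energy C/2 r0^2 (lambda_b^cr - 1)^2, units of kT."""
        return 0.5 * self.C_over_kT * self.r0**2 * (self.lambda_bond_cr - 1.0)**2

    def mean_critical(self, n_bonds) -> np.ndarray | float:
        """lambda_bar_b^cr(N_b) for chains of ``n_bonds`` bonds."""
        return critical_mean_bond_stretch(n_bonds, self.lambda_bond_cr)


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x with the series limit at 0."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def inverse_langevin(y, tol: float = 1e-12, max_iter: int = 50):
    """Inverse Langevin via the Pade approximant y(3 - y^2)/(1 - y^2)
    refined by Newton iterations to |L(L^-1(y)) - y| < 1e-10.

    Domain |y| < 1 (finite extensibility).
    """
    y_arr = np.asarray(y, dtype=np.float64)
    if np.any(np.abs(y_arr) >= 1.0):
        raise FiniteExtensibilityError("inverse Langevin requires |y| < 1")
    x = y_arr * (3.0 - y_arr**2) / (1.0 - y_arr**2)
    for _ in range(max_iter):
        fx = langevin(x) - y_arr
        # L'(x) = 1/x^2 - 1/sinh^2(x); series limit 1/3 at x = 0
        # np.where evaluates both branches: silence the x -> 0 divide
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            deriv = np.where(np.abs(x) < 1e-4, 1.0 / 3.0 - np.minimum(x, 1e4)**2 / 15.0,
                             1.0 / x**2 - 1.0 / np.sinh(np.clip(x, -700, 700))**2)
        x = x - fx / np.maximum(deriv, 1e-300)
        if np.all(np.abs(fx) < tol):
            break
    return x if x.ndim else float(x)


def chain_free_energy(lambda_c, params: TheoryParams):
    """Free energy per chain, units of kT: N (x beta + ln(beta/sinh beta)).

    x = lambda_c * l0 is the fractional extension; x >= 1 is beyond finite
    extensibility and raises.
    """
    x = np.asarray(lambda_c, dtype=np.float64) * params.l0
    if np.any(x >= 1.0):
        raise FiniteExtensibilityError("lambda_c * l0 must stay below 1")
    beta = np.asarray(inverse_langevin(x))
    # beta -> 0: x*beta + ln(beta/sinh(beta)) -> 3x^2/2 (Gaussian limit)
    small = np.abs(beta) < 1e-8
    w = np.empty_like(beta)
    w[small] = 1.5 * x[small]**2 if np.ndim(x) else 1.5 * float(x)**2
    bl = beta[~small]
    w[~small] = x[~small] * bl + np.log(bl / np.sinh(np.clip(bl, -700, 700)))
    out = params.N * w
    return out if out.ndim else float(out)


def bond_chain_relation(lambda_b, params: TheoryParams):
    """Mean chain stretch sqrt(I1/3) implied by a mean bond stretch.

    sqrt(I1/3) = (lambda_b / l0) * L((N_b/2N)(C r0^2/kT) lambda_b (lambda_b-1)).
    At lambda_b = 1 the Langevin argument vanishes and so does the result;
    the physical branch starts above 1.
    """
    lb = np.asarray(lambda_b, dtype=np.float64)
    arg = (params.N_b / (2.0 * params.N)) * params.C_over_kT * params.r0**2 \
        * lb * (lb - 1.0)
    out = lb / params.l0 * np.asarray(langevin(arg))
    return out if out.ndim else float(out)


def model_stretch_from_first_invariant(I1: float) -> float:
    """The tensile stretch lambda >= 1 with lambda^2 + 2/lambda = I1."""
    if I1 < 3.0 - 1e-12:
        raise ValueError("I1 must be >= 3")
    f = lambda lam: lam**2 + 2.0 / lam - I1
    hi = max(2.0, np.sqrt(I1))
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1.0, hi, xtol=1e-12, rtol=8.9e-16))


def solve_lambda_b(model_stretch, params: TheoryParams,
                   tol: float = 1e-14):
    """Mean bond stretch lambda_b at a given model stretch lambda.

    Root-finds bond_chain_relation(lambda_b) = sqrt((lambda^2 + 2/lambda)/3)
    on a bracket starting at 1; monotone non-decreasing in the model
    stretch.  Vectorised over ``model_stretch``.
    """
    lam_arr = np.atleast_1d(np.asarray(model_stretch, dtype=np.float64))
    if np.any(lam_arr < 1.0):
        raise ValueError("model stretch must be >= 1")
    out = np.empty_like(lam_arr)
    for k, lam in enumerate(lam_arr):
        target = np.sqrt((lam**2 + 2.0 / lam) / 3.0)
        f = lambda lb: bond_chain_relation(lb, params) - target
        lo = 1.0
        hi = target * params.l0 + 10.0
        if f(hi) < 0:
            raise SolverError(
                f"no bracketing root for lambda={lam}: f({hi})={f(hi)}")
        out[k] = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    return out if np.ndim(model_stretch) else float(out[0])


def theory_curve(params: TheoryParams, max_stretch: float,
                 n_points: int = 200):
    """(lambda, lambda_b) theoretical curve up to ``max_stretch``."""
    lam = np.linspace(1.0, max_stretch, n_points)
    return lam, solve_lambda_b(lam, params)


def critical_mean_bond_stretch(n_bonds, lambda_bond_cr: float):
    """lambda_bar_b^cr = 1 + (lambda_b^cr - 1)/sqrt(N_b); decreasing in N_b."""
    nb = np.asarray(n_bonds, dtype=np.float64)
    if np.any(nb < 1):
        raise ValueError("N_b must be >= 1")
    out = 1.0 + (lambda_bond_cr - 1.0) / np.sqrt(nb)
    return out if out.ndim else float(out)


def invert_to_bond_critical(mean_critical: float, n_bonds: float) -> float:
    """lambda_b^cr = 1 + (lambda_bar_b^cr - 1) sqrt(N_b)."""
    if n_bonds < 1:
        raise ValueError("N_b must be >= 1")
    return 1.0 + (mean_critical - 1.0) * np.sqrt(n_bonds)


def fracture_window(trace, criterion: FractureCriterion):
    """Lower/upper fracture stretch bounds from a tension trace.

    Lower: first model stretch at which any tracked chain's mean bond
    stretch reaches its own per-chain threshold lambda_bar_b^cr(N_b(c)).
    Upper: model stretch at which the all-chain mean bond stretch reaches
    the threshold at the mean bond count.  Crossings are linearly
    interpolated; bounds that are never reached are returned as NaN with a
    flag.

    Returns ``(lower, upper, open_ended)``.
    """
    if trace.lambda_b_chain is None or trace.chain_n_bonds is None:
        raise ValueError("trace must carry per-chain bond stretches")
    lam = trace.stretch
    thresholds = criterion.mean_critical(trace.chain_n_bonds)

    def first_crossing(series, thr):
        above = series >= thr
        if not above.any():
            return np.nan
        k = int(np.argmax(above))
        if k == 0:
            return float(lam[0])
        x0, x1 = series[k - 1], series[k]
        w = (thr - x0) / (x1 - x0) if x1 != x0 else 1.0
        return float(lam[k - 1] + w * (lam[k] - lam[k - 1]))

    per_chain = [first_crossing(trace.lambda_b_chain[:, c], thresholds[c])
                 for c in range(trace.lambda_b_chain.shape[1])]
    finite = [p for p in per_chain if np.isfinite(p)]
    lower = min(finite) if finite else np.nan
    mean_thr = criterion.mean_critical(float(np.mean(trace.chain_n_bonds)))
    upper = first_crossing(trace.lambda_b_mean, mean_thr)
    open_ended = not (np.isfinite(lower) and np.isfinite(upper))
    return lower, upper, open_ended
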