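"""Deformation, stress and transport observables.

Stress convention: tension-positive Cauchy stress, sigma = -(K + W)/V with
K_a = sum m v_a^2 and W_a = sum_pairs r_a F_a (force-on-i, each pair once),
so a stretched network gives positive axial stress and the mechanical
pressure is -mean(sigma).  The nominal stress of an incompressible
uniaxial test is P11 = (2 sigma_1 - sigma_2 - sigma_3) / (2 lambda).

Transport: the self-diffusivity D_simu is the zero-intercept least-squares
fit of the through-origin law <r^2> = 6 D t to the multi-origin MSD over
the first two DPD time units (the window over which a bead displaces by
about one cutoff); sqrt(6 D_simu) is then the diffusion length per DPD
time unit.  The asymptotic MSD slope (which exceeds the short-window value
because of slow hydrodynamic build-up) is exposed alongside it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, irfft, rfft

from . import engine
from .errors import StateError
from .state import BeadSystem, ForceField

#: physical constants of the coarse-grain time mapping (config defaults)
R_CUT_REAL_M = 6.98e-10      # real size of the cutoff, 6.98 Angstrom
D_WATER_REAL_M2_S = 2.43e-9  # self-diffusivity of real water
N_M_WATER = 8                # water molecules per bead


@dataclass
class TensionTrace:
    """Time series of an incompressible uniaxial tension test.

    ``stress`` rows are interval-averaged (sigma_1, sigma_2, sigma_3);
    ``lambda_b_chain`` has one column per tracked chain.
    """

    times: np.ndarray
    stretch: np.ndarray
    stress: np.ndarray
    P11: np.ndarray
    lambda_b_mean: np.ndarray
    lambda_b_chain: np.ndarray | None = None
    chain_n_bonds: np.ndarray | None = None

    @property
    def lateral_stretch(self) -> np.ndarray:
        return self.stretch ** -0.5

    @property
    def I1(self) -> np.ndarray:
        return self.stretch**2 + 2.0 / self.stretch

    @property
    def volume_ratio(self) -> np.ndarray:
        """lambda_1 * lambda_2 * lambda_3; 1 by construction."""
        return self.stretch * self.lateral_stretch**2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.times, "stretch": self.stretch,
            "sigma1": self.stress[:, 0], "sigma2": self.stress[:, 1],
            "sigma3": self.stress[:, 2], "P11": self.P11,
            "lambda_b_mean": self.lambda_b_mean,
        })
        if self.lambda_b_chain is not None:
            for c in range(self.lambda_b_chain.shape[1]):
                df[f"lambda_b_chain_{c}"] = self.lambda_b_chain[:, c]
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class TransportResult:
    """MSD curve and derived transport quantities (reduced units + ps)."""

    lag_times: np.ndarray
    msd: np.ndarray
    D_simu: float            # through-origin fit of <r^2> = 6 D t, t <= 2
    D_slope: float           # asymptotic slope fit / 6
    diffusion_length: float  # sqrt(6 D_simu * 1) per DPD time unit
    tau_real_ps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_time": self.lag_times, "msd": self.msd})


def nominal_stress(sigma, stretch: float) -> float:
    """P11 = (2 sigma_1 - sigma_2 - sigma_3) / (2 lambda)."""
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    sigma = np.asarray(sigma, dtype=np.float64)
    return float((2.0 * sigma[..., 0] - sigma[..., 1] - sigma[..., 2])
                 / (2.0 * stretch))


def virial_stress(system: BeadSystem, ff: ForceField,
                  rng: np.random.Generator | None = None,
                  alpha: np.ndarray | None = None) -> np.ndarray:
    """One-shot diagonal Cauchy stress of the current state (tension > 0).

    Includes the kinetic term and all pairwise contributions (conservative,
    dissipative, random if supplied, bond).  For time-averaged stress during
    a run use the interval averages recorded by the integrator.
    """
    fp, wp = engine.pair_forces(system, ff, rng=rng, alpha=alpha)
    fb, wb = engine.bond_force(system, ff)
    kin = system.mass * (system.velocities**2).sum(axis=0)
    return -(kin + wp + wb) / system.volume


def pressure(sigma) -> float:
    """Mechanical pressure, -trace(sigma)/3 in the tension-positive convention."""
    return float(-np.mean(np.asarray(sigma)))


def bond_stretch(system: BeadSystem, chains, r0: float = 1.0):
    """Per-chain mean bond stretch and the mean over all chain bonds.

    ``chains`` is a list of chain records (``bead_path`` attribute) or bead
    index sequences; bond vectors use the minimum image.
    """
    per_chain = np.empty(len(chains))
    all_lengths = []
    for c, chain in enumerate(chains):
        path = getattr(chain, "bead_path", chain)
        idx = np.asarray(path, dtype=np.int64)
        d = system.minimum_image(system.positions[idx[1:]]
                                 - system.positions[idx[:-1]])
        lengths = np.linalg.norm(d, axis=1)
        per_chain[c] = lengths.mean() / r0
        all_lengths.append(lengths)
    mean = float(np.concatenate(all_lengths).mean() / r0) if all_lengths else float("nan")
    return per_chain, mean


def _chain_paths(chains):
    out = []
    for chain in chains:
        path = getattr(chain, "bead_path", chain)
        out.append(np.asarray(path, dtype=np.int64))
    return out


def run_uniaxial_tension(system: BeadSystem, ff: ForceField, rate: float,
                         max_stretch: float | None = None,
                         n_steps: int | None = None, *,
                         seed: int | None = None, sample_every: int = 200,
                         chains=None) -> TensionTrace:
    """Incompressible uniaxial tension at constant true strain rate.

    Each step rescales the box to lambda_1 = exp(rate t),
    lambda_2 = lambda_3 = exp(-rate t / 2) and remaps coordinates affinely,
    then advances DPD dynamics; the volume is constant to round-off.  With
    ``rate = 0`` an undeformed control run of ``n_steps`` is performed.
    Stresses are averaged over each sampling interval.
    """
    if rate < 0:
        raise ValueError("loading rate must be >= 0")
    if rate > 0:
        if max_stretch is None or max_stretch <= 1:
            raise ValueError("max_stretch > 1 required for rate > 0")
        n_steps = int(np.ceil(np.log(max_stretch) / (rate * ff.dt)))
    elif n_steps is None:
        raise ValueError("n_steps required when rate = 0")

    paths = _chain_paths(chains) if chains is not None else None
    L0 = system.box[0]
    traj_stretch, traj_P11, lam_b_mean, lam_b_chain = [], [], [], []
    if seed is not None:
        engine.seed(seed)

    times, stresses = [], []
    done = 0
    while done < n_steps:
        k = min(sample_every, n_steps - done)
        t = engine.advance(system, ff, k,
                           strain_rates=(rate, -rate / 2.0, -rate / 2.0))
        done += k
        lam = system.box[0] / L0
        sig = t.stress[0]
        times.append(done * ff.dt)
        stresses.append(sig)
        traj_stretch.append(lam)
        traj_P11.append(nominal_stress(sig, lam))
        if paths is not None:
            pc, pm = bond_stretch(system, paths, r0=ff.bond_r0)
            lam_b_chain.append(pc)
            lam_b_mean.append(pm)
        else:
            lam_b_mean.append(np.nan)

    return TensionTrace(
        times=np.asarray(times), stretch=np.asarray(traj_stretch),
        stress=np.asarray(stresses), P11=np.asarray(traj_P11),
        lambda_b_mean=np.asarray(lam_b_mean),
        lambda_b_chain=np.asarray(lam_b_chain) if paths is not None else None,
        chain_n_bonds=(np.asarray([len(p) - 1 for p in paths])
                       if paths is not None else None))


def prepare_for_tension(system: BeadSystem, ff: ForceField,
                        target_C: float = 116_000.0, dt: float = 0.001,
                        stages: int = 12, steps_per_stage: int = 2_000,
                        seed: int | None = None) -> ForceField:
    """Anneal the bond stiffness from the gelation value up to ``target_C``.

    Switching C = 4 -> 116,000 abruptly would store ~C/2 <dr^2>_soft >> kT
    of elastic energy per bond; a geometric ramp with a short NVT run per
    stage lets the thermostat drain it.  Returns the stiff-bond force field.
    """
    if seed is not None:
        engine.seed(seed)
    C0 = max(ff.bond_C, 1.0)
    for s in range(1, stages + 1):
        C = C0 * (target_C / C0) ** (s / stages)
        engine.advance(system, ff.with_(bond_C=C, dt=dt), steps_per_stage)
    return ff.with_(bond_C=target_C, dt=dt)


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def msd_curve(frames: np.ndarray, lag_dt: float):
    """Multi-origin mean-square displacement via the FFT autocorrelation trick.

    ``frames``: (F, n, 3) unwrapped coordinates at uniform spacing
    ``lag_dt``.  Returns (lag_times, msd) for lags 1 .. F-1.
    """
    frames = np.asarray(frames, dtype=np.float64)
    F = frames.shape[0]
    if F < 3:
        raise StateError("trajectory too short for an MSD curve")
    nfft = next_fast_len(2 * F)
    X = rfft(frames, n=nfft, axis=0)
    acf = irfft(np.abs(X)**2, n=nfft, axis=0)[:F].sum(axis=2)
    sq = (frames**2).sum(axis=2)
    cs = np.cumsum(sq, axis=0)
    total = cs[-1]
    msd = np.empty(F - 1)
    for m in range(1, F):
        s1 = (total - (cs[m - 1] if m >= 1 else 0.0)) + cs[F - 1 - m]
        msd[m - 1] = np.mean((s1 - 2.0 * acf[m]) / (F - m))
    lags = lag_dt * np.arange(1, F)
    return lags, msd


def msd_and_diffusivity(frames: np.ndarray, times: np.ndarray, *,
                        fit_window: float = 2.0, fit_skip_fraction: float = 0.1,
                        n_m: int = N_M_WATER, r_cut_real: float = R_CUT_REAL_M,
                        d_water_real: float = D_WATER_REAL_M2_S) -> TransportResult:
    """MSD curve plus diffusivity estimators and the real-time mapping.

    ``D_simu`` is the zero-intercept least-squares fit of <r^2> = 6 D t to
    the lags up to ``fit_window`` DPD time units; ``D_slope`` is the free
    least-squares slope of the whole MSD after discarding the leading
    ``fit_skip_fraction`` (ballistic regime).  ``tau_real_ps`` =
    N_m D_simu R_cr^2 / D_water, in picoseconds.
    """
    times = np.asarray(times, dtype=np.float64)
    if len(times) != len(frames):
        raise StateError("times and frames disagree in length")
    if len(times) < 3:
        raise StateError("trajectory shorter than the fit window")
    lag_dt = float(times[1] - times[0])
    lags, msd = msd_curve(frames, lag_dt)
    if lags[0] > fit_window:
        raise StateError("trajectory thinner than the fit window")
    w = lags <= fit_window
    D_simu = float(np.sum(lags[w] * msd[w]) / (6.0 * np.sum(lags[w] ** 2)))
    # fit between 10% and 50% of the longest lag: beyond half the window
    # the multi-origin average has too few independent origins
    mask = (lags > fit_skip_fraction * lags[-1]) & (lags <= 0.5 * lags[-1])
    D_slope = float(np.polyfit(lags[mask], msd[mask], 1)[0] / 6.0)
    tau_s = n_m * D_simu * r_cut_real**2 / d_water_real
    return TransportResult(lag_times=lags, msd=msd, D_simu=D_simu,
                           D_slope=D_slope,
                           diffusion_length=float(np.sqrt(6.0 * D_simu)),
                           tau_real_ps=tau_s * 1e12)


def real_time_per_dpd_unit(D_simu: float, n_m: int = N_M_WATER,
                           r_cut_real: float = R_CUT_REAL_M,
                           d_water_real: float = D_WATER_REAL_M2_S) -> float:
    """Real time per DPD unit, tau = N_m D_simu R_cr^2 / D_water, in ps."""
    return float(n_m * D_simu * r_cut_real**2 / d_water_real * 1e12)
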