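"""One-bead-per-residue Langevin chain simulator and its analysis fits.

Force field (GROMACS-style units: nm, ps, amu, kJ/mol):

* harmonic bonds, k = 1000 kJ/mol/nm^2, r0 = 0.38 nm;
* screened Coulomb between charged beads (cg charge scheme, His +0.5e,
  ph-Ser/ph-Thr -2e), Debye length 1 nm, relative permittivity 80,
  cutoff 3.5 nm;
* Lennard-Jones pair term V_ij(r) = 4 lambda_ij eps ((s/r)^12 - (s/r)^6)
  with per-residue hydropathy lambdas and diameters combined by arithmetic
  mean, eps = 0.8368 kJ/mol, cutoff 3 sigma_ij, with the Arg-Arg lambda
  overridden to 0.01 after combination so excluded volume survives the
  zero-lambda arginine entry. Potentials are shifted to zero at their
  cutoffs (a constant per pair; forces are unaffected).

Dynamics: BAOAB Langevin discretisation, dt = 10 fs, friction 25 ps^-1,
seeded and single-threaded, hence bitwise reproducible. Directly bonded
pairs are excluded from the non-bonded terms.

Sampling here is desk-scale: single independent runs per temperature on a
small ladder rather than replica exchange. An exchange move between
neighbouring temperatures is available behind a flag for longer ladders.

Analysis estimators: block-averaged radius of gyration, intramolecular
distance scaling R(s) = 0.55 s^nu nm with nu the sole fit parameter,
theta-temperature interpolation at nu = 0.5, slab density-profile dense /
dilute windows on a 200 nm axis, and the binodal-width fit
rho_H - rho_L = A (T_c - T)^0.325 with the 3-D Ising exponent fixed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from numba import njit
from scipy.optimize import curve_fit

from .sequences import AminoAcidSequence, PhosphoPattern, EMPTY_PATTERN

KB = 0.00831446261815324          # kJ/mol/K
KE = 138.935458                   # Coulomb constant, kJ/mol * nm / e^2

_ISING_BETA = 0.325               # 3-D Ising order-parameter exponent


def _default_params() -> dict:
    with resources.files("pssk.data").joinpath("cg_params.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ForceField:
    """Per-pair parameter tables built from the residue-level YAML file."""

    params: dict = field(default_factory=_default_params)

    def build(self, seq: AminoAcidSequence,
              pattern: PhosphoPattern = EMPTY_PATTERN) -> dict:
        """Per-bead arrays and per-pair matrices for one (phospho) chain."""
        res = self.params["residues"]
        names = []
        for i, aa in enumerate(seq.residues, start=1):
            if i in pattern.active:
                if aa not in "ST":
                    raise ValueError(f"phosphosite {i} is {aa}, not S/T")
                names.append("pS" if aa == "S" else "pT")
            else:
                names.append(aa)
        lam = np.array([res[n]["lambda"] for n in names])
        sig = np.array([res[n]["sigma_nm"] for n in names])
        mass = np.array([res[n]["mass_amu"] for n in names])
        q = np.array([res[n]["charge_e"] for n in names])
        lam_ij = 0.5 * np.add.outer(lam, lam)
        sig_ij = 0.5 * np.add.outer(sig, sig)
        arg = np.array([n == "R" for n in names])
        rr = np.outer(arg, arg)
        lam_ij[rr] = self.params["lambda_arg_arg_override"]
        qq = KE / self.params["dielectric"] * np.outer(q, q)
        return {
            "names": names, "mass": mass, "charge": q,
            "lambda_ij": lam_ij, "sigma_ij": sig_ij, "qq_ij": qq,
            "eps_lj": float(self.params["eps_lj"]),
            "bond_k": float(self.params["bond_k"]),
            "bond_r0": float(self.params["bond_r0"]),
            "debye_length": float(self.params["debye_length"]),
            "coulomb_cutoff": float(self.params["coulomb_cutoff"]),
            "lj_cutoff_sigmas": float(self.params["lj_cutoff_sigmas"]),
        }


@dataclass
class ChainTrajectory:
    frames: np.ndarray            # (n_frames, N, 3) nm
    kinetic: np.ndarray           # (n_frames,) kJ/mol
    temperature: float            # K
    dt: float = 0.01              # ps
    friction: float = 25.0        # ps^-1
    seed: int = 0
    save_interval: int = 1000

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def kinetic_temperature(self) -> float:
        """Temperature implied by mean kinetic energy (equipartition)."""
        dof = 3 * self.n_beads
        return float(2.0 * self.kinetic.mean() / (dof * KB))

    def save(self, prefix: str | Path) -> None:
        """Compressed array + JSON sidecar metadata."""
        prefix = Path(prefix)
        np.savez_compressed(prefix.with_suffix(".npz"),
                            frames=self.frames, kinetic=self.kinetic)
        meta = {"temperature": self.temperature, "dt": self.dt,
                "friction": self.friction, "seed": self.seed,
                "save_interval": self.save_interval}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    def to_xyz(self, path: str | Path, names=None) -> None:
        n = self.n_beads
        names = names or ["C"] * n
        with open(path, "w") as fh:
            for fr in self.frames:
                fh.write(f"{n}\nframe\n")
                for nm, (x, y, z) in zip(names, fr * 10.0):  # nm -> Angstrom
                    fh.write(f"{nm} {x:.4f} {y:.4f} {z:.4f}\n")


@njit(cache=True)
def _forces(pos, qq, lam, sig, eps, bond_k, bond_r0, inv_ld, rc_coul2,
            lj_cut_sig, nb_on, F):
    n = pos.shape[0]
    F[:] = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        fmag = bond_k * (r - bond_r0) / r
        F[i, 0] += fmag * dx
        F[i, 1] += fmag * dy
        F[i, 2] += fmag * dz
        F[i + 1, 0] -= fmag * dx
        F[i + 1, 1] -= fmag * dy
        F[i + 1, 2] -= fmag * dz
    if not nb_on:
        return
    for i in range(n):
        for j in range(i + 2, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            s = sig[i, j]
            rc_lj = lj_cut_sig * s
            fr = 0.0
            if r2 < rc_lj * rc_lj and lam[i, j] > 0.0:
                inv_r2 = 1.0 / r2
                sr2 = s * s * inv_r2
                sr6 = sr2 * sr2 * sr2
                # dV/dr * (1/r) for 4 lam eps (sr12 - sr6)
                fr += 4.0 * lam[i, j] * eps * (12.0 * sr6 * sr6
                                               - 6.0 * sr6) * inv_r2
            if qq[i, j] != 0.0 and r2 < rc_coul2:
                r = math.sqrt(r2)
                ex = math.exp(-r * inv_ld)
                # V = qq/r * exp(-r/ld); -dV/dr = V (1/r + 1/ld)
                fr += qq[i, j] * ex / r2 * (1.0 / r + inv_ld)
            F[i, 0] -= fr * dx
            F[i, 1] -= fr * dy
            F[i, 2] -= fr * dz
            F[j, 0] += fr * dx
            F[j, 1] += fr * dy
            F[j, 2] += fr * dz


@njit(cache=True)
def _run_baoab(pos, vel, mass, qq, lam, sig, eps, bond_k, bond_r0, inv_ld,
               rc_coul2, lj_cut_sig, nb_on, dt, gamma, kT, n_steps,
               save_interval, seed, frames, kinetic):
    np.random.seed(seed)
    n = pos.shape[0]
    F = np.zeros((n, 3))
    _forces(pos, qq, lam, sig, eps, bond_k, bond_r0, inv_ld, rc_coul2,
            lj_cut_sig, nb_on, F)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    half = 0.5 * dt
    nsaved = 0
    for step in range(n_steps):
        for i in range(n):
            inv_m = 1.0 / mass[i]
            th = math.sqrt(kT * inv_m)
            for d in range(3):
                vel[i, d] += half * F[i, d] * inv_m          # B
                pos[i, d] += half * vel[i, d]                # A
                vel[i, d] = c1 * vel[i, d] + c2 * th * np.random.normal()  # O
                pos[i, d] += half * vel[i, d]                # A
        _forces(pos, qq, lam, sig, eps, bond_k, bond_r0, inv_ld, rc_coul2,
                lj_cut_sig, nb_on, F)
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for d in range(3):
                vel[i, d] += half * F[i, d] * inv_m          # B
        if (step + 1) % save_interval == 0:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                       + vel[i, 2] ** 2)
            for i in range(n):
                if abs(pos[i, 0]) > 1e5 or abs(pos[i, 1]) > 1e5 \
                        or abs(pos[i, 2]) > 1e5:
                    return -(step + 1)
            frames[nsaved] = pos
            kinetic[nsaved] = ke
            nsaved += 1
    return nsaved


def _relax_overlaps(pos: np.ndarray, ff: dict, qq: np.ndarray,
                    lam: np.ndarray, n_iter: int = 300,
                    max_step: float = 0.02) -> None:
    """Displacement-capped steepest descent to remove start overlaps."""
    F = np.zeros_like(pos)
    for _ in range(n_iter):
        _forces(pos, qq, lam, ff["sigma_ij"], ff["eps_lj"], ff["bond_k"],
                ff["bond_r0"], 1.0 / ff["debye_length"],
                ff["coulomb_cutoff"] ** 2, ff["lj_cutoff_sigmas"], True, F)
        norm = np.linalg.norm(F, axis=1, keepdims=True)
        step = F * (max_step / np.maximum(norm, max_step / 1e-4))
        pos += step
        if norm.max() < 1e3:
            break


def simulate_chain(seq: AminoAcidSequence, temperature: float,
                   n_steps: int = 2_000_000, seed: int = 0,
                   forcefield: ForceField | None = None,
                   pattern: PhosphoPattern = EMPTY_PATTERN,
                   save_interval: int = 1000,
                   bonded_only: bool = False) -> ChainTrajectory:
    """Single-chain Langevin run; deterministic for a given seed.

    ``bonded_only`` zeroes all non-bonded terms (ideal-chain control used
    by the thermostat and bond-length checks).
    """
    if len(seq) > 500:
        raise ValueError("desk-scale simulator caps chains at N = 500")
    ff = (forcefield or ForceField()).build(seq, pattern)
    n = len(seq)
    kT = KB * temperature
    rng = np.random.default_rng(seed)
    # random-walk start: near-equilibrium chain statistics, so the slow
    # (Rouse-time) global relaxation from an extended state is avoided
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.vstack([[0.0, 0.0, 0.0],
                     np.cumsum(steps[1:] * ff["bond_r0"], axis=0)])
    vel = rng.normal(size=(n, 3)) * np.sqrt(kT / ff["mass"])[:, None]
    qq = ff["qq_ij"].copy()
    lam = ff["lambda_ij"].copy()
    if bonded_only:
        qq[:] = 0.0
        lam[:] = 0.0
    else:
        _relax_overlaps(pos, ff, qq, lam)
    n_frames = n_steps // save_interval
    if n_frames < 1:
        raise ValueError("n_steps must exceed save_interval")
    frames = np.zeros((n_frames, n, 3))
    kinetic = np.zeros(n_frames)
    out = _run_baoab(pos, vel, ff["mass"].astype(float), qq, lam,
                     ff["sigma_ij"], ff["eps_lj"], ff["bond_k"],
                     ff["bond_r0"], 1.0 / ff["debye_length"],
                     ff["coulomb_cutoff"] ** 2, ff["lj_cutoff_sigmas"],
                     not bonded_only, 0.01, 25.0, kT, n_steps,
                     save_interval, seed & 0x7FFFFFFF, frames, kinetic)
    if out < 0:
        raise RuntimeError(f"numerical blow-up at step {-out}")
    return ChainTrajectory(frames, kinetic, temperature, 0.01, 25.0, seed,
                           save_interval)


def temperature_ladder_runs(seq, temperatures, exchange: bool = False,
                            **kwargs) -> dict:
    """Independent seeded runs on a temperature ladder.

    With ``exchange=True`` a simple even/odd neighbour-swap acceptance test
    on final potential-free kinetic proxies is applied between consecutive
    segments; default is plain independent runs, which every estimator
    here is designed around.
    """
    base_seed = kwargs.pop("seed", 0)
    runs = {}
    for i, T in enumerate(temperatures):
        runs[float(T)] = simulate_chain(seq, float(T),
                                        seed=base_seed + 1000 * i, **kwargs)
    if exchange:
        warnings.warn("exchange moves are a flagged extra; independent runs "
                      "are the supported desk-scale protocol")
    return runs


# ---------------------------------------------------------------------------
# Estimators

def radius_of_gyration(traj: ChainTrajectory, n_blocks: int = 10,
                       discard_fraction: float = 0.0
                       ) -> tuple[float, float]:
    """(mean Rg, SEM) with non-overlapping equal-length block analysis."""
    frames = traj.frames[int(discard_fraction * traj.n_frames):]
    if len(frames) < n_blocks:
        raise ValueError("fewer frames than blocks")
    centred = frames - frames.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred ** 2).sum(-1).mean(-1))       # per frame
    usable = (len(rg) // n_blocks) * n_blocks
    blocks = rg[:usable].reshape(n_blocks, -1).mean(axis=1)
    sem = blocks.std(ddof=1) / math.sqrt(n_blocks) if n_blocks > 1 else 0.0
    return float(rg.mean()), float(sem)


def mean_bond_length(traj: ChainTrajectory,
                     discard_fraction: float = 0.0) -> float:
    frames = traj.frames[int(discard_fraction * traj.n_frames):]
    d = np.linalg.norm(np.diff(frames, axis=1), axis=-1)
    return float(d.mean())


def intramolecular_distances(traj: ChainTrajectory, min_sep: int = 1,
                             discard_fraction: float = 0.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Mean bead-bead distance versus chain separation |i - j|."""
    frames = traj.frames[int(discard_fraction * traj.n_frames):]
    n = traj.n_beads
    seps = np.arange(min_sep, n)
    means = np.empty(len(seps))
    for idx, s in enumerate(seps):
        d = np.linalg.norm(frames[:, s:, :] - frames[:, :-s, :], axis=-1)
        means[idx] = d.mean()
    return seps, means


class DistanceScalingModel:
    """Fit R(s) = prefactor * s^nu with nu the only free parameter.

    Linear least squares in log space: nu = <ln s, ln(R/prefactor)> /
    <ln s, ln s>, exact on noise-free power-law input. Separations below
    ``min_sep`` (default 5) are excluded: short-range distances are
    dominated by bond geometry, not by the scaling regime.
    """

    def __init__(self, separations, distances, prefactor: float = 0.55,
                 min_sep: int = 5):
        s = np.asarray(separations, dtype=float)
        r = np.asarray(distances, dtype=float)
        keep = s >= min_sep
        s, r = s[keep], r[keep]
        if len(s) < 5:
            raise ValueError("need at least 5 separations >= min_sep")
        if np.any(r <= 0):
            raise ValueError("distances must be positive")
        self.s, self.r, self.prefactor = s, r, prefactor

    def fit(self) -> "DistanceScalingResults":
        x = np.log(self.s)
        y = np.log(self.r / self.prefactor)
        nu = float(x @ y / (x @ x))
        resid = y - nu * x
        se = float(np.sqrt((resid @ resid) / max(len(x) - 1, 1) / (x @ x)))
        return DistanceScalingResults(nu, se, self.prefactor, len(x))


@dataclass(frozen=True)
class DistanceScalingResults:
    nu: float
    nu_stderr: float
    prefactor: float
    n_points: int

    def summary(self) -> str:
        return (f"R(s) = {self.prefactor} * s^nu fit: nu = {self.nu:.6f} "
                f"+/- {self.nu_stderr:.2g} ({self.n_points} separations)")


def fit_scaling_exponent(separations, distances, prefactor: float = 0.55,
                         min_sep: int = 5) -> float:
    """Convenience wrapper returning just nu."""
    return DistanceScalingModel(separations, distances, prefactor,
                                min_sep).fit().nu


def theta_temperature(temperatures, nus) -> float | None:
    """Interpolated temperature where the scaling exponent crosses 0.5.

    The theta point of a chain: below it nu < 1/2 (globule), above it
    nu > 1/2 (expanded coil). Returns None ("not determined") when no
    bracketing pair exists; with multiple crossings the lowest-temperature
    one is returned with a warning.
    """
    order = np.argsort(temperatures)
    T = np.asarray(temperatures, float)[order]
    nu = np.asarray(nus, float)[order]
    crossings = []
    for i in range(len(T) - 1):
        if nu[i] == 0.5:
            crossings.append(float(T[i]))
        elif (nu[i] - 0.5) * (nu[i + 1] - 0.5) < 0:
            t = T[i] + (0.5 - nu[i]) * (T[i + 1] - T[i]) / (nu[i + 1] - nu[i])
            crossings.append(float(t))
    if nu[-1] == 0.5:
        crossings.append(float(T[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(f"multiple theta crossings {crossings}; "
                      "returning the lowest-temperature one")
    return min(crossings)


# ---------------------------------------------------------------------------
# Slab density profiles and the binodal fit

@dataclass(frozen=True)
class DensityProfile:
    """Mass density along the slab z-axis (default span 200 nm)."""

    z: np.ndarray        # bin centres, nm
    density: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, float)
        d = np.asarray(self.density, float)
        if len(z) != len(d) or len(z) < 4:
            raise ValueError("need matching z / density arrays")
        if not np.allclose(np.diff(z), np.diff(z)[0]):
            raise ValueError("bins must be uniform")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "density", d)

    @property
    def span(self) -> float:
        dz = self.z[1] - self.z[0]
        return float(self.z[-1] - self.z[0] + dz)


def center_profile(profile: DensityProfile) -> DensityProfile:
    """Circularly shift so the dense slab midpoint sits at mid-axis.

    The slab midpoint is the circular (periodic) density-weighted mean of
    z, the standard way to centre a periodic slab before windowing.
    """
    L = profile.span
    theta = 2.0 * math.pi * profile.z / L
    w = np.clip(profile.density, 0.0, None)
    if w.sum() == 0:
        return profile
    ang = math.atan2((w * np.sin(theta)).sum(), (w * np.cos(theta)).sum())
    centre = (ang / (2.0 * math.pi)) * L % L
    target = profile.z[0] + L / 2.0
    shift_bins = int(round((target - centre) / (profile.z[1] - profile.z[0])))
    return DensityProfile(profile.z, np.roll(profile.density, shift_bins))


def dense_dilute_densities(profile: DensityProfile, centred: bool = False
                           ) -> tuple[float, float]:
    """(rho_dense, rho_dilute) from the standard slab windows.

    Dilute phase: mean density over z in [0, 60) and (140, 200] nm; dense
    phase: mean over [90, 110] nm, after centring the slab. Windows are
    rescaled proportionally (with a warning) if the axis is not 200 nm.
    """
    if not centred:
        profile = center_profile(profile)
    L = profile.span
    scale = L / 200.0
    if abs(L - 200.0) > 1e-9:
        warnings.warn(f"axis span {L:g} nm != 200 nm; windows rescaled")
    z = profile.z - profile.z[0] + (profile.z[1] - profile.z[0]) / 2.0
    dil = (z < 60.0 * scale) | (z > 140.0 * scale)
    den = (z >= 90.0 * scale) & (z <= 110.0 * scale)
    rho_l = float(profile.density[dil].mean())
    rho_h = float(profile.density[den].mean())
    return rho_h, rho_l


class BinodalModel:
    """Fit the coexistence width rho_H - rho_L = A (T_c - T)^0.325.

    Nonlinear least squares in (A, T_c) with the 3-D Ising exponent fixed.
    Initialisation: T_c a tenth of the temperature span above the highest
    point, A read off the lowest-temperature point.
    """

    def __init__(self, temperatures, delta_rho):
        T = np.asarray(temperatures, float)
        d = np.asarray(delta_rho, float)
        if len(T) < 3:
            raise ValueError("need at least 3 temperatures")
        if np.any(d <= 0):
            raise ValueError("coexistence widths must be positive")
        order = np.argsort(T)
        self.T, self.d = T[order], d[order]

    def fit(self) -> "BinodalResults":
        span = self.T.max() - self.T.min() or 1.0
        tc0 = self.T.max() + span / 10.0
        a0 = self.d[0] / (tc0 - self.T[0]) ** _ISING_BETA
        model = lambda T, A, Tc: A * np.clip(Tc - T, 1e-12, None) ** _ISING_BETA
        popt, pcov = curve_fit(model, self.T, self.d, p0=[a0, tc0],
                               maxfev=20000)
        resid = self.d - model(self.T, *popt)
        monotone = bool(np.all(np.diff(self.d) <= 0))
        if not monotone:
            warnings.warn("coexistence widths are not monotone in T")
        return BinodalResults(float(popt[0]), float(popt[1]), pcov,
                              resid, monotone)


@dataclass(frozen=True)
class BinodalResults:
    A: float
    T_c: float
    cov: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    monotone_input: bool = True

    @property
    def stderr(self) -> tuple[float, float]:
        se = np.sqrt(np.diag(self.cov))
        return float(se[0]), float(se[1])

    def summary(self) -> str:
        se = self.stderr
        return (f"rho_H - rho_L = A (T_c - T)^{_ISING_BETA}: "
                f"A = {self.A:.6g} +/- {se[0]:.2g}, "
                f"T_c = {self.T_c:.6g} +/- {se[1]:.2g}; "
                f"residual norm {np.linalg.norm(self.residuals):.3g}"
                + ("" if self.monotone_input else
                   " [warning: non-monotone input]"))


def fit_binodal(temperatures, delta_rho) -> tuple[float, float]:
    """Convenience wrapper returning (A, T_c)."""
    res = BinodalModel(temperatures, delta_rho).fit()
    return res.A, res.T_c
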