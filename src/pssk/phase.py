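"""Sequence-dependent polymer-solution free energy and phase diagrams.

The model describes a solution of one charged, intrinsically disordered
chain species in implicit solvent on a unit lattice. The free energy per
lattice site, in units of kT, is

    f(phi) = (phi/N) ln phi                         (chain translational entropy)
           + phi_c ln(phi_c)                        (counterion entropy)
           + (1 - phi - phi_c) ln(1 - phi - phi_c)  (solvent entropy)
           - chi * phi**2,   chi = eps_fh / T*      (Flory-Huggins attraction)
           + f_el(phi)                              (electrostatic correlation)

where ``phi`` is the monomer volume fraction, ``N`` the chain length and
``T*`` the reduced temperature (bond length over Bjerrum length, so the
Coulomb coupling scales as 1/T*). A chain with net charge per monomer
sigma = |sum q| / N brings neutralising counterions phi_c = sigma * phi:
their mixing entropy is the principal penalty against condensing a
net-charged chain, and they participate in screening. Without them a
salt-free RPA free energy becomes more attractive for ANY added charge
and cannot describe charge-driven suppression of phase separation.

The correlation term is the random-phase-approximation one-loop integral
over the charge structure factor (lengths in bond units b = 1):

    f_el = 1/(4 pi^2) * Int_0^inf dk k^2 [ ln(1 + A(k)) - A(k) ]
    A(k) = 4 pi / (T* (k^2 + kappa^2)) * (phi S(k) + sigma phi)
    S(k) = 1/N * sum_{m,n} q_m q_n exp(-k^2 |m - n| / 6)

with the Gaussian-chain charge structure factor S(k); subtracting A removes
the self energy and renders the integral convergent. ``kappa`` is an
optional dimensionless added-salt screening constant (default 0).

Electrostatics modes:

* ``"rpa"``   - Gaussian-chain statistics, as above (reference mode).
* ``"rg_rpa"``- chain statistics renormalised by a single-chain variational
  (uniform-expansion) condition: the squared bond length is scaled by the
  factor x(T*) that minimises the single-chain elastic + mean Coulomb free
  energy, so strongly charged chains swell and blocky neutral ones contract
  before entering the correlation integral.
* ``"off"``   - Flory-Huggins solution theory only (used by closed-form
  oracles: phi_c = 1/(1+sqrt(N)), chi_c = (1+1/sqrt(N))^2 / 2).

All derivatives of f with respect to phi are analytic (differentiation
under the integral), so chemical potential mu = df/dphi and osmotic
pressure Pi = phi mu - f come from the same quadrature grid used for f.
The k-quadrature is a fixed log-spaced trapezoid grid; it is part of the
model definition, and every solver tolerance below refers to the model so
defined. Temperatures are in reduced units throughout: only orderings and
ratios between sequences are meaningful, not absolute temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .sequences import (AminoAcidSequence, ChargeSequence, PhosphoPattern,
                        assign_charges, enumerate_phospho_patterns)

__all__ = [
    "PhaseNumerics", "CriticalPoint", "PhaseDiagram", "SequencePhaseModel",
    "ScanResult", "phospho_scan",
]


@dataclass(frozen=True)
class PhaseNumerics:
    """Quadrature and solver controls (part of the model definition)."""

    n_k: int = 512
    k_min: float = 1e-5
    k_max: float = 100.0
    n_phi_scan: int = 160
    phi_floor: float = 1e-250    # dilute-branch log-bracket lower end
    phi_margin: float = 1e-9     # keep away from the solvent-exhaustion pole
    xatol: float = 1e-14
    rtol: float = 1e-12


@dataclass(frozen=True)
class CriticalPoint:
    T: float
    phi: float


@dataclass
class PhaseDiagram:
    """Binodal and spinodal branches over reduced temperature.

    Rows are sorted by decreasing T; all volume fractions satisfy
    phi_dilute <= phi_spin_lo <= phi_c <= phi_spin_hi <= phi_dense for
    every T below the critical temperature.
    """

    critical: CriticalPoint
    T: np.ndarray
    phi_dilute: np.ndarray
    phi_spin_lo: np.ndarray
    phi_spin_hi: np.ndarray
    phi_dense: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.T,
            "phi_dilute": self.phi_dilute,
            "phi_spin_lo": self.phi_spin_lo,
            "phi_c": np.full_like(self.T, self.critical.phi),
            "phi_spin_hi": self.phi_spin_hi,
            "phi_dense": self.phi_dense,
        })

    def summary(self) -> str:
        lines = [
            "Phase diagram (reduced units)",
            f"  critical point: T* = {self.critical.T:.6g}, "
            f"phi_c = {self.critical.phi:.6g}",
            f"  {len(self.T)} temperatures from "
            f"{self.T.max():.4g} down to {self.T.min():.4g}",
        ]
        return "\n".join(lines)


def _ln1p_minus(a: np.ndarray) -> np.ndarray:
    """ln(1 + a) - a, series-protected against cancellation at small a."""
    a = np.asarray(a, dtype=float)
    small = a < 1e-5
    safe = np.where(small, 0.0, a)
    out = np.log1p(safe) - safe
    series = a * a * (-0.5 + a * (1.0 / 3.0 - 0.25 * a))
    return np.where(small, series, out)


class SequencePhaseModel:
    """Free-energy model for one charge sequence at a given FH strength.

    Parameters
    ----------
    charges
        Per-residue charge array (elementary charges) or a
        :class:`~pssk.sequences.ChargeSequence` built under the ``scdm``
        scheme.
    eps_fh
        Flory-Huggins strength epsilon in kT units; chi = eps_fh / T*.
    electrostatics
        "rpa", "rg_rpa" or "off".
    kappa
        Dimensionless added-salt screening constant (default 0).
    counterions
        Include neutralising counterions for net-charged chains (entropy
        plus screening). Ignored when electrostatics is "off".
    """

    def __init__(self, charges, eps_fh: float = 2.0,
                 electrostatics: str = "rpa", kappa: float = 0.0,
                 counterions: bool = True,
                 numerics: PhaseNumerics | None = None):
        if isinstance(charges, ChargeSequence):
            if charges.scheme.name != "scdm":
                raise ValueError("phase model expects the 'scdm' scheme")
            charges = charges.charges
        self.q = np.asarray(charges, dtype=float)
        if self.q.ndim != 1 or len(self.q) < 1:
            raise ValueError("need a 1-D charge array with N >= 1")
        if eps_fh < 0:
            raise ValueError("eps_fh must be >= 0")
        if electrostatics not in ("rpa", "rg_rpa", "off"):
            raise ValueError(f"unknown electrostatics mode {electrostatics!r}")
        self.N = len(self.q)
        self.eps_fh = float(eps_fh)
        self.mode = electrostatics
        self.kappa = float(kappa)
        self.counterions = bool(counterions)
        self.num = numerics or PhaseNumerics()

        self.net_charge = float(self.q.sum())
        self.sigma = (abs(self.net_charge) / self.N
                      if (self.counterions and self.mode != "off") else 0.0)
        # charge autocorrelation c_d = sum_m q_m q_{m+d}
        full = np.correlate(self.q, self.q, mode="full")
        self._c = full[self.N - 1:]          # d = 0 .. N-1
        self._k = np.geomspace(self.num.k_min, self.num.k_max, self.num.n_k)
        self._w = self._trapezoid_weights(self._k)
        self._x_cache: dict[float, float] = {}
        self._B1_cache: dict[float, np.ndarray] = {}

    # -- infrastructure -----------------------------------------------------

    @staticmethod
    def _trapezoid_weights(k: np.ndarray) -> np.ndarray:
        w = np.zeros_like(k)
        dk = np.diff(k)
        w[:-1] += 0.5 * dk
        w[1:] += 0.5 * dk
        return w

    @property
    def phi_max(self) -> float:
        """Volume-fraction ceiling: monomers plus counterions fill space."""
        return (1.0 - self.num.phi_margin) / (1.0 + self.sigma)

    def structure_factor(self, k, T: float | None = None) -> np.ndarray:
        """Per-monomer Gaussian-chain charge structure factor S(k)."""
        k = np.atleast_1d(np.asarray(k, dtype=float))
        x = self._expansion_factor(T) if self.mode == "rg_rpa" else 1.0
        d = np.arange(1, self.N)
        decay = np.exp(-np.outer(k ** 2, d) * (x / 6.0))
        return (self._c[0] + 2.0 * decay @ self._c[1:]) / self.N

    def _expansion_factor(self, T: float | None) -> float:
        """Variational uniform-expansion factor x(T*) for rg_rpa mode.

        Minimises the single-chain trial free energy
        (3/2)(x + 1/x - 2) + (1/T*) sqrt(6/pi) Q / sqrt(x), where x scales
        the squared bond length, the symmetric elastic term penalises both
        swelling and compression, and Q = sum_{m<n} q_m q_n / sqrt(n - m)
        is the mean unscreened Coulomb energy of the Gaussian chain. Net
        repulsion (Q > 0) gives x > 1 (swollen statistics), net attraction
        x < 1 (contracted), feeding back into the structure factor.
        """
        if T is None:
            raise ValueError("rg_rpa structure factor needs a temperature")
        key = round(float(T), 12)
        if key in self._x_cache:
            return self._x_cache[key]
        d = np.arange(1, self.N)
        Q = float((self._c[1:] / np.sqrt(d)).sum())
        coef = math.sqrt(6.0 / math.pi) * Q / T
        # stationarity: (3/2)(1 - x^-2) - (coef/2) x^(-3/2) = 0
        g = lambda x: 1.5 * (1.0 - x ** -2) - 0.5 * coef * x ** -1.5
        lo, hi = 1e-6, 1e6
        x = brentq(g, lo, hi, xtol=1e-14, rtol=1e-14) \
            if g(lo) < 0 < g(hi) else 1.0
        self._x_cache[key] = x
        return x

    def _B1(self, T: float) -> np.ndarray:
        """B1(k) with A(k) = phi * B1(k) / T*."""
        key = round(float(T), 12) if self.mode == "rg_rpa" else 0.0
        if key not in self._B1_cache:
            S = self.structure_factor(self._k, T)
            self._B1_cache[key] = (4.0 * math.pi * (S + self.sigma)
                                   / (self._k ** 2 + self.kappa ** 2))
        return self._B1_cache[key]

    # -- free energy and derivatives ---------------------------------------

    def _check_phi(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        if np.any(phi <= 0) or np.any(phi * (1.0 + self.sigma) >= 1.0):
            raise ValueError("phi must satisfy 0 < phi(1 + sigma) < 1")
        return phi

    def free_energy(self, phi, T: float):
        """(f, mu, Pi) per lattice site in kT units at volume fraction phi."""
        phi = self._check_phi(phi)
        s = self.sigma
        v = 1.0 - (1.0 + s) * phi
        chi = self.eps_fh / T
        f = (phi / self.N) * np.log(phi) + v * np.log(v) - chi * phi ** 2
        mu = (np.log(phi) + 1.0) / self.N - (1.0 + s) * (np.log(v) + 1.0) \
            - 2.0 * chi * phi
        if s > 0:
            f = f + s * phi * np.log(s * phi)
            mu = mu + s * (np.log(s * phi) + 1.0)
        if self.mode != "off":
            B = self._B1(T) / T
            a = np.multiply.outer(phi, B)
            pref = 1.0 / (4.0 * math.pi ** 2)
            f = f + pref * (_ln1p_minus(a) * (self._k ** 2 * self._w)).sum(-1)
            integ = -(a * B) / (1.0 + a)
            mu = mu + pref * (integ * (self._k ** 2 * self._w)).sum(-1)
        Pi = phi * mu - f
        return f, mu, Pi

    def d2f(self, phi, T: float):
        """Second phi-derivative of f (curvature; zero on the spinodal)."""
        phi = self._check_phi(phi)
        s = self.sigma
        v = 1.0 - (1.0 + s) * phi
        out = 1.0 / (self.N * phi) + s / phi + (1.0 + s) ** 2 / v \
            - 2.0 * self.eps_fh / T
        if self.mode != "off":
            B = self._B1(T) / T
            a = np.multiply.outer(phi, B)
            integ = -(B ** 2) / (1.0 + a) ** 2
            out = out + (integ * (self._k ** 2 * self._w)).sum(-1) \
                / (4.0 * math.pi ** 2)
        return out

    def d3f(self, phi, T: float):
        phi = self._check_phi(phi)
        s = self.sigma
        v = 1.0 - (1.0 + s) * phi
        out = -1.0 / (self.N * phi ** 2) - s / phi ** 2 \
            + (1.0 + s) ** 3 / v ** 2
        if self.mode != "off":
            B = self._B1(T) / T
            a = np.multiply.outer(phi, B)
            integ = 2.0 * B ** 3 / (1.0 + a) ** 3
            out = out + (integ * (self._k ** 2 * self._w)).sum(-1) \
                / (4.0 * math.pi ** 2)
        return out

    # -- solvers ------------------------------------------------------------

    def _phi_scan(self) -> np.ndarray:
        return np.geomspace(1e-8, self.phi_max * (1.0 - 1e-6),
                            self.num.n_phi_scan)

    def _min_d2f(self, T: float) -> tuple[float, float]:
        """(min over phi of f'', argmin)."""
        grid = self._phi_scan()
        vals = self.d2f(grid, T)
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(lambda p: float(self.d2f(p, T)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": self.num.xatol})
        if res.fun < vals[i]:
            return float(res.fun), float(res.x)
        return float(vals[i]), float(grid[i])

    def critical_point(self) -> CriticalPoint | None:
        """Simultaneous zero of f'' and f''' (the argmin of f'' at T_c).

        Returns ``None`` when the model admits no criticality (e.g. pure
        entropy of mixing): an explicit "no phase separation" result.
        """
        m = lambda T: self._min_d2f(T)[0]
        # m(T) is monotone increasing in T: both interaction terms ~ 1/T.
        T_hi = 1.0
        while m(T_hi) < 0:
            T_hi *= 2.0
            if T_hi > 1e9:
                raise RuntimeError("no stable region found below T* = 1e9")
        T_lo = T_hi / 2.0
        while m(T_lo) > 0:
            T_lo /= 2.0
            if T_lo < 1e-9:
                return None
        T_c = brentq(m, T_lo, T_hi, xtol=1e-13, rtol=1e-15)
        phi_c = self._min_d2f(T_c)[1]
        return CriticalPoint(float(T_c), float(phi_c))

    def spinodal_at(self, T: float, critical: CriticalPoint | None = None
                    ) -> tuple[float, float] | None:
        """The two roots of f'' = 0 bracketing phi_c at T < T_c."""
        critical = critical or self.critical_point()
        if critical is None or T >= critical.T:
            return None
        g = lambda p: float(self.d2f(p, T))
        phi_c = critical.phi
        if g(phi_c) >= 0:
            return None
        eps_lo, eps_hi = 1e-14, self.phi_max * (1.0 - 1e-9)
        lo = brentq(g, eps_lo, phi_c, xtol=1e-16, rtol=1e-12)
        hi = brentq(g, phi_c, eps_hi, xtol=1e-16, rtol=1e-12)
        return float(lo), float(hi)

    def binodal_at(self, T: float, critical: CriticalPoint | None = None,
                   tol: float = 1e-8) -> tuple[float, float]:
        """Coexisting (phi_dilute, phi_dense) at T: equal mu and Pi.

        Nested bracketing: for a trial dense phi the dilute branch is
        solved for equal chemical potential (mu is monotone there), and the
        dense phi is then rooted on the osmotic-pressure mismatch.
        """
        critical = critical or self.critical_point()
        if critical is None or T >= critical.T:
            raise ValueError("binodal requires T below the critical point")
        sp = self.spinodal_at(T, critical)
        if sp is None:
            raise ValueError("no spinodal found at this temperature")
        s_lo, s_hi = sp

        log_floor = math.log(self.num.phi_floor)

        def dilute_for(mu_target: float) -> float | None:
            g = lambda t: self.free_energy(math.exp(t), T)[1] - mu_target
            b = math.log(s_lo * (1.0 - 1e-12))
            if g(b) < 0:
                return None           # mu on the whole dilute branch below target
            if g(log_floor) > 0:
                return None
            return math.exp(brentq(g, log_floor, b, xtol=1e-15, rtol=1e-15))

        def mismatch(phi_h: float) -> float | None:
            _, mu_h, pi_h = self.free_energy(phi_h, T)
            phi_l = dilute_for(mu_h)
            if phi_l is None:
                return None
            return self.free_energy(phi_l, T)[2] - pi_h

        grid = np.linspace(s_hi * (1.0 + 1e-10),
                           self.phi_max * (1.0 - 1e-9), 200)
        prev_phi, prev_val = None, None
        bracket = None
        for ph in grid:
            val = mismatch(float(ph))
            if val is None:
                continue
            if prev_val is not None and np.sign(val) != np.sign(prev_val):
                bracket = (prev_phi, float(ph))
                break
            prev_phi, prev_val = float(ph), val
        if bracket is None:
            raise RuntimeError(
                f"binodal solver found no pressure-balance bracket at T={T}; "
                f"spinodal=({s_lo:.3g},{s_hi:.3g}), phi_max={self.phi_max:.3g}"
            )
        phi_h = brentq(lambda p: mismatch(float(p)), *bracket,
                       xtol=1e-16, rtol=1e-15)
        _, mu_h, pi_h = self.free_energy(phi_h, T)
        phi_l = dilute_for(mu_h)
        _, mu_l, pi_l = self.free_energy(phi_l, T)
        if abs(mu_l - mu_h) > tol or abs(pi_l - pi_h) > tol:
            raise RuntimeError(
                f"coexistence tolerances not met at T={T}: "
                f"|dmu|={abs(mu_l - mu_h):.2e}, |dPi|={abs(pi_l - pi_h):.2e}"
            )
        return float(phi_l), float(phi_h)

    def phase_diagram(self, n_T: int = 12, t_lowest: float = 0.75,
                      critical: CriticalPoint | None = None) -> PhaseDiagram:
        """Binodal + spinodal on a grid of T = frac * T_c.

        ``t_lowest`` is the lowest fraction of T_c computed; the dilute
        branch collapses extremely fast below the critical region, which
        is why the default grid stays within 25% of T_c.
        """
        critical = critical or self.critical_point()
        if critical is None:
            raise ValueError("model does not phase separate")
        fracs = np.linspace(0.995, t_lowest, n_T)
        rows = []
        for fr in fracs:
            T = critical.T * fr
            sp = self.spinodal_at(T, critical)
            bi = self.binodal_at(T, critical)
            rows.append((T, bi[0], sp[0], sp[1], bi[1]))
        arr = np.array(rows)
        return PhaseDiagram(critical, arr[:, 0], arr[:, 1], arr[:, 2],
                            arr[:, 3], arr[:, 4])


# ---------------------------------------------------------------------------
# Combinatorial phosphosite scan

@dataclass
class ScanResult:
    """Critical points for every phosphorylation pattern of one sequence."""

    protein_id: str
    candidate_sites: tuple
    eps_fh: float
    mode: str
    table: pd.DataFrame = field(repr=False)
    diagrams: dict = field(default_factory=dict, repr=False)

    @property
    def n_patterns(self) -> int:
        return len(self.table)

    def critical_of(self, pattern: PhosphoPattern) -> CriticalPoint | None:
        row = self.table.loc[self.table.bitmask == pattern.bitmask]
        if row.empty or not np.isfinite(row.T_c.iloc[0]):
            return None
        return CriticalPoint(float(row.T_c.iloc[0]), float(row.phi_c.iloc[0]))

    def summary(self) -> str:
        t = self.table
        un = t.loc[t.stoichiometry == 0, "T_c"].iloc[0]
        lines = [f"Phosphosite scan of {self.protein_id} "
                 f"({len(self.candidate_sites)} sites, {len(t)} patterns, "
                 f"eps_fh={self.eps_fh}, mode={self.mode})",
                 f"  unmodified: T*_c = {un:.6g}",
                 "  per-stoichiometry critical-temperature range:"]
        for k, grp in t.groupby("stoichiometry"):
            lines.append(f"    {k:2d} sites: [{grp.T_c.min():.6g}, "
                         f"{grp.T_c.max():.6g}]  ({len(grp)} patterns)")
        return "\n".join(lines)


def phospho_scan(seq: AminoAcidSequence,
                 candidate_sites: Sequence[int],
                 eps_fh: float = 2.5,
                 mode: str = "rpa",
                 kappa: float = 0.0,
                 cap: int = 20,
                 compute_extreme_diagrams: bool = False,
                 n_T: int = 8,
                 numerics: PhaseNumerics | None = None) -> ScanResult:
    """Critical point for every phosphorylation pattern of the sites.

    Patterns are enumerated by bitmask; each pattern's charge sequence and
    critical point are computed independently, so the result is invariant
    to candidate-site ordering and any caching. Solver failures are kept
    as NaN rows ("no phase separation"), never dropped. Per-stoichiometry
    extremes are flagged, and with ``compute_extreme_diagrams`` the full
    binodal is computed for those extremes plus the unmodified sequence.
    """
    patterns = enumerate_phospho_patterns(candidate_sites, cap=cap)
    rows = []
    for pat in patterns:
        cs = assign_charges(seq, "scdm", pat)
        model = SequencePhaseModel(cs.charges, eps_fh=eps_fh,
                                   electrostatics=mode, kappa=kappa,
                                   numerics=numerics)
        cp = model.critical_point()
        rows.append({
            "bitmask": pat.bitmask,
            "stoichiometry": pat.stoichiometry,
            "active_sites": ";".join(map(str, sorted(pat.active))),
            "T_c": cp.T if cp else np.nan,
            "phi_c": cp.phi if cp else np.nan,
        })
    table = pd.DataFrame(rows).sort_values("bitmask").reset_index(drop=True)
    table["is_max_in_stoich"] = False
    table["is_min_in_stoich"] = False
    for _, grp in table.groupby("stoichiometry"):
        finite = grp.dropna(subset=["T_c"])
        if finite.empty:
            continue
        table.loc[finite.T_c.idxmax(), "is_max_in_stoich"] = True
        table.loc[finite.T_c.idxmin(), "is_min_in_stoich"] = True

    result = ScanResult(seq.id, tuple(sorted(set(candidate_sites))),
                        eps_fh, mode, table)
    if compute_extreme_diagrams:
        flagged = table.loc[table.is_max_in_stoich | table.is_min_in_stoich
                            | (table.stoichiometry == 0)]
        for _, row in flagged.iterrows():
            pat = PhosphoPattern.from_bitmask(result.candidate_sites,
                                              int(row.bitmask))
            cs = assign_charges(seq, "scdm", pat)
            model = SequencePhaseModel(cs.charges, eps_fh=eps_fh,
                                       electrostatics=mode, kappa=kappa,
                                       numerics=numerics)
            result.diagrams[int(row.bitmask)] = model.phase_diagram(n_T=n_T)
    return result
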