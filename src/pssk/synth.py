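"""Seeded synthetic-data generators.

Every downstream stage of the package can be exercised without any
external download: these generators produce inputs with the statistical
structure each stage assumes, together with ground-truth sidecars
sufficient to score the stage's output. All generators are pure functions
of their parameters and seed.

What is emulated (and what is not): synthetic proteomes carry disorder
blocks with S/T/P compositional bias and a planted phospho-in-IDR odds
ratio, time-structured "dynamic" phosphosite intensities with
intensity-dependent (left-censored) missingness — the structure a
cell-cycle phosphoproteomics time course exhibits — but no peptide-level
artefacts (missed cleavages, retention times, spectral interference).
Physics generators produce exact model curves (power-law intramolecular
distances, Ising-exponent coexistence widths, slab density profiles,
exponential FRAP recoveries) plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cgsim import DensityProfile
from .disorder import DisorderTrack
from .enrichment import IntensityMatrix
from .frap import FrapTrace
from .sequences import AminoAcidSequence

# residue sampling weights: disordered regions are depleted in
# order-promoting hydrophobics and enriched in S/T/P/G and charges
_AA = list("ACDEFGHIKLMNPQRSTVWY")
_IDR_W = np.array([6, 0.5, 5, 7, 1, 8, 2, 1, 7, 3, 1, 4, 9, 5, 6, 10, 7,
                   3, 0.5, 1], float)
_ORD_W = np.array([8, 2, 5, 6, 5, 6, 2, 6, 6, 10, 3, 4, 4, 4, 5, 6, 5,
                   7, 2, 4], float)


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    n_proteins: int = 150
    mean_length: int = 400
    idr_fraction: float = 0.35       # expected fraction of residues in IDRs
    phospho_rate_structured: float = 0.08   # P(phospho | structured S/T)
    odds_ratio: float = 4.6          # planted phospho-in-IDR odds ratio
    dynamic_fraction: float = 0.25   # fraction of phosphosites made dynamic
    n_timepoints: int = 4
    n_replicates: int = 3
    effect_sd: float = 4.0           # dynamic group shift, in noise-sd units
    noise_sd: float = 1.0            # replicate noise, log2 units
    base_intensity: float = 22.0
    missing_rate: float = 0.10
    seed: int = 0


@dataclass
class SyntheticProteome:
    sequences: list
    tracks: dict
    sites: pd.DataFrame
    intensities: IntensityMatrix
    ground_truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        from .sequences import write_fasta
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / "proteome.fasta")
        self.sites.to_csv(out / "sites.csv", index=False)
        self.intensities.data.to_csv(out / "intensities.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=1, default=str))


def synth_proteome(spec: SyntheticProteomeSpec,
                   with_intensities: bool = True) -> SyntheticProteome:
    """Proteome + pLDDT tracks + phosphosite table + intensity matrix.

    Phosphorylation probabilities inside and outside IDRs are chosen so
    the odds ratio of phosphorylation-in-IDR equals the planted value:
    odds_in = OR * odds_out.
    """
    if spec.odds_ratio <= 0:
        raise ValueError("planted odds ratio must be positive")
    o_out = spec.phospho_rate_structured / (1 - spec.phospho_rate_structured)
    p_in = spec.odds_ratio * o_out / (1 + spec.odds_ratio * o_out)
    if not 0 < p_in < 1:
        raise ValueError("infeasible odds ratio for the structured rate")
    rng = np.random.default_rng(spec.seed)
    p_idr, p_ord = _IDR_W / _IDR_W.sum(), _ORD_W / _ORD_W.sum()

    sequences, tracks, site_rows = [], {}, []
    for i in range(spec.n_proteins):
        pid = f"SYN{i:04d}"
        n = max(60, int(rng.normal(spec.mean_length,
                                   spec.mean_length * 0.25)))
        # one planted IDR block of the requested expected size
        idr_len = max(20, int(n * rng.normal(spec.idr_fraction, 0.08)))
        idr_len = min(idr_len, n - 10)
        start = int(rng.integers(0, n - idr_len + 1))
        mask = np.zeros(n, bool)
        mask[start:start + idr_len] = True
        res = np.where(mask,
                       rng.choice(_AA, size=n, p=p_idr),
                       rng.choice(_AA, size=n, p=p_ord))
        seq = AminoAcidSequence(pid, "".join(res))
        sequences.append(seq)
        scores = np.where(mask, rng.normal(32, 8, n), rng.normal(85, 7, n))
        tracks[pid] = DisorderTrack(pid, np.clip(scores, 0, 100), "plddt")
        for pos0 in np.nonzero(np.isin(res, ["S", "T"]))[0]:
            in_idr = bool(mask[pos0])
            p_ph = p_in if in_idr else spec.phospho_rate_structured
            site_rows.append((pid, int(pos0 + 1), res[pos0],
                              bool(rng.random() < p_ph), in_idr))
    sites = pd.DataFrame(site_rows, columns=["protein_id", "position",
                                             "residue", "phosphorylated",
                                             "in_idr"])
    sites["dynamic"] = False
    ph_idx = sites.index[sites.phosphorylated]
    n_dyn = int(round(spec.dynamic_fraction * len(ph_idx)))
    dyn_idx = rng.choice(ph_idx, size=n_dyn, replace=False) if n_dyn else []
    sites.loc[dyn_idx, "dynamic"] = True

    intensities = _synth_intensities(sites, spec, rng) if with_intensities \
        else IntensityMatrix(pd.DataFrame(columns=["t0_r0", "t0_r1"]),
                             {"t0_r0": "t0", "t0_r1": "t0"})
    truth = {
        "odds_ratio": spec.odds_ratio,
        "p_phospho_idr": p_in,
        "p_phospho_structured": spec.phospho_rate_structured,
        "dynamic_sites": sites.loc[sites.dynamic, ["protein_id", "position"]]
                              .apply(tuple, axis=1).tolist(),
        "n_phosphosites": int(sites.phosphorylated.sum()),
    }
    return SyntheticProteome(sequences, tracks, sites, intensities, truth)


def _synth_intensities(sites: pd.DataFrame, spec: SyntheticProteomeSpec,
                       rng: np.random.Generator) -> IntensityMatrix:
    ph = sites[sites.phosphorylated]
    ids = [f"{r.protein_id}_{r.position}" for r in ph.itertuples()]
    samples, groups = [], {}
    for t in range(spec.n_timepoints):
        for r in range(spec.n_replicates):
            name = f"t{t}_r{r}"
            samples.append(name)
            groups[name] = f"t{t}"
    base = rng.normal(spec.base_intensity, 2.0, size=len(ids))
    data = np.empty((len(ids), len(samples)))
    dyn = ph.dynamic.to_numpy()
    shifted_tp = rng.integers(0, spec.n_timepoints, size=len(ids))
    for j, name in enumerate(samples):
        tp = int(name.split("_")[0][1:])
        mean = base.copy()
        bump = (dyn & (shifted_tp == tp))
        mean[bump] += spec.effect_sd * spec.noise_sd
        data[:, j] = rng.normal(mean, spec.noise_sd)
    # left-censored missingness: logistic in the true intensity, tuned to
    # the requested overall rate
    flat = data.ravel()
    thr = np.quantile(flat, spec.missing_rate)
    p_miss = 1.0 / (1.0 + np.exp((data - thr) / (0.4 * spec.noise_sd)))
    p_miss *= spec.missing_rate / max(p_miss.mean(), 1e-12)
    data[rng.random(data.shape) < np.clip(p_miss, 0, 1)] = np.nan
    return IntensityMatrix(pd.DataFrame(data, index=ids, columns=samples),
                           groups)


# ---------------------------------------------------------------------------
# Physics generators

def synth_polyampholyte(block_size: int, n: int, seed: int = 0
                        ) -> AminoAcidSequence:
    """Neutral E/K polyampholyte of controlled blockiness.

    ``block_size`` 1 gives the strict alternator EKEK...; ``block_size``
    n/2 the diblock. Composition (n/2 E, n/2 K) is identical across the
    family, so the family isolates charge patterning. The blockiness index
    (the block size) is the ground truth.
    """
    if n % 2 or n % (2 * block_size):
        raise ValueError("need n divisible by 2*block_size")
    unit = "E" * block_size + "K" * block_size
    seqres = (unit * (n // len(unit)))
    return AminoAcidSequence(f"EK_b{block_size}_n{n}", seqres,
                             description=f"blockiness={block_size}")


def synth_frap(a: float = 0.6, k: float = 0.1, c: float = 1.0,
               noise_sd: float = 0.0, n_points: int = 100,
               seed: int = 0) -> tuple[FrapTrace, dict]:
    """Exponential-recovery trace y = c - a exp(-k t) plus Gaussian noise.

    Two pre-bleach samples at t = -2, -1 s sit at the plateau level 1;
    nucleus and unbleached channels are constant. Ground truth in the
    sidecar dict.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    t = np.concatenate([[-2.0, -1.0], np.arange(0.0, n_points, 1.0)])
    y = np.where(t < 0, 1.0, c - a * np.exp(-k * np.clip(t, 0, None)))
    y = np.clip(y + rng.normal(0, noise_sd, size=len(t)), 0.0, None)
    ones = np.ones_like(t)
    trace = FrapTrace(t, y, unbleached=ones.copy(), nucleus=ones.copy())
    return trace, {"a": a, "k": k, "c": c, "noise_sd": noise_sd,
                   "seed": seed}


def synth_distance_curve(nu: float = 0.5, prefactor: float = 0.55,
                         min_sep: int = 5, max_sep: int = 100,
                         noise_sd: float = 0.0, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Intramolecular distances R(s) = prefactor * s^nu (+ multiplicative
    Gaussian noise), for separations min_sep..max_sep."""
    rng = np.random.default_rng(seed)
    s = np.arange(min_sep, max_sep + 1, dtype=float)
    r = prefactor * s ** nu
    if noise_sd:
        r = r * np.exp(rng.normal(0, noise_sd, size=len(s)))
    return s, r, {"nu": nu, "prefactor": prefactor, "noise_sd": noise_sd}


def synth_binodal_points(A: float = 1.0, T_c: float = 2.0,
                         temperatures=None, noise_sd: float = 0.0,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray,
                                                 dict]:
    """Coexistence widths rho_H - rho_L = A (T_c - T)^0.325 (+ noise)."""
    rng = np.random.default_rng(seed)
    T = np.asarray(temperatures if temperatures is not None
                   else np.linspace(0.5 * T_c, 0.95 * T_c, 8), float)
    if np.any(T >= T_c):
        raise ValueError("temperatures must lie below T_c")
    d = A * (T_c - T) ** 0.325
    if noise_sd:
        d = d + rng.normal(0, noise_sd * d.mean(), size=len(T))
    return T, d, {"A": A, "T_c": T_c, "noise_sd": noise_sd}


def synth_density_profile(rho_dense: float = 300.0, rho_dilute: float = 5.0,
                          centre: float = 100.0, width: float = 30.0,
                          n_bins: int = 200, span: float = 200.0,
                          noise_sd: float = 0.0, seed: int = 0
                          ) -> tuple[DensityProfile, dict]:
    """Slab density profile on a periodic z-axis.

    A smooth (tanh-edged) slab of the given width is placed at ``centre``
    (deliberately off-centre inputs exercise the re-centring step).
    """
    rng = np.random.default_rng(seed)
    dz = span / n_bins
    z = dz / 2 + dz * np.arange(n_bins)
    # periodic distance to the slab centre
    d = np.abs((z - centre + span / 2) % span - span / 2)
    edge = 2.0
    prof = rho_dilute + (rho_dense - rho_dilute) * 0.5 * (
        1.0 - np.tanh((d - width / 2) / edge))
    if noise_sd:
        prof = np.clip(prof + rng.normal(0, noise_sd, n_bins), 0, None)
    return (DensityProfile(z, prof),
            {"rho_dense": rho_dense, "rho_dilute": rho_dilute,
             "centre": centre, "width": width})
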