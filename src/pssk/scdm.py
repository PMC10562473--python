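"""Sequence charge decoration matrices (SCDM).

An SCDM assigns every residue pair (i, j) a number summarising how the
electrostatic patterning of the intervening sequence promotes (negative,
attractive) or opposes (positive, repulsive) contact between i and j.
The default kernel is a windowed charge-decoration sum: for the segment
[i, j] (1-based, closed),

    SCDM(i, j) = (1 / (j - i)) * sum_{i <= n < m <= j} q_m q_n (m - n)^(1/2)

i.e. the distance-weighted pair-charge sum over the window, normalised by
window length. Oppositely charged pairs contribute negative (attractive)
terms; like charges positive ones. The kernel is bilinear in the charge
vector and vanishes identically for neutral sequences.

Kernels are looked up by name in a registry so alternative literature
kernels can be swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .sequences import ChargeSequence

_KERNELS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_kernel(name: str):
    def deco(fn):
        _KERNELS[name] = fn
        return fn
    return deco


@dataclass(frozen=True)
class SCDMatrix:
    protein_id: str
    values: np.ndarray = field(repr=False)
    kernel_name: str = "windowed_scd"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SCDM must be square")
        if not np.isfinite(v).all():
            raise ValueError("SCDM entries must be finite")
        object.__setattr__(self, "values", v)
        v.setflags(write=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@register_kernel("windowed_scd")
def _windowed_scd(q: np.ndarray) -> np.ndarray:
    """Windowed charge-decoration kernel, O(N^2).

    Uses the recurrences T(i,j) = T(i,j-1) + q_j * C(i,j) and
    C(i,j) = C(i+1,j) + q_i * sqrt(j-i), where T is the unnormalised
    double sum over the window and C the cross term against residue j.
    """
    n = len(q)
    T = np.zeros((n, n))
    for j in range(1, n):
        i_idx = np.arange(j)
        cross = q[i_idx] * np.sqrt(j - i_idx)
        C = np.cumsum(cross[::-1])[::-1]  # suffix sums: C[i] over n = i..j-1
        T[:j, j] = T[:j, j - 1] + q[j] * C
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(dist > 0, T / np.where(dist > 0, dist, 1), 0.0)
    return m + m.T  # symmetric completion, zero diagonal


def compute_scdm(cs: ChargeSequence, kernel: str = "windowed_scd"
                 ) -> SCDMatrix:
    """SCDM of a charge sequence under a named kernel.

    Requires the ``scdm`` charge scheme: the coarse-grained scheme's
    half-charged histidine follows a different convention and mixing the
    two silently would corrupt comparisons between maps.
    """
    if cs.scheme.name != "scdm":
        raise ValueError(
            f"SCDM requires the 'scdm' charge scheme, got {cs.scheme.name!r}"
        )
    if len(cs) < 3:
        raise ValueError("sequence too short for an SCDM (N >= 3)")
    try:
        fn = _KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}; "
                         f"available: {sorted(_KERNELS)}") from None
    return SCDMatrix(cs.sequence.id, fn(cs.charges), kernel)


def scdm_composite(non_p: SCDMatrix, p: SCDMatrix) -> np.ndarray:
    """Composite map: lower triangle unmodified, upper phosphorylated.

    The conventional side-by-side rendering of the two states of one
    sequence; the diagonal is zero.
    """
    if non_p.n != p.n:
        raise ValueError("matrix dimensions differ")
    if non_p.kernel_name != p.kernel_name:
        raise ValueError("matrices computed under different kernels")
    out = np.tril(non_p.values, -1) + np.triu(p.values, 1)
    return out


def brute_force_scdm(q: np.ndarray) -> np.ndarray:
    """Independent O(N^4) evaluation of the default kernel, for validation."""
    q = np.asarray(q, float)
    n = len(q)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.0
            for mm in range(i, j + 1):
                for nn in range(i, mm):
                    s += q[mm] * q[nn] * np.sqrt(mm - nn)
            m[i, j] = m[j, i] = s / (j - i)
    return m


def save_scdm(matrix: SCDMatrix, out_dir: str | Path) -> None:
    """Write CSV and compressed binary forms of the matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{matrix.protein_id}_scdm.csv", matrix.values,
               delimiter=",")
    np.savez_compressed(out_dir / f"{matrix.protein_id}_scdm.npz",
                        values=matrix.values,
                        kernel=np.array(matrix.kernel_name))


def plot_scdm(values: np.ndarray, path: str | Path, title: str = "") -> None:
    """Red/blue diverging heatmap (red repulsive, blue attractive)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.abs(values).max() or 1.0
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(values, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   origin="lower", interpolation="bicubic")
    ax.set_xlabel("residue j")
    ax.set_ylabel("residue i")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="SCDM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
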