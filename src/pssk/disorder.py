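"""Per-residue disorder tracks and IDR selection.

Disorder is read either from AlphaFold2 model confidence (pLDDT, stored in
the mmCIF B-factor field; residues with pLDDT < 50 are taken as disordered)
or from IUPred-style scores (disordered above 0.5).

The analysis region ("parent IDR") of a protein is chosen by protocol:

* pLDDT: the longest contiguous window in which strictly more than 60% of
  residues score below 50, trimmed so it starts and ends on disordered
  residues (the majority criterion alone lets a window begin or end inside
  an ordered flank, which no IDR boundary should). The window is then
  refined: if its longest ordered run (LOR, consecutive residues at or
  above the cutoff) exceeds 15% of the window, the window is truncated to
  end just before the LOR, and the rule is re-applied to the remainder.
  The 15% threshold is an adjustable convention.
* IUPred: the longest maximal run of consecutive residues scoring above
  0.5.

Ties between equal-length candidates are always broken towards the smallest
start position, so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DisorderTrack:
    protein_id: str
    scores: np.ndarray
    source: str  # "plddt" | "iupred"

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if self.source == "plddt":
            if s.min() < 0 or s.max() > 100:
                raise ValueError("pLDDT scores must lie in [0, 100]")
        elif self.source == "iupred":
            if s.min() < 0 or s.max() > 1:
                raise ValueError("IUPred scores must lie in [0, 1]")
        else:
            raise ValueError(f"unknown disorder source {self.source!r}")
        object.__setattr__(self, "scores", s)
        s.setflags(write=False)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def disorder_mask(self) -> np.ndarray:
        """True where the residue is called disordered."""
        if self.source == "plddt":
            return self.scores < 50.0
        return self.scores > 0.5


@dataclass(frozen=True)
class IDRInterval:
    """A 1-based closed residue interval called as the parent IDR."""

    protein_id: str
    start: int
    end: int
    disordered_fraction: float
    truncated_by_lor: bool = False

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid interval")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def to_bed_row(self) -> tuple:
        """(chrom-like id, 0-based start, exclusive end) for BED export."""
        return (self.protein_id, self.start - 1, self.end)


def disorder_fraction(track: DisorderTrack) -> float:
    """Fraction of residues called disordered, in [0, 1]."""
    return float(track.disorder_mask.mean())


# ---------------------------------------------------------------------------
# Readers

def read_track_tsv(path: str | Path, source: str,
                   protein_id: str | None = None) -> DisorderTrack:
    """Read a score track from TSV with header columns position, aa, score."""
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "aa", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pos = df["position"].to_numpy(dtype=int)
    expected = np.arange(1, len(pos) + 1)
    if not np.array_equal(np.sort(pos), expected):
        gaps = sorted(set(expected) - set(pos))
        raise ValueError(f"{path}: missing residue positions {gaps[:10]}")
    df = df.sort_values("position")
    return DisorderTrack(protein_id or Path(path).stem,
                         df["score"].to_numpy(dtype=float), source)


def read_plddt(path: str | Path, protein_id: str | None = None
               ) -> DisorderTrack:
    """Read per-residue pLDDT from an AlphaFold mmCIF file or a TSV track.

    In AF2 model files the pLDDT is deposited in the B-factor field, one
    identical value per atom of a residue. Multi-model files are refused,
    and gaps in residue numbering raise with the missing positions listed.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return read_track_tsv(path, "plddt", protein_id)
    st = gemmi.read_structure(str(path))
    if len(st) != 1:
        raise ValueError(f"{path}: multi-model structure ({len(st)} models)")
    model = st[0]
    if len(model) != 1:
        raise ValueError(f"{path}: expected one chain, found {len(model)}")
    chain = model[0]
    seqids, scores = [], []
    for residue in chain:
        seqids.append(residue.seqid.num)
        scores.append(residue[0].b_iso)
    seqids = np.asarray(seqids)
    expected = np.arange(seqids.min(), seqids.max() + 1)
    if not np.array_equal(seqids, expected):
        gaps = sorted(set(expected) - set(seqids))
        raise ValueError(f"{path}: missing residues {gaps[:10]}")
    return DisorderTrack(protein_id or st.name or path.stem,
                         np.asarray(scores, float), "plddt")


def write_track_tsv(track: DisorderTrack, path: str | Path,
                    residues: str | None = None) -> None:
    n = len(track)
    pd.DataFrame({
        "position": np.arange(1, n + 1),
        "aa": list(residues) if residues else ["X"] * n,
        "score": track.scores,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Selection

_EPS = 1e-9


def _longest_window_above_fraction(x: np.ndarray, majority: float
                                   ) -> tuple[int, int] | None:
    """Longest [i, j) with mean(x[i:j]) strictly > majority; smallest start.

    Exact search via prefix sums of x - majority and a monotonically
    decreasing stack of prefix minima (O(n)); ties resolved by a final
    left-to-right scan at the maximal length.
    """
    n = len(x)
    p = np.concatenate([[0.0], np.cumsum(x - majority)])
    # indices of strictly decreasing prefix values, scanned from the left
    stack = [0]
    for i in range(1, n + 1):
        if p[i] < p[stack[-1]] - _EPS:
            stack.append(i)
    best = 0
    for j in range(n, 0, -1):
        while stack and p[j] > p[stack[-1]] + _EPS:
            best = max(best, j - stack.pop())
    if best == 0:
        return None
    for i in range(0, n - best + 1):
        if p[i + best] > p[i] + _EPS:
            return i, i + best
    raise AssertionError("window search inconsistency")  # pragma: no cover


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start0, length) of the longest True run; ties to smallest start."""
    best_start, best_len, cur_start = 0, 0, None
    for i, v in enumerate(mask):
        if v and cur_start is None:
            cur_start = i
        if (not v or i == len(mask) - 1) and cur_start is not None:
            end = i + 1 if v else i
            if end - cur_start > best_len:
                best_start, best_len = cur_start, end - cur_start
            cur_start = None
    return best_start, best_len


def select_idr_plddt(track: DisorderTrack, cutoff: float = 50.0,
                     majority: float = 0.6, lor_frac: float = 0.15
                     ) -> IDRInterval | None:
    """Parent-IDR selection from a pLDDT track.

    Returns ``None`` when no window satisfies the majority criterion (an
    explicit "no IDR" result). Truncation by the longest ordered run is
    applied repeatedly, so the returned interval never contains an ordered
    run longer than ``lor_frac`` times its length.
    """
    if track.source != "plddt":
        raise ValueError("select_idr_plddt requires a pLDDT track")
    disordered = (track.scores < cutoff).astype(float)
    win = _longest_window_above_fraction(disordered, majority)
    if win is None:
        return None
    s, e = win  # 0-based half-open
    # the majority window may begin or end inside an ordered flank; an IDR
    # boundary is always a disordered residue, so trim the edges first
    while s < e and not disordered[s]:
        s += 1
    while e > s and not disordered[e - 1]:
        e -= 1
    if e <= s:
        return None
    truncated = False
    while True:
        ordered = track.scores[s:e] >= cutoff
        lor_start, lor_len = _longest_run(ordered)
        if lor_len <= lor_frac * (e - s):
            break
        truncated = True
        e = s + lor_start  # keep only the prefix before the LOR
        if e <= s:
            return None
    frac = float(disordered[s:e].mean())
    return IDRInterval(track.protein_id, s + 1, e, frac, truncated)


def select_idr_iupred(track: DisorderTrack, cutoff: float = 0.5
                      ) -> IDRInterval | None:
    """Longest maximal run of consecutive residues scoring above the cutoff."""
    if track.source != "iupred":
        raise ValueError("select_idr_iupred requires an IUPred track")
    mask = track.scores > cutoff
    start0, length = _longest_run(mask)
    if length == 0:
        return None
    return IDRInterval(track.protein_id, start0 + 1, start0 + length, 1.0)


def select_idr(track: DisorderTrack, **kwargs) -> IDRInterval | None:
    """Dispatch on the track source."""
    if track.source == "plddt":
        return select_idr_plddt(track, **kwargs)
    return select_idr_iupred(track, **kwargs)


def write_bed(intervals, path: str | Path) -> None:
    """Write IDR intervals as BED (0-based half-open, per the format)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv is None:
                continue
            pid, s0, e0 = iv.to_bed_row()
            fh.write(f"{pid}\t{s0}\t{e0}\tIDR\t{iv.disordered_fraction:.4f}\n")
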