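"""Protein sequences, charge schemes and phosphorylation patterns.

Residue positions are 1-based and intervals closed throughout the package,
matching the residue numbering conventions of structural biology; exporters
convert where a file format demands otherwise (e.g. BED).

Two fixed-charge schemes are provided:

``scdm``
    D, E = -1e; R, K = +1e; everything else 0. Used for sequence charge
    decoration matrices and for the polymer free-energy model.
``cg``
    Identical except histidine carries +0.5e, as in the one-bead-per-residue
    coarse-grained force field.

Phosphorylated Ser/Thr carry -2e in both schemes (the phosphate group's
double negative charge at physiological pH); phosphomimetic substitutions
(S/T -> D/E) carry -1e. Phosphosites are represented by position via
:class:`PhosphoPattern`, never by non-standard letters, so sequences stay
FASTA-clean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: default refusal threshold for pattern enumeration (2^n memory)
ENUMERATION_CAP = 20


@dataclass(frozen=True)
class AminoAcidSequence:
    """A protein (or IDR) sequence over the canonical 20-letter alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - set(AA_ALPHABET)
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(
                f"{self.id}: position {position} outside 1..{len(self)}"
            )
        return self.residues[position - 1]

    def subsequence(self, start: int, end: int, id: str | None = None
                    ) -> "AminoAcidSequence":
        """Closed-interval 1-based slice [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(f"invalid interval [{start}, {end}]")
        return AminoAcidSequence(
            id=id or f"{self.id}_{start}-{end}",
            residues=self.residues[start - 1:end],
        )


@dataclass(frozen=True)
class ChargeScheme:
    name: str
    table: dict
    phospho_charge: float = -2.0
    mimic_charge: float = -1.0

    def charge(self, residue: str) -> float:
        return self.table.get(residue, 0.0)


_BASE_TABLE = {"D": -1.0, "E": -1.0, "R": +1.0, "K": +1.0}

SCDM_SCHEME = ChargeScheme("scdm", dict(_BASE_TABLE))
CG_SCHEME = ChargeScheme("cg", {**_BASE_TABLE, "H": +0.5})

_SCHEMES = {"scdm": SCDM_SCHEME, "cg": CG_SCHEME}


def get_scheme(name: str) -> ChargeScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown charge scheme {name!r}; choose from {sorted(_SCHEMES)}"
        ) from None


@dataclass(frozen=True)
class PhosphoPattern:
    """A set of candidate S/T phosphosites and the currently active subset."""

    candidate_sites: tuple = ()
    active: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "candidate_sites",
                           tuple(sorted(set(self.candidate_sites))))
        object.__setattr__(self, "active", frozenset(self.active))
        if not self.active <= set(self.candidate_sites):
            raise ValueError("active sites must be a subset of candidates")

    @property
    def stoichiometry(self) -> int:
        return len(self.active)

    @property
    def bitmask(self) -> int:
        """Bit i set iff candidate_sites[i] is active (site order = position order)."""
        return sum(1 << i for i, p in enumerate(self.candidate_sites)
                   if p in self.active)

    @classmethod
    def from_bitmask(cls, candidate_sites: Sequence[int], mask: int
                     ) -> "PhosphoPattern":
        sites = tuple(sorted(set(candidate_sites)))
        active = frozenset(p for i, p in enumerate(sites) if mask >> i & 1)
        return cls(sites, active)


EMPTY_PATTERN = PhosphoPattern()


@dataclass(frozen=True)
class ChargeSequence:
    """A sequence together with per-residue charges under a scheme + pattern."""

    sequence: AminoAcidSequence
    scheme: ChargeScheme
    pattern: PhosphoPattern
    charges: np.ndarray = field(repr=False)

    def __post_init__(self):
        q = np.asarray(self.charges, dtype=float)
        if q.shape != (len(self.sequence),):
            raise ValueError("charge array length must equal sequence length")
        object.__setattr__(self, "charges", q)
        q.setflags(write=False)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.sequence)


def _check_sites(seq: AminoAcidSequence, positions: Iterable[int]) -> None:
    for p in positions:
        r = seq.residue(p)  # raises IndexError if out of range
        if r not in "ST":
            raise ValueError(
                f"{seq.id}: position {p} holds {r}, not S/T"
            )


def assign_charges(seq: AminoAcidSequence,
                   scheme: ChargeScheme | str = SCDM_SCHEME,
                   pattern: PhosphoPattern = EMPTY_PATTERN) -> ChargeSequence:
    """Per-residue charges under a named scheme with phospho overrides.

    Active pattern positions (which must hold S or T) are set to the scheme's
    ``phospho_charge`` (-2e); everything else is a table lookup. Deterministic
    and idempotent.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    _check_sites(seq, pattern.candidate_sites)
    q = np.array([scheme.charge(r) for r in seq.residues], dtype=float)
    for p in pattern.active:
        q[p - 1] = scheme.phospho_charge
    return ChargeSequence(seq, scheme, pattern, q)


def apply_phosphomimetic(seq: AminoAcidSequence,
                         positions: Iterable[int],
                         scheme: ChargeScheme | str = SCDM_SCHEME
                         ) -> ChargeSequence:
    """Charges with phosphomimetic (S/T -> D/E-like) substitutions.

    Each mimic adds a single negative charge (-1e), versus phosphorylation's
    two; the distinction is the point of the comparison the model makes.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    positions = sorted(set(positions))
    _check_sites(seq, positions)
    q = np.array([scheme.charge(r) for r in seq.residues], dtype=float)
    for p in positions:
        q[p - 1] = scheme.mimic_charge
    return ChargeSequence(seq, scheme, EMPTY_PATTERN, q)


def enumerate_phospho_patterns(candidate_sites: Sequence[int],
                               stoichiometry: int | None = None,
                               cap: int = ENUMERATION_CAP
                               ) -> list[PhosphoPattern]:
    """All phosphorylation patterns over a candidate-site set.

    Without ``stoichiometry``: all 2^n subsets (including the empty pattern),
    ordered by bitmask. With ``stoichiometry`` k: the C(n, k) subsets of size
    k, in lexicographic site order. Refuses n > ``cap`` (default 20) because
    the full enumeration is exponential; pass a larger cap explicitly to
    override.
    """
    sites = tuple(sorted(set(candidate_sites)))
    n = len(sites)
    if n > cap:
        raise ValueError(
            f"{n} candidate sites exceed the enumeration cap of {cap} "
            f"(2^{n} patterns); pass cap={n} to override"
        )
    if stoichiometry is not None:
        if not 0 <= stoichiometry <= n:
            raise ValueError("stoichiometry outside 0..n")
        return [PhosphoPattern(sites, frozenset(c))
                for c in itertools.combinations(sites, stoichiometry)]
    return [PhosphoPattern.from_bitmask(sites, m) for m in range(2 ** n)]


def candidate_proline_directed_sites(seq: AminoAcidSequence) -> list[int]:
    """1-based positions of S/T followed by P (the minimal CDK consensus)."""
    return [i + 1 for i in range(len(seq) - 1)
            if seq.residues[i] in "ST" and seq.residues[i + 1] == "P"]


# ---------------------------------------------------------------------------
# File I/O

def read_fasta(path: str | Path) -> list[AminoAcidSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [AminoAcidSequence(id=r.id, residues=str(r.seq).upper(),
                              description=r.description)
            for r in records]


def write_fasta(seqs: Iterable[AminoAcidSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id,
                         description=s.description or "")
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Pattern CSV with columns protein_id, position, state in {phospho, mimic}."""
    df = pd.read_csv(path)
    required = {"protein_id", "position", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["state"]) - {"phospho", "mimic"}
    if bad:
        raise ValueError(f"{path}: unknown states {sorted(bad)}")
    df["position"] = df["position"].astype(int)
    return df


def charges_table(cs: ChargeSequence) -> pd.DataFrame:
    """Long-format per-residue charge table for CSV export."""
    n = len(cs)
    return pd.DataFrame({
        "protein_id": [cs.sequence.id] * n,
        "position": np.arange(1, n + 1),
        "residue": list(cs.sequence.residues),
        "charge": cs.charges,
    })
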