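"""Bundled reference sequences.

KI67_CONSENSUS_REPEAT_SYNTHETIC is a synthetic stand-in for a single
"consensus" Ki-67 repeat unit: a designed 122-residue disordered sequence
carrying exactly 11 proline-directed (S/T-P) phosphosites, a basic net
charge of +7e (18 Lys/Arg against 11 Asp/Glu) and a repeat-like
composition rich in S/T/P/G/A/Q/N. It is NOT the natural repeat; it is a
model substrate with the same charge arithmetic: each phosphorylation
adds -2e, so the net charge changes sign between 3 and 4 sites and its
magnitude exceeds the unmodified value beyond 7 sites — the regime where
multisite phosphorylation can switch phase-separation propensity.
"""

from __future__ import annotations

from .sequences import AminoAcidSequence, candidate_proline_directed_sites

_KI67_BLOCKS = (
    "MKTPARELAGV",
    "GKSPTKAENLG",
    "AQSPKAVEGFG",
    "NKTPGRAEALG",
    "QASPKGVDNLA",
    "GKSPARAEGVN",
    "ATSPKGLENAG",
    "GRTPAKVEGLQ",
    "NASPKGAEVLG",
    "GKSPHRAENAV",
    "QATPKGLEGAN",
    "K",
)

KI67_CONSENSUS_REPEAT_SYNTHETIC = AminoAcidSequence(
    id="KI67_CR_synthetic",
    residues="".join(_KI67_BLOCKS),
    description="synthetic Ki-67 consensus-like repeat, 122 aa, "
                "11 S/T-P sites, net +7e",
)


def ki67_consensus_repeat() -> AminoAcidSequence:
    """The synthetic consensus-like repeat (see module docstring)."""
    return KI67_CONSENSUS_REPEAT_SYNTHETIC


def ki67_repeat_phosphosites() -> list[int]:
    """The repeat's 11 proline-directed candidate phosphosites (1-based)."""
    return candidate_proline_directed_sites(KI67_CONSENSUS_REPEAT_SYNTHETIC)
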