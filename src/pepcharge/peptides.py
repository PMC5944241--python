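"""Peptide descriptors: sequence-derived molar mass and maximum charge.

The cationic octapeptides studied here are lysine and arginine homo-octamers
(Lys8, Arg8).  Their maximum charge is the number of ionizable cationic
sidechains (8), and molar masses are average masses of the free peptide
computed from the sequence; salt forms can be accommodated by overriding
``molar_mass``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

__all__ = ["PeptideDescriptor", "LYS8", "ARG8", "get_peptide"]

_CATIONIC_RESIDUES = frozenset("KR")


@dataclass(frozen=True)
class PeptideDescriptor:
    """Sequence, molar mass (g/mol) and maximum cationic charge of a peptide."""

    name: str
    sequence: str
    molar_mass: float
    z_max: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.z_max < 0:
            raise ValueError("z_max must be non-negative")

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: str,
        molar_mass: float | None = None,
        z_max: int | None = None,
    ) -> "PeptideDescriptor":
        """Build a descriptor from a one-letter residue string.

        Molar mass defaults to the average mass of the free (unionized)
        peptide; ``z_max`` defaults to the number of Lys/Arg sidechains.
        """
        if not sequence:
            raise ValueError("sequence must be non-empty")
        if molar_mass is None:
            molar_mass = float(molecular_weight(sequence, seq_type="protein"))
        if z_max is None:
            z_max = sum(1 for r in sequence.upper() if r in _CATIONIC_RESIDUES)
        return cls(name=name, sequence=sequence.upper(), molar_mass=molar_mass, z_max=z_max)


LYS8 = PeptideDescriptor.from_sequence("Lys8", "K" * 8)
ARG8 = PeptideDescriptor.from_sequence("Arg8", "R" * 8)

_REGISTRY = {"LYS8": LYS8, "ARG8": ARG8}


def get_peptide(name: str) -> PeptideDescriptor:
    """Look up a built-in peptide descriptor by case-insensitive name."""
    try:
        return _REGISTRY[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown peptide {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
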