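"""Scattering-length bookkeeping and SLD arithmetic.

The neutron scattering length density (SLD) of a molecule is the sum of the
coherent scattering lengths ``b_i`` of its atoms divided by the molecular
volume ``V_m``::

    SLD = sum_i n_i * b_i / V_m     [1/Angstrom^2]

Because hydrogen (b_H < 0) and deuterium (b_D > 0) scatter very differently,
isotopic substitution — in the solvent, the lipid acyl chains, or selected
peptide side chains — moves the SLD of a component without changing its
chemistry.  This module holds the scattering-length table, composition
arithmetic, and the SLD of a selectively deuterated peptide whose labile
hydrogens exchange with the solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

__all__ = [
    "ScatteringTable",
    "Composition",
    "LabeledPeptide",
    "compute_sld",
    "mix_sld",
    "peptide_sld",
    "default_table",
    "combine",
    "solvent_sld",
    "material_sld",
    "MATERIALS",
]

FRACTION_TOL = 0.01


class MaterialsError(ValueError):
    """Raised for unknown isotopes, bad volumes or bad fractions."""


# --------------------------------------------------------------------------
# Scattering-length table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringTable:
    """Coherent scattering lengths b_i in Angstrom, keyed by isotope symbol."""

    lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        required = {"H", "D", "C", "N", "O", "P", "S", "Si"}
        missing = required - set(self.lengths)
        if missing:
            raise MaterialsError(f"scattering table missing isotopes: {sorted(missing)}")
        if not self.lengths["H"] < 0 < self.lengths["D"]:
            raise MaterialsError("expected b_H < 0 < b_D")

    def b(self, symbol: str) -> float:
        try:
            return self.lengths[symbol]
        except KeyError:
            raise MaterialsError(f"unknown isotope symbol: {symbol!r}") from None


def _load_table() -> ScatteringTable:
    text = resources.files("nrdecomp").joinpath("scattering_lengths.dat").read_text()
    lengths: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym, val = line.split()
        lengths[sym] = float(val)
    return ScatteringTable(lengths)


_DEFAULT_TABLE: ScatteringTable | None = None


def default_table() -> ScatteringTable:
    """The bundled coherent scattering-length table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _load_table()
    return _DEFAULT_TABLE


# --------------------------------------------------------------------------
# Compositions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Atomic composition (isotope -> count) with a molecular volume in A^3.

    ``exchangeable_h`` counts how many of the H atoms are labile and take on
    the isotopic composition of the solvent.
    """

    counts: Mapping[str, float]
    volume: float
    exchangeable_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise MaterialsError(f"molecular volume must be > 0, got {self.volume}")
        for sym, n in self.counts.items():
            if n < 0:
                raise MaterialsError(f"negative count for {sym}: {n}")
        if self.exchangeable_h > self.counts.get("H", 0.0) + 1e-9:
            raise MaterialsError("exchangeable_h exceeds hydrogen count")


def compute_sld(
    composition: Composition,
    table: ScatteringTable | None = None,
    solvent_d_fraction: float = 0.0,
) -> float:
    """SLD (1/A^2) of a composition: sum(n_i * b_i) / V_m.

    Labile hydrogens (``composition.exchangeable_h``) scatter with
    ``(1 - f) * b_H + f * b_D`` where ``f`` is the deuterium fraction of the
    solvent they equilibrate with.
    """
    table = table or default_table()
    if not 0.0 <= solvent_d_fraction <= 1.0:
        raise MaterialsError(f"solvent_d_fraction outside [0, 1]: {solvent_d_fraction}")
    total = 0.0
    for sym, n in composition.counts.items():
        total += n * table.b(sym)
    # replace the labile share of b_H by the solvent-averaged value
    total += composition.exchangeable_h * solvent_d_fraction * (table.b("D") - table.b("H"))
    return total / composition.volume


def combine(parts: Sequence[tuple[Composition, float]]) -> Composition:
    """Mole-fraction-weighted average composition (counts and volume)."""
    counts: dict[str, float] = {}
    volume = 0.0
    exch = 0.0
    for comp, x in parts:
        if x < 0:
            raise MaterialsError(f"negative mole fraction: {x}")
        for sym, n in comp.counts.items():
            counts[sym] = counts.get(sym, 0.0) + x * n
        volume += x * comp.volume
        exch += x * comp.exchangeable_h
    return Composition(counts, volume, exch)


def mix_sld(components: Sequence[tuple[float, float]], tol: float = FRACTION_TOL) -> float:
    """Volume-fraction-weighted SLD of a layer.

    ``components`` is a sequence of ``(sld, volume_fraction)`` pairs.  The
    fractions of all components of a layer should sum to 1; a deviation larger
    than ``tol`` triggers a warning (incomplete bookkeeping), a negative
    fraction is an error.
    """
    total_phi = 0.0
    sld = 0.0
    for value, phi in components:
        if phi < 0:
            raise MaterialsError(f"negative volume fraction: {phi}")
        if phi > 1 + tol:
            raise MaterialsError(f"volume fraction exceeds 1: {phi}")
        sld += value * phi
        total_phi += phi
    if abs(total_phi - 1.0) > tol:
        warnings.warn(
            f"layer volume fractions sum to {total_phi:.4f}, not 1", stacklevel=2
        )
    return sld


# --------------------------------------------------------------------------
# Peptides
# --------------------------------------------------------------------------

# In-chain residue formulas (free amino acid minus one water).
_RESIDUE_FORMULA: dict[str, dict[str, float]] = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
}

# Residue volumes in A^3 (Zamyatnin-style consensus values).
_RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Labile (solvent-exchangeable) side-chain hydrogens per residue.
_SIDECHAIN_LABILE_H: dict[str, float] = {
    "R": 5, "N": 2, "Q": 2, "D": 1, "E": 1, "C": 1, "H": 1,
    "K": 3, "S": 1, "T": 1, "W": 1, "Y": 1,
}

# Side-chain methyl hydrogens — the positions deuterated in d-Mac1.
_METHYL_H: dict[str, float] = {"A": 3, "V": 6, "L": 6, "I": 6, "T": 3, "M": 3}

MAC1_SEQUENCE = "GLFGVLAKVAAHVVPAIAEHF"
# Default deuteration scheme: the six methyl-bearing residues in the
# N-terminal half (positions are 1-based).
MAC1_DEFAULT_D_POSITIONS = frozenset({2, 5, 6, 7, 9, 10})


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide with an explicit per-residue deuteration scheme.

    ``deuterated_positions`` are 1-based residue indices whose side-chain
    methyl hydrogens are replaced by deuterium (non-exchangeable).  Labile
    hydrogens (backbone amides, termini, exchangeable side-chain protons)
    equilibrate with the solvent.
    """

    sequence: str
    deuterated_positions: frozenset[int] = frozenset()
    c_terminal_amide: bool = True
    volume: float = field(default=0.0)  # 0 -> derived from residue volumes

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MaterialsError("empty peptide sequence")
        bad = [a for a in self.sequence if a not in _RESIDUE_FORMULA]
        if bad:
            raise MaterialsError(f"unknown residues: {bad}")
        if not set(self.deuterated_positions) <= set(range(1, len(self.sequence) + 1)):
            raise MaterialsError("deuterated positions outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def deuteron_count(self, position: int) -> float:
        """Non-exchangeable deuterons carried by the residue at ``position``."""
        if position in self.deuterated_positions:
            return _METHYL_H.get(self.sequence[position - 1], 0.0)
        return 0.0

    def segment_residues(self, segment: Literal["whole", "n_half", "c_half"]) -> range:
        """1-based residue range of a segment.

        The sequence is split at the midpoint residue; for odd lengths the
        midpoint residue is assigned to the C-terminal half (a 21-mer splits
        1-10 / 11-21).
        """
        n = len(self.sequence)
        if segment == "whole":
            return range(1, n + 1)
        if segment == "n_half":
            return range(1, n // 2 + 1)
        if segment == "c_half":
            return range(n // 2 + 1, n + 1)
        raise MaterialsError(f"unknown segment: {segment!r}")

    def segment_composition(
        self, segment: Literal["whole", "n_half", "c_half"] = "whole"
    ) -> Composition:
        """Atomic composition of a segment, termini included.

        The N-terminus contributes a charged amine (+2 H, both labile) to the
        N-half; the C-terminus contributes an amide (+N, +2 labile H) or a
        carboxylate to the C-half.
        """
        residues = self.segment_residues(segment)
        if len(residues) == 0:
            raise MaterialsError(f"empty segment: {segment!r}")
        counts: dict[str, float] = {}
        labile = 0.0
        for pos in residues:
            aa = self.sequence[pos - 1]
            formula = dict(_RESIDUE_FORMULA[aa])
            n_d = self.deuteron_count(pos)
            if n_d:
                formula["H"] = formula.get("H", 0) - n_d
                formula["D"] = formula.get("D", 0) + n_d
            for sym, n in formula.items():
                counts[sym] = counts.get(sym, 0.0) + n
            if aa != "P":
                labile += 1.0  # backbone amide NH
            labile += _SIDECHAIN_LABILE_H.get(aa, 0.0)
        if residues[0] == 1:  # N-terminal NH3+
            counts["H"] = counts.get("H", 0.0) + 2
            labile += 2.0
        if residues[-1] == len(self.sequence):  # C-terminus
            if self.c_terminal_amide:
                counts["N"] = counts.get("N", 0.0) + 1
                counts["H"] = counts.get("H", 0.0) + 2
                labile += 2.0
            else:
                counts["O"] = counts.get("O", 0.0) + 1
        volume = sum(_RESIDUE_VOLUME[self.sequence[p - 1]] for p in residues)
        if self.volume:
            volume *= self.volume / sum(_RESIDUE_VOLUME[a] for a in self.sequence)
        return Composition(counts, volume, exchangeable_h=labile)

    @property
    def labile_h(self) -> float:
        return self.segment_composition("whole").exchangeable_h

    @property
    def molecular_volume(self) -> float:
        return self.segment_composition("whole").volume


def mac1(deuterated: bool = True) -> LabeledPeptide:
    """Maculatin 1.1 (21 residues, C-terminally amidated); ``deuterated``
    selects the d-Mac1 labeling scheme with six methyl-deuterated residues in
    the N-terminal half."""
    positions = MAC1_DEFAULT_D_POSITIONS if deuterated else frozenset()
    return LabeledPeptide(MAC1_SEQUENCE, positions)


def peptide_sld(
    peptide: LabeledPeptide,
    solvent_d_fraction: float = 0.0,
    segment: Literal["whole", "n_half", "c_half"] = "whole",
    table: ScatteringTable | None = None,
) -> float:
    """SLD of a peptide segment with labile-H exchange at the solvent's
    deuterium fraction.  The segment uses its own share of the molecular
    volume (residue-volume weighted)."""
    comp = peptide.segment_composition(segment)
    return compute_sld(comp, table=table, solvent_d_fraction=solvent_d_fraction)


# --------------------------------------------------------------------------
# Default materials registry (overridable via the run configuration)
# --------------------------------------------------------------------------

# DMPC = C36H72NO8P: phosphocholine head C10H18NO8P (V ~ 320.9 A^3) +
# two myristoyl chains C26H54 (V ~ 756 A^3, fluid).  DMPG (Na salt)
# = C34H66O10PNa: head C8H12O10PNa with two exchangeable glycerol OH.
MATERIALS: dict[str, Composition] = {
    "silicon": Composition({"Si": 1}, volume=20.02),
    "silica": Composition({"Si": 1, "O": 2}, volume=46.0),
    "d2o": Composition({"D": 2, "O": 1}, volume=30.0),
    "h2o": Composition({"H": 2, "O": 1}, volume=30.0, exchangeable_h=0),
    "dmpc_head": Composition({"C": 10, "H": 18, "N": 1, "O": 8, "P": 1}, volume=320.9),
    "dmpg_head": Composition(
        {"C": 8, "H": 12, "O": 10, "P": 1, "Na": 1}, volume=289.0, exchangeable_h=2
    ),
    "myristoyl_tails_h": Composition({"C": 26, "H": 54}, volume=756.0),
    "myristoyl_tails_d54": Composition({"C": 26, "D": 54}, volume=756.0),
}

# 3:1 DMPC:DMPG headgroup region, the anionic membrane composition studied.
MATERIALS["pcpg_head_3to1"] = combine(
    [(MATERIALS["dmpc_head"], 0.75), (MATERIALS["dmpg_head"], 0.25)]
)


def solvent_sld(d_fraction: float, table: ScatteringTable | None = None) -> float:
    """SLD of a D2O/H2O mixture with deuterium fraction ``d_fraction``."""
    if not 0.0 <= d_fraction <= 1.0:
        raise MaterialsError(f"d_fraction outside [0, 1]: {d_fraction}")
    d2o = compute_sld(MATERIALS["d2o"], table)
    h2o = compute_sld(MATERIALS["h2o"], table)
    return d_fraction * d2o + (1 - d_fraction) * h2o


def material_sld(
    name: str, solvent_d_fraction: float = 0.0, table: ScatteringTable | None = None
) -> float:
    """SLD of a registered material, with labile-H exchange where defined."""
    try:
        comp = MATERIALS[name]
    except KeyError:
        raise MaterialsError(f"unknown material: {name!r}") from None
    return compute_sld(comp, table=table, solvent_d_fraction=solvent_d_fraction)
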