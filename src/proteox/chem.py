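"""Deterministic peptide chemistry.

Monoisotopic and average masses of modified peptides, adduct m/z values,
isotope-peak positions, b/y fragment ions with neutral losses, and in-silico
tryptic digestion.  All downstream quantitation modules obtain their target
m/z values from here.

Masses are computed from elemental compositions.  Monoisotopic atomic masses
are CODATA/IUPAC values to >=5 decimals; charging uses the proton mass
(1.007276 Da), not the H-atom mass, and adduct m/z subtracts the electron
mass explicitly.  Heavy-isotope (A+k) peaks use a fixed +k * 1.00336 Da
spacing (the 13C-dominant approximation); full isotopic fine structure is
out of scope.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModifiedPeptide",
    "Modification",
    "ModificationTable",
    "DEFAULT_MODIFICATIONS",
    "IonSpecies",
    "DigestPeptide",
    "monoisotopic_mass",
    "average_mass",
    "formula_of",
    "apply_modification",
    "remove_modification",
    "adduct_mz",
    "fragment_ions",
    "precursor_loss_mz",
    "tryptic_digest",
    "parse_peptide",
    "read_fasta",
    "write_ion_table",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ISOTOPE_SPACING",
]

# --- elemental masses -------------------------------------------------------

MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

# IUPAC 2021 standard atomic weights (conventional values)
AVERAGE = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.973761998,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990907
ISOTOPE_SPACING = 1.00336  # A+1 spacing, 13C-dominant approximation

# neutral (atomic) masses of adduct cations before electron removal
CATION_ATOM_MASS = {
    "H": MONOISOTOPIC["H"],
    "Na": 22.98976928,
    "K": 38.9637064864,
}

WATER = {"H": 2, "O": 1}

# amino-acid residue compositions (monomer minus water)
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def _formula_mass(formula: Mapping[str, int], table: Mapping[str, float]) -> float:
    return sum(table[el] * n for el, n in formula.items())


# --- modifications ----------------------------------------------------------

OXIDATION_LABELS = frozenset({"ox", "diox", "triox"})


@dataclass(frozen=True)
class Modification:
    """A mass modification with its elemental composition and allowed targets.

    ``targets`` holds one-letter residue codes and/or the sentinels
    ``"n_term"`` / ``"c_term"``.
    """

    label: str
    formula: Mapping[str, int]
    targets: frozenset[str]

    @property
    def monoisotopic_delta(self) -> float:
        return _formula_mass(self.formula, MONOISOTOPIC)

    @property
    def average_delta(self) -> float:
        return _formula_mass(self.formula, AVERAGE)


class ModificationTable:
    """Registry of modification labels; editable via :meth:`register`."""

    def __init__(self, mods: Iterable[Modification] = ()):
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self.register(m)

    def register(self, mod: Modification) -> None:
        self._mods[mod.label] = mod

    def __contains__(self, label: str) -> bool:
        return label in self._mods

    def __getitem__(self, label: str) -> Modification:
        try:
            return self._mods[label]
        except KeyError:
            raise KeyError(
                f"unknown modification label {label!r}; known: {sorted(self._mods)}"
            ) from None

    def labels(self) -> list[str]:
        return sorted(self._mods)


DEFAULT_MODIFICATIONS = ModificationTable(
    [
        # phospho on His (the substrate here) and the usual S/T/Y
        Modification("phospho", {"H": 1, "P": 1, "O": 3}, frozenset("HSTY")),
        Modification("ox", {"O": 1}, frozenset("MCYW")),
        Modification("diox", {"O": 2}, frozenset("MCYW")),
        Modification("triox", {"O": 3}, frozenset("C")),
        Modification("carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1}, frozenset("C")),
        # terminal groups, expressed as deltas vs the free terminus
        Modification("succinyl", {"C": 4, "H": 4, "O": 3}, frozenset({"n_term"})),
        # condensation with p-nitroaniline (C6H6N2O2 - H2O) vs the free acid
        Modification("p-nitroanilide", {"C": 6, "H": 4, "N": 2, "O": 1}, frozenset({"c_term"})),
    ]
)

N_TERM_FREE = "free-amine"
C_TERM_FREE = "free-acid"

# terminal label -> modification label ("" = the free terminus, delta 0)
N_TERM_GROUPS = {N_TERM_FREE: None, "succinyl": "succinyl"}
C_TERM_GROUPS = {C_TERM_FREE: None, "p-nitroanilide": "p-nitroanilide"}


# --- peptide ----------------------------------------------------------------


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with terminal groups and per-residue modifications.

    ``mods`` is a tuple of ``(position, label)`` with 1-based positions.
    A residue carries at most one oxidation-state label (ox/diox/triox).
    """

    sequence: str
    n_term: str = N_TERM_FREE
    c_term: str = C_TERM_FREE
    mods: tuple[tuple[int, str], ...] = ()
    table: ModificationTable = field(default=DEFAULT_MODIFICATIONS, compare=False, repr=False)

    def __post_init__(self):
        for aa in self.sequence:
            if aa not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue letter {aa!r} in sequence {self.sequence!r}")
        if self.n_term not in N_TERM_GROUPS:
            raise ValueError(f"unknown N-terminal group {self.n_term!r}")
        if self.c_term not in C_TERM_GROUPS:
            raise ValueError(f"unknown C-terminal group {self.c_term!r}")
        ox_seen: set[int] = set()
        for pos, label in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            mod = self.table[label]  # raises on unknown label
            aa = self.sequence[pos - 1]
            if aa not in mod.targets:
                raise ValueError(
                    f"modification {label!r} not allowed on residue {aa!r} at position {pos}"
                )
            if label in OXIDATION_LABELS:
                if pos in ox_seen:
                    raise ValueError(
                        f"residue at position {pos} carries more than one oxidation-state label"
                    )
                ox_seen.add(pos)

    # convenience accessors -------------------------------------------------

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def average_mass(self) -> float:
        return average_mass(self)

    def mods_at(self, position: int) -> list[str]:
        return [label for pos, label in self.mods if pos == position]

    def mz(self, adduct: str = "H", charge: int = 1, isotope_index: int = 0) -> float:
        return adduct_mz(self, adduct, charge, isotope_index)


@dataclass(frozen=True)
class IonSpecies:
    """A charged, adducted, isotope-resolved form of a peptide."""

    peptide: ModifiedPeptide
    adduct: str = "H"
    charge: int = 1
    isotope_index: int = 0

    def __post_init__(self):
        if self.adduct not in CATION_ATOM_MASS:
            raise ValueError(f"unknown adduct {self.adduct!r}; known: {sorted(CATION_ATOM_MASS)}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.isotope_index < 0:
            raise ValueError("isotope_index must be >= 0")

    @property
    def mz(self) -> float:
        return adduct_mz(self.peptide, self.adduct, self.charge, self.isotope_index)


# --- mass computation -------------------------------------------------------


def formula_of(p: ModifiedPeptide) -> dict[str, int]:
    """Elemental composition of the neutral peptide, mods included."""
    comp: Counter[str] = Counter(WATER)
    for aa in p.sequence:
        comp.update(RESIDUE_FORMULAS[aa])
    for _, label in p.mods:
        comp.update(p.table[label].formula)
    for term, groups in ((p.n_term, N_TERM_GROUPS), (p.c_term, C_TERM_GROUPS)):
        mod_label = groups[term]
        if mod_label is not None:
            comp.update(p.table[mod_label].formula)
    return dict(comp)


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Monoisotopic mass of the neutral peptide in Da."""
    return _formula_mass(formula_of(p), MONOISOTOPIC)


def average_mass(p: ModifiedPeptide) -> float:
    """Isotope-abundance-weighted (average) mass of the neutral peptide in Da."""
    return _formula_mass(formula_of(p), AVERAGE)


def apply_modification(p: ModifiedPeptide, mod: str, position: int) -> ModifiedPeptide:
    """Return a copy of ``p`` with ``mod`` added at 1-based ``position``.

    Validation (allowed residue, single oxidation state) happens in the
    returned peptide's constructor.
    """
    return replace(p, mods=p.mods + ((position, mod),))


def remove_modification(p: ModifiedPeptide, mod: str, position: int) -> ModifiedPeptide:
    """Inverse of :func:`apply_modification` for one occurrence."""
    mods = list(p.mods)
    try:
        mods.remove((position, mod))
    except ValueError:
        raise ValueError(f"modification {mod!r} not present at position {position}") from None
    return replace(p, mods=tuple(mods))


def adduct_mz(
    p: ModifiedPeptide, adduct: str = "H", charge: int = 1, isotope_index: int = 0
) -> float:
    """m/z of [M + n*cation]^n+ shifted to the requested isotope peak.

    m/z = (M + n*(m_cation_atom - m_e)) / n + isotope_index * 1.00336 / n.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if adduct not in CATION_ATOM_MASS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(CATION_ATOM_MASS)}")
    m = monoisotopic_mass(p)
    cation = CATION_ATOM_MASS[adduct] - ELECTRON_MASS
    return (m + charge * cation) / charge + isotope_index * ISOTOPE_SPACING / charge


def nominal_mz(
    p: ModifiedPeptide, adduct: str = "H", charge: int = 1, isotope_index: int = 0
) -> int:
    """Integer-rounded monoisotopic m/z, for comparison with unit-resolution peak labels."""
    return round(adduct_mz(p, adduct, charge, isotope_index))


# --- fragments --------------------------------------------------------------

# neutral-loss labels -> (formula, predicate on the fragment peptide)
_LOSS_FORMULAS = {
    # methanesulfenic acid loss, diagnostic of methionine sulfoxide
    "CH4SO": {"C": 1, "H": 4, "S": 1, "O": 1},
    # phosphate-group losses from the acid-labile P-N bond of phosphohistidine
    "HPO3": {"H": 1, "P": 1, "O": 3},
    "H3PO4": {"H": 3, "P": 1, "O": 4},
    "H3PO4+H2O": {"H": 5, "P": 1, "O": 5},
}


def _loss_applies(loss: str, fragment: ModifiedPeptide) -> bool:
    if loss == "CH4SO":
        return any(
            label == "ox" and fragment.sequence[pos - 1] == "M" for pos, label in fragment.mods
        )
    # phospho losses require a phosphorylated residue in the fragment
    return any(label == "phospho" for _, label in fragment.mods)


def _loss_mass(loss: str) -> float:
    try:
        return _formula_mass(_LOSS_FORMULAS[loss], MONOISOTOPIC)
    except KeyError:
        raise ValueError(f"unknown neutral-loss label {loss!r}; known: {sorted(_LOSS_FORMULAS)}") from None


def fragment_ions(
    p: ModifiedPeptide,
    series: Sequence[str] = ("b", "y"),
    losses: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """Singly charged b/y fragment ions, with neutral-loss companions.

    b_i covers residues 1..i (keeping the N-terminal group); y_j covers the
    last j residues (keeping the C-terminal group).  For every requested loss
    that is chemically possible for a fragment (an oxidized Met for CH4SO, a
    phospho residue for the phosphate losses) a companion peak at
    parent - loss is emitted, labelled e.g. ``"b3-CH4SO"``.
    """
    if not p.sequence:
        raise ValueError("cannot fragment an empty sequence")
    losses = list(losses)
    for loss in losses:
        _loss_mass(loss)  # validate labels up front
    n = len(p.sequence)
    out: list[tuple[str, float]] = []

    def emit(label: str, fragment: ModifiedPeptide, neutral: float) -> None:
        mz = neutral + PROTON_MASS
        out.append((label, mz))
        for loss in losses:
            if _loss_applies(loss, fragment):
                out.append((f"{label}-{loss}", mz - _loss_mass(loss)))

    for i in range(1, n):
        if "b" in series:
            frag = ModifiedPeptide(
                p.sequence[:i],
                n_term=p.n_term,
                c_term=C_TERM_FREE,
                mods=tuple((pos, lab) for pos, lab in p.mods if pos <= i),
                table=p.table,
            )
            # b ion = prefix neutral - water (acylium form)
            neutral = monoisotopic_mass(frag) - _formula_mass(WATER, MONOISOTOPIC)
            emit(f"b{i}", frag, neutral)
        if "y" in series:
            j = n - i
            frag = ModifiedPeptide(
                p.sequence[i:],
                n_term=N_TERM_FREE,
                c_term=p.c_term,
                mods=tuple((pos - i, lab) for pos, lab in p.mods if pos > i),
                table=p.table,
            )
            emit(f"y{j}", frag, monoisotopic_mass(frag))
    return out


def precursor_loss_mz(
    p: ModifiedPeptide,
    losses: Iterable[str] = ("HPO3", "H3PO4", "H3PO4+H2O"),
    adduct: str = "H",
    charge: int = 1,
) -> list[tuple[str, float]]:
    """Precursor neutral-loss peaks, e.g. the M-80/M-98/M-116 phosphate series."""
    base = adduct_mz(p, adduct, charge)
    return [(f"M-{loss}", base - _loss_mass(loss) / charge) for loss in losses]


# --- digestion --------------------------------------------------------------


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    missed_cleavages: int


def tryptic_digest(protein: str, max_missed: int = 0) -> list[DigestPeptide]:
    """In-silico tryptic digestion: cleave after K/R, suppressed before P.

    Returns peptides with 0..max_missed missed cleavages, each annotated with
    its 1-based span in the protein.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = [0]
    for i, aa in enumerate(protein):
        if aa in "KR" and not (i + 1 < len(protein) and protein[i + 1] == "P"):
            cuts.append(i + 1)
    if cuts[-1] != len(protein):
        cuts.append(len(protein))
    peptides = []
    for a in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            start, end = cuts[a], cuts[b]
            peptides.append(DigestPeptide(protein[start:end], start + 1, end, missed))
    return peptides


# --- peptide spec strings ---------------------------------------------------

_N_TERM_TOKENS = {"Suc": "succinyl", "succinyl": "succinyl"}
_C_TERM_TOKENS = {"pNA": "p-nitroanilide", "p-nitroanilide": "p-nitroanilide"}
_MOD_ALIASES = {
    "ox": "ox", "diox": "diox", "ox2": "diox", "triox": "triox", "ox3": "triox",
    "p": "phospho", "ph": "phospho", "phospho": "phospho",
    "cam": "carbamidomethyl", "carbamidomethyl": "carbamidomethyl",
}

_INLINE_MOD = re.compile(r"([A-Z])(?:\(([a-zA-Z0-9]+)\))?")


def parse_peptide(spec: str, table: ModificationTable = DEFAULT_MODIFICATIONS) -> ModifiedPeptide:
    """Parse peptide spec strings like ``"Suc-AHPF-pNA"`` or ``"VYEAGM(ox)K"``.

    Dash-separated leading/trailing tokens name terminal groups; an inline
    ``(label)`` modifies the residue it follows.
    """
    parts = spec.split("-")
    n_term, c_term = N_TERM_FREE, C_TERM_FREE
    if len(parts) > 1 and parts[0] in _N_TERM_TOKENS:
        n_term = _N_TERM_TOKENS[parts.pop(0)]
    if len(parts) > 1 and parts[-1] in _C_TERM_TOKENS:
        c_term = _C_TERM_TOKENS[parts.pop()]
    body = "".join(parts)
    if not re.fullmatch(r"(?:[A-Z](?:\([a-zA-Z0-9]+\))?)*", body):
        raise ValueError(f"cannot parse peptide spec {spec!r}")
    sequence = []
    mods = []
    for m in _INLINE_MOD.finditer(body):
        sequence.append(m.group(1))
        if m.group(2):
            alias = m.group(2)
            if alias not in _MOD_ALIASES:
                raise ValueError(f"unknown inline modification {alias!r} in {spec!r}")
            mods.append((len(sequence), _MOD_ALIASES[alias]))
    return ModifiedPeptide("".join(sequence), n_term, c_term, tuple(mods), table)


# --- I/O --------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein sequences from FASTA as (id, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_ion_table(path, ions: Iterable[tuple[str, float]]) -> None:
    """Write (label, m/z) pairs as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ion", "mz"])
        for label, mz in ions:
            w.writerow([label, f"{mz:.5f}"])
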