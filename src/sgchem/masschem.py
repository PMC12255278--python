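"""Monoisotopic mass arithmetic for glycosylated steroids.

Steroidal glycosides (SGs) fragment in-source into ladders of ions separated
by neutral losses of glycosyl residues (hexose, deoxyhexose, pentose,
malonylhexoside) or small biotransformations (hydroxylation, saturation,
acetylation).  This module provides the residue mass table, elemental-formula
assignment with ring-double-bond-equivalent (RDBE) computation, fragment
ladder prediction, and bounded decomposition of a glycan chain mass into
residue compositions.

All m/z comparisons use an absolute tolerance (default 0.02 Da, matching
two-decimal printed m/z values).  Ions are treated as singly protonated
[M+H]+; multiply charged species are not modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

#: Mass of a proton, Da ([M+H]+ assumption).
PROTON_MASS = 1.00728

#: Default absolute m/z tolerance, Da.
DEFAULT_TOL = 0.02

# Monoisotopic atom masses for the CHNO formula space.
ATOM_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

# Short aliases accepted wherever a residue name is expected.
RESIDUE_ALIASES = {
    "hex": "hexose",
    "dhex": "deoxyhexose",
    "deoxhex": "deoxyhexose",
    "pen": "pentose",
    "pent": "pentose",
    "malhex": "malonylhexoside",
    "mal": "malonylhexoside",
    "o": "hydroxylation",
    "oh": "hydroxylation",
    "h2": "saturation",
    "acetyl": "acetylation",
    "ac": "acetylation",
    "h2o": "water",
}


class UnknownResidueError(KeyError):
    """Raised when a residue/transformation name is not in the table."""


@dataclass(frozen=True)
class Residue:
    name: str
    composition: str
    mass: float
    kind: str  # "glycosyl" or "biotransformation"


class ResidueTable:
    """Named residues/biotransformations with monoisotopic masses.

    The default table ships with the package (``data/residues.tsv``); extra
    entries can be supplied as ``(name, composition)`` pairs, with the mass
    derived from the composition.
    """

    def __init__(self, entries: Mapping[str, Residue] | None = None):
        if entries is None:
            entries = _load_default_entries()
        self.entries: dict[str, Residue] = dict(entries)
        for res in self.entries.values():
            derived = _pmass.calculate_mass(formula=res.composition)
            if abs(derived - res.mass) > 1e-4:
                raise ValueError(
                    f"residue {res.name}: tabulated mass {res.mass} deviates "
                    f"from composition mass {derived:.6f}"
                )
            if res.mass <= 0:
                raise ValueError(f"residue {res.name}: non-positive mass")

    def canonical(self, name: str) -> str:
        key = name.strip().lower()
        key = RESIDUE_ALIASES.get(key, key)
        if key not in self.entries:
            raise UnknownResidueError(f"unknown residue or loss name: {name!r}")
        return key

    def __getitem__(self, name: str) -> Residue:
        return self.entries[self.canonical(name)]

    def __contains__(self, name: str) -> bool:
        try:
            self.canonical(name)
            return True
        except UnknownResidueError:
            return False

    def mass(self, name: str) -> float:
        return self[name].mass

    def subset(self, names: Sequence[str]) -> "ResidueTable":
        keep = {self.canonical(n) for n in names}
        return ResidueTable({k: v for k, v in self.entries.items() if k in keep})

    def add(self, name: str, composition: str, kind: str = "glycosyl") -> None:
        m = _pmass.calculate_mass(formula=composition)
        self.entries[name.strip().lower()] = Residue(name.strip().lower(), composition, m, kind)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def glycosyl_names(self) -> list[str]:
        return [n for n, r in self.entries.items() if r.kind == "glycosyl"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.name, r.composition, r.mass, r.kind) for r in self.entries.values()],
            columns=["name", "composition", "mass", "kind"],
        )


def _load_default_entries() -> dict[str, Residue]:
    path = resources.files("sgchem").joinpath("data/residues.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return {
        row["name"]: Residue(row["name"], row["composition"], float(row["mass"]), row["kind"])
        for _, row in df.iterrows()
    }


_DEFAULT_TABLE: ResidueTable | None = None


def default_residue_table() -> ResidueTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueTable()
    return _DEFAULT_TABLE


def residue_mass(name: str, table: ResidueTable | None = None) -> float:
    """Monoisotopic mass (Da) of a named residue or biotransformation."""
    table = table or default_residue_table()
    return table.mass(name)


@dataclass(frozen=True, order=True)
class Formula:
    """CHNO elemental formula with non-negative atom counts."""

    C: int
    H: int
    N: int = 0
    O: int = 0

    def __post_init__(self):
        if min(self.C, self.H, self.N, self.O) < 0:
            raise ValueError("negative atom count")
        if self.C + self.H + self.N + self.O == 0:
            raise ValueError("empty formula")

    @property
    def mass(self) -> float:
        return (
            self.C * ATOM_MASS["C"]
            + self.H * ATOM_MASS["H"]
            + self.N * ATOM_MASS["N"]
            + self.O * ATOM_MASS["O"]
        )

    def __str__(self) -> str:
        parts = []
        for el, n in (("C", self.C), ("H", self.H), ("N", self.N), ("O", self.O)):
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


def rdbe(formula: Formula) -> float:
    """Ring-double-bond equivalent, C - H/2 + N/2 + 1.

    Integer for even-electron neutral CHNO species (even H+N); half-integer
    values flag open-shell or charged formulas.
    """
    return formula.C - formula.H / 2 + formula.N / 2 + 1


@dataclass(frozen=True)
class FormulaAssignment:
    formula: Formula | None
    mass_error: float | None  # observed - theoretical, Da

    @property
    def assigned(self) -> bool:
        return self.formula is not None


def assign_formula(
    neutral_mass: float,
    tolerance: float = 0.005,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    rdbe_center: float = 7.0,
    require_even_electron: bool = True,
) -> FormulaAssignment:
    """Assign the best CHNO formula to a neutral monoisotopic mass.

    Exhaustive search over the bounded composition space.  Candidates are
    restricted to chemically valid even-electron neutrals (integer RDBE >= 0)
    unless ``require_even_electron`` is False; steroidal-aglycone assignments
    are only reliable under this constraint, since spurious radical formulas
    can otherwise win on mass error alone.  The best match
    minimises |mass error|, with ties broken by |RDBE - rdbe_center| (steroidal
    aglycones cluster near RDBE 5-8) and then lexicographic composition.

    Returns a :class:`FormulaAssignment` with ``formula=None`` when nothing
    lies within tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if bounds is None:
        bounds = {"C": (20, 35), "H": (10, 60), "N": (0, 1), "O": (0, 6)}
    if not bounds:
        raise ValueError("bounds must be non-empty")
    lo = {el: bounds.get(el, (0, 0))[0] for el in "CHNO"}
    hi = {el: bounds.get(el, (0, 0))[1] for el in "CHNO"}

    c = np.arange(lo["C"], hi["C"] + 1)
    h = np.arange(lo["H"], hi["H"] + 1)
    n = np.arange(lo["N"], hi["N"] + 1)
    o = np.arange(lo["O"], hi["O"] + 1)
    C, H, N, O = np.meshgrid(c, h, n, o, indexing="ij")
    M = (
        C * ATOM_MASS["C"]
        + H * ATOM_MASS["H"]
        + N * ATOM_MASS["N"]
        + O * ATOM_MASS["O"]
    )
    err = M - neutral_mass
    ok = np.abs(err) <= tolerance
    if require_even_electron:
        rd = C - H / 2 + N / 2 + 1
        ok &= ((H + N) % 2 == 0) & (rd >= 0)
    if not ok.any():
        return FormulaAssignment(None, None)
    idx = np.argwhere(ok)
    best = None
    for i, j, k, l in idx:
        f = Formula(int(C[i, j, k, l]), int(H[i, j, k, l]), int(N[i, j, k, l]), int(O[i, j, k, l]))
        key = (abs(float(err[i, j, k, l])), abs(rdbe(f) - rdbe_center), (f.C, f.H, f.N, f.O))
        if best is None or key < best[0]:
            best = (key, f, float(err[i, j, k, l]))
    return FormulaAssignment(best[1], best[2])


@dataclass(frozen=True)
class IonLadder:
    """Descending series of ion m/z values linked by named neutral losses."""

    ions: tuple[float, ...]
    losses: tuple[str, ...]

    def __post_init__(self):
        if len(self.ions) != len(self.losses) + 1:
            raise ValueError("ladder must have one more ion than losses")
        if any(b >= a for a, b in zip(self.ions, self.ions[1:])):
            raise ValueError("ladder ions must be strictly descending")

    @property
    def molecular_ion(self) -> float:
        return self.ions[0]

    @property
    def aglycone_ion(self) -> float:
        return self.ions[-1]


def predict_fragment_ladder(
    molecular_ion_mz: float,
    losses: Sequence[str],
    table: ResidueTable | None = None,
) -> IonLadder:
    """Predict the in-source fragment ladder for an ordered loss series.

    Ion ``k`` is the molecular ion minus the first ``k`` loss masses; the
    terminal value is the predicted aglycone ion m/z.
    """
    if not losses:
        raise ValueError("losses must be non-empty")
    table = table or default_residue_table()
    names = tuple(table.canonical(n) for n in losses)
    ions = [float(molecular_ion_mz)]
    for name in names:
        nxt = ions[-1] - table.mass(name)
        if nxt <= 0:
            raise ValueError(f"predicted ion {nxt:.4f} <= 0 after loss of {name}")
        ions.append(nxt)
    return IonLadder(tuple(ions), names)


@dataclass(frozen=True)
class GlycanComposition:
    """Residue counts of a glycoside chain, with total monoisotopic mass."""

    counts: tuple[tuple[str, int], ...]
    total_mass: float

    def as_dict(self) -> dict[str, int]:
        return {k: v for k, v in self.counts if v > 0}

    def __str__(self) -> str:
        short = {"hexose": "Hex", "deoxyhexose": "dHex", "pentose": "Pen",
                 "malonylhexoside": "MalHex", "acetylation": "Ac"}
        return "".join(
            f"{short.get(k, k)}{v if v > 1 else ''}" for k, v in self.counts if v > 0
        ) or "(empty)"


def decompose_glycan(
    molecular_ion_mz: float,
    aglycone_ion_mz: float,
    tolerance: float = DEFAULT_TOL,
    max_per_residue: int = 6,
    table: ResidueTable | None = None,
    residues: Sequence[str] | None = None,
) -> list[GlycanComposition]:
    """Enumerate residue compositions matching a chain mass.

    The chain mass is ``molecular_ion - aglycone_ion``.  Counts are bounded by
    ``max_per_residue`` for sugars and by 1 for malonylhexoside/acetylation
    (observed SG chains carry at most one acyl decoration).  Results are
    sorted by |mass error|, best first; an empty list means no match.
    """
    if molecular_ion_mz <= aglycone_ion_mz:
        raise ValueError("molecular ion must exceed aglycone ion")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    table = table or default_residue_table()
    if residues is None:
        residues = ["hexose", "deoxyhexose", "pentose", "malonylhexoside"]
    residues = [table.canonical(r) for r in residues]
    target = molecular_ion_mz - aglycone_ion_mz
    caps = [
        1 if r in ("malonylhexoside", "acetylation") else max_per_residue
        for r in residues
    ]
    masses = [table.mass(r) for r in residues]
    out: list[GlycanComposition] = []
    for combo in itertools.product(*[range(c + 1) for c in caps]):
        if sum(combo) == 0:
            continue
        total = sum(k * m for k, m in zip(combo, masses))
        if abs(total - target) <= tolerance:
            out.append(
                GlycanComposition(tuple(zip(residues, combo)), total)
            )
    out.sort(key=lambda g: abs(g.total_mass - target))
    return out
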