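"""Lipid nomenclature model, class registry, masses, fluidity and omega flags.

Lipid species are handled at the "FA acyl/alkyl" annotation level: a class
code plus total chain carbons and total double bonds, optionally refined to
individual fatty-acid residues (e.g. ``PE 16:0/22:6``) or a sphingoid base
(``Cer d18:1/17:0``).  sn-positions, double-bond positions and stereochemistry
are never represented.

The class registry is data-driven: each class carries the number of carbon
chain residues typical for the class, a base elemental formula such that

    neutral formula = base + C(total_carbons) + H(2*total_carbons - 2*total_db)

and the adducts eligible per ionization polarity.  The default registry merges
some LIPID MAPS subclasses (all free fatty acids in one ``FA`` class; ``Cer``
covering dihydro- and phytoceramides; ``HexCer`` covering both glucosyl- and
galactosylceramides), matching common practice for brain lipidomics.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "AdductSpec",
    "LipidClassSpec",
    "LipidSpecies",
    "ADDUCTS",
    "default_registry",
    "load_registry",
    "save_registry",
    "parse_shorthand",
    "format_shorthand",
    "species_formula",
    "neutral_mass",
    "monoisotopic_mass",
    "fluidity_score",
    "omega_flags",
    "AnnotationError",
    "ChemistryError",
]


class AnnotationError(ValueError):
    """Raised for unparseable or unregistered lipid names."""


class ChemistryError(ValueError):
    """Raised when an elemental formula cannot be composed for a species."""


# Monoisotopic atomic masses (Da), CODATA/AME2020 values.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727646...
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C8H16NO8P`` into counts."""
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ChemistryError(f"malformed formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise ChemistryError(f"unknown element {el!r} in {formula!r}")
        out[el] = out.get(el, 0) + (int(n) if n else 1)
    if pos != len(formula):
        raise ChemistryError(f"malformed formula {formula!r}")
    return out


def format_formula(counts: Mapping[str, int]) -> str:
    order = ["C", "H", "N", "O", "P", "S", "Na"]
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def formula_mass(counts: Mapping[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, polarity, mass shift and charge."""

    name: str
    polarity: str  # "pos" | "neg"
    mass_delta: float  # Da added to the neutral monoisotopic mass
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if (self.charge > 0) != (self.polarity == "pos"):
            raise ValueError(
                f"adduct {self.name}: polarity {self.polarity} inconsistent "
                f"with charge {self.charge:+d}"
            )


# Standard adducts; deltas include the electron mass.
ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", "pos", PROTON_MASS, 1),
        AdductSpec(
            "[M+NH4]+",
            "pos",
            ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] - ELECTRON_MASS,
            1,
        ),
        AdductSpec("[M+Na]+", "pos", ATOMIC_MASS["Na"] - ELECTRON_MASS, 1),
        AdductSpec("[M-H]-", "neg", -PROTON_MASS, -1),
        AdductSpec(
            "[M+HCOO]-",
            "neg",
            ATOMIC_MASS["C"]
            + ATOMIC_MASS["H"]
            + 2 * ATOMIC_MASS["O"]
            + ELECTRON_MASS,
            -1,
        ),
    ]
}


@dataclass(frozen=True)
class LipidClassSpec:
    """Registry entry for one lipid class.

    ``base_formula`` is the headgroup+backbone composition with chain hydrogens
    folded in, so the neutral species formula is ``base + C_n H_(2n-2d)`` for
    ``n`` total carbons and ``d`` total double bonds.  ``chainless`` classes
    (cholesterol) use ``base_formula`` as the complete molecule and are
    excluded from fluidity scoring.
    """

    class_code: str
    n_chains: int
    base_formula: str
    adducts: tuple[AdductSpec, ...]
    chainless: bool = False

    def __post_init__(self) -> None:
        if not self.chainless and self.n_chains not in (1, 2, 3):
            raise ValueError(f"{self.class_code}: n_chains must be 1, 2 or 3")
        if not self.adducts:
            raise ValueError(f"{self.class_code}: at least one adduct required")


def _spec(code: str, n: int, base: str, adduct_names: Sequence[str],
          chainless: bool = False) -> LipidClassSpec:
    return LipidClassSpec(
        code, n, base, tuple(ADDUCTS[a] for a in adduct_names), chainless
    )


def default_registry() -> dict[str, LipidClassSpec]:
    """The built-in 23-class registry (plus cholesterol), brain-lipidome style.

    Base formulas reproduce standard diacyl/alkyl-acyl glycerophospholipid,
    sphingolipid and glycerolipid compositions; e.g. PC n:d -> C(n+8)
    H(2n-2d+16) N O8 P.
    """
    both = ("[M+H]+", "[M-H]-")
    return {
        s.class_code: s
        for s in [
            # glycerophospholipids (2 chains)
            _spec("PC", 2, "C8H16NO8P", ("[M+H]+", "[M+HCOO]-")),
            _spec("PE", 2, "C5H10NO8P", both),
            _spec("PS", 2, "C6H10NO10P", both),
            _spec("PG", 2, "C6H11O10P", both),
            _spec("PA", 2, "C3H5O8P", ("[M-H]-",)),
            _spec("PI", 2, "C9H15O13P", ("[M-H]-",)),
            # ether (plasmanyl, -O) and plasmalogen (plasmenyl, -P) forms
            _spec("PC-O", 2, "C8H18NO7P", ("[M+H]+", "[M+HCOO]-")),
            _spec("PC-P", 2, "C8H16NO7P", ("[M+H]+", "[M+HCOO]-")),
            _spec("PE-O", 2, "C5H12NO7P", both),
            _spec("PE-P", 2, "C5H10NO7P", both),
            # lyso forms (1 chain)
            _spec("LPC", 1, "C8H18NO7P", ("[M+H]+", "[M+HCOO]-")),
            _spec("LPE", 1, "C5H12NO7P", both),
            _spec("LPC-O", 1, "C8H20NO6P", ("[M+H]+", "[M+HCOO]-")),
            _spec("LPE-O", 1, "C5H14NO6P", both),
            _spec("LPS", 1, "C6H12NO9P", both),
            _spec("LPA", 1, "C3H7O7P", ("[M-H]-",)),
            # sphingolipids (sphingoid base + N-acyl = 2 chains)
            _spec("Cer", 2, "HNO3", both),
            _spec("SM", 2, "C5H13N2O6P", ("[M+H]+", "[M+HCOO]-")),
            _spec("HexCer", 2, "C6H11NO8", both),
            _spec("SHexCer", 2, "C6H11NO11S", ("[M-H]-", "[M+H]+")),
            # glycerolipids
            _spec("MAG", 1, "C3H6O4", ("[M+NH4]+",)),
            _spec("DAG", 2, "C3H4O5", ("[M+NH4]+",)),
            _spec("TAG", 3, "C3H2O6", ("[M+NH4]+",)),
            # others
            _spec("FA", 1, "O2", ("[M-H]-",)),
            _spec("CAR", 1, "C7H13NO4", ("[M+H]+",)),
            _spec("CE", 1, "C27H44O2", ("[M+NH4]+",)),
            _spec("Chol", 0, "C27H46O", ("[M+Na]+",), chainless=True),
        ]
    }


def save_registry(registry: Mapping[str, LipidClassSpec], path) -> None:
    """Write a registry to a CSV config file."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_code", "n_chains", "base_formula", "adducts",
                    "chainless"])
        for spec in registry.values():
            w.writerow([
                spec.class_code,
                spec.n_chains,
                spec.base_formula,
                ";".join(a.name for a in spec.adducts),
                int(spec.chainless),
            ])


def load_registry(path) -> dict[str, LipidClassSpec]:
    """Load a class registry from a CSV config file (see ``save_registry``)."""
    out: dict[str, LipidClassSpec] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            code = row["class_code"]
            names = [a for a in row["adducts"].split(";") if a]
            unknown = [a for a in names if a not in ADDUCTS]
            if unknown:
                raise AnnotationError(
                    f"class {code}: unknown adduct names {unknown}"
                )
            out[code] = _spec(
                code,
                int(row["n_chains"]),
                row["base_formula"],
                names,
                chainless=bool(int(row.get("chainless", "0") or 0)),
            )
    return out


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at annotation level: class + total carbons:double bonds.

    ``fa_residues`` holds per-residue (carbons, double_bonds) pairs when the
    fatty-acid composition is known; ``sphingoid_base`` keeps the base code
    (e.g. ``d18:1``) for sphingolipids annotated at residue level.
    """

    lipid_id: str
    class_code: str
    total_carbons: int
    total_double_bonds: int
    fa_residues: tuple[tuple[int, int], ...] | None = None
    sphingoid_base: str | None = None

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise ValueError(f"{self.lipid_id}: total_carbons must be > 0")
        if self.total_double_bonds < 0:
            raise ValueError(f"{self.lipid_id}: total_double_bonds must be >= 0")
        if self.fa_residues is not None:
            c = sum(r[0] for r in self.fa_residues)
            d = sum(r[1] for r in self.fa_residues)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"{self.lipid_id}: residue sums {c}:{d} do not match "
                    f"totals {self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def n_chains(self) -> int | None:
        return len(self.fa_residues) if self.fa_residues is not None else None


_CD_TOKEN = re.compile(r"^(?P<base>[dtm])?(?P<c>\d+):(?P<db>\d+)$")


def parse_shorthand(name: str,
                    registry: Mapping[str, LipidClassSpec] | None = None
                    ) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepted forms: ``PC 34:1``, ``PC-P 36:2`` (ether/plasmalogen suffixes are
    distinct classes), residue-level ``PE 16:0/22:6`` or ``Cer d18:1/17:0``,
    and the chainless ``Chol``.
    """
    registry = registry if registry is not None else default_registry()
    name = name.strip()
    parts = name.split()
    if not parts:
        raise AnnotationError("empty lipid name")
    cls = parts[0]
    if cls not in registry:
        raise AnnotationError(f"unknown lipid class token {cls!r} in {name!r}")
    spec = registry[cls]
    if spec.chainless:
        if len(parts) > 1:
            raise AnnotationError(
                f"{name!r}: class {cls} takes no chain composition"
            )
        base = parse_formula(spec.base_formula)
        return LipidSpecies(name, cls, base.get("C", 27), 1)
    if len(parts) != 2:
        raise AnnotationError(f"cannot parse lipid name {name!r}")
    tokens = parts[1].split("/")
    residues: list[tuple[int, int]] = []
    sphingoid = None
    for tok in tokens:
        m = _CD_TOKEN.match(tok)
        if m is None:
            raise AnnotationError(
                f"malformed carbons:double-bonds token {tok!r} in {name!r}"
            )
        if m.group("base"):
            sphingoid = tok
        residues.append((int(m.group("c")), int(m.group("db"))))
    if len(tokens) == 1 and sphingoid is None:
        c, d = residues[0]
        fa = ((c, d),) if spec.n_chains == 1 else None
        return LipidSpecies(name, cls, c, d, fa_residues=fa)
    return LipidSpecies(
        name,
        cls,
        sum(r[0] for r in residues),
        sum(r[1] for r in residues),
        fa_residues=tuple(residues),
        sphingoid_base=sphingoid,
    )


def format_shorthand(species: LipidSpecies,
                     residue_level: bool = False) -> str:
    """Canonical shorthand name; inverse of :func:`parse_shorthand`."""
    if species.class_code == "Chol":
        return "Chol"
    if residue_level and species.fa_residues:
        toks = []
        for i, (c, d) in enumerate(species.fa_residues):
            tok = f"{c}:{d}"
            if i == 0 and species.sphingoid_base:
                tok = species.sphingoid_base
            toks.append(tok)
        return f"{species.class_code} {'/'.join(toks)}"
    return (f"{species.class_code} "
            f"{species.total_carbons}:{species.total_double_bonds}")


def species_formula(species: LipidSpecies,
                    registry: Mapping[str, LipidClassSpec] | None = None
                    ) -> dict[str, int]:
    """Elemental composition of the neutral species."""
    registry = registry if registry is not None else default_registry()
    if species.class_code not in registry:
        raise AnnotationError(f"unregistered class {species.class_code!r}")
    spec = registry[species.class_code]
    counts = parse_formula(spec.base_formula)
    if spec.chainless:
        if species.fa_residues:
            raise ChemistryError(
                f"{species.lipid_id}: chainless class {spec.class_code} "
                "cannot carry fatty-acid residues"
            )
        return counts
    n, d = species.total_carbons, species.total_double_bonds
    n_h = 2 * n - 2 * d
    if n_h < 0:
        raise ChemistryError(
            f"{species.lipid_id}: {d} double bonds impossible for {n} carbons"
        )
    counts["C"] = counts.get("C", 0) + n
    counts["H"] = counts.get("H", 0) + n_h
    return counts


def neutral_mass(species: LipidSpecies,
                 registry: Mapping[str, LipidClassSpec] | None = None) -> float:
    return formula_mass(species_formula(species, registry))


def monoisotopic_mass(species: LipidSpecies, adduct: AdductSpec,
                      registry: Mapping[str, LipidClassSpec] | None = None
                      ) -> float:
    """m/z of the species under the given adduct:
    (neutral mass + adduct delta) / |charge|."""
    return (neutral_mass(species, registry) + adduct.mass_delta) / abs(
        adduct.charge
    )


def fluidity_score(species_set: Sequence[LipidSpecies],
                   registry: Mapping[str, LipidClassSpec] | None = None
                   ) -> dict[str, float]:
    """Relative membrane-fluidity contribution of each lipid, in [0, 1].

    Per lipid, double bonds per chain ``d`` and chain length ``L`` are the
    totals divided by the class-typical chain count.  Both are min-max
    normalized over the input set; the score is ``(d_norm + (1 - L_norm))/2``
    so that more unsaturated, shorter-chain lipids score higher.  When a
    dimension is constant over the set its normalized value is fixed at 0.5
    (neutral contribution).  Cholesterol (chainless) is excluded.
    """
    registry = registry if registry is not None else default_registry()
    scored = [
        s for s in species_set
        if not registry[s.class_code].chainless
    ]
    if len(scored) < 2:
        raise ValueError(
            "fluidity_score needs >= 2 non-cholesterol lipids "
            "(min-max normalization undefined otherwise)"
        )
    d_vals, l_vals = [], []
    for s in scored:
        nch = registry[s.class_code].n_chains
        d_vals.append(s.total_double_bonds / nch)
        l_vals.append(s.total_carbons / nch)

    def norm(vals: list[float]) -> list[float]:
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return [0.5] * len(vals)
        return [(v - lo) / (hi - lo) for v in vals]

    dn, ln = norm(d_vals), norm(l_vals)
    return {
        s.lipid_id: (dni + (1.0 - lni)) / 2.0
        for s, dni, lni in zip(scored, dn, ln)
    }


def omega_flags(species: LipidSpecies) -> dict[str, bool]:
    """DHA (22:6, omega-3) / adrenic acid (22:4, omega-6) residue occurrence.

    Returns ``{"omega3", "omega6", "residues_unknown"}``; when fatty-acid
    residues are not annotated both flags are False and ``residues_unknown``
    is True.
    """
    if species.fa_residues is None:
        return {"omega3": False, "omega6": False, "residues_unknown": True}
    res = set(species.fa_residues)
    return {
        "omega3": (22, 6) in res,
        "omega6": (22, 4) in res,
        "residues_unknown": False,
    }
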