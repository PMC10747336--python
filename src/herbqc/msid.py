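"""Exact-mass, adduct and ppm arithmetic for small-molecule identification.

This module implements the mass bookkeeping behind LC-MS compound and
metabolite annotation: monoisotopic masses from molecular formulas, ionic
m/z for the common soft-ionization adducts, ppm errors, MS2 neutral-loss
fragmentation ladders, and combinatorial biotransformation annotation of
plasma features against parent compounds.

All charged-species arithmetic is electron-corrected: protonation and
deprotonation use the proton mass (H atom minus one electron), and the
chloride adduct adds a Cl atom plus one electron.  Atomic masses are frozen
here rather than taken from a library so that results are stable across
dependency versions.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .exceptions import DomainError, FormulaParseError, ParameterError

# Monoisotopic atomic masses (Da).  Frozen: the annotation outputs must not
# drift with external mass-table updates.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "Cl": 34.96885268,
}

PROTON_MASS = 1.0072765  # H atom minus one electron
ELECTRON_MASS = 0.0005486

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element-count map of a molecular formula.

    Counts may be negative only in *delta* formulas used by modification
    rules; a standalone molecular formula must be non-negative.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Formula":
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n != 0))
        return cls(items)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return Formula.from_dict(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return Formula.from_dict(d)

    def __neg__(self) -> "Formula":
        return Formula.from_dict({el: -n for el, n in self.counts})

    def is_valid_molecule(self) -> bool:
        return len(self.counts) > 0 and all(n > 0 for _, n in self.counts)

    def __str__(self) -> str:
        # Hill order: C, then H, then the rest alphabetically.
        d = self.to_dict()
        parts = []
        for el in ["C", "H"]:
            if el in d:
                n = d.pop(el)
                parts.append(f"{el}{n if n != 1 else ''}")
        for el in sorted(d):
            n = d[el]
            parts.append(f"{el}{n if n != 1 else ''}")
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style molecular formula (no parentheses or isotopes).

    >>> parse_formula("C7H13NO2").to_dict()
    {'C': 7, 'H': 13, 'N': 1, 'O': 2}
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError(f"empty or non-string formula: {text!r}")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaParseError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaParseError(f"unknown element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaParseError(f"malformed formula {text!r}")
    return Formula.from_dict(counts)


def _as_formula(f) -> Formula:
    return f if isinstance(f, Formula) else parse_formula(f)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic (exact) mass of a neutral formula, in Da."""
    f = _as_formula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)


# Formic acid HCOOH, used by the formate adduct.
_FA_MASS = monoisotopic_mass(parse_formula("CH2O2"))

#: adduct label -> (mass shift added to the neutral monoisotopic mass, mode)
ADDUCT_SHIFTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (PROTON_MASS, "+"),
    "[M-H]-": (-PROTON_MASS, "-"),
    "[M+FA-H]-": (_FA_MASS - PROTON_MASS, "-"),
    "[M+Cl]-": (MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS, "-"),
}


@dataclass(frozen=True)
class IonSpec:
    """An adduct rule turning a neutral molecule into an observed ion."""

    adduct: str

    def __post_init__(self):
        if self.adduct not in ADDUCT_SHIFTS:
            raise ParameterError(
                f"unsupported adduct {self.adduct!r}; "
                f"supported: {sorted(ADDUCT_SHIFTS)}"
            )

    @property
    def mode(self) -> str:
        return ADDUCT_SHIFTS[self.adduct][1]

    @property
    def shift(self) -> float:
        return ADDUCT_SHIFTS[self.adduct][0]


def normalize_adduct(label: str) -> str:
    """Canonicalize an adduct label: strip spaces and unicode minus signs."""
    s = label.replace(" ", "").replace("−", "-").replace("–", "-")
    return s


def ion_mz(f: Formula | str, ion: IonSpec | str) -> float:
    """Theoretical m/z of an adduct ion of the neutral formula ``f``.

    Electron mass is accounted for in every charged species: [M+H]+ adds a
    proton (1.0072765 Da) and [M+Cl]- adds a chlorine atom plus an electron.
    """
    if isinstance(ion, str):
        ion = IonSpec(normalize_adduct(ion))
    return monoisotopic_mass(f) + ion.shift


def ppm_error(measured: float, calc: float) -> float:
    """Relative mass error in parts per million: (measured - calc)/calc * 1e6."""
    if calc <= 0:
        raise ParameterError("calculated m/z must be positive")
    return (measured - calc) / calc * 1e6


@dataclass(frozen=True)
class ModificationRule:
    """A biotransformation as a signed element delta.

    ``delta`` is added to the parent formula; a negated rule undoes it.
    """

    name: str
    delta: Formula

    @property
    def mass_shift(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.delta.counts)

    def negate(self) -> "ModificationRule":
        return ModificationRule(f"de-{self.name}", -self.delta)


def _rule(name: str, **counts: int) -> ModificationRule:
    return ModificationRule(name, Formula.from_dict(counts))


#: The phase-I/II biotransformations observed for flavonoid metabolites.
STANDARD_RULES: dict[str, ModificationRule] = {
    r.name: r
    for r in [
        _rule("glucuronidation", C=6, H=8, O=6),     # +176.0321
        _rule("sulfation", S=1, O=3),                # +79.9568
        _rule("demethylation", C=-1, H=-2),          # -14.0157
        _rule("hydroxylation", O=1),                 # +15.9949
        _rule("hydrogenation", H=2),                 # +2.0157
        _rule("deglycosylation", C=-6, H=-10, O=-5), # -162.0528
    ]
}

#: Common MS2 neutral losses (sugar residues and small radicals/molecules).
NEUTRAL_LOSSES: dict[str, Formula] = {
    "glucose": parse_formula("C6H10O5"),      # 162.0528
    "xylose": parse_formula("C5H8O4"),        # 132.0423
    "deoxyhexose": parse_formula("C6H10O4"),  # 146.0579
    "CH3": parse_formula("CH3"),              # 15.0235
    "CO": parse_formula("CO"),                # 27.9949
    "CH3OH": parse_formula("CH4O"),           # 32.0262
}


@dataclass(frozen=True)
class Feature:
    """An observed LC-MS feature (one measured m/z in one ion mode)."""

    id: str
    measured_mz: float
    ion_mode: str  # "+" or "-"
    rt: float | None = None

    def __post_init__(self):
        if self.measured_mz <= 0:
            raise ParameterError(f"feature {self.id}: measured_mz must be > 0")
        if self.ion_mode not in ("+", "-"):
            raise ParameterError(f"feature {self.id}: ion_mode must be '+' or '-'")


@dataclass(frozen=True)
class AnnotationResult:
    feature_id: str
    parent: str
    modifications: tuple[str, ...]
    adduct: str
    formula: Formula
    calc_mz: float
    ppm: float

    @property
    def label(self) -> str:
        return " + ".join((self.parent,) + self.modifications)


def enumerate_candidates(
    parents: dict[str, Formula | str],
    rules: list[ModificationRule] | None = None,
    adducts: list[str] | None = None,
    max_depth: int = 3,
) -> list[tuple[str, tuple[str, ...], str, Formula, float]]:
    """All (parent, modification multiset, adduct) candidate ions.

    Multisets of size 0..max_depth are enumerated with replacement;
    candidates whose element counts go negative are dropped.  Returns tuples
    (parent, mods, adduct, formula, calc_mz).
    """
    if not parents:
        raise ParameterError("parents must be non-empty")
    rules = list(STANDARD_RULES.values()) if rules is None else list(rules)
    adducts = list(ADDUCT_SHIFTS) if adducts is None else [
        normalize_adduct(a) for a in adducts
    ]
    out = []
    for pname, pform in sorted(parents.items()):
        pform = _as_formula(pform)
        for depth in range(max_depth + 1):
            for combo in itertools.combinations_with_replacement(
                sorted(rules, key=lambda r: r.name), depth
            ):
                f = pform
                for rule in combo:
                    f = f + rule.delta
                if not f.is_valid_molecule():
                    continue
                mods = tuple(r.name for r in combo)
                for adduct in adducts:
                    out.append((pname, mods, adduct, f, ion_mz(f, adduct)))
    return out


def annotate_features(
    features: list[Feature],
    parents: dict[str, Formula | str],
    rules: list[ModificationRule] | None = None,
    adducts: list[str] | None = None,
    tol_ppm: float = 10.0,
    max_depth: int = 3,
) -> list[AnnotationResult]:
    """Annotate features as parent x biotransformation-combination ions.

    Every candidate within ``tol_ppm`` of a feature's measured m/z is
    returned, ordered per feature by absolute ppm error, then by number of
    modifications, then by parent name (deterministic tie-break).
    """
    if tol_ppm <= 0:
        raise ParameterError("tol_ppm must be > 0")
    candidates = enumerate_candidates(parents, rules, adducts, max_depth)
    by_mode: dict[str, list] = {"+": [], "-": []}
    for cand in candidates:
        by_mode[IonSpec(cand[2]).mode].append(cand)

    results: list[AnnotationResult] = []
    for feat in features:
        hits = []
        for pname, mods, adduct, f, calc in by_mode[feat.ion_mode]:
            ppm = ppm_error(feat.measured_mz, calc)
            if abs(ppm) <= tol_ppm:
                hits.append(
                    AnnotationResult(feat.id, pname, mods, adduct, f, calc, ppm)
                )
        hits.sort(key=lambda a: (abs(a.ppm), len(a.modifications), a.parent, a.adduct))
        results.extend(hits)
    return results


def best_annotations(results: list[AnnotationResult]) -> dict[str, AnnotationResult]:
    """First (best-ranked) annotation per feature id, preserving input order."""
    best: dict[str, AnnotationResult] = {}
    for r in results:
        best.setdefault(r.feature_id, r)
    return best


@dataclass(frozen=True)
class FragmentLadder:
    """Expected MS2 fragment sequence from successive neutral losses."""

    precursor_mz: float
    losses: tuple[str, ...]
    mz: tuple[float, ...]  # precursor first, then after each loss

    def __post_init__(self):
        if any(b >= a for a, b in zip(self.mz, self.mz[1:])):
            raise DomainError("fragment ladder m/z must be strictly decreasing")


def fragment_ladder(
    precursor: Formula | str,
    ion: IonSpec | str,
    losses: list[Formula | str],
) -> FragmentLadder:
    """Build the m/z ladder of a precursor ion losing neutrals in sequence.

    ``losses`` entries may be Formula objects, formula strings, or names from
    the built-in :data:`NEUTRAL_LOSSES` library.
    """
    precursor = _as_formula(precursor)
    if isinstance(ion, str):
        ion = IonSpec(normalize_adduct(ion))
    resolved: list[tuple[str, Formula]] = []
    for loss in losses:
        if isinstance(loss, Formula):
            resolved.append((str(loss), loss))
        elif loss in NEUTRAL_LOSSES:
            resolved.append((loss, NEUTRAL_LOSSES[loss]))
        else:
            resolved.append((loss, parse_formula(loss)))

    mzs = [ion_mz(precursor, ion)]
    current = precursor
    for step, (name, loss) in enumerate(resolved, start=1):
        current = current - loss
        if not current.is_valid_molecule():
            raise DomainError(
                f"loss {step} ({name}) leaves negative element counts"
            )
        mzs.append(ion_mz(current, ion))
    return FragmentLadder(mzs[0], tuple(n for n, _ in resolved), tuple(mzs))


def match_fragments(
    observed_mz: list[float],
    ladder: FragmentLadder,
    tol_ppm: float = 20.0,
) -> tuple[list[tuple[int, float, float]], float]:
    """Greedily match observed MS2 peaks to ladder steps by nearest ppm.

    Each observed peak and each ladder step is used at most once; pairs are
    assigned in order of increasing absolute ppm deviation.  Returns the
    matched (step index, ladder m/z, observed m/z) triples and the coverage
    fraction (matched steps / total steps).
    """
    if not ladder.mz:
        raise ParameterError("ladder must be non-empty")
    pairs = []
    for i, lmz in enumerate(ladder.mz):
        for omz in observed_mz:
            dev = abs(ppm_error(omz, lmz))
            if dev <= tol_ppm:
                pairs.append((dev, i, lmz, omz))
    pairs.sort()
    used_steps: set[int] = set()
    used_obs: set[float] = set()
    matches = []
    for dev, i, lmz, omz in pairs:
        if i in used_steps or omz in used_obs:
            continue
        used_steps.add(i)
        used_obs.add(omz)
        matches.append((i, lmz, omz))
    matches.sort()
    return matches, len(matches) / len(ladder.mz)
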