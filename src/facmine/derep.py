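"""Accurate-mass dereplication of LC-HRMS components.

Identifies detected components as known compounds by matching observed m/z
against theoretical adduct m/z values computed from molecular formulas, within
a part-per-million (ppm) tolerance. Atomic masses come from the NIST table
shipped with :mod:`pyteomics` (``pyteomics.mass.nist_mass``); the formula
parser and mass summation are implemented here so that the matching chain is
auditable end to end.

Identity is confirmed in two stages, mirroring standard natural-product
practice: an accurate-mass database search (default tolerance 3 ppm), then
matching of observed MS2 fragment peaks against a user-supplied list of
predicted fragment masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics.mass import nist_mass

__all__ = [
    "CompoundRecord",
    "MatchHit",
    "Ms2Match",
    "FormulaError",
    "DEFAULT_ADDUCTS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "adduct_mz",
    "ppm_error",
    "match_database",
    "match_fragments",
]

#: Mass of the electron in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Monoisotopic mass of each element's most abundant isotope, in Da.
#: nist_mass[element][0] is pyteomics' convention for that value.
MONOISOTOPIC = {el: isotopes[0][0] for el, isotopes in nist_mass.items()}

#: Mass of the proton (H minus one electron), in Da.
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

#: Positive-electrospray adducts handled by default: label -> (mass shift, charge).
#: The shift is the cation mass (neutral atoms minus one electron).
DEFAULT_ADDUCTS: Mapping[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (MONOISOTOPIC["Na"] - ELECTRON_MASS, 1),
    "[M+NH4]+": (MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"] - ELECTRON_MASS, 1),
    "[M+K]+": (MONOISOTOPIC["K"] - ELECTRON_MASS, 1),
}


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid molecular formulas."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    Accepts plain element symbols with optional integer counts (count omitted
    means 1), e.g. ``"C6H12O6"`` -> ``{"C": 6, "H": 12, "O": 6}``. Repeated
    symbols accumulate. Parentheses, isotopes and charges are not supported.

    Raises
    ------
    FormulaError
        If the string contains anything but valid element tokens, or an
        element symbol not present in the atomic-mass table.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a composition: sum of count x most-abundant-isotope mass."""
    try:
        return float(sum(n * MONOISOTOPIC[el] for el, n in counts.items()))
    except KeyError as exc:  # pragma: no cover - parse_formula screens symbols
        raise FormulaError(f"unknown element {exc.args[0]!r}") from None


def formula_mass(text: str) -> float:
    """Monoisotopic mass (Da) of a Hill-style formula string."""
    return monoisotopic_mass(parse_formula(text))


def adduct_mz(
    neutral_mass: float,
    adduct: str,
    adducts: Mapping[str, tuple[float, int]] = DEFAULT_ADDUCTS,
) -> float:
    """Theoretical m/z of ``neutral_mass`` observed as the given adduct.

    m/z = (M + shift) / z, with the shift being the full cation mass (so the
    electron deficit is accounted for).
    """
    if adduct not in adducts:
        raise KeyError(f"adduct {adduct!r} not configured (have {sorted(adducts)})")
    shift, charge = adducts[adduct]
    return (neutral_mass + shift) / charge


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million.

    (observed - theoretical) / theoretical * 1e6; positive means the observed
    mass is high. The reference is the theoretical m/z.
    """
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class CompoundRecord:
    """One accurate-mass database entry.

    If ``formula`` is given the monoisotopic mass is derived from it; a mass
    supplied alongside a formula must agree with the derived value to 1e-4 Da.
    """

    name: str
    formula: str | None = None
    monoisotopic_mass: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.formula is not None:
            derived = formula_mass(self.formula)
            if self.monoisotopic_mass is not None:
                if abs(self.monoisotopic_mass - derived) > 1e-4:
                    raise ValueError(
                        f"{self.name}: stated mass {self.monoisotopic_mass} "
                        f"disagrees with formula mass {derived:.5f}"
                    )
            object.__setattr__(self, "monoisotopic_mass", derived)
        if self.monoisotopic_mass is None:
            raise ValueError(f"{self.name}: need a formula or a monoisotopic mass")
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")


@dataclass(frozen=True)
class MatchHit:
    """A component/compound accurate-mass match for one adduct."""

    component_id: str
    compound: CompoundRecord
    adduct: str
    ppm_error: float
    observed_mz: float
    theoretical_mz: float


def match_database(
    components: Iterable,
    db: Sequence[CompoundRecord],
    tol_ppm: float = 3.0,
    adducts: Mapping[str, tuple[float, int]] = DEFAULT_ADDUCTS,
) -> list[MatchHit]:
    """Search component consensus m/z values against a compound database.

    Every (component, compound, adduct) combination whose absolute ppm error
    is within ``tol_ppm`` yields a hit. Components need ``component_id`` and
    ``mz`` attributes. Hits are sorted by |ppm error| ascending, then by
    component id, compound name and adduct for a stable order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    hits: list[MatchHit] = []
    for comp in components:
        mz = float(comp.mz)
        for rec in db:
            for label in adducts:
                theo = adduct_mz(rec.monoisotopic_mass, label, adducts)
                err = ppm_error(mz, theo)
                if abs(err) <= tol_ppm:
                    hits.append(
                        MatchHit(
                            component_id=comp.component_id,
                            compound=rec,
                            adduct=label,
                            ppm_error=err,
                            observed_mz=mz,
                            theoretical_mz=theo,
                        )
                    )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.component_id, h.compound.name, h.adduct))
    return hits


@dataclass(frozen=True)
class Ms2Match:
    """Result of matching observed MS2 peaks to predicted fragment masses."""

    n_predicted: int
    n_matched: int
    pairs: tuple[tuple[float, float, float], ...] = field(default=())
    # each pair: (observed m/z, predicted m/z, signed ppm error)

    @property
    def score(self) -> float:
        """Fraction of predicted fragments recovered, in [0, 1]."""
        return self.n_matched / self.n_predicted


def match_fragments(
    observed_ms2: Sequence[float],
    predicted: Sequence[float],
    tol_ppm: float = 10.0,
) -> Ms2Match:
    """Greedy one-to-one pairing of observed and predicted fragment m/z.

    Candidate pairs within ``tol_ppm`` are taken in order of increasing
    |ppm error|; each observed and each predicted peak is used at most once.
    The score is matched/predicted.
    """
    if len(predicted) == 0:
        raise ValueError("predicted fragment list is empty; score undefined")
    candidates = []
    for i, obs in enumerate(observed_ms2):
        for j, pred in enumerate(predicted):
            err = ppm_error(obs, pred)
            if abs(err) <= tol_ppm:
                candidates.append((abs(err), i, j, obs, pred, err))
    candidates.sort()
    used_obs: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[float, float, float]] = []
    for _, i, j, obs, pred, err in candidates:
        if i in used_obs or j in used_pred:
            continue
        used_obs.add(i)
        used_pred.add(j)
        pairs.append((obs, pred, err))
    return Ms2Match(n_predicted=len(predicted), n_matched=len(pairs), pairs=tuple(pairs))
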