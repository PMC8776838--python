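"""Siderophore identification in LC-MS feature tables.

Candidate compounds are screened by matching observed MS1 feature m/z
against theoretical adduct m/z derived from molecular formulas, and
optionally confirmed by counting diagnostic MS2 fragment ions.  The
canonical use case is identifying petrobactin (C34H50N6O11, the
catecholate/citrate siderophore of *Alteromonas macleodii* ATCC 27126)
and its norspermidine-derived variant (C32H46N6O11) in seawater-extract
feature lists: their [M+H]+ ions fall at 719.361 and 691.330 m/z.

Reference masses are always recomputed from formulas; a mass column in a
reference table is validated against the formula, never trusted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "PETROBACTIN_MS2_FRAGMENTS",
    "MsFeature",
    "SiderophoreRecord",
    "MatchResult",
    "Ms2Match",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "match_features",
    "match_ms2",
    "load_reference_table",
    "load_feature_table",
]

# Monoisotopic atomic masses (Da).  C is exactly 12 by definition of the
# unified atomic mass unit; the rest are CODATA/AME values truncated at
# the precision carried through all derived m/z.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
    "Fe": 55.93493633,
    "Na": 22.98976928,
}

PROTON_MASS = 1.00727646  # H+ (H atom minus one electron), Da
ELECTRON_MASS = 0.00054858

# Each adduct maps to (mass delta added to the neutral M, charge z):
# m/z = (M + delta) / z.  Charge is carried by proton transfer, hence the
# proton (not H-atom) mass.  The ferric adduct models an Fe(III) complex
# in which the metal displaces three protons from the ligand while two
# deprotonations are counted in the ion formula, leaving net charge +1:
# m/z = M + m(Fe) - 2*m(H atom) - m(e-).
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+2H]2+": (2 * PROTON_MASS, 2),
    "[M-H]-": (-PROTON_MASS, 1),
    "[M+Fe-2H]+": (
        MONOISOTOPIC_MASS["Fe"] - 2 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS,
        1,
    ),
}

# Diagnostic petrobactin MS2 fragment ions (m/z), as reported for the
# authentic standard; used to confirm an MS1 match at 719.361.
PETROBACTIN_MS2_FRAGMENTS: tuple[float, ...] = (194.0, 282.0, 438.0, 565.0)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into an element-count mapping.

    An omitted count means 1 ("H2O" -> {H: 2, O: 1}).  Repeated element
    symbols accumulate.  Unknown element symbols raise ``FormulaError``
    naming the offending token.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unparseable at {text[pos:match.start()]!r}"
            )
        pos = match.end()
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    return counts


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an element-count mapping."""
    for element in formula:
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {element!r}")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items())


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of ``adduct`` for a neutral monoisotopic mass.

    Full precision is kept; round only for display.
    """
    try:
        delta, charge = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        ) from None
    return (neutral_mass + delta) / charge


@dataclass(frozen=True)
class SiderophoreRecord:
    """A named reference compound with formula-derived masses."""

    name: str
    formula: Mapping[str, int]
    neutral_monoisotopic_mass: float
    adduct_mz: Mapping[str, float]

    @classmethod
    def from_formula(
        cls, name: str, formula: str | Mapping[str, int],
        adducts: Sequence[str] = ("[M+H]+",),
    ) -> "SiderophoreRecord":
        counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
        mass = monoisotopic_mass(counts)
        return cls(name, counts, mass, {a: adduct_mz(mass, a) for a in adducts})


@dataclass(frozen=True)
class MsFeature:
    """One aligned LC-MS feature (MS1 peak).

    ``intensity`` is MS1 peak height, used downstream as the abundance
    proxy; ``ms2_peaks`` is the fragment list of an associated MS2
    spectrum, if one was acquired.
    """

    mz: float
    retention_time: float = 0.0
    intensity: float = 0.0
    ms2_peaks: tuple[float, ...] | None = None
    sample_id: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("feature intensity must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    feature: MsFeature
    compound: str
    adduct: str
    ppm_error: float
    iron_form: str  # "apo" or "ferric"
    n_ms2_matched: int | None = None


@dataclass(frozen=True)
class Ms2Match:
    n_matched: int
    has_ms2: bool  # False flags a feature with no MS2 spectrum


def iron_form_of(adduct: str) -> str:
    return "ferric" if "Fe" in adduct else "apo"


def match_features(
    features: Iterable[MsFeature],
    references: Sequence[SiderophoreRecord],
    tol_ppm: float = 5.0,
    adducts: Sequence[str] = ("[M+H]+",),
) -> list[MatchResult]:
    """Match features against reference compounds at a ppm tolerance.

    A feature matches a (compound, adduct) pair when
    |observed - theoretical| / theoretical * 1e6 <= tol_ppm.  All
    qualifying pairs are returned, sorted by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    references = list(references)
    if not references:
        warnings.warn("empty reference table: no matches possible", stacklevel=2)
        return []
    theoreticals = [
        (ref.name, adduct, adduct_mz(ref.neutral_monoisotopic_mass, adduct))
        for ref in references
        for adduct in adducts
    ]
    out: list[MatchResult] = []
    for feat in features:
        for name, adduct, mz in theoreticals:
            ppm = (feat.mz - mz) / mz * 1e6
            if abs(ppm) <= tol_ppm:
                out.append(MatchResult(feat, name, adduct, ppm, iron_form_of(adduct)))
    out.sort(key=lambda m: abs(m.ppm_error))
    return out


def match_ms2(
    observed: Sequence[float] | None,
    reference_fragments: Sequence[float],
    tol_mz: float = 0.5,
) -> Ms2Match:
    """Count reference fragments confirmed by an observed MS2 peak list.

    Each reference fragment counts once if any observed peak lies within
    +/- ``tol_mz`` Th; one observed peak may confirm several references.
    A feature without an MS2 spectrum yields 0 with ``has_ms2=False``.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    if observed is None:
        return Ms2Match(0, False)
    observed = list(observed)
    n = sum(
        1 for ref in reference_fragments
        if any(abs(obs - ref) <= tol_mz for obs in observed)
    )
    return Ms2Match(n, True)


def load_reference_table(path: str) -> list[SiderophoreRecord]:
    """Read a TSV reference table (columns: name, formula[, mass]).

    If a mass column is present it is validated against the formula to
    1e-3 Da and an inconsistency raises; the formula-derived mass is
    used regardless.
    """
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        rec = SiderophoreRecord.from_formula(str(row.name), str(row.formula))
        if hasattr(row, "mass") and not pd.isna(row.mass):
            if abs(float(row.mass) - rec.neutral_monoisotopic_mass) > 1e-3:
                raise ValueError(
                    f"reference mass for {rec.name} ({row.mass}) disagrees with "
                    f"formula-derived {rec.neutral_monoisotopic_mass:.6f}"
                )
        records.append(rec)
    return records


def load_feature_table(path: str) -> list[MsFeature]:
    """Read a TSV feature table (sample_id, mz, rt_min, intensity, ms2).

    ``ms2`` is a semicolon-joined m/z list; empty/missing means no MS2
    spectrum was acquired for the feature.
    """
    df = pd.read_csv(path, sep="\t")
    feats = []
    for i, row in enumerate(df.itertuples(index=False)):
        ms2 = None
        raw = getattr(row, "ms2", None)
        if raw is not None and not pd.isna(raw) and str(raw).strip():
            ms2 = tuple(float(x) for x in str(raw).split(";") if x.strip())
        feats.append(
            MsFeature(
                mz=float(row.mz),
                retention_time=float(getattr(row, "rt_min", 0.0) or 0.0),
                intensity=float(getattr(row, "intensity", 0.0) or 0.0),
                ms2_peaks=ms2,
                sample_id=str(getattr(row, "sample_id", "")),
                feature_id=f"F{i:05d}",
            )
        )
    return feats


def matches_to_frame(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Flatten match results into a report table."""
    return pd.DataFrame(
        [
            {
                "sample_id": m.feature.sample_id,
                "feature_id": m.feature.feature_id,
                "mz": m.feature.mz,
                "rt_min": m.feature.retention_time,
                "intensity": m.feature.intensity,
                "compound": m.compound,
                "adduct": m.adduct,
                "ppm_error": m.ppm_error,
                "iron_form": m.iron_form,
                "n_ms2_matched": m.n_ms2_matched,
            }
            for m in matches
        ]
    )
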