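"""Data model and arithmetic for archaeal tetraether (GDGT) lipid tables.

Isoprenoid GDGTs (iGDGTs) are membrane-spanning archaeal lipids whose two
C40 chains carry between zero and eight internal rings.  A sample's lipid
inventory is summarised as the relative abundance (percent) of fourteen
canonical species, measured separately for the core fraction (C-iGDGT,
head groups lost, a sedimentary/legacy signal) and the intact polar
fraction (P-iGDGT, taken to represent living cells).  The Ring Index (RI)
is the abundance-weighted mean number of rings per lipid molecule and is
the principal univariate descriptor of cyclisation.

Two RI weighting variants are exposed.  ``cren_weight5`` counts
crenarchaeol and its regioisomer at weight 5 (four cyclopentyl rings plus
one cyclohexyl ring); this is the variant the published per-sample RI
values reflect.  ``as_published`` excludes both crenarchaeol species from
the numerator, which is what the published formula states.  The
discrepancy between the two is documented in docs/methods.md; both are
first-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Literal, NamedTuple

import pandas as pd

from .errors import FormatError, UndefinedRatioError, ValidationError

__all__ = [
    "LipidSpecies",
    "LipidProfile",
    "SPECIES",
    "SPECIES_CODES",
    "ring_weights",
    "parse_lipid_table",
    "normalize",
    "ring_index",
    "absolute_abundances",
    "polar_to_core_ratio",
]

RIVariant = Literal["as_published", "cren_weight5"]
Fraction = Literal["core", "polar"]


class LipidSpecies(NamedTuple):
    """One canonical tetraether species.

    ``ring_weight`` is the weight the species carries in the Ring-Index
    numerator; ``None`` marks the two crenarchaeol species whose weight
    depends on the RI variant.
    """

    code: str
    mz: int
    ring_weight: int | None


#: The fourteen canonical species, in published column order.  GDGT-4p and
#: GDGT-5p are the 4'/5' regioisomers; neither crenarchaeol species is a
#: GDGT-5 (crenarchaeol carries a cyclohexyl ring and merely shares m/z 1292).
SPECIES: tuple[LipidSpecies, ...] = (
    LipidSpecies("GTGT-0", 1304, 0),
    LipidSpecies("GDGT-0", 1302, 0),
    LipidSpecies("GDGT-1", 1300, 1),
    LipidSpecies("GDGT-2", 1298, 2),
    LipidSpecies("GDGT-3", 1296, 3),
    LipidSpecies("GDGT-4", 1294, 4),
    LipidSpecies("GDGT-4p", 1294, 4),
    LipidSpecies("GDGT-5", 1292, 5),
    LipidSpecies("GDGT-5p", 1292, 5),
    LipidSpecies("CREN", 1292, None),
    LipidSpecies("CREN-ISO", 1292, None),
    LipidSpecies("GDGT-6", 1290, 6),
    LipidSpecies("GDGT-7", 1288, 7),
    LipidSpecies("GDGT-8", 1286, 8),
)

SPECIES_CODES: tuple[str, ...] = tuple(s.code for s in SPECIES)

# Header spellings accepted on ingest, keyed by canonical code.  Unicode
# primes and the dotted crenarchaeol abbreviations of the published tables
# are all tolerated.
_HEADER_ALIASES: dict[str, str] = {}
for _s in SPECIES:
    _HEADER_ALIASES[_s.code.lower()] = _s.code
for _alias, _code in {
    "gdgt-4′": "GDGT-4p",
    "gdgt-4'": "GDGT-4p",
    "gdgt-5′": "GDGT-5p",
    "gdgt-5'": "GDGT-5p",
    "cren": "CREN",
    "cren.": "CREN",
    "crenarchaeol": "CREN",
    "cren-iso": "CREN-ISO",
    "cren. iso": "CREN-ISO",
    "cren. iso.": "CREN-ISO",
    "cren iso": "CREN-ISO",
}.items():
    _HEADER_ALIASES[_alias] = _code


def ring_weights(variant: RIVariant = "cren_weight5") -> dict[str, float]:
    """Return the species -> Ring-Index weight map for ``variant``."""
    if variant not in ("as_published", "cren_weight5"):
        raise ValueError(f"unknown RI variant: {variant!r}")
    cren = 5.0 if variant == "cren_weight5" else 0.0
    return {
        s.code: (cren if s.ring_weight is None else float(s.ring_weight))
        for s in SPECIES
    }


@dataclass(frozen=True)
class LipidProfile:
    """Lipid inventory of one spring in one fraction.

    Parameters
    ----------
    spring_id
        Sample identifier (e.g. ``"E1"``).
    fraction
        ``"core"`` or ``"polar"``.
    rel_abundance
        Percent relative abundance per canonical species.  Species absent
        from the mapping are treated as 0 %.
    total_igdgt
        Total iGDGT concentration, ng per g dry-weight sediment.
    archaeol
        Archaeol (diether lipid) concentration, ng per g dry-weight sediment.
    ri_printed
        The Ring-Index value printed alongside the source table, retained
        for reproduction reports only; never used in computation.
    """

    spring_id: str
    fraction: Fraction
    rel_abundance: dict[str, float]
    total_igdgt: float = 0.0
    archaeol: float = 0.0
    ri_printed: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.fraction not in ("core", "polar"):
            raise ValidationError(
                f"{self.spring_id}: fraction must be 'core' or 'polar', "
                f"got {self.fraction!r}"
            )
        unknown = set(self.rel_abundance) - set(SPECIES_CODES)
        if unknown:
            raise ValidationError(
                f"{self.spring_id}: unknown lipid species {sorted(unknown)}"
            )
        for code, value in self.rel_abundance.items():
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"{self.spring_id}: relative abundance of {code} "
                    f"must be finite and >= 0, got {value}"
                )
        if self.total_igdgt < 0 or self.archaeol < 0:
            raise ValidationError(
                f"{self.spring_id}: concentrations must be >= 0"
            )

    def abundance_vector(self) -> list[float]:
        """Percent abundances over the 14 canonical species, in order."""
        return [self.rel_abundance.get(c, 0.0) for c in SPECIES_CODES]

    @property
    def abundance_sum(self) -> float:
        return sum(self.rel_abundance.values())


def _canonical_header(name: str) -> str | None:
    return _HEADER_ALIASES.get(str(name).strip().lower())


def parse_lipid_table(
    path: str | PathLike, fraction: Fraction
) -> list[LipidProfile]:
    """Parse a TSV lipid table (one spring per row) into profiles.

    The header must name the 14 canonical species (unicode primes and the
    ``Cren.`` abbreviations are accepted), a total-iGDGT column and an
    archaeol column.  A ``Ring index`` column, if present, is kept as
    ``ri_printed`` but quarantined from all computation.  Species
    abundances must be non-negative and sum to within [98, 102] per row
    (published rows carry rounding error).
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty lipid table") from exc
    if df.empty:
        raise FormatError(f"{path}: lipid table has no data rows")

    colmap: dict[str, str] = {}
    ri_col = total_col = arch_col = id_col = None
    for col in df.columns:
        low = str(col).strip().lower()
        code = _canonical_header(col)
        if code is not None:
            colmap[code] = col
        elif low in ("spring_id", "id", "sample", "spring"):
            id_col = col
        elif "ring" in low and "index" in low:
            ri_col = col
        elif low == "total_igdgt" or ("igdgt" in low and "ng" in low):
            total_col = col
        elif "archaeol" in low:
            arch_col = col
    if id_col is None:
        id_col = df.columns[0]

    missing = [c for c in SPECIES_CODES if c not in colmap]
    if missing:
        raise FormatError(f"{path}: missing species column(s) {missing}")
    for label, col in (("total iGDGT", total_col), ("archaeol", arch_col)):
        if col is None:
            raise FormatError(f"{path}: missing {label} column")

    profiles: list[LipidProfile] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row[id_col])
        if sid in seen:
            raise ValidationError(f"{path}: duplicate spring id {sid!r}")
        seen.add(sid)
        rel: dict[str, float] = {}
        for code in SPECIES_CODES:
            raw = row[colmap[code]]
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: row {idx} ({sid}), column {colmap[code]!r}: "
                    f"unparseable value {raw!r}"
                ) from exc
            if value < 0:
                raise ValidationError(
                    f"{path}: row {idx} ({sid}), column {colmap[code]!r}: "
                    f"negative abundance {value}"
                )
            rel[code] = value
        total = sum(rel.values())
        if not 98.0 <= total <= 102.0:
            raise ValidationError(
                f"{path}: row {idx} ({sid}): abundances sum to {total:.2f}, "
                "expected within [98, 102]"
            )
        profiles.append(
            LipidProfile(
                spring_id=sid,
                fraction=fraction,
                rel_abundance=rel,
                total_igdgt=float(row[total_col]),
                archaeol=float(row[arch_col]),
                ri_printed=float(row[ri_col]) if ri_col is not None else None,
            )
        )
    return profiles


def normalize(profile: LipidProfile) -> LipidProfile:
    """Rescale relative abundances to sum to exactly 100.

    All other fields are unchanged.  Raises :class:`ValidationError` on an
    all-zero profile.
    """
    total = profile.abundance_sum
    if total <= 0:
        raise ValidationError(
            f"{profile.spring_id}: cannot normalize an all-zero profile"
        )
    scaled = {c: v * 100.0 / total for c, v in profile.rel_abundance.items()}
    return replace(profile, rel_abundance=scaled)


def ring_index(
    profile: LipidProfile, variant: RIVariant = "cren_weight5"
) -> float:
    """Weighted mean number of rings per lipid molecule (the Ring Index).

    The numerator sums ring-weight x percent over the species the variant
    includes; the denominator is the constant 100 of the published formula,
    not the row sum, so an un-normalized row reproduces the published
    per-sample values exactly.
    """
    weights = ring_weights(variant)
    return (
        sum(weights[c] * v for c, v in profile.rel_abundance.items()) / 100.0
    )


def absolute_abundances(profile: LipidProfile) -> dict[str, float]:
    """Per-species concentration, ng per g dry-weight sediment.

    Each species' value is its relative abundance (as a fraction of 100)
    times the fraction's total iGDGT concentration.
    """
    if not math.isfinite(profile.total_igdgt):
        raise ValidationError(
            f"{profile.spring_id}: total_igdgt must be finite"
        )
    return {
        c: profile.rel_abundance.get(c, 0.0) / 100.0 * profile.total_igdgt
        for c in SPECIES_CODES
    }


def polar_to_core_ratio(core: LipidProfile, polar: LipidProfile) -> float:
    """Ratio of total polar to total core iGDGT concentration."""
    if core.spring_id != polar.spring_id:
        raise ValidationError(
            f"spring id mismatch: {core.spring_id!r} vs {polar.spring_id!r}"
        )
    if core.total_igdgt <= 0:
        raise UndefinedRatioError(
            f"{core.spring_id}: core total iGDGT is zero; ratio undefined"
        )
    return polar.total_igdgt / core.total_igdgt
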