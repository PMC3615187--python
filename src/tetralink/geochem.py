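"""Spring geochemistry: parsing, below-detection substitution, distances.

Each spring carries pH, temperature and nine aqueous analytes.  Cells
recorded as ``BD`` (below the instrument detection limit) are flagged on
ingest and must be substituted with a minimal detectable value before any
distance computation.  The default (``auto``) substitution uses, per
analyte, the smallest positive value observed anywhere in the table — a
deterministic stand-in for instrument limits that the source tables do
not state.

Environmental distance is plain Euclidean distance over a chosen variable
subset; for a single variable this is ``|Δvalue|``.  Because the Mantel
statistic is invariant under positive affine rescaling, single-variable
models need no standardization; z-scoring is exposed for multi-variable
distances where units would otherwise dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "VARIABLES",
    "ANALYTES",
    "SpringGeochem",
    "parse_geochem",
    "substitute_bd",
    "env_distance",
    "geochem_frame",
]

#: The eleven environmental variables, in published column order, with units:
#: pH (pH units), temp (deg C), conductivity (umhos/cm), salinity (%),
#: sulfide and fe2 (uM), no2 and no3 (nM), nh4 (uM), cl and so4 (mM).
VARIABLES: tuple[str, ...] = (
    "ph",
    "temp",
    "conductivity",
    "salinity",
    "sulfide",
    "fe2",
    "no2",
    "no3",
    "nh4",
    "cl",
    "so4",
)

#: Concentration variables in which a BD token may appear.
ANALYTES: tuple[str, ...] = VARIABLES[2:]

_BD_TOKENS = {"bd", "b.d.", "nd", "<dl"}


@dataclass(frozen=True)
class SpringGeochem:
    """One spring's aqueous chemistry.

    ``values`` maps variable name to a float, or ``None`` for analytes
    flagged below detection (listed in ``bd_flags``).  An analyte is either
    a number or BD, never both.
    """

    spring_id: str
    values: dict[str, float | None]
    bd_flags: frozenset[str] = field(default_factory=frozenset)
    #: Analytes whose BD cell has been substituted (provenance only).
    bd_substituted: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for flagged in self.bd_flags:
            if flagged not in ANALYTES:
                raise ValidationError(
                    f"{self.spring_id}: BD flag on non-analyte {flagged!r}"
                )
            if self.values.get(flagged) is not None:
                raise ValidationError(
                    f"{self.spring_id}: {flagged} is both numeric and BD"
                )
        ph = self.values.get("ph")
        if ph is not None and not 0.0 <= ph <= 14.0:
            raise ValidationError(f"{self.spring_id}: pH {ph} outside [0, 14]")
        temp = self.values.get("temp")
        if temp is not None and not 0.0 <= temp <= 110.0:
            raise ValidationError(
                f"{self.spring_id}: temperature {temp} outside [0, 110]"
            )
        for var in ANALYTES:
            v = self.values.get(var)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{self.spring_id}: {var} must be finite and >= 0, got {v}"
                )

    def __getitem__(self, var: str) -> float | None:
        return self.values[var]


def parse_geochem(path: str | PathLike) -> list[SpringGeochem]:
    """Parse a TSV geochemistry table into one record per spring.

    The header must name the eleven variables (GPS/location columns are
    ignored); a ``BD`` token is accepted in any concentration cell and is
    recorded as a flag with the value left unset.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty geochemistry table") from exc
    if df.empty:
        raise FormatError(f"{path}: geochemistry table has no data rows")

    cols = {str(c).strip().lower(): c for c in df.columns}
    missing = [v for v in VARIABLES if v not in cols]
    if missing:
        raise FormatError(f"{path}: missing variable column(s) {missing}")
    id_col = cols.get("spring_id", df.columns[0])

    records: list[SpringGeochem] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row[id_col]).strip()
        if sid in seen:
            raise ValidationError(f"{path}: duplicate spring id {sid!r}")
        seen.add(sid)
        values: dict[str, float | None] = {}
        flags: set[str] = set()
        for var in VARIABLES:
            raw = str(row[cols[var]]).strip()
            if raw.lower() in _BD_TOKENS:
                if var not in ANALYTES:
                    raise FormatError(
                        f"{path}: row {idx} ({sid}), column {var!r}: "
                        "BD token not allowed in pH/temperature"
                    )
                values[var] = None
                flags.add(var)
                continue
            try:
                values[var] = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {idx} ({sid}), column {var!r}: "
                    f"unparseable cell {raw!r}"
                ) from exc
        records.append(
            SpringGeochem(spring_id=sid, values=values, bd_flags=frozenset(flags))
        )
    return records


def substitute_bd(
    records: Sequence[SpringGeochem],
    limits: Mapping[str, float] | str = "auto",
) -> list[SpringGeochem]:
    """Replace every below-detection cell with a minimal detectable value.

    With ``limits="auto"`` each analyte's limit is the smallest positive
    value observed for that analyte across the table.  With an explicit
    mapping, a flagged analyte without a limit raises
    :class:`ConfigurationError`.  Records without BD flags pass through
    unchanged; BD flags are retained for provenance.
    """
    flagged = sorted({a for r in records for a in r.bd_flags})
    if not flagged:
        return list(records)

    if isinstance(limits, str):
        if limits != "auto":
            raise ConfigurationError(f"unknown limits mode {limits!r}")
        resolved: dict[str, float] = {}
        for analyte in flagged:
            observed = [
                v
                for r in records
                if (v := r.values.get(analyte)) is not None and v > 0
            ]
            if not observed:
                raise ConfigurationError(
                    f"no positive observation of {analyte!r} from which to "
                    "derive an automatic detection limit"
                )
            resolved[analyte] = min(observed)
    else:
        missing = [a for a in flagged if a not in limits]
        if missing:
            raise ConfigurationError(
                f"detection limit missing for flagged analyte(s) {missing}"
            )
        resolved = {a: float(limits[a]) for a in flagged}
        for analyte, lim in resolved.items():
            if lim <= 0:
                raise ConfigurationError(
                    f"detection limit for {analyte!r} must be > 0, got {lim}"
                )

    out: list[SpringGeochem] = []
    for rec in records:
        if not rec.bd_flags:
            out.append(rec)
            continue
        values = dict(rec.values)
        for analyte in rec.bd_flags:
            values[analyte] = resolved[analyte]
        out.append(
            replace(
                rec,
                values=values,
                bd_flags=frozenset(),
                bd_substituted=rec.bd_substituted | rec.bd_flags,
            )
        )
    return out


def geochem_frame(records: Sequence[SpringGeochem]) -> pd.DataFrame:
    """Records as a spring x variable DataFrame (BD cells become NaN)."""
    return pd.DataFrame(
        [[r.values.get(v) for v in VARIABLES] for r in records],
        index=pd.Index([r.spring_id for r in records], name="spring_id"),
        columns=list(VARIABLES),
        dtype=float,
    )


def env_distance(
    records: Sequence[SpringGeochem],
    variables: Iterable[str],
    standardize: bool = False,
) -> DistanceMatrix:
    """Pairwise Euclidean distance over the chosen environmental variables.

    For a single variable this is ``|Δvalue|``.  With ``standardize`` each
    variable is z-scored (sample SD) first.  BD cells must already have
    been substituted.
    """
    variables = list(variables)
    unknown = [v for v in variables if v not in VARIABLES]
    if unknown:
        raise ConfigurationError(f"unknown environmental variable(s) {unknown}")
    if not variables:
        raise ConfigurationError("at least one variable is required")
    if len(records) < 2:
        raise ValidationError("need at least two springs for a distance matrix")

    frame = geochem_frame(records)[variables]
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValidationError(
            f"unsubstituted below-detection values in {bad}; "
            "run substitute_bd first"
        )
    X = frame.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            flat = [variables[i] for i in np.flatnonzero(sd == 0)]
            raise ValidationError(f"variable(s) {flat} are constant; cannot z-score")
        X = (X - X.mean(axis=0)) / sd
    return DistanceMatrix(squareform(pdist(X)), ids=list(frame.index))
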