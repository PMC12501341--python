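"""Declarative point-weight tables for the five dementia risk indices.

Each index (ANU-ADRI, CAIDE, CogDrisk, LIBRA, LIBRA2) is an additive
point score over categorical risk/protective factor levels.  The entire
computational content of an index lives in a YAML data file shipped with
the package: one entry per (factor, level, optional sex/age condition)
carrying the published points and the verbatim source cell it was
transcribed from.  Weights live in data files rather than code because a
few source cells are typographically ambiguous and must be correctable
(per-cell overrides) without touching the scorer.

Points are stored internally as integer centi-points (points * 100, all
published weights have at most two decimals) so sums are exact and
order-independent.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from ._util import FACTOR_LEVELS

INDICES = ["ANU-ADRI", "CAIDE", "CogDrisk", "LIBRA", "LIBRA2"]

_INDEX_FILES = {
    "ANU-ADRI": "anu_adri.yaml",
    "CAIDE": "caide.yaml",
    "CogDrisk": "cogdrisk.yaml",
    "LIBRA": "libra.yaml",
    "LIBRA2": "libra2.yaml",
}

#: factors whose entries may legitimately be demographic-flagged
_DEMOGRAPHIC_FACTORS = {"sex", "age", "education_level"}


class WeightTableError(ValueError):
    """Schema or coverage defect in a weight-table file."""


@dataclasses.dataclass(frozen=True)
class WeightEntry:
    index: str
    factor: str
    level: str
    centi_points: int  # points * 100, exact
    sex: str | None = None
    age_min: float | None = None  # inclusive
    age_max: float | None = None  # exclusive
    demographic: bool = False
    borrowed: bool = False
    source_quote: str = ""

    @property
    def points(self) -> float:
        return self.centi_points / 100.0

    def matches(self, level: str, sex: str | None, age: float | None) -> bool:
        if self.factor == "age":
            if age is None:
                return False
            if self.sex is not None and self.sex != sex:
                return False
            lo_ok = self.age_min is None or age >= self.age_min
            hi_ok = self.age_max is None or age < self.age_max
            return lo_ok and hi_ok
        if self.level != level:
            return False
        if self.sex is not None and self.sex != sex:
            return False
        return True


@dataclasses.dataclass
class WeightTable:
    index: str
    entries: list[WeightEntry]
    version: int = 1
    source: str = ""

    def covered_factors(self, include_demographics: bool = True) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if not include_demographics and e.demographic:
                continue
            if e.factor not in seen:
                seen.append(e.factor)
        return seen

    def factor_levels(self, factor: str) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.factor == factor and e.level not in out:
                out.append(e.level)
        return out

    def lookup(
        self,
        factor: str,
        level: str | None = None,
        sex: str | None = None,
        age: float | None = None,
    ) -> WeightEntry:
        hits = [
            e
            for e in self.entries
            if e.factor == factor and e.matches(level, sex, age)
        ]
        if len(hits) != 1:
            raise WeightTableError(
                f"{self.index}: expected exactly one entry for "
                f"(factor={factor!r}, level={level!r}, sex={sex!r}, age={age!r}); "
                f"found {len(hits)}"
            )
        return hits[0]


def _to_centi(points, where: str) -> int:
    c = round(float(points) * 100)
    if abs(float(points) * 100 - c) > 1e-9:
        raise WeightTableError(
            f"{where}: points {points} have more than two decimals"
        )
    return int(c)


def _validate(table: WeightTable) -> None:
    # duplicate / gapped coverage checks, naming the offending cell
    for factor in table.covered_factors():
        entries = [e for e in table.entries if e.factor == factor]
        if factor == "age":
            sexes = sorted({e.sex for e in entries}, key=str)
            for sex in sexes:
                bands = sorted(
                    (e for e in entries if e.sex == sex),
                    key=lambda e: (-1e9 if e.age_min is None else e.age_min),
                )
                prev_hi: float | None = -1e9
                for e in bands:
                    lo = -1e9 if e.age_min is None else e.age_min
                    if lo != prev_hi:
                        raise WeightTableError(
                            f"{table.index}: age bands for sex={sex!r} have a "
                            f"gap or overlap at cell (age, {e.level!r})"
                        )
                    prev_hi = 1e9 if e.age_max is None else e.age_max
                if prev_hi != 1e9:
                    raise WeightTableError(
                        f"{table.index}: age bands for sex={sex!r} do not "
                        "reach an open upper bound"
                    )
            continue
        known = FACTOR_LEVELS.get(factor)
        if known is None:
            raise WeightTableError(
                f"{table.index}: unknown factor {factor!r}"
            )
        seen: dict[tuple[str, str | None], int] = {}
        for e in entries:
            key = (e.level, e.sex)
            if key in seen:
                raise WeightTableError(
                    f"{table.index}: duplicate cell (factor={factor!r}, "
                    f"level={e.level!r}, sex={e.sex!r})"
                )
            seen[key] = 1
            if e.level not in known:
                raise WeightTableError(
                    f"{table.index}: unknown level in cell "
                    f"(factor={factor!r}, level={e.level!r})"
                )
        levels = {lvl for (lvl, _s) in seen}
        required = set(known)
        if factor == "smoking" and "former" not in levels:
            # indices other than ANU-ADRI group ex-smokers with never-smokers
            required = required - {"former"}
        if levels != required:
            missing = sorted(required - levels)
            raise WeightTableError(
                f"{table.index}: gapped level coverage for factor "
                f"{factor!r}; missing cells for levels {missing}"
            )
        # sex-conditioned entries must cover both sexes for their level
        for lvl, sx in seen:
            if sx is not None:
                other = "male" if sx == "female" else "female"
                if (lvl, other) not in seen:
                    raise WeightTableError(
                        f"{table.index}: cell (factor={factor!r}, "
                        f"level={lvl!r}) covers sex={sx!r} only"
                    )
    for e in table.entries:
        if e.demographic and e.factor not in _DEMOGRAPHIC_FACTORS:
            raise WeightTableError(
                f"{table.index}: demographic flag on non-demographic cell "
                f"(factor={e.factor!r}, level={e.level!r})"
            )


def _parse(raw: dict, overrides: dict | None = None) -> WeightTable:
    index = raw["index"]
    overrides = overrides or {}
    entries = []
    for item in raw["entries"]:
        factor = item["factor"]
        level = str(item["level"])
        points = item["points"]
        okey = (factor, level, item.get("sex"))
        if okey in overrides:
            points = overrides[okey]
        entries.append(
            WeightEntry(
                index=index,
                factor=factor,
                level=level,
                centi_points=_to_centi(
                    points, f"{index} (factor={factor!r}, level={level!r})"
                ),
                sex=item.get("sex"),
                age_min=item.get("age_min"),
                age_max=item.get("age_max"),
                demographic=bool(item.get("demographic", False)),
                borrowed=bool(item.get("borrowed", False)),
                source_quote=str(item.get("source_quote", "")),
            )
        )
    table = WeightTable(
        index=index,
        entries=entries,
        version=int(raw.get("version", 1)),
        source=str(raw.get("source", "")),
    )
    _validate(table)
    return table


def load_weight_table(source, overrides: dict | None = None) -> WeightTable:
    """Load and validate one index weight table.

    Parameters
    ----------
    source
        An index name (one of :data:`INDICES`) to load the packaged
        default, or a path to a YAML file with the same schema.
    overrides
        Optional per-cell overrides ``{(factor, level, sex): points}``
        applied before validation, for correcting ambiguous source cells.
    """
    if isinstance(source, (str, Path)) and str(source) in _INDEX_FILES:
        ref = resources.files("demrisk") / "data" / "weights" / _INDEX_FILES[str(source)]
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    return _parse(raw, overrides)


def load_all_weight_tables(directory=None) -> dict[str, WeightTable]:
    """Load the five packaged tables (or same-named files from a directory)."""
    out = {}
    for idx in INDICES:
        if directory is None:
            out[idx] = load_weight_table(idx)
        else:
            out[idx] = load_weight_table(Path(directory) / _INDEX_FILES[idx])
    return out
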