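"""ICD-9 billing events to per-phenotype case/control/excluded status.

Phenotypes are phecodes: curated groupings of ICD-9 billing codes, each with
an *exclusion range* of related phecodes whose carriers may not serve as
controls.  A person is a CASE for a phenotype when codes mapping to its
phecode occur on at least two distinct calendar days; a person who is not a
case is EXCLUDED from the control group when any of their codes maps into the
phenotype's exclusion interval (a single mention of the phenotype itself
always does, since every phecode lies inside its own interval) or when the
phenotype carries a sex restriction conflicting with the person's recorded
sex; everyone else is a CONTROL.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_ICD9_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})(?:\.\d{1,2})?$")

__all__ = [
    "Status",
    "PhecodeEntry",
    "PhecodeMap",
    "PhenotypeMatrix",
    "normalize_icd9",
    "assign_status",
    "build_phenotype_matrix",
    "make_composite",
    "load_fixture_map",
]


class Status(IntEnum):
    """Case/control/excluded state of one person for one phenotype."""

    EXCLUDED = -1
    CONTROL = 0
    CASE = 1


class MalformedIcd9Error(ValueError):
    pass


class UnknownPhecodeError(KeyError):
    pass


def normalize_icd9(raw: str) -> str:
    """Normalize a raw ICD-9 string to canonical dotted form.

    Uppercases, strips whitespace, and inserts the decimal point after the
    third character (fourth for E-codes) when absent.  Idempotent.

    >>> normalize_icd9("25000")
    '250.00'
    >>> normalize_icd9(" v70 ")
    'V70'
    """
    if raw is None:
        raise MalformedIcd9Error("empty ICD-9 code")
    code = str(raw).strip().upper()
    if not code:
        raise MalformedIcd9Error("empty ICD-9 code")
    if "." not in code:
        head = 4 if code.startswith("E") else 3
        if len(code) > head:
            code = code[:head] + "." + code[head:]
    if not _ICD9_RE.match(code):
        raise MalformedIcd9Error(f"malformed ICD-9 code: {raw!r}")
    return code


def _phecode_value(phecode: str) -> float:
    try:
        value = float(phecode)
    except ValueError as exc:
        raise ValueError(f"phecode is not decimal-valued: {phecode!r}") from exc
    return value


@dataclass(frozen=True)
class PhecodeEntry:
    """One ICD-9 → phecode mapping row."""

    icd9: str
    phecode: str
    description: str
    category: str
    exclusion_lo: float
    exclusion_hi: float
    sex_restriction: str = "none"  # none | female | male

    def __post_init__(self) -> None:
        value = _phecode_value(self.phecode)
        if value <= 0:
            raise ValueError(f"phecode must be positive: {self.phecode}")
        if not (self.exclusion_lo <= value <= self.exclusion_hi):
            raise ValueError(
                f"phecode {self.phecode} outside its exclusion interval "
                f"[{self.exclusion_lo}, {self.exclusion_hi}]"
            )
        if self.sex_restriction not in ("none", "female", "male"):
            raise ValueError(f"bad sex restriction: {self.sex_restriction}")


@dataclass(frozen=True)
class PhecodeInfo:
    phecode: str
    description: str
    category: str
    exclusion_lo: float
    exclusion_hi: float
    sex_restriction: str


class PhecodeMap:
    """ICD-9 → phenotype dictionary, indexed both by icd9 and by phecode.

    Lookup of an unmapped icd9 returns an empty set, never an error.  Every
    distinct phecode has exactly one exclusion interval, category and sex
    restriction (validated on construction).
    """

    def __init__(self, entries):
        self._entries = [e if isinstance(e, PhecodeEntry) else PhecodeEntry(**e) for e in entries]
        self._by_icd9: dict[str, set[str]] = {}
        self._info: dict[str, PhecodeInfo] = {}
        self._codes_for: dict[str, list[str]] = {}
        for e in self._entries:
            icd9 = normalize_icd9(e.icd9)
            info = PhecodeInfo(
                e.phecode, e.description, e.category,
                float(e.exclusion_lo), float(e.exclusion_hi), e.sex_restriction,
            )
            prior = self._info.get(e.phecode)
            if prior is not None and prior != info:
                raise ValueError(
                    f"inconsistent metadata for phecode {e.phecode}: {prior} vs {info}"
                )
            self._info[e.phecode] = info
            self._by_icd9.setdefault(icd9, set()).add(e.phecode)
            self._codes_for.setdefault(e.phecode, [])
            if icd9 not in self._codes_for[e.phecode]:
                self._codes_for[e.phecode].append(icd9)

    @property
    def entries(self) -> list[PhecodeEntry]:
        return list(self._entries)

    @property
    def phecodes(self) -> list[str]:
        return sorted(self._info, key=_phecode_value)

    def __contains__(self, phecode: str) -> bool:
        return phecode in self._info

    def __len__(self) -> int:
        return len(self._info)

    def phecodes_for(self, icd9: str) -> frozenset[str]:
        """Phecodes an ICD-9 code maps to (empty for unmapped codes)."""
        try:
            code = normalize_icd9(icd9)
        except MalformedIcd9Error:
            return frozenset()
        return frozenset(self._by_icd9.get(code, ()))

    def codes_for(self, phecode: str) -> list[str]:
        self.info(phecode)
        return list(self._codes_for[phecode])

    def info(self, phecode: str) -> PhecodeInfo:
        try:
            return self._info[phecode]
        except KeyError:
            raise UnknownPhecodeError(f"phecode not in map: {phecode}") from None

    # -- round trips ---------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhecodeMap":
        entries = [
            PhecodeEntry(
                icd9=str(r.icd9),
                phecode=str(r.phecode),
                description=str(r.description),
                category=str(r.category),
                exclusion_lo=float(r.exclusion_lo),
                exclusion_hi=float(r.exclusion_hi),
                sex_restriction=str(getattr(r, "sex", "none") or "none"),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        df = pd.read_csv(path, dtype=str)
        df["exclusion_lo"] = df["exclusion_lo"].astype(float)
        df["exclusion_hi"] = df["exclusion_hi"].astype(float)
        if "sex" not in df.columns:
            df["sex"] = "none"
        df["sex"] = df["sex"].fillna("none")
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "icd9": e.icd9,
                    "phecode": e.phecode,
                    "description": e.description,
                    "category": e.category,
                    "exclusion_lo": e.exclusion_lo,
                    "exclusion_hi": e.exclusion_hi,
                    "sex": e.sex_restriction,
                }
                for e in self._entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_fixture_map() -> PhecodeMap:
    """Bundled miniature phecode map covering the headline phenotypes."""
    with resources.as_file(
        resources.files("phewaskit.data") / "phecode_map_fixture.csv"
    ) as path:
        return PhecodeMap.from_csv(path)


def _sex_conflict(sex: str, restriction: str) -> bool:
    if restriction == "none":
        return False
    sex = (sex or "").strip().upper()
    if restriction == "female":
        return sex == "M"
    return sex == "F"


def assign_status(events: pd.DataFrame, phecode: str, pmap: PhecodeMap,
                  sex: str = "") -> Status:
    """Status of one person for one phenotype from their billing events.

    ``events`` holds the person's rows with columns ``date`` and ``icd9``.
    CASE requires codes mapping to ``phecode`` on >= 2 distinct days;
    otherwise any code in the exclusion interval (including a single mention
    of the phenotype itself) or a conflicting sex restriction EXCLUDEs the
    person from controls.
    """
    info = pmap.info(phecode)
    target_days: set = set()
    in_exclusion = False
    if len(events):
        dates = pd.to_datetime(events["date"]).dt.date
        for date, code in zip(dates, events["icd9"]):
            mapped = pmap.phecodes_for(code)
            if phecode in mapped:
                target_days.add(date)
            for m in mapped:
                if info.exclusion_lo <= _phecode_value(m) <= info.exclusion_hi:
                    in_exclusion = True
    if len(target_days) >= 2:
        return Status.CASE
    if in_exclusion or _sex_conflict(sex, info.sex_restriction):
        return Status.EXCLUDED
    return Status.CONTROL


@dataclass
class PhenotypeMatrix:
    """Individuals x phenotypes grid of :class:`Status` codes (int8)."""

    status: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.status.index)

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def case_counts(self) -> pd.Series:
        return (self.status == Status.CASE).sum(axis=0)

    @property
    def control_counts(self) -> pd.Series:
        return (self.status == Status.CONTROL).sum(axis=0)

    def case_indicator(self) -> pd.DataFrame:
        """CASE=1, CONTROL=0, EXCLUDED=NaN — pairwise-complete correlations."""
        ind = self.status.astype(float)
        return ind.where(self.status != Status.EXCLUDED)


def build_phenotype_matrix(events: pd.DataFrame, demographics: pd.DataFrame,
                           pmap: PhecodeMap, min_cases: int = 20) -> PhenotypeMatrix:
    """Construct the full case/control/excluded matrix for a cohort.

    ``events``: columns ``person_id, date, icd9``; ``demographics`` supplies
    the individual ordering and (optionally) ``sex``.  Phenotypes with fewer
    than ``min_cases`` cases are dropped and reported in the log.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    persons = [str(p) for p in demographics["person_id"]]
    sex = (
        demographics.set_index(demographics["person_id"].astype(str))["sex"]
        .astype(str)
        .str.upper()
        if "sex" in demographics.columns
        else pd.Series("", index=persons)
    )
    phecodes = pmap.phecodes
    values = np.array([_phecode_value(p) for p in phecodes])

    if len(events):
        ev = events.copy()
        ev["person_id"] = ev["person_id"].astype(str)
        ev["icd9"] = ev["icd9"].map(normalize_icd9)
        ev["date"] = pd.to_datetime(ev["date"]).dt.normalize()
        map_df = (
            pmap.to_frame()[["icd9", "phecode"]]
            .assign(icd9=lambda d: d["icd9"].map(normalize_icd9))
            .drop_duplicates()
        )
        mapped = ev.merge(map_df, on="icd9")
        mapped = mapped.drop_duplicates(["person_id", "phecode", "date"])
        day_counts = (
            mapped.groupby(["person_id", "phecode"]).size().unstack(fill_value=0)
        )
    else:
        day_counts = pd.DataFrame(index=pd.Index([], dtype=object))
    day_counts = day_counts.reindex(index=persons, columns=phecodes, fill_value=0)
    presence = day_counts.to_numpy() > 0
    counts = day_counts.to_numpy()

    status = np.zeros((len(persons), len(phecodes)), dtype=np.int8)
    sex_arr = sex.reindex(persons).fillna("").to_numpy()
    for j, p in enumerate(phecodes):
        info = pmap.info(p)
        in_excl = presence[:, (values >= info.exclusion_lo) & (values <= info.exclusion_hi)].any(axis=1)
        if info.sex_restriction == "female":
            in_excl = in_excl | (sex_arr == "M")
        elif info.sex_restriction == "male":
            in_excl = in_excl | (sex_arr == "F")
        col = np.where(in_excl, np.int8(Status.EXCLUDED), np.int8(Status.CONTROL))
        col = np.where(counts[:, j] >= 2, np.int8(Status.CASE), col)
        status[:, j] = col

    frame = pd.DataFrame(status, index=pd.Index(persons, name="person_id"),
                         columns=phecodes)
    matrix = PhenotypeMatrix(frame)
    n_cases = matrix.case_counts
    keep = n_cases[n_cases >= min_cases].index
    dropped = [p for p in phecodes if p not in set(keep)]
    for p in dropped:
        log.info("phenotype %s dropped: %d cases < min_cases=%d", p, n_cases[p], min_cases)
    log.info("phenotype matrix: %d individuals, %d/%d phenotypes retained",
             len(persons), len(keep), len(phecodes))
    return PhenotypeMatrix(frame.loc[:, list(keep)])


def make_composite(phecodes: list[str], matrix: PhenotypeMatrix) -> pd.Series:
    """Composite phenotype: CASE for any member, CONTROL for all members,
    otherwise EXCLUDED."""
    if not phecodes:
        raise ValueError("composite needs at least one phecode")
    missing = [p for p in phecodes if p not in matrix.status.columns]
    if missing:
        raise UnknownPhecodeError(f"phecodes absent from matrix: {missing}")
    sub = matrix.status.loc[:, phecodes].to_numpy()
    out = np.where(
        (sub == Status.CASE).any(axis=1),
        np.int8(Status.CASE),
        np.where((sub == Status.CONTROL).all(axis=1),
                 np.int8(Status.CONTROL), np.int8(Status.EXCLUDED)),
    )
    return pd.Series(out, index=matrix.status.index, name="+".join(phecodes))
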