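"""Hospital-stay records: parsing, study-population selection, diagnosis matrices.

The input is one row per hospital stay (patient pseudonym, entry/exit dates,
one primary and any number of secondary 3-character diagnosis codes,
region, sex, birth year, in-hospital death flag).  The study timeline is
split into four consecutive windows — no-admission, feature, target and
follow-up — and a patient enters the study population when they have no
stay in the no-admission window and at least one stay in each of the
feature and target windows.

Diagnosis codes are role-suffixed: ``E66p`` means code E66 used as a
primary diagnosis, ``E66s`` as a secondary one.  The feature-period
indicator matrix X0 records role-suffixed codes received during the
feature window; the target matrix Y accumulates codes through the end of
the target window (monotonicity: once diagnosed, always positive), so each
patient's X0 support is a subset of their Y support.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "StayRecord",
    "StudyPeriods",
    "CsvDialect",
    "DiagnosisMatrix",
    "load_stays",
    "write_stays",
    "select_study_population",
    "build_matrices",
    "patient_demographics",
    "code_and_role",
    "ICD3_PATTERN",
]

#: Any letter followed by two digits; synthetic codes need not be real ICD-10.
ICD3_PATTERN = re.compile(r"^[A-Za-z][0-9]{2}$")


@dataclass(frozen=True)
class StayRecord:
    """One hospital stay."""

    patient_id: str
    entry_date: date
    exit_date: date
    primary_dx: str
    secondary_dx: tuple[str, ...]
    region: str
    sex: str
    birth_year: int
    death: bool = False

    def validate(self) -> None:
        if self.entry_date > self.exit_date:
            raise ValueError(
                f"stay for {self.patient_id}: exit {self.exit_date} before "
                f"entry {self.entry_date}"
            )
        if not ICD3_PATTERN.match(self.primary_dx):
            raise ValueError(f"malformed primary diagnosis {self.primary_dx!r}")
        for code in self.secondary_dx:
            if not ICD3_PATTERN.match(code):
                raise ValueError(f"malformed secondary diagnosis {code!r}")


@dataclass(frozen=True)
class StudyPeriods:
    """Timeline anchors t0 < t1 < t2 < t3 < t4.

    [t0,t1) no-admission, [t1,t2) feature, [t2,t3) target, [t3,t4) follow-up.
    """

    t0: date
    t1: date
    t2: date
    t3: date
    t4: date

    def __post_init__(self) -> None:
        ts = (self.t0, self.t1, self.t2, self.t3, self.t4)
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ValueError(f"period anchors must be strictly increasing: {ts}")

    def period_of(self, stay: StayRecord, attribution: str = "exit") -> str | None:
        """Window containing the stay under the chosen date-attribution rule.

        A stay spanning a boundary counts for exactly one window: the one
        containing its exit date (default; the source data are keyed on exit
        dates) or its entry date.
        """
        if attribution == "exit":
            d = stay.exit_date
        elif attribution == "entry":
            d = stay.entry_date
        else:
            raise ValueError(f"unknown attribution rule {attribution!r}")
        if self.t0 <= d < self.t1:
            return "no_admission"
        if self.t1 <= d < self.t2:
            return "feature"
        if self.t2 <= d < self.t3:
            return "target"
        if self.t3 <= d < self.t4:
            return "followup"
        return None


def default_periods() -> StudyPeriods:
    """The 18-year reference timeline: 6y no-admission, 3y feature, 3y target, 6y follow-up."""
    return StudyPeriods(
        t0=date(1997, 1, 1),
        t1=date(2003, 1, 1),
        t2=date(2006, 1, 1),
        t3=date(2009, 1, 1),
        t4=date(2015, 1, 1),
    )


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of the stay CSV (UTF-8, comma-separated, header required)."""

    columns: tuple[str, ...] = (
        "patient_id",
        "entry_date",
        "exit_date",
        "primary_dx",
        "secondary_dx",
        "region",
        "sex",
        "birth_year",
        "death",
    )
    secondary_sep: str = ";"


def _parse_date(text: str) -> date:
    return datetime.strptime(text.strip(), "%Y-%m-%d").date()


def load_stays(
    path, dialect: CsvDialect | None = None, strict: bool = False
) -> list[StayRecord]:
    """Read stay records from CSV.

    Malformed rows (bad dates, bad code patterns, exit before entry) are
    rejected with a logged diagnostic; with ``strict=True`` the first
    malformed row aborts the load with ``ValueError``.
    """
    dialect = dialect or CsvDialect()
    stays: list[StayRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = set(dialect.columns) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: header is missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                secondary = tuple(
                    c.strip()
                    for c in (row["secondary_dx"] or "").split(dialect.secondary_sep)
                    if c.strip()
                )
                stay = StayRecord(
                    patient_id=row["patient_id"].strip(),
                    entry_date=_parse_date(row["entry_date"]),
                    exit_date=_parse_date(row["exit_date"]),
                    primary_dx=row["primary_dx"].strip(),
                    secondary_dx=secondary,
                    region=row["region"].strip(),
                    sex=row["sex"].strip(),
                    birth_year=int(row["birth_year"]),
                    death=row["death"].strip() in ("1", "true", "True"),
                )
                stay.validate()
            except (ValueError, KeyError) as exc:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: rejected row (%s)", path, lineno, exc)
                continue
            stays.append(stay)
    return stays


def write_stays(path, stays: Iterable[StayRecord], dialect: CsvDialect | None = None) -> None:
    """Write stay records in the CSV dialect read by :func:`load_stays`."""
    dialect = dialect or CsvDialect()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(dialect.columns)
        for s in stays:
            writer.writerow(
                [
                    s.patient_id,
                    s.entry_date.isoformat(),
                    s.exit_date.isoformat(),
                    s.primary_dx,
                    dialect.secondary_sep.join(s.secondary_dx),
                    s.region,
                    s.sex,
                    s.birth_year,
                    int(s.death),
                ]
            )


def select_study_population(
    stays: Sequence[StayRecord],
    periods: StudyPeriods,
    attribution: str = "exit",
) -> set[str]:
    """Patients with no no-admission stay, ≥1 feature-period and ≥1 target-period stay."""
    seen_no_admission: set[str] = set()
    seen_feature: set[str] = set()
    seen_target: set[str] = set()
    for stay in stays:
        window = periods.period_of(stay, attribution=attribution)
        if window == "no_admission":
            seen_no_admission.add(stay.patient_id)
        elif window == "feature":
            seen_feature.add(stay.patient_id)
        elif window == "target":
            seen_target.add(stay.patient_id)
    return (seen_feature & seen_target) - seen_no_admission


@dataclass
class DiagnosisMatrix:
    """Binary patients × role-suffixed-codes indicator with sparse storage."""

    patients: list[str]
    codes: list[str]
    values: sp.csr_matrix

    _patient_index: dict[str, int] = field(init=False, repr=False)
    _code_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient ids")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("duplicate codes")
        self.values = sp.csr_matrix(self.values, dtype=np.int8)
        if self.values.shape != (len(self.patients), len(self.codes)):
            raise ValueError("matrix shape does not match labels")
        self._patient_index = {p: i for i, p in enumerate(self.patients)}
        self._code_index = {c: j for j, c in enumerate(self.codes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def code_index(self, code: str) -> int:
        try:
            return self._code_index[code]
        except KeyError:
            raise KeyError(f"code {code!r} not in matrix") from None

    def patient_index(self, patient_id: str) -> int:
        return self._patient_index[patient_id]

    def column(self, code: str) -> np.ndarray:
        """Dense boolean indicator of one code over all patients."""
        return np.asarray(
            self.values[:, self.code_index(code)].todense(), dtype=bool
        ).ravel()

    def to_dense_bool(self) -> np.ndarray:
        return self.values.toarray().astype(bool)

    def subset_patients(self, patient_ids: Sequence[str]) -> "DiagnosisMatrix":
        rows = [self._patient_index[p] for p in patient_ids]
        return DiagnosisMatrix(list(patient_ids), list(self.codes), self.values[rows])

    def to_coo_tsv(self, path) -> None:
        """Export nonzeros as (patient_id, code, 1) triples."""
        coo = self.values.tocoo()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("patient_id\tcode\tvalue\n")
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{self.patients[i]}\t{self.codes[j]}\t1\n")


def code_and_role(suffixed: str) -> tuple[str, str]:
    """Split 'E66s' into ('E66', 's')."""
    return suffixed[:-1], suffixed[-1]


def _period_code_sets(
    stays: Sequence[StayRecord],
    population: set[str],
    periods: StudyPeriods,
    windows: tuple[str, ...],
    attribution: str,
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {p: set() for p in population}
    for stay in stays:
        if stay.patient_id not in out:
            continue
        if periods.period_of(stay, attribution=attribution) not in windows:
            continue
        codes = out[stay.patient_id]
        codes.add(stay.primary_dx + "p")
        for c in stay.secondary_dx:
            codes.add(c + "s")
    return out


def _to_matrix(per_patient: dict[str, set[str]], patients: list[str], codes: list[str]) -> sp.csr_matrix:
    code_idx = {c: j for j, c in enumerate(codes)}
    rows: list[int] = []
    cols: list[int] = []
    for i, p in enumerate(patients):
        for c in per_patient[p]:
            rows.append(i)
            cols.append(code_idx[c])
    data = np.ones(len(rows), dtype=np.int8)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(patients), len(codes)), dtype=np.int8
    )


def build_matrices(
    stays: Sequence[StayRecord],
    population: set[str],
    periods: StudyPeriods,
    attribution: str = "exit",
) -> tuple[DiagnosisMatrix, DiagnosisMatrix]:
    """Feature-period indicator X0 and accumulated target indicator Y.

    X0(p,d)=1 iff patient p received role-suffixed code d during the feature
    window; Y(p,t)=1 iff p received t during the feature *or* target window
    (monotone accumulation), so X0's nonzeros are a per-patient subset of Y's.
    Both matrices share the same patient ordering and the code universe
    observed anywhere in [t1,t3).
    """
    if not population <= {s.patient_id for s in stays}:
        raise ValueError("population contains patients with no stay records")
    feature_sets = _period_code_sets(stays, population, periods, ("feature",), attribution)
    accumulated = _period_code_sets(
        stays, population, periods, ("feature", "target"), attribution
    )
    patients = sorted(population)
    codes = sorted(set().union(*accumulated.values()) if accumulated else set())
    X0 = DiagnosisMatrix(patients, codes, _to_matrix(feature_sets, patients, codes))
    Y = DiagnosisMatrix(patients, codes, _to_matrix(accumulated, patients, codes))
    return X0, Y


def patient_demographics(
    stays: Sequence[StayRecord], population: set[str] | None = None
) -> pd.DataFrame:
    """One row per patient: sex, region, birth_year (from their first stay)."""
    rows: dict[str, tuple[str, str, int]] = {}
    for stay in sorted(stays, key=lambda s: (s.patient_id, s.entry_date)):
        if population is not None and stay.patient_id not in population:
            continue
        rows.setdefault(stay.patient_id, (stay.sex, stay.region, stay.birth_year))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["sex", "region", "birth_year"]
    )
    df.index.name = "patient_id"
    return df.sort_index()
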