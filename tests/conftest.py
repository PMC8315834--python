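"""Shared fixtures and builders for the phenonet test suite."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from phenonet.claims import DiagnosisMatrix, StayRecord, StudyPeriods
from phenonet.features import Feature, OrderedFeatureSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def periods() -> StudyPeriods:
    return StudyPeriods(
        t0=date(1997, 1, 1),
        t1=date(2003, 1, 1),
        t2=date(2006, 1, 1),
        t3=date(2009, 1, 1),
        t4=date(2015, 1, 1),
    )


def make_stay(
    pid: str,
    entry: date,
    exit_: date,
    primary: str = "E66",
    secondary: tuple[str, ...] = (),
    **kw,
) -> StayRecord:
    defaults = dict(region="R1", sex="f", birth_year=1950, death=False)
    defaults.update(kw)
    return StayRecord(
        patient_id=pid,
        entry_date=entry,
        exit_date=exit_,
        primary_dx=primary,
        secondary_dx=tuple(secondary),
        **defaults,
    )


def make_matrix(rows: dict[str, set[str]], codes: list[str] | None = None) -> DiagnosisMatrix:
    """DiagnosisMatrix from {patient: {suffixed codes}}."""
    patients = sorted(rows)
    if codes is None:
        codes = sorted(set().union(*rows.values())) if rows else []
    dense = np.zeros((len(patients), len(codes)), dtype=np.int8)
    idx = {c: j for j, c in enumerate(codes)}
    for i, p in enumerate(patients):
        for c in rows[p]:
            dense[i, idx[c]] = 1
    return DiagnosisMatrix(patients, list(codes), sp.csr_matrix(dense))


def make_feature(codes, minidp: float = 0.0, support: int = 100) -> Feature:
    return Feature(codes=frozenset(codes), minidp=minidp, raw_support=support)


def make_feature_set(*features: Feature) -> OrderedFeatureSet:
    return OrderedFeatureSet(sorted(features, key=lambda f: f.order_key))
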