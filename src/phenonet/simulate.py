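"""Seeded synthetic hospital-claims generator with planted structure.

The generator emulates the structure of an administrative claims dataset:
every simulated patient passes the study-selection criteria by construction
(no stay in the no-admission window, at least one stay in each of the
feature and target windows), diagnoses are sparse binary indicators, and
three kinds of latent structure can be planted:

* **Phenotypes** — latent patient groups whose core codes have elevated
  feature-period probabilities and whose target codes have elevated
  target-period incidence.  Two phenotypes may share an index code (e.g.
  E66) while having disjoint comorbidity cores; this is the ground truth
  for phenotype-recovery experiments.
* **Three-way co-occurrence clusters** — triples of codes drawn from a
  mixture of an all-three component (mass ``m``), a compensating exactly-one
  component (mass ``3u``) and an iid component, with ``u`` solved so that
  every pair of the triple is *exactly* pairwise independent.  The triple
  co-occurs more than chance predicts while no pair does — genuinely
  beyond-pairwise structure that only an order-3 feature can capture.
* **Synergies** — a multiplicative boost on the odds of a target code,
  applied only to patients carrying the *full* feature-code set in the
  feature period.  The planted beyond-pairwise ground truth is therefore
  exactly 10·log10(boost) decibans.

Codes are Bernoulli-independent given the latent assignments, so pairwise
and triple-wise statistics are analytically controllable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np

from .claims import ICD3_PATTERN, StayRecord, StudyPeriods, default_periods

__all__ = [
    "PhenotypeSpec",
    "SynergySpec",
    "ThreeWayCluster",
    "SimConfig",
    "GroundTruth",
    "simulate",
    "two_phenotype_fixture",
    "synergy_fixture",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """A latent patient group with elevated code probabilities.

    ``core_codes`` maps feature-period codes to their within-group
    probability; ``target_codes`` maps target-period codes to their
    within-group incidence.  ``weight`` is the mixing weight of the group in
    the population.  ``index_code`` marks the shared index disease (must be
    a core code).
    """

    label: str
    weight: float
    core_codes: Mapping[str, float]
    target_codes: Mapping[str, float] = field(default_factory=dict)
    index_code: str | None = None
    mortality: float | None = None
    birth_year_range: tuple[int, int] | None = None

    def validate(self, background_rate: float) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"{self.label}: weight must be in (0,1]")
        if self.index_code is not None and self.index_code not in self.core_codes:
            raise ValueError(f"{self.label}: index code must be a core code")
        for code, p in {**self.core_codes, **self.target_codes}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.label}: probability of {code} out of range")
            if p <= background_rate:
                raise ValueError(
                    f"{self.label}: planted probability of {code} must exceed "
                    f"the background rate {background_rate}"
                )


@dataclass(frozen=True)
class SynergySpec:
    """Multiplicative odds boost on ``target_code`` when all ``feature_codes`` are present."""

    feature_codes: frozenset[str]
    target_code: str
    boost: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_codes", frozenset(self.feature_codes))
        if not 2 <= len(self.feature_codes) <= 3:
            raise ValueError("synergy needs 2 or 3 feature codes")
        if self.boost <= 0:
            raise ValueError("boost must be positive")


@dataclass(frozen=True)
class ThreeWayCluster:
    """Three codes with triple-wise but *zero pairwise* excess co-occurrence.

    Each patient's (A,B,C) indicator is drawn from the mixture:
    with probability ``m`` all three are present; with probability ``u``
    each, exactly one of the three is present; otherwise the three are iid
    Bernoulli(``q0``).  ``u`` is solved from m and q0 so that
    P(A∧B) = P(A)·P(B) exactly (and symmetrically for the other pairs),
    leaving P(A∧B∧C) > P(A)P(B)P(C).
    """

    codes: tuple[str, str, str]
    m: float
    q0: float

    def __post_init__(self) -> None:
        if len(set(self.codes)) != 3:
            raise ValueError("cluster needs three distinct codes")
        if not (0 <= self.m < 1 and 0 <= self.q0 < 1):
            raise ValueError("m and q0 must be in [0,1)")
        self.solve_u()  # validates feasibility

    def solve_u(self) -> float:
        """One-hot component mass making each pair exactly independent.

        With β = 1−m−3u:  P(A) = m+u+βq0 and P(A∧B) = m+βq0²; setting
        P(A∧B) = P(A)² gives a quadratic in u whose smaller positive root
        is used.
        """
        m, q = self.m, self.q0
        # (m+u+βq)² = m+βq² with β = 1−m−3u
        a = (1 - 3 * q) ** 2
        b = 2 * (m + (1 - m) * q) * (1 - 3 * q) + 3 * q * q
        c = (m + (1 - m) * q) ** 2 - m - (1 - m) * q * q
        if abs(a) < 1e-12:
            u = -c / b
        else:
            disc = b * b - 4 * a * c
            if disc < 0:
                raise ValueError("no pairwise-independent solution for (m, q0)")
            u = (-b + math.sqrt(disc)) / (2 * a)
        if u < -1e-12 or m + 3 * u > 1:
            raise ValueError("infeasible one-hot mass for (m, q0)")
        return max(u, 0.0)

    @property
    def marginal_rate(self) -> float:
        u = self.solve_u()
        beta = 1 - self.m - 3 * u
        return self.m + u + beta * self.q0

    @property
    def triple_rate(self) -> float:
        u = self.solve_u()
        beta = 1 - self.m - 3 * u
        return self.m + beta * self.q0**3

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n × 3 boolean presence matrix."""
        u = self.solve_u()
        beta = 1 - self.m - 3 * u
        comp = rng.choice(5, size=n, p=[self.m, u, u, u, beta])
        out = np.zeros((n, 3), dtype=bool)
        out[comp == 0] = True
        for k in range(3):
            out[comp == k + 1, k] = True
        iid = comp == 4
        out[iid] = rng.random((int(iid.sum()), 3)) < self.q0
        return out


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic claims study."""

    n_patients: int
    code_universe: tuple[str, ...]
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    background_rate: float = 0.05
    background_target_rate: float | None = None  # defaults to background_rate
    feature_rates: Mapping[str, float] = field(default_factory=dict)
    target_rates: Mapping[str, float] = field(default_factory=dict)
    synergies: tuple[SynergySpec, ...] = ()
    cooccurrence_clusters: tuple[ThreeWayCluster, ...] = ()
    periods: StudyPeriods = field(default_factory=default_periods)
    seed: int = 0
    regions: tuple[str, ...] = ("R1", "R2", "R3")
    sexes: tuple[str, ...] = ("f", "m")
    birth_year_range: tuple[int, int] = (1935, 1985)
    base_mortality: float = 0.02
    primary_policy: str = "first"  # "first" or "filler"
    filler_code: str = "Z00"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not self.code_universe:
            raise ValueError("code universe must not be empty")
        for code in self.code_universe:
            if not ICD3_PATTERN.match(code):
                raise ValueError(f"bad code {code!r}")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate out of range")
        if sum(p.weight for p in self.phenotypes) > 1 + 1e-9:
            raise ValueError("phenotype weights must sum to at most 1")
        for p in self.phenotypes:
            p.validate(self.background_rate)
            for code in list(p.core_codes) + list(p.target_codes):
                if code not in self.code_universe:
                    raise ValueError(f"{p.label}: code {code} not in universe")
        cluster_codes: set[str] = set()
        for cl in self.cooccurrence_clusters:
            for code in cl.codes:
                if code not in self.code_universe:
                    raise ValueError(f"cluster code {code} not in universe")
                if code in cluster_codes:
                    raise ValueError(f"code {code} in more than one cluster")
                cluster_codes.add(code)
        for s in self.synergies:
            if s.target_code not in self.code_universe:
                raise ValueError(f"synergy target {s.target_code} not in universe")
            for code in s.feature_codes:
                if code not in self.code_universe:
                    raise ValueError(f"synergy code {code} not in universe")
        if self.primary_policy not in ("first", "filler"):
            raise ValueError("primary_policy must be 'first' or 'filler'")


@dataclass
class GroundTruth:
    """Planted structure, for test assertions; serialisable as JSON."""

    phenotype_label: dict[str, str | None]
    synergies: tuple[SynergySpec, ...]
    clusters: tuple[ThreeWayCluster, ...]
    feature_presence: dict[str, list[str]]

    def to_json(self, path) -> None:
        payload = {
            "phenotype_label": self.phenotype_label,
            "synergies": [
                {
                    "feature_codes": sorted(s.feature_codes),
                    "target_code": s.target_code,
                    "boost": s.boost,
                }
                for s in self.synergies
            ],
            "clusters": [
                {"codes": list(c.codes), "m": c.m, "q0": c.q0} for c in self.clusters
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_dates(
    rng: np.random.Generator, lo: date, hi: date, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit day offsets with exit in [lo, hi) and entry ≤ exit."""
    span = (hi - lo).days
    exit_off = rng.integers(0, span, size=n)
    duration = np.minimum(rng.integers(0, 8, size=n), exit_off)
    return exit_off - duration, exit_off


def simulate(config: SimConfig) -> tuple[list[StayRecord], GroundTruth]:
    """Draw a synthetic claims dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    codes = list(config.code_universe)
    code_idx = {c: j for j, c in enumerate(codes)}
    n_codes = len(codes)
    patient_ids = [f"P{i:06d}" for i in range(n)]

    # --- latent phenotype assignment ---------------------------------------
    weights = [p.weight for p in config.phenotypes]
    probs = weights + [1.0 - sum(weights)]
    z = rng.choice(len(config.phenotypes) + 1, size=n, p=probs)
    labels: list[str | None] = [
        config.phenotypes[k].label if k < len(config.phenotypes) else None for k in z
    ]

    # --- feature-period presence -------------------------------------------
    fp = np.empty((n, n_codes))
    for j, c in enumerate(codes):
        fp[:, j] = config.feature_rates.get(c, config.background_rate)
    for k, ph in enumerate(config.phenotypes):
        members = z == k
        for c, p in ph.core_codes.items():
            fp[members, code_idx[c]] = p
    F = rng.random((n, n_codes)) < fp
    for cl in config.cooccurrence_clusters:
        cols = [code_idx[c] for c in cl.codes]
        F[:, cols] = cl.draw(rng, n)

    # --- target-period incidence -------------------------------------------
    bt = (
        config.background_target_rate
        if config.background_target_rate is not None
        else config.background_rate
    )
    tp = np.empty((n, n_codes))
    for j, c in enumerate(codes):
        tp[:, j] = config.target_rates.get(c, bt)
    for k, ph in enumerate(config.phenotypes):
        members = z == k
        for c, p in ph.target_codes.items():
            tp[members, code_idx[c]] = p
    # synergy boosts act multiplicatively on the odds, only for carriers of
    # the full feature-code set
    odds = tp / (1.0 - np.clip(tp, None, 1 - 1e-12))
    for syn in config.synergies:
        carrier = F[:, [code_idx[c] for c in syn.feature_codes]].all(axis=1)
        odds[carrier, code_idx[syn.target_code]] *= syn.boost
    tp = odds / (1.0 + odds)
    T = rng.random((n, n_codes)) < tp

    # --- demographics -------------------------------------------------------
    sex = rng.choice(list(config.sexes), size=n)
    region = rng.choice(list(config.regions), size=n)
    lo_y, hi_y = config.birth_year_range
    birth_year = rng.integers(lo_y, hi_y + 1, size=n)
    for k, ph in enumerate(config.phenotypes):
        if ph.birth_year_range is not None:
            members = z == k
            a, b = ph.birth_year_range
            birth_year[members] = rng.integers(a, b + 1, size=int(members.sum()))
    p_death = np.full(n, config.base_mortality)
    for k, ph in enumerate(config.phenotypes):
        if ph.mortality is not None:
            p_death[z == k] = ph.mortality
    dies = rng.random(n) < p_death

    # --- emit stays ----------------------------------------------------------
    per = config.periods
    fe_entry, fe_exit = _random_dates(rng, per.t1, per.t2, n)
    ta_entry, ta_exit = _random_dates(rng, per.t2, per.t3, n)
    fu_entry, fu_exit = _random_dates(rng, per.t3, per.t4, n)

    def make_stay(i: int, present: np.ndarray, entry: date, exit_: date, death: bool) -> StayRecord:
        drawn = [codes[j] for j in np.flatnonzero(present[i])]
        if config.primary_policy == "filler":
            primary, secondary = config.filler_code, drawn
        elif drawn:
            primary, secondary = drawn[0], drawn[1:]
        else:
            primary, secondary = config.filler_code, []
        return StayRecord(
            patient_id=patient_ids[i],
            entry_date=entry,
            exit_date=exit_,
            primary_dx=primary,
            secondary_dx=tuple(secondary),
            region=str(region[i]),
            sex=str(sex[i]),
            birth_year=int(birth_year[i]),
            death=death,
        )

    stays: list[StayRecord] = []
    for i in range(n):
        stays.append(
            make_stay(
                i,
                F,
                per.t1 + timedelta(days=int(fe_entry[i])),
                per.t1 + timedelta(days=int(fe_exit[i])),
                False,
            )
        )
        stays.append(
            make_stay(
                i,
                T,
                per.t2 + timedelta(days=int(ta_entry[i])),
                per.t2 + timedelta(days=int(ta_exit[i])),
                False,
            )
        )
        if dies[i]:
            stays.append(
                make_stay(
                    i,
                    np.zeros_like(F),
                    per.t3 + timedelta(days=int(fu_entry[i])),
                    per.t3 + timedelta(days=int(fu_exit[i])),
                    True,
                )
            )

    truth = GroundTruth(
        phenotype_label=dict(zip(patient_ids, labels)),
        synergies=config.synergies,
        clusters=config.cooccurrence_clusters,
        feature_presence={
            patient_ids[i]: [codes[j] for j in np.flatnonzero(F[i])] for i in range(n)
        },
    )
    return stays, truth


# ---------------------------------------------------------------------------
# Canned study conditions
# ---------------------------------------------------------------------------

#: Background codes shared by the canned fixtures.
_BACKGROUND_CODES = ("A09", "F32", "H25", "J18", "K52", "L30", "N39", "R10", "S52", "J45")


def _padding_codes(n: int) -> tuple[str, ...]:
    """Unstructured disease codes that fill out the feature universe."""
    out: list[str] = []
    for letter in "ABFHJKLNRSUV":
        for digit in range(40, 100):
            out.append(f"{letter}{digit}")
            if len(out) == n:
                return tuple(out)
    raise ValueError("padding universe exhausted")


def two_phenotype_fixture(
    seed: int, n_patients: int = 20000, synergy_boost: float | None = None
) -> SimConfig:
    """Two latent obesity phenotypes sharing index code E66.

    A metabolic-like group (weight 0.16; core E66, E11, E78, I10 at 0.6;
    elevated incident diabetes, ischaemic heart disease and heart failure)
    and a musculoskeletal-like group (weight 0.02; core E66, M54, M17, M81
    at 0.6; elevated incident osteoporosis and joint disease).  Both groups
    develop the shared obesity sequelae G47 (sleep apnoea) and R07 (chest
    pain) with high penetrance in the target period — the strong shared
    coefficient axis that keeps index features of both phenotypes connected
    in the disease network while their disjoint comorbidity cores separate
    the clusters.  Forty unstructured background codes at rate 0.05 fill
    out the feature universe so that the network's null model is estimated
    over a realistic number of nodes.  The 1:8 phenotype weight ratio
    leaves the larger cohort more than three times the size of the smaller,
    as required by 1:3:10 matching.

    With ``synergy_boost`` set, a three-way co-occurrence cluster
    (G20, G21, G22, zero pairwise excess) with a planted odds boost on
    target G55 is added, giving order-3 features genuine signal beyond
    pairs and singletons.
    """
    shared_sequelae = {"G47": 0.95, "R07": 0.95}
    metabolic = PhenotypeSpec(
        label="metabolic",
        weight=0.16,
        core_codes={"E66": 0.6, "E11": 0.6, "E78": 0.6, "I10": 0.6},
        target_codes={"E14": 0.35, "I25": 0.35, "I50": 0.30, **shared_sequelae},
        index_code="E66",
        mortality=0.06,
    )
    musculoskeletal = PhenotypeSpec(
        label="musculoskeletal",
        weight=0.02,
        core_codes={"E66": 0.6, "M54": 0.6, "M17": 0.6, "M81": 0.6},
        target_codes={"M80": 0.35, "M25": 0.35, **shared_sequelae},
        index_code="E66",
        mortality=0.03,
    )
    universe = (
        "E66", "E11", "E78", "I10", "M54", "M17", "M81",
        "E14", "I25", "I50", "G47", "R07", "M80", "M25",
    ) + _padding_codes(40)
    synergies: tuple[SynergySpec, ...] = ()
    clusters: tuple[ThreeWayCluster, ...] = ()
    feature_rates = {"E66": 0.008, "G47": 0.0, "R07": 0.0}
    target_rates: dict[str, float] = {"G47": 0.002, "R07": 0.002}
    if synergy_boost is not None:
        universe = universe + ("G20", "G21", "G22", "G55")
        clusters = (ThreeWayCluster(codes=("G20", "G21", "G22"), m=0.005, q0=0.16),)
        synergies = (
            SynergySpec(
                feature_codes=frozenset({"G20", "G21", "G22"}),
                target_code="G55",
                boost=synergy_boost,
            ),
        )
        feature_rates["G55"] = 0.0
        target_rates["G55"] = 0.25
    return SimConfig(
        n_patients=n_patients,
        code_universe=universe,
        phenotypes=(metabolic, musculoskeletal),
        background_rate=0.05,
        feature_rates=feature_rates,
        target_rates=target_rates,
        synergies=synergies,
        cooccurrence_clusters=clusters,
        seed=seed,
        primary_policy="filler",
    )


def synergy_fixture(seed: int, boost: float, n_patients: int = 20000, n_triples: int = 5) -> SimConfig:
    """Planted beyond-pairwise synergies on otherwise independent codes.

    ``n_triples`` disjoint three-way co-occurrence clusters (zero pairwise
    excess, m=0.005, q0=0.16) each boost the odds of a dedicated target code
    (base incidence 0.25, never seen in the feature period) by ``boost``.
    With boost=1 this is the null generator for coefficient and lift
    calibration.
    """
    if not 1 <= n_triples <= 5:
        raise ValueError("n_triples must be between 1 and 5")
    triple_codes = [
        ("C10", "C11", "C12"),
        ("D20", "D21", "D22"),
        ("G30", "G31", "G32"),
        ("K40", "K41", "K42"),
        ("N17", "N18", "N19"),
    ][:n_triples]
    target_codes = ["T50", "T51", "T52", "T53", "T54"][:n_triples]
    universe = tuple(c for t in triple_codes for c in t) + tuple(target_codes) + _BACKGROUND_CODES[:5]
    clusters = tuple(ThreeWayCluster(codes=t, m=0.005, q0=0.16) for t in triple_codes)
    synergies = tuple(
        SynergySpec(feature_codes=frozenset(t), target_code=tc, boost=boost)
        for t, tc in zip(triple_codes, target_codes)
    )
    return SimConfig(
        n_patients=n_patients,
        code_universe=universe,
        cooccurrence_clusters=clusters,
        synergies=synergies,
        background_rate=0.05,
        feature_rates={tc: 0.0 for tc in target_codes},
        target_rates={tc: 0.25 for tc in target_codes},
        seed=seed,
        primary_policy="filler",
    )
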