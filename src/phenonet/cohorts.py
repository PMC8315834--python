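"""Index-disease phenotype cohorts: matching and deciban comparisons.

The two network clusters richest in index-code features (e.g. the two
largest obesity clusters) define two candidate phenotype cohorts: a
patient joins a cluster's cohort when at least one of that cluster's
index-code features was assigned to them for the feature period.
Controls are the patients with no index-code diagnosis (either role)
during the feature period.  Patients carrying index features of both
clusters, or index-positive patients outside both clusters, are excluded.

The smaller cohort anchors a matched design: each anchor is matched
without replacement to ``k_large`` patients of the larger cohort and
``k_control`` controls with identical sex and region and a birth-year
difference of at most two years; anchors with insufficient pools are
excluded.  Groups are then compared block-wise (inclusive ICD3 code
ranges such as E10–E14) on feature-period prevalence, target-period
incidence (first-ever occurrence), follow-up in-hospital mortality and
hospitalisation days, with effect sizes

    ES_{i,j} = 10·(log10 n_j − log10 n_i)   [db]

on the groups' relative frequencies and a likelihood-ratio G-test
(2·Σ O·ln(O/E), χ² with one degree of freedom) for each pairwise
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .claims import DiagnosisMatrix, StayRecord, StudyPeriods, code_and_role
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CohortAssignment",
    "MatchedSet",
    "MatchBlock",
    "assign_cohorts",
    "match",
    "effect_size",
    "g_test",
    "compare",
    "format_report",
    "significance_stars",
]


@dataclass
class CohortAssignment:
    """Per-patient label: control / cohort_1 / cohort_2 / excluded."""

    labels: pd.Series  # index patient_id
    icd3: str
    cluster_of_cohort: dict[str, int]  # cohort name -> cluster id
    n_both: int  # excluded because positive in features of both clusters

    def members(self, name: str) -> list[str]:
        return list(self.labels.index[self.labels == name])

    @property
    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def assign_cohorts(
    G,
    X: FeatureMatrix,
    X0: DiagnosisMatrix,
    icd3: str,
) -> CohortAssignment:
    """Split the study population by the two largest index-disease clusters.

    Cluster size is the number of index-code features it contains;
    cohort_1 is the larger of the two by that count (ties broken by
    cluster id).  Controls are patients with no index-code diagnosis in
    the feature period.
    """
    wanted = {icd3 + "p", icd3 + "s"}
    cluster_features: dict[int, list[frozenset[str]]] = {}
    for node, data in G.nodes(data=True):
        codes = frozenset(data.get("codes", node).split())
        if codes & wanted:
            cluster_features.setdefault(data["cluster_id"], []).append(codes)
    if len(cluster_features) < 2:
        raise ValueError(
            f"index code {icd3} features occur in {len(cluster_features)} cluster(s); "
            "need at least two"
        )
    ranked = sorted(cluster_features.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    (c1, feats1), (c2, feats2) = ranked[:2]

    def membership(feats: list[frozenset[str]]) -> np.ndarray:
        out = np.zeros(len(X.patients), dtype=bool)
        for codes in feats:
            try:
                out |= X.column(codes)
            except KeyError:
                continue
        return out

    in1 = membership(feats1)
    in2 = membership(feats2)
    # obesity (index) status at the diagnosis level, either role
    index_positive = np.zeros(len(X0.patients), dtype=bool)
    for code in wanted:
        if code in X0.codes:
            index_positive |= X0.column(code)
    if X.patients != X0.patients:
        raise ValueError("X and X0 must share patient ordering")

    labels = np.full(len(X.patients), "excluded", dtype=object)
    labels[~index_positive] = "control"
    labels[in1 & ~in2] = "cohort_1"
    labels[in2 & ~in1] = "cohort_2"
    labels[in1 & in2] = "excluded"
    n_both = int((in1 & in2).sum())
    if n_both:
        logger.info("%d patients positive in features of both clusters; excluded", n_both)
    return CohortAssignment(
        labels=pd.Series(labels, index=X.patients, name="cohort"),
        icd3=icd3,
        cluster_of_cohort={"cohort_1": c1, "cohort_2": c2},
        n_both=n_both,
    )


@dataclass(frozen=True)
class MatchBlock:
    anchor: str
    large_matches: tuple[str, ...]
    control_matches: tuple[str, ...]


@dataclass
class MatchedSet:
    """Anchor-wise matched blocks plus the group bookkeeping."""

    blocks: list[MatchBlock]
    anchor_cohort: str  # cohort name of the (smaller) anchor group
    larger_cohort: str
    excluded_count: int
    criteria: dict = field(default_factory=dict)

    def anchors(self) -> list[str]:
        return [b.anchor for b in self.blocks]

    def large_group(self) -> list[str]:
        return [p for b in self.blocks for p in b.large_matches]

    def control_group(self) -> list[str]:
        return [p for b in self.blocks for p in b.control_matches]

    def group(self, name: str) -> list[str]:
        if name == "control":
            return self.control_group()
        if name == self.anchor_cohort:
            return self.anchors()
        if name == self.larger_cohort:
            return self.large_group()
        raise KeyError(name)


def match(
    assignment: CohortAssignment,
    demographics: pd.DataFrame,
    k_large: int = 3,
    k_control: int = 10,
    max_age_diff: int = 2,
    seed: int = 0,
) -> MatchedSet:
    """Random exact-sex/exact-region, age-windowed matching without replacement.

    The anchor group is the smaller of the two cohorts.  Anchors are
    processed in seeded random order; each draws ``k_large`` matches from
    the larger cohort and ``k_control`` controls with the same sex and
    region and |birth-year difference| ≤ ``max_age_diff``.  Anchors whose
    pools are too small are excluded and counted.  No patient is used twice.
    """
    rng = np.random.default_rng(seed)
    n1 = (assignment.labels == "cohort_1").sum()
    n2 = (assignment.labels == "cohort_2").sum()
    anchor_name, larger_name = ("cohort_1", "cohort_2") if n1 <= n2 else ("cohort_2", "cohort_1")
    anchors = assignment.members(anchor_name)
    pools = {
        "large": assignment.members(larger_name),
        "control": assignment.members("control"),
    }
    demo = demographics[["sex", "region", "birth_year"]]

    def bucket(ids: list[str]) -> dict[tuple, list[tuple[int, str]]]:
        out: dict[tuple, list[tuple[int, str]]] = {}
        sub = demo.loc[ids]
        for pid, (sex, region, by) in sub.iterrows():
            out.setdefault((sex, region), []).append((int(by), pid))
        return out

    large_by = bucket(pools["large"])
    control_by = bucket(pools["control"])
    used: set[str] = set()
    blocks: list[MatchBlock] = []
    excluded = 0
    order = list(rng.permutation(anchors))
    for anchor in order:
        sex, region, by = demo.loc[anchor]
        key = (sex, region)
        by = int(by)
        cand_large = [
            pid for y, pid in large_by.get(key, [])
            if abs(y - by) <= max_age_diff and pid not in used
        ]
        cand_control = [
            pid for y, pid in control_by.get(key, [])
            if abs(y - by) <= max_age_diff and pid not in used
        ]
        if len(cand_large) < k_large or len(cand_control) < k_control:
            excluded += 1
            continue
        chosen_large = tuple(rng.choice(cand_large, size=k_large, replace=False))
        chosen_control = tuple(rng.choice(cand_control, size=k_control, replace=False))
        used.update(chosen_large)
        used.update(chosen_control)
        blocks.append(MatchBlock(anchor, chosen_large, chosen_control))
    return MatchedSet(
        blocks=blocks,
        anchor_cohort=anchor_name,
        larger_cohort=larger_name,
        excluded_count=excluded,
        criteria={
            "k_large": k_large,
            "k_control": k_control,
            "max_age_diff": max_age_diff,
            "exact": ["sex", "region"],
        },
    )


def effect_size(n_i: float, n_j: float) -> float:
    """ES = 10·(log10 n_j − log10 n_i) db on two relative frequencies.

    Scale-invariant (percentages and proportions give the same value);
    returns NaN when either frequency is zero (undefined, reported missing).
    """
    if n_i < 0 or n_j < 0:
        raise ValueError("relative frequencies must be non-negative")
    if n_i == 0 or n_j == 0:
        return float("nan")
    return 10.0 * (math.log10(n_j) - math.log10(n_i))


def g_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Likelihood-ratio test of independence on the 2×2 table [[a,b],[c,d]].

    G = 2·Σ O·ln(O/E) with independence expecteds; empty cells contribute 0;
    p from χ² with one degree of freedom, no continuity correction.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("G-test undefined for a zero margin")
    expected = np.outer(row, col) / total
    mask = obs > 0
    G = 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())
    return G, float(chi2.sf(G, df=1))


def significance_stars(p: float) -> str:
    if p < 1e-6:
        return "***"
    if p < 1e-4:
        return "**"
    if p < 1e-2:
        return "*"
    return ""


def _block_members(codes: set[str], lo: str, hi: str) -> set[str]:
    out = set()
    for suffixed in codes:
        code, _role = code_and_role(suffixed)
        if lo <= code <= hi:
            out.add(suffixed)
    return out


def compare(
    matched: MatchedSet,
    stays: Sequence[StayRecord],
    periods: StudyPeriods,
    blocks: Sequence[tuple[str, str, str]],
    demographics: pd.DataFrame,
    attribution: str = "exit",
) -> pd.DataFrame:
    """Block-wise prevalence/incidence/mortality comparison of matched groups.

    ``blocks`` are (label, low_code, high_code) inclusive ICD3 ranges,
    matched in both diagnosis roles.  Output rows: one per section × block
    × sex, with per-group counts and relative frequencies, pairwise effect
    sizes (control→anchor and anchor→larger, mirroring the published group
    ordering 0→1→2) and G-test annotations.  Prevalence counts any block
    diagnosis during the feature period; incidence counts first-ever block
    diagnoses during the target period; mortality is the in-hospital death
    fraction during follow-up; hospitalisation days sum feature- and
    target-period stay lengths (nights + 1).
    """
    group_names = ["control", matched.anchor_cohort, matched.larger_cohort]
    groups = {name: matched.group(name) for name in group_names}
    all_ids = {p for ids in groups.values() for p in ids}

    feature_codes: dict[str, set[str]] = {p: set() for p in all_ids}
    target_codes: dict[str, set[str]] = {p: set() for p in all_ids}
    hosp_days: dict[str, int] = {p: 0 for p in all_ids}
    died: dict[str, bool] = {p: False for p in all_ids}
    dx_counts: dict[str, list[int]] = {p: [0, 0] for p in all_ids}  # primary, secondary in feature period
    for stay in stays:
        pid = stay.patient_id
        if pid not in all_ids:
            continue
        window = periods.period_of(stay, attribution=attribution)
        if window == "feature":
            feature_codes[pid].add(stay.primary_dx + "p")
            feature_codes[pid].update(c + "s" for c in stay.secondary_dx)
            dx_counts[pid][0] += 1
            dx_counts[pid][1] += len(stay.secondary_dx)
        elif window == "target":
            target_codes[pid].add(stay.primary_dx + "p")
            target_codes[pid].update(c + "s" for c in stay.secondary_dx)
        if window in ("feature", "target"):
            hosp_days[pid] += (stay.exit_date - stay.entry_date).days + 1
        if window == "followup" and stay.death:
            died[pid] = True

    sexes = sorted(demographics.loc[sorted(all_ids), "sex"].unique())
    rows: list[dict] = []

    def add_comparison_row(section, label, sex, members_by_group, positive) -> None:
        stats = {}
        for g in group_names:
            ids = members_by_group[g]
            n = len(ids)
            k = sum(1 for p in ids if positive(p))
            stats[g] = (n, k, k / n if n else float("nan"))
        row = {"section": section, "block": label, "sex": sex}
        for g in group_names:
            n, k, frac = stats[g]
            row[f"n_{g}"] = n
            row[f"count_{g}"] = k
            row[f"frac_{g}"] = frac
        for gi, gj, tag in (
            (group_names[0], group_names[1], "es_0_1"),
            (group_names[1], group_names[2], "es_1_2"),
        ):
            ni, ki, fi = stats[gi]
            nj, kj, fj = stats[gj]
            row[tag] = effect_size(fi, fj) if ni and nj else float("nan")
            try:
                G, p = g_test(ki, ni - ki, kj, nj - kj)
            except ValueError:
                G, p = float("nan"), float("nan")
            row[f"{tag}_p"] = p
            row[f"{tag}_stars"] = significance_stars(p) if np.isfinite(p) else ""
        rows.append(row)

    members_all = {g: [p for p in ids] for g, ids in groups.items()}
    by_sex = {
        sex: {
            g: [p for p in ids if demographics.loc[p, "sex"] == sex]
            for g, ids in groups.items()
        }
        for sex in sexes
    }

    for label, lo, hi in blocks:
        def prevalent(pid, lo=lo, hi=hi):
            return bool(_block_members(feature_codes[pid], lo, hi))

        def incident(pid, lo=lo, hi=hi):
            return bool(_block_members(target_codes[pid], lo, hi)) and not bool(
                _block_members(feature_codes[pid], lo, hi)
            )

        for sex in sexes:
            add_comparison_row("prevalence", label, sex, by_sex[sex], prevalent)
        for sex in sexes:
            add_comparison_row("incidence", label, sex, by_sex[sex], incident)

    add_comparison_row("mortality", "in-hospital death (follow-up)", "all",
                       members_all, lambda p: died[p])

    for g in group_names:
        ids = members_all[g]
        rows.append(
            {
                "section": "hospitalization",
                "block": "days per patient (feature+target)",
                "sex": "all",
                f"n_{g}": len(ids),
                f"mean_{g}": float(np.mean([hosp_days[p] for p in ids])) if ids else float("nan"),
            }
        )
        rows.append(
            {
                "section": "diagnoses",
                "block": "primary/secondary per patient (feature)",
                "sex": "all",
                f"n_{g}": len(ids),
                f"mean_primary_{g}": float(np.mean([dx_counts[p][0] for p in ids])) if ids else float("nan"),
                f"mean_secondary_{g}": float(np.mean([dx_counts[p][1] for p in ids])) if ids else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame, matched: MatchedSet) -> str:
    """Plain-text comparison report mirroring the tabular layout."""
    from .units import evidence_grade

    lines = [
        "Matched cohort comparison",
        f"  anchor cohort: {matched.anchor_cohort} "
        f"(n={len(matched.blocks)}; {matched.excluded_count} anchors excluded)",
        f"  matched {matched.criteria.get('k_large')}x larger cohort, "
        f"{matched.criteria.get('k_control')}x controls; exact sex/region, "
        f"age window ±{matched.criteria.get('max_age_diff')}y",
        "",
    ]
    comp = table[table["section"].isin(["prevalence", "incidence", "mortality"])]
    for _, r in comp.iterrows():
        es01 = r.get("es_0_1")
        es12 = r.get("es_1_2")
        frac_cols = [c for c in table.columns if c.startswith("frac_")]
        fracs = "  ".join(
            f"{c[5:]}={100 * r[c]:.1f}%" for c in frac_cols if pd.notna(r.get(c))
        )
        seg = f"  {r['section']:<10} {r['block']:<40} {r['sex']:<4} {fracs}"
        if pd.notna(es01):
            seg += f"  ES01={es01:+.1f}db{r.get('es_0_1_stars', '')}"
        if pd.notna(es12):
            seg += f"  ES12={es12:+.1f}db{r.get('es_1_2_stars', '')}"
        lines.append(seg)
    return "\n".join(lines)
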