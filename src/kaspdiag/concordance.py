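"""Agreement between KASP assignments/calls and reference genotyping.

Produces the three summaries a diagnostic validation reports:

* a confusion matrix of reference haplogroup x KASP assignment (named
  assignments in the body; unresolved / non-target tallied in separate
  columns) with the overall concordance percentage (100 * trace / total);
* per-marker accuracy rows — for each reference class (the groups sharing
  one expected homozygous state at the marker): n, observed state counts,
  accuracy %, mismatch % and the countries the mismatches came from;
* a COI-misidentification summary: how often the legacy single-locus
  barcode label fails to identify the genome-wide haplogroup.

All percentages are rounded half-away-from-zero to one decimal. The module
also packages the published 152-sample field-validation summary counts for
the cassava *Bemisia tabaci* panel, expanded into synthetic per-sample
records so every number is recomputed rather than quoted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import (
    NON_TARGET,
    UNRESOLVED,
    ClassificationResult,
    PanelDefinition,
    SampleMetadata,
    percent,
)

# Nominal one-to-one correspondence between legacy COI labels and
# genome-wide haplogroups. COI labels outside this map (e.g. compound or
# superseded labels) identify no haplogroup and therefore count as
# misidentifications; blank labels are excluded from the count.
DEFAULT_COI_EXPECTATION: dict[str, str] = {
    "SSA1-SG1": "SSA-ECA",
    "SSA1-SG3": "SSA-ESA",
    "SSA1-SG5": "SSA-WA",
    "SSA2": "SSA2",
    "SSA4": "SSA4",
}


def confusion_matrix(
    assignments: Sequence[ClassificationResult],
    reference: Sequence[SampleMetadata],
) -> pd.DataFrame:
    """Reference group (rows) x assigned group (columns) counts.

    Named assignments form the square body; unresolved and non-target are
    separate columns and do not enter the concordance trace/total."""
    ref_by_id = {m.sample_id: m for m in reference}
    missing = [a.sample_id for a in assignments if a.sample_id not in ref_by_id]
    if missing:
        raise ValueError(f"samples without reference labels: {missing}")
    ref_groups = sorted({m.reference_group for m in reference if m.reference_group})
    named = sorted({a.assignment for a in assignments} - {UNRESOLVED, NON_TARGET} | set(ref_groups))
    cols = named + [UNRESOLVED, NON_TARGET]
    mat = pd.DataFrame(0, index=pd.Index(ref_groups, name="reference"), columns=cols)
    for a in assignments:
        g = ref_by_id[a.sample_id].reference_group
        mat.loc[g, a.assignment] += 1
    return mat


def overall_concordance(matrix: pd.DataFrame) -> float:
    """100 * trace / total over named assignments, one decimal."""
    named = [c for c in matrix.columns if c not in (UNRESOLVED, NON_TARGET)]
    body = matrix[named]
    total = int(body.to_numpy().sum())
    if total == 0:
        raise ValueError("no named assignments to compare")
    trace = sum(int(body.at[g, g]) for g in matrix.index if g in body.columns)
    return percent(trace, total)


@dataclass
class MarkerAccuracyRow:
    marker: str
    reference_groups: tuple[str, ...]
    expected_state: str  # "XX" | "YY"
    expected_display: str  # e.g. "A:A"
    n: int
    observed: dict[str, int]  # state -> count (includes "XY", "no_call")
    accuracy_pct: float
    mismatch_pct: float
    mismatch_countries: tuple[str, ...]


@dataclass
class MarkerAccuracy:
    marker: str
    rows: list[MarkerAccuracyRow]
    pooled_n: int
    pooled_matches: int
    pooled_accuracy_pct: float
    excluded_out_of_scope: int = 0


def per_marker_accuracy(
    marker_calls: Mapping[str, str],
    reference: Sequence[SampleMetadata],
    panel: PanelDefinition,
    marker_id: str,
) -> MarkerAccuracy:
    """Accuracy of one marker's calls against reference-implied states.

    Samples whose reference group lies outside the marker's scope are
    excluded (their count is reported); samples with no call entry are
    ignored. A call matches when its state equals the state the marker's
    partition assigns to the sample's reference group; heterozygous and
    no_call states always count as mismatches."""
    marker = panel.marker(marker_id)
    ref_by_id = {m.sample_id: m for m in reference}
    per_class: dict[str, list[tuple[str, SampleMetadata]]] = {"XX": [], "YY": []}
    excluded = 0
    for sample_id, state in marker_calls.items():
        meta = ref_by_id.get(sample_id)
        if meta is None:
            raise ValueError(f"sample {sample_id} has no reference metadata")
        group = meta.reference_group
        if group in marker.partition["XX"]:
            per_class["XX"].append((state, meta))
        elif group in marker.partition["YY"]:
            per_class["YY"].append((state, meta))
        else:
            excluded += 1
    rows: list[MarkerAccuracyRow] = []
    pooled_n = pooled_match = 0
    for expected_state in ("XX", "YY"):
        entries = per_class[expected_state]
        if not entries:
            continue  # a class with zero samples yields no row
        groups = tuple(sorted(marker.partition[expected_state]))
        observed = Counter(state for state, _ in entries)
        n = len(entries)
        matches = observed.get(expected_state, 0)
        mism_countries = tuple(
            sorted({m.country for s, m in entries if s != expected_state and m.country})
        )
        rows.append(
            MarkerAccuracyRow(
                marker=marker_id,
                reference_groups=groups,
                expected_state=expected_state,
                expected_display=marker.display_state(expected_state),
                n=n,
                observed=dict(observed),
                accuracy_pct=percent(matches, n),
                mismatch_pct=percent(n - matches, n),
                mismatch_countries=mism_countries,
            )
        )
        pooled_n += n
        pooled_match += matches
    return MarkerAccuracy(
        marker=marker_id,
        rows=rows,
        pooled_n=pooled_n,
        pooled_matches=pooled_match,
        pooled_accuracy_pct=percent(pooled_match, pooled_n) if pooled_n else float("nan"),
        excluded_out_of_scope=excluded,
    )


@dataclass
class CoiMismatchSummary:
    n_misidentified: int
    pct_misidentified: float
    total: int
    breakdown: list[dict]  # {coi, reference_group, count, reason}
    n_missing_coi: int = 0


def coi_mismatch_summary(
    reference: Sequence[SampleMetadata],
    coi_to_haplogroup: Optional[Mapping[str, str]] = None,
) -> CoiMismatchSummary:
    """Samples whose COI-implied haplogroup differs from the reference
    haplogroup. COI labels with no expectation mapping count as
    misidentified and are flagged "unmappable" in the breakdown; samples
    with a blank/unknown COI label are excluded from the count (but remain
    in the denominator, which is all samples)."""
    exp = dict(DEFAULT_COI_EXPECTATION if coi_to_haplogroup is None else coi_to_haplogroup)
    total = len(reference)
    if total == 0:
        raise ValueError("empty reference metadata")
    cats: Counter[tuple[str, str, str]] = Counter()
    n_missing = 0
    n_mis = 0
    for m in reference:
        coi = m.coi_identity.strip()
        if coi in ("", "unknown", "NA"):
            n_missing += 1
            continue
        if coi not in exp:
            n_mis += 1
            cats[(coi, m.reference_group, "unmappable")] += 1
        elif exp[coi] != m.reference_group:
            n_mis += 1
            cats[(coi, m.reference_group, "mismatch")] += 1
    breakdown = [
        {"coi": c, "reference_group": g, "count": n, "reason": reason}
        for (c, g, reason), n in sorted(cats.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return CoiMismatchSummary(
        n_misidentified=n_mis,
        pct_misidentified=percent(n_mis, total),
        total=total,
        breakdown=breakdown,
        n_missing_coi=n_missing,
    )


# ---------------------------------------------------------------------------
# Packaged validation summary (published field-validation counts)
# ---------------------------------------------------------------------------


@dataclass
class ValidationFixture:
    """The published 152-sample validation summary, expanded to synthetic
    per-sample records (ids are invented; counts are the published ones)."""

    assignments: list[ClassificationResult]
    metadata: list[SampleMetadata]
    marker_calls: dict[str, dict[str, str]]  # marker -> sample -> state
    marker_metadata: dict[str, list[SampleMetadata]]


def load_validation_counts() -> dict:
    text = resources.files("kaspdiag.data").joinpath("validation_counts.json").read_text()
    return json.loads(text)


def load_validation_fixture() -> ValidationFixture:
    counts = load_validation_counts()
    # Cohort roster: reference group, KASP assignment, COI label.
    assignments: list[ClassificationResult] = []
    metadata: list[SampleMetadata] = []
    i = 0
    for entry in counts["cohort"]:
        for _ in range(entry["count"]):
            i += 1
            sid = f"V{i:03d}"
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    country=entry.get("country", ""),
                    reference_group=entry["reference"],
                    coi_identity=entry.get("coi", ""),
                )
            )
            assignments.append(ClassificationResult(sample_id=sid, assignment=entry["assigned"]))
    # Per-marker call tables (tested subsets differ per marker).
    marker_calls: dict[str, dict[str, str]] = {}
    marker_metadata: dict[str, list[SampleMetadata]] = {}
    for marker_id, rows in counts["markers"].items():
        calls: dict[str, str] = {}
        meta: list[SampleMetadata] = []
        j = 0
        for row in rows:
            for state, n in row["observed"].items():
                for _ in range(n):
                    j += 1
                    sid = f"{marker_id}-S{j:03d}"
                    country = ""
                    if state != row["expected_state"] and row.get("mismatch_countries"):
                        country = row["mismatch_countries"][
                            (j - 1) % len(row["mismatch_countries"])
                        ]
                    calls[sid] = state
                    meta.append(
                        SampleMetadata(
                            sample_id=sid,
                            country=country,
                            reference_group=row["reference_groups"][0],
                        )
                    )
        marker_calls[marker_id] = calls
        marker_metadata[marker_id] = meta
    return ValidationFixture(
        assignments=assignments,
        metadata=metadata,
        marker_calls=marker_calls,
        marker_metadata=marker_metadata,
    )


# ---------------------------------------------------------------------------
# Report assembly and writers
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    confusion: pd.DataFrame
    overall_pct: float
    matched: int
    total: int
    markers: list[MarkerAccuracy] = field(default_factory=list)
    coi: Optional[CoiMismatchSummary] = None

    def to_json(self) -> dict:
        return {
            "overall": {
                "matched": self.matched,
                "total": self.total,
                "percent": self.overall_pct,
            },
            "confusion": {
                ref: {col: int(self.confusion.at[ref, col]) for col in self.confusion.columns}
                for ref in self.confusion.index
            },
            "markers": [
                {
                    "marker": m.marker,
                    "pooled_n": m.pooled_n,
                    "pooled_matches": m.pooled_matches,
                    "pooled_accuracy_pct": m.pooled_accuracy_pct,
                    "excluded_out_of_scope": m.excluded_out_of_scope,
                    "rows": [
                        {
                            "reference_groups": list(r.reference_groups),
                            "expected": r.expected_display,
                            "n": r.n,
                            "observed": r.observed,
                            "accuracy_pct": r.accuracy_pct,
                            "mismatch_pct": r.mismatch_pct,
                            "mismatch_countries": list(r.mismatch_countries),
                        }
                        for r in m.rows
                    ],
                }
                for m in self.markers
            ],
            "coi": None
            if self.coi is None
            else {
                "n_misidentified": self.coi.n_misidentified,
                "pct_misidentified": self.coi.pct_misidentified,
                "total": self.coi.total,
                "n_missing_coi": self.coi.n_missing_coi,
                "breakdown": self.coi.breakdown,
            },
        }

    def to_markdown(self) -> str:
        lines = [
            "# Concordance report",
            "",
            f"Overall: {self.matched}/{self.total} named assignments match the "
            f"reference ({self.overall_pct}%).",
            "",
            "## Confusion matrix (reference rows x assignment columns)",
            "",
            self.confusion.to_markdown(),
            "",
        ]
        if self.markers:
            lines += ["## Per-marker accuracy", ""]
            lines.append("| marker | reference class | expected | n | accuracy | mismatch (origin) |")
            lines.append("|---|---|---|---|---|---|")
            for m in self.markers:
                for r in m.rows:
                    origin = ", ".join(r.mismatch_countries)
                    lines.append(
                        f"| {r.marker} | {'/'.join(r.reference_groups)} | {r.expected_display} "
                        f"| {r.n} | {r.accuracy_pct}% | {r.mismatch_pct}% ({origin}) |"
                    )
                lines.append(
                    f"| {m.marker} | pooled | | {m.pooled_n} | {m.pooled_accuracy_pct}% | |"
                )
            lines.append("")
        if self.coi is not None:
            lines += [
                "## COI misidentification",
                "",
                f"{self.coi.n_misidentified}/{self.coi.total} samples "
                f"({self.coi.pct_misidentified}%) carry a COI label that does not "
                "identify their genome-wide haplogroup.",
                "",
            ]
        return "\n".join(lines)


def build_report(
    assignments: Sequence[ClassificationResult],
    reference: Sequence[SampleMetadata],
    panel: Optional[PanelDefinition] = None,
    marker_calls: Optional[Mapping[str, Mapping[str, str]]] = None,
    coi_map: Optional[Mapping[str, str]] = None,
    with_coi: bool = False,
) -> ConcordanceReport:
    mat = confusion_matrix(assignments, reference)
    named = [c for c in mat.columns if c not in (UNRESOLVED, NON_TARGET)]
    total = int(mat[named].to_numpy().sum())
    matched = sum(int(mat.at[g, g]) for g in mat.index if g in named)
    report = ConcordanceReport(
        confusion=mat,
        overall_pct=overall_concordance(mat),
        matched=matched,
        total=total,
    )
    if panel is not None and marker_calls:
        for marker_id, calls in marker_calls.items():
            report.markers.append(per_marker_accuracy(dict(calls), reference, panel, marker_id))
    if with_coi:
        report.coi = coi_mismatch_summary(reference, coi_map)
    return report
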