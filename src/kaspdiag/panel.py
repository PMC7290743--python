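"""Diagnostic-SNP panel discovery and decision-key construction.

Automates the marker-design workflow for a fixed-difference SNP diagnostic:

1. profile loci per group (fixed homozygous allele vs mixed, call rate);
2. scan a labelled genotype matrix for loci at which every group in a
   chosen scope is fixed and the two alleles split the scope — each such
   locus is a candidate diagnostic marker, possibly valid only within a
   restricted scope;
3. verify flanking sequence suitability (>= N clean bases either side of
   the SNP, no neighbouring variant inside the flank) and emit
   assay-submission sequences with the variant site in ``[X/Y]`` bracket
   notation;
4. assemble markers into a hierarchical decision tree (greedy most-balanced
   split; redundant markers for an identical split become confirmations).

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import (
    DecisionNode,
    DecisionTree,
    DiagnosticMarker,
    GenotypeMatrix,
    InvalidSpecError,
    Leaf,
    SampleMetadata,
    alleles_of,
    is_missing,
    parse_genotype,
)


@dataclass(frozen=True)
class GroupProfile:
    status: str  # "fixed" | "mixed" | "no_samples"
    allele: Optional[str]
    call_rate: float


@dataclass
class LocusProfile:
    locus: str
    groups: dict[str, GroupProfile]

    @property
    def all_fixed(self) -> bool:
        return all(g.status == "fixed" for g in self.groups.values())

    def fixed_alleles(self) -> set[str]:
        return {g.allele for g in self.groups.values() if g.status == "fixed"}


def profile_locus(
    matrix: GenotypeMatrix,
    labels: Mapping[str, str],
    locus: str,
    scope: Sequence[str],
    min_call_rate: float = 0.8,
) -> LocusProfile:
    """Per-group fixation summary for one locus within ``scope``.

    A group is "fixed" only when *all* of its non-missing calls are
    homozygous for the same allele and its call rate is at least
    ``min_call_rate``; a group with no samples in scope is flagged
    ``no_samples`` (never fixed).
    """
    if not scope:
        raise InvalidSpecError("scope must be nonempty")
    if locus not in matrix.calls.columns:
        raise KeyError(f"locus {locus} not in matrix")
    col = matrix.calls[locus]
    groups: dict[str, GroupProfile] = {}
    for group in scope:
        members = [s for s in matrix.sample_ids if labels.get(s) == group]
        if not members:
            groups[group] = GroupProfile("no_samples", None, 0.0)
            continue
        calls = [col[s] for s in members]
        present = [gt for gt in calls if not is_missing(gt)]
        call_rate = len(present) / len(calls)
        alleles = set()
        homozygous = True
        for gt in present:
            a, b = alleles_of(gt)
            if a != b:
                homozygous = False
                break
            alleles.add(a)
        if present and homozygous and len(alleles) == 1 and call_rate >= min_call_rate:
            groups[group] = GroupProfile("fixed", alleles.pop(), call_rate)
        else:
            groups[group] = GroupProfile("mixed", None, call_rate)
    return LocusProfile(locus=locus, groups=groups)


def find_diagnostic_loci(
    matrix: GenotypeMatrix,
    labels: Mapping[str, str],
    scope: Sequence[str],
    min_call_rate: float = 0.8,
) -> list[DiagnosticMarker]:
    """All loci at which every group in ``scope`` is fixed and both alleles
    are represented, i.e. strict fixed differences that bipartition the
    scope. Allele X is the locus reference allele when the reference allele
    is among the fixed alleles, otherwise the alphabetically first fixed
    allele. Results are sorted by (contig, position)."""
    scope = list(scope)
    if len(set(scope)) < 2:
        raise InvalidSpecError("scope needs at least two groups")
    found: list[DiagnosticMarker] = []
    for locus in matrix.locus_ids:
        prof = profile_locus(matrix, labels, locus, scope, min_call_rate)
        if not prof.all_fixed:
            continue
        alleles = prof.fixed_alleles()
        if len(alleles) != 2:
            continue
        ref = matrix.loci.at[locus, "ref"]
        allele_x = ref if ref in alleles else min(alleles)
        allele_y = (alleles - {allele_x}).pop()
        side_x = frozenset(g for g, p in prof.groups.items() if p.allele == allele_x)
        side_y = frozenset(scope) - side_x
        found.append(
            DiagnosticMarker(
                marker_id=locus,
                contig=str(matrix.loci.at[locus, "contig"]),
                pos=int(matrix.loci.at[locus, "pos"]),
                allele_x=allele_x,
                allele_y=allele_y,
                scope=frozenset(scope),
                partition={"XX": side_x, "YY": side_y},
            )
        )
    found.sort(key=lambda m: (m.contig, m.pos))
    return found


# ---------------------------------------------------------------------------
# Flank checks and submission sequences
# ---------------------------------------------------------------------------


def check_flanks(
    reference: Mapping[str, str],
    marker: DiagnosticMarker,
    all_loci: pd.DataFrame,
    flank: int = 50,
) -> tuple[bool, list[str]]:
    """Whether >= ``flank`` clean bases exist on both sides of the SNP.

    ``reference`` maps contig name to sequence; ``all_loci`` is a loci table
    (columns contig/pos) of every known variant — any *other* variant within
    ``flank`` bp disqualifies the site (allele-specific primers must not sit
    on a polymorphism). Returns (ok, reasons-for-failure)."""
    if marker.contig not in reference:
        raise KeyError(f"contig {marker.contig} absent from reference")
    seq = reference[marker.contig]
    if not (1 <= marker.pos <= len(seq)):
        raise ValueError(f"position {marker.pos} outside contig {marker.contig}")
    reasons: list[str] = []
    if marker.pos - 1 < flank:
        reasons.append("left flank short")
    if len(seq) - marker.pos < flank:
        reasons.append("right flank short")
    near = all_loci[
        (all_loci["contig"] == marker.contig)
        & (all_loci["pos"] != marker.pos)
        & ((all_loci["pos"] - marker.pos).abs() <= flank)
    ]
    for other, row in near.iterrows():
        reasons.append(f"variant {other} within {flank} bp (pos {int(row['pos'])})")
    return (not reasons, reasons)


def extract_submission_sequence(
    reference: Mapping[str, str],
    marker: DiagnosticMarker,
    window: int = 200,
) -> str:
    """Window of genomic context centred on the SNP, variant rendered as
    ``[X/Y]`` (marker allele order, regardless of which allele the
    reference carries). The returned string covers ``window`` bases (the
    variant base counted once) unless the contig ends truncate it, in which
    case a warning is emitted."""
    if marker.contig not in reference:
        raise KeyError(f"contig {marker.contig} absent from reference")
    seq = reference[marker.contig]
    if not (1 <= marker.pos <= len(seq)):
        raise ValueError(f"position {marker.pos} outside contig {marker.contig}")
    base = seq[marker.pos - 1].upper()
    if base not in (marker.allele_x, marker.allele_y):
        raise ValueError(
            f"{marker.marker_id}: reference base {base} at {marker.contig}:{marker.pos} "
            f"matches neither allele {marker.allele_x}/{marker.allele_y} "
            "(strand or coordinate mismatch)"
        )
    left_want = (window - 1) // 2
    right_want = window - 1 - left_want
    left = seq[max(0, marker.pos - 1 - left_want) : marker.pos - 1]
    right = seq[marker.pos : marker.pos + right_want]
    if len(left) < left_want or len(right) < right_want:
        warnings.warn(
            f"{marker.marker_id}: submission window truncated by contig ends",
            stacklevel=2,
        )
    return f"{left}[{marker.allele_x}/{marker.allele_y}]{right}"


# ---------------------------------------------------------------------------
# Decision tree construction
# ---------------------------------------------------------------------------


def build_decision_tree(
    markers: Sequence[DiagnosticMarker],
    groups: Sequence[str],
    root_marker: Optional[str] = None,
) -> DecisionTree:
    """Greedy hierarchical key over ``groups``.

    At each node the candidate markers are those whose scope covers the
    current group set and whose partition splits it; the most balanced
    split wins, ties broken by position in the input marker list (pin a
    specific root with ``root_marker``). Markers inducing a split already
    chosen at a node are attached to that node as confirmations rather than
    new nodes. Raises if some group pair cannot be separated, naming the
    indistinguishable pairs."""
    groups = list(dict.fromkeys(groups))
    order = {m.marker_id: i for i, m in enumerate(markers)}
    by_id = {m.marker_id: m for m in markers}
    if root_marker is not None and root_marker not in by_id:
        raise InvalidSpecError(f"root marker {root_marker} not among markers")

    def split_of(marker: DiagnosticMarker, node_set: frozenset[str]):
        if not node_set <= marker.scope:
            return None
        side_x = frozenset(marker.partition["XX"]) & node_set
        side_y = frozenset(marker.partition["YY"]) & node_set
        if not side_x or not side_y:
            return None
        return side_x, side_y

    unresolvable: list[tuple[str, str]] = []

    def recurse(node_set: frozenset[str], used: frozenset[str], pin: Optional[str]):
        if len(node_set) == 1:
            return Leaf(next(iter(node_set)))
        candidates = [
            (m, s)
            for m in markers
            if m.marker_id not in used and (s := split_of(m, node_set)) is not None
        ]
        if not candidates:
            gs = sorted(node_set)
            unresolvable.extend(
                (gs[i], gs[j]) for i in range(len(gs)) for j in range(i + 1, len(gs))
            )
            return Leaf("unresolved")
        if pin is not None:
            chosen = next(((m, s) for m, s in candidates if m.marker_id == pin), None)
            if chosen is None:
                raise InvalidSpecError(f"pinned root {pin} does not split the group set")
        else:
            chosen = min(
                candidates,
                key=lambda ms: (abs(len(ms[1][0]) - len(ms[1][1])), order[ms[0].marker_id]),
            )
        marker, (side_x, side_y) = chosen
        same_split = [
            m.marker_id
            for m, s in candidates
            if m.marker_id != marker.marker_id and {s[0], s[1]} == {side_x, side_y}
        ]
        confirmations = list(dict.fromkeys(same_split + ([marker.fallback] if marker.fallback else [])))
        confirmations = [c for c in confirmations if c in by_id and c != marker.marker_id]
        used_next = used | {marker.marker_id} | set(confirmations)
        node = DecisionNode(
            marker=marker.marker_id,
            confirmations=confirmations,
            edges={
                "XX": recurse(side_x, used_next, None),
                "YY": recurse(side_y, used_next, None),
            },
        )
        return node

    root = recurse(frozenset(groups), frozenset(), root_marker)
    if unresolvable:
        pairs = ", ".join(f"{a}|{b}" for a, b in sorted(set(unresolvable)))
        raise InvalidSpecError(f"markers cannot separate group pairs: {pairs}")
    if isinstance(root, Leaf):
        raise InvalidSpecError("fewer than two groups: nothing to split")
    return DecisionTree(root=root, groups=frozenset(groups))


# ---------------------------------------------------------------------------
# I/O: VCF / TSV matrices, metadata, reference FASTA, panel JSON
# ---------------------------------------------------------------------------


def read_matrix_vcf(path) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a GenotypeMatrix via cyvcf2.

    Multi-allelic and non-SNP records are rejected; their count is reported
    in the raised error if any are present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, list[str]] = {}
    loci_rows: list[dict] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        locus = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci_rows.append(
            {"locus": locus, "contig": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]}
        )
        columns[locus] = [parse_genotype(gt.replace("|", "/")) for gt in var.gt_bases]
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic/non-SNP records", stacklevel=2)
    calls = pd.DataFrame(columns, index=pd.Index(samples, name="sample"))
    loci = pd.DataFrame(loci_rows).set_index("locus")
    return GenotypeMatrix(calls=calls, loci=loci)


def read_metadata_csv(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sid = col("sample", "sample_id")
    if sid is None:
        raise ValueError("metadata CSV needs a 'sample' column")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=row[sid],
                country=row[col("country")] if col("country") else "",
                reference_group=row[col("group", "reference_group", "nextrad_group")] or ""
                if col("group", "reference_group", "nextrad_group")
                else "",
                coi_identity=row[col("coi_identity", "coi")] if col("coi_identity", "coi") else "",
            )
        )
    return out


def read_reference_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def tree_to_json(node) -> dict:
    if isinstance(node, Leaf):
        return {"leaf": node.name}
    return {
        "marker": node.marker,
        "confirmations": list(node.confirmations),
        "edges": {state: tree_to_json(child) for state, child in node.edges.items()},
    }


def tree_from_json(obj: dict):
    if "leaf" in obj:
        return Leaf(obj["leaf"])
    return DecisionNode(
        marker=obj["marker"],
        confirmations=list(obj.get("confirmations", [])),
        edges={state: tree_from_json(child) for state, child in obj["edges"].items()},
    )


def marker_to_json(m: DiagnosticMarker) -> dict:
    return {
        "id": m.marker_id,
        "contig": m.contig,
        "position": m.pos,
        "allele_x": m.allele_x,
        "allele_y": m.allele_y,
        "scope": sorted(m.scope),
        "partition": {"XX": sorted(m.partition["XX"]), "YY": sorted(m.partition["YY"])},
        "fallback": m.fallback,
        "metadata": dict(m.metadata),
    }


def marker_from_json(obj: dict) -> DiagnosticMarker:
    return DiagnosticMarker(
        marker_id=obj["id"],
        contig=obj["contig"],
        pos=int(obj["position"]),
        allele_x=obj["allele_x"],
        allele_y=obj["allele_y"],
        scope=frozenset(obj["scope"]),
        partition={
            "XX": frozenset(obj["partition"]["XX"]),
            "YY": frozenset(obj["partition"]["YY"]),
        },
        fallback=obj.get("fallback"),
        metadata=obj.get("metadata", {}),
    )
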