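"""Shared domain types for the KASP diagnostic toolkit.

Conventions used throughout the package:

* Diploid genotypes are unordered nucleotide pairs written ``"A/G"``
  (normalised so ``"A/G" == "G/A"``); missing data is ``"./."``.
  Published-style ``"A:A"`` notation is accepted on input.
* Genomic coordinates are 1-based inclusive.
* Fluorescence geometry: theta is measured in degrees from the FAM axis
  (allele X, 0 deg) toward the HEX axis (allele Y, 90 deg); magnitude is
  the Euclidean norm of the background-subtracted (FAM, HEX) signal.
* Genotype *states* at a marker are ``XX`` (homozygous allele X), ``XY``
  (heterozygous), ``YY`` (homozygous allele Y) and ``no_call``.
* Percentages are rounded half-away-from-zero to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

MISSING = "./."
STATES = ("XX", "XY", "YY")
NO_CALL = "no_call"
UNRESOLVED = "unresolved"
NON_TARGET = "non-target"

NUCLEOTIDES = ("A", "C", "G", "T")


class InvalidSpecError(ValueError):
    """Raised when a simulation/panel specification is internally inconsistent."""


def genotype(a: str, b: str) -> str:
    """Normalised unordered diploid genotype string."""
    return "/".join(sorted((a, b)))


def parse_genotype(text: str) -> str:
    """Accept ``A/G``, ``A:G`` or ``A:A``-style notation; normalise order."""
    t = text.strip().replace(":", "/")
    if t in ("", ".", MISSING, "-", "NA"):
        return MISSING
    parts = t.split("/")
    if len(parts) != 2:
        raise ValueError(f"not a diploid genotype: {text!r}")
    if "." in parts:
        return MISSING
    return genotype(parts[0], parts[1])


def is_missing(gt: str) -> bool:
    return gt == MISSING


def alleles_of(gt: str) -> tuple[str, str]:
    a, b = gt.split("/")
    return a, b


def is_het(gt: str) -> bool:
    if is_missing(gt):
        return False
    a, b = alleles_of(gt)
    return a != b


def percent(numer: float, denom: float, ndigits: int = 1) -> float:
    """``100 * numer / denom`` rounded half-away-from-zero to `ndigits`.

    Decimal arithmetic avoids binary-float artefacts at the rounding
    boundary (e.g. 33/41 -> 80.5, 39/41 -> 95.1, 151/152 -> 99.3).
    """
    if denom == 0:
        raise ZeroDivisionError("percentage of an empty total")
    q = Decimal(1).scaleb(-ndigits)
    val = (Decimal(100) * Decimal(str(numer)) / Decimal(str(denom))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(val)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid nucleotide calls plus per-locus metadata.

    ``calls`` is a DataFrame indexed by sample id with one column per locus
    id, holding normalised genotype strings. ``loci`` is indexed by locus id
    with columns ``contig``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    calls: pd.DataFrame
    loci: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    def validate(self) -> None:
        if list(self.calls.columns) != list(self.loci.index):
            raise ValueError("calls columns and loci index disagree")
        for locus in self.locus_ids:
            allowed = {self.loci.at[locus, "ref"], self.loci.at[locus, "alt"]}
            for gt in self.calls[locus]:
                if is_missing(gt):
                    continue
                if not set(alleles_of(gt)) <= allowed:
                    raise ValueError(
                        f"genotype {gt} at {locus} uses alleles outside {allowed}"
                    )


# ---------------------------------------------------------------------------
# Markers, trees, panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticMarker:
    """A bi-allelic diagnostic SNP and the group bipartition it induces.

    ``partition`` maps the homozygous states ``XX``/``YY`` to the disjoint
    subsets of ``scope`` fixed for allele X / allele Y respectively.
    """

    marker_id: str
    contig: str
    pos: int
    allele_x: str
    allele_y: str
    scope: frozenset[str]
    partition: Mapping[str, frozenset[str]]
    fallback: Optional[str] = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        xx = frozenset(self.partition["XX"])
        yy = frozenset(self.partition["YY"])
        if not xx or not yy or (xx & yy) or (xx | yy) != frozenset(self.scope):
            raise InvalidSpecError(
                f"{self.marker_id}: partition must be a nonempty proper "
                f"split covering the scope"
            )

    def state_of(self, gt: str) -> str:
        """Genotype string -> state at this marker (``no_call`` if missing
        or using alleles outside {X, Y})."""
        if is_missing(gt):
            return NO_CALL
        a, b = alleles_of(gt)
        allowed = {self.allele_x, self.allele_y}
        if not {a, b} <= allowed:
            return NO_CALL
        if a == b:
            return "XX" if a == self.allele_x else "YY"
        return "XY"

    def genotype_for_state(self, state: str) -> str:
        if state == "XX":
            return genotype(self.allele_x, self.allele_x)
        if state == "YY":
            return genotype(self.allele_y, self.allele_y)
        if state == "XY":
            return genotype(self.allele_x, self.allele_y)
        return MISSING

    def display_state(self, state: str) -> str:
        """Published-style ``A:A`` notation for a state."""
        gt = self.genotype_for_state(state)
        return gt.replace("/", ":") if gt != MISSING else "-"


@dataclass(frozen=True)
class Leaf:
    name: str  # a group name, "unresolved" or "non-target"


@dataclass
class DecisionNode:
    marker: str
    edges: dict  # state "XX"/"YY" -> DecisionNode | Leaf
    confirmations: list[str] = field(default_factory=list)

    def children(self) -> Iterable[Union["DecisionNode", Leaf]]:
        return self.edges.values()


@dataclass
class DecisionTree:
    root: DecisionNode
    groups: frozenset[str]

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, Leaf):
                out.append(node.name)
                return
            for child in node.children():
                walk(child)

        walk(self.root)
        return out

    def depth(self) -> int:
        def d(node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(d(c) for c in node.children())

        return d(self.root)

    def markers_used(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, Leaf):
                return
            out.append(node.marker)
            for child in node.children():
                walk(child)

        walk(self.root)
        return out


@dataclass
class PanelDefinition:
    """A named marker panel plus its hierarchical decision key."""

    name: str
    version: str
    groups: frozenset[str]
    markers: dict[str, DiagnosticMarker]
    tree: DecisionTree
    metadata: Mapping[str, object] = field(default_factory=dict)

    def marker(self, marker_id: str) -> DiagnosticMarker:
        return self.markers[marker_id]


# ---------------------------------------------------------------------------
# Fluorescence calls / classification results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """Per-well endpoint genotype call with cluster-quality annotation."""

    state: str  # XX | XY | YY | no_call
    theta: float  # degrees from FAM axis; NaN when signal is (0, 0)
    magnitude: float
    quality: float  # silhouette-style separation in [-1, 1]
    reason: str = ""  # populated for no_call


@dataclass
class SampleCallSet:
    """All marker calls for one sample, ready for tree classification."""

    sample_id: str
    calls: dict[str, str]  # marker id -> state
    amplified: Optional[bool] = None  # explicit gateway PCR-product flag


FLAG_USED_FALLBACK = "used_fallback"
FLAG_CONFIRMATION_DISCORDANT = "confirmation_discordant"
FLAG_MISSING_MARKER = "missing_marker"
FLAG_INCONSISTENT_PROFILE = "inconsistent_profile"


@dataclass
class ClassificationResult:
    sample_id: str
    assignment: str  # group name, "unresolved" or "non-target"
    path: list[tuple[str, str]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    country: str = ""
    reference_group: str = ""  # e.g. NextRAD haplogroup
    coi_identity: str = ""
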