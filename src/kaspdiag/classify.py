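"""Hierarchical haplogroup classification from per-sample marker calls.

Walks a panel's decision tree: at each node the primary marker's homozygous
state picks a branch; a heterozygous or failed call falls through to the
node's confirmation/fallback markers; decisive confirmation calls that
contradict the primary branch flag the sample as discordant and leave it
unresolved. A sample whose gateway amplification failed (explicit flag, or
every marker no_call) is "non-target" — outside the species/complex the
panel covers.

The packaged default panel is the six-haplogroup key for cassava-colonising
*Bemisia tabaci* in sub-Saharan Africa (SSA-ECA, SSA-WA, SSA-ESA, SSA-CA,
SSA2, SSA4): seven markers, with BTS99-319 doubling as the species gateway.
"""

from __future__ import annotations

import json
from collections import Counter
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    FLAG_CONFIRMATION_DISCORDANT,
    FLAG_INCONSISTENT_PROFILE,
    FLAG_MISSING_MARKER,
    FLAG_USED_FALLBACK,
    NO_CALL,
    NON_TARGET,
    STATES,
    UNRESOLVED,
    ClassificationResult,
    DecisionNode,
    DecisionTree,
    Leaf,
    PanelDefinition,
    SampleCallSet,
)
from .panel import marker_from_json, marker_to_json, tree_from_json, tree_to_json

CANONICAL_PANEL_NAME = "cassava-bemisia-v1"


def load_panel_json(obj: dict) -> PanelDefinition:
    markers = {m["id"]: marker_from_json(m) for m in obj["markers"]}
    tree = DecisionTree(root=tree_from_json(obj["tree"]), groups=frozenset(obj["groups"]))
    panel = PanelDefinition(
        name=obj["name"],
        version=obj.get("version", "0"),
        groups=frozenset(obj["groups"]),
        markers=markers,
        tree=tree,
        metadata=obj.get("metadata", {}),
    )
    for mid in tree.markers_used():
        if mid not in markers:
            raise ValueError(f"tree references unknown marker {mid}")
    return panel


def panel_to_json(panel: PanelDefinition) -> dict:
    return {
        "name": panel.name,
        "version": panel.version,
        "groups": sorted(panel.groups),
        "markers": [marker_to_json(m) for m in panel.markers.values()],
        "tree": tree_to_json(panel.tree.root),
        "metadata": dict(panel.metadata),
    }


def load_panel(source: str) -> PanelDefinition:
    """Load a panel from ``builtin:<name>`` or a JSON file path."""
    if source.startswith("builtin:"):
        name = source.split(":", 1)[1]
        if name != CANONICAL_PANEL_NAME:
            raise ValueError(f"unknown builtin panel {name!r}")
        return load_canonical_panel()
    with open(source) as fh:
        return load_panel_json(json.load(fh))


def load_canonical_panel() -> PanelDefinition:
    """The packaged six-haplogroup cassava *B. tabaci* panel: seven markers
    with their genotype->group partitions, amplicon and KASP primer
    metadata, and the hierarchical decision key."""
    text = resources.files("kaspdiag.data").joinpath("cassava_bemisia_v1.json").read_text()
    return load_panel_json(json.loads(text))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _decisive(state: Optional[str]) -> bool:
    return state in ("XX", "YY")


def classify_sample(calls: SampleCallSet, panel: PanelDefinition) -> ClassificationResult:
    """Walk the panel tree for one sample.

    Soundness rule: a named haplogroup is only ever reached through
    decisive homozygous calls (primary or fallback) at every node on the
    path; anything else ends in "unresolved" with an explanatory flag.
    """
    if not calls.calls:
        raise ValueError(f"sample {calls.sample_id}: empty call set")
    unknown = set(calls.calls) - set(panel.markers)
    if unknown:
        raise ValueError(f"sample {calls.sample_id}: calls for unknown markers {sorted(unknown)}")

    result = ClassificationResult(sample_id=calls.sample_id, assignment=UNRESOLVED)

    # Species gateway: explicit amplification flag wins; otherwise a sample
    # with no successful call at any marker is outside the panel's target.
    if calls.amplified is False:
        result.assignment = NON_TARGET
        return result
    states = {m: (s if s in STATES else NO_CALL) for m, s in calls.calls.items()}
    if calls.amplified is None and all(s == NO_CALL for s in states.values()):
        result.assignment = NON_TARGET
        return result

    def side_for(marker_id: str, state: str) -> Optional[str]:
        """Which edge ("XX"/"YY") of the current node a decisive call on
        ``marker_id`` points to, translated through that marker's partition."""
        marker = panel.marker(marker_id)
        target = frozenset(marker.partition[state])
        for edge_state in ("XX", "YY"):
            edge_groups = _groups_under(node.edges[edge_state])
            if edge_groups and edge_groups <= target:
                return edge_state
        return None

    node = panel.tree.root
    while True:
        if isinstance(node, Leaf):
            result.assignment = node.name
            return result
        primary_state = states.get(node.marker, NO_CALL)
        secondary = [m for m in node.confirmations if m in panel.markers]
        chosen_edge: Optional[str] = None

        if _decisive(primary_state):
            edge = side_for(node.marker, primary_state)
            if edge is None:
                result.flags.add(FLAG_INCONSISTENT_PROFILE)
                result.path.append((node.marker, primary_state))
                return result
            result.path.append((node.marker, primary_state))
            # Confirmation check: decisive secondary calls must agree.
            for m in secondary:
                s = states.get(m)
                if _decisive(s):
                    conf_edge = side_for(m, s)
                    if conf_edge is not None and conf_edge != edge:
                        result.flags.add(FLAG_CONFIRMATION_DISCORDANT)
                        result.path.append((m, s))
                        return result
            chosen_edge = edge
        else:
            # Primary unusable: het or no_call. Try fallback markers.
            result.path.append((node.marker, primary_state))
            for m in secondary:
                s = states.get(m, NO_CALL)
                if _decisive(s):
                    edge = side_for(m, s)
                    if edge is not None:
                        result.flags.add(FLAG_USED_FALLBACK)
                        result.path.append((m, s))
                        chosen_edge = edge
                        break
            if chosen_edge is None:
                result.flags.add(
                    FLAG_MISSING_MARKER if primary_state == NO_CALL else FLAG_INCONSISTENT_PROFILE
                )
                return result
        node = node.edges[chosen_edge]


def _groups_under(node) -> frozenset[str]:
    if isinstance(node, Leaf):
        return frozenset() if node.name in (UNRESOLVED, NON_TARGET) else frozenset({node.name})
    out: set[str] = set()
    for child in node.children():
        out |= _groups_under(child)
    return frozenset(out)


def classify_cohort(
    callsets: Sequence[SampleCallSet], panel: PanelDefinition
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Element-wise classification preserving order, plus per-assignment
    counts. Duplicate sample ids are an error."""
    ids = [c.sample_id for c in callsets]
    dupes = [s for s, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    results = [classify_sample(c, panel) for c in callsets]
    counts = dict(Counter(r.assignment for r in results))
    return results, counts


# ---------------------------------------------------------------------------
# I/O: call sets from caller output or direct genotype tables
# ---------------------------------------------------------------------------


def callsets_from_calls(calls: pd.DataFrame) -> list[SampleCallSet]:
    """Group a caller calls table (one row per well) into per-sample call
    sets. A sample with several wells for one marker keeps the decisive
    call if the calls agree, else no_call."""
    out: dict[str, dict[str, str]] = {}
    for r in calls.itertuples():
        if not r.sample:
            continue
        d = out.setdefault(r.sample, {})
        prev = d.get(r.marker)
        if prev is None:
            d[r.marker] = r.state
        elif prev != r.state:
            d[r.marker] = prev if prev != NO_CALL and r.state == NO_CALL else (
                r.state if prev == NO_CALL else NO_CALL
            )
    return [SampleCallSet(sample_id=s, calls=d) for s, d in out.items()]


def callsets_from_genotype_table(df: pd.DataFrame, panel: PanelDefinition) -> list[SampleCallSet]:
    """Per-sample marker *genotypes* (e.g. ``A:A`` from reference
    sequencing) -> call sets in marker state space. Expects a 'sample'
    column plus one column per marker id."""
    from .core import parse_genotype

    out = []
    marker_cols = [c for c in df.columns if c in panel.markers]
    for _, row in df.iterrows():
        states = {}
        for m in marker_cols:
            raw = row[m]
            if pd.isna(raw) or str(raw).strip() in ("", "nan"):
                continue  # marker not typed for this sample
            gt = parse_genotype(str(raw))
            states[m] = panel.marker(m).state_of(gt)
        out.append(SampleCallSet(sample_id=str(row["sample"]), calls=states))
    return out


def results_to_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "assignment": r.assignment,
                "path": ">".join(f"{m}:{s}" for m, s in r.path),
                "flags": "|".join(sorted(r.flags)),
            }
            for r in results
        ],
        columns=["sample", "assignment", "path", "flags"],
    )


def results_from_frame(df: pd.DataFrame) -> list[ClassificationResult]:
    out = []
    for r in df.fillna("").itertuples():
        path = [tuple(p.split(":")) for p in r.path.split(">") if p]
        flags = {f for f in r.flags.split("|") if f}
        out.append(
            ClassificationResult(
                sample_id=r.sample, assignment=r.assignment, path=path, flags=flags
            )
        )
    return out
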