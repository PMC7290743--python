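"""Shared fixtures: the canonical panel, small synthetic cohorts, and the
independent brute-force oracle for diagnostic-locus discovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kaspdiag import (
    DiagnosticLocusSpec,
    GenotypeMatrix,
    load_canonical_panel,
    simulate_genotype_matrix,
)
from kaspdiag.core import MISSING

SIX_GROUPS = ["SSA-ECA", "SSA-WA", "SSA-ESA", "SSA-CA", "SSA2", "SSA4"]

# The published marker table, one row per marker: per-group homozygous
# genotype ("-" where the marker does not apply).
TABLE1 = {
    "BTS99-319": dict(zip(SIX_GROUPS, ["A:A", "A:A", "G:G", "G:G", "G:G", "G:G"])),
    "BTS22-762": dict(zip(SIX_GROUPS, ["A:A", "G:G", "-", "-", "-", "-"])),
    "BTS141": dict(zip(SIX_GROUPS, ["C:C", "C:C", "C:C", "C:C", "T:T", "T:T"])),
    "BTS55-473": dict(zip(SIX_GROUPS, ["C:C", "C:C", "C:C", "C:C", "T:T", "C:C"])),
    "BTS613": dict(zip(SIX_GROUPS, ["A:A", "A:A", "G:G", "G:G", "A:A", "A:A"])),
    "BTS46-203": dict(zip(SIX_GROUPS, ["-", "-", "A:A", "G:G", "-", "-"])),
    "BTS1161": dict(zip(SIX_GROUPS, ["-", "-", "C:C", "A:A", "-", "-"])),
}

COHORT_SIZES = {
    "SSA-ECA": 60,
    "SSA-WA": 52,
    "SSA2": 33,
    "SSA4": 10,
    "SSA-ESA": 50,
    "SSA-CA": 12,
}


@pytest.fixture(scope="session")
def panel():
    return load_canonical_panel()


@pytest.fixture(scope="session")
def table1_spec(panel):
    """Planting spec equivalent to the canonical marker table."""
    return [
        DiagnosticLocusSpec(
            locus_id=m.marker_id,
            side_x=tuple(sorted(m.partition["XX"])),
            side_y=tuple(sorted(m.partition["YY"])),
            allele_x=m.allele_x,
            allele_y=m.allele_y,
        )
        for m in panel.markers.values()
    ]


@pytest.fixture(scope="session")
def cohort_matrix(table1_spec):
    """217-sample six-group matrix with the canonical loci planted (clean:
    no missing data or residual heterozygosity)."""
    matrix, truth = simulate_genotype_matrix(
        COHORT_SIZES, 100, table1_spec, missing_rate=0.0, het_rate=0.0, seed=42
    )
    return matrix, truth


def random_matrix(seed: int, n_samples: int = 12, n_loci: int = 30, n_groups: int = 3):
    """A fully random small matrix (no structure planted) plus labels —
    input for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    labels = {s: f"g{rng.integers(n_groups)}" for s in samples}
    # ensure every group has at least one sample
    for i in range(n_groups):
        labels[samples[i % n_samples]] = f"g{i}"
    cols = {}
    rows = []
    for j in range(n_loci):
        ref, alt = [["A", "C", "G", "T"][k] for k in rng.choice(4, 2, replace=False)]
        gts = []
        for s in samples:
            r = rng.random()
            if r < 0.1:
                gts.append(MISSING)
            else:
                a = ref if rng.random() < 0.5 else alt
                b = ref if rng.random() < 0.5 else alt
                gts.append("/".join(sorted((a, b))))
        cols[f"L{j}"] = gts
        rows.append({"locus": f"L{j}", "contig": "c1", "pos": 100 + j, "ref": ref, "alt": alt})
    matrix = GenotypeMatrix(
        calls=pd.DataFrame(cols, index=pd.Index(samples, name="sample")),
        loci=pd.DataFrame(rows).set_index("locus"),
    )
    return matrix, labels


def oracle_diagnostic_loci(matrix, labels, scope, min_call_rate=0.8):
    """Independent direct-counting oracle: the set of loci at which every
    group in scope is 100% homozygous-fixed (call rate >= threshold) and
    the fixed alleles split the scope two ways."""
    out = set()
    for locus in matrix.locus_ids:
        fixed = {}
        ok = True
        for g in scope:
            members = [s for s in matrix.sample_ids if labels.get(s) == g]
            if not members:
                ok = False
                break
            calls = [matrix.calls.at[s, locus] for s in members]
            present = [c for c in calls if c != MISSING]
            if not present or len(present) / len(calls) < min_call_rate:
                ok = False
                break
            alleles = set()
            for c in present:
                a, b = c.split("/")
                if a != b:
                    ok = False
                    break
                alleles.add(a)
            if not ok or len(alleles) != 1:
                ok = False
                break
            fixed[g] = alleles.pop()
        if ok and len(set(fixed.values())) == 2:
            out.add(locus)
    return out
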