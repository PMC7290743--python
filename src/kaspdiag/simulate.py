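"""Synthetic genotype matrices and endpoint-fluorescence plates with known truth.

The generator emulates the kind of cohort used to design a fixed-difference
SNP diagnostic for a cryptic species complex: several populations
("haplogroups") of diploid samples, a handful of loci carrying strictly
fixed homozygous differences between designated sides of a bipartition
(optionally valid only within a restricted scope of groups), a background of
loci polymorphic irrespective of group, plus missing calls, residual
heterozygosity and allelic dropout. Endpoint KASP plates are emulated as
three angular clusters in the FAM/HEX plane plus no-template controls near
the origin.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    NO_CALL,
    GenotypeMatrix,
    InvalidSpecError,
    PanelDefinition,
    genotype,
    is_het,
    is_missing,
    alleles_of,
)

# Default cluster geometry, mimicking the three-arm cluster plots of a
# well-behaved KASP assay: homozygous-X wells hug the FAM axis, heterozygous
# wells sit on the diagonal, homozygous-Y wells hug the HEX axis. NTCs sit
# near the origin at <= 10% of the sample magnitude.
DEFAULT_CLUSTER_PARAMS: dict[str, tuple[float, float]] = {
    "XX": (10.0, 1000.0),
    "XY": (45.0, 1000.0),
    "YY": (80.0, 1000.0),
}
DEFAULT_NOISE_SD = 50.0  # 5% of the default 1000-unit magnitude
NTC_MAG_FRACTION = 0.05
NTC_MAG_SD_FRACTION = 0.02
PRE_READ_FRACTION = 0.05  # pre-read baseline as a fraction of post-read
LOGNORMAL_SIGMA = 0.15

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "marker",
    "sample",
    "fam_pre",
    "fam_post",
    "hex_pre",
    "hex_post",
]


@dataclass(frozen=True)
class DiagnosticLocusSpec:
    """A locus to plant: groups on ``side_x`` are fixed homozygous for
    ``allele_x``, groups on ``side_y`` for ``allele_y``; groups outside
    ``scope`` receive genotypes independent of group."""

    locus_id: str
    side_x: tuple[str, ...]
    side_y: tuple[str, ...]
    allele_x: str
    allele_y: str

    @property
    def scope(self) -> frozenset[str]:
        return frozenset(self.side_x) | frozenset(self.side_y)

    def validate(self, groups: Sequence[str]) -> None:
        sx, sy = frozenset(self.side_x), frozenset(self.side_y)
        if not sx or not sy or sx & sy:
            raise InvalidSpecError(
                f"{self.locus_id}: bipartition sides must be disjoint and nonempty"
            )
        if not (sx | sy) <= set(groups):
            raise InvalidSpecError(
                f"{self.locus_id}: bipartition is not a subset of the simulated groups"
            )
        if self.allele_x == self.allele_y:
            raise InvalidSpecError(f"{self.locus_id}: alleles must differ")


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort.

    ``genotype_truth`` holds the biological (pre-observation-noise)
    genotypes; missing-data noise only affects the observed matrix.
    ``call_truth`` maps (sample, marker/locus id) to the genotype state the
    assay should recover.
    """

    sample_to_group: dict[str, str]
    locus_roles: dict[str, object]  # locus -> DiagnosticLocusSpec | "background"
    genotype_truth: dict[tuple[str, str], str]
    call_truth: dict[tuple[str, str], str] = field(default_factory=dict)


def _sample_names(group_sizes: Mapping[str, int]) -> dict[str, list[str]]:
    out = {}
    for group, n in group_sizes.items():
        tag = "".join(ch for ch in group if ch.isalnum()) or "G"
        out[group] = [f"{tag}_{i:03d}" for i in range(1, n + 1)]
    return out


def simulate_genotype_matrix(
    group_sizes: Mapping[str, int],
    n_background_loci: int,
    diagnostic_spec: Sequence[DiagnosticLocusSpec],
    missing_rate: float = 0.0,
    het_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a labelled genotype matrix with planted diagnostic loci.

    ``het_rate`` perturbs the *biological* genotype of in-scope samples at
    diagnostic loci (residual within-group heterozygosity) and is reflected
    in the truth; ``missing_rate`` masks observed calls only. Background
    loci draw a per-locus allele frequency and Hardy-Weinberg genotypes
    shared across groups, so they carry no group signal.
    """
    if not group_sizes or any(n < 1 for n in group_sizes.values()):
        raise InvalidSpecError("every group needs at least one sample")
    if not (0 <= missing_rate < 1 and 0 <= het_rate < 1):
        raise InvalidSpecError("rates must lie in [0, 1)")
    groups = list(group_sizes)
    for spec in diagnostic_spec:
        spec.validate(groups)

    rng = np.random.default_rng(seed)
    names = _sample_names(group_sizes)
    samples = [s for g in groups for s in names[g]]
    sample_group = {s: g for g in groups for s in names[g]}

    locus_ids: list[str] = []
    loci_rows: list[dict] = []
    columns: dict[str, list[str]] = {}
    truth = SimTruth(sample_to_group=sample_group, locus_roles={}, genotype_truth={})

    pos_step = 1000  # spacing leaves clean >50bp flanks on synthetic contigs
    for i, spec in enumerate(diagnostic_spec):
        locus = spec.locus_id
        locus_ids.append(locus)
        loci_rows.append(
            {
                "locus": locus,
                "contig": f"diag_ctg{i + 1:02d}",
                "pos": 500 + pos_step * i,
                "ref": spec.allele_x,
                "alt": spec.allele_y,
            }
        )
        col = []
        hom_x = genotype(spec.allele_x, spec.allele_x)
        hom_y = genotype(spec.allele_y, spec.allele_y)
        het = genotype(spec.allele_x, spec.allele_y)
        for s in samples:
            g = sample_group[s]
            if g in spec.side_x:
                gt = hom_x
            elif g in spec.side_y:
                gt = hom_y
            else:
                gt = (hom_x, het, hom_y)[rng.integers(3)]
            if g in spec.scope and het_rate > 0 and rng.random() < het_rate:
                gt = het
            truth.genotype_truth[(s, locus)] = gt
            truth.call_truth[(s, locus)] = _state(gt, spec.allele_x, spec.allele_y)
            col.append(gt)
        columns[locus] = col
        truth.locus_roles[locus] = spec

    for j in range(n_background_loci):
        locus = f"BG{j + 1:04d}"
        ref, alt = rng.choice(4, size=2, replace=False)
        ref, alt = "ACGT"[ref], "ACGT"[alt]
        locus_ids.append(locus)
        loci_rows.append(
            {
                "locus": locus,
                "contig": f"bg_ctg{j // 50 + 1:02d}",
                "pos": 500 + pos_step * (j % 50),
                "ref": ref,
                "alt": alt,
            }
        )
        p = rng.uniform(0.05, 0.95)  # shared across groups: no group signal
        dose = rng.binomial(2, p, size=len(samples))
        col = []
        for s, d in zip(samples, dose):
            gt = (
                genotype(alt, alt),
                genotype(ref, alt),
                genotype(ref, ref),
            )[d]
            truth.genotype_truth[(s, locus)] = gt
            col.append(gt)
        columns[locus] = col
        truth.locus_roles[locus] = "background"

    calls = pd.DataFrame(columns, index=pd.Index(samples, name="sample"))
    calls = calls[locus_ids]
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns), MISSING)

    loci = pd.DataFrame(loci_rows).set_index("locus")
    matrix = GenotypeMatrix(calls=calls, loci=loci)
    return matrix, truth


def _state(gt: str, allele_x: str, allele_y: str) -> str:
    if is_missing(gt):
        return NO_CALL
    a, b = alleles_of(gt)
    if a == b == allele_x:
        return "XX"
    if a == b == allele_y:
        return "YY"
    if {a, b} == {allele_x, allele_y}:
        return "XY"
    return NO_CALL


def apply_allelic_dropout(
    matrix: GenotypeMatrix, dropout_rate: float, seed: int = 0
) -> GenotypeMatrix:
    """Convert each heterozygous call to a random homozygote with the given
    probability (emulating allele loss at low read depth); homozygous and
    missing calls pass through unchanged."""
    if not (0 <= dropout_rate <= 1):
        raise InvalidSpecError("dropout_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    for locus in calls.columns:
        col = calls[locus].to_numpy(copy=True)
        for i, gt in enumerate(col):
            if is_het(gt) and rng.random() < dropout_rate:
                a, b = alleles_of(gt)
                kept = a if rng.random() < 0.5 else b
                col[i] = genotype(kept, kept)
        calls[locus] = col
    return GenotypeMatrix(calls=calls, loci=matrix.loci.copy())


# ---------------------------------------------------------------------------
# Fluorescence plates
# ---------------------------------------------------------------------------


def _well_name(index: int) -> tuple[int, str]:
    """Sequential well index -> (plate number, row-major 96-well coordinate)."""
    plate, slot = divmod(index, 96)
    row, col = divmod(slot, 12)
    return plate + 1, f"{string.ascii_uppercase[row]}{col + 1}"


def simulate_plate(
    panel: PanelDefinition,
    truth: SimTruth,
    cluster_params: Optional[Mapping[str, tuple[float, float]]] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_ntc: int = 2,
    seed: int = 0,
    markers: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate endpoint FAM/HEX plates for every (sample, marker) pair.

    Sample wells are placed on the polar ray of their true genotype state
    (theta from ``cluster_params``, magnitude lognormal around the state's
    mean) with additive Gaussian axis noise; NTC wells sit near the origin.
    The pre-read baseline is ``PRE_READ_FRACTION`` of the post-read signal.
    Wells whose truth state is ``no_call`` are rendered as NTC-level signal
    (failed amplification). One 96-well plate per marker, with ``n_ntc``
    no-template controls per plate; cohorts larger than a plate continue on
    further plates, each with its own NTCs.
    """
    if n_ntc < 1:
        raise InvalidSpecError("need at least one NTC well per plate")
    params = dict(DEFAULT_CLUSTER_PARAMS)
    if cluster_params:
        params.update(cluster_params)
    for state in ("XX", "XY", "YY"):
        if state not in params:
            raise InvalidSpecError(f"cluster_params must define {state}")

    marker_ids = list(markers) if markers is not None else list(panel.markers)
    for m in marker_ids:
        if m not in panel.markers:
            raise InvalidSpecError(f"marker {m} not in panel {panel.name}")
    truth_markers = {m for (_, m) in truth.call_truth}
    for m in truth_markers:
        if m not in panel.markers and markers is None:
            raise InvalidSpecError(f"truth references marker {m} absent from panel")

    rng = np.random.default_rng(seed)
    samples = list(truth.sample_to_group)
    mean_mag = float(np.mean([params[s][1] for s in ("XX", "XY", "YY")]))
    rows: list[dict] = []
    for marker_id in marker_ids:
        per_plate = 96 - n_ntc
        n_plates = max(1, math.ceil(len(samples) / per_plate))
        idx = 0
        for p in range(n_plates):
            chunk = samples[p * per_plate : (p + 1) * per_plate]
            plate_id = f"{marker_id}-P{p + 1}"
            wells_here = [(s, "sample") for s in chunk] + [("", "NTC")] * n_ntc
            for s, role in wells_here:
                _, well = _well_name(idx % 96)
                idx += 1
                if role == "NTC":
                    fam, hx = _ntc_signal(rng, mean_mag, noise_sd)
                else:
                    state = truth.call_truth.get((s, marker_id), NO_CALL)
                    if state == NO_CALL:
                        fam, hx = _ntc_signal(rng, mean_mag, noise_sd)
                    else:
                        theta_deg, mag_mean = params[state]
                        mag = mag_mean * rng.lognormal(0.0, LOGNORMAL_SIGMA if noise_sd > 0 else 0.0)
                        th = math.radians(theta_deg)
                        fam = mag * math.cos(th) + rng.normal(0.0, noise_sd)
                        hx = mag * math.sin(th) + rng.normal(0.0, noise_sd)
                fam, hx = max(fam, 0.0), max(hx, 0.0)
                fam_pre = PRE_READ_FRACTION * fam
                hex_pre = PRE_READ_FRACTION * hx
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "role": role,
                        "marker": marker_id,
                        "sample": s,
                        "fam_pre": fam_pre,
                        "fam_post": fam_pre + fam,
                        "hex_pre": hex_pre,
                        "hex_post": hex_pre + hx,
                    }
                )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def _ntc_signal(rng: np.random.Generator, mean_mag: float, noise_sd: float) -> tuple[float, float]:
    mag = abs(
        rng.normal(NTC_MAG_FRACTION * mean_mag, NTC_MAG_SD_FRACTION * mean_mag)
        if noise_sd > 0
        else NTC_MAG_FRACTION * mean_mag
    )
    th = math.radians(rng.uniform(0.0, 90.0))
    return mag * math.cos(th), mag * math.sin(th)


# ---------------------------------------------------------------------------
# Matrix / plate / truth serialisation
# ---------------------------------------------------------------------------


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str, "marker": str})
    df["sample"] = df["sample"].fillna("").astype(str)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    return df[PLATE_COLUMNS]


def write_matrix_tsv(matrix: GenotypeMatrix, calls_path, loci_path) -> None:
    matrix.calls.to_csv(calls_path, sep="\t")
    matrix.loci.to_csv(loci_path, sep="\t")


def read_matrix_tsv(calls_path, loci_path) -> GenotypeMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
    from .core import parse_genotype

    calls = calls.apply(lambda col: col.map(parse_genotype))
    loci = pd.read_csv(loci_path, sep="\t", index_col=0, dtype={"contig": str, "ref": str, "alt": str})
    loci["pos"] = loci["pos"].astype(int)
    return GenotypeMatrix(calls=calls, loci=loci)


def write_matrix_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal biallelic-SNP VCF (GT-only)."""
    loci = matrix.loci.sort_values(["contig", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(loci["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for locus, row in loci.iterrows():
            ref, alt = row["ref"], row["alt"]
            fields = [row["contig"], str(int(row["pos"])), str(locus), ref, alt, ".", "PASS", ".", "GT"]
            for s in matrix.sample_ids:
                gt = matrix.calls.at[s, locus]
                if is_missing(gt):
                    fields.append("./.")
                else:
                    a, b = alleles_of(gt)
                    idx = sorted(("0" if x == ref else "1") for x in (a, b))
                    fields.append("/".join(idx))
            fh.write("\t".join(fields) + "\n")


def truth_to_json(truth: SimTruth) -> dict:
    return {
        "sample_to_group": truth.sample_to_group,
        "locus_roles": {
            k: (
                "background"
                if v == "background"
                else {
                    "side_x": list(v.side_x),
                    "side_y": list(v.side_y),
                    "allele_x": v.allele_x,
                    "allele_y": v.allele_y,
                }
            )
            for k, v in truth.locus_roles.items()
        },
        "genotype_truth": {f"{s}|{l}": gt for (s, l), gt in truth.genotype_truth.items()},
        "call_truth": {f"{s}|{m}": st for (s, m), st in truth.call_truth.items()},
    }
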