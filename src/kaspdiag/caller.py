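"""Endpoint-fluorescence genotype calling for KASP plates.

The published workflow scores cluster plots by eye and keeps "only samples
in distinct clusters"; no algorithm exists to replicate, so this module
implements a deterministic, auditable analogue:

1. background-subtract each well (post-read minus pre-read, floored at 0)
   and convert to polar coordinates (theta from the FAM axis in degrees,
   magnitude = Euclidean norm);
2. NTC gate: sample wells whose magnitude does not exceed
   ``ntc_factor * (mean NTC magnitude + ntc_sd_mult * NTC SD)`` are
   ``no_call("low signal")`` — amplification failures;
3. fixed theta bands assign states: XX [0, 30), XY [30, 60], YY (60, 90]
   (absolute bands, not cluster ranks, so plates showing only one or two
   genotype classes are still called correctly);
4. cluster-quality gate: thetas of the surviving wells are clustered in
   one dimension with k in {1, 2, 3}, k chosen by mean silhouette; wells
   with silhouette below ``quality_threshold``, or lying within
   ``band_margin`` degrees of a band boundary while their cluster mean sits
   in a different band, are ``no_call("ambiguous cluster")``.

NTC wells are never genotyped; a fluorescing NTC surfaces as a QC warning.
All thresholds are relative, so calls are invariant to rescaling every
fluorescence value by a common positive factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .core import NO_CALL, GenotypeCall

BAND_LOW = 30.0  # XX | XY boundary (degrees)
BAND_HIGH = 60.0  # XY | YY boundary (degrees)

CALLS_COLUMNS = [
    "plate",
    "well",
    "sample",
    "marker",
    "state",
    "theta",
    "magnitude",
    "quality",
    "reason",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds for plate calling (defaults are the declared
    package defaults, not values inferred from any published analysis)."""

    ntc_factor: float = 2.0
    ntc_sd_mult: float = 3.0
    quality_threshold: float = 0.5
    band_margin: float = 5.0
    split_silhouette: float = 0.6  # below this, wells are one cluster
    allow_ntc_free: bool = False
    absolute_floor: float = 100.0  # used only in NTC-free mode


def normalize_well(fam_pre: float, fam_post: float, hex_pre: float, hex_post: float) -> tuple[float, float]:
    """Background-subtracted (FAM, HEX) signal, floored at zero."""
    for v in (fam_pre, fam_post, hex_pre, hex_post):
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"negative or non-finite fluorescence value: {v}")
    return max(0.0, fam_post - fam_pre), max(0.0, hex_post - hex_pre)


def polar_transform(fam: float, hex_: float) -> tuple[float, float]:
    """(theta degrees from FAM axis, magnitude). theta is NaN at (0, 0)."""
    mag = math.hypot(fam, hex_)
    if mag == 0.0:
        return float("nan"), 0.0
    return math.degrees(math.atan2(hex_, fam)), mag


def _band(theta: float) -> str:
    if theta < BAND_LOW:
        return "XX"
    if theta <= BAND_HIGH:
        return "XY"
    return "YY"


def _cluster_thetas(thetas: np.ndarray, params: CallerParams) -> tuple[np.ndarray, np.ndarray]:
    """1-D clustering of well angles; returns (labels, per-well silhouette).

    k is selected among {1, 2, 3} by mean silhouette; if the best k >= 2
    scores below ``split_silhouette`` the wells are treated as a single
    cluster, whose per-well quality is distance-to-centre based (1 at the
    cluster mean, 0 at 45 degrees away)."""
    n = len(thetas)
    x = thetas.reshape(-1, 1)
    best = None  # (mean silhouette, labels, samples)
    for k in (2, 3):
        if n <= k or len(np.unique(thetas)) < k:
            continue
        init = np.percentile(thetas, np.linspace(100 / (2 * k), 100 - 100 / (2 * k), k)).reshape(-1, 1)
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=100)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if best is None or score > best[0]:
            best = (score, labels, silhouette_samples(x, labels))
    if best is None or best[0] < params.split_silhouette:
        centre = float(np.mean(thetas))
        quality = np.clip(1.0 - np.abs(thetas - centre) / 45.0, -1.0, 1.0)
        return np.zeros(n, dtype=int), quality
    return best[1], best[2]


def call_plate(
    wells: pd.DataFrame,
    params: CallerParams = CallerParams(),
) -> tuple[dict[tuple[str, str], GenotypeCall], list[str]]:
    """Call every sample well of one plate x marker group.

    ``wells`` uses the plate CSV schema (plate_id, well, role, marker,
    sample, fam_pre, fam_post, hex_pre, hex_post). Returns a map
    (plate_id, well) -> GenotypeCall for sample wells, plus QC warnings.
    """
    ntc = wells[wells["role"] == "NTC"]
    samples = wells[wells["role"] == "sample"]
    sig = {
        idx: polar_transform(*normalize_well(r.fam_pre, r.fam_post, r.hex_pre, r.hex_post))
        for idx, r in wells.iterrows()
    }
    if len(ntc) == 0:
        if not params.allow_ntc_free:
            raise ValueError("plate has no NTC wells (enable NTC-free mode to override)")
        gate = params.absolute_floor
        ntc_mags = np.array([])
    else:
        ntc_mags = np.array([sig[i][1] for i in ntc.index])
        gate = params.ntc_factor * (ntc_mags.mean() + params.ntc_sd_mult * ntc_mags.std())

    warnings_out: list[str] = []
    calls: dict[tuple[str, str], GenotypeCall] = {}
    if len(samples) == 0:
        return calls, warnings_out

    sample_mags = np.array([sig[i][1] for i in samples.index])
    if len(ntc_mags) and len(sample_mags) and ntc_mags.max() > 0.5 * np.median(sample_mags):
        plate_id = wells["plate_id"].iloc[0]
        warnings_out.append(f"{plate_id}: NTC fluorescence approaches sample signal (contamination?)")

    passing_idx = []
    for i, row in samples.iterrows():
        theta, mag = sig[i]
        if mag <= gate or math.isnan(theta):
            calls[(row.plate_id, row.well)] = GenotypeCall(
                state=NO_CALL, theta=theta, magnitude=mag, quality=float("nan"), reason="low signal"
            )
        else:
            passing_idx.append(i)

    if passing_idx:
        thetas = np.array([sig[i][0] for i in passing_idx])
        labels, quality = _cluster_thetas(thetas, params)
        cluster_means = {lab: float(thetas[labels == lab].mean()) for lab in np.unique(labels)}
        for j, i in enumerate(passing_idx):
            row = samples.loc[i]
            theta, mag = sig[i]
            state = _band(theta)
            q = float(quality[j])
            reason = ""
            if q < params.quality_threshold:
                state, reason = NO_CALL, "ambiguous cluster"
            else:
                near_boundary = min(abs(theta - BAND_LOW), abs(theta - BAND_HIGH)) < params.band_margin
                if near_boundary and _band(cluster_means[labels[j]]) != _band(theta):
                    state, reason = NO_CALL, "ambiguous cluster"
            calls[(row.plate_id, row.well)] = GenotypeCall(
                state=state, theta=theta, magnitude=mag, quality=q, reason=reason
            )
    return calls, warnings_out


def call_plates(
    plates: pd.DataFrame,
    params: CallerParams = CallerParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Call every (plate, marker) group of a plate table; returns the calls
    table (sample wells only; NTCs are never genotyped) and QC warnings."""
    rows: list[dict] = []
    warnings_out: list[str] = []
    for (plate_id, marker), group in plates.groupby(["plate_id", "marker"], sort=True):
        calls, warns = call_plate(group, params)
        warnings_out.extend(warns)
        sample_rows = group[group["role"] == "sample"]
        for _, r in sample_rows.iterrows():
            c = calls[(r.plate_id, r.well)]
            rows.append(
                {
                    "plate": plate_id,
                    "well": r.well,
                    "sample": r["sample"],
                    "marker": marker,
                    "state": c.state,
                    "theta": c.theta,
                    "magnitude": c.magnitude,
                    "quality": c.quality,
                    "reason": c.reason,
                }
            )
    return pd.DataFrame(rows, columns=CALLS_COLUMNS), warnings_out


def write_calls_csv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False, float_format="%.6g")


def read_calls_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "marker": str})
    df["sample"] = df["sample"].fillna("").astype(str)
    df["reason"] = df["reason"].fillna("").astype(str)
    return df


def render_cluster_plot(plates: pd.DataFrame, calls: pd.DataFrame, marker: str, path) -> None:
    """FAM-vs-HEX scatter for one marker, coloured by called state (a
    facsimile of the instrument's cluster plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = plates[plates["marker"] == marker]
    call_map = {
        (r.plate, r.well): r.state for r in calls[calls["marker"] == marker].itertuples()
    }
    colors = {"XX": "tab:blue", "XY": "tab:purple", "YY": "tab:red", NO_CALL: "0.6", "NTC": "olive"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for _, r in sub.iterrows():
        fam, hex_ = normalize_well(r.fam_pre, r.fam_post, r.hex_pre, r.hex_post)
        key = "NTC" if r.role == "NTC" else call_map.get((r.plate_id, r.well), NO_CALL)
        ax.scatter(fam, hex_, c=colors.get(key, "0.6"), s=18)
    ax.set_xlabel("FAM (allele X)")
    ax.set_ylabel("HEX (allele Y)")
    ax.set_title(marker)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
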