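"""Endpoint-fluorescence KASP genotype calling.

Kompetitive allele-specific PCR reads out as two endpoint dye signals per
well (FAM for allele 1, HEX for allele 2).  Homozygotes light one channel,
heterozygotes both, and failed wells or no-template controls stay near the
baseline.  The caller normalizes against the NTC centroid, discards
low-magnitude wells as no-calls, clusters the rest in polar coordinates
(angle carries the genotype, magnitude the amplification strength), and
labels clusters by their angular position between the FAM and HEX axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

GENOTYPE_ORDER = ["hom1", "het", "hom2"]
#: reference angles of the three genotype classes in (FAM, HEX) space
_REF_ANGLES = {"hom1": 0.0, "het": np.pi / 4, "hom2": np.pi / 2}


@dataclass
class GenotypeCalls:
    calls: pd.Series                 # sample -> hom1/het/hom2/no_call
    cluster_centers: pd.DataFrame    # label, theta, magnitude
    confidence: pd.Series            # distance-ratio confidence per sample
    marker: str | None = None
    metadata: dict = field(default_factory=dict)

    def genotype_strings(self, allele1: str, allele2: str) -> pd.Series:
        """Map class labels to allele strings, e.g. CC / CT / TT."""
        mapping = {
            "hom1": allele1 + allele1,
            "het": allele1 + allele2,
            "hom2": allele2 + allele2,
            "no_call": "NA",
        }
        return self.calls.map(mapping)


def call_genotypes(
    plate: pd.DataFrame,
    seed: int = 0,
    tau: float = 0.25,
    merge_angle: float = 0.2,
    marker: str | None = None,
) -> GenotypeCalls:
    """Cluster endpoint (FAM, HEX) signals into genotype calls.

    Steps: subtract the NTC centroid (floored at zero); flag wells whose
    signal magnitude falls below ``tau`` times the median non-NTC magnitude
    as no-calls; k-means (k = 3, 20 seeded restarts) on (angle, normalized
    magnitude); merge clusters closer than ``merge_angle`` radians (a
    genotype class absent from the plate would otherwise be split); label
    clusters by nearest reference angle (FAM axis = allele-1 homozygote,
    diagonal = heterozygote, HEX axis = allele-2 homozygote).  The whole
    procedure is invariant to a common positive scaling of the raw signals.
    """
    required = {"sample", "FAM", "HEX", "is_ntc"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    data = plate.loc[~plate["is_ntc"].astype(bool)].copy()
    if len(data) < 6:
        raise ValueError("need at least 6 non-NTC wells to form clusters")
    ntc = plate.loc[plate["is_ntc"].astype(bool)]
    baseline = (
        ntc[["FAM", "HEX"]].mean().to_numpy() if len(ntc) else np.zeros(2)
    )
    sig = np.maximum(data[["FAM", "HEX"]].to_numpy(dtype=float) - baseline, 0.0)
    mag = np.hypot(sig[:, 0], sig[:, 1])
    med = np.median(mag)
    callable_mask = mag >= tau * med
    if not callable_mask.any():
        warnings.warn("all wells below magnitude threshold; no calls made",
                      stacklevel=2)
        calls = pd.Series("no_call", index=data["sample"])
        return GenotypeCalls(
            calls=calls, cluster_centers=pd.DataFrame(),
            confidence=pd.Series(0.0, index=data["sample"]), marker=marker,
            metadata={"normalization": "ntc-centroid-subtracted", "tau": tau},
        )
    theta = np.arctan2(sig[:, 1], sig[:, 0])
    norm_mag = mag / med
    feats = np.column_stack([theta, norm_mag])[callable_mask]

    k = min(3, len(np.unique(np.round(feats[:, 0], 6))))
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(feats)
    labels = km.labels_
    centers = km.cluster_centers_

    # merge clusters with nearly identical angle: an absent genotype class
    # makes k-means split a true cluster in two
    order = np.argsort(centers[:, 0])
    remap = {}
    groups: list[list[int]] = []
    for c in order:
        if groups and abs(centers[c, 0] - centers[groups[-1][-1], 0]) < merge_angle:
            groups[-1].append(c)
        else:
            groups.append([c])
    for gi, members in enumerate(groups):
        for c in members:
            remap[c] = gi
    merged_labels = np.array([remap[c] for c in labels])
    group_theta = [
        float(np.mean(feats[np.isin(merged_labels, gi), 0])) for gi in range(len(groups))
    ]

    # assign genotype names by nearest reference angle; fall back to angle
    # order if two groups collide on the same reference
    names = [min(_REF_ANGLES, key=lambda g: abs(_REF_ANGLES[g] - th)) for th in group_theta]
    if len(set(names)) != len(names):
        ordered = [g for g in GENOTYPE_ORDER]
        if len(groups) == 2:
            names = ["hom1", "hom2"]
        else:
            names = ordered[: len(groups)]

    calls_arr = np.full(len(data), "no_call", dtype=object)
    conf = np.zeros(len(data))
    callable_idx = np.where(callable_mask)[0]
    for row, lab in zip(callable_idx, merged_labels):
        calls_arr[row] = names[lab]
        d = [abs(theta[row] - t) for t in group_theta]
        d_sorted = sorted(d)
        conf[row] = (
            1.0 if len(d_sorted) == 1 or d_sorted[1] == 0
            else 1.0 - d_sorted[0] / d_sorted[1]
        )
    centers_df = pd.DataFrame(
        {
            "label": names,
            "theta": group_theta,
            "magnitude": [
                float(np.mean(feats[np.isin(merged_labels, gi), 1]))
                for gi in range(len(groups))
            ],
        }
    )
    return GenotypeCalls(
        calls=pd.Series(calls_arr, index=data["sample"], name="call"),
        cluster_centers=centers_df,
        confidence=pd.Series(conf, index=data["sample"], name="confidence"),
        marker=marker,
        metadata={"normalization": "ntc-centroid-subtracted", "tau": tau,
                  "k_used": len(groups)},
    )


def concordance(calls: GenotypeCalls, expected: pd.Series | dict) -> dict:
    """Call rate, agreement over called wells, and a confusion table."""
    exp = pd.Series(expected)
    if exp.empty:
        raise ValueError("expected genotype map is empty")
    common = calls.calls.index.intersection(exp.index)
    if len(common) == 0:
        raise ValueError("no overlap between called and expected samples")
    got = calls.calls.loc[common]
    truth = exp.loc[common]
    called = got != "no_call"
    call_rate = float(called.mean())
    agree = float((got[called] == truth[called]).mean()) if called.any() else np.nan
    confusion = pd.crosstab(truth, got, rownames=["expected"], colnames=["called"])
    return {
        "n": int(len(common)),
        "call_rate": call_rate,
        "agreement": agree,
        "confusion": confusion,
    }
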