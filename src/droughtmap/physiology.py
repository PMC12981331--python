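"""Assay arithmetic for drought-stress physiology panels.

Covers malondialdehyde (MDA) from thiobarbituric-acid absorbances, leaf
relative water content (RWC), chlorophyll/carotenoid concentrations from the
classic three-wavelength spectrophotometric forms, water-use efficiency, the
pre/post-stress adverse-change table that feeds the composite drought index,
and qPCR relative expression (2^-dCt / 2^-ddCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eleven physiological indicators, in canonical column order.
TRAITS = [
    "Pn", "Trmmol", "Cond", "WUE", "FvFm", "MDA",
    "RWC", "Chla", "Chlb", "Chl", "Car",
]

#: Adverse-change sign per trait: +1 when a decline under stress is adverse
#: (the change mean_pre - mean_post is the adverse magnitude), -1 when an
#: increase is adverse (MDA, a membrane-damage marker, accumulates under
#: stress).  Pigments rose in most accessions of a diverse panel, so their
#: direction is data, not logic: pass a modified table to flip them.
DEFAULT_DIRECTIONS = {t: (-1 if t == "MDA" else +1) for t in TRAITS}


def mda_content(A532: float, A600: float, W: float) -> float:
    """MDA (nmol/g fresh weight) = 51.6 * (A532 - A600) / W.

    A532 carries the MDA-TBA adduct signal; A600 corrects for turbidity.
    """
    if W <= 0:
        raise ValueError(f"fresh weight must be positive, got {W}")
    return 51.6 * (A532 - A600) / W


def relative_water_content(W0: float, Wd: float) -> float:
    """Leaf RWC (%) = (W0 - Wd) / W0 * 100 from fresh and dry weight."""
    if Wd <= 0 or W0 <= 0:
        raise ValueError("weights must be positive")
    if Wd > W0:
        raise ValueError(f"dry weight {Wd} exceeds fresh weight {W0}")
    return (W0 - Wd) / W0 * 100.0


def pigment_concentrations(A470: float, A649: float, A665: float) -> tuple[float, float, float]:
    """Chlorophyll a/b and carotenoid concentration (mg/L) in the extract.

        Ca = 13.95*A665 - 6.88*A649
        Cb = 24.96*A649 - 7.32*A665
        Cc = (1000*A470 - 2.05*Ca - 114.8*Cb) / 245

    The linear forms can return negative values for unusual absorbance
    combinations; these are kept (the forms are used as printed) but warned
    about, since they normally indicate a blank or dilution problem.
    """
    if min(A470, A649, A665) < 0:
        raise ValueError("absorbances must be non-negative")
    Ca = 13.95 * A665 - 6.88 * A649
    Cb = 24.96 * A649 - 7.32 * A665
    Cc = (1000.0 * A470 - 2.05 * Ca - 114.8 * Cb) / 245.0
    if Ca < 0 or Cb < 0 or Cc < 0:
        warnings.warn(
            "negative pigment concentration computed; check blanks/dilution",
            stacklevel=2,
        )
    return Ca, Cb, Cc


def pigment_content_fw(C: float, V: float, W: float) -> float:
    """Convert extract concentration (mg/L) to tissue content (mg/g FW).

    content = C * V / (W * 1000) with V the extract volume in ml and W the
    fresh weight in g.
    """
    if W <= 0 or V <= 0:
        raise ValueError("volume and weight must be positive")
    return C * V / (W * 1000.0)


def water_use_efficiency(Pn: float, Trmmol: float) -> float:
    """WUE = Pn / Trmmol (umol CO2 per mmol H2O)."""
    if Trmmol <= 0:
        raise ValueError(f"transpiration rate must be positive, got {Trmmol}")
    return Pn / Trmmol


def relative_expression(
    Ct_target: float,
    Ct_ref: float,
    Ct_target_cal: float | None = None,
    Ct_ref_cal: float | None = None,
) -> float:
    """qPCR relative expression by 2^-dCt, or 2^-ddCt when a calibrator is given."""
    dct = Ct_target - Ct_ref
    if Ct_target_cal is None:
        return float(2.0 ** (-dct))
    if Ct_ref_cal is None:
        raise ValueError("calibrator requires both target and reference Ct")
    ddct = dct - (Ct_target_cal - Ct_ref_cal)
    return float(2.0 ** (-ddct))


@dataclass
class TraitChangeTable:
    """Per-accession adverse-change magnitudes for the 11 indicators.

    ``values`` has one row per accession and one column per trait; entry
    (i, j) is s_j * (mean_pre - mean_post) for accession i and trait j,
    where s_j comes from the direction table, so a larger value always
    means a larger *adverse* response to stress.
    """

    values: pd.DataFrame
    directions: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    excluded: list[str] = field(default_factory=list)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)


def trait_changes(
    panel: pd.DataFrame,
    directions: dict[str, int] | None = None,
    aggregate: str = "mean",
) -> TraitChangeTable:
    """Collapse a pre/post replicate panel into adverse-change magnitudes.

    ``panel`` must have columns ``accession``, ``phase`` (``pre``/``post``),
    optionally ``replicate``, plus the trait columns.  Replicates are
    averaged (or median-pooled) within accession x phase first; the change
    for trait j is then s_j * (mean_pre - mean_post).  Accessions missing a
    phase are excluded and reported rather than silently dropped.
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    traits = [t for t in TRAITS if t in panel.columns]
    if not traits:
        raise ValueError("panel contains none of the expected trait columns")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    pooled = panel.groupby(["accession", "phase"])[traits].agg(aggregate)

    rows, excluded = {}, []
    for acc in panel["accession"].unique():
        try:
            pre = pooled.loc[(acc, "pre")]
            post = pooled.loc[(acc, "post")]
        except KeyError:
            excluded.append(str(acc))
            continue
        s = np.array([directions[t] for t in traits], dtype=float)
        rows[acc] = s * (pre.to_numpy(dtype=float) - post.to_numpy(dtype=float))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=traits)
    return TraitChangeTable(values=values, directions=directions, excluded=excluded)
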