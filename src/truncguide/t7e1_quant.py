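"""T7 endonuclease I (T7E1) indel quantification.

In the T7E1 assay a PCR amplicon spanning the cut site is denatured and
reannealed; duplexes pairing a wildtype strand with an indel-bearing strand
form mismatched heteroduplexes that T7E1 cleaves.  With indel allele
fraction x, the heteroduplex (cleaved) fraction under random reannealing is
f_c = 1 − (1 − x)² (a wildtype/wildtype duplex requires both strands
wildtype... more precisely homoduplex fraction = x² + (1−x)², but the
convention used here and standard in the field drops the rare
indel/indel-matched term), giving the inversion

    % indel = 100 × (1 − sqrt(1 − f_c)).

Band intensities from the gel give f_c = Σcleaved / (uncleaved + Σcleaved).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "T7E1Measurement",
    "fraction_cleaved",
    "indel_percent",
    "invert_indel_percent",
    "call_detection",
    "quantify_bands_table",
    "DEFAULT_ND_THRESHOLD",
]

#: Default detection threshold (% indel) below which a site is called ND.
DEFAULT_ND_THRESHOLD = 2.0

#: Ceiling applied to noisy simulated cleavage fractions before conversion.
FC_CLAMP = 0.999999


def fraction_cleaved(uncut: float, cut: Sequence[float]) -> float:
    """Cleaved fraction from band intensities: Σcut / (uncut + Σcut).

    Returns 1.0 (with a warning) when the uncut band is absent — the indel
    conversion formula is undefined there.
    """
    cut = list(cut)
    if uncut < 0 or any(c < 0 for c in cut):
        raise ValueError("band intensities must be nonnegative")
    total = uncut + sum(cut)
    if total <= 0:
        raise ValueError("all band intensities are zero")
    fc = sum(cut) / total
    if fc >= 1.0:
        warnings.warn(
            "no uncut band: fraction cleaved = 1, outside the domain of the "
            "indel conversion",
            stacklevel=2,
        )
    return fc


def indel_percent(f_c: float) -> float:
    """% indel = 100 × (1 − sqrt(1 − f_c)), for f_c in [0, 1)."""
    if not (0.0 <= f_c < 1.0):
        raise ValueError(f"fraction cleaved {f_c} outside [0, 1)")
    return 100.0 * (1.0 - math.sqrt(1.0 - f_c))


def invert_indel_percent(p: float) -> float:
    """Cleaved fraction implied by an indel percentage: f_c = 1 − (1 − p/100)²."""
    if not (0.0 <= p < 100.0):
        raise ValueError(f"indel percent {p} outside [0, 100)")
    return 1.0 - (1.0 - p / 100.0) ** 2


def call_detection(p: float, threshold: float = DEFAULT_ND_THRESHOLD) -> str:
    """'detected' if p ≥ threshold else 'ND' (closed lower bound)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return "detected" if p >= threshold else "ND"


@dataclass(frozen=True)
class T7E1Measurement:
    """One quantified T7E1 lane: band intensities → f_c → % indel."""

    site_id: str
    uncut_intensity: float
    cut_intensities: tuple[float, ...]
    fraction_cleaved: float
    indel_percent: float
    detected: bool

    @classmethod
    def from_bands(
        cls,
        site_id: str,
        uncut: float,
        cuts: Sequence[float],
        nd_threshold: float = DEFAULT_ND_THRESHOLD,
    ) -> "T7E1Measurement":
        fc = fraction_cleaved(uncut, cuts)
        p = indel_percent(min(fc, FC_CLAMP) if fc >= 1.0 else fc)
        return cls(
            site_id=site_id,
            uncut_intensity=float(uncut),
            cut_intensities=tuple(float(c) for c in cuts),
            fraction_cleaved=fc,
            indel_percent=p,
            detected=call_detection(p, nd_threshold) == "detected",
        )

    @classmethod
    def from_fraction(
        cls,
        site_id: str,
        f_c: float,
        nd_threshold: float = DEFAULT_ND_THRESHOLD,
        *,
        clamp: bool = False,
    ) -> "T7E1Measurement":
        """Build directly from a cleaved fraction.  ``clamp`` tolerates
        simulated values that exceed 1 numerically; real inputs ≥ 1 raise."""
        if clamp:
            f_c = min(max(f_c, 0.0), FC_CLAMP)
        p = indel_percent(f_c)
        return cls(
            site_id=site_id,
            uncut_intensity=float("nan"),
            cut_intensities=(),
            fraction_cleaved=f_c,
            indel_percent=p,
            detected=call_detection(p, nd_threshold) == "detected",
        )

    def report_value(self) -> str:
        """Table-style cell: the indel percentage, or ND below threshold."""
        return f"{self.indel_percent:.2f}" if self.detected else "ND"


def quantify_bands_table(
    bands: pd.DataFrame, nd_threshold: float = DEFAULT_ND_THRESHOLD
) -> pd.DataFrame:
    """Quantify a table of band intensities.

    Expects columns ``site_id``, ``uncut`` and one or more ``cut*`` columns;
    returns site_id, fraction_cleaved, indel_percent and the ND call.
    """
    cut_cols = [c for c in bands.columns if c.startswith("cut")]
    if not cut_cols:
        raise ValueError("no cut* intensity columns found")
    rows = []
    for _, r in bands.iterrows():
        cuts = [float(r[c]) for c in cut_cols if pd.notna(r[c])]
        m = T7E1Measurement.from_bands(str(r["site_id"]), float(r["uncut"]), cuts, nd_threshold)
        rows.append(
            {
                "site_id": m.site_id,
                "fraction_cleaved": m.fraction_cleaved,
                "indel_percent": m.indel_percent,
                "call": m.report_value(),
            }
        )
    return pd.DataFrame(rows)
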