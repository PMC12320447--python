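"""Balanced-translocation frequency from droplet digital PCR counts.

Each well reports FAM-positive droplets (translocation junction assay) and
HEX-positive droplets (single-copy reference gene, RPP30).  The
translocation frequency is the FAM count normalized to the HEX count,
expressed as a percentage.  A Poisson mode is also provided: at higher
droplet occupancy the positive-droplet count under-represents the number of
template molecules, and the per-channel concentration lambda = -ln(1 - k/N)
corrects for droplets that received more than one template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class DdpcrWell:
    fam_positive: int
    hex_positive: int
    total_droplets: int
    well_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.fam_positive <= self.total_droplets:
            raise ValueError("FAM count outside [0, total droplets]")
        if not 0 <= self.hex_positive <= self.total_droplets:
            raise ValueError("HEX count outside [0, total droplets]")


def _poisson_lambda(k: int, total: int) -> float:
    if k >= total:
        raise ValueError("channel saturated: every droplet positive")
    return -math.log(1.0 - k / total)


def translocation_frequency(well: DdpcrWell, mode: str = "naive") -> float:
    """Percentage of alleles carrying the balanced translocation.

    ``naive``: 100 * FAM+/HEX+ (the ratio of positive droplet counts).
    ``poisson``: 100 * lambda_FAM/lambda_HEX with lambda = -ln(1 - k/N).
    The two agree as occupancy goes to 0; naive never exceeds poisson.
    """
    if well.hex_positive == 0:
        raise ValueError("reference (HEX) channel has no positive droplets")
    if mode == "naive":
        return 100.0 * well.fam_positive / well.hex_positive
    if mode == "poisson":
        lam_fam = _poisson_lambda(well.fam_positive, well.total_droplets)
        lam_hex = _poisson_lambda(well.hex_positive, well.total_droplets)
        return 100.0 * lam_fam / lam_hex
    raise ValueError(f"unknown mode {mode!r}")


def analyze_wells(wells: pd.DataFrame, mode: str = "naive") -> pd.DataFrame:
    """TSV-level interface: columns well_id, fam_positive, hex_positive,
    total_droplets → same table with a translocation_pct column."""
    out = wells.copy()
    out["translocation_pct"] = [
        translocation_frequency(
            DdpcrWell(
                fam_positive=int(r.fam_positive),
                hex_positive=int(r.hex_positive),
                total_droplets=int(r.total_droplets),
                well_id=str(getattr(r, "well_id", "")),
            ),
            mode=mode,
        )
        for r in wells.itertuples(index=False)
    ]
    return out
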