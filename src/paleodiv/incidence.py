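"""Strata: occurrence multisets and distinct-taxon assemblages.

A *stratum* is the slice of the dataset for one (group, interval) pair,
optionally restricted to a region and, for corals, to one ecology
(zooxanthellate / azooxanthellate).  Its occurrence list is the sampling
universe for rarefaction; its assemblage (the set of distinct taxon names)
carries the raw richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import INTERVALS, REGIONS, OccurrenceDataset


@dataclass(frozen=True)
class StratumKey:
    group: str
    interval: str
    region: str | None = None       # None = whole Mediterranean
    coral_ecology: str | None = None  # None/'all' = all ecologies

    def label(self) -> str:
        parts = [self.group, self.interval]
        if self.region:
            parts.append(self.region)
        if self.coral_ecology and self.coral_ecology != "all":
            parts.append(self.coral_ecology)
        return "/".join(parts)


@dataclass
class Stratum:
    """Occurrences and assemblage of one dataset slice.

    ``taxa`` has one entry per occurrence (taxon names, duplicates across
    localities retained — they are distinct occurrences).
    """

    key: StratumKey
    taxa: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = np.asarray(self.taxa, dtype=object)

    @property
    def n_occurrences(self) -> int:
        return int(self.taxa.size)

    @property
    def assemblage(self) -> frozenset:
        return frozenset(self.taxa.tolist())

    @property
    def richness_raw(self) -> int:
        return len(self.assemblage)

    @property
    def is_empty(self) -> bool:
        return self.taxa.size == 0


def build_stratum(
    ds: OccurrenceDataset,
    group: str,
    interval: str,
    region: str | None = None,
    coral_ecology: str | None = None,
) -> Stratum:
    """Extract the stratum for a (group, interval[, region][, ecology]) key.

    Only non-reworked occurrences enter a stratum.  For corals,
    ``coral_ecology=None`` or ``'all'`` keeps every record (z, az and
    unresolved); ``'z'``/``'az'`` keep only the matching attribution.
    An empty stratum is returned (not an error) so callers can flag it.
    """
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval {interval!r}")
    if region is not None and region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    df = ds.frame
    mask = (df["group"] == group) & (df["interval"] == interval) & (~df["reworked"])
    if region is not None:
        mask &= df["region"] == region
    if coral_ecology not in (None, "all"):
        if group != "corals":
            raise ValueError("coral_ecology filter is only valid for corals")
        if coral_ecology not in ("z", "az"):
            raise ValueError(f"unknown coral ecology {coral_ecology!r}")
        mask &= df["coral_ecology"] == coral_ecology
    key = StratumKey(group, interval, region, coral_ecology)
    return Stratum(key, df.loc[mask, "taxon_name"].to_numpy(dtype=object))


def build_interval_strata(
    ds: OccurrenceDataset,
    group: str,
    intervals: Sequence[str] = INTERVALS,
    region: str | None = None,
    coral_ecology: str | None = None,
) -> list[Stratum]:
    """One stratum per interval, in the given (stratigraphic) order."""
    return [
        build_stratum(ds, group, iv, region=region, coral_ecology=coral_ecology)
        for iv in intervals
    ]


def stratum_table(strata: Iterable[Stratum]) -> pd.DataFrame:
    """Summaries (key, n_occurrences, richness_raw) as a DataFrame."""
    rows = []
    for s in strata:
        rows.append(
            {
                "group": s.key.group,
                "interval": s.key.interval,
                "region": s.key.region or "all",
                "coral_ecology": s.key.coral_ecology or "all",
                "n_occurrences": s.n_occurrences,
                "richness_raw": s.richness_raw,
            }
        )
    return pd.DataFrame(rows)
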