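"""Reading, validating, filtering and writing fossil-occurrence tables.

An *occurrence* is the unique combination of a taxon found at a specific
locality within one time interval.  Tables are delimited text (CSV/TSV) with
one row per occurrence and, at minimum, columns mappable onto the canonical
schema below.  Loading validates every row, rejects records from outside the
three analysis intervals (the evaporitic crisis interval is excluded by
design), collapses duplicate (taxon, locality, interval) rows within a group
to a single occurrence, and records a machine-readable validation report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("paleodiv")

# --------------------------------------------------------------------------
# Controlled vocabularies

#: The three analysis intervals, in stratigraphic order.
INTERVALS: tuple[str, ...] = (
    "tortonian",
    "messinian_pre_evaporitic",
    "zanclean",
)

#: Short labels used in report tables and figures.
INTERVAL_LABELS: Mapping[str, str] = {
    "tortonian": "T",
    "messinian_pre_evaporitic": "M",
    "zanclean": "Z",
}

#: The three Mediterranean regions distinguished by the analysis.
REGIONS: tuple[str, ...] = (
    "western_mediterranean",
    "eastern_mediterranean",
    "po_adriatic",
)

#: The 13 organism groups the schema recognises.
GROUPS: tuple[str, ...] = (
    "calcareous_nannoplankton",
    "dinocysts",
    "planktic_foraminifera",
    "benthic_foraminifera",
    "ostracods",
    "corals",
    "bivalves",
    "gastropods",
    "bryozoans",
    "echinoids",
    "bony_fishes",
    "sharks",
    "marine_mammals",
)

#: Groups loaded and validated but excluded from statistical operations by
#: default (too few determinable specimens for per-group statistics).
NOT_ANALYZED_GROUPS: tuple[str, ...] = ("sharks", "marine_mammals")

RANKS: tuple[str, ...] = ("species", "genus", "indeterminate")

#: Coral ecology attribution.  ``unresolved`` is legal only for corals whose
#: genus contains both zooxanthellate and azooxanthellate species and whose
#: record carries no per-record attribution; ``not_applicable`` is mandatory
#: for every non-coral record.
CORAL_ECOLOGIES: tuple[str, ...] = ("z", "az", "unresolved", "not_applicable")

#: Minimum number of occurrences for a stratum to be statistically evaluable.
EVALUABILITY_FLOOR: int = 15

CANONICAL_COLUMNS: tuple[str, ...] = (
    "taxon_name",
    "rank",
    "genus",
    "group",
    "locality_id",
    "region",
    "interval",
    "reworked",
    "coral_ecology",
)

#: Columns that must be present (possibly via a column map); ``genus``,
#: ``rank``, ``reworked`` and ``coral_ecology`` get defaults when absent.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "taxon_name",
    "group",
    "locality_id",
    "region",
    "interval",
)

_INTERVAL_ALIASES = {
    "tortonian": "tortonian",
    "t": "tortonian",
    "messinian_pre_evaporitic": "messinian_pre_evaporitic",
    "pre-evaporitic messinian": "messinian_pre_evaporitic",
    "pre_evaporitic_messinian": "messinian_pre_evaporitic",
    "preevaporitic messinian": "messinian_pre_evaporitic",
    "messinian (pre-evaporitic)": "messinian_pre_evaporitic",
    "messinian": "messinian_pre_evaporitic",
    "m": "messinian_pre_evaporitic",
    "zanclean": "zanclean",
    "z": "zanclean",
}

_REGION_ALIASES = {
    "western_mediterranean": "western_mediterranean",
    "western mediterranean": "western_mediterranean",
    "west": "western_mediterranean",
    "wmed": "western_mediterranean",
    "w": "western_mediterranean",
    "eastern_mediterranean": "eastern_mediterranean",
    "eastern mediterranean": "eastern_mediterranean",
    "east": "eastern_mediterranean",
    "emed": "eastern_mediterranean",
    "e": "eastern_mediterranean",
    "po_adriatic": "po_adriatic",
    "po plain-northern adriatic": "po_adriatic",
    "po plain - northern adriatic": "po_adriatic",
    "po plain–northern adriatic": "po_adriatic",
    "po": "po_adriatic",
}

_GROUP_ALIASES = {g: g for g in GROUPS}
_GROUP_ALIASES.update(
    {
        "calcareous nannoplankton": "calcareous_nannoplankton",
        "nannoplankton": "calcareous_nannoplankton",
        "dinoflagellate cysts": "dinocysts",
        "planktic foraminifera": "planktic_foraminifera",
        "planktonic foraminifera": "planktic_foraminifera",
        "benthic foraminifera": "benthic_foraminifera",
        "bony fishes": "bony_fishes",
        "fishes": "bony_fishes",
        "marine mammals": "marine_mammals",
    }
)

_RANK_ALIASES = {
    "species": "species",
    "sp": "species",
    "genus": "genus",
    "gen": "genus",
    "indeterminate": "indeterminate",
    "indet": "indeterminate",
    "": "species",
}

_ECOLOGY_ALIASES = {
    "z": "z",
    "zoox": "z",
    "zooxanthellate": "z",
    "az": "az",
    "azoox": "az",
    "azooxanthellate": "az",
    "unresolved": "unresolved",
    "not_applicable": "not_applicable",
    "na": "not_applicable",
    "": "not_applicable",
}

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}

#: Interval spellings that are recognised as the excluded crisis interval, so
#: the error message can say *why* the row is rejected rather than just
#: "unknown interval".
_EXCLUDED_INTERVAL_HINTS = ("msc", "evaporit", "lago mare", "lago-mare")


class ValidationError(ValueError):
    """Raised when an occurrence table fails validation.

    Attributes
    ----------
    report : dict
        Machine-readable description of every problem found.
    """

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


# --------------------------------------------------------------------------
# Dataset container


@dataclass
class OccurrenceDataset:
    """A validated, deduplicated collection of fossil occurrences.

    ``frame`` holds one row per occurrence with the canonical columns of
    :data:`CANONICAL_COLUMNS`.  Within a group, (taxon_name, locality_id,
    interval) triples are unique — each such triple is ONE occurrence.
    """

    frame: pd.DataFrame
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> pd.DataFrame:
        return self.frame

    def counts(
        self, by: Sequence[str] = ("group", "interval", "region")
    ) -> pd.Series:
        """Occurrence tallies per stratum (default: group × interval × region)."""
        return self.frame.groupby(list(by), observed=True).size()

    # -- filters ------------------------------------------------------------

    def filter_reworked(self) -> "OccurrenceDataset":
        """Drop occurrences flagged as reworked (redeposited fossils).

        Idempotent; the number of removed records is logged and recorded in
        ``meta['n_reworked_removed']``.
        """
        keep = ~self.frame["reworked"]
        removed = int((~keep).sum())
        if removed:
            logger.info("filter_reworked: removed %d reworked occurrences", removed)
        meta = dict(self.meta)
        meta["n_reworked_removed"] = meta.get("n_reworked_removed", 0) + removed
        return OccurrenceDataset(self.frame.loc[keep], self.source_label, meta)

    def aggregate_to_genus(self) -> "OccurrenceDataset":
        """Collapse the dataset to genus level.

        taxon_name is replaced by the genus, occurrences are re-deduplicated
        on (group, genus, locality, interval) and rank is set to ``genus``.
        Indeterminate-rank records without a genus are dropped (logged);
        species-rank records without a genus are a hard error.
        """
        df = self.frame.copy()
        no_genus = df["genus"] == ""
        bad = no_genus & (df["rank"] == "species")
        if bad.any():
            raise ValidationError(
                f"aggregate_to_genus: {int(bad.sum())} species-rank records "
                f"lack a genus (rows {list(df.index[bad][:10])})"
            )
        dropped = no_genus & (df["rank"] == "indeterminate")
        if dropped.any():
            logger.info(
                "aggregate_to_genus: dropped %d indeterminate records without genus",
                int(dropped.sum()),
            )
        df = df.loc[~no_genus].copy()
        df["taxon_name"] = df["genus"]
        df["rank"] = "genus"
        df, n_dup = _deduplicate(df)
        meta = dict(self.meta)
        meta["level"] = "genus"
        meta["n_indeterminate_dropped"] = int(dropped.sum())
        meta["n_genus_duplicates_collapsed"] = n_dup
        return OccurrenceDataset(df, self.source_label, meta)

    # -- output -------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the canonical dialect: UTF-8 CSV with the canonical columns."""
        out = self.frame.loc[:, list(CANONICAL_COLUMNS)].copy()
        out["reworked"] = out["reworked"].map({True: "true", False: "false"})
        out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Reading and validation


def _normalize_column(
    values: pd.Series,
    aliases: Mapping[str, str],
    colname: str,
    errors: list[dict],
    extra_hint: Sequence[str] = (),
) -> pd.Series:
    cleaned = values.str.strip().str.lower()
    mapped = cleaned.map(aliases)
    bad = mapped.isna()
    if bad.any():
        for idx, raw in values[bad].items():
            msg = f"unknown {colname} value {raw!r}"
            low = str(raw).strip().lower()
            if any(h in low for h in extra_hint):
                msg = (
                    f"{colname} value {raw!r} falls in the excluded salinity-"
                    "crisis interval; only the three analysis intervals are "
                    "accepted"
                )
            errors.append({"row": int(idx), "column": colname, "error": msg})
    return mapped


def _parse_bool(values: pd.Series, colname: str, errors: list[dict]) -> pd.Series:
    cleaned = values.str.strip().str.lower()
    out = pd.Series(pd.NA, index=values.index, dtype="object")
    out[cleaned.isin(_TRUE)] = True
    out[cleaned.isin(_FALSE)] = False
    bad = out.isna()
    for idx, raw in values[bad].items():
        errors.append(
            {"row": int(idx), "column": colname, "error": f"not a boolean: {raw!r}"}
        )
    return out


def _deduplicate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate (group, taxon, locality, interval) rows.

    When duplicate rows disagree on the reworked flag, the non-reworked copy
    wins: at least one record of the occurrence is in place.
    """
    key = ["group", "taxon_name", "locality_id", "interval"]
    before = len(df)
    df = df.sort_values("reworked", kind="stable")  # False first
    df = df.drop_duplicates(subset=key, keep="first")
    df = df.sort_index().reset_index(drop=True)
    return df, before - len(df)


def validate_frame(
    raw: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    source_label: str = "",
) -> OccurrenceDataset:
    """Validate a raw occurrence table and build an :class:`OccurrenceDataset`.

    Parameters
    ----------
    raw : DataFrame
        One row per occurrence record, string-typed.
    column_map : mapping, optional
        Maps source header names to canonical column names, so arbitrary
        source schemas can be adapted.

    Raises
    ------
    ValidationError
        On a missing mandatory column, an empty table, or any row-level
        problem (unknown interval/region/group, empty taxon name, species
        without genus, coral-ecology inconsistencies).  The exception's
        ``report`` lists every offending row.
    """
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    raw = raw.copy()
    raw.columns = [str(c).strip().lower() for c in raw.columns]

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(
            f"missing mandatory column(s): {', '.join(missing)}",
            {"missing_columns": missing},
        )
    if len(raw) == 0:
        raise ValidationError("empty occurrence table", {"n_rows": 0})

    for col, default in (
        ("rank", "species"),
        ("genus", ""),
        ("reworked", "false"),
        ("coral_ecology", ""),
    ):
        if col not in raw.columns:
            raw[col] = default

    df = pd.DataFrame(index=raw.index)
    errors: list[dict] = []

    str_cols = {c: raw[c].astype(str) for c in CANONICAL_COLUMNS}
    df["taxon_name"] = str_cols["taxon_name"].str.strip()
    df["genus"] = str_cols["genus"].str.strip()
    df["locality_id"] = str_cols["locality_id"].str.strip()
    df["rank"] = _normalize_column(str_cols["rank"], _RANK_ALIASES, "rank", errors)
    df["group"] = _normalize_column(str_cols["group"], _GROUP_ALIASES, "group", errors)
    df["region"] = _normalize_column(
        str_cols["region"], _REGION_ALIASES, "region", errors
    )
    df["interval"] = _normalize_column(
        str_cols["interval"],
        _INTERVAL_ALIASES,
        "interval",
        errors,
        extra_hint=_EXCLUDED_INTERVAL_HINTS,
    )
    df["reworked"] = _parse_bool(str_cols["reworked"], "reworked", errors)
    df["coral_ecology"] = _normalize_column(
        str_cols["coral_ecology"], _ECOLOGY_ALIASES, "coral_ecology", errors
    )

    for idx in df.index[df["taxon_name"] == ""]:
        errors.append({"row": int(idx), "column": "taxon_name", "error": "empty"})
    bad_genus = (df["rank"] == "species") & (df["genus"] == "")
    for idx in df.index[bad_genus.fillna(False)]:
        errors.append(
            {
                "row": int(idx),
                "column": "genus",
                "error": "species-rank record requires a genus",
            }
        )

    is_coral = df["group"] == "corals"
    # non-corals must carry not_applicable; corals must not
    bad_eco = (~is_coral) & df["coral_ecology"].isin(["z", "az", "unresolved"])
    for idx in df.index[bad_eco.fillna(False)]:
        errors.append(
            {
                "row": int(idx),
                "column": "coral_ecology",
                "error": "coral ecology given for a non-coral record",
            }
        )
    df.loc[is_coral.fillna(False) & (df["coral_ecology"] == "not_applicable"),
           "coral_ecology"] = "unresolved"

    if errors:
        preview = "; ".join(
            f"row {e['row']}: {e['error']}" for e in errors[:5]
        )
        raise ValidationError(
            f"{len(errors)} invalid row(s): {preview}"
            + (" …" if len(errors) > 5 else ""),
            {"row_errors": errors},
        )

    df = df.loc[:, list(CANONICAL_COLUMNS)]
    df["reworked"] = df["reworked"].astype(bool)
    df, n_dup = _deduplicate(df)
    if n_dup:
        logger.info("collapsed %d duplicate occurrence rows", n_dup)
    meta = {
        "validation": {
            "n_rows_read": int(len(raw)),
            "n_occurrences": int(len(df)),
            "n_duplicates_collapsed": n_dup,
            "row_errors": [],
        }
    }
    return OccurrenceDataset(df, source_label, meta)


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    source_label: str | None = None,
) -> OccurrenceDataset:
    """Read and validate a delimited occurrence table.

    The delimiter is inferred from the file extension (``.tsv`` → tab,
    otherwise comma) unless ``sep`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return validate_frame(
        raw, column_map=column_map, source_label=source_label or path.name
    )


def write_validation_report(ds: OccurrenceDataset, path: str | Path) -> None:
    """Write the dataset's validation report as JSON."""
    report = dict(ds.meta.get("validation", {}))
    report["source_label"] = ds.source_label
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# Evaluability


def check_evaluability(
    ds: OccurrenceDataset,
    groups: Iterable[str] | None = None,
    intervals: Iterable[str] | None = None,
    region: str | None = None,
    floor: int = EVALUABILITY_FLOOR,
) -> pd.DataFrame:
    """Report which (group, interval) strata clear the occurrence floor.

    Rarefaction cannot meaningfully standardise strata with very few
    occurrences, so strata under ``floor`` occurrences (default 15, boundary
    inclusive: exactly 15 passes) are flagged non-evaluable.  Counts are of
    non-reworked occurrences, within ``region`` when given.

    Returns a DataFrame with columns group, interval, region, n_occurrences,
    evaluable, note.
    """
    ds = ds.filter_reworked()
    df = ds.frame
    if region is not None:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        df = df[df["region"] == region]
    groups = list(groups) if groups is not None else sorted(df["group"].unique())
    intervals = list(intervals) if intervals is not None else list(INTERVALS)

    rows = []
    tallies = df.groupby(["group", "interval"], observed=True).size()
    for g in groups:
        for iv in intervals:
            n = int(tallies.get((g, iv), 0))
            rows.append(
                {
                    "group": g,
                    "interval": iv,
                    "region": region or "all",
                    "n_occurrences": n,
                    "evaluable": n >= floor,
                    "note": "no data" if n == 0 else "",
                }
            )
    return pd.DataFrame(rows)
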