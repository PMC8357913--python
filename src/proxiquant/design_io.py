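"""Experiment designs, PSM-table ingest, and PSM-level filtering.

A TMT experiment is described by an :class:`ExperimentDesign` mapping each
(run, channel) pair to a sample, its condition, and whether it is a pooled
reference channel. PSM-level quantification exported by a search /
quantification tool is read into a flat :class:`pandas.DataFrame` (the "PSM
table") with one row per peptide-spectrum match and one ``intensity_<channel>``
column per reporter channel; :class:`PsmRecord` is the record-level view of a
single row.

Ingest-time quality filters are the standard ones for isobaric reporter
quantification: co-isolation interference at most 70%, search q-value below
1%, and unique (single-accession) peptides only. Protein quantifiability
follows the two-unique-feature rule: a protein is summarised only if it has
at least two distinct unique (peptide, charge) features; proteins carried by
a single high-confidence feature are set aside for descriptive "single-PSM
rescue" reporting rather than inferential testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from proxiquant.errors import SchemaError, ValidationError

__all__ = [
    "ExperimentDesign", "PsmRecord", "QuantifiabilityPartition",
    "PSM_COLUMNS", "NATIVE_DIALECT", "PD_DIALECT",
    "read_design", "read_psm_table", "write_psm_table",
    "filter_psms", "partition_quantifiable",
    "records_from_frame", "frame_from_records", "intensity_columns",
]

DESIGN_COLUMNS = ["run", "channel", "sample", "condition", "replicate", "is_reference"]

#: metadata columns of the canonical PSM table (plus one intensity_<ch> per channel)
PSM_COLUMNS = ["accessions", "is_unique", "peptide", "charge",
               "search_q", "coisolation_pct", "run", "fraction"]

#: identity dialect for tables already in the native schema
NATIVE_DIALECT: dict[str, str] = {
    "columns": {c: c for c in PSM_COLUMNS if c != "is_unique"},
    "channel_prefix": "intensity_",
    "accession_sep": ";",
}  # type: ignore[assignment]

#: Proteome Discoverer-style export headers
PD_DIALECT: dict[str, str] = {
    "columns": {
        "Master Protein Accessions": "accessions",
        "Annotated Sequence": "peptide",
        "Charge": "charge",
        "Percolator q-Value": "search_q",
        "Isolation Interference [%]": "coisolation_pct",
        "Spectrum File": "run",
        "Fraction": "fraction",
    },
    "channel_prefix": "Abundance: ",
    "accession_sep": ";",
}  # type: ignore[assignment]


@dataclass(frozen=True)
class ExperimentDesign:
    """Mapping of (run, channel) to sample, condition and reference status.

    Parameters
    ----------
    table
        One row per TMT channel with columns
        ``run, channel, sample, condition, replicate, is_reference``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        t = self.table
        dup = t.duplicated(subset=["run", "channel"])
        if dup.any():
            pairs = t.loc[dup, ["run", "channel"]].apply(tuple, axis=1).tolist()
            raise ValidationError(f"duplicate (run, channel) pairs in design: {pairs}")
        if t["sample"].duplicated().any():
            dups = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        nonref = t[~t["is_reference"].astype(bool)]
        if (nonref["condition"].astype(str).str.len() == 0).any():
            raise ValidationError("non-reference sample with empty condition")

    @property
    def runs(self) -> list[str]:
        return list(dict.fromkeys(self.table["run"].astype(str)))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"].astype(str))

    @property
    def conditions(self) -> list[str]:
        nonref = self.table[~self.table["is_reference"].astype(bool)]
        return list(dict.fromkeys(nonref["condition"].astype(str)))

    def channels_for_run(self, run: str) -> list[str]:
        sel = self.table[self.table["run"].astype(str) == str(run)]
        return list(sel["channel"].astype(str))

    def sample_for(self, run: str, channel: str) -> str:
        t = self.table
        sel = t[(t["run"].astype(str) == str(run)) & (t["channel"].astype(str) == str(channel))]
        if len(sel) != 1:
            raise ValidationError(f"no unique design entry for ({run}, {channel})")
        return str(sel["sample"].iloc[0])

    def reference_samples(self, run: str | None = None) -> list[str]:
        t = self.table
        sel = t[t["is_reference"].astype(bool)]
        if run is not None:
            sel = sel[sel["run"].astype(str) == str(run)]
        return list(sel["sample"].astype(str))

    def run_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample"].astype(str), self.table["run"].astype(str)))

    def condition_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample"].astype(str), self.table["condition"].astype(str)))

    def require_references(self) -> None:
        """Raise unless every run contains at least one reference channel."""
        for run in self.runs:
            if not self.reference_samples(run):
                raise ValidationError(
                    f"reference normalization requested but run {run!r} has no reference channel"
                )


@dataclass
class PsmRecord:
    """One peptide-spectrum match with per-channel reporter intensities."""

    accessions: list[str]
    peptide: str
    charge: int
    search_q: float
    coisolation_pct: float
    run: str
    intensities: dict[str, float]
    fraction: str | None = None

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValidationError("PsmRecord needs at least one accession")
        if not 0.0 <= self.search_q <= 1.0:
            raise ValidationError(f"search_q {self.search_q} outside [0, 1]")
        if not 0.0 <= self.coisolation_pct <= 100.0:
            raise ValidationError(f"coisolation_pct {self.coisolation_pct} outside [0, 100]")
        if self.charge < 1:
            raise ValidationError(f"charge must be positive, got {self.charge}")

    @property
    def is_unique(self) -> bool:
        return len(self.accessions) == 1


@dataclass
class QuantifiabilityPartition:
    """Disjoint, exhaustive partition of post-filter accessions."""

    quantifiable: set[str]
    single_psm_rescue: set[str]
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.quantifiable, self.single_psm_rescue, set(self.dropped)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError("quantifiability partition sets overlap")

    @property
    def all_accessions(self) -> set[str]:
        return self.quantifiable | self.single_psm_rescue | set(self.dropped)


def read_design(path: str | Path | io.IOBase) -> ExperimentDesign:
    """Read and validate an experiment-design CSV.

    Expected columns: ``run, channel, sample, condition, replicate,
    is_reference``. Duplicate (run, channel) pairs raise a ValidationError.
    """
    df = pd.read_csv(path, dtype={"run": str, "channel": str, "sample": str,
                                  "condition": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"design file missing columns: {missing}")
    df["is_reference"] = df["is_reference"].map(_to_bool)
    return ExperimentDesign(df[DESIGN_COLUMNS].copy())


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "t", "1", "yes", "y"}
    return bool(v)


def intensity_columns(frame: pd.DataFrame) -> list[str]:
    """Names of the reporter-intensity columns of a canonical PSM table."""
    return [c for c in frame.columns if c.startswith("intensity_")]


def read_psm_table(
    path: str | Path | io.IOBase,
    design: ExperimentDesign,
    dialect: Mapping | None = None,
    sep: str = "\t",
    with_report: bool = False,
):
    """Read a PSM quantification export into the canonical PSM table.

    Parameters
    ----------
    path
        TSV/CSV file with one row per PSM.
    design
        Experiment design; every channel referenced by an intensity column
        must appear in the design.
    dialect
        Column-name mapping: ``{"columns": {src: dst}, "channel_prefix": str,
        "accession_sep": str}``. Defaults to the native schema.
    with_report
        Also return a dict of ingest counts (rows read, non-positive
        intensities blanked, unparseable cells).

    Zero or negative reporter intensities are converted to missing: their
    log2 is undefined and they carry no quantitative information.
    """
    dialect = dict(NATIVE_DIALECT if dialect is None else dialect)
    colmap: Mapping[str, str] = dialect["columns"]
    prefix: str = dialect.get("channel_prefix", "intensity_")
    sep_acc: str = dialect.get("accession_sep", ";")

    raw = pd.read_csv(path, sep=sep, dtype=str)
    inv = {src: dst for src, dst in colmap.items() if src in raw.columns}
    required = {"accessions", "peptide", "charge", "search_q", "coisolation_pct", "run"}
    mapped = set(inv.values())
    if not required <= mapped:
        raise SchemaError(f"PSM table missing columns mapping to: {sorted(required - mapped)}")
    out = raw[list(inv)].rename(columns=inv)

    known_channels = {str(c) for c in design.table["channel"].astype(str)}
    chan_cols = [c for c in raw.columns if c.startswith(prefix)]
    unknown = [c for c in chan_cols if c[len(prefix):] not in known_channels]
    if unknown:
        raise SchemaError(f"intensity columns for channels absent from design: {unknown}")

    report = {"rows_read": int(len(raw)), "nonpositive_intensities": 0,
              "unparseable_cells": 0}
    for c in chan_cols:
        vals = pd.to_numeric(raw[c], errors="coerce")
        bad = raw[c].notna() & (raw[c].astype(str).str.strip() != "") & vals.isna()
        report["unparseable_cells"] += int(bad.sum())
        nonpos = vals.notna() & (vals <= 0)
        report["nonpositive_intensities"] += int(nonpos.sum())
        vals[nonpos] = np.nan
        out["intensity_" + c[len(prefix):]] = vals.astype(float)

    out["accessions"] = out["accessions"].astype(str).str.replace(
        f"{sep_acc} ", sep_acc, regex=False).str.strip()
    out["is_unique"] = ~out["accessions"].str.contains(sep_acc, regex=False)
    if sep_acc != ";":
        out["accessions"] = out["accessions"].str.replace(sep_acc, ";", regex=False)
    for col, kind in [("charge", int), ("search_q", float), ("coisolation_pct", float)]:
        out[col] = pd.to_numeric(out[col], errors="raise").astype(kind)
    if (out["search_q"].lt(0) | out["search_q"].gt(1)).any():
        raise ValidationError("search_q outside [0, 1]")
    if (out["coisolation_pct"].lt(0) | out["coisolation_pct"].gt(100)).any():
        raise ValidationError("coisolation_pct outside [0, 100]")
    if "fraction" not in out.columns:
        out["fraction"] = pd.NA
    out = out[PSM_COLUMNS + ["intensity_" + c[len(prefix):] for c in chan_cols]]
    out = out.reset_index(drop=True)
    return (out, report) if with_report else out


def write_psm_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical PSM table as TSV (native dialect)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def filter_psms(
    frame: pd.DataFrame,
    coisolation_max: float = 70.0,
    q_max: float = 0.01,
    unique_only: bool = True,
    with_report: bool = False,
):
    """Apply the standard PSM-level quality filters.

    Retains rows with co-isolation interference ``<= coisolation_max``,
    search q-value strictly ``< q_max`` and, when ``unique_only``, a single
    protein accession. Row order is preserved; an empty result is allowed.
    """
    keep_coiso = frame["coisolation_pct"] <= coisolation_max
    keep_q = frame["search_q"] < q_max
    keep_unique = frame["is_unique"].astype(bool) | (not unique_only)
    keep = keep_coiso & keep_q & keep_unique
    out = frame[keep].reset_index(drop=True)
    if not with_report:
        return out
    report = {
        "rows_in": int(len(frame)),
        "rows_out": int(len(out)),
        "removed_coisolation": int((~keep_coiso).sum()),
        "removed_search_q": int((~keep_q).sum()),
        "removed_shared_peptide": int((~keep_unique).sum()),
    }
    return out, report


def partition_quantifiable(
    frame: pd.DataFrame, min_unique_features: int = 2
) -> QuantifiabilityPartition:
    """Split proteins into quantifiable / single-PSM rescue / dropped.

    A protein is quantifiable when its unique PSMs span at least
    ``min_unique_features`` distinct (peptide, charge) features — two unique
    peptides, or one unique peptide seen at two different charges, both
    qualify. A protein whose unique PSMs collapse to a single feature is set
    aside for descriptive single-PSM rescue. Proteins seen only through
    shared (multi-accession) peptides are dropped.
    """
    uniq = frame[frame["is_unique"].astype(bool)]
    feats = uniq[["accessions", "peptide", "charge"]].drop_duplicates()
    n_features = (feats.groupby("accessions").size()
                  if len(feats) else pd.Series(dtype=int))
    quantifiable = set(n_features[n_features >= min_unique_features].index.astype(str))
    rescue = set(n_features[n_features < min_unique_features].index.astype(str))

    dropped: dict[str, str] = {}
    shared = frame[~frame["is_unique"].astype(bool)]
    for accs in shared["accessions"].astype(str):
        for acc in accs.split(";"):
            if acc and acc not in quantifiable and acc not in rescue:
                dropped[acc] = "no unique PSMs (shared peptides only)"
    return QuantifiabilityPartition(quantifiable, rescue, dropped)


def records_from_frame(frame: pd.DataFrame) -> list[PsmRecord]:
    """Record-level view of a canonical PSM table."""
    chans = [c[len("intensity_"):] for c in intensity_columns(frame)]
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        intens = {ch: d[f"intensity_{ch}"] for ch in chans
                  if not pd.isna(d[f"intensity_{ch}"])}
        frac = d.get("fraction")
        records.append(PsmRecord(
            accessions=str(d["accessions"]).split(";"),
            peptide=str(d["peptide"]),
            charge=int(d["charge"]),
            search_q=float(d["search_q"]),
            coisolation_pct=float(d["coisolation_pct"]),
            run=str(d["run"]),
            fraction=None if pd.isna(frac) else str(frac),
            intensities=intens,
        ))
    return records


def frame_from_records(records: Sequence[PsmRecord],
                       channels: Iterable[str] | None = None) -> pd.DataFrame:
    """Canonical PSM table from a sequence of records."""
    if channels is None:
        seen: dict[str, None] = {}
        for r in records:
            for ch in r.intensities:
                seen.setdefault(ch, None)
        channels = list(seen)
    rows = []
    for r in records:
        row = {
            "accessions": ";".join(r.accessions),
            "is_unique": r.is_unique,
            "peptide": r.peptide,
            "charge": r.charge,
            "search_q": r.search_q,
            "coisolation_pct": r.coisolation_pct,
            "run": r.run,
            "fraction": r.fraction,
        }
        for ch in channels:
            row[f"intensity_{ch}"] = r.intensities.get(ch, np.nan)
        rows.append(row)
    cols = PSM_COLUMNS + [f"intensity_{ch}" for ch in channels]
    return pd.DataFrame(rows, columns=cols)
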