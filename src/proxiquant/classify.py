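"""Two-filter classification of proximity-labeled proteins.

Filter 1 (specificity): a protein is cell-type specific when it is enriched
in Cre-positive construct samples over the Cre-negative control — positive
log2FC with BH q below 5% in the construct-minus-control moderated-t
contrast. Everything else (nonspecific bead binders, endogenously
biotinylated proteins) is discarded as background.

Filter 2 (compartment): among Filter-1 survivors, construct-versus-construct
contrasts assign compartments. In the three-construct design, H2B - NES
calls the nucleus (q < 0.05 and log2FC > 0) and H2B - LCK calls the membrane
(q < 0.05 and log2FC < 0); in the two-compartment design (H2B vs NES only),
proteins failing the nuclear rule fall back to cytosol_nonH2B.

Also here: contaminant-list removal, rank-based / static alternative
cutoffs, and the descriptive single-PSM rescue report for proteins excluded
from inferential testing by the two-feature quantifiability rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from proxiquant.design_io import ExperimentDesign
from proxiquant.errors import ValidationError
from proxiquant.quantnorm import ProteinMatrix, reference_normalize, summarize_proteins

__all__ = [
    "ContaminantList", "read_contaminant_list",
    "filter1_specific", "remove_contaminants", "filter2_compartment",
    "alt_cutoff", "rescue_single_psm",
]

COMPARTMENT_CALL_COLUMNS = ["accession", "compartment", "basis"]


@dataclass
class ContaminantList:
    """Accessions to exclude, each with a provenance tag."""

    accessions: dict[str, str] = field(default_factory=dict)  # accession -> tag
    name: str = "contaminants"

    def __post_init__(self) -> None:
        for acc, tag in self.accessions.items():
            if not tag:
                raise ValidationError(f"contaminant {acc!r} has an empty tag")

    def __len__(self) -> int:
        return len(self.accessions)

    def __contains__(self, acc: str) -> bool:
        return acc in self.accessions


def read_contaminant_list(path: str | Path, name: str | None = None) -> ContaminantList:
    """Read a plain-text contaminant list: one accession per line.

    Lines starting with ``#`` set the provenance tag for subsequent entries
    (e.g. ``#keratin``); blank lines are ignored.
    """
    path = Path(path)
    tag = "unspecified"
    accessions: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            tag = line.lstrip("#").strip() or "unspecified"
            continue
        accessions[line] = tag
    return ContaminantList(accessions, name=name or path.stem)


def _check_contrast(results: pd.DataFrame, expected_control: str | None) -> None:
    if expected_control is None:
        return
    labels = set(results["contrast"].astype(str))
    for lab in labels:
        parts = [p.strip() for p in lab.split(" - ")]
        if len(parts) != 2 or parts[1] != expected_control:
            raise ValidationError(
                f"contrast {lab!r} is not a (construct - {expected_control}) "
                "comparison; refusing to apply the specificity filter")


def filter1_specific(results: pd.DataFrame, q_max: float = 0.05,
                     expected_control: str | None = None,
                     with_report: bool = False):
    """Specificity filter: retain positively enriched, significant proteins.

    ``results`` is a moderated-contrast table for (Cre+ construct) - (Cre-
    control); retained accessions satisfy ``log2FC > 0 and q < q_max``.
    Passing ``expected_control`` guards against feeding the wrong contrast.
    With ``with_report`` also returns per-accession discard reasons.
    """
    _check_contrast(results, expected_control)
    pos = results["log2FC"] > 0
    sig = results["q"] < q_max
    retained = set(results.loc[pos & sig, "accession"].astype(str))
    if not with_report:
        return retained
    reasons = np.where(~pos & ~sig, "not enriched, not significant",
                       np.where(~pos, "wrong direction", "not significant"))
    report = {
        str(a): str(r)
        for a, r in zip(results.loc[~(pos & sig), "accession"], reasons[~(pos & sig)])
    }
    return retained, report


def remove_contaminants(accessions, *lists: ContaminantList,
                        with_report: bool = False):
    """Set-difference contaminant removal with per-tag attribution.

    A removed accession appearing on several lists is attributed to every
    matching (list, tag) pair in the report.
    """
    accs = set(map(str, accessions))
    removed: dict[str, list[str]] = {}
    for lst in lists:
        for acc, tag in lst.accessions.items():
            if acc in accs:
                removed.setdefault(acc, []).append(f"{lst.name}:{tag}")
    retained = accs - set(removed)
    if not with_report:
        return retained
    tag_counts: dict[str, int] = {}
    for tags in removed.values():
        for t in tags:
            tag_counts[t] = tag_counts.get(t, 0) + 1
    report = {"n_removed": len(removed), "by_tag": tag_counts,
              "removed": {a: sorted(t) for a, t in sorted(removed.items())}}
    return retained, report


def filter2_compartment(h2b_vs_nes: pd.DataFrame,
                        h2b_vs_lck: pd.DataFrame | None = None,
                        q_max: float = 0.05) -> pd.DataFrame:
    """Compartment assignment from construct-versus-construct contrasts.

    Three-construct mode (``h2b_vs_lck`` given): nucleus when the H2B - NES
    contrast is significantly positive, membrane when the H2B - LCK contrast
    is significantly negative, else unassigned. The H2B - LCK sign rule
    makes the two calls mutually exclusive; when both nominally fire, the
    membrane (negative H2B - LCK) evidence wins because a genuinely nuclear
    protein cannot be depleted relative to the membrane construct.

    Two-compartment mode (no LCK table): proteins failing the nuclear rule
    are cytosol_nonH2B. Proteins present only in the LCK table are processed
    with that basis alone and flagged.
    """
    nes = h2b_vs_nes.set_index(h2b_vs_nes["accession"].astype(str))
    two_compartment = h2b_vs_lck is None
    lck = (None if two_compartment
           else h2b_vs_lck.set_index(h2b_vs_lck["accession"].astype(str)))

    accs = list(dict.fromkeys(
        list(nes.index) + (list(lck.index) if lck is not None else [])))
    rows = []
    for acc in accs:
        basis = []
        nucleus = membrane = False
        flagged = acc not in nes.index
        if acc in nes.index:
            r = nes.loc[acc]
            basis.append(f"{r['contrast']}: log2FC={r['log2FC']:.4g}, q={r['q']:.4g}")
            nucleus = (r["q"] < q_max) and (r["log2FC"] > 0)
        if lck is not None and acc in lck.index:
            r = lck.loc[acc]
            basis.append(f"{r['contrast']}: log2FC={r['log2FC']:.4g}, q={r['q']:.4g}")
            membrane = (r["q"] < q_max) and (r["log2FC"] < 0)
        if membrane:
            call = "membrane"
        elif nucleus:
            call = "nucleus"
        else:
            call = "cytosol_nonH2B" if two_compartment else "unassigned"
        rows.append({"accession": acc, "compartment": call,
                     "basis": "; ".join(basis), "flagged": flagged})
    return pd.DataFrame(rows, columns=COMPARTMENT_CALL_COLUMNS + ["flagged"])


def alt_cutoff(results: pd.DataFrame, mode: str, k: int | None = None,
               threshold: float | None = None) -> set[str]:
    """Rank-based or static alternative to the q-value cutoff.

    ``mode='rank_top_k'`` returns the top-k accessions by log2FC (ties broken
    by log2FC desc, q asc, accession asc); ``mode='static_log2fc'`` returns
    accessions with log2FC >= threshold (inclusive).
    """
    if mode == "rank_top_k":
        if k is None:
            raise ValidationError("rank_top_k needs k")
        ordered = results.assign(accession=results["accession"].astype(str)).sort_values(
            ["log2FC", "q", "accession"], ascending=[False, True, True],
            kind="stable")
        if k > len(ordered):
            warnings.warn(f"k={k} exceeds table size {len(ordered)}; returning all")
            k = len(ordered)
        return set(ordered["accession"].iloc[:k])
    if mode == "static_log2fc":
        if threshold is None:
            raise ValidationError("static_log2fc needs threshold")
        return set(results.loc[results["log2FC"] >= threshold, "accession"].astype(str))
    raise ValidationError(f"unknown alt_cutoff mode {mode!r}")


def rescue_single_psm(frame: pd.DataFrame, design: ExperimentDesign,
                      rescue: set[str], apply_reference_norm: bool = True,
                      already_log2: bool = False) -> pd.DataFrame:
    """Descriptive per-sample report for single-feature rescued proteins.

    Each rescued protein's reporter values are carried through the same
    summarization and (optionally) reference normalization as the main
    matrix — for a single PSM the median polish is an identity, so these are
    the PSM's own log2 values, batch-corrected. Returns a tidy table with
    one row per protein: per-sample log2 values plus per-condition counts of
    non-missing samples (``n_<condition>``). These proteins stay out of
    inferential testing.
    """
    rescue = set(map(str, rescue))
    if not rescue:
        return pd.DataFrame(columns=["accession"])
    sub = frame[frame["accessions"].astype(str).isin(rescue)
                & frame["is_unique"].astype(bool)]
    pm = summarize_proteins(sub, design, already_log2=already_log2)
    if apply_reference_norm:
        pm = reference_normalize(pm, design)
    cond_of = design.condition_of_sample()
    conds = design.conditions
    out = pm.values.copy()
    out.index.name = "accession"
    for c in conds:
        cols = [s for s in pm.samples if cond_of.get(s) == c]
        out[f"n_{c}"] = pm.values[cols].notna().sum(axis=1).astype(int)
    return out.reset_index()
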