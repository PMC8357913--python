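"""Stratified differential expression, proteogenomics, enrichment and QC.

After compartment assignment, case-control contrasts are re-run separately
within each compartment stratum (each stratum re-estimates its own variance
prior) and significance is flagged by a configurable p- or q-rule. The
proteome is compared to reference transcriptomic differential-expression
sets via Pearson correlation of log2 fold changes, and protein lists are
tested for annotation-set enrichment with the hypergeometric upper tail
against the full identified-protein background. QC statistics mirror common
TMT practice: leading-log-fold-change MDS of samples, per-condition %CV of
log2 abundances, and pairwise replicate Pearson correlation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from proxiquant.design_io import ExperimentDesign
from proxiquant.errors import ParameterError, ValidationError
from proxiquant.modstats import PriorEstimate, bh_adjust, moderated_contrasts
from proxiquant.quantnorm import ProteinMatrix

__all__ = [
    "stratified_de", "merge_transcript_degs", "proteogenomic_correlation",
    "annotation_enrichment", "read_gmt", "qc_mds", "qc_cv",
    "qc_replicate_correlation",
]


def stratified_de(matrix: ProteinMatrix, design: ExperimentDesign,
                  strata: pd.DataFrame, contrast: tuple[str, str],
                  alpha_rule: str = "q", alpha: float = 0.05,
                  prior: PriorEstimate | None = None) -> dict[str, pd.DataFrame]:
    """Moderated contrasts run separately inside each compartment stratum.

    ``strata`` is a compartment-call table (columns ``accession,
    compartment``). Each stratum gets its own moderated-t fit, prior and BH
    adjustment; a ``significant`` flag applies the configured rule
    (``alpha_rule`` of ``"p"`` or ``"q"`` at level ``alpha``) and
    ``direction`` records the log2FC sign. Empty strata yield empty tables.
    """
    if alpha_rule not in {"p", "q"}:
        raise ParameterError(f"alpha_rule must be 'p' or 'q', got {alpha_rule!r}")
    out: dict[str, pd.DataFrame] = {}
    for comp, grp in strata.groupby("compartment"):
        accs = set(grp["accession"].astype(str))
        keep = matrix.values.index.astype(str).isin(accs)
        if not keep.any():
            warnings.warn(f"stratum {comp!r} has no quantified proteins")
            out[str(comp)] = pd.DataFrame()
            continue
        sub = ProteinMatrix(matrix.values[keep], matrix.psm_support[keep],
                            matrix.stage_tag)
        tab = moderated_contrasts(sub, design, contrast, prior=prior)
        stat = tab["p"] if alpha_rule == "p" else tab["q"]
        tab["significant"] = stat < alpha
        tab["direction"] = np.where(tab["log2FC"] > 0, "up", "down")
        out[str(comp)] = tab
    return out


def merge_transcript_degs(tables: list[pd.DataFrame], adj_p_max: float = 0.05,
                          abs_log2fc_min: float = 1.0,
                          mapping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge transcriptomic DEG sources into one non-redundant reference set.

    Each source table has columns ``gene, log2fc, adj_p, source`` (log2fc
    oriented the same way in every source). A gene qualifies from a source
    when ``adj_p < adj_p_max and |log2fc| > abs_log2fc_min``, or
    unconditionally when the source marks cluster membership instead of a
    test (``adj_p`` missing). Duplicates are collapsed by gene symbol,
    keeping all source tags; genes whose direction conflicts across sources
    are kept and flagged. An optional two-column ``mapping`` (gene,
    accession) attaches protein accessions; unmapped genes keep NaN.
    """
    kept = []
    for tab in tables:
        missing = {"gene", "log2fc", "source"} - set(tab.columns)
        if missing:
            raise ValidationError(f"DEG table missing columns {sorted(missing)}")
        t = tab.copy()
        if "adj_p" not in t.columns:
            t["adj_p"] = np.nan
        cluster = t["adj_p"].isna()
        passing = cluster | ((t["adj_p"] < adj_p_max)
                             & (t["log2fc"].abs() > abs_log2fc_min))
        kept.append(t[passing])
    if not kept:
        return pd.DataFrame(columns=["gene", "log2fc", "adj_p", "sources",
                                     "direction_conflict", "accession"])
    allrows = pd.concat(kept, ignore_index=True)
    merged = []
    for gene, grp in allrows.groupby("gene", sort=True):
        signs = set(np.sign(grp["log2fc"].dropna()))
        conflict = len(signs - {0.0}) > 1
        best = grp.iloc[grp["log2fc"].abs().to_numpy().argmax()]
        merged.append({
            "gene": str(gene),
            "log2fc": float(best["log2fc"]),
            "adj_p": best["adj_p"],
            "sources": ",".join(sorted(set(grp["source"].astype(str)))),
            "direction_conflict": bool(conflict),
        })
    out = pd.DataFrame(merged)
    if mapping is not None:
        m = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
        out["accession"] = out["gene"].map(m)
    else:
        out["accession"] = np.nan
    return out


def proteogenomic_correlation(protein_fc: pd.Series,
                              transcript_fc: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation of protein vs transcript log2FC on shared keys.

    Both inputs are indexed by accession (or gene); the correlation is
    computed over the intersection, which must contain at least 3 entries.
    Returns ``(r, two-sided p, n)``.
    """
    shared = protein_fc.dropna().index.intersection(transcript_fc.dropna().index)
    n = len(shared)
    if n < 3:
        raise ValidationError(f"need >= 3 shared entries, got {n}")
    res = stats.pearsonr(protein_fc.loc[shared].astype(float),
                         transcript_fc.loc[shared].astype(float))
    return float(res.statistic), float(res.pvalue), n


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT annotation collection: term -> {description, members}."""
    sets: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {"description": parts[1],
                          "members": set(p for p in parts[2:] if p)}
    return sets


def annotation_enrichment(foreground, background, sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    Terms are intersected with the identified-protein ``background``; for a
    term of size K in a background of size N, with a foreground of size n
    overlapping the term in k proteins, the p value is the hypergeometric
    upper tail P(X >= k) and fold enrichment is (k/n)/(K/N). BH adjustment
    across terms. ``foreground`` must be a non-empty subset of
    ``background``.
    """
    fg = set(map(str, foreground))
    bg = set(map(str, background))
    if not fg:
        raise ValidationError("empty foreground")
    if not fg <= bg:
        raise ValidationError("foreground must be a subset of the background")
    N, n = len(bg), len(fg)
    rows = []
    for term, spec in sets.items():
        members = set(map(str, spec["members"])) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append({"term": term, "description": spec.get("description", ""),
                     "term_size": K, "overlap": k, "fold_enrichment": fold,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "description", "term_size",
                                      "overlap", "fold_enrichment", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out


def qc_mds(matrix: ProteinMatrix, top_n: int = 500) -> pd.DataFrame:
    """Leading-log-fold-change MDS of samples (classical scaling to 2-D).

    Proteins with any missing value are omitted. The distance between two
    samples is the root-mean-square of the ``top_n`` largest absolute log2
    differences for that pair (pairwise top-n selection); coordinates come
    from Torgerson double-centering, with each axis's sign fixed so its
    largest-magnitude coordinate is positive.
    """
    V = matrix.values.dropna(axis=0, how="any").to_numpy(dtype=float)
    samples = matrix.samples
    S = len(samples)
    if S < 3:
        raise ValidationError("MDS needs at least 3 samples")
    if V.shape[0] < 3:
        raise ValidationError("fewer than 3 complete proteins")
    if V.shape[0] < top_n:
        warnings.warn(f"only {V.shape[0]} complete proteins; using all")
        top_n = V.shape[0]
    D = np.zeros((S, S))
    for i in range(S):
        diff = np.abs(V[:, i][:, None] - V[:, i + 1:])
        if diff.shape[1]:
            part = np.partition(diff ** 2, diff.shape[0] - top_n, axis=0)[-top_n:]
            d = np.sqrt(part.mean(axis=0))
            D[i, i + 1:] = d
            D[i + 1:, i] = d
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D ** 2) @ J
    w, U = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    coords = U[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"])


def qc_cv(matrix: ProteinMatrix, design: ExperimentDesign) -> dict[str, dict]:
    """Per-condition %CV of log2 abundances across replicates.

    For each protein and condition with >= 2 observed replicates,
    %CV = 100 * sd / mean of the observed log2 values; proteins with a
    non-positive mean are excluded (the ratio is meaningless there) and
    counted. Returns per condition the %CV values, their mean, and the
    exclusion count; conditions with a single replicate are skipped.
    """
    cond_of = design.condition_of_sample()
    out: dict[str, dict] = {}
    for cond in design.conditions:
        cols = [s for s in matrix.samples if cond_of.get(s) == cond]
        if len(cols) < 2:
            warnings.warn(f"condition {cond!r} has < 2 replicates; skipped")
            continue
        sub = matrix.values[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(sub), axis=1)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            warnings.filterwarnings("ignore", message="Degrees of freedom")
            mean = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
        usable = (n >= 2) & np.isfinite(mean)
        bad_mean = usable & (mean <= 0)
        ok = usable & (mean > 0)
        cvs = 100.0 * sd[ok] / mean[ok]
        out[cond] = {"values": cvs, "mean": float(np.mean(cvs)) if len(cvs) else np.nan,
                     "n_excluded_nonpositive_mean": int(bad_mean.sum())}
    return out


def qc_replicate_correlation(matrix: ProteinMatrix,
                             min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of samples over proteins.

    Pairs sharing fewer than ``min_shared`` observed proteins get NaN.
    The diagonal is exactly 1.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("need at least 2 samples")
    corr = matrix.values.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr
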