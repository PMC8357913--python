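"""Protein summarization (Tukey median polish) and the three normalizations.

PSM-level log2 reporter intensities are summarised to one protein abundance
per sample by a two-way median polish of the PSM x channel matrix, run by
run: the protein's abundance in a channel is the polish's overall effect plus
that channel's column effect. Around the summarization sit three optional
normalizations:

* ``global_peptide_median_normalize`` — align per run x channel median log2
  PSM intensity to the grand median (equalises loading differences; switched
  off when construct-level enrichment differences are themselves the signal);
* ``reference_normalize`` — protein-by-protein between-run (TMT batch)
  correction against the pooled reference channel carried in every plex;
* ``protein_median_normalize`` — align per-sample median protein abundance.

All operations treat missing values as missing (no imputation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from proxiquant.design_io import ExperimentDesign, intensity_columns
from proxiquant.errors import ValidationError

__all__ = [
    "ProteinMatrix", "median_polish", "global_peptide_median_normalize",
    "summarize_protein_medianpolish", "summarize_proteins",
    "reference_normalize", "protein_median_normalize",
]


@dataclass
class ProteinMatrix:
    """Proteins x samples log2 abundance matrix with provenance.

    Attributes
    ----------
    values
        DataFrame indexed by protein accession, one column per sample,
        log2 abundances (NaN = missing).
    psm_support
        DataFrame indexed by accession, one column per run: number of PSM
        rows used in that run's summarization (0 = absent).
    stage_tag
        Label of the last transform applied ("summarized",
        "reference_normalized", ...).
    unanchored
        Boolean DataFrame (accession x run) marking runs left unshifted by
        reference normalization because the protein had no reference value.
    """

    values: pd.DataFrame
    psm_support: pd.DataFrame
    stage_tag: str = "summarized"
    unanchored: pd.DataFrame | None = None

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns.astype(str))

    def copy(self, stage_tag: str | None = None) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(), self.psm_support.copy(),
            stage_tag or self.stage_tag,
            None if self.unanchored is None else self.unanchored.copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the wide abundance TSV plus a JSON sidecar."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="accession",
                           float_format="%.10g")
        sidecar = {
            "stage_tag": self.stage_tag,
            "psm_support": {
                acc: {run: int(v) for run, v in row.items()}
                for acc, row in self.psm_support.to_dict("index").items()
            },
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteinMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="accession")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        support = pd.DataFrame.from_dict(sidecar["psm_support"], orient="index")
        return cls(values, support.reindex(values.index).fillna(0).astype(int),
                   sidecar["stage_tag"])


def _polish_batch(mats: np.ndarray, tol: float, max_iter: int):
    """Median-polish a stack of matrices ``(k, rows, cols)`` jointly.

    Row sweep first; stops when the largest absolute effect update across the
    whole stack drops below ``tol``. Returns (overall, row_effects,
    col_effects, residuals). All-NaN columns yield NaN column effects.
    """
    k, r, c = mats.shape
    t = np.zeros(k)
    re = np.zeros((k, r))
    ce = np.zeros((k, c))
    resid = mats.astype(float).copy()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for _ in range(max_iter):
            rowmed = np.nanmedian(resid, axis=2)
            rowmed = np.where(np.isnan(rowmed), 0.0, rowmed)
            resid -= rowmed[:, :, None]
            re += rowmed
            d_ce = np.nanmedian(ce, axis=1)
            d_ce = np.where(np.isnan(d_ce), 0.0, d_ce)
            t += d_ce
            ce -= d_ce[:, None]

            colmed = np.nanmedian(resid, axis=1)
            resid -= colmed[:, None, :]
            ce += np.where(np.isnan(colmed), np.nan, colmed)
            d_re = np.nanmedian(re, axis=1)
            d_re = np.where(np.isnan(d_re), 0.0, d_re)
            t += d_re
            re -= d_re[:, None]

            delta = max(
                np.max(np.abs(rowmed), initial=0.0),
                np.nanmax(np.abs(colmed), initial=0.0) if not np.all(np.isnan(colmed)) else 0.0,
                np.max(np.abs(d_ce), initial=0.0),
                np.max(np.abs(d_re), initial=0.0),
            )
            if delta < tol:
                break
    return t, re, ce, resid


def median_polish(matrix, tol: float = 1e-4, max_iter: int = 100):
    """Two-way median polish of one matrix (rows x columns, NaN allowed).

    Returns ``(overall, row_effects, col_effects, residuals)`` with
    ``matrix ≈ overall + row_effects[:, None] + col_effects[None, :] +
    residuals``. Even-length medians are midpoints of the two central order
    statistics; convergence is a sweep whose largest effect update is below
    ``tol`` (at most ``max_iter`` sweeps, row sweep first).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("median_polish expects a 2-D matrix")
    t, re, ce, resid = _polish_batch(x[None, :, :], tol, max_iter)
    return t[0], re[0], ce[0], resid[0]


def _log2_intensities(frame: pd.DataFrame, cols: list[str],
                      already_log2: bool) -> np.ndarray:
    x = frame[cols].to_numpy(dtype=float)
    if already_log2:
        return x
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(np.where(x > 0, x, np.nan))
    return out


def global_peptide_median_normalize(
    frame: pd.DataFrame,
    design: ExperimentDesign,
    enabled: bool = True,
) -> pd.DataFrame:
    """Equalise per run x channel median log2 PSM intensity.

    For every (run, channel), the median log2 PSM intensity is shifted to the
    grand median of all run x channel medians; on the raw intensity scale
    this is a per-channel multiplicative rescaling. With ``enabled=False``
    the input is returned unchanged (the setting used when construct-level
    loading differences are biologically meaningful).
    """
    if not enabled:
        return frame
    out = frame.copy()
    medians: list[tuple[str, str, float]] = []
    for run in design.runs:
        mask = out["run"].astype(str) == run
        for ch in design.channels_for_run(run):
            col = f"intensity_{ch}"
            if col not in out.columns:
                continue
            vals = out.loc[mask, col].to_numpy(dtype=float)
            vals = np.where(vals > 0, vals, np.nan)
            if np.all(np.isnan(vals)):
                warnings.warn(f"run {run} channel {ch}: no observed PSM "
                              "intensities; left unshifted")
                continue
            medians.append((run, ch, float(np.nanmedian(np.log2(vals)))))
    if not medians:
        return out
    grand = float(np.median([m for _, _, m in medians]))
    for run, ch, med in medians:
        mask = out["run"].astype(str) == run
        col = f"intensity_{ch}"
        out.loc[mask, col] = out.loc[mask, col] * 2.0 ** (grand - med)
    return out


def summarize_proteins(
    frame: pd.DataFrame,
    design: ExperimentDesign,
    proteins=None,
    tol: float = 1e-4,
    max_iter: int = 100,
    already_log2: bool = False,
) -> ProteinMatrix:
    """Summarise a filtered PSM table to a proteins x samples log2 matrix.

    Per protein and run, all PSM rows (fractions pooled) form a PSM x channel
    matrix of log2 intensities which is median-polished; the abundance in a
    channel is overall + column effect. Channels with no data stay missing,
    and a protein absent from a run is missing in that run's samples.

    Proteins sharing the same PSM-row count within a run are polished as one
    vectorised stack, so the per-protein loop never materialises in Python.
    """
    if proteins is not None:
        proteins = set(map(str, proteins))
        frame = frame[frame["accessions"].astype(str).isin(proteins)]
    acc_all = pd.unique(frame["accessions"].astype(str))
    acc_index = pd.Index(sorted(acc_all), name="accession")
    samples = design.samples
    runs = design.runs
    values = np.full((len(acc_index), len(samples)), np.nan)
    support = np.zeros((len(acc_index), len(runs)), dtype=int)
    sample_pos = {s: j for j, s in enumerate(samples)}
    acc_pos = {a: i for i, a in enumerate(acc_index)}

    for ri, run in enumerate(runs):
        chans = design.channels_for_run(run)
        cols = [f"intensity_{c}" for c in chans]
        cols = [c for c in cols if c in frame.columns]
        chans = [c[len("intensity_"):] for c in cols]
        sub = frame[frame["run"].astype(str) == run]
        if not len(sub) or not cols:
            continue
        X = _log2_intensities(sub, cols, already_log2)
        ok_rows = ~np.all(np.isnan(X), axis=1)
        X = X[ok_rows]
        accs = sub["accessions"].astype(str).to_numpy()[ok_rows]
        if not len(X):
            continue
        codes, uniques = pd.factorize(accs, sort=True)
        order = np.argsort(codes, kind="stable")
        Xs = X[order]
        counts = np.bincount(codes)
        starts = np.concatenate([[0], np.cumsum(counts)])
        col_targets = np.array([sample_pos[design.sample_for(run, c)] for c in chans])
        for k in np.unique(counts):
            gidx = np.where(counts == k)[0]
            row_sel = (starts[gidx][:, None] + np.arange(k)[None, :]).ravel()
            batch = Xs[row_sel].reshape(len(gidx), k, len(chans))
            t, _, ce, _ = _polish_batch(batch, tol, max_iter)
            fitted = t[:, None] + ce
            prot_rows = np.array([acc_pos[uniques[g]] for g in gidx])
            values[prot_rows[:, None], col_targets[None, :]] = fitted
            support[prot_rows, ri] = k

    return ProteinMatrix(
        values=pd.DataFrame(values, index=acc_index, columns=samples),
        psm_support=pd.DataFrame(support, index=acc_index, columns=runs),
        stage_tag="summarized",
    )


def summarize_protein_medianpolish(
    frame: pd.DataFrame, design: ExperimentDesign, accession: str,
    tol: float = 1e-4, max_iter: int = 100, already_log2: bool = False,
) -> dict[str, dict[str, float]]:
    """Median-polish summarization of one protein: run -> channel -> log2.

    Convenience view over :func:`summarize_proteins` restricted to a single
    accession; runs where the protein has no observed PSM are absent.
    """
    pm = summarize_proteins(frame, design, proteins=[accession], tol=tol,
                            max_iter=max_iter, already_log2=already_log2)
    if accession not in pm.values.index:
        return {}
    row = pm.values.loc[accession]
    out: dict[str, dict[str, float]] = {}
    for run in design.runs:
        per_run = {}
        for ch in design.channels_for_run(run):
            s = design.sample_for(run, ch)
            v = row[s]
            if not pd.isna(v):
                per_run[ch] = float(v)
        if per_run:
            out[run] = per_run
    return out


def reference_normalize(matrix: ProteinMatrix, design: ExperimentDesign) -> ProteinMatrix:
    """Protein-by-protein between-run correction using reference channels.

    For each protein, every run is shifted so its mean reference-channel
    abundance equals the protein's grand mean of per-run reference
    abundances (runs where the protein has no reference value are left
    unshifted and flagged in ``unanchored``). Within-run differences between
    channels are untouched, so single-run contrasts are invariant.
    """
    design.require_references()
    runs = design.runs
    samples = matrix.samples
    V = matrix.values.to_numpy(dtype=float).copy()
    run_of = design.run_of_sample()
    run_cols = {r: [j for j, s in enumerate(samples) if run_of.get(s) == r] for r in runs}
    ref_cols = {r: [j for j, s in enumerate(samples)
                    if s in set(design.reference_samples(r))] for r in runs}

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        ref_means = np.column_stack([
            np.nanmean(V[:, ref_cols[r]], axis=1) if ref_cols[r]
            else np.full(V.shape[0], np.nan)
            for r in runs
        ])  # proteins x runs
        grand = np.nanmean(ref_means, axis=1)
    shifts = ref_means - grand[:, None]  # NaN where no reference value

    unanchored = np.zeros_like(ref_means, dtype=bool)
    for ri, r in enumerate(runs):
        cols = run_cols[r]
        s = shifts[:, ri]
        missing = np.isnan(s)
        present = ~np.all(np.isnan(V[:, cols]), axis=1) if cols else np.zeros(len(s), bool)
        unanchored[:, ri] = missing & present
        apply = np.where(missing, 0.0, s)
        V[:, cols] -= apply[:, None]

    out = matrix.copy(stage_tag="reference_normalized")
    out.values = pd.DataFrame(V, index=matrix.values.index, columns=samples)
    out.unanchored = pd.DataFrame(unanchored, index=matrix.values.index, columns=runs)
    return out


def protein_median_normalize(matrix: ProteinMatrix) -> ProteinMatrix:
    """Align every sample's median protein abundance to the common level.

    Subtracts from each sample column (its observed median − the median of
    all column medians); afterwards all column medians are equal. Idempotent.
    A column with no observed values is an error.
    """
    V = matrix.values.to_numpy(dtype=float).copy()
    if V.shape[1] == 0:
        raise ValidationError("matrix has no sample columns")
    empty = np.all(np.isnan(V), axis=0)
    if empty.any():
        bad = [s for s, e in zip(matrix.samples, empty) if e]
        raise ValidationError(f"columns with no observed values: {bad}")
    col_med = np.nanmedian(V, axis=0)
    V -= (col_med - np.median(col_med))[None, :]
    out = matrix.copy(stage_tag="protein_median_normalized")
    out.values = pd.DataFrame(V, index=matrix.values.index, columns=matrix.samples)
    return out
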