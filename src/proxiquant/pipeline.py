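"""Staged pipeline composing ingest, quantification, statistics and calls.

``run_pipeline`` executes the configured stages in order — ingest and PSM
filtering, optional global peptide median normalization, median-polish
summarization, reference normalization, optional protein median
normalization, specificity (Filter 1) contrasts against the Cre-negative
control, contaminant removal, compartment (Filter 2) assignment, stratified
differential expression, single-PSM rescue and QC — writing every result
table plus a JSON manifest (parameters, input digests, per-stage event log)
into a run directory. Re-running with identical config and inputs
reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from proxiquant.classify import (filter1_specific, filter2_compartment,
                                 read_contaminant_list, remove_contaminants,
                                 rescue_single_psm)
from proxiquant.design_io import (NATIVE_DIALECT, PD_DIALECT, filter_psms,
                                  partition_quantifiable, read_design,
                                  read_psm_table)
from proxiquant.downstream import qc_cv, qc_mds, qc_replicate_correlation, stratified_de
from proxiquant.errors import StageError, ValidationError
from proxiquant.modstats import moderated_contrasts
from proxiquant.quantnorm import (global_peptide_median_normalize,
                                  protein_median_normalize, reference_normalize,
                                  summarize_proteins)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DIALECTS = {"native": NATIVE_DIALECT, "proteome_discoverer": PD_DIALECT}


@dataclass
class PipelineConfig:
    """All stage toggles and parameters for one pipeline run.

    ``de_contrasts`` entries are dicts with keys ``case``, ``control`` and
    optional ``stratified`` (bool, default True), ``alpha_rule`` ("p"/"q")
    and ``alpha``.
    """

    design: str
    psms: str
    out_dir: str
    dialect: str = "native"
    coisolation_max: float = 70.0
    search_q_max: float = 0.01
    unique_only: bool = True
    min_unique_features: int = 2
    global_median_normalization: bool = False
    reference_normalization: bool = True
    protein_median_normalization: bool = False
    contaminant_lists: list = field(default_factory=list)
    specificity_control: str | None = "CTRL"
    specificity_cases: list | None = None
    specificity_q_max: float = 0.05
    nucleus_contrast: tuple | None = ("H2B", "NES")
    membrane_contrast: tuple | None = ("H2B", "LCK")
    compartment_q_max: float = 0.05
    de_contrasts: list = field(default_factory=list)
    qc: bool = True
    mds_top_n: int = 500
    seed: int = 0

    def validate(self, design) -> None:
        conds = set(design.conditions)
        referenced = []
        if self.specificity_control is not None:
            referenced.append(self.specificity_control)
            referenced += list(self.specificity_cases
                               or [c for c in conds if c != self.specificity_control])
        for pair in (self.nucleus_contrast, self.membrane_contrast):
            if pair is not None:
                referenced += list(pair)
        for de in self.de_contrasts:
            referenced += [de["case"], de["control"]]
        missing = [c for c in referenced if c not in conds]
        if missing:
            raise ValidationError(
                f"config references conditions absent from the design: {missing}")
        if self.dialect not in DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("nucleus_contrast", "membrane_contrast"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory.

    Any stage error aborts with the stage name and cause (StageError);
    partial outputs are retained alongside an ``INCOMPLETE`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress or aborted\n")
    from proxiquant import __version__ as _version  # deferred: avoids import cycle

    events: list[dict] = []
    manifest = {
        "proxiquant_version": _version,
        "config": dataclasses.asdict(config),
        "inputs": {}, "events": events, "seed": config.seed,
    }

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.time()
                try:
                    r = fn(*a, **kw)
                except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                    events.append({"stage": name, "status": "error", "error": str(exc)})
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                                  default=str))
                    raise StageError(name, exc) from exc
                events.append({"stage": name, "status": "ok",
                               "seconds": round(time.time() - t0, 3)})
                return r
            return wrapped
        return deco

    @stage("ingest")
    def ingest():
        design = read_design(config.design)
        manifest["inputs"]["design"] = _sha256(Path(config.design))
        config.validate(design)
        frame, report = read_psm_table(config.psms, design,
                                       dialect=DIALECTS[config.dialect],
                                       with_report=True)
        manifest["inputs"]["psms"] = _sha256(Path(config.psms))
        filtered, freport = filter_psms(frame, config.coisolation_max,
                                        config.search_q_max, config.unique_only,
                                        with_report=True)
        part = partition_quantifiable(filtered, config.min_unique_features)
        (out / "ingest_report.json").write_text(json.dumps(
            {"read": report, "filter": freport,
             "quantifiable": len(part.quantifiable),
             "single_psm_rescue": len(part.single_psm_rescue),
             "dropped": len(part.dropped)}, indent=1))
        return design, filtered, part

    design, filtered, part = ingest()

    @stage("quantify")
    def quantify():
        frame = global_peptide_median_normalize(
            filtered, design, enabled=config.global_median_normalization)
        pm = summarize_proteins(frame, design, proteins=part.quantifiable)
        if config.reference_normalization:
            pm = reference_normalize(pm, design)
        if config.protein_median_normalization:
            pm = protein_median_normalize(pm)
        pm.to_tsv(out / "protein_matrix.tsv")
        return frame, pm

    norm_frame, pm = quantify()

    retained = set(pm.proteins)
    if config.specificity_control is not None:
        @stage("filter1_specificity")
        def filter1():
            control = config.specificity_control
            cases = config.specificity_cases or [
                c for c in design.conditions if c != control]
            retained_union: set[str] = set()
            for case in cases:
                tab = moderated_contrasts(pm, design, (case, control))
                _write_tsv(tab, out / f"contrast_{case}_vs_{control}.tsv")
                retained_union |= filter1_specific(
                    tab, q_max=config.specificity_q_max, expected_control=control)
            return retained_union
        retained = filter1()

    if config.contaminant_lists:
        @stage("contaminants")
        def contaminants():
            lists = [read_contaminant_list(p) for p in config.contaminant_lists]
            kept, report = remove_contaminants(retained, *lists, with_report=True)
            (out / "contaminant_report.json").write_text(json.dumps(report, indent=1))
            return kept
        retained = contaminants()

    calls = None
    if config.nucleus_contrast is not None:
        @stage("filter2_compartment")
        def filter2():
            keep = pm.values.index.astype(str).isin(retained)
            sub = dataclasses.replace(pm, values=pm.values[keep],
                                      psm_support=pm.psm_support[keep])
            nes_tab = moderated_contrasts(sub, design, tuple(config.nucleus_contrast))
            _write_tsv(nes_tab, out / "contrast_nucleus.tsv")
            lck_tab = None
            if config.membrane_contrast is not None:
                lck_tab = moderated_contrasts(sub, design,
                                              tuple(config.membrane_contrast))
                _write_tsv(lck_tab, out / "contrast_membrane.tsv")
            calls = filter2_compartment(nes_tab, lck_tab,
                                        q_max=config.compartment_q_max)
            _write_tsv(calls, out / "compartment_calls.tsv")
            return calls
        calls = filter2()

    if config.de_contrasts:
        @stage("stratified_de")
        def de_stage():
            for de in config.de_contrasts:
                pair = (de["case"], de["control"])
                rule = de.get("alpha_rule", "q")
                alpha = de.get("alpha", 0.05)
                if de.get("stratified", True) and calls is not None:
                    tabs = stratified_de(pm, design, calls, pair,
                                         alpha_rule=rule, alpha=alpha)
                    for comp, tab in tabs.items():
                        _write_tsv(tab, out / f"de_{de['case']}_vs_{de['control']}_{comp}.tsv")
                else:
                    tab = moderated_contrasts(pm, design, pair)
                    stat = tab["p"] if rule == "p" else tab["q"]
                    tab["significant"] = stat < alpha
                    _write_tsv(tab, out / f"de_{de['case']}_vs_{de['control']}.tsv")
        de_stage()

    @stage("rescue")
    def rescue():
        tab = rescue_single_psm(filtered, design, part.single_psm_rescue,
                                apply_reference_norm=config.reference_normalization)
        _write_tsv(tab, out / "single_psm_rescue.tsv")
    rescue()

    if config.qc:
        @stage("qc")
        def qc():
            summary: dict = {}
            try:
                mds = qc_mds(pm, top_n=config.mds_top_n)
                mds.to_csv(out / "qc_mds.tsv", sep="\t", float_format="%.10g")
            except ValidationError as e:
                summary["mds_skipped"] = str(e)
            cv = qc_cv(pm, design)
            summary["cv_mean_by_condition"] = {
                c: (None if pd.isna(d["mean"]) else round(d["mean"], 4))
                for c, d in cv.items()}
            corr = qc_replicate_correlation(pm)
            corr.to_csv(out / "qc_replicate_correlation.tsv", sep="\t",
                        float_format="%.10g")
            (out / "qc_summary.json").write_text(json.dumps(summary, indent=1))
        qc()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "INCOMPLETE").unlink(missing_ok=True)
    return out
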