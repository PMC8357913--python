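"""Ground-truth-labelled synthetic PSM tables for proximity-labeling TMT.

The generator emulates the statistical structure the analysis assumes, on the
log2 scale where the whole pipeline operates:

    log2 I(protein p, PSM f, run r, channel c) =
        baseline_p + peptide_offset_f + capture(construct(c), p)
        + de(condition(c), p) + batch_r + channel_{r,c} + noise

* Each protein has a compartment mixture over {nucleus, cytosol, membrane}
  drawn from a Dirichlet; a construct (H2B -> nucleus, NES -> cytosol,
  LCK -> membrane) captures ``sum(capture_weights * mixture) + leak`` of it,
  and the capture term is ``enrichment_scale_log2 * log2`` of that fraction.
* Cre-negative control samples see only the leak — except for nonspecific
  bead binders and endogenously biotinylated proteins, which are captured
  equally in every sample (their true Cre+/Cre- difference is zero).
* Reference channels carry the pooled equal-mix average of all study
  samples (linear-scale mean), identical in expectation across runs: the
  basis of protein-by-protein reference normalization.
* Missingness is a deterministic detection floor plus uniform MCAR; PSM
  metadata (charge, search q, co-isolation, shared peptides) is sampled
  independently of intensity and only exercises the ingest filters.

Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from proxiquant.design_io import ExperimentDesign, write_psm_table
from proxiquant.errors import ParameterError

__all__ = [
    "COMPARTMENTS", "TMT10_CHANNELS", "TMT11_CHANNELS",
    "SimParams", "SimTruth",
    "simulate_truth", "simulate_psm_table", "simulate_experiment",
    "simulate_proteogenomic",
    "design_three_construct", "design_two_group", "design_activity",
    "balanced_design", "write_simulation",
]

COMPARTMENTS = ("nucleus", "cytosol", "membrane")
TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131"]
TMT11_CHANNELS = TMT10_CHANNELS + ["131C"]

_DEFAULT_CAPTURE = {
    "H2B": {"nucleus": 1.0, "cytosol": 0.1, "membrane": 0.1},
    "NES": {"nucleus": 0.1, "cytosol": 1.0, "membrane": 0.1},
    "LCK": {"nucleus": 0.1, "cytosol": 0.1, "membrane": 1.0},
}


@dataclass
class SimParams:
    """Generator parameters; defaults are the reference study conditions.

    Distribution specs are tuples: ``("constant", v)``,
    ``("normal", mu, sd)`` for effect sizes; ``("constant", k)``,
    ``("negbin", size, p)`` (shifted by +1) or ``("poisson", lam)``
    (shifted by +1) for PSM counts per protein per run.
    """

    n_proteins: int = 3000
    frac_background_binders: float = 0.10
    frac_endogenous_biotin: float = 0.05
    frac_celltype_de: float = 0.0
    frac_activity_de: float = 0.0
    compartment_mixture_concentration: tuple = (0.05, 0.05, 0.05)
    construct_capture: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_CAPTURE.items()})
    background_leak: float = 0.02
    enrichment_scale_log2: float = 1.0
    effect_size_log2: tuple = ("normal", 0.0, 0.5)
    activity_effect_log2: tuple = ("constant", 0.8)
    celltype_case_conditions: tuple = ()
    activity_case_conditions: tuple = ()
    activity_de_compartment: str | None = None
    condition_construct: dict = field(default_factory=dict)
    psm_count_dist: tuple = ("negbin", 2, 0.5)
    baseline_mean_log2: float = 14.0
    baseline_sd_log2: float = 2.0
    peptide_sd_log2: float = 1.0
    noise_sd_log2: float = 0.25
    batch_sd_log2: float = 0.5
    channel_sd_log2: float = 0.1
    detection_floor_log2: float = 3.0
    mcar_rate: float = 0.02
    frac_fail_coisolation: float = 0.05
    frac_fail_search_q: float = 0.05
    frac_shared_peptide: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_background_binders": self.frac_background_binders,
            "frac_endogenous_biotin": self.frac_endogenous_biotin,
            "frac_celltype_de": self.frac_celltype_de,
            "frac_activity_de": self.frac_activity_de,
            "mcar_rate": self.mcar_rate,
            "frac_fail_coisolation": self.frac_fail_coisolation,
            "frac_fail_search_q": self.frac_fail_search_q,
            "frac_shared_peptide": self.frac_shared_peptide,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_background_binders + self.frac_endogenous_biotin > 1.0:
            raise ParameterError("class fractions sum above 1")
        for name in ("noise_sd_log2", "batch_sd_log2", "channel_sd_log2",
                     "peptide_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if any(a <= 0 for a in self.compartment_mixture_concentration):
            raise ParameterError("Dirichlet concentrations must be positive")
        for cons, w in self.construct_capture.items():
            if any(x < 0 for x in w.values()):
                raise ParameterError(f"negative capture weight for {cons}")
        if self.background_leak < 0:
            raise ParameterError("background_leak must be >= 0")
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


@dataclass
class SimTruth:
    """Per-protein ground truth plus per-run / per-channel nuisance shifts."""

    table: pd.DataFrame            # accession, mix_*, flags, effects, baseline
    batch_shifts: dict | None = None      # run -> shift (log2)
    channel_shifts: dict | None = None    # (run, channel) -> shift (log2)

    @property
    def accessions(self) -> list[str]:
        return list(self.table["accession"])

    def dominant_compartment(self, min_weight: float = 0.5) -> pd.Series:
        """Dominant compartment per protein; 'mixed' below ``min_weight``."""
        mix = self.table[[f"mix_{c}" for c in COMPARTMENTS]].to_numpy()
        arg = mix.argmax(axis=1)
        dom = np.array(COMPARTMENTS, dtype=object)[arg]
        dom[mix.max(axis=1) < min_weight] = "mixed"
        return pd.Series(dom, index=self.table["accession"], name="dominant")


def _construct_of(condition: str, params: SimParams) -> str | None:
    if condition in params.condition_construct:
        return params.condition_construct[condition]
    cu = condition.upper()
    for cons in ("H2B", "NES", "LCK"):
        if cons in cu:
            return cons
    return None  # Cre-negative / control-like: leak only


def _draw_effect(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        return np.full(size, float(spec[1]))
    if kind == "normal":
        return rng.normal(float(spec[1]), float(spec[2]), size)
    raise ParameterError(f"unknown effect-size spec {spec!r}")


def _draw_counts(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        return np.full(size, int(spec[1]))
    if kind == "negbin":
        return 1 + rng.negative_binomial(float(spec[1]), float(spec[2]), size)
    if kind == "poisson":
        return 1 + rng.poisson(float(spec[1]), size)
    raise ParameterError(f"unknown PSM-count spec {spec!r}")


def simulate_truth(params: SimParams) -> SimTruth:
    """Draw per-protein ground truth (deterministic given ``params.seed``).

    Class flags (background binder, endogenous biotin) and the differential
    effects are assigned over a seeded permutation of the protein list, so
    classes are disjoint; DE effects live only on specific (non-background,
    non-endogenous) proteins.
    """
    rng = np.random.default_rng([int(params.seed) % (2 ** 31), 0])
    n = params.n_proteins
    acc = np.array([f"ACC{i + 1:05d}" for i in range(n)])
    mix = rng.dirichlet(params.compartment_mixture_concentration, size=n)
    baseline = rng.normal(params.baseline_mean_log2, params.baseline_sd_log2, n)

    perm = rng.permutation(n)
    n_bg = int(round(params.frac_background_binders * n))
    n_eb = int(round(params.frac_endogenous_biotin * n))
    is_bg = np.zeros(n, bool)
    is_eb = np.zeros(n, bool)
    is_bg[perm[:n_bg]] = True
    is_eb[perm[n_bg:n_bg + n_eb]] = True
    specific = ~(is_bg | is_eb)

    ct_fc = np.zeros(n)
    act_fc = np.zeros(n)
    if params.frac_celltype_de > 0:
        pool = np.flatnonzero(specific)
        k = int(round(params.frac_celltype_de * len(pool)))
        chosen = rng.choice(pool, size=k, replace=False)
        ct_fc[chosen] = _draw_effect(params.effect_size_log2, k, rng)
    if params.frac_activity_de > 0:
        pool = np.flatnonzero(specific)
        if params.activity_de_compartment is not None:
            ci = COMPARTMENTS.index(params.activity_de_compartment)
            dom = (mix.argmax(axis=1) == ci) & (mix.max(axis=1) >= 0.5)
            pool = np.flatnonzero(specific & dom)
        k = int(round(params.frac_activity_de * len(pool)))
        chosen = rng.choice(pool, size=k, replace=False)
        act_fc[chosen] = _draw_effect(params.activity_effect_log2, k, rng)

    table = pd.DataFrame({
        "accession": acc,
        **{f"mix_{c}": mix[:, i] for i, c in enumerate(COMPARTMENTS)},
        "is_background": is_bg,
        "is_endogenous_biotin": is_eb,
        "celltype_log2fc": ct_fc,
        "activity_log2fc": act_fc,
        "baseline_log2": baseline,
    })
    return SimTruth(table=table)


def _condition_effects(truth: SimTruth, design: ExperimentDesign,
                      params: SimParams) -> tuple[list[str], np.ndarray]:
    """Capture + DE term per (protein, condition), log2 scale."""
    t = truth.table
    n = len(t)
    mix = t[[f"mix_{c}" for c in COMPARTMENTS]].to_numpy()
    special = (t["is_background"] | t["is_endogenous_biotin"]).to_numpy()
    conds = design.conditions
    eff = np.zeros((n, len(conds)))
    leak = params.background_leak
    for j, cond in enumerate(conds):
        cons = _construct_of(cond, params)
        if cons is None:
            frac = np.full(n, leak)
        else:
            w = params.construct_capture[cons]
            wvec = np.array([w.get(c, 0.0) for c in COMPARTMENTS])
            frac = mix @ wvec + leak
        frac = np.where(special, 1.0 + leak, frac)
        eff[:, j] = params.enrichment_scale_log2 * np.log2(frac)
        if cond in params.celltype_case_conditions:
            eff[:, j] += t["celltype_log2fc"].to_numpy()
        if cond in params.activity_case_conditions:
            eff[:, j] += t["activity_log2fc"].to_numpy()
    return conds, eff


def simulate_psm_table(truth: SimTruth, design: ExperimentDesign,
                       params: SimParams) -> pd.DataFrame:
    """Generate a canonical PSM table for ``design`` under ``truth``.

    Batch and channel shifts are drawn here (one per run / per run-channel)
    and recorded on ``truth`` for downstream scoring. Reference channels
    carry the linear-scale mean of all non-reference study samples.
    """
    rng = np.random.default_rng([int(params.seed) % (2 ** 31), 1])
    t = truth.table
    n = len(t)
    runs = design.runs
    conds, eff = _condition_effects(truth, design, params)
    cond_idx = {c: j for j, c in enumerate(conds)}
    baseline = t["baseline_log2"].to_numpy()

    batch = {r: rng.normal(0.0, params.batch_sd_log2) for r in runs}
    chan_shift = {}
    for r in runs:
        for ch in design.channels_for_run(r):
            chan_shift[(r, ch)] = rng.normal(0.0, params.channel_sd_log2)
    truth.batch_shifts = batch
    truth.channel_shifts = chan_shift

    # pooled reference: equal-mix linear average over all study samples
    nonref = design.table[~design.table["is_reference"].astype(bool)]
    study_cond_idx = np.array([cond_idx[c] for c in nonref["condition"].astype(str)])
    ref_effect = np.log2(np.mean(2.0 ** eff[:, study_cond_idx], axis=1))

    counts = {r: _draw_counts(params.psm_count_dist, n, rng) for r in runs}
    k_max = int(max(int(c.max()) for c in counts.values()))
    pep_offsets = rng.normal(0.0, params.peptide_sd_log2, (n, k_max))

    all_channels = list(dict.fromkeys(
        ch for r in runs for ch in design.channels_for_run(r)))
    frames = []
    for r in runs:
        k = counts[r]
        prot = np.repeat(np.arange(n), k)
        pep_idx = np.concatenate([np.arange(c) for c in k]).astype(int)
        n_rows = len(prot)
        chans = design.channels_for_run(r)
        is_ref = np.array([design.sample_for(r, ch) in
                           set(design.reference_samples(r)) for ch in chans])
        ch_cond = np.array([
            -1 if is_ref[i] else
            cond_idx[design.condition_of_sample()[design.sample_for(r, ch)]]
            for i, ch in enumerate(chans)])
        sample_part = np.empty((n_rows, len(chans)))
        for i, ch in enumerate(chans):
            if is_ref[i]:
                sample_part[:, i] = ref_effect[prot]
            else:
                sample_part[:, i] = eff[prot, ch_cond[i]]
            sample_part[:, i] += batch[r] + chan_shift[(r, ch)]
        mu = (baseline[prot] + pep_offsets[prot, pep_idx])[:, None] + sample_part
        x = mu + rng.normal(0.0, params.noise_sd_log2, mu.shape)
        x[x < params.detection_floor_log2] = np.nan
        if params.mcar_rate > 0:
            x[rng.random(x.shape) < params.mcar_rate] = np.nan

        charge = rng.choice([2, 3, 4], size=n_rows, p=[0.55, 0.35, 0.10])
        q_fail = rng.random(n_rows) < params.frac_fail_search_q
        search_q = np.where(q_fail, rng.uniform(0.011, 0.05, n_rows),
                            rng.uniform(0.0, 0.009, n_rows))
        co_fail = rng.random(n_rows) < params.frac_fail_coisolation
        coiso = np.where(co_fail, rng.uniform(70.01, 100.0, n_rows),
                         rng.uniform(0.0, 60.0, n_rows))
        shared = rng.random(n_rows) < params.frac_shared_peptide

        accs = t["accession"].to_numpy()[prot].astype(object)
        accs[shared] = accs[shared] + ";XSHARED"
        frame = pd.DataFrame({
            "accessions": accs.astype(str),
            "is_unique": ~shared,
            "peptide": [f"PEP{p + 1:05d}_{j + 1}" for p, j in zip(prot, pep_idx)],
            "charge": charge,
            "search_q": search_q,
            "coisolation_pct": coiso,
            "run": r,
            "fraction": pd.NA,
        })
        for ch in all_channels:
            if ch in chans:
                i = chans.index(ch)
                frame[f"intensity_{ch}"] = 2.0 ** x[:, i]
            else:
                frame[f"intensity_{ch}"] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(params: SimParams, design: ExperimentDesign):
    """Convenience wrapper: draw truth then its PSM table.

    Returns ``(psm_frame, truth)``, both deterministic given the seed.
    """
    truth = simulate_truth(params)
    frame = simulate_psm_table(truth, design, params)
    return frame, truth


def simulate_proteogenomic(n: int, r: float, seed: int,
                           protein_sd: float = 1.0,
                           transcript_sd: float = 1.0) -> pd.DataFrame:
    """Paired protein / transcript log2FC with generating correlation ``r``."""
    if not -1.0 <= r <= 1.0:
        raise ParameterError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    cov = np.array([[protein_sd ** 2, r * protein_sd * transcript_sd],
                    [r * protein_sd * transcript_sd, transcript_sd ** 2]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    return pd.DataFrame({
        "accession": [f"ACC{i + 1:05d}" for i in range(n)],
        "protein_log2fc": xy[:, 0],
        "transcript_log2fc": xy[:, 1],
    })


def balanced_design(condition_sizes: dict[str, int], n_runs: int = 2,
                    ref_per_run: int = 1,
                    channels: list[str] | None = None) -> ExperimentDesign:
    """Round-robin allocation of replicates to runs, plus reference channels.

    Conditions are spread as evenly as possible across runs, emulating a
    randomized multiplex layout while staying deterministic.
    """
    channels = list(TMT10_CHANNELS if channels is None else channels)
    slots: list[list[tuple[str, str, int, bool]]] = [[] for _ in range(n_runs)]
    for ri in range(n_runs):
        for j in range(ref_per_run):
            slots[ri].append((f"Ref_r{ri + 1}_{j + 1}", "Reference", j + 1, True))
    turn = 0
    for cond, size in condition_sizes.items():
        for rep in range(1, size + 1):
            slots[turn % n_runs].append((f"{cond}_{rep}", cond, rep, False))
            turn += 1
    rows = []
    for ri, entries in enumerate(slots):
        if len(entries) > len(channels):
            raise ParameterError(
                f"run {ri + 1} needs {len(entries)} channels, plex has {len(channels)}")
        for (sample, cond, rep, is_ref), ch in zip(entries, channels):
            rows.append({"run": f"run{ri + 1}", "channel": ch, "sample": sample,
                         "condition": cond, "replicate": rep,
                         "is_reference": is_ref})
    return ExperimentDesign(pd.DataFrame(rows))


def design_three_construct(n_per_construct: int = 4, n_ctrl: int = 6) -> ExperimentDesign:
    """Two TMT-10 plexes: CTRL plus H2B / NES / LCK constructs with references.

    The default layout (n = 4 per construct, n = 6 Cre-negative controls, one
    pooled reference per plex) fills 2 x 10 channels.
    """
    return balanced_design(
        {"CTRL": n_ctrl, "H2B": n_per_construct, "NES": n_per_construct,
         "LCK": n_per_construct},
        n_runs=2, ref_per_run=1, channels=TMT10_CHANNELS)


def design_two_group(n_per_group: int = 4, conditions: tuple[str, str] = ("A", "B"),
                     n_runs: int = 2) -> ExperimentDesign:
    """Minimal two-condition design across ``n_runs`` plexes with references."""
    return balanced_design({c: n_per_group for c in conditions},
                           n_runs=n_runs, ref_per_run=1, channels=TMT10_CHANNELS)


def design_activity(n_case: int = 7, n_control: int = 7, n_nes: int = 3,
                    n_ctrl: int = 3) -> ExperimentDesign:
    """Two TMT-11 plexes for a chemogenetic-activation comparison.

    hM3Dq_H2B vs mCherry_H2B nuclear proteomes with NES compartment
    references and Cre-negative controls, one pooled reference per plex.
    """
    return balanced_design(
        {"hM3Dq_H2B": n_case, "mCherry_H2B": n_control, "NES": n_nes,
         "CTRL": n_ctrl},
        n_runs=2, ref_per_run=1, channels=TMT11_CHANNELS)


def write_simulation(out_dir: str | Path, frame: pd.DataFrame, truth: SimTruth,
                     design: ExperimentDesign) -> dict[str, Path]:
    """Write PSM TSV, truth TSV and design CSV into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "psm": out / "psms.tsv",
        "truth": out / "truth.tsv",
        "design": out / "design.csv",
    }
    write_psm_table(frame, paths["psm"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    design.table.to_csv(paths["design"], index=False)
    return paths
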