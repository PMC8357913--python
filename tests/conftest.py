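import numpy as np
import pandas as pd
import pytest

from proxiquant import (ExperimentDesign, SimParams, design_three_construct,
                        design_two_group, simulate_experiment)


@pytest.fixture(scope="session")
def exp1_design() -> ExperimentDesign:
    """Two TMT-10 plexes: CTRL(6) + H2B/NES/LCK(4 each) + one ref per plex."""
    return design_three_construct()


@pytest.fixture(scope="session")
def two_group_design() -> ExperimentDesign:
    return design_two_group(n_per_group=4)


@pytest.fixture(scope="session")
def small_experiment(exp1_design):
    """A 400-protein three-construct experiment with default conditions."""
    params = SimParams(n_proteins=400, seed=11)
    frame, truth = simulate_experiment(params, exp1_design)
    return frame, truth, exp1_design


def make_design(rows) -> ExperimentDesign:
    """Build a design from (run, channel, sample, condition, replicate, is_ref)."""
    return ExperimentDesign(pd.DataFrame(
        rows, columns=["run", "channel", "sample", "condition", "replicate",
                       "is_reference"]))


def toy_psm_frame(rows, channels) -> pd.DataFrame:
    """Canonical PSM table from dicts; intensity_<ch> keys optional."""
    out = []
    for r in rows:
        rec = {
            "accessions": r.get("accessions", "P1"),
            "peptide": r.get("peptide", "PEPTIDEK"),
            "charge": r.get("charge", 2),
            "search_q": r.get("search_q", 0.001),
            "coisolation_pct": r.get("coisolation_pct", 0.0),
            "run": r.get("run", "run1"),
            "fraction": r.get("fraction", pd.NA),
        }
        rec["is_unique"] = ";" not in str(rec["accessions"])
        for ch in channels:
            rec[f"intensity_{ch}"] = r.get(f"intensity_{ch}", np.nan)
        out.append(rec)
    cols = ["accessions", "is_unique", "peptide", "charge", "search_q",
            "coisolation_pct", "run", "fraction"] + [f"intensity_{c}" for c in channels]
    return pd.DataFrame(out, columns=cols)
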