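"""Per-protein group means, empirical-Bayes variance moderation, moderated t.

Each protein's log2 abundances are modelled with a fixed-effects group-means
model over conditions; the pooled within-condition variance s^2 with d
residual degrees of freedom is shrunk towards a prior via the scaled
inverse-chi-square empirical-Bayes scheme: the prior (d0, s0^2) is estimated
across proteins by method of moments on log s^2 (digamma/trigamma
identities), and the moderated variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with t statistics referred to a t distribution on d0 + d degrees of freedom
(standard normal when d0 is infinite). Multiple testing is controlled per
contrast by Benjamini-Hochberg adjustment, implemented here as the exact
step-up definition because the adjusted q values are the decision statistic
of the whole classification workflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from proxiquant.design_io import ExperimentDesign
from proxiquant.errors import ParameterError, ValidationError
from proxiquant.quantnorm import ProteinMatrix

__all__ = [
    "ProteinFit", "PriorEstimate", "fit_protein", "fit_proteins",
    "estimate_prior", "moderated_contrast", "moderated_contrasts", "bh_adjust",
    "trigamma_inverse",
]

CONTRAST_COLUMNS = ["accession", "contrast", "log2FC", "SE", "df", "t", "p",
                    "q", "n_features"]


@dataclass
class ProteinFit:
    """Group-means fit of one protein.

    ``resid_var`` is the pooled within-condition variance (NaN when no
    condition has two observations); ``resid_df = sum(n_g - 1)`` over
    observed conditions.
    """

    accession: str
    group_means: dict[str, float]
    resid_var: float
    resid_df: int
    n_obs: dict[str, int]


@dataclass
class PriorEstimate:
    """Scaled inverse-chi-square variance prior: d0 (may be inf) and s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ParameterError(f"d0 must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ParameterError(f"s0_sq must be positive, got {self.s0_sq}")


def fit_protein(values: pd.Series | dict, design: ExperimentDesign,
                conditions: list[str] | None = None,
                accession: str = "") -> ProteinFit | None:
    """Fit per-condition means and pooled residual variance for one protein.

    ``values`` maps sample id to log2 abundance (NaN = missing). Returns
    None when the protein is observed in no listed condition.
    """
    if conditions is None:
        conditions = design.conditions
    cond_of = design.condition_of_sample()
    groups: dict[str, list[float]] = {c: [] for c in conditions}
    for s, v in dict(values).items():
        c = cond_of.get(str(s))
        if c in groups and v is not None and not pd.isna(v):
            groups[c].append(float(v))
    n_obs = {c: len(v) for c, v in groups.items()}
    if sum(n_obs.values()) == 0:
        return None
    means = {c: float(np.mean(v)) for c, v in groups.items() if v}
    ss = 0.0
    df = 0
    for c, v in groups.items():
        if len(v) >= 2:
            ss += float(np.sum((np.asarray(v) - means[c]) ** 2))
            df += len(v) - 1
    var = ss / df if df > 0 else float("nan")
    return ProteinFit(accession=accession, group_means=means,
                      resid_var=var, resid_df=df, n_obs=n_obs)


def fit_proteins(matrix: ProteinMatrix, design: ExperimentDesign,
                 conditions: list[str] | None = None):
    """Vectorised group-means fits for every protein in a matrix.

    Returns ``(means, counts, var, df)``: DataFrames of per-condition means
    and observation counts (proteins x conditions) and Series of pooled
    variance / residual df per protein. Reference samples never enter.
    """
    if conditions is None:
        conditions = design.conditions
    cond_of = design.condition_of_sample()
    V = matrix.values.to_numpy(dtype=float)
    idx = matrix.values.index
    means = np.full((V.shape[0], len(conditions)), np.nan)
    counts = np.zeros((V.shape[0], len(conditions)), dtype=int)
    ss = np.zeros(V.shape[0])
    df = np.zeros(V.shape[0], dtype=int)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for j, c in enumerate(conditions):
            cols = [k for k, s in enumerate(matrix.samples) if cond_of.get(s) == c]
            if not cols:
                continue
            sub = V[:, cols]
            n = np.sum(~np.isnan(sub), axis=1)
            m = np.nanmean(sub, axis=1)
            means[:, j] = m
            counts[:, j] = n
            dev = sub - m[:, None]
            grp_ss = np.nansum(dev * dev, axis=1)
            use = n >= 2
            ss[use] += grp_ss[use]
            df[use] += n[use] - 1
    var = np.where(df > 0, ss / np.maximum(df, 1), np.nan)
    return (pd.DataFrame(means, index=idx, columns=conditions),
            pd.DataFrame(counts, index=idx, columns=conditions),
            pd.Series(var, index=idx, name="resid_var"),
            pd.Series(df, index=idx, name="resid_df"))


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ParameterError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_prior(variances) -> PriorEstimate:
    """Method-of-moments estimate of the variance prior across proteins.

    ``variances`` is an iterable of ``(s2, d)`` pairs. Working on
    z = log s^2, whose conditional distribution given the true variance is a
    shifted log-chi-square, the first two moments give s0^2 from the mean
    and d0 from the excess of var(z) over the trigamma term; when the
    observed spread does not exceed the chi-square prediction the prior is
    degenerate (d0 infinite, all true variances equal).
    """
    pairs = [(float(s2), float(d)) for s2, d in variances
             if d >= 1 and np.isfinite(s2) and s2 > 0]
    if len(pairs) < 2:
        raise ParameterError(
            "estimate_prior needs >= 2 proteins with positive variance and "
            "d >= 1; run without moderation instead")
    s2 = np.array([p[0] for p in pairs])
    d = np.array([p[1] for p in pairs])
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    # expected sampling variance of e given a point-mass prior
    exp_var = float(np.mean(special.polygamma(1, d / 2.0)))
    excess = e_var - exp_var
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return PriorEstimate(d0=d0, s0_sq=s0_sq)


def _moderate(var: np.ndarray, df: np.ndarray, prior: PriorEstimate):
    """Moderated variance and total df arrays (NaN var treated as d = 0)."""
    var = np.where(np.isnan(var), 0.0, var)
    if math.isinf(prior.d0):
        s2_tilde = np.full_like(var, prior.s0_sq, dtype=float)
        df_total = np.full_like(var, np.inf, dtype=float)
    else:
        s2_tilde = (prior.d0 * prior.s0_sq + df * var) / (prior.d0 + df)
        df_total = prior.d0 + df
    return s2_tilde, df_total


def moderated_contrast(fit: ProteinFit, prior: PriorEstimate | None,
                       contrast: tuple[str, str]) -> dict | None:
    """Moderated two-group contrast (condition_a - condition_b) for one fit.

    With ``prior=None`` the ordinary pooled t-test is performed (requires
    d > 0). Returns None when either condition is unobserved. The ``q``
    field is left NaN; adjust per contrast with :func:`bh_adjust`.
    """
    a, b = contrast
    n_a = fit.n_obs.get(a, 0)
    n_b = fit.n_obs.get(b, 0)
    if n_a == 0 or n_b == 0:
        return None
    fc = fit.group_means[a] - fit.group_means[b]
    d = float(fit.resid_df)
    s2 = fit.resid_var
    if prior is None:
        if d <= 0 or not np.isfinite(s2):
            return None
        s2_t, df_total = s2, d
    else:
        s2_arr, df_arr = _moderate(np.array([s2]), np.array([d]), prior)
        s2_t, df_total = float(s2_arr[0]), float(df_arr[0])
    if s2_t <= 0:
        return None
    se = math.sqrt(s2_t * (1.0 / n_a + 1.0 / n_b))
    t = fc / se
    if math.isinf(df_total):
        p = 2.0 * float(stats.norm.sf(abs(t)))
    else:
        p = 2.0 * float(stats.t.sf(abs(t), df_total))
    return {"accession": fit.accession, "contrast": f"{a} - {b}",
            "log2FC": fc, "SE": se, "df": df_total, "t": t, "p": p,
            "q": float("nan"), "n_features": None}


def moderated_contrasts(
    matrix: ProteinMatrix,
    design: ExperimentDesign,
    contrast: tuple[str, str],
    prior: PriorEstimate | None = None,
    moderate: bool = True,
    adjust: bool = True,
) -> pd.DataFrame:
    """Moderated t-test of ``condition_a - condition_b`` for every protein.

    Fits all proteins, estimates the variance prior across them (unless one
    is supplied or ``moderate=False``), computes the moderated t and, when
    ``adjust``, Benjamini-Hochberg q values within this contrast. Returns a
    tidy table with columns ``accession, contrast, log2FC, SE, df, t, p, q,
    n_features``.
    """
    a, b = contrast
    for c in (a, b):
        if c not in design.conditions:
            raise ValidationError(f"condition {c!r} not in design")
    means, counts, var, df = fit_proteins(matrix, design)
    if moderate and prior is None:
        usable = [(s2, d) for s2, d in zip(var, df) if d >= 1 and s2 > 0]
        prior = estimate_prior(usable) if len(usable) >= 2 else None

    n_a = counts[a].to_numpy()
    n_b = counts[b].to_numpy()
    ok = (n_a > 0) & (n_b > 0)
    fc = means[a].to_numpy() - means[b].to_numpy()
    v = var.to_numpy()
    d = df.to_numpy(dtype=float)
    if prior is not None:
        s2_t, df_total = _moderate(v, d, prior)
    else:
        s2_t, df_total = v, d
        ok &= (d > 0) & np.isfinite(v)
    ok &= np.nan_to_num(s2_t, nan=-1.0) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_t * (1.0 / np.maximum(n_a, 1) + 1.0 / np.maximum(n_b, 1)))
        t = fc / se
    p = np.where(np.isinf(df_total), 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)))
    run_support = matrix.psm_support.to_numpy().max(axis=1)

    out = pd.DataFrame({
        "accession": matrix.values.index.astype(str),
        "contrast": f"{a} - {b}",
        "log2FC": fc, "SE": se, "df": df_total, "t": t, "p": p,
        "q": np.nan, "n_features": run_support,
    })[CONTRAST_COLUMNS]
    out = out[ok].reset_index(drop=True)
    if adjust and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    ``q_(i) = min_(j >= i) p_(j) * m / j`` clipped at 1, where p_(j) are the
    order statistics of the m input p values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D array")
    if len(p) == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
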