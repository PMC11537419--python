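"""Linear mixed-effects models of the behavioral and gaze measures.

Five model families are registered, one per outcome: epoch durations
(log-transformed), object displacements (human vs model), relative net
transitions, and first-fixation latencies in preparation and execution
epochs.  Two-level categorical predictors are effect-coded (sum-to-zero,
+/-1) with the level of interest mapped to +1, so each coefficient is
half the marginal difference between levels and reads directly as a main
effect.  The eight-level ROI factor of the latency models is coded
against the current-target-object reference so every coefficient
compares an ROI's latency with the just-in-time target.

Fitting is by REML through ``statsmodels`` MixedLM with random intercepts
and slopes grouped by subject.  If the requested random structure fails
to converge, a documented fallback ladder retries with simplified
structures down to a random intercept.  Degrees of freedom for fixed
effects use a between-within approximation (residual df minus subject
df); a normal approximation is available as an option.  Estimates and
confidence bounds of log-response models are exponentiated in the
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
import statsmodels.formula.api as smf


#: preferred level orders; the first level is coded +1 under sum coding
FACTOR_LEVELS = {
    "trial_type": ["HARD", "EASY"],
    "epoch_kind": ["preparation", "execution"],
    "solver_type": ["HUMAN", "MODEL"],
}

ROI_REFERENCE = "cur_target_object"


@dataclass(frozen=True)
class ModelSpec:
    name: str
    response: str
    fixed: str                  # patsy right-hand side
    re_formula: str             # random-effects structure (slopes)
    log_response: bool = False
    subset: Optional[tuple[str, str]] = None   # (column, value) row filter


MODEL_SPECS: dict[str, ModelSpec] = {
    s.name: s
    for s in [
        ModelSpec(
            "duration", "duration",
            "C(trial_type, Sum) * C(epoch_kind, Sum) * grasp_index",
            "1 + C(trial_type, Sum) + C(epoch_kind, Sum) + grasp_index",
            log_response=True,
        ),
        ModelSpec(
            "displacements", "n_moves",
            "C(trial_type, Sum) * C(solver_type, Sum)",
            "1 + C(trial_type, Sum) + C(solver_type, Sum)",
        ),
        ModelSpec(
            "transitions", "relative_net_transitions",
            "C(trial_type, Sum) * C(epoch_kind, Sum)",
            "1 + C(trial_type, Sum) * C(epoch_kind, Sum)",
        ),
        ModelSpec(
            "latency_prep", "latency",
            f"C(trial_type, Sum) * C(roi, Treatment('{ROI_REFERENCE}'))",
            "1 + C(trial_type, Sum)",
            subset=("epoch_kind", "preparation"),
        ),
        ModelSpec(
            "latency_exec", "latency",
            f"C(trial_type, Sum) * C(roi, Treatment('{ROI_REFERENCE}'))",
            "1 + C(trial_type, Sum)",
            subset=("epoch_kind", "execution"),
        ),
    ]
}


@dataclass
class FitReport:
    spec: ModelSpec
    table: pd.DataFrame          # term, estimate, se, ci_low, ci_high, t, df, p (+ back-transformed)
    converged: bool
    re_formula_used: str
    n_obs: int
    n_groups: int

    def __str__(self) -> str:  # Table-style text rendering
        cols = ["term", "estimate", "ci_low", "ci_high", "t", "p"]
        if self.spec.log_response:
            cols = ["term", "estimate_bt", "ci_low_bt", "ci_high_bt", "t", "p"]
        lines = [f"Model {self.spec.name}: {self.spec.response} ~ {self.spec.fixed}",
                 f"random: ({self.re_formula_used} | subject), n={self.n_obs}, groups={self.n_groups}"]
        sub = self.table[cols].copy()
        for c in sub.columns[1:]:
            sub[c] = sub[c].map(lambda v: f"{v:.3g}")
        lines.extend(sub.to_string(index=False).splitlines())
        return "\n".join(lines)


def _prepare(data: pd.DataFrame, spec: ModelSpec, min_level_count: int = 10) -> pd.DataFrame:
    df = data.copy()
    if spec.subset is not None:
        col, val = spec.subset
        df = df[df[col] == val].copy()
    if "roi" in spec.fixed and "roi" in df.columns:
        # levels observed too rarely make the design singular; drop them
        counts = df["roi"].value_counts()
        sparse = set(counts[counts < min_level_count].index) - {ROI_REFERENCE}
        if sparse:
            warnings.warn(f"dropping sparse ROI levels from the fit: {sorted(sparse)}")
            df = df[~df["roi"].isin(sparse)].copy()
        df["roi"] = df["roi"].astype(str)
    for col, levels in FACTOR_LEVELS.items():
        if col in df.columns and df[col].dtype == object:
            present = [l for l in levels if l in set(df[col])]
            df[col] = pd.Categorical(df[col], categories=present)
    return df


def build_design(data: pd.DataFrame, spec: ModelSpec) -> dict:
    """Validate the data against a model spec and materialize the fixed
    design matrix (effect/reference coding applied).

    Raises
    ------
    ValueError
        On missing columns or single-level factors.
    """
    df = _prepare(data, spec)
    if spec.response not in df.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    for col in FACTOR_LEVELS:
        if col in spec.fixed and df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than two levels")
    X = dmatrix(spec.fixed, df, return_type="dataframe")
    y = np.log(df[spec.response]) if spec.log_response else df[spec.response]
    return {"X": X, "y": np.asarray(y, dtype=float), "data": df,
            "terms": list(X.columns)}


def _clean_term(term: str) -> str:
    out = term
    for col in ("trial_type", "epoch_kind", "solver_type", "roi"):
        out = out.replace(f"C({col}, Sum)[S.", f"{col}[")
        out = out.replace(f"C({col}, Treatment('{ROI_REFERENCE}'))[T.", f"{col}[")
    return out.replace("]", "]")


def fit_and_report(
    data: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = True,
    df_method: str = "between_within",
    maxiter: int = 20000,
) -> FitReport:
    """Fit a registered mixed model and report fixed effects.

    The random structure fallback ladder is ``[spec.re_formula,
    "1 + C(trial_type, Sum)", "1"]`` (deduplicated); the first structure
    that converges with finite standard errors is reported.
    """
    df = _prepare(data, spec)
    build_design(data, spec)  # validation
    response = "__y"
    df[response] = np.log(df[spec.response]) if spec.log_response else df[spec.response]
    formula = f"{response} ~ {spec.fixed}"

    ladder = []
    for rf in (spec.re_formula, "1 + C(trial_type, Sum)", "1"):
        if rf not in ladder:
            ladder.append(rf)
    result = None
    used = ladder[-1]
    for rf in ladder:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=rf)
                res = model.fit(reml=reml, maxiter=maxiter, method="lbfgs")
            if res.params.isna().any() or np.isnan(res.bse_fe).any():
                continue
            result = res
            used = rf
            break
        except Exception:
            continue
    if result is None:
        raise RuntimeError(f"mixed model {spec.name!r} failed to converge on every ladder step")

    k_fe = len(result.fe_params)
    n_obs = int(result.nobs)
    n_groups = df["subject"].nunique()
    if df_method == "between_within":
        dof = max(n_obs - k_fe - (n_groups - 1), n_groups - 1, 1)
    elif df_method == "normal":
        dof = np.inf
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    tcrit = stats.norm.ppf(0.975) if np.isinf(dof) else stats.t.ppf(0.975, dof)

    rows = []
    for term, est, se in zip(result.fe_params.index, result.fe_params, result.bse_fe):
        t = est / se
        p = 2 * (stats.norm.sf(abs(t)) if np.isinf(dof) else stats.t.sf(abs(t), dof))
        row = {
            "term": _clean_term(term), "estimate": est, "se": se,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
            "t": t, "df": dof, "p": p,
        }
        if spec.log_response:
            row["estimate_bt"] = np.exp(est)
            row["ci_low_bt"] = np.exp(row["ci_low"])
            row["ci_high_bt"] = np.exp(row["ci_high"])
        rows.append(row)
    return FitReport(
        spec=spec, table=pd.DataFrame(rows),
        converged=bool(getattr(result, "converged", True)),
        re_formula_used=used, n_obs=n_obs, n_groups=n_groups,
    )


def simulate_recovery_dataset(
    spec: ModelSpec,
    betas: Sequence[float],
    n_subjects: int = 12,
    n_rep: int = 6,
    re_sd: float = 0.3,
    resid_sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Balanced synthetic dataset drawn from a registered model family
    with known fixed coefficients (for parameter-recovery checks).

    Each subject contributes ``n_rep`` replicates of every factor cell;
    subjects get random intercepts of SD ``re_sd``.  ``betas`` are on the
    design scale (log scale for log-response specs) and must match the
    fixed design's column count.
    """
    rng = rng or np.random.default_rng(0)
    cells: dict[str, list] = {}
    if "trial_type" in spec.fixed:
        cells["trial_type"] = FACTOR_LEVELS["trial_type"]
    if "epoch_kind" in spec.fixed:
        cells["epoch_kind"] = FACTOR_LEVELS["epoch_kind"]
    if "solver_type" in spec.fixed:
        cells["solver_type"] = FACTOR_LEVELS["solver_type"]
    if "roi" in spec.fixed:
        from .epochs import ROI_LABELS
        cells["roi"] = list(ROI_LABELS)

    rows = []
    for s in range(n_subjects):
        for rep in range(n_rep):
            combos = [{}]
            for col, levels in cells.items():
                combos = [dict(c, **{col: l}) for c in combos for l in levels]
            for c in combos:
                c = dict(c, subject=s)
                if "grasp_index" in spec.fixed:
                    c["grasp_index"] = int(rng.integers(0, 10))
                rows.append(c)
    df = pd.DataFrame(rows)
    if spec.subset is not None:
        df[spec.subset[0]] = spec.subset[1]
    for col in FACTOR_LEVELS:
        if col in df.columns:
            df[col] = pd.Categorical(df[col], categories=[
                l for l in FACTOR_LEVELS[col] if l in set(df[col])
            ])
    X = dmatrix(spec.fixed, df, return_type="dataframe")
    betas = np.asarray(betas, dtype=float)
    if len(betas) != X.shape[1]:
        raise ValueError(f"expected {X.shape[1]} coefficients, got {len(betas)}")
    u = rng.normal(0, re_sd, n_subjects)
    y = X.to_numpy() @ betas + u[df["subject"].to_numpy()] + rng.normal(0, resid_sd, len(df))
    df[spec.response] = np.exp(y) if spec.log_response else y
    df["__true_betas"] = [tuple(betas)] * len(df)
    return df
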