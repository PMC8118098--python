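"""The five analysis stages over the response-statistics tables.

1. Distinct-pronunciation counts, tested against the no-variability
   population mean of 1 with one-sample t tests (per participant and per
   item).
2. Response diversity modelled by a linear mixed model:
   ``diversity ~ consistency * literacy + (1|item) + (1 + consistency|participant)``.
3. Novel-pronunciation use modelled by a binomial mixed model with session,
   consistency and literacy plus all two-way interactions, and random
   intercepts for participant and item.
4. Inter-participant Gower distances modelled by an LMM with session
   (standardised) and correlated random intercepts and session slopes for
   each pair member.
5. Pronunciation-frequency trajectories: an intercept-only LMM with
   correlated random intercepts and session slopes per pronunciation; the
   intercept-slope correlation summarises whether frequent pronunciations
   spread while rare ones drop out of use.

Each fit follows the maximal-feasible random-effects ladder: the requested
structure first, then the same structure with random-effect correlations
dropped, then random intercepts only; the applied fallback is recorded in
the returned :class:`ModelResult`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .mixed import BinomialMixedModel, LinearMixedModel, RandomTerm


@dataclass
class ModelResult:
    """Fixed effects, variance components and fit diagnostics of one stage."""

    formula: str
    fixed_effects: pd.DataFrame
    variance_components: dict[str, pd.DataFrame]
    r2_marginal: float
    r2_conditional: float
    converged: bool
    fallback_applied: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "fixed_effects": self.fixed_effects.reset_index(names="term").to_dict("records"),
            "variance_components": {k: v.to_dict() for k, v in self.variance_components.items()},
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "converged": self.converged,
            "fallback_applied": self.fallback_applied,
            "extra": {k: v for k, v in self.extra.items() if _jsonable(v)},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, dict))


def composite_literacy(df: pd.DataFrame) -> pd.DataFrame:
    """Composite literacy skill: the average of within-sample standardised
    spelling and vocabulary scores (centred by construction).

    Expects columns participant, spelling, vocabulary; participants with a
    missing score are excluded with a warning.
    """
    out = df.copy()
    incomplete = out["spelling"].isna() | out["vocabulary"].isna()
    if incomplete.any():
        warnings.warn(f"excluding {int(incomplete.sum())} participant(s) with a missing score")
        out = out[~incomplete]
    if len(out) < 2:
        raise ValueError("need at least two complete participants")
    for col in ("spelling", "vocabulary"):
        v = out[col].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"{col} scores have zero variance")
        out[f"z_{col}"] = (v - v.mean()) / sd
    out["literacy"] = (out["z_spelling"] + out["z_vocabulary"]) / 2.0
    return out[["participant", "spelling", "vocabulary", "z_spelling", "z_vocabulary", "literacy"]]


def ttest_vs_one(means) -> tuple[float, int, float]:
    """One-sample t test of per-unit mean distinct-pronunciation counts
    against the no-variability population mean mu = 1."""
    x = np.asarray(means, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two units")
    if np.std(x, ddof=1) == 0:
        if np.all(x == 1.0):  # no variability anywhere: t = 0 by convention
            return 0.0, len(x) - 1, 1.0
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=1.0)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def _result_from_lmm(model: LinearMixedModel, formula: str,
                     fallback: str | None) -> ModelResult:
    fe = pd.DataFrame({
        "estimate": model.fe_params_, "se": model.fe_se_,
        "stat": model.fe_t_, "df": model.fe_df_, "p": model.fe_p_,
    })
    return ModelResult(
        formula=formula, fixed_effects=fe,
        variance_components={**model.varcomp_,
                             "Residual": pd.DataFrame({"var": [model.sigma2_]})},
        r2_marginal=model.r2_marginal_, r2_conditional=model.r2_conditional_,
        converged=model.converged_, fallback_applied=fallback,
        extra={"n_obs": model.n_obs_, "model": model},
    )


def _result_from_glmm(model: BinomialMixedModel, formula: str,
                      fallback: str | None) -> ModelResult:
    fe = pd.DataFrame({
        "estimate": model.fe_params_, "se": model.fe_se_,
        "stat": model.fe_z_, "df": np.inf, "p": model.fe_p_,
    })
    return ModelResult(
        formula=formula, fixed_effects=fe,
        variance_components=model.varcomp_,
        r2_marginal=model.r2_marginal_, r2_conditional=model.r2_conditional_,
        converged=model.converged_, fallback_applied=fallback,
        extra={"n_obs": model.n_obs_, "model": model,
               "r2_marginal_delta": model.r2_marginal_delta_,
               "r2_conditional_delta": model.r2_conditional_delta_},
    )


def _fit_with_ladder(response, fixed, random_full, df, formula):
    """Maximal-feasible random effects: full structure, then correlations
    dropped, then intercepts only."""
    ladder = [
        (None, random_full),
        ("dropped random-effect correlations",
         [RandomTerm(t.group, t.slopes, correlated=False) for t in random_full]),
        ("dropped random slopes",
         [RandomTerm(t.group) for t in random_full]),
    ]
    last_err = None
    for i, (desc, random) in enumerate(ladder):
        if i > 0 and all(not t.slopes for t in random_full):
            break  # nothing left to simplify
        try:
            model = LinearMixedModel(response=response, fixed=fixed, random=random).fit(df)
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            continue
        if model.converged_:
            return _result_from_lmm(model, formula, desc)
        last_err = RuntimeError("optimiser did not converge")
    if last_err is not None and not isinstance(last_err, RuntimeError):
        raise last_err
    # return the final (simplest) fit flagged as non-converged
    model = LinearMixedModel(response=response, fixed=fixed, random=ladder[-1][1]).fit(df)
    return _result_from_lmm(model, formula, "dropped random slopes (non-converged)")


def fit_diversity_lmm(df: pd.DataFrame) -> ModelResult:
    """Response diversity ~ item consistency x literacy skill, with a random
    intercept per item and correlated random intercept and consistency
    slope per participant.  Expects columns diversity, consistency,
    literacy, participant, item (covariates already centred)."""
    formula = ("diversity ~ consistency * literacy + (1|item) "
               "+ (1 + consistency|participant)")
    return _fit_with_ladder(
        "diversity",
        ["consistency", "literacy", "consistency:literacy"],
        [RandomTerm("item"), RandomTerm("participant", ("consistency",))],
        df, formula)


def fit_novelty_glmm(df: pd.DataFrame, center_session: bool = True) -> ModelResult:
    """Novel-pronunciation use (binary, sessions >= 2) as a binomial GLMM
    with session, consistency, literacy and all two-way interactions, and
    random intercepts for participant and item."""
    df = df.copy()
    df["session_c"] = df["session"].astype(float)
    if center_session:
        df["session_c"] -= df["session_c"].mean()
    formula = ("novel ~ session * consistency + session * literacy "
               "+ consistency * literacy + (1|participant) + (1|item)")
    model = BinomialMixedModel(
        response="novel",
        fixed=["session_c", "consistency", "literacy",
               "session_c:consistency", "session_c:literacy",
               "consistency:literacy"],
        random=[RandomTerm("participant"), RandomTerm("item")],
    ).fit(df)
    return _result_from_glmm(model, formula, None)


def fit_distance_lmm(df: pd.DataFrame, scale_session: bool = True) -> ModelResult:
    """Per-session inter-participant Gower distance ~ session, with
    correlated random intercepts and session slopes for each member of the
    pair.  Expects columns distance, session, participant_a, participant_b."""
    df = df.copy()
    s = df["session"].astype(float)
    df["session_z"] = (s - s.mean()) / s.std(ddof=1) if scale_session else s
    formula = "distance ~ session + (1 + session|participant_a) + (1 + session|participant_b)"
    return _fit_with_ladder(
        "distance", ["session_z"],
        [RandomTerm("participant_a", ("session_z",)),
         RandomTerm("participant_b", ("session_z",))],
        df, formula)


@dataclass
class TrajectorySummary:
    """Per-pronunciation conditional intercepts and session slopes."""

    table: pd.DataFrame              # item, pronunciation, intercept, slope
    r: float                         # Pearson r between intercepts and slopes
    p: float
    n: int
    result: ModelResult
    degenerate: bool = False         # True when slopes have ~zero variance


def fit_trajectories(freq: pd.DataFrame, center_frequency: bool = True) -> TrajectorySummary:
    """Pronunciation-frequency trajectories across sessions.

    Fits ``frequency_c ~ 1 + (1 + session|pronunciation)`` on the
    zero-filled frequency table (columns item, pronunciation, session,
    frequency; frequency centred after zero-filling) and extracts each
    pronunciation's conditional intercept and slope (fixed effect plus
    BLUP).  Pronunciations observed in few sessions are shrunk toward the
    mean, never dropped.
    """
    df = freq.copy()
    df["pron_id"] = df["item"].astype(str) + "::" + df["pronunciation"].astype(str)
    df["freq_c"] = df["frequency"].astype(float)
    if center_frequency:
        df["freq_c"] -= df["freq_c"].mean()
    df["session_n"] = df["session"].astype(float)
    formula = "pronunciation_frequency ~ 1 + (1 + session|pronunciation)"
    result = _fit_with_ladder("freq_c", [],
                              [RandomTerm("pron_id", ("session_n",))], df, formula)
    model = result.extra["model"]
    ranef = model.ranef_[list(model.ranef_)[0]]
    intercept = model.fe_params_["(Intercept)"] + ranef["(Intercept)"]
    slope = ranef["session_n"] if "session_n" in ranef.columns else pd.Series(0.0, index=ranef.index)
    table = pd.DataFrame({
        "pron_id": ranef.index,
        "intercept": intercept.to_numpy(),
        "slope": slope.to_numpy(),
    })
    parts = table["pron_id"].str.split("::", n=1, expand=True)
    table.insert(0, "item", parts[0])
    table.insert(1, "pronunciation", parts[1])
    table = table.drop(columns="pron_id")

    degenerate = float(np.std(table["slope"])) < 1e-10
    if degenerate or float(np.std(table["intercept"])) < 1e-10:
        warnings.warn("intercepts or slopes have ~zero variance; "
                      "intercept-slope correlation undefined")
        r, p = float("nan"), float("nan")
        degenerate = True
    else:
        r, p = stats.pearsonr(table["intercept"], table["slope"])
    return TrajectorySummary(table=table, r=float(r), p=float(p),
                             n=len(table), result=result, degenerate=degenerate)


def r2_mixed(result: ModelResult) -> tuple[float, float]:
    """(marginal, conditional) R2 of a fitted stage: variance explained by
    the fixed effects alone vs fixed plus random effects."""
    return result.r2_marginal, result.r2_conditional


def semipartial_r2(model, df: pd.DataFrame, term: str) -> float:
    """Variance uniquely attributable to one fixed-effect term: the drop in
    marginal R2 when the term and every interaction containing it are
    removed and the model refit.

    ``model`` is an (unfitted or fitted) LinearMixedModel /
    BinomialMixedModel; refit non-convergence raises with the term named.
    """
    full = clone(model).fit(df)
    reduced_terms = [t for t in model.fixed if term not in t.split(":")]
    if len(reduced_terms) == len(model.fixed):
        raise ValueError(f"{term!r} is not a fixed-effect term of the model")
    reduced = clone(model).set_params(fixed=reduced_terms).fit(df)
    if not reduced.converged_:
        warnings.warn(f"reduced model without {term!r} did not converge; "
                      "semi-partial R2 is unreliable")
    return float(full.r2_marginal_ - reduced.r2_marginal_)
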