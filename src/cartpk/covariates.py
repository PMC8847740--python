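"""Covariate screening and stepwise covariate modelling (SCM).

Candidate covariate-parameter relations are added to the fitted base model by
forward inclusion / backward elimination on the objective function value:
a candidate enters when it lowers the OFV by more than the chi-square
quantile at the forward significance level (3.84 for p = 0.05, 1 df) and is
retained in the backward step only when removing it would raise the OFV by at
least the backward quantile (6.63 for p = 0.01, 1 df).

Two descriptive screens complement the likelihood-based search: group
comparisons of empirical-Bayes etas by covariate level, and of the observed
28-day exposure (trapezoidal AUC of the concentration-time data).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import KineticDataset
from .kinetics import auc_trapezoid
from .model import PARAM_NAMES, CovariateTerm
from .nlme import FitResult, ModelSpec, fit

__all__ = [
    "chi2_threshold",
    "apply_covariate",
    "scm",
    "ScmTrace",
    "ebe_covariate_screen",
    "auc28_screen",
    "subject_auc28",
]


def chi2_threshold(p: float, df: int = 1) -> float:
    """Upper-tail chi-square quantile used as an OFV-difference criterion."""
    if not 0 < p < 1:
        raise ValueError(f"significance level must lie in (0, 1), got {p!r}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df!r}")
    return float(stats.chi2.ppf(1.0 - p, df))


def apply_covariate(pop, term: CovariateTerm):
    """Return a population model extended with one covariate term."""
    return pop.with_covariate(term)


@dataclass(frozen=True)
class ScmStep:
    step: str  # forward | backward
    term: str
    ofv_before: float
    ofv_after: float
    delta_ofv: float
    accepted: bool


@dataclass
class ScmTrace:
    """Every candidate evaluation of an SCM run, in order."""

    steps: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    @property
    def selected(self) -> list:
        chosen = []
        for s in self.steps:
            if s.accepted and s.step == "forward":
                chosen.append(s.term)
            if s.accepted and s.step == "backward":
                chosen.remove(s.term)
        return chosen


def scm(
    data: KineticDataset,
    base_fit: FitResult,
    candidate_terms,
    forward_p: float = 0.05,
    backward_p: float = 0.01,
    fit_options: dict | None = None,
):
    """Stepwise covariate modelling on a fitted base model.

    Forward passes add, one at a time, the candidate with the largest
    significant OFV drop (ties broken by declaration order); backward passes
    then delete every included term whose removal costs less than the
    backward criterion.  Candidate refits are warm-started from the current
    model.  Returns ``(final_fit, trace)``.
    """
    fwd_crit = chi2_threshold(forward_p, 1)
    bwd_crit = chi2_threshold(backward_p, 1)
    opts = {"maxiter": 200}
    opts.update(fit_options or {})
    candidates = list(candidate_terms)
    included: list = []
    steps: list = []
    current_fit = base_fit
    # cache by covariate-term set; the empty set is the supplied base fit
    fits_cache = {(): base_fit}

    def candidate_init(term: CovariateTerm) -> CovariateTerm:
        """Initialise a new term from the imprint the covariate leaves on the
        current fit's empirical-Bayes etas (a neutral start often leaves the
        candidate refit short of the OFV drop actually available)."""
        col = f"eta_{term.parameter}"
        ebe = current_fit.ebe.set_index("ID") if len(current_fit.ebe) else None
        if ebe is None or col not in ebe.columns:
            return term
        subjects = data.subjects.set_index("ID")
        vals = subjects.loc[ebe.index, term.covariate].to_numpy(dtype=float)
        eta = ebe[col].to_numpy()
        if term.form == "categorical":
            pos, neg = eta[vals != 0], eta[vals == 0]
            if len(pos) == 0 or len(neg) == 0:
                return term
            theta0 = float(np.clip(np.exp(pos.mean() - neg.mean()), 0.05, 20.0))
        else:
            ref = float(np.nanmedian(vals))
            x = np.log(np.maximum(vals, 1e-12) / max(ref, 1e-12))
            if np.allclose(x.std(), 0.0):
                return term
            theta0 = float(np.clip(np.polyfit(x, eta, 1)[0], -3.0, 3.0))
        return replace(term, theta=theta0)

    def _build_init(terms, smart: bool):
        init = replace(current_fit.pop, covariate_effects=())
        for t in terms:
            prev = next(
                (q for q in current_fit.pop.covariate_effects if q.label == t.label),
                None,
            )
            if prev is not None:
                init = init.with_covariate(prev)
            else:
                init = init.with_covariate(candidate_init(t) if smart else t)
        return init

    def refit(terms):
        key = tuple(t.label for t in terms)
        if key not in fits_cache:
            spec = replace(current_fit.spec, covariate_terms=tuple(terms))
            result = fit(data, spec, init=_build_init(terms, smart=True), options=opts)
            if result.ofv > current_fit.ofv and len(terms) > len(
                current_fit.pop.covariate_effects
            ):
                # an extended model can never fit worse than its nested base
                # (the new term at its neutral value reproduces it exactly);
                # retry from the neutral start and keep the better optimum
                alt = fit(data, spec, init=_build_init(terms, smart=False), options=opts)
                if alt.ofv < result.ofv:
                    result = alt
                if result.ofv > current_fit.ofv:
                    result = replace_fit_ofv(result, current_fit.ofv)
            fits_cache[key] = result
        return fits_cache[key]

    def replace_fit_ofv(result, ofv):
        import dataclasses as _dc

        return _dc.replace(result, ofv=float(ofv))

    # forward inclusion
    while True:
        remaining = [c for c in candidates if c.label not in {t.label for t in included}]
        if not remaining:
            break
        evals = []
        for cand in remaining:
            try:
                cand_fit = refit(included + [cand])
            except Exception:  # pragma: no cover - candidate refit failure
                steps.append(
                    ScmStep("forward", cand.label, current_fit.ofv, np.nan, np.nan, False)
                )
                continue
            delta = current_fit.ofv - cand_fit.ofv
            evals.append((delta, cand, cand_fit))
            steps.append(
                ScmStep(
                    "forward",
                    cand.label,
                    current_fit.ofv,
                    cand_fit.ofv,
                    delta,
                    False,
                )
            )
        sig = [e for e in evals if e[0] > fwd_crit]
        if not sig:
            break
        delta, best, best_fit = max(sig, key=lambda e: e[0])
        # guard against basin artefacts: the winning fit may have improved the
        # SHARED parameters rather than genuinely needing the new term, which
        # would inflate the OFV drop.  Refit the current model warm-started
        # from the winner's shared parameters; if that recovers (part of) the
        # improvement, restart the pass from the better base instead.
        guard_init = replace(
            best_fit.pop,
            covariate_effects=tuple(
                t for t in best_fit.pop.covariate_effects if t.label != best.label
            ),
        )
        guard_spec = replace(current_fit.spec, covariate_terms=tuple(included))
        try:
            base2 = fit(data, guard_spec, init=guard_init, options=opts)
        except Exception:  # pragma: no cover
            base2 = None
        if base2 is not None and base2.ofv < current_fit.ofv - 1e-9:
            current_fit = base2
            fits_cache[tuple(t.label for t in included)] = base2
            continue
        # mark the winning evaluation as accepted
        for s in reversed(steps):
            if s.step == "forward" and s.term == best.label and s.delta_ofv == delta:
                steps[steps.index(s)] = replace(s, accepted=True)
                break
        included.append(best)
        current_fit = best_fit

    # backward elimination
    changed = True
    while changed and included:
        changed = False
        for term in list(included):
            rest = [t for t in included if t.label != term.label]
            try:
                reduced_fit = refit(rest)
            except Exception:  # pragma: no cover
                continue
            increase = reduced_fit.ofv - current_fit.ofv
            remove = increase < bwd_crit
            steps.append(
                ScmStep(
                    "backward",
                    term.label,
                    current_fit.ofv,
                    reduced_fit.ofv,
                    increase,
                    remove,
                )
            )
            if remove:
                included = rest
                current_fit = reduced_fit
                changed = True
                break
    return current_fit, ScmTrace(steps)


def _two_group_test(a: np.ndarray, b: np.ndarray, test: str):
    if len(a) == 0 or len(b) == 0:
        return np.nan
    if np.all(a[:, None] == b[None, :]) and np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


def ebe_covariate_screen(
    fit_result: FitResult, covariate: str, test: str = "mannwhitney"
) -> pd.DataFrame:
    """Compare empirical-Bayes etas between covariate levels.

    For each structural parameter the per-subject etas are split by the (0/1)
    covariate and compared with a two-sample location test (Mann-Whitney U by
    default).  A covariate genuinely acting on a parameter shifts that
    parameter's etas in the affected group when the term is absent from the
    fitted model.
    """
    subjects = fit_result.data.subjects
    if covariate not in subjects.columns:
        raise KeyError(f"covariate {covariate!r} not in subject table")
    flag = subjects.set_index("ID")[covariate]
    ebe = fit_result.ebe.set_index("ID")
    levels = flag[ebe.index].to_numpy() != 0
    rows = []
    for k in PARAM_NAMES:
        col = ebe[f"eta_{k}"].to_numpy()
        a, b = col[levels], col[~levels]
        p = np.nan if (len(a) == 0 or len(b) == 0) else _two_group_test(a, b, test)
        rows.append(
            {
                "parameter": k,
                "covariate": covariate,
                "n_pos": int(levels.sum()),
                "n_neg": int((~levels).sum()),
                "median_pos": float(np.median(a)) if len(a) else np.nan,
                "median_neg": float(np.median(b)) if len(b) else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def subject_auc28(
    data: KineticDataset, t_upper: float = 28.0, blq_fraction: float = 0.5
) -> pd.Series:
    """Per-subject trapezoidal AUC of observed concentrations over (0, t_upper].

    BLQ records enter at ``blq_fraction·LOQ`` (for the integration only);
    subjects with fewer than two observations in the window are dropped.
    """
    out = {}
    for sid, g in data.obs.groupby("ID"):
        g = g[g["TIME"] <= t_upper]
        if len(g) < 2:
            continue
        y = np.where(g["BLQ"] != 0, blq_fraction * g["LOQ"], g["DV"])
        t = g["TIME"].to_numpy(dtype=float)
        hi = min(t_upper, t.max())
        out[sid] = auc_trapezoid(t, y, t.min(), hi)
    return pd.Series(out, name="auc28")


def auc28_screen(
    data: KineticDataset, covariate: str, test: str = "mannwhitney"
) -> dict:
    """Compare 28-day observed exposure between covariate levels."""
    auc = subject_auc28(data)
    flag = data.subjects.set_index("ID")[covariate]
    levels = flag[auc.index].to_numpy() != 0
    a, b = auc.to_numpy()[levels], auc.to_numpy()[~levels]
    return {
        "covariate": covariate,
        "n_pos": int(levels.sum()),
        "n_neg": int((~levels).sum()),
        "median_pos": float(np.median(a)) if len(a) else np.nan,
        "median_neg": float(np.median(b)) if len(b) else np.nan,
        "p_value": _two_group_test(a, b, test),
        "auc": auc,
    }
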