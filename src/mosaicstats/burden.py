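"""Genome-wide mutation-burden statistics.

Case/control burden is compared with a forward-AIC negative-binomial (NB)
regression: covariates are selected without the diagnosis term, diagnosis is
then added, and inference on its coefficient comes from label permutation.
A companion power simulation draws NB cohorts whose control mean is reduced
by a fold while the variance is preserved.  Small exact-test helpers
(Fisher 2x2) round out the module.

The NB is parameterised as (mean mu, size k) with variance mu + mu^2/k;
statsmodels' alpha is 1/k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# ---------------------------------------------------------------------------
# Low-level NB fit
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    """Maximum-likelihood NB regression fit (log link).

    ``params``/``bse``/``pvalues`` are indexed by column name; ``alpha`` is
    statsmodels' dispersion (variance = mu + alpha * mu^2).  When the NB
    likelihood fails to converge the fit falls back to Poisson and
    ``model_type`` records it.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    llf: float
    alpha: float
    converged: bool
    model_type: str = "negative_binomial"


def _design(counts, covariates: pd.DataFrame | None) -> tuple[np.ndarray, pd.DataFrame]:
    counts = np.asarray(counts, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame({"const": np.ones(len(counts))})
    else:
        X = sm.add_constant(covariates.astype(float), has_constant="add")
    return counts, X


def nb_fit(counts, covariates: pd.DataFrame | None = None) -> NBFit:
    """NB regression of counts on covariates (intercept added).

    The AIC counts the dispersion as a parameter.  Non-convergence or a
    degenerate dispersion triggers a flagged Poisson fallback rather than a
    silent failure.
    """
    counts, X = _design(counts, covariates)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if len(counts) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(counts, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            if converged and np.all(np.isfinite(res.bse.iloc[:-1])):
                return NBFit(
                    params=res.params.iloc[:-1], bse=res.bse.iloc[:-1],
                    pvalues=res.pvalues.iloc[:-1],
                    aic=float(-2 * res.llf + 2 * len(res.params)),
                    llf=float(res.llf), alpha=float(res.params.iloc[-1]),
                    converged=True,
                )
        except Exception:
            pass
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    warnings.warn("NB fit did not converge; Poisson fallback", stacklevel=2)
    return NBFit(
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        aic=float(res.aic), llf=float(res.llf), alpha=0.0,
        converged=bool(res.converged), model_type="poisson",
    )


# ---------------------------------------------------------------------------
# Forward AIC selection
# ---------------------------------------------------------------------------

@dataclass
class StepFitResult:
    """Forward-AIC covariate selection trace and the final NB fit."""

    selected: list[str]
    aic_trace: list[float]
    fit: NBFit


def forward_step_nb(counts, candidates: pd.DataFrame) -> StepFitResult:
    """Forward stepwise NB regression, AIC-greedy.

    Starts from the intercept-only model and at each step adds the single
    candidate whose inclusion minimises the AIC, stopping when no addition
    lowers it.  Ties break by candidate name order; a candidate supplied
    twice (same name) enters at most once.
    """
    if candidates.isna().any().any():
        raise ValueError("candidate covariates contain missing values")
    candidates = candidates.loc[:, ~candidates.columns.duplicated()]
    remaining = sorted(candidates.columns)
    selected: list[str] = []
    current = nb_fit(counts, None)
    trace = [current.aic]
    while remaining:
        best_name, best_fit = None, None
        for name in remaining:
            try:
                trial = nb_fit(counts, candidates[selected + [name]])
            except Exception:
                continue
            if best_fit is None or trial.aic < best_fit.aic - 1e-12:
                best_name, best_fit = name, trial
        if best_fit is None or best_fit.aic >= trace[-1]:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit
        trace.append(best_fit.aic)
    return StepFitResult(selected=selected, aic_trace=trace, fit=current)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Permutation inference on the diagnosis coefficient."""

    observed_coef: float
    n_perm: int
    null_coefs: np.ndarray
    p_value: float
    ks_uniformity: float | None = None

    def __post_init__(self) -> None:
        assert 1.0 / (self.n_perm + 1) <= self.p_value <= 1.0


class BurdenModel:
    """Case/control somatic-burden model.

    Parameters
    ----------
    counts : array-like
        Per-sample somatic SNV counts.
    diagnosis : array-like
        1 for cases, 0 for controls (or 'case'/'control' strings).
    covariates : DataFrame, optional
        Candidate technical/biological covariates for forward selection.
    """

    def __init__(self, counts, diagnosis, covariates: pd.DataFrame | None = None):
        self.counts = np.asarray(counts)
        dx = np.asarray(diagnosis)
        if dx.dtype.kind in "OUS":
            dx = (dx == "case").astype(int)
        self.diagnosis = dx.astype(int)
        if self.diagnosis.sum() == 0 or self.diagnosis.sum() == len(self.diagnosis):
            raise ValueError("both diagnosis groups must be non-empty")
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, count_col: str = "n_ssnv",
                       dx_col: str = "diagnosis", covariate_cols=None) -> "BurdenModel":
        cov = frame[list(covariate_cols)] if covariate_cols else None
        return cls(frame[count_col], frame[dx_col], cov)

    def fit(self, n_perm: int = 10_000, seed: int | None = None,
            reselect_in_perm: bool = False) -> "BurdenResults":
        """Two-stage fit: select covariates without diagnosis, then add it.

        The permutation null refits the final model with shuffled diagnosis
        labels (covariate selection is not re-run unless
        ``reselect_in_perm``); the two-sided p uses the add-one estimator.
        """
        if n_perm < 100:
            warnings.warn("n_perm < 100 gives a coarse permutation p-value")
        step = (forward_step_nb(self.counts, self.covariates)
                if self.covariates is not None
                else StepFitResult([], [nb_fit(self.counts).aic], nb_fit(self.counts)))
        X = pd.DataFrame({"Dx": self.diagnosis})
        if step.selected:
            X = pd.concat(
                [self.covariates[step.selected].reset_index(drop=True), X], axis=1)
        fit = nb_fit(self.counts, X)
        beta_obs = float(fit.params["Dx"])

        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            dx_perm = rng.permutation(self.diagnosis)
            if reselect_in_perm and self.covariates is not None:
                sel = forward_step_nb(self.counts, self.covariates).selected
            else:
                sel = step.selected
            Xp = pd.DataFrame({"Dx": dx_perm})
            if sel:
                Xp = pd.concat(
                    [self.covariates[sel].reset_index(drop=True), Xp], axis=1)
            try:
                null[b] = nb_fit(self.counts, Xp).params["Dx"]
            except Exception:
                null[b] = np.nan
        ok = np.isfinite(null)
        n_eff = int(ok.sum())
        p = (1 + np.sum(np.abs(null[ok]) >= abs(beta_obs))) / (n_eff + 1)
        perm = PermutationResult(
            observed_coef=beta_obs, n_perm=n_eff, null_coefs=null[ok], p_value=float(p))
        return BurdenResults(self, step, fit, perm)


@dataclass
class BurdenResults:
    """Results of the staged burden regression."""

    model: BurdenModel
    step: StepFitResult
    fit: NBFit
    permutation: PermutationResult

    @property
    def diagnosis_coef(self) -> float:
        return float(self.fit.params["Dx"])

    @property
    def diagnosis_pvalue_wald(self) -> float:
        return float(self.fit.pvalues["Dx"])

    @property
    def diagnosis_pvalue_perm(self) -> float:
        return self.permutation.p_value

    def summary(self) -> str:
        lines = ["Somatic burden: staged NB regression",
                 "=" * 44,
                 f"selected covariates : {', '.join(self.step.selected) or '(none)'}",
                 f"AIC trace           : {' -> '.join(f'{a:.1f}' for a in self.step.aic_trace)}",
                 f"model               : {self.fit.model_type}",
                 f"dispersion alpha    : {self.fit.alpha:.4f}",
                 "-" * 44,
                 f"{'term':<12}{'coef':>10}{'se':>10}{'wald p':>10}"]
        for name in self.fit.params.index:
            lines.append(f"{name:<12}{self.fit.params[name]:>10.4f}"
                         f"{self.fit.bse[name]:>10.4f}{self.fit.pvalues[name]:>10.4g}")
        lines += ["-" * 44,
                  f"diagnosis permutation p ({self.permutation.n_perm} perms): "
                  f"{self.permutation.p_value:.4g}"]
        return "\n".join(lines)


def permutation_burden_test(counts, covariates, diagnosis, n_perm: int = 10_000,
                            seed: int | None = None) -> PermutationResult:
    """Functional wrapper around :class:`BurdenModel` permutation inference."""
    return BurdenModel(counts, diagnosis, covariates).fit(
        n_perm=n_perm, seed=seed).permutation


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

@dataclass
class PowerCurve:
    """Rejection fraction of the NB group test across control-mean folds."""

    case_mean: float
    case_var: float
    folds: np.ndarray
    power: np.ndarray
    n_case: int
    n_control: int
    n_reps: int
    seed: int | None


def _nb_size(mean: float, var: float) -> float:
    if var <= mean:
        raise ValueError(
            f"variance {var:.3g} <= mean {mean:.3g}: not NB-representable")
    return mean ** 2 / (var - mean)


def power_simulation(case_counts=None, case_mean: float | None = None,
                     case_var: float | None = None, n_case: int = 60,
                     n_control: int = 25, folds=(1.0, 1.2, 1.4, 1.7, 2.0),
                     n_reps: int = 500, alpha: float = 0.05,
                     seed: int | None = None) -> PowerCurve:
    """Power of the NB group test under variance-preserving mean shifts.

    Cases are NB(mean, var); for each fold f the control distribution keeps
    the case variance but has mean ``case_mean / f`` (size re-solved as
    mean^2 / (var - mean)).  Each replicate draws a cohort, fits the NB
    regression on the group indicator, and tests the group Wald p at
    ``alpha``; the curve reports rejection fractions.
    """
    if case_counts is not None:
        case_counts = np.asarray(case_counts, dtype=float)
        fit = nb_fit(case_counts)
        case_mean = float(np.exp(fit.params["const"]))
        case_var = case_mean + fit.alpha * case_mean ** 2
    if case_mean is None or case_var is None:
        raise ValueError("supply case_counts or (case_mean, case_var)")
    folds = np.asarray(folds, dtype=float)
    size_case = _nb_size(case_mean, case_var)
    rng = np.random.default_rng(seed)
    group = np.r_[np.ones(n_case), np.zeros(n_control)]
    X = pd.DataFrame({"group": group})
    power = np.empty(len(folds))
    for i, f in enumerate(folds):
        m_ctrl = case_mean / f
        try:
            size_ctrl = _nb_size(m_ctrl, case_var)
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        rejections = 0
        for _ in range(n_reps):
            y = np.r_[
                rng.negative_binomial(size_case, size_case / (size_case + case_mean), n_case),
                rng.negative_binomial(size_ctrl, size_ctrl / (size_ctrl + m_ctrl), n_control),
            ]
            try:
                p = nb_fit(y, X).pvalues["group"]
            except Exception:
                continue
            rejections += p < alpha
        power[i] = rejections / n_reps
    return PowerCurve(case_mean=case_mean, case_var=case_var, folds=folds,
                      power=power, n_case=n_case, n_control=n_control,
                      n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# Exact helpers
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float
    flagged_zero_margin: bool = False


def fisher_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's (the classic two-sided convention).  A zero margin
    yields p = 1 with a flag; the sample odds ratio is reported (inf when
    the off-diagonal product is zero).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(p_value=1.0, odds_ratio=np.nan, flagged_zero_margin=True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(p_value=float(p), odds_ratio=float(odds))


def cohort_mean_burden(total: int, n_samples: int, excluded: int = 0,
                       n_excluded: int = 0) -> float:
    """Mean burden per sample after excluding outlier samples' counts."""
    return (total - excluded) / (n_samples - n_excluded)
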