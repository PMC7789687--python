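"""Association recovery: adjusted multinomial models of related outcomes.

Fits baseline-category multinomial logistic models of smoking status
(reference "never") and sleep-duration category (reference 7-9 h) on
dichotomized ideation — self-reported truth or an imputed completed set —
adjusted for sex, age group, race/ethnicity, marital status and
education.  Imputed-exposure fits are pooled across the m datasets by
Rubin's rules on the log-odds scale and compared with the self-report
benchmark by 95% CI overlap.

Models are fit on the target wave only (the wave at which the exposure
was masked); the long-format duplication never enters an analysis model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import columns as C
from .fcs import CompletedSet, dichotomized_target
from .pooling import pool_rubin

__all__ = [
    "AssociationSpec",
    "AORResult",
    "MultinomialFit",
    "SeparationError",
    "fit_multinomial",
    "pooled_aor",
    "self_report_aor",
    "ci_overlap",
]

_EXPOSURE = "ideation"
_COEF_BOUND = 20.0  # |log-odds| beyond this is treated as separation


class SeparationError(RuntimeError):
    """Raised when a fit diverges, indicating complete separation."""


@dataclass
class AssociationSpec:
    """Outcome, its reference level, adjustment covariates and wave."""

    outcome: str
    outcome_ref: str
    covariates: tuple = C.DEMOGRAPHICS
    wave: str = "W2"

    @classmethod
    def smoking(cls) -> "AssociationSpec":
        return cls(outcome=C.SMOKING, outcome_ref="never")

    @classmethod
    def sleep(cls) -> "AssociationSpec":
        return cls(outcome=C.SLEEP_CAT, outcome_ref=C.SLEEP_REF)


@dataclass
class AORResult:
    """Adjusted odds ratios of the exposure per non-reference outcome level."""

    levels: list
    aor: dict
    ci95: dict
    log_or: dict = field(default_factory=dict)
    log_var: dict = field(default_factory=dict)
    overlap_with_benchmark: dict = field(default_factory=dict)

    def flag_overlap(self, benchmark: "AORResult") -> None:
        for lev in self.levels:
            self.overlap_with_benchmark[lev] = ci_overlap(self.ci95[lev], benchmark.ci95[lev])


@dataclass
class MultinomialFit:
    """Coefficients and variances of a baseline-category logit fit."""

    levels: list          # non-reference outcome levels, model order
    terms: list           # exog column names
    coef: pd.DataFrame    # terms x levels
    var: pd.DataFrame     # squared standard errors, terms x levels
    converged: bool


def _design(table: pd.DataFrame, exposure: np.ndarray, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, _EXPOSURE: np.asarray(exposure, dtype=float)},
                     index=table.index)
    for cov in covariates:
        levels = sorted(table[cov].dropna().unique(), key=str)
        for lev in levels[1:]:
            X[f"{cov}[{lev}]"] = (table[cov] == lev).astype(float)
    return X


def fit_multinomial(
    table: pd.DataFrame,
    outcome: str,
    exposure: np.ndarray,
    covariates=C.DEMOGRAPHICS,
    outcome_ref: str | None = None,
) -> MultinomialFit:
    """Maximum-likelihood baseline-category logit of ``outcome``.

    ``exposure`` is a binary vector aligned with ``table``; covariates are
    entered as treatment-coded indicators.  Newton iterations to a tight
    gradient tolerance; the covariance is the inverse observed
    information.  Divergent coefficients (complete separation) raise
    :class:`SeparationError`.
    """
    y = table[outcome]
    if y.isna().any() or pd.isna(np.asarray(exposure, dtype=float)).any():
        raise ValueError("modeled columns must have no missing cells")
    levels = sorted(y.unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"outcome {outcome!r} needs at least 2 levels")
    if outcome_ref is None:
        outcome_ref = levels[0]
    if outcome_ref not in levels:
        raise ValueError(f"reference level {outcome_ref!r} absent from {outcome!r}")
    ordered = [outcome_ref] + [lev for lev in levels if lev != outcome_ref]
    codes = y.map({lev: i for i, lev in enumerate(ordered)}).to_numpy()

    X = _design(table, exposure, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    model = sm.MNLogit(codes, X.to_numpy())
    res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=0)
    params = np.asarray(res.params)          # (k_exog, J-1)
    bse = np.asarray(res.bse).reshape(params.shape, order="F")
    if np.any(np.abs(params) > _COEF_BOUND):
        raise SeparationError("coefficient diverged; likely complete separation")

    nonref = ordered[1:]
    coef = pd.DataFrame(params, index=X.columns, columns=nonref)
    var = pd.DataFrame(bse**2, index=X.columns, columns=nonref)
    return MultinomialFit(levels=nonref, terms=list(X.columns), coef=coef, var=var,
                          converged=bool(res.mle_retvals.get("converged", True)))


def _aor_from_fit(fit: MultinomialFit) -> AORResult:
    from scipy import stats

    aor, ci, log_or, log_var = {}, {}, {}, {}
    z = stats.norm.ppf(0.975)
    for lev in fit.levels:
        b = float(fit.coef.loc[_EXPOSURE, lev])
        v = float(fit.var.loc[_EXPOSURE, lev])
        aor[lev] = float(np.exp(b))
        ci[lev] = (float(np.exp(b - z * np.sqrt(v))), float(np.exp(b + z * np.sqrt(v))))
        log_or[lev], log_var[lev] = b, v
    return AORResult(levels=list(fit.levels), aor=aor, ci95=ci,
                     log_or=log_or, log_var=log_var)


def self_report_aor(table: pd.DataFrame, spec: AssociationSpec,
                    exposure: np.ndarray | None = None,
                    target_item: str = C.IDEATION_ITEM) -> AORResult:
    """Benchmark fit using the true (self-reported) dichotomized exposure."""
    from .synthetic_cohort import dichotomize_ideation

    sub = table.loc[table[C.WAVE] == spec.wave]
    if exposure is None:
        exposure = dichotomize_ideation(sub[target_item].to_numpy(dtype=np.int64))
    fit = fit_multinomial(sub, spec.outcome, exposure, spec.covariates, spec.outcome_ref)
    return _aor_from_fit(fit)


def pooled_aor(completed: CompletedSet, spec: AssociationSpec) -> AORResult:
    """Rubin-pooled AORs of the imputed exposure across the m datasets.

    Per dataset: dichotomize the imputed target, fit the adjusted
    multinomial model on the analysis wave, keep the exposure log-odds
    and its variance per outcome level; pool on the log scale and
    exponentiate the point and interval.  A failed per-dataset fit is
    reported with its dataset index.
    """
    if completed.m < 2:
        raise ValueError("pooling requires at least 2 completed datasets")
    wave_mask = completed.tables[0][C.WAVE] == spec.wave
    exposures = dichotomized_target(completed, wave_mask.to_numpy())

    per_level_b, per_level_v, levels = {}, {}, None
    for i, (tab, expo) in enumerate(zip(completed.tables, exposures)):
        sub = tab.loc[wave_mask]
        try:
            fit = fit_multinomial(sub, spec.outcome, expo, spec.covariates, spec.outcome_ref)
        except Exception as exc:  # noqa: BLE001 - annotate with dataset index
            raise RuntimeError(f"fit failed on imputed dataset {i}: {exc}") from exc
        if levels is None:
            levels = fit.levels
            per_level_b = {lev: [] for lev in levels}
            per_level_v = {lev: [] for lev in levels}
        for lev in levels:
            per_level_b[lev].append(float(fit.coef.loc[_EXPOSURE, lev]))
            per_level_v[lev].append(float(fit.var.loc[_EXPOSURE, lev]))

    aor, ci, log_or, log_var = {}, {}, {}, {}
    for lev in levels:
        pe = pool_rubin(per_level_b[lev], per_level_v[lev])
        aor[lev] = float(np.exp(pe.point))
        ci[lev] = (float(np.exp(pe.ci95[0])), float(np.exp(pe.ci95[1])))
        log_or[lev], log_var[lev] = pe.point, pe.total_var
    return AORResult(levels=list(levels), aor=aor, ci95=ci,
                     log_or=log_or, log_var=log_var)


def ci_overlap(ci_a: tuple, ci_b: tuple) -> bool:
    """True iff the two intervals share at least one point.

    A shared endpoint counts as overlap.
    """
    (la, ha), (lb, hb) = ci_a, ci_b
    if la > ha or lb > hb:
        raise ValueError("interval low endpoint exceeds high endpoint")
    return max(la, lb) <= min(ha, hb)


def association_report(results: dict, benchmark: AORResult, spec: AssociationSpec) -> pd.DataFrame:
    """Report: rows = exposure source, columns = outcome level AOR (CI) + overlap."""
    rows = {}
    rows["self_report"] = {
        lev: f"{benchmark.aor[lev]:.2f} ({benchmark.ci95[lev][0]:.2f}, {benchmark.ci95[lev][1]:.2f})"
        for lev in benchmark.levels
    }
    for model, res in results.items():
        res.flag_overlap(benchmark)
        rows[model] = {
            lev: f"{res.aor[lev]:.2f} ({res.ci95[lev][0]:.2f}, {res.ci95[lev][1]:.2f})"
            + ("" if res.overlap_with_benchmark[lev] else " [no overlap]")
            for lev in res.levels
        }
    return pd.DataFrame(rows).T
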