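"""Two-wave synthetic cohort generator.

Emulates the data structure of a large longitudinal military cohort in
which a 9-item depression screener (4-level items), a 17-item PTSD
checklist (5-level items), physical-functioning and alcohol items,
smoking status and sleep duration are measured at two survey waves.

The ordinal questionnaire items follow a graded-response (ordinal probit)
construction: each participant carries a latent severity per wave, the
two wave latents are bivariate normal with configurable correlation, and
an item response is the latent times a loading plus unit-variance item
noise, cut at per-item increasing thresholds.  The ninth depression item
(suicidal ideation) is calibrated so that its dichotomized prevalence
matches a configurable target, 4.05% by default.  Smoking status and
sleep-duration category are drawn from multinomial-logit models whose
ideation coefficients are the logs of configurable odds ratios, so the
generator's association structure is known exactly and can be recovered
by maximum likelihood.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import columns as C

__all__ = [
    "GeneratorParams",
    "generate_cohort",
    "calibrate_ideation_threshold",
    "screen_ptsd",
    "dichotomize_ideation",
    "write_cohort",
    "read_cohort",
]


def _default_covariate_marginals() -> dict:
    return {
        C.SEX: {"M": 0.72, "F": 0.28},
        C.AGE_GROUP: {"<25": 0.20, "25-34": 0.35, "35-44": 0.30, "45+": 0.15},
        C.RACE_ETH: {"white": 0.70, "black": 0.12, "hispanic": 0.10, "other": 0.08},
        C.MARITAL: {"married": 0.55, "never_married": 0.33, "sep_div_wid": 0.12},
        C.EDUCATION: {"hs_or_less": 0.35, "some_college": 0.40, "college_plus": 0.25},
    }


def _default_covariate_effects() -> dict:
    # Small additive shifts on the latent depression severity.
    return {
        C.SEX: {"F": 0.10},
        C.AGE_GROUP: {"<25": 0.15},
    }


def _default_item_thresholds() -> np.ndarray:
    # Items 1-8: first cuts chosen to give endorsement rates typical of a
    # depression screener, with item 4 ("feeling tired") the most commonly
    # endorsed (~43% at or above "several days").  Item 9 (ideation) cuts
    # are calibrated so the dichotomized prevalence is 4.05% under the
    # default latent structure (see calibrate_ideation_threshold).
    first = np.array([0.55, 0.65, 0.45, 0.32, 0.75, 0.85, 0.95, 1.05])
    t = np.column_stack([first, first + 1.1, first + 2.0])
    ideation = np.array([[2.527, 3.0, 3.4]])
    return np.vstack([t, ideation])


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic two-wave cohort.

    Attributes
    ----------
    n_participants : int
        Cohort size; every participant is observed at both waves.
    cross_wave_rho : float
        Correlation of the latent depression severity between waves,
        in [0, 1).
    item_loadings : (9,) array
        Positive weights of the 9 depression items on the latent severity.
    item_thresholds : (9, 3) array
        Strictly increasing cut points per item mapping latent + noise to
        the 4 ordinal levels 0-3.
    target_ideation_prevalence : float
        Intended dichotomized prevalence of the ninth item (default 0.0405).
        The default thresholds already realize it; pass the params through
        :func:`calibrate_ideation_threshold` after changing the latent
        structure.
    covariate_marginals, covariate_effects : dict
        Category probabilities for the five demographics, and additive
        shifts of selected categories on the latent severity.
    ptsd_rho : float
        Correlation of the PTSD latent with the depression latent.
    pf_rho, alc_rho : float
        Correlations of the physical-functioning and alcohol latents with
        the depression latent.
    smoking_aors : (former, current) odds ratios of dichotomized ideation
        for the smoking outcome, reference "never" (defaults 1.23, 1.87).
    sleep_aors : (<=5h, 6h, >=10h) odds ratios of dichotomized ideation for
        the sleep-category outcome, reference 7-9h
        (defaults 5.44, 2.08, 6.19).
    smoking_marginals, sleep_marginals : baseline category probabilities of
        the outcomes among participants without ideation.
    outcome_covariate_effects : optional dict
        Additive log-odds shifts of demographic categories on every
        non-reference outcome level (defaults to none).
    seed : int
        Master seed; identical params produce byte-identical cohorts.
    """

    n_participants: int = 5000
    cross_wave_rho: float = 0.6
    item_loadings: np.ndarray = field(default_factory=lambda: np.ones(9))
    item_thresholds: np.ndarray = field(default_factory=_default_item_thresholds)
    target_ideation_prevalence: float = 0.0405
    covariate_marginals: dict = field(default_factory=_default_covariate_marginals)
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    ptsd_rho: float = 0.5
    pf_rho: float = 0.3
    alc_rho: float = 0.3
    pcl_loadings: np.ndarray = field(default_factory=lambda: np.ones(17))
    pcl_thresholds: np.ndarray = field(
        default_factory=lambda: np.tile(np.array([0.9, 1.7, 2.5, 3.3]), (17, 1))
    )
    pf_thresholds: np.ndarray = field(
        default_factory=lambda: np.tile(np.array([0.9, 1.9]), (10, 1))
    )
    alc_threshold: float = 1.8
    smoking_aors: tuple = (1.23, 1.87)
    sleep_aors: tuple = (5.44, 2.08, 6.19)
    smoking_marginals: tuple = (0.593, 0.268, 0.139)
    sleep_marginals: tuple = (0.182, 0.330, 0.465, 0.024)
    outcome_covariate_effects: dict | None = None
    seed: int = 0

    def __post_init__(self):
        self.item_loadings = np.asarray(self.item_loadings, dtype=float)
        self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
        self.pcl_loadings = np.asarray(self.pcl_loadings, dtype=float)
        self.pcl_thresholds = np.asarray(self.pcl_thresholds, dtype=float)
        self.pf_thresholds = np.asarray(self.pf_thresholds, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name, rho in [
            ("cross_wave_rho", self.cross_wave_rho),
            ("ptsd_rho", self.ptsd_rho),
            ("pf_rho", self.pf_rho),
            ("alc_rho", self.alc_rho),
        ]:
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {rho}")
        if not (0.0 < self.target_ideation_prevalence < 1.0):
            raise ValueError("target_ideation_prevalence must be in (0, 1)")
        # Zero loadings are legal (items independent of the latent); negative
        # weights would flip item orientation and are rejected.
        if self.item_loadings.shape != (9,) or np.any(self.item_loadings < 0):
            raise ValueError("item_loadings must be 9 nonnegative weights")
        for label, thr in [
            ("item_thresholds", self.item_thresholds),
            ("pcl_thresholds", self.pcl_thresholds),
            ("pf_thresholds", self.pf_thresholds),
        ]:
            if np.any(np.diff(thr, axis=1) <= 0):
                raise ValueError(f"{label} must be strictly increasing per item")
        if self.item_thresholds.shape != (9, 3):
            raise ValueError("item_thresholds must have shape (9, 3)")
        for var, marg in self.covariate_marginals.items():
            p = np.array(list(marg.values()), dtype=float)
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"covariate_marginals[{var}] must sum to 1")
        for probs in (self.smoking_marginals, self.sleep_marginals):
            p = np.asarray(probs, dtype=float)
            # Allow distributions quoted from rounded percentages (e.g. a
            # printed 18.2/33.0/46.5/2.4 split sums to 100.1); they are
            # renormalized where used.
            if np.any(p < 0) or abs(p.sum() - 1.0) > 5e-3:
                raise ValueError("outcome marginals must be probabilities summing to 1")
        if np.any(np.asarray(self.smoking_aors) <= 0) or np.any(
            np.asarray(self.sleep_aors) <= 0
        ):
            raise ValueError("odds ratios must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        for k in ("smoking_aors", "sleep_aors", "smoking_marginals", "sleep_marginals"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def dichotomize_ideation(level):
    """Dichotomize a 4-level ideation item: positive at "several days" or more.

    Level 0 is "not at all"; any level >= 1 counts as present.
    """
    arr = np.asarray(level)
    if arr.size and (np.any(arr < 0) | np.any(arr > 3)):
        raise ValueError("ideation levels must be coded 0..3")
    out = (arr >= 1).astype(np.int64)
    return out if arr.ndim else int(out)


def screen_ptsd(pcl_items) -> np.ndarray:
    """DSM-IV "sensitive" PTSD screen from 17 checklist items coded 0-4.

    Positive iff "moderately" or greater (code >= 2) is endorsed on at
    least 1 intrusion, 3 avoidance and 2 hyperarousal items simultaneously.
    Accepts a (17,) vector or an (n, 17) matrix in instrument order
    (5 intrusion, 7 avoidance, 5 hyperarousal).
    """
    arr = np.atleast_2d(np.asarray(pcl_items))
    if arr.shape[1] != 17:
        raise ValueError(f"expected 17 checklist items, got {arr.shape[1]}")
    mod = arr >= 2
    intr = mod[:, 0:5].sum(axis=1)
    avoid = mod[:, 5:12].sum(axis=1)
    hyper = mod[:, 12:17].sum(axis=1)
    flag = ((intr >= 1) & (avoid >= 3) & (hyper >= 2)).astype(np.int64)
    return flag if np.asarray(pcl_items).ndim == 2 else int(flag[0])


def _cut(ystar: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Ordinal level = number of thresholds at or below the latent response."""
    return (ystar[:, None] >= thresholds[None, :]).sum(axis=1).astype(np.int64)


def _draw_categorical(rng, logits: np.ndarray, levels: tuple) -> np.ndarray:
    """Draw one category per row from unnormalized log-probabilities."""
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


def _latent_shift(params: GeneratorParams, demo: dict) -> np.ndarray:
    n = params.n_participants
    shift = np.zeros(n)
    for var, effects in (params.covariate_effects or {}).items():
        for lev, eff in effects.items():
            shift += np.where(demo[var] == lev, eff, 0.0)
    return shift


def _outcome_logits(
    base_probs, aors, si, ref_index, demo, effects: dict | None
) -> np.ndarray:
    """Multinomial-logit linear predictors, reference level at ref_index."""
    base = np.asarray(base_probs, dtype=float)
    k = base.size
    n = si.size
    logits = np.zeros((n, k))
    nonref = [j for j in range(k) if j != ref_index]
    for pos, j in enumerate(nonref):
        logits[:, j] = np.log(base[j] / base[ref_index]) + np.log(aors[pos]) * si
        if effects:
            for var, levs in effects.items():
                for lev, eff in levs.items():
                    logits[:, j] += np.where(demo[var] == lev, eff, 0.0)
    return logits


def generate_cohort(params: GeneratorParams) -> pd.DataFrame:
    """Generate a long-format cohort: one row per participant per wave.

    Deterministic given ``params`` (including the seed).  Returns a
    DataFrame sorted by participant then wave, with integer item codes,
    float sleep hours and string categoricals.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    pid = np.array([f"P{i:07d}" for i in range(1, n + 1)], dtype=object)

    demo = {}
    for var, marg in params.covariate_marginals.items():
        levels = list(marg.keys())
        demo[var] = rng.choice(np.asarray(levels, dtype=object), size=n, p=list(marg.values()))
    shift = _latent_shift(params, demo)

    # Latent depression severity, bivariate normal across waves.
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.cross_wave_rho
    u = {"W1": z1, "W2": rho * z1 + np.sqrt(1.0 - rho**2) * z2}

    wave_frames = []
    for wave in C.WAVES:
        theta = shift + u[wave]
        rec = {C.PID: pid, C.WAVE: np.repeat(wave, n)}
        rec.update(demo)

        for j, item in enumerate(C.PHQ_ITEMS):
            ystar = params.item_loadings[j] * theta + rng.standard_normal(n)
            rec[item] = _cut(ystar, params.item_thresholds[j])

        psi = params.ptsd_rho * u[wave] + np.sqrt(1 - params.ptsd_rho**2) * rng.standard_normal(n)
        pcl = np.empty((n, 17), dtype=np.int64)
        for j, item in enumerate(C.PCL_ITEMS):
            ystar = params.pcl_loadings[j] * psi + rng.standard_normal(n)
            pcl[:, j] = _cut(ystar, params.pcl_thresholds[j])
            rec[item] = pcl[:, j]
        rec[C.PTSD_SCREEN] = screen_ptsd(pcl)

        phi = params.pf_rho * u[wave] + np.sqrt(1 - params.pf_rho**2) * rng.standard_normal(n)
        for j, item in enumerate(C.PF_ITEMS):
            rec[item] = _cut(phi + rng.standard_normal(n), params.pf_thresholds[j])

        alpha = params.alc_rho * u[wave] + np.sqrt(1 - params.alc_rho**2) * rng.standard_normal(n)
        for item in C.ALC_ITEMS:
            rec[item] = ((alpha + rng.standard_normal(n)) >= params.alc_threshold).astype(np.int64)

        si = dichotomize_ideation(rec[C.IDEATION_ITEM]).astype(float)

        logits = _outcome_logits(
            params.smoking_marginals, params.smoking_aors, si, 0,
            demo, params.outcome_covariate_effects,
        )
        rec[C.SMOKING] = _draw_categorical(rng, logits, C.SMOKING_LEVELS)

        logits = _outcome_logits(
            params.sleep_marginals, params.sleep_aors, si, 2,
            demo, params.outcome_covariate_effects,
        )
        cat = _draw_categorical(rng, logits, C.SLEEP_LEVELS)
        hours = np.empty(n)
        for lev, choices, probs in [
            ("le5", [3.0, 4.0, 5.0], [0.15, 0.35, 0.5]),
            ("6", [6.0], [1.0]),
            ("7-9", [7.0, 8.0, 9.0], [0.45, 0.40, 0.15]),
            ("ge10", [10.0, 11.0], [0.8, 0.2]),
        ]:
            mask = cat == lev
            hours[mask] = rng.choice(choices, size=int(mask.sum()), p=probs)
        rec[C.SLEEP_HOURS] = hours
        rec[C.SLEEP_CAT] = C.categorize_sleep(hours)

        wave_frames.append(pd.DataFrame(rec))

    table = pd.concat(wave_frames, ignore_index=True)
    table = table.sort_values([C.PID, C.WAVE], kind="stable", ignore_index=True)
    return table[list(C.ALL_VARIABLES)]


def calibrate_ideation_threshold(
    params: GeneratorParams,
    tol: float = 0.001,
    n_draws: int = 200_000,
    max_iter: int = 200,
) -> GeneratorParams:
    """Set the ninth item's first threshold to hit the target prevalence.

    Bisects the first cut point of the ideation item against the empirical
    distribution of its latent response (loading x latent severity + item
    noise) over ``n_draws`` Monte-Carlo draws, until the simulated
    dichotomized prevalence is within ``tol`` of
    ``params.target_ideation_prevalence``.  The upper cuts are shifted up
    if needed to remain strictly increasing.  Returns a new params object.
    """
    target = params.target_ideation_prevalence
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x1DEA]))

    # Latent margin of the ideation item at one wave.
    demo = {}
    for var, marg in params.covariate_marginals.items():
        levels = np.asarray(list(marg.keys()), dtype=object)
        demo[var] = rng.choice(levels, size=n_draws, p=list(marg.values()))
    shift = np.zeros(n_draws)
    for var, effects in (params.covariate_effects or {}).items():
        for lev, eff in effects.items():
            shift += np.where(demo[var] == lev, eff, 0.0)
    lam = params.item_loadings[8]
    s = lam * (shift + rng.standard_normal(n_draws)) + rng.standard_normal(n_draws)

    lo, hi = float(s.min()) - 1.0, float(s.max()) + 1.0
    if not (np.mean(s >= lo) >= target >= np.mean(s >= hi)):
        raise ValueError("search interval does not bracket the target prevalence")
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        prev = float(np.mean(s >= t))
        if abs(prev - target) <= tol:
            break
        if prev > target:
            lo = t
        else:
            hi = t
    else:
        raise ValueError("bisection did not converge to the target prevalence")

    thr = params.item_thresholds.copy()
    thr[8, 0] = t
    if thr[8, 1] <= t:
        thr[8, 1] = t + 0.4
    if thr[8, 2] <= thr[8, 1]:
        thr[8, 2] = thr[8, 1] + 0.4
    return dataclasses.replace(params, item_thresholds=thr)


def write_cohort(table: pd.DataFrame, path, params: GeneratorParams | None = None) -> None:
    """Write a cohort to CSV with an optional sidecar JSON of the parameters."""
    table.to_csv(path, index=False)
    if params is not None:
        sidecar = str(path) + ".params.json"
        with open(sidecar, "w") as fh:
            json.dump(params.to_dict(), fh, indent=1)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, keeping item codes integer where fully observed."""
    df = pd.read_csv(path, dtype={C.PID: str, C.WAVE: str})
    for col in df.columns:
        if df[col].dtype == np.float64 and col != C.SLEEP_HOURS:
            if not df[col].isna().any() and np.allclose(df[col] % 1, 0):
                df[col] = df[col].astype(np.int64)
    return df
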