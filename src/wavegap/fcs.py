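"""Fully-conditional-specification multiple imputation engine.

Imputes each incomplete variable from a univariate conditional model
given the other modeled variables, cycling through the visit sequence,
and produces ``m`` completed copies of the input table.  Categorical
variables (binary, 4-level ordinal, nominal) are drawn from linear-
discriminant class posteriors; continuous variables from a Bayesian
linear model (see :mod:`wavegap.imputers`).

The model presets mirror a validation design for a depression-module
item that is completely missing at the second of two survey waves:

* ``PHQ-BIN`` / ``PHQ-ORD`` — the 8 remaining depression items predict
  the target, treated as dichotomized or as the full 4-level item.
* ``ALL-BIN`` / ``ALL-ORD`` — adds demographics, 10 physical-functioning
  items, the 17 PTSD-checklist items plus the composite screen, smoking,
  sleep duration (continuous) and 5 alcohol items: 48 predictors.
* ``RAN`` — the uninformed baseline: the target is assigned at random at
  its observed prevalence, with no predictive information.

Because the tables are in long format, the conditionals are learned from
the wave at which the target is observed and applied to the wave at
which it is missing: the cross-wave transfer is the point of the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import columns as C
from .imputers import BayesianLinearImputer, DiscriminantImputer
from .synthetic_cohort import dichotomize_ideation

__all__ = [
    "VariableSpec",
    "ImputationConfig",
    "CompletedSet",
    "PRESETS",
    "apply_preset",
    "prepare_target_column",
    "fit_fcs",
    "ran_assign",
]

PRESETS = ("RAN", "PHQ-BIN", "PHQ-ORD", "ALL-BIN", "ALL-ORD")

_LEVELS = ("binary", "ordinal4", "nominal", "continuous")
_FORMS = ("discriminant", "linear")
_ROLES = ("target", "predictor", "excluded")


@dataclass(frozen=True)
class VariableSpec:
    """Measurement level, imputation form and model role of one variable."""

    name: str
    level: str
    imputation_form: str
    role: str

    def __post_init__(self):
        if self.level not in _LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.imputation_form not in _FORMS:
            raise ValueError(f"unknown imputation form {self.imputation_form!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.level == "continuous" and self.imputation_form != "linear":
            raise ValueError("continuous variables use the linear form")
        if self.level != "continuous" and self.imputation_form != "discriminant":
            raise ValueError("categorical variables use the discriminant form")


@dataclass
class ImputationConfig:
    """Engine configuration: preset, number of imputations, cycling, seed."""

    preset: str = "custom"
    m_imputations: int = 100
    burn_in_cycles: int = 10
    visit_sequence: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be at least 2 for pooling")
        if self.burn_in_cycles < 1:
            raise ValueError("burn_in_cycles must be positive")


@dataclass
class CompletedSet:
    """m completed copies of a masked table, plus provenance.

    Observed cells are identical across all ``m`` tables and to the
    input; only the originally missing cells vary between copies.
    """

    tables: list
    config: ImputationConfig
    target: str
    child_seeds: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.tables)

    def imputed_values(self, rows_mask: np.ndarray, variable: str | None = None) -> list:
        """Per-imputation values of ``variable`` at the given row mask."""
        variable = variable or self.target
        return [t.loc[rows_mask, variable].to_numpy() for t in self.tables]


def _spec(name, level, role="predictor"):
    form = "linear" if level == "continuous" else "discriminant"
    return VariableSpec(name, level, form, role)


def prepare_target_column(table: pd.DataFrame, target_item: str, form: str):
    """Return (table, target-name) for the requested target form.

    ``form`` "ordinal4" models the 4-level item itself; "binary" adds a
    dichotomized working column (positive at level >= 1, missing where the
    item is missing) and models that.
    """
    if form == "ordinal4":
        return table, target_item
    if form != "binary":
        raise ValueError(f"unknown target form {form!r}")
    name = f"{target_item}_bin"
    out = table.copy()
    col = table[target_item]
    vals = np.where(col.isna(), np.nan, 0.0)
    vals[(col >= 1).to_numpy(dtype=bool)] = 1.0
    out[name] = vals
    return out, name


def apply_preset(preset: str, target_item: str = C.IDEATION_ITEM):
    """Model preset -> (variable specs, visit sequence).

    PHQ-* presets predict the target from the 8 remaining depression
    items; ALL-* presets add demographics, physical functioning, the PTSD
    items plus composite, smoking, continuous sleep duration and the
    alcohol items (48 predictors).  *-BIN presets model the dichotomized
    target, *-ORD the 4-level item.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if preset == "RAN":
        raise ValueError("the RAN baseline has no imputation model; use ran_assign")
    if target_item not in C.PHQ_ITEMS:
        raise ValueError(f"target must be one of the 9 depression items, got {target_item!r}")

    form = "binary" if preset.endswith("BIN") else "ordinal4"
    target_name = f"{target_item}_bin" if form == "binary" else target_item
    target_level = "binary" if form == "binary" else "ordinal4"

    other_phq = [it for it in C.PHQ_ITEMS if it != target_item]
    specs = [_spec(target_name, target_level, role="target")]
    specs += [_spec(it, "ordinal4") for it in other_phq]
    if preset.startswith("ALL"):
        specs += [_spec(v, "nominal") for v in C.DEMOGRAPHICS]
        specs += [_spec(it, "ordinal4") for it in C.PF_ITEMS]
        specs += [_spec(it, "ordinal4") for it in C.PCL_ITEMS]
        specs += [_spec(C.PTSD_SCREEN, "binary")]
        specs += [_spec(C.SMOKING, "nominal")]
        specs += [_spec(C.SLEEP_HOURS, "continuous")]
        specs += [_spec(it, "binary") for it in C.ALC_ITEMS]
    visit_sequence = [s.name for s in specs]
    return specs, visit_sequence


def _categories(table: pd.DataFrame, specs: dict) -> dict:
    cats = {}
    for name, s in specs.items():
        if s.level == "nominal":
            vals = table[name].dropna().unique().tolist()
            cats[name] = sorted(vals, key=str)
    return cats


def _encode(df: pd.DataFrame, predictor_names, specs: dict, cats: dict) -> np.ndarray:
    cols = []
    for name in predictor_names:
        s = specs[name]
        if s.level == "nominal":
            col = df[name].to_numpy()
            for lev in cats[name][1:]:
                cols.append((col == lev).astype(float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def fit_fcs(
    masked: pd.DataFrame, specs: list, config: ImputationConfig
) -> CompletedSet:
    """Run chained-equations imputation, returning m completed tables.

    For each imputation (independent seed stream): missing cells are
    initialized by draws from the observed margins, then for each burn-in
    cycle the incomplete variables are visited in sequence, the variable's
    univariate model is refit on the currently complete data and its
    missing cells are redrawn; the final cycle's values are kept.  When a
    single variable is incomplete its conditional model does not depend on
    any imputed value, so the chain is converged after one cycle and the
    engine takes that exact shortcut.
    """
    spec_map = {s.name: s for s in specs}
    if len(spec_map) != len(specs):
        raise ValueError("duplicate variable specs")
    targets = [s for s in specs if s.role == "target"]
    if len(targets) != 1:
        raise ValueError("exactly one target variable is required")
    predictors = [s.name for s in specs if s.role == "predictor"]
    if not predictors:
        raise ValueError("at least one predictor is required")
    modeled = [s.name for s in specs if s.role != "excluded"]
    for name in modeled:
        if name not in masked.columns:
            raise KeyError(f"modeled variable {name!r} not in table")

    miss = {v: masked[v].isna().to_numpy() for v in modeled}
    missing_vars = [v for v in modeled if miss[v].any()]
    if not missing_vars:
        # Nothing to impute: m identical copies of the input.
        return CompletedSet(
            tables=[masked.copy() for _ in range(config.m_imputations)],
            config=config, target=targets[0].name,
        )
    for v in missing_vars:
        if miss[v].all():
            raise ValueError(f"{v!r} has no observed rows to fit on")

    cats = _categories(masked, spec_map)
    visit = [v for v in (config.visit_sequence or modeled) if v in missing_vars]
    if set(visit) != set(missing_vars):
        raise ValueError("visit_sequence must cover every incomplete variable")
    n_cycles = 1 if len(missing_vars) == 1 else config.burn_in_cycles

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.m_imputations)
    tables, child_ids = [], []

    for child in children:
        rng = np.random.default_rng(child)
        work = masked.copy()

        for v in missing_vars:
            obs_vals = masked.loc[~miss[v], v].to_numpy()
            fill = rng.choice(obs_vals, size=int(miss[v].sum()), replace=True)
            work.loc[miss[v], v] = fill

        for _ in range(n_cycles):
            for v in visit:
                s = spec_map[v]
                if s.role == "target":
                    pred_names = predictors
                else:
                    pred_names = [u for u in modeled if u != v]
                X = _encode(work, pred_names, spec_map, cats)
                obs, mis = ~miss[v], miss[v]
                if s.imputation_form == "discriminant":
                    y_obs = masked.loc[obs, v].to_numpy()
                    model = DiscriminantImputer().fit(X[obs], y_obs, rng)
                    work.loc[mis, v] = model.draw(X[mis], rng)
                else:
                    y_obs = masked.loc[obs, v].to_numpy(dtype=float)
                    model = BayesianLinearImputer().fit(X[obs], y_obs, rng)
                    work.loc[mis, v] = model.draw(X[mis], rng)

        tables.append(work)
        child_ids.append(int(child.entropy) if isinstance(child.entropy, int) else 0)

    return CompletedSet(tables=tables, config=config, target=targets[0].name,
                        child_seeds=child_ids)


def ran_assign(n: int, p: float, rng) -> np.ndarray:
    """Random-assignment baseline: n i.i.d. Bernoulli(p) draws.

    Independent of any participant data; mirrors assigning the target at
    its observed prevalence without predictive information.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return (rng.random(int(n)) < p).astype(np.int64)


def dichotomized_target(cs: CompletedSet, rows_mask: np.ndarray) -> list:
    """Per-imputation binary target at the masked rows.

    Ordinal-target presets are dichotomized after imputation (level >= 1);
    binary-target presets are returned as-is.
    """
    out = []
    for vals in cs.imputed_values(rows_mask):
        vals = np.asarray(vals, dtype=float)
        if cs.target.endswith("_bin"):
            out.append(vals.astype(np.int64))
        else:
            out.append(dichotomize_ideation(vals.astype(np.int64)))
    return out
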