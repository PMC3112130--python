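"""Five-group ACE liability model fitted by full-information maximum likelihood.

The liability of each twin is decomposed into additive genetic (A), common
(shared) environmental (C) and unique environmental (E) influences with
standardized path coefficients a, c, e per sex and cohort, constrained to
unit liability variance (a^2 + c^2 + e^2 = 1).  The model implies the twin
liability correlations

* MZ same-sex:  a^2 + c^2
* DZ same-sex:  0.5 a^2 + c^2
* DZ opposite-sex (DOS):  0.5 a_M a_F + Rcdos c_M c_F

where Rcdos is the correlation between the shared-environment factors of the
male and the female co-twin; Rcdos = 1 means no qualitative sex difference in
the shared environment.  The DOS additive-genetic correlation is fixed at
0.5.  Thresholds are always free per sex x zygosity x cohort (8 for two
cohorts).

Fitting maximizes the raw-data likelihood: complete pairs contribute the
bivariate-normal joint-outcome probability of their cell, singletons the
Bernoulli margin of their own threshold.  The likelihood reduces exactly to
the per-group concordance tables, which is what the optimizer consumes.

A ladder of nested models (1-8) tests, in order: qualitative sex differences
(Rcdos = 1), cohort equality of A/C/E per sex and jointly (the gene-by-
environment question), quantitative sex differences, and whether A or C can
be dropped.  Degrees of freedom follow the raw-data convention
``df = n_individuals - n_free_parameters + n_constraint_equations`` with one
unit-variance constraint per sex x cohort, counting a, c and e all as free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import norm

from .liability import _phi_bar
from .tetrachoric import _table_m2ll_grad, concordance_table
from .twin_io import GROUPS, GROUP_SEXES, GROUP_ZYGOSITY, TwinDataset, TwinPairRecord

__all__ = [
    "ACEParams",
    "ModelSpec",
    "MODELS",
    "FitResult",
    "implied_correlation",
    "pair_loglik",
    "fit",
    "fit_saturated",
    "model_df",
    "profile_ci",
]

_CHI2_95_1DF = 3.841458820694124
_RHO_CAP = 0.999999
#: Rcdos is allowed well past +-1 (the likelihood only needs the implied DOS
#: correlation inside (-1, 1)) so that the Rcdos = 1 hypothesis is interior
#: and its likelihood-ratio test is regular; the binding constraint is then
#: the implied-correlation clamp, the natural information boundary.
_RC_SCALE = 4.0

_SEXES = ("M", "F")
_ZYGS = ("MZ", "DZ")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACEParams:
    """Standardized ACE paths, shared-environment sex correlation, thresholds.

    ``paths[(sex, cohort)] = (a, c, e)`` with a^2+c^2+e^2 = 1;
    ``rcdos[cohort]``; ``thresholds[(sex, zygosity, cohort)]`` in
    standard-normal units.
    """

    paths: Mapping[tuple, tuple]
    rcdos: Mapping[str, float]
    thresholds: Mapping[tuple, float]

    def __post_init__(self):
        for key, (a, c, e) in self.paths.items():
            if abs(a * a + c * c + e * e - 1.0) > 1e-8:
                raise ValueError(f"unit-variance violation at {key}: {(a, c, e)}")

    def shares(self, sex: str, cohort: str) -> tuple:
        a, c, e = self.paths[(sex, cohort)]
        return (a * a, c * c, e * e)

    @classmethod
    def from_shares(cls, shares, rcdos, thresholds) -> "ACEParams":
        paths = {}
        for key, (A, C, E) in shares.items():
            s = A + C + E
            paths[key] = (math.sqrt(A / s), math.sqrt(C / s), math.sqrt(E / s))
        return cls(paths=paths, rcdos=dict(rcdos), thresholds=dict(thresholds))


def implied_correlation(params: ACEParams, group: str, cohort: str) -> float:
    """Twin liability correlation implied by the model for one group."""
    if group == "DOS":
        a_m, c_m, _ = params.paths[("M", cohort)]
        a_f, c_f, _ = params.paths[("F", cohort)]
        return 0.5 * a_m * a_f + params.rcdos[cohort] * c_m * c_f
    sex = GROUP_SEXES[group][0]
    a, c, _ = params.paths[(sex, cohort)]
    gen = 1.0 if GROUP_ZYGOSITY[group] == "MZ" else 0.5
    return gen * a * a + c * c


def pair_loglik(rec: TwinPairRecord, params: ACEParams) -> float:
    """Raw-data log-likelihood contribution of one record.

    Complete pairs use the joint-outcome cell probability at the implied
    correlation; singletons use the Bernoulli margin of their own threshold.
    A zero-probability cell yields a large negative sentinel (-1e10) rather
    than -inf so optimizers and sums stay finite.
    """
    from .liability import cell_probabilities

    cohort = rec.cohort
    zyg = GROUP_ZYGOSITY[rec.group]
    sexes = rec.sexes
    t1 = params.thresholds[(sexes[0], zyg, cohort)]
    t2 = params.thresholds[(sexes[1], zyg, cohort)]
    if rec.is_pair:
        rho = implied_correlation(params, rec.group, cohort)
        cp = cell_probabilities(t1, t2, min(max(rho, -1.0), 1.0))
        p = {(1, 1): cp.p11, (1, 0): cp.p10, (0, 1): cp.p01, (0, 0): cp.p00}[
            (rec.pheno1, rec.pheno2)
        ]
    else:
        pheno, tau = ((rec.pheno1, t1) if rec.pheno1 is not None else (rec.pheno2, t2))
        p = _phi_bar(tau) if pheno == 1 else 1.0 - _phi_bar(tau)
    if p <= 0.0:
        return -1e10
    return math.log(p)


# ---------------------------------------------------------------------------
# Model specifications (the Table-4 ladder)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Equality/fixing structure of one nested model.

    ``share_classes`` maps (sex, cohort position) to an equality-class label:
    cells in the same class share one (a, c, e) triple.  ``fixed_shares``
    pins variance shares (e.g. ``{"A": 0.0}`` drops the genetic factor) in
    every class.  ``rcdos_fixed`` pins the DOS shared-environment correlation
    in every cohort (None = free per cohort).  ``parent`` is the comparison
    model of the likelihood-ratio ladder.
    """

    model_id: int
    description: str
    share_classes: Mapping[tuple, str]
    rcdos_fixed: Optional[float] = None
    fixed_shares: Mapping[str, float] = field(default_factory=dict)
    parent: Optional[int] = None

    @property
    def class_labels(self) -> tuple:
        return tuple(dict.fromkeys(self.share_classes.values()))

    def n_cohort_positions(self) -> int:
        return 1 + max(pos for (_, pos) in self.share_classes)

    def n_free_params(self, n_cohorts: int = 2) -> int:
        """Free-parameter count in the a/c/e-all-free accounting."""
        per_class = 3 - len(self.fixed_shares)
        n_paths = per_class * len(self.class_labels)
        n_thresholds = 2 * len(_ZYGS) * n_cohorts
        n_rc = 0 if self.rcdos_fixed is not None else n_cohorts
        return n_paths + n_thresholds + n_rc

    def n_constraints(self, n_cohorts: int = 2) -> int:
        """One unit-variance constraint per sex x cohort, regardless of
        equality classes."""
        return 2 * n_cohorts

    def is_nested_in(self, other: "ModelSpec") -> bool:
        spec = self
        while spec.parent is not None:
            if spec.parent == other.model_id:
                return True
            spec = MODELS[spec.parent]
        return False


def _classes(men: Sequence[str], women: Sequence[str]) -> dict:
    return {
        ("M", 0): men[0], ("M", 1): men[1],
        ("F", 0): women[0], ("F", 1): women[1],
    }


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "Full ACE", _classes(["M0", "M1"], ["F0", "F1"])),
    2: ModelSpec(2, "Constrain Rcdos at 1", _classes(["M0", "M1"], ["F0", "F1"]),
                 rcdos_fixed=1.0, parent=1),
    3: ModelSpec(3, "EQ ACE for men over cohorts", _classes(["M", "M"], ["F0", "F1"]),
                 rcdos_fixed=1.0, parent=2),
    4: ModelSpec(4, "EQ ACE for women over cohorts", _classes(["M0", "M1"], ["F", "F"]),
                 rcdos_fixed=1.0, parent=2),
    5: ModelSpec(5, "EQ ACE for both sexes over cohorts", _classes(["M", "M"], ["F", "F"]),
                 rcdos_fixed=1.0, parent=2),
    6: ModelSpec(6, "No sex differences in contributions of A,C,E",
                 _classes(["MF", "MF"], ["MF", "MF"]), rcdos_fixed=1.0, parent=5),
    7: ModelSpec(7, "Drop A", _classes(["MF", "MF"], ["MF", "MF"]),
                 rcdos_fixed=1.0, fixed_shares={"A": 0.0}, parent=6),
    8: ModelSpec(8, "Drop C", _classes(["MF", "MF"], ["MF", "MF"]),
                 rcdos_fixed=1.0, fixed_shares={"C": 0.0}, parent=6),
}


def raw_df(n_individuals: int, n_free_params: int,
           n_constraint_equations: int = 0) -> int:
    """Raw-data degrees of freedom:
    ``n_individuals - n_free_params + n_constraint_equations``."""
    return n_individuals - n_free_params + n_constraint_equations


def model_df(spec: ModelSpec, n_individuals: int, n_cohorts: int = 2) -> int:
    """Ladder-model df; the a/c/e-all-free accounting with one unit-variance
    constraint per sex x cohort."""
    return raw_df(n_individuals, spec.n_free_params(n_cohorts),
                  spec.n_constraints(n_cohorts))


# ---------------------------------------------------------------------------
# Share-class parameterizations (internal)
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


class _ShareParam:
    """Maps unconstrained optimizer parameters to variance shares (A, C).

    Free shares use stick-breaking on the unit simplex: A = sigmoid(u),
    C = (1 - A) sigmoid(v), E the remainder — all shares stay in (0, 1) and
    sum to one by construction.  Any subset of {A, C, E} may be pinned, which
    serves both the drop-A/drop-C models and the profile-likelihood CIs.
    """

    def __init__(self, fixed: Optional[Mapping[str, float]] = None):
        self.fixed = dict(fixed or {})
        if len(self.fixed) >= 2:
            self.n_params = 0
        elif self.fixed:
            self.n_params = 1
        else:
            self.n_params = 2

    def start(self, A0: float, C0: float) -> list:
        f = self.fixed
        if self.n_params == 0:
            return []
        if not f:
            A0 = min(max(A0, 1e-6), 1 - 2e-6)
            return [_logit(A0), _logit(min(max(C0 / (1.0 - A0), 1e-6), 1 - 1e-6))]
        if "A" in f:
            rem = max(1.0 - f["A"], 1e-12)
            return [_logit(min(max(C0 / rem, 1e-6), 1 - 1e-6))]
        if "C" in f:
            rem = max(1.0 - f["C"], 1e-12)
            return [_logit(min(max(A0 / rem, 1e-6), 1 - 1e-6))]
        rem = max(1.0 - f["E"], 1e-12)
        return [_logit(min(max(A0 / rem, 1e-6), 1 - 1e-6))]

    def value_jac(self, theta) -> tuple:
        """Returns (A, C, dA/dtheta, dC/dtheta) with jacobians as lists."""
        f = self.fixed
        if self.n_params == 0:
            A = f["A"] if "A" in f else 1.0 - f["C"] - f["E"]
            C = f["C"] if "C" in f else 1.0 - f["A"] - f["E"]
            return A, C, [], []
        if not f:
            u, v = theta
            A = _sigmoid(u)
            sv = _sigmoid(v)
            C = (1.0 - A) * sv
            dA = A * (1.0 - A)
            return A, C, [dA, 0.0], [-dA * sv, (1.0 - A) * sv * (1.0 - sv)]
        t = theta[0]
        s = _sigmoid(t)
        ds = s * (1.0 - s)
        if "A" in f:
            A = f["A"]
            rem = 1.0 - A
            return A, rem * s, [0.0], [rem * ds]
        if "C" in f:
            C = f["C"]
            rem = 1.0 - C
            return rem * s, C, [rem * ds], [0.0]
        rem = 1.0 - f["E"]
        return rem * s, rem * (1.0 - s), [rem * ds], [-rem * ds]


# ---------------------------------------------------------------------------
# The FIML optimization problem
# ---------------------------------------------------------------------------

def _suffstats(ds: TwinDataset) -> dict:
    out = {}
    for cohort in ds.cohorts:
        for group in GROUPS:
            sub = ds.subset(group=group, cohort=cohort)
            if sub.records:
                out[(group, cohort)] = concordance_table(ds, group, cohort)
    return out


def _threshold_starts(stats: dict, cohorts) -> dict:
    """Moment starts: thresholds at the observed (sex, zygosity, cohort)
    prevalence quantiles."""
    tallies = {}
    for (group, cohort), tab in stats.items():
        zyg = GROUP_ZYGOSITY[group]
        sexes = GROUP_SEXES[group]
        for role, sex in enumerate(sexes):
            (aff, tot) = tab.margins()[role]
            key = (sex, zyg, cohort)
            a0, t0 = tallies.get(key, (0.0, 0.0))
            tallies[key] = (a0 + aff, t0 + tot)
    out = {}
    for cohort in cohorts:
        for sex in _SEXES:
            for zyg in _ZYGS:
                key = (sex, zyg, cohort)
                aff, tot = tallies.get(key, (0.0, 0.0))
                if tot > 0:
                    prev = min(max(aff / tot, 0.5 / (tot + 1)), 1 - 0.5 / (tot + 1))
                    out[key] = float(norm.isf(prev))
                else:
                    out[key] = 0.0
    return out


class _Problem:
    """Assembles the transformed parameter vector, the -2 log-likelihood and
    its analytic gradient for one ModelSpec on one dataset."""

    def __init__(self, stats: dict, cohorts: Sequence[str], spec: ModelSpec,
                 class_fixed_override: Optional[dict] = None,
                 rc_fixed_override: Optional[dict] = None):
        self.stats = stats
        self.cohorts = tuple(cohorts)
        self.spec = spec
        if spec.n_cohort_positions() > len(self.cohorts):
            raise ValueError(
                f"model {spec.model_id} needs {spec.n_cohort_positions()} cohorts, "
                f"dataset has {len(self.cohorts)}"
            )
        # share classes
        self.class_param = {}
        for label in spec.class_labels:
            fixed = dict(spec.fixed_shares)
            if class_fixed_override and label in class_fixed_override:
                fixed.update(class_fixed_override[label])
            self.class_param[label] = _ShareParam(fixed)
        self.class_offset = {}
        off = 0
        for label, par in self.class_param.items():
            self.class_offset[label] = off
            off += par.n_params
        # Rcdos per cohort
        self.rc_fixed = {}
        self.rc_offset = {}
        for j, cohort in enumerate(self.cohorts):
            if rc_fixed_override and cohort in rc_fixed_override:
                self.rc_fixed[cohort] = rc_fixed_override[cohort]
            elif spec.rcdos_fixed is not None:
                self.rc_fixed[cohort] = spec.rcdos_fixed
            else:
                self.rc_offset[cohort] = off
                off += 1
        # thresholds
        self.thr_offset = {}
        for cohort in self.cohorts:
            for sex in _SEXES:
                for zyg in _ZYGS:
                    self.thr_offset[(sex, zyg, cohort)] = off
                    off += 1
        self.n_params = off
        self.cell_list = []
        for (group, cohort), tab in stats.items():
            pos = self.cohorts.index(cohort)
            zyg = GROUP_ZYGOSITY[group]
            sexes = GROUP_SEXES[group]
            self.cell_list.append(
                (tab, group, cohort, pos,
                 self.thr_offset[(sexes[0], zyg, cohort)],
                 self.thr_offset[(sexes[1], zyg, cohort)])
            )

    def start_vector(self, A0: float, C0: float, rc0: float,
                     thr: Mapping[tuple, float]) -> np.ndarray:
        x = np.zeros(self.n_params)
        for label, par in self.class_param.items():
            off = self.class_offset[label]
            x[off:off + par.n_params] = par.start(A0, C0)
        for cohort, off in self.rc_offset.items():
            x[off] = math.atanh(min(max(rc0 / _RC_SCALE, -0.999), 0.999))
        for key, off in self.thr_offset.items():
            x[off] = thr.get(key, 0.0)
        return x

    def m2ll_grad(self, x: np.ndarray) -> tuple:
        spec = self.spec
        vals = {}
        for label, par in self.class_param.items():
            off = self.class_offset[label]
            vals[label] = par.value_jac(x[off:off + par.n_params])
        rc = {}
        drc = {}
        for cohort in self.cohorts:
            if cohort in self.rc_fixed:
                rc[cohort] = self.rc_fixed[cohort]
                drc[cohort] = 0.0
            else:
                t = math.tanh(x[self.rc_offset[cohort]])
                rc[cohort] = _RC_SCALE * t
                drc[cohort] = _RC_SCALE * (1.0 - t * t)
        total = 0.0
        grad = np.zeros(self.n_params)
        for tab, group, cohort, pos, i1, i2 in self.cell_list:
            t1 = x[i1]
            t2 = x[i2]
            if group == "DOS":
                lab_m = spec.share_classes[("M", pos)]
                lab_f = spec.share_classes[("F", pos)]
                A_m, C_m, jA_m, jC_m = vals[lab_m]
                A_f, C_f, jA_f, jC_f = vals[lab_f]
                a_m, a_f = math.sqrt(A_m), math.sqrt(A_f)
                c_m, c_f = math.sqrt(C_m), math.sqrt(C_f)
                rho = 0.5 * a_m * a_f + rc[cohort] * c_m * c_f
            else:
                lab = spec.share_classes[(GROUP_SEXES[group][0], pos)]
                A, C, jA, jC = vals[lab]
                gen = 1.0 if GROUP_ZYGOSITY[group] == "MZ" else 0.5
                rho = gen * A + C
            clamped = abs(rho) > _RHO_CAP
            rho_c = min(max(rho, -_RHO_CAP), _RHO_CAP)
            v, (g1, g2, gr) = _table_m2ll_grad(tab, t1, t2, rho_c)
            total += v
            grad[i1] += g1
            grad[i2] += g2
            if clamped:
                continue
            if group == "DOS":
                # d rho / d theta through both sexes' paths and Rcdos
                for lab_s, a_self, a_other, c_self, c_other, jA_s, jC_s in (
                    (lab_m, a_m, a_f, c_m, c_f, jA_m, jC_m),
                    (lab_f, a_f, a_m, c_f, c_m, jA_f, jC_f),
                ):
                    off = self.class_offset[lab_s]
                    for k in range(len(jA_s)):
                        da = jA_s[k] / (2.0 * max(a_self, 1e-150))
                        dc = jC_s[k] / (2.0 * max(c_self, 1e-150))
                        grad[off + k] += gr * (0.5 * a_other * da
                                               + rc[cohort] * c_other * dc)
                if cohort in self.rc_offset:
                    grad[self.rc_offset[cohort]] += gr * c_m * c_f * drc[cohort]
            else:
                off = self.class_offset[lab]
                for k in range(len(jA)):
                    grad[off + k] += gr * (gen * jA[k] + jC[k])
        return total, grad

    def unpack(self, x: np.ndarray) -> ACEParams:
        shares = {}
        for pos, cohort in enumerate(self.cohorts):
            for sex in _SEXES:
                label = self.spec.share_classes.get((sex, pos))
                if label is None:
                    continue
                par = self.class_param[label]
                off = self.class_offset[label]
                A, C, _, _ = par.value_jac(x[off:off + par.n_params])
                shares[(sex, cohort)] = (A, C, max(1.0 - A - C, 0.0))
        rcdos = {}
        for cohort in self.cohorts:
            if cohort in self.rc_fixed:
                rcdos[cohort] = self.rc_fixed[cohort]
            else:
                rcdos[cohort] = _RC_SCALE * math.tanh(x[self.rc_offset[cohort]])
        thresholds = {k: float(x[off]) for k, off in self.thr_offset.items()}
        return ACEParams.from_shares(shares, rcdos, thresholds)


#: deterministic multi-start schedule: (A0, C0, rc0)
_STARTS = (
    (0.45, 0.25, 0.8),
    (0.60, 0.15, 0.8),
    (0.20, 0.45, 0.8),
    (0.35, 0.35, 0.2),
    (0.55, 0.30, -0.2),
)


@dataclass
class FitResult:
    """Converged FIML fit of one ModelSpec."""

    spec: ModelSpec
    params: ACEParams
    minus2LL: float
    df: int
    n_individuals: int
    converged: bool
    n_starts: int
    boundary: bool
    _problem: _Problem = field(repr=False, compare=False, default=None)
    _x: np.ndarray = field(repr=False, compare=False, default=None)

    def shares(self, sex: str, cohort: str) -> tuple:
        return self.params.shares(sex, cohort)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.model_id,
            "description": self.spec.description,
            "minus2LL": self.minus2LL,
            "df": self.df,
            "shares": {
                f"{s}/{c}": list(self.params.shares(s, c))
                for (s, c) in self.params.paths
            },
            "rcdos": dict(self.params.rcdos),
            "thresholds": {"/".join(k): v for k, v in self.params.thresholds.items()},
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _minimize(problem: _Problem, x0: np.ndarray):
    # ftol is relative: 2e-12 resolves the deviance to ~1e-8 at its typical
    # scale of a few thousand
    return minimize(
        problem.m2ll_grad, x0, jac=True, method="L-BFGS-B",
        options={"ftol": 2e-12, "gtol": 1e-5, "maxiter": 1000},
    )


def _fit_problem(problem: _Problem, thr0: dict,
                 warm_start: Optional[np.ndarray] = None):
    best = None
    n_used = 0
    starts = []
    if warm_start is not None and len(warm_start) == problem.n_params:
        starts.append(np.asarray(warm_start, dtype=float))
    starts += [problem.start_vector(A0, C0, rc0, thr0) for (A0, C0, rc0) in _STARTS]
    for x0 in starts:
        res = _minimize(problem, x0)
        n_used += 1
        if res.success and best is not None and abs(res.fun - best.fun) < 1e-4:
            break  # two agreeing optima: stop early
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("FIML optimization failed to converge from all starts")
    return best, n_used


def fit(ds: TwinDataset, spec: ModelSpec,
        warm_start: Optional[FitResult] = None) -> FitResult:
    """Fit one model of the ladder by FIML; deterministic multi-start."""
    stats = _suffstats(ds)
    problem = _Problem(stats, ds.cohorts, spec)
    thr0 = _threshold_starts(stats, ds.cohorts)
    ws = None
    if warm_start is not None and warm_start._problem is not None:
        ws = _carry_start(warm_start, problem)
    best, n_used = _fit_problem(problem, thr0, warm_start=ws)
    params = problem.unpack(best.x)
    n_ind = ds.n_individuals
    boundary = any(
        s < 1e-4 or s > 1 - 1e-4
        for key in params.paths
        for s in params.shares(*key)
        if not _is_fixed_share(problem, key, params)
    )
    return FitResult(
        spec=spec, params=params, minus2LL=float(best.fun),
        df=model_df(spec, n_ind, len(ds.cohorts)), n_individuals=n_ind,
        converged=bool(best.success), n_starts=n_used, boundary=boundary,
        _problem=problem, _x=best.x.copy(),
    )


def _is_fixed_share(problem: _Problem, key, params) -> bool:
    pos = problem.cohorts.index(key[1])
    label = problem.spec.share_classes[(key[0], pos)]
    return bool(problem.class_param[label].fixed)


def _carry_start(parent_fit: FitResult, problem: _Problem) -> Optional[np.ndarray]:
    """Translate a parent fit into a start vector for a sub-model: average
    the parent's shares over each new equality class, copy thresholds."""
    p = parent_fit.params
    x = np.zeros(problem.n_params)
    for label, par in problem.class_param.items():
        cells = [(s, problem.cohorts[pos])
                 for (s, pos), lab in problem.spec.share_classes.items()
                 if lab == label and pos < len(problem.cohorts)]
        cells = [c for c in cells if c in p.paths]
        if not cells:
            continue
        A0 = float(np.mean([p.shares(*c)[0] for c in cells]))
        C0 = float(np.mean([p.shares(*c)[1] for c in cells]))
        off = problem.class_offset[label]
        x[off:off + par.n_params] = par.start(A0, C0)
    for cohort, off in problem.rc_offset.items():
        rc0 = p.rcdos.get(cohort, 1.0)
        x[off] = math.atanh(min(max(rc0 / _RC_SCALE, -0.999), 0.999))
    for key, off in problem.thr_offset.items():
        x[off] = p.thresholds.get(key, 0.0)
    return x


# ---------------------------------------------------------------------------
# Saturated correlation fit (per-group, used as an internal cross-check)
# ---------------------------------------------------------------------------

def fit_saturated(ds: TwinDataset):
    """Free correlation and free thresholds per group x cohort.

    Factorizes into independent per-group tetrachoric fits; returns
    ``{(group, cohort): TetrachoricResult}`` plus the summed deviance under
    key ``"minus2LL"``.
    """
    from .tetrachoric import estimate_tetrachoric

    out = {}
    total = 0.0
    for cohort in ds.cohorts:
        for group in GROUPS:
            sub = ds.subset(group=group, cohort=cohort)
            if not sub.records:
                continue
            res = estimate_tetrachoric(concordance_table(ds, group, cohort), ci=False)
            out[(group, cohort)] = res
            total += res.minus2LL
    out["minus2LL"] = total
    return out


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profiled_m2ll(fit_result: FitResult, component, value: float) -> float:
    """Minimum -2LL with one component pinned at ``value``."""
    base = fit_result._problem
    spec = fit_result.spec
    if component[0] == "rcdos":
        problem = _Problem(base.stats, base.cohorts, spec,
                           rc_fixed_override={component[1]: value})
    else:
        comp, sex, cohort = component
        pos = base.cohorts.index(cohort)
        label = spec.share_classes[(sex, pos)]
        if comp in spec.fixed_shares:
            raise ValueError(f"{comp} is fixed by model {spec.model_id}")
        problem = _Problem(base.stats, base.cohorts, spec,
                           class_fixed_override={label: {comp: value}})
    thr0 = dict(fit_result.params.thresholds)
    ws = _carry_start(fit_result, problem)
    best, _ = _fit_problem(problem, thr0, warm_start=ws)
    return float(best.fun)


def profile_ci(fit_result: FitResult, component, level_chi2: float = _CHI2_95_1DF):
    """95% likelihood-based interval for one component.

    ``component`` is ``("A"|"C"|"E", sex, cohort)`` for a variance share or
    ``("rcdos", cohort)``.  The bound is the component value at which the
    re-optimized -2LL exceeds the minimum by 3.84; intervals are truncated at
    [0, 1] (shares) or [-1, 1] (correlations).
    """
    target = fit_result.minus2LL + level_chi2
    is_rc = component[0] == "rcdos"
    lo_lim, hi_lim = (-1.0, 1.0) if is_rc else (0.0, 1.0)
    if is_rc:
        mle = fit_result.params.rcdos[component[1]]
    else:
        comp, sex, cohort = component
        idx = {"A": 0, "C": 1, "E": 2}[comp]
        mle = fit_result.params.shares(sex, cohort)[idx]
    mle = min(max(mle, lo_lim), hi_lim)

    def excess(v):
        return _profiled_m2ll(fit_result, component, v) - target

    eps = 1e-9

    def bound(side: str) -> float:
        lim = hi_lim - eps if side == "high" else lo_lim + eps
        if (lim - mle if side == "high" else mle - lim) <= 1e-7:
            return hi_lim if side == "high" else lo_lim
        if excess(lim) <= 0.0:
            return hi_lim if side == "high" else lo_lim
        a, b = (mle, lim) if side == "high" else (lim, mle)
        return float(brentq(excess, a, b, xtol=1e-4))

    return bound("low"), bound("high")
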