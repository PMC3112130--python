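"""Tetrachoric twin correlations with free thresholds and profile-likelihood CIs.

The tetrachoric correlation is the correlation of the two latent liabilities
of a twin pair, inferred from the 2x2 concordance table of the binary trait.
Estimation maximizes the multinomial likelihood whose cell probabilities come
from :mod:`twinliab.liability`; singleton twins enter through their Bernoulli
margins (full-information likelihood).  Thresholds are estimated jointly with
the correlation — within a same-sex group both twins share one threshold,
while an opposite-sex (DOS) table carries a male and a female threshold.

Confidence intervals are 95% profile-likelihood intervals: the bound is where
the threshold-profiled deviance rises 3.84 above its minimum, truncated at
+-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import norm

from .liability import _phi, _phi_bar, bvn_upper_tail_grad

__all__ = [
    "ConcordanceTable",
    "TetrachoricResult",
    "concordance_table",
    "estimate_tetrachoric",
    "correlation_table",
    "format_correlation_table",
]

_CHI2_95_1DF = 3.841458820694124  # chi2.ppf(0.95, 1)
_R_CAP = 1.0 - 1e-9


@dataclass(frozen=True)
class ConcordanceTable:
    """Pair counts by joint phenotype plus singleton margin counts.

    ``n11`` both affected ... ``n00`` neither; ``s1a``/``s1u`` are
    affected/unaffected singletons observed in the twin-1 role (the male role
    for DOS tables), ``s2a``/``s2u`` in the twin-2 role.
    """

    n11: float
    n10: float
    n01: float
    n00: float
    s1a: float = 0.0
    s1u: float = 0.0
    s2a: float = 0.0
    s2u: float = 0.0
    group: Optional[str] = None

    def __post_init__(self):
        if any(v < 0 for v in self.counts()):
            raise ValueError("counts must be non-negative")

    def counts(self) -> tuple:
        return (self.n11, self.n10, self.n01, self.n00,
                self.s1a, self.s1u, self.s2a, self.s2u)

    @property
    def n_pairs(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def n_records(self) -> float:
        return self.n_pairs + self.s1a + self.s1u + self.s2a + self.s2u

    def margins(self) -> tuple:
        """(affected, total) per twin role, singletons included."""
        a1 = self.n11 + self.n10 + self.s1a
        t1 = self.n_pairs + self.s1a + self.s1u
        a2 = self.n11 + self.n01 + self.s2a
        t2 = self.n_pairs + self.s2a + self.s2u
        return (a1, t1), (a2, t2)

    def __add__(self, other: "ConcordanceTable") -> "ConcordanceTable":
        g = self.group if self.group == other.group else None
        return ConcordanceTable(
            *(a + b for a, b in zip(self.counts(), other.counts())), group=g
        )


@dataclass(frozen=True)
class TetrachoricResult:
    """MLE of the liability correlation with its 95% profile interval."""

    r: float
    ci_low: float
    ci_high: float
    thresholds: tuple  # one (tau1, tau2) pair per fitted table
    minus2LL: float
    n_pairs: float
    boundary: bool = False

    @property
    def tau1(self) -> float:
        return self.thresholds[0][0]

    @property
    def tau2(self) -> float:
        return self.thresholds[0][1]


def concordance_table(ds, group: str, cohort: Optional[str] = None) -> ConcordanceTable:
    """Cross-tabulate one zygosity group (``cohort=None`` pools all cohorts)."""
    sub = ds.subset(group=group, cohort=cohort)
    if not sub.records:
        raise ValueError(f"no records for group {group!r}"
                         + (f", cohort {cohort!r}" if cohort else ""))
    n = {"11": 0, "10": 0, "01": 0, "00": 0}
    s1a = s1u = s2a = s2u = 0
    for r in sub.records:
        if r.is_pair:
            n[f"{r.pheno1}{r.pheno2}"] += 1
        elif r.pheno1 is not None:
            s1a, s1u = s1a + (r.pheno1 == 1), s1u + (r.pheno1 == 0)
        else:
            s2a, s2u = s2a + (r.pheno2 == 1), s2u + (r.pheno2 == 0)
    return ConcordanceTable(
        n11=n["11"], n10=n["10"], n01=n["01"], n00=n["00"],
        s1a=s1a, s1u=s1u, s2a=s2a, s2u=s2u, group=group,
    )


def _table_m2ll_grad(tab: ConcordanceTable, t1: float, t2: float, r: float):
    """-2 log-likelihood of one table and its gradient wrt (t1, t2, r)."""
    p, dp1, dp2, dpr = bvn_upper_tail_grad(t1, t2, r)
    m1, m2 = _phi_bar(t1), _phi_bar(t2)
    dm1, dm2 = -_phi(t1), -_phi(t2)
    cells = (
        (tab.n11, p, dp1, dp2, dpr),
        (tab.n10, m1 - p, dm1 - dp1, -dp2, -dpr),
        (tab.n01, m2 - p, -dp1, dm2 - dp2, -dpr),
        (tab.n00, 1.0 - m1 - m2 + p, dp1 - dm1, dp2 - dm2, dpr),
        (tab.s1a, m1, dm1, 0.0, 0.0),
        (tab.s1u, 1.0 - m1, -dm1, 0.0, 0.0),
        (tab.s2a, m2, 0.0, dm2, 0.0),
        (tab.s2u, 1.0 - m2, 0.0, -dm2, 0.0),
    )
    val = 0.0
    g = [0.0, 0.0, 0.0]
    for cnt, prob, g1, g2, gr in cells:
        if cnt == 0.0:
            continue
        # floor keeps the gradient finite when the optimizer probes a region
        # that makes an observed cell (near-)impossible; legitimate cells at
        # plausible thresholds sit many orders of magnitude above it
        prob = max(prob, 1e-12)
        val -= 2.0 * cnt * math.log(prob)
        w = -2.0 * cnt / prob
        g[0] += w * g1
        g[1] += w * g2
        g[2] += w * gr
    return val, g


def _start_thresholds(tab: ConcordanceTable) -> tuple:
    out = []
    for (aff, tot) in tab.margins():
        prev = min(max(aff / max(tot, 1.0), 0.5 / (tot + 1)), 1 - 0.5 / (tot + 1))
        out.append(float(norm.isf(prev)))
    return tuple(out)


def _check_identified(tables: Sequence[ConcordanceTable]) -> None:
    discordant = any(t.n10 + t.n01 > 0 for t in tables)
    mixed = any(t.n11 > 0 for t in tables) and any(t.n00 > 0 for t in tables)
    if not (discordant or mixed):
        raise ValueError("correlation unidentified: no discordant or mixed pattern")
    for t in tables:
        for (aff, tot) in t.margins():
            if tot > 0 and (aff == 0 or aff == tot):
                raise ValueError("margin with a single outcome: threshold unidentified")


def _pooled_m2ll(tables, shared, z, taus):
    """taus: flat threshold vector, one entry (shared) or two per table."""
    r = math.tanh(z)
    r = max(-_R_CAP, min(_R_CAP, r))
    dr_dz = 1.0 - r * r
    val = 0.0
    grad = np.zeros(1 + len(taus))
    i = 0
    for tab in tables:
        if shared:
            t1 = t2 = taus[i]
        else:
            t1, t2 = taus[i], taus[i + 1]
        v, (g1, g2, gr) = _table_m2ll_grad(tab, t1, t2, r)
        val += v
        grad[0] += gr * dr_dz
        if shared:
            grad[1 + i] += g1 + g2
            i += 1
        else:
            grad[1 + i] += g1
            grad[2 + i] += g2
            i += 2
    return val, grad


def _fit_r(tables, shared, fixed_r: Optional[float] = None,
           start_taus: Optional[np.ndarray] = None):
    """Maximize the pooled likelihood; returns (m2ll, r, taus).

    With ``fixed_r`` the correlation is held and only thresholds move (used
    by the profile CI and by the grid-search oracle in the tests).
    """
    tau0 = []
    for tab in tables:
        s = _start_thresholds(tab)
        tau0.extend([0.5 * (s[0] + s[1])] if shared else list(s))
    tau0 = np.asarray(tau0) if start_taus is None else np.asarray(start_taus)

    if fixed_r is not None:
        zfix = math.atanh(max(-_R_CAP, min(_R_CAP, fixed_r)))

        def f(taus):
            v, g = _pooled_m2ll(tables, shared, zfix, taus)
            return v, g[1:]

        res = minimize(f, tau0, jac=True, method="L-BFGS-B",
                       options={"ftol": 1e-13, "gtol": 1e-10})
        return res.fun, fixed_r, res.x

    best = None
    for r0 in (-0.5, 0.0, 0.5):
        x0 = np.concatenate([[math.atanh(r0)], tau0])

        def f(x):
            return _pooled_m2ll(tables, shared, x[0], x[1:])

        res = minimize(f, x0, jac=True, method="L-BFGS-B",
                       options={"ftol": 1e-13, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    r_hat = max(-_R_CAP, min(_R_CAP, math.tanh(best.x[0])))
    return best.fun, r_hat, best.x[1:]


def _profile_bound(tables, shared, m2ll_min, r_hat, taus_hat, side: str) -> float:
    target = m2ll_min + _CHI2_95_1DF
    limit = 0.999999 if side == "high" else -0.999999

    def dev(r):
        v, _, _ = _fit_r(tables, shared, fixed_r=r, start_taus=taus_hat)
        return v - target

    if dev(limit) <= 0.0:
        return 1.0 if side == "high" else -1.0
    lo, hi = (r_hat, limit) if side == "high" else (limit, r_hat)
    return float(brentq(dev, lo, hi, xtol=1e-4))


def estimate_tetrachoric(
    tab, shared_threshold: Optional[bool] = None, ci: bool = True
) -> TetrachoricResult:
    """Estimate the liability correlation of one group.

    ``tab`` may be a single :class:`ConcordanceTable` or a sequence of tables
    (one per cohort) that share the correlation but keep their own thresholds.
    ``shared_threshold`` defaults to True except for DOS tables, whose male
    and female margins get separate thresholds.
    """
    tables = [tab] if isinstance(tab, ConcordanceTable) else list(tab)
    if shared_threshold is None:
        shared_threshold = all(t.group != "DOS" for t in tables)
    _check_identified(tables)
    m2ll, r_hat, taus = _fit_r(tables, shared_threshold)
    boundary = abs(r_hat) > 0.999
    if ci:
        lo = _profile_bound(tables, shared_threshold, m2ll, r_hat, taus, "low")
        hi = _profile_bound(tables, shared_threshold, m2ll, r_hat, taus, "high")
    else:
        lo = hi = float("nan")
    thr = []
    i = 0
    for _ in tables:
        if shared_threshold:
            thr.append((float(taus[i]), float(taus[i])))
            i += 1
        else:
            thr.append((float(taus[i]), float(taus[i + 1])))
            i += 2
    return TetrachoricResult(
        r=float(r_hat), ci_low=lo, ci_high=hi, thresholds=tuple(thr),
        minus2LL=float(m2ll), n_pairs=sum(t.n_pairs for t in tables),
        boundary=boundary,
    )


def correlation_table(ds, pooled_cohort_thresholds: bool = True, ci: bool = True):
    """Per-group correlations for each cohort and for the pooled cohorts.

    Returns ``{group: {column: TetrachoricResult}}`` with one column per
    cohort plus ``"combined"``.  When ``pooled_cohort_thresholds`` is True the
    combined column keeps cohort-specific thresholds (sharing only r);
    otherwise the cohorts' tables are summed first, forcing equal thresholds.
    """
    from .twin_io import GROUPS

    out = {}
    for group in GROUPS:
        cols = {}
        per_cohort = []
        for cohort in ds.cohorts:
            tab = concordance_table(ds, group, cohort)
            per_cohort.append(tab)
            cols[cohort] = estimate_tetrachoric(tab, ci=ci)
        if len(per_cohort) == 1:
            cols["combined"] = cols[ds.cohorts[0]]
        elif pooled_cohort_thresholds:
            cols["combined"] = estimate_tetrachoric(per_cohort, ci=ci)
        else:
            pooled = per_cohort[0]
            for t in per_cohort[1:]:
                pooled = pooled + t
            cols["combined"] = estimate_tetrachoric(pooled, ci=ci)
        out[group] = cols
    return out


def format_correlation_table(table: dict) -> str:
    """Aligned text rendering: r and 'low - high' CI strings at 2 decimals."""
    columns = list(next(iter(table.values())).keys())
    lines = ["".join([f"{'':6s}"] + [f"{c:>12s}{'95%CI':>14s}" for c in columns])]
    for group, cols in table.items():
        cells = []
        for c in columns:
            res = cols[c]
            cells.append(f"{res.r:>12.2f}{res.ci_low:>7.2f} -{res.ci_high:>5.2f}")
        lines.append(f"{group:<6s}" + "".join(cells))
    return "\n".join(lines)
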