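"""Nested-model likelihood-ratio ladder.

Eight models are fitted in a fixed comparison topology (sub vs parent:
2 vs 1; 3, 4, 5 vs 2; 6 vs 5; 7, 8 vs 6).  Twice the log-likelihood
difference of two nested models is referred to a central chi-square with
degrees of freedom equal to the difference in model df.  A sub-model is
retained when its p-value is at least alpha (default 0.01); the accepted
model is the most constrained model on the acceptance path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional

from scipy.stats import chi2 as chi2_dist

from .ace import MODELS, FitResult, fit
from .twin_io import TwinDataset

__all__ = ["LadderRow", "LadderReport", "chi2_pvalue", "lrt",
           "lrt_from_deviances", "run_ladder", "format_ladder"]

#: comparison topology: sub-model id -> parent id
LADDER_VERSUS = {2: 1, 3: 2, 4: 2, 5: 2, 6: 5, 7: 6, 8: 6}
#: the inferential path along which the accepted model is chosen
_ACCEPT_PATH = (2, 5, 6, 7, 8)


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail probability of the central chi-square distribution."""
    if chi2 < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return float(chi2_dist.sf(chi2, df))


@dataclass(frozen=True)
class LadderRow:
    """One line of the model-comparison table."""

    model_id: int
    description: str
    minus2LL: float
    df: int
    versus: Optional[int]
    chi2: Optional[float]
    delta_df: Optional[int]
    p: Optional[float]
    clamped: bool = False  # negative deviance difference clamped to zero

    def display_p(self) -> str:
        if self.p is None:
            return ""
        if self.p < 0.00005:
            return "< 0.0001"
        return str(Decimal(self.p).quantize(Decimal("0.0001"),
                                            rounding=ROUND_HALF_EVEN))


def lrt_from_deviances(sub_m2ll: float, sub_df: int,
                       parent_m2ll: float, parent_df: int,
                       model_id: int = 0, description: str = "",
                       versus: Optional[int] = None) -> LadderRow:
    """Likelihood-ratio comparison from raw deviance/df pairs.

    Negative chi-square within optimizer tolerance is clamped to zero and
    flagged; a clearly negative difference indicates non-nested fits and
    raises.
    """
    delta_df = sub_df - parent_df
    if delta_df <= 0:
        raise ValueError("sub-model must have strictly more df than its parent")
    chi2 = sub_m2ll - parent_m2ll
    clamped = False
    if chi2 < 0:
        if chi2 < -1e-3:
            raise ValueError(
                f"sub-model deviance {sub_m2ll} below parent {parent_m2ll}: not nested"
            )
        chi2, clamped = 0.0, True
    return LadderRow(
        model_id=model_id, description=description,
        minus2LL=sub_m2ll, df=sub_df, versus=versus,
        chi2=chi2, delta_df=delta_df, p=chi2_pvalue(chi2, delta_df),
        clamped=clamped,
    )


def lrt(sub: FitResult, parent: FitResult) -> LadderRow:
    """Likelihood-ratio test of a fitted sub-model against its fitted parent."""
    if not sub.spec.is_nested_in(parent.spec):
        raise ValueError(
            f"model {sub.spec.model_id} is not nested in model {parent.spec.model_id}"
        )
    return lrt_from_deviances(
        sub.minus2LL, sub.df, parent.minus2LL, parent.df,
        model_id=sub.spec.model_id, description=sub.spec.description,
        versus=parent.spec.model_id,
    )


@dataclass
class LadderReport:
    """Rows 1-8, the fitted models, and the accepted model."""

    rows: list
    fits: dict = field(repr=False)
    accepted_id: int = 6
    alpha: float = 0.01
    errors: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.errors

    @property
    def accepted(self) -> FitResult:
        return self.fits[self.accepted_id]

    def row(self, model_id: int) -> Optional[LadderRow]:
        return next((r for r in self.rows if r.model_id == model_id), None)

    def cohort_equality_rejected(self) -> bool:
        """The gene-by-environment verdict: were the A/C/E contributions
        significantly different between cohorts (rows 3-5)?"""
        rows = [self.row(m) for m in (3, 4, 5)]
        return any(r is not None and r.p is not None and r.p < self.alpha
                   for r in rows)

    def sex_difference_rejected(self) -> bool:
        r = self.row(6)
        return r is not None and r.p is not None and r.p < self.alpha


def run_ladder(ds: TwinDataset, alpha: float = 0.01) -> LadderReport:
    """Fit all eight models in order and assemble the comparison table.

    Parent estimates warm-start each sub-model.  The accepted model is the
    most constrained model along the path 1 -> 2 -> 5 -> 6 -> {7, 8} whose
    LRT p-value stays >= alpha; rows 3 and 4 are reported but branch off the
    path.
    """
    fits: dict[int, FitResult] = {}
    rows: list[LadderRow] = []
    errors: list[str] = []
    for mid in range(1, 9):
        spec = MODELS[mid]
        parent_fit = fits.get(spec.parent)
        if spec.parent is not None and spec.parent not in fits:
            errors.append(f"model {mid}: skipped, parent {spec.parent} failed")
            continue
        try:
            fits[mid] = fit(ds, spec, warm_start=parent_fit)
        except RuntimeError as exc:  # partial report: downstream rows skipped
            errors.append(f"model {mid}: {exc}")
            continue
        if spec.parent is None:
            rows.append(LadderRow(
                model_id=mid, description=spec.description,
                minus2LL=fits[mid].minus2LL, df=fits[mid].df,
                versus=None, chi2=None, delta_df=None, p=None,
            ))
        else:
            rows.append(lrt(fits[mid], fits[spec.parent]))
    accepted = 1
    for mid in (2, 5, 6):
        row = next((r for r in rows if r.model_id == mid), None)
        if row is not None and row.p is not None and row.p >= alpha:
            accepted = mid
        else:
            break
    if accepted == 6:
        # terminal single-component drops; on a tie in df keep the one with
        # the least evidence against it
        terminal = [next((r for r in rows if r.model_id == m), None) for m in (7, 8)]
        ok = [r for r in terminal if r is not None and r.p is not None and r.p >= alpha]
        if ok:
            accepted = max(ok, key=lambda r: r.p).model_id
    return LadderReport(rows=rows, fits=fits, accepted_id=accepted, alpha=alpha,
                        errors=errors)


def format_ladder(report: LadderReport) -> str:
    """Aligned text table: -2LL, df, versus, chi2, delta df, p per row."""
    lines = [f"{'':3s}{'model':<42s}{'-2LL':>10s}{'df':>6s}"
             f"{'vs':>4s}{'chi2':>8s}{'ddf':>5s}{'p':>10s}"]
    for r in report.rows:
        tail = (f"{r.versus:>4d}{r.chi2:>8.3f}{r.delta_df:>5d}{r.display_p():>10s}"
                if r.versus is not None else "")
        lines.append(f"{r.model_id:<3d}{r.description:<42s}"
                     f"{r.minus2LL:>10.3f}{r.df:>6d}{tail}")
    for err in report.errors:
        lines.append(f"error: {err}")
    lines.append(f"accepted model: {report.accepted_id} "
                 f"({MODELS[report.accepted_id].description})")
    return "\n".join(lines)
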