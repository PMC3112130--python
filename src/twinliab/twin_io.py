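"""Twin-pair dataset I/O and descriptive prevalence statistics.

Datasets are plain UTF-8, comma-separated CSV files with a mandatory header
``family_id,group,cohort,pheno1,pheno2`` (optional ``sex1,sex2`` columns may
override the default sex convention).  ``group`` is one of MZM, DZM, MZF,
DZF, DOS; phenotypes are 0/1 with a missing co-twin encoded as an empty field
or ``NA``.  By convention twin 1 is the male twin in opposite-sex (DOS)
pairs.  Singleton twins — one phenotype missing — are first-class records:
the likelihood machinery uses their marginal distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger("twinliab")

GROUPS = ("MZM", "DZM", "MZF", "DZF", "DOS")

#: default sexes of (twin 1, twin 2) per zygosity group
GROUP_SEXES = {
    "MZM": ("M", "M"),
    "DZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZF": ("F", "F"),
    "DOS": ("M", "F"),
}

#: zygosity class used for descriptive tables (opposite-sex DZ kept apart)
GROUP_ZYG_CLASS = {"MZM": "MZ", "DZM": "DZss", "MZF": "MZ", "DZF": "DZss", "DOS": "DZos"}

#: zygosity used for the threshold scheme (MZ vs DZ only)
GROUP_ZYGOSITY = {"MZM": "MZ", "DZM": "DZ", "MZF": "MZ", "DZF": "DZ", "DOS": "DZ"}

_REQUIRED_COLUMNS = ("family_id", "group", "cohort", "pheno1", "pheno2")


@dataclass(frozen=True)
class TwinPairRecord:
    """One observed twin pair (or singleton, with one phenotype missing)."""

    family_id: str
    group: str
    cohort: str
    pheno1: Optional[int]
    pheno2: Optional[int]
    sex1: Optional[str] = None
    sex2: Optional[str] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown zygosity group {self.group!r}")
        if not self.cohort:
            raise ValueError("cohort label must be non-empty")
        for p in (self.pheno1, self.pheno2):
            if p is not None and p not in (0, 1):
                raise ValueError(f"phenotype must be 0, 1 or missing, got {p!r}")
        if self.pheno1 is None and self.pheno2 is None:
            raise ValueError("at least one phenotype must be observed")

    @property
    def sexes(self) -> tuple[str, str]:
        default = GROUP_SEXES[self.group]
        return (self.sex1 or default[0], self.sex2 or default[1])

    @property
    def is_pair(self) -> bool:
        return self.pheno1 is not None and self.pheno2 is not None


@dataclass(frozen=True)
class ReadLog:
    """Row-level bookkeeping from :func:`read_dataset`."""

    n_rows: int = 0
    n_excluded_unknown_group: int = 0
    n_excluded_missing_both: int = 0
    n_excluded_bad_phenotype: int = 0

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_unknown_group
            + self.n_excluded_missing_both
            + self.n_excluded_bad_phenotype
        )


@dataclass(frozen=True)
class TwinDataset:
    """An ordered collection of twin-pair records plus the cohort labels."""

    records: tuple[TwinPairRecord, ...]
    cohorts: tuple[str, ...]
    read_log: Optional[ReadLog] = field(default=None, compare=False)

    @classmethod
    def from_records(cls, records: Iterable[TwinPairRecord],
                     read_log: Optional[ReadLog] = None) -> "TwinDataset":
        recs = tuple(records)
        cohorts = tuple(dict.fromkeys(r.cohort for r in recs))
        return cls(records=recs, cohorts=cohorts, read_log=read_log)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_pairs(self) -> int:
        return sum(r.is_pair for r in self.records)

    @property
    def n_singletons(self) -> int:
        return sum(not r.is_pair for r in self.records)

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_pairs + self.n_singletons

    def subset(self, group: Optional[str] = None,
               cohort: Optional[str] = None) -> "TwinDataset":
        recs = [
            r for r in self.records
            if (group is None or r.group == group)
            and (cohort is None or r.cohort == cohort)
        ]
        return TwinDataset.from_records(recs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": r.family_id,
                "group": r.group,
                "cohort": r.cohort,
                "pheno1": r.pheno1,
                "pheno2": r.pheno2,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))

    def individuals(self) -> pd.DataFrame:
        """One row per observed individual phenotype.

        Columns: group, cohort, sex, zyg_class (MZ / DZss / DZos),
        zygosity (MZ / DZ), pheno.  DOS twins are tallied under their own sex.
        """
        rows = []
        for r in self.records:
            sexes = r.sexes
            for pheno, sex in ((r.pheno1, sexes[0]), (r.pheno2, sexes[1])):
                if pheno is None:
                    continue
                rows.append(
                    (r.group, r.cohort, sex, GROUP_ZYG_CLASS[r.group],
                     GROUP_ZYGOSITY[r.group], pheno)
                )
        return pd.DataFrame(
            rows, columns=["group", "cohort", "sex", "zyg_class", "zygosity", "pheno"]
        )


class FormatError(ValueError):
    """Raised when an input file does not conform to the dataset dialect."""


def _parse_pheno(value) -> Optional[int]:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan"):
        return None
    f = float(s)
    i = int(f)
    if f != i or i not in (0, 1):
        raise ValueError(f"phenotype must be 0/1/missing, got {value!r}")
    return i


def read_dataset(path) -> TwinDataset:
    """Read a twin-pair CSV; invalid rows are dropped and counted.

    Rows with an unknown group label, with both phenotypes missing, or with a
    non-binary phenotype are excluded; counts go to the ``twinliab`` logger
    and to ``dataset.read_log``.  A missing required column raises
    :class:`FormatError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    n_unknown = n_both_missing = n_bad = 0
    for row in df.itertuples(index=False):
        group = str(row.group).strip()
        if group not in GROUPS:
            n_unknown += 1
            continue
        try:
            p1 = _parse_pheno(row.pheno1)
            p2 = _parse_pheno(row.pheno2)
        except ValueError:
            n_bad += 1
            continue
        if p1 is None and p2 is None:
            n_both_missing += 1
            continue
        records.append(
            TwinPairRecord(
                family_id=str(row.family_id),
                group=group,
                cohort=str(row.cohort).strip(),
                pheno1=p1,
                pheno2=p2,
                sex1=getattr(row, "sex1", None) or None,
                sex2=getattr(row, "sex2", None) or None,
            )
        )
    log = ReadLog(
        n_rows=len(df),
        n_excluded_unknown_group=n_unknown,
        n_excluded_missing_both=n_both_missing,
        n_excluded_bad_phenotype=n_bad,
    )
    if log.n_excluded:
        logger.warning(
            "%s: excluded %d of %d rows (%d unknown group, %d both phenotypes "
            "missing, %d malformed phenotype)",
            path, log.n_excluded, log.n_rows, n_unknown, n_both_missing, n_bad,
        )
    return TwinDataset.from_records(records, read_log=log)


def write_dataset(ds: TwinDataset, path) -> None:
    """Write a dataset back to the CSV dialect read by :func:`read_dataset`."""
    df = ds.to_dataframe()
    for col in ("pheno1", "pheno2"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Prevalence tables
# ---------------------------------------------------------------------------

def percent_ever(n_ever: int, n_total: int) -> float:
    """Percentage to one decimal, round-half-up (table formatting rule)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = Decimal(100 * n_ever) / Decimal(n_total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_ROW_ORDER = ("MZ", "DZss", "DZos", "Total")


def prevalence_table(ds: TwinDataset) -> pd.DataFrame:
    """Descriptive prevalence per sex x zygosity-class x cohort.

    Every observed individual phenotype is counted exactly once; DOS twins
    count toward their own sex.  Returns a long-format frame with columns
    ``sex, zyg_class, cohort, n_total, n_ever, percent`` including per-sex
    ``Total`` rows.
    """
    if not ds.records:
        raise ValueError("empty dataset")
    ind = ds.individuals()
    rows = []
    for cohort in ds.cohorts:
        sub_c = ind[ind["cohort"] == cohort]
        for sex in ("M", "F"):
            sub_s = sub_c[sub_c["sex"] == sex]
            for zc in _ROW_ORDER:
                sub = sub_s if zc == "Total" else sub_s[sub_s["zyg_class"] == zc]
                n_total = len(sub)
                n_ever = int(sub["pheno"].sum()) if n_total else 0
                rows.append(
                    {
                        "sex": sex,
                        "zyg_class": zc,
                        "cohort": cohort,
                        "n_total": n_total,
                        "n_ever": n_ever,
                        "percent": percent_ever(n_ever, n_total) if n_total else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def format_prevalence_table(table: pd.DataFrame) -> str:
    """Aligned text rendering of :func:`prevalence_table` output."""
    wide = table.pivot_table(
        index=["sex", "zyg_class"], columns="cohort",
        values=["n_total", "n_ever", "percent"], sort=False, aggfunc="first",
    )
    cohorts = list(dict.fromkeys(table["cohort"]))
    lines = []
    header = f"{'':10s}" + "".join(f"{c:>12s}{'ever':>7s}{'%':>8s}" for c in cohorts)
    lines.append(header)
    for sex in ("M", "F"):
        lines.append("Men:" if sex == "M" else "Women:")
        for zc in _ROW_ORDER:
            if (sex, zc) not in wide.index:
                continue
            row = wide.loc[(sex, zc)]
            cells = "".join(
                f"{int(row[('n_total', c)]):>12d}{int(row[('n_ever', c)]):>7d}"
                f"{row[('percent', c)]:>7.1f}%"
                for c in cohorts
            )
            lines.append(f"  {zc:<8s}{cells}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Prevalence-difference tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceComparison:
    """Two-proportion comparison by Pearson chi-square and by the
    threshold-equality likelihood-ratio test (two free thresholds against one
    pooled threshold); both are 1-df tests and neither is privileged."""

    label: str
    counts: tuple[tuple[int, int], tuple[int, int]]  # (n_ever, n_total) per level
    chi2: float
    chi2_p: float
    lrt: float
    lrt_p: float
    df: int = 1


def _binomial_loglik(k: int, n: int) -> float:
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return k * np.log(p) + (n - k) * np.log1p(-p)


def _two_proportion_tests(k1, n1, k2, n2, label) -> PrevalenceComparison:
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both comparison levels need a positive denominator")
    # Pearson chi-square on the 2x2 individual-level table (no continuity corr.)
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / total
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    chi2_p = float(chi2_dist.sf(chi2, 1))
    # Threshold-equality LRT: the liability threshold is a 1-1 reparameterization
    # of the prevalence, so separate-vs-pooled threshold fits reduce to the
    # binomial deviance difference.
    ll_sep = _binomial_loglik(k1, n1) + _binomial_loglik(k2, n2)
    ll_pool = _binomial_loglik(k1 + k2, n1 + n2)
    lrt = float(max(0.0, 2.0 * (ll_sep - ll_pool)))
    lrt_p = float(chi2_dist.sf(lrt, 1))
    return PrevalenceComparison(
        label=label, counts=((k1, n1), (k2, n2)),
        chi2=chi2, chi2_p=chi2_p, lrt=lrt, lrt_p=lrt_p,
    )


def compare_prevalence(
    ds: TwinDataset,
    factor: Literal["cohort", "zygosity"],
    sex: str,
    zyg_class: Optional[str] = None,
    cohort: Optional[str] = None,
) -> PrevalenceComparison:
    """Test equality of two prevalences within a stratum.

    ``factor="cohort"`` compares the two cohorts within ``sex`` (optionally a
    single zygosity class); ``factor="zygosity"`` compares MZ against all DZ
    (same- plus opposite-sex) within ``sex`` and ``cohort``.
    """
    ind = ds.individuals()
    ind = ind[ind["sex"] == sex]
    if factor == "cohort":
        if len(ds.cohorts) != 2:
            raise ValueError("cohort comparison requires exactly two cohorts")
        if zyg_class is not None and zyg_class != "Total":
            ind = ind[ind["zyg_class"] == zyg_class]
        levels = ds.cohorts
        sub = [ind[ind["cohort"] == c] for c in levels]
        label = f"{sex}/{zyg_class or 'Total'}: {levels[0]} vs {levels[1]}"
    elif factor == "zygosity":
        if cohort is not None:
            ind = ind[ind["cohort"] == cohort]
        levels = ("MZ", "DZ")
        sub = [ind[ind["zygosity"] == z] for z in levels]
        label = f"{sex}/{cohort or 'combined'}: MZ vs DZ"
    else:
        raise ValueError(f"unknown factor {factor!r}")
    (k1, n1), (k2, n2) = [(int(s["pheno"].sum()), len(s)) for s in sub]
    return _two_proportion_tests(k1, n1, k2, n2, label)
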