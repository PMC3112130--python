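"""Synthetic twin-cohort generator.

Generates twin-pair datasets with exactly the statistical structure the
analysis assumes: per pair, two standard-normal liabilities with the
group's model-implied correlation, dichotomized at sex x zygosity x cohort
thresholds; singletons drawn from the univariate margin.  The default preset
emulates the two Netherlands Twin Register young-adult survey cohorts
(1993-1995, n = 2669; 2009-2010, n = 2339) whose raw records are not
publicly deposited: published pair/singleton counts, per-cell smoking-
initiation prevalences, and the published combined-cohort ACE estimates
serve as generating values.

Randomness contract: one generator stream per group x cohort, derived from
the master seed via ``default_rng([seed, cohort_index, group_index])``, so
changing one group's counts never perturbs another group's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np

from .ace import MODELS, ACEParams, implied_correlation
from .liability import threshold_from_prevalence
from .twin_io import (GROUP_SEXES, GROUP_ZYGOSITY, GROUPS, TwinDataset,
                      TwinPairRecord)

__all__ = [
    "GroupCounts",
    "SimConfig",
    "paper_combined",
    "simulate",
    "simulate_under_model",
    "apply_model_structure",
    "config_to_dict",
    "config_from_dict",
    "REFERENCE_PREVALENCE_COUNTS",
    "REFERENCE_COMBINED_CORRELATIONS",
    "REFERENCE_SEX_SHARES",
    "REFERENCE_OVERALL_SHARES",
    "pooled_prevalence",
]

COHORT_1, COHORT_2 = "1993-1995", "2009-2010"

#: Published per-cell smoking-initiation counts of the two NTR young-adult
#: survey cohorts: (n_total individuals, n_ever smoked) per
#: (sex, zygosity class, cohort).  These define the preset's thresholds and
#: are reused by the descriptive-table checks.
REFERENCE_PREVALENCE_COUNTS: dict = {
    ("M", "MZ", COHORT_1): (415, 190),
    ("M", "DZss", COHORT_1): (363, 184),
    ("M", "DZos", COHORT_1): (384, 218),
    ("F", "MZ", COHORT_1): (658, 224),
    ("F", "DZss", COHORT_1): (462, 195),
    ("F", "DZos", COHORT_1): (385, 176),
    ("M", "MZ", COHORT_2): (301, 44),
    ("M", "DZss", COHORT_2): (239, 69),
    ("M", "DZos", COHORT_2): (228, 62),
    ("F", "MZ", COHORT_2): (728, 128),
    ("F", "DZss", COHORT_2): (445, 122),
    ("F", "DZos", COHORT_2): (400, 102),
}

#: Published combined-cohort tetrachoric twin correlations per zygosity group.
REFERENCE_COMBINED_CORRELATIONS = {
    "MZM": 0.80, "DZM": 0.47, "MZF": 0.78, "DZF": 0.67, "DOS": 0.38,
}

#: Published combined-cohort variance shares (A, C, E) per sex.
REFERENCE_SEX_SHARES = {"M": (0.66, 0.14, 0.20), "F": (0.21, 0.57, 0.22)}

#: Published combined-cohort shares with sexes pooled.  The printed values
#: 0.55/0.23/0.21 sum to 0.99 (rounding); E absorbs the remainder so the
#: liability variance is exactly 1.
REFERENCE_OVERALL_SHARES = (0.55, 0.23, 0.22)

#: Published pair counts per cohort; singleton counts chosen so that each
#: group's individual total matches the published per-cell totals and each
#: cohort's grand total matches the published cohort sizes (2669 and 2339).
#: The published per-group figures are not mutually consistent at the margin;
#: the two-individual discrepancy per cohort is absorbed by the DOS
#: singleton count.
_PRESET_COUNTS = {
    (COHORT_1, "MZM"): (206, 3),
    (COHORT_1, "DZM"): (178, 7),
    (COHORT_1, "MZF"): (326, 6),
    (COHORT_1, "DZF"): (227, 8),
    (COHORT_1, "DOS"): (377, 17),
    (COHORT_2, "MZM"): (105, 91),
    (COHORT_2, "DZM"): (74, 91),
    (COHORT_2, "MZF"): (269, 190),
    (COHORT_2, "DZF"): (149, 147),
    (COHORT_2, "DOS"): (166, 294),
}


def pooled_prevalence(sex: str, zyg_class: str) -> float:
    """Cohort-pooled published prevalence for one sex x zygosity-class cell."""
    tot = aff = 0
    for (s, z, _c), (n, k) in REFERENCE_PREVALENCE_COUNTS.items():
        if s == sex and z == zyg_class:
            tot += n
            aff += k
    return aff / tot


@dataclass(frozen=True)
class GroupCounts:
    pairs: int
    singletons: int

    @property
    def individuals(self) -> int:
        return 2 * self.pairs + self.singletons


@dataclass(frozen=True)
class SimConfig:
    """Generating configuration: counts, ACE shares, prevalences, seed."""

    cohorts: tuple
    counts: Mapping[tuple, GroupCounts]           # (cohort, group) -> counts
    shares: Mapping[tuple, tuple]                 # (sex, cohort) -> (A, C, E)
    rcdos: Mapping[str, float]                    # cohort -> Rcdos
    prevalence: Mapping[tuple, float]             # (sex, zyg, cohort) -> prev
    dos_singleton_male_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for key, (A, C, E) in self.shares.items():
            if min(A, C, E) < 0 or abs(A + C + E - 1.0) > 1e-8:
                raise ValueError(f"shares at {key} must be >= 0 and sum to 1")
        for key, gc in self.counts.items():
            if gc.pairs < 0 or gc.singletons < 0:
                raise ValueError(f"negative counts at {key}")
        for key, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence at {key} must be in (0, 1)")
        for cohort in self.cohorts:
            rho = implied_correlation(self.params(), "DOS", cohort)
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"implied DOS correlation {rho} outside [-1, 1]")

    def params(self) -> ACEParams:
        thresholds = {
            key: threshold_from_prevalence(p) for key, p in self.prevalence.items()
        }
        return ACEParams.from_shares(dict(self.shares), dict(self.rcdos), thresholds)

    def n_individuals(self, cohort: Optional[str] = None) -> int:
        return sum(
            gc.individuals for (c, _g), gc in self.counts.items()
            if cohort is None or c == cohort
        )


def paper_combined(seed: int = 0) -> SimConfig:
    """Preset emulating the two published survey cohorts.

    Pair/singleton counts and per-cell prevalences follow the published
    cohort description; the generating ACE shares are the published
    combined-cohort per-sex estimates (equal across cohorts, Rcdos = 1).
    """
    prevalence = {}
    for cohort in (COHORT_1, COHORT_2):
        for sex in ("M", "F"):
            n_mz, k_mz = REFERENCE_PREVALENCE_COUNTS[(sex, "MZ", cohort)]
            prevalence[(sex, "MZ", cohort)] = k_mz / n_mz
            n_ss, k_ss = REFERENCE_PREVALENCE_COUNTS[(sex, "DZss", cohort)]
            n_os, k_os = REFERENCE_PREVALENCE_COUNTS[(sex, "DZos", cohort)]
            prevalence[(sex, "DZ", cohort)] = (k_ss + k_os) / (n_ss + n_os)
    shares = {
        (sex, cohort): REFERENCE_SEX_SHARES[sex]
        for sex in ("M", "F") for cohort in (COHORT_1, COHORT_2)
    }
    return SimConfig(
        cohorts=(COHORT_1, COHORT_2),
        counts={k: GroupCounts(*v) for k, v in _PRESET_COUNTS.items()},
        shares=shares,
        rcdos={COHORT_1: 1.0, COHORT_2: 1.0},
        prevalence=prevalence,
        seed=seed,
    )


def config_to_dict(config: SimConfig) -> dict:
    """Plain key-value form of a config (JSON-serializable)."""
    return {
        "cohorts": list(config.cohorts),
        "counts": {f"{c}/{g}": [gc.pairs, gc.singletons]
                   for (c, g), gc in config.counts.items()},
        "shares": {f"{s}/{c}": list(v) for (s, c), v in config.shares.items()},
        "rcdos": dict(config.rcdos),
        "prevalence": {f"{s}/{z}/{c}": v
                       for (s, z, c), v in config.prevalence.items()},
        "dos_singleton_male_fraction": config.dos_singleton_male_fraction,
        "seed": config.seed,
    }


def config_from_dict(d: Mapping) -> SimConfig:
    """Inverse of :func:`config_to_dict` (keys are '/'-joined tuples)."""
    split = lambda k, n: tuple(k.split("/", n - 1))
    return SimConfig(
        cohorts=tuple(d["cohorts"]),
        counts={split(k, 2): GroupCounts(*v) for k, v in d["counts"].items()},
        shares={split(k, 2): tuple(v) for k, v in d["shares"].items()},
        rcdos=dict(d["rcdos"]),
        prevalence={split(k, 3): v for k, v in d["prevalence"].items()},
        dos_singleton_male_fraction=d.get("dos_singleton_male_fraction", 0.5),
        seed=int(d.get("seed", 0)),
    )


def _group_stream(seed: int, cohort_idx: int, group_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, cohort_idx, group_idx])


def simulate(config: SimConfig, seed: Optional[int] = None) -> TwinDataset:
    """Draw a dataset from the generating model; reproducible from the seed."""
    config.validate()
    master = config.seed if seed is None else seed
    params = config.params()
    records = []
    for ci, cohort in enumerate(config.cohorts):
        for gi, group in enumerate(GROUPS):
            gc = config.counts.get((cohort, group))
            if gc is None or (gc.pairs == 0 and gc.singletons == 0):
                continue
            rng = _group_stream(master, ci, gi)
            zyg = GROUP_ZYGOSITY[group]
            sexes = GROUP_SEXES[group]
            t1 = params.thresholds[(sexes[0], zyg, cohort)]
            t2 = params.thresholds[(sexes[1], zyg, cohort)]
            rho = implied_correlation(params, group, cohort)
            rho = min(max(rho, -1.0), 1.0)
            if gc.pairs:
                z1 = rng.standard_normal(gc.pairs)
                z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(gc.pairs)
                y1 = (z1 > t1).astype(int)
                y2 = (z2 > t2).astype(int)
                for i in range(gc.pairs):
                    records.append(TwinPairRecord(
                        family_id=f"{cohort}-{group}-p{i:05d}",
                        group=group, cohort=cohort,
                        pheno1=int(y1[i]), pheno2=int(y2[i]),
                    ))
            if gc.singletons:
                if group == "DOS":
                    male = rng.random(gc.singletons) < config.dos_singleton_male_fraction
                else:
                    male = np.ones(gc.singletons, dtype=bool)
                z = rng.standard_normal(gc.singletons)
                for i in range(gc.singletons):
                    tau = t1 if male[i] else t2
                    y = int(z[i] > tau)
                    p1, p2 = (y, None) if male[i] else (None, y)
                    records.append(TwinPairRecord(
                        family_id=f"{cohort}-{group}-s{i:05d}",
                        group=group, cohort=cohort, pheno1=p1, pheno2=p2,
                    ))
    return TwinDataset(records=tuple(records), cohorts=tuple(config.cohorts))


def _normalized(A: float, C: float) -> tuple:
    s = A + C
    if s >= 1.0:
        A, C = A / (s + 1e-12), C / (s + 1e-12)
    return (A, C, max(1.0 - A - C, 0.0))


def apply_model_structure(config: SimConfig, model_id: int) -> SimConfig:
    """Impose a ladder model's equality/fixing structure on the generating
    parameters: equality classes average their members' shares, fixed shares
    are pinned (remaining shares rescaled to unit variance), and a fixed
    Rcdos replaces the configured one."""
    spec = MODELS[model_id]
    shares = dict(config.shares)
    for label in spec.class_labels:
        cells = [
            (sex, config.cohorts[pos])
            for (sex, pos), lab in spec.share_classes.items()
            if lab == label and pos < len(config.cohorts)
        ]
        if not cells:
            continue
        A = float(np.mean([shares[c][0] for c in cells]))
        C = float(np.mean([shares[c][1] for c in cells]))
        for comp, v in spec.fixed_shares.items():
            if comp == "A":
                scale = (1.0 - v) / max(C + (1.0 - A - C), 1e-12)
                A, C = v, C * scale
            elif comp == "C":
                scale = (1.0 - v) / max(A + (1.0 - A - C), 1e-12)
                A, C = A * scale, v
        val = _normalized(A, C)
        for c in cells:
            shares[c] = val
    rcdos = dict(config.rcdos)
    if spec.rcdos_fixed is not None:
        rcdos = {c: spec.rcdos_fixed for c in config.cohorts}
    return replace(config, shares=shares, rcdos=rcdos)


def simulate_under_model(model_id: int, base_config: SimConfig,
                         seed: Optional[int] = None) -> TwinDataset:
    """Simulate after imposing a ladder model's structure on the generator."""
    return simulate(apply_model_structure(base_config, model_id), seed=seed)
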