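"""Clinical endpoints and group statistics.

Late lumen loss (LLL) and recoil are derived from quantitative
angiography diameters:

    LLL = minimal lumen diameter(implantation) - minimal lumen diameter(follow-up)   [mm]
    R   = (mean LD(implantation) - mean LD(follow-up)) / mean LD(implantation) x 100 [%]

Group differences are assessed with one-way ANOVA followed by post hoc
Tukey-Kramer tests (studentized-range distribution, valid for unequal
group sizes), significant at p < 0.05. The association between severely
degraded scaffold volume and the ordinal peri-strut inflammation score
(Kornowski grading, 0-3) is a Spearman rank correlation with midranks
for ties; Pearson is available via ``method``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05
GROUPS = ("G130_10%", "G95_10%_POBA", "G95_10%_DCB", "G95_5%_DCB")

LUMEN_CSV_COLUMNS = [
    "sample_id",
    "group",
    "mld_implant",
    "mld_fup",
    "mean_ld_implant",
    "mean_ld_fup",
    "inflammation_score",
    "severe_volume_mm3",
]


@dataclass
class LumenRecord:
    """Per-vessel lumen diameters, inflammation grade and severe volume."""

    sample_id: str
    group: str
    mld_implant: float
    mld_fup: float
    mean_ld_implant: float
    mean_ld_fup: float
    inflammation_score: int
    severe_volume_mm3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mld_implant", "mld_fup", "mean_ld_implant", "mean_ld_fup"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite diameter {name}")
            if v < 0:
                raise ValueError(f"negative diameter {name}")
        if self.inflammation_score not in (0, 1, 2, 3):
            raise ValueError("inflammation_score must be an integer in 0..3")


@dataclass
class GroupStats:
    """One-way ANOVA + Tukey-Kramer pairwise comparisons + correlation."""

    anova_F: float
    anova_p: float
    tukey_pairs: pd.DataFrame  # group1, group2, meandiff, ci_low, ci_high, p_adj, reject
    correlation_rho: float | None = None
    correlation_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "tukey_pairs": self.tukey_pairs.to_dict(orient="records"),
            "correlation_rho": self.correlation_rho,
            "correlation_p": self.correlation_p,
        }


# ---------------------------------------------------------------------------
# per-vessel endpoints


def late_lumen_loss(record: LumenRecord) -> float:
    """LLL in mm; negative values (late lumen gain) are permitted."""
    lll = record.mld_implant - record.mld_fup
    if lll < 0:
        warnings.warn(
            f"{record.sample_id}: negative LLL ({lll:.3f} mm) indicates lumen gain",
            stacklevel=2,
        )
    return lll


def recoil(record: LumenRecord) -> float:
    """Recoil in percent of the implantation mean lumen diameter."""
    if record.mean_ld_implant <= 0:
        raise ValueError("mean lumen diameter at implantation must be positive")
    return (
        (record.mean_ld_implant - record.mean_ld_fup) / record.mean_ld_implant * 100.0
    )


# ---------------------------------------------------------------------------
# group statistics


def anova_tukey(values_by_group: Mapping[str, Sequence[float]]) -> GroupStats:
    """One-way ANOVA F/p plus Tukey-Kramer pairwise adjusted comparisons.

    Handles unequal group sizes. All-identical data yield the F = 0,
    p = 1 convention. Groups with fewer than two observations are
    rejected by name.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    for name, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    flat = np.concatenate(list(arrays.values()))
    if np.ptp(flat) == 0:
        pairs = [
            (a, b)
            for i, a in enumerate(arrays)
            for b in list(arrays)[i + 1 :]
        ]
        table = pd.DataFrame(
            [
                {
                    "group1": a,
                    "group2": b,
                    "meandiff": 0.0,
                    "ci_low": 0.0,
                    "ci_high": 0.0,
                    "p_adj": 1.0,
                    "reject": False,
                }
                for a, b in pairs
            ]
        )
        return GroupStats(anova_F=0.0, anova_p=1.0, tukey_pairs=table)

    F, p = stats.f_oneway(*arrays.values())
    endog = flat
    groups = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    res = pairwise_tukeyhsd(endog, groups, alpha=ALPHA)
    uniq = np.asarray(res.groupsunique)
    i1, i2 = np.triu_indices(len(uniq), 1)  # statsmodels pair ordering
    table = pd.DataFrame(
        {
            "group1": [str(g) for g in uniq[i1]],
            "group2": [str(g) for g in uniq[i2]],
            "meandiff": res.meandiffs,
            "ci_low": res.confint[:, 0],
            "ci_high": res.confint[:, 1],
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    return GroupStats(anova_F=float(F), anova_p=float(p), tukey_pairs=table)


def correlate_severe_inflammation(
    records: Iterable[LumenRecord], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between severe-degradation volume and inflammation score.

    Spearman rank correlation by default (the score is ordinal), with
    midranks for ties; Pearson via ``method='pearson'``. Returns
    (rho, two-sided p); constant scores yield (nan, nan) with a warning.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([r.severe_volume_mm3 for r in records], dtype=float)
    y = np.array([r.inflammation_score for r in records], dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("constant values; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# tabular front end


def load_lumen_records(path: str | Path) -> list[LumenRecord]:
    """Read per-vessel records from CSV (see LUMEN_CSV_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(LUMEN_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return [
        LumenRecord(
            sample_id=str(row.sample_id),
            group=str(row.group),
            mld_implant=float(row.mld_implant),
            mld_fup=float(row.mld_fup),
            mean_ld_implant=float(row.mean_ld_implant),
            mean_ld_fup=float(row.mean_ld_fup),
            inflammation_score=int(row.inflammation_score),
            severe_volume_mm3=float(row.severe_volume_mm3),
        )
        for row in df.itertuples()
    ]


def summarize_records(records: Iterable[LumenRecord]) -> pd.DataFrame:
    """Per-vessel endpoint table with LLL (and gain flag) and recoil."""
    rows = []
    for r in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lll = late_lumen_loss(r)
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "lll_mm": lll,
                "lumen_gain": lll < 0,
                "recoil_pct": recoil(r),
                "inflammation_score": r.inflammation_score,
                "severe_volume_mm3": r.severe_volume_mm3,
            }
        )
    return pd.DataFrame(rows)
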