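"""Cold-injury phenotype metrics: electrolyte leakage index and recovery score.

ELI is the ratio of mean induced electrolyte leakage under stress to that
under control conditions; values above 1 indicate cold injury, declared
significant by a one-sided two-sample t-test at p < 0.05.  Recovery is
summarized on the 0–10 standard evaluation scale (0 = death, 10 = full
recovery), derived here from a recovery fraction by half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LeakageRecord", "PhenotypeSummary", "compute_eli", "ses_score", "phenotype_table"]


@dataclass(frozen=True)
class LeakageRecord:
    """One conductivity measurement: initial / autoclaved-total ratio in [0, 1]."""

    accession: str
    condition: str  # control | stress
    replicate: int
    conductivity: float

    def __post_init__(self) -> None:
        if self.condition not in ("control", "stress"):
            raise ValueError(f"condition must be control or stress, got {self.condition!r}")
        if not 0.0 <= self.conductivity <= 1.0:
            raise ValueError("conductivity ratio must lie in [0, 1]")


@dataclass(frozen=True)
class PhenotypeSummary:
    accession: str
    eli: float
    eli_p: float
    eli_significant: bool
    ses: int | None = None


def compute_eli(records: Sequence[LeakageRecord]) -> PhenotypeSummary:
    """ELI for one accession: mean stress leakage over mean control leakage.

    The significance flag requires both ELI > 1 and a one-sided two-sample
    t-test (stress > control) at p < 0.05.
    """
    accessions = {r.accession for r in records}
    if len(accessions) != 1:
        raise ValueError(f"records span multiple accessions: {sorted(accessions)}")
    control = np.array([r.conductivity for r in records if r.condition == "control"])
    strs = np.array([r.conductivity for r in records if r.condition == "stress"])
    if len(control) == 0 or len(strs) == 0:
        raise ValueError("both control and stress records are required")
    if control.mean() == 0:
        raise ValueError("control mean leakage is zero; ELI undefined")
    eli = float(strs.mean() / control.mean())
    if np.ptp(control) == 0 and np.ptp(strs) == 0:
        p = 1.0 if strs.mean() <= control.mean() else 0.0
    else:
        p = float(stats.ttest_ind(strs, control, alternative="greater", equal_var=False).pvalue)
    return PhenotypeSummary(
        accession=accessions.pop(),
        eli=eli,
        eli_p=p,
        eli_significant=bool(eli > 1.0 and p < 0.05),
    )


def ses_score(recovery_fraction: float) -> int:
    """Standard evaluation score: round(10 × recovery fraction), half-up."""
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery fraction must lie in [0, 1]")
    return int(math.floor(10.0 * recovery_fraction + 0.5))


def phenotype_table(
    leakage: pd.DataFrame,
    recovery: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-accession phenotype summary from tidy measurement tables.

    ``leakage`` needs columns accession/condition/replicate/conductivity;
    ``recovery`` (optional) needs accession/recovery_fraction.
    """
    rows = []
    for accession, grp in leakage.groupby("accession"):
        records = [
            LeakageRecord(accession, r.condition, int(r.replicate), float(r.conductivity))
            for r in grp.itertuples()
        ]
        summary = compute_eli(records)
        row = dict(
            accession=accession,
            eli=summary.eli,
            eli_p=summary.eli_p,
            eli_significant=summary.eli_significant,
        )
        if recovery is not None:
            match = recovery[recovery["accession"] == accession]
            if len(match):
                row["ses"] = ses_score(float(match["recovery_fraction"].iloc[0]))
        rows.append(row)
    return pd.DataFrame(rows)
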