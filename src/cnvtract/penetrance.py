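"""CNV penetrance scores: Bayes-rate computation and cohort assignment.

The penetrance of a CNV for a phenotype (schizophrenia, Sz, or
intellectual disability / developmental delay / autism, DD) is the
probability that a carrier manifests the phenotype. By Bayes' rule,

    P(disease | CNV) = P(CNV | disease) · P(disease) / P(CNV),

i.e. the CNV's rate among cases, scaled by disease prevalence, divided
by its rate in the general population. Scores are expressed in percent
and clamped at 100. The bundled lookup table carries the twelve
neuropsychiatric risk CNVs of the study cohort plus a zero-penetrance
control row; controls always score P_Sz = P_DD = 0. The two table
entries whose source digits are typographically ambiguous are flagged
``transcription_uncertain`` in the resource metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_LABEL",
    "PenetranceTable",
    "load_penetrance_table",
    "compute_penetrance",
    "assign_scores",
]

CONTROL_LABEL = "control"


@dataclass
class PenetranceTable:
    """Per-CNV penetrance (percent) for Sz and DD, keyed by CNV label."""

    table: pd.DataFrame  # index: label; columns incl. p_sz, p_dd, locus_hg19

    def __post_init__(self) -> None:
        for col in ("p_sz", "p_dd"):
            if col not in self.table.columns:
                raise ValueError(f"penetrance table lacks column {col!r}")
            vals = self.table[col].to_numpy(dtype=float)
            if np.any(vals < 0) or np.any(vals > 100):
                raise ValueError(f"{col} must lie in [0, 100]")

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    def lookup(self, label: str) -> tuple[float, float]:
        """Return ``(P_Sz, P_DD)`` in percent for a CNV label."""
        if label not in self.table.index:
            raise KeyError(
                f"unknown CNV label {label!r}; valid labels: {self.labels}")
        row = self.table.loc[label]
        return float(row["p_sz"]), float(row["p_dd"])

    def carrier_summary(self, counts: dict[str, int] | None = None,
                        ) -> tuple[float, float]:
        """Carrier-count-weighted mean ``(P_Sz, P_DD)`` over CNV rows.

        ``counts`` defaults to the table's own ``n`` column (the study
        cohort); the control row is excluded.
        """
        rows = self.table.drop(index=CONTROL_LABEL, errors="ignore")
        if counts is None:
            n = rows["n"].to_numpy(dtype=float)
        else:
            n = np.array([counts.get(l, 0) for l in rows.index], dtype=float)
        if n.sum() == 0:
            return 0.0, 0.0
        return (float(np.average(rows["p_sz"], weights=n)),
                float(np.average(rows["p_dd"], weights=n)))


def load_penetrance_table() -> PenetranceTable:
    """Load the bundled CNV penetrance lookup (percent, hg19 loci)."""
    with resources.files("cnvtract.data").joinpath("penetrance_table.csv").open() as fh:
        df = pd.read_csv(fh, index_col="label")
    return PenetranceTable(table=df)


def compute_penetrance(freq_in_cases: float, freq_in_population: float,
                       prevalence: float = 1.0) -> float:
    """Penetrance in percent from carrier rates via Bayes' rule.

    ``100 · min(1, freq_in_cases · prevalence / freq_in_population)``.
    With ``prevalence = 1`` this reduces to the plain case/population
    rate ratio; supplying the phenotype prevalence gives a dimensionally
    correct probability of manifesting the phenotype. Monotone increasing
    in ``freq_in_cases`` and ``prevalence``, decreasing in
    ``freq_in_population``.
    """
    if freq_in_population <= 0:
        raise ValueError("freq_in_population must be > 0")
    if not 0 <= freq_in_cases <= 1:
        raise ValueError("freq_in_cases must be a rate in [0, 1]")
    if freq_in_population > 1:
        raise ValueError("freq_in_population must be a rate in [0, 1]")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be a fraction in (0, 1]")
    return 100.0 * min(1.0, freq_in_cases * prevalence / freq_in_population)


def assign_scores(cohort: pd.DataFrame,
                  table: PenetranceTable | None = None) -> pd.DataFrame:
    """Populate ``P_Sz``/``P_DD`` (percent) and ``carrier`` on a cohort table.

    ``cohort`` needs a ``cnv_label`` column; every label must resolve in
    the penetrance table. Controls score zero on both phenotypes.
    """
    if table is None:
        table = load_penetrance_table()
    if "cnv_label" not in cohort.columns:
        raise ValueError("cohort table needs a 'cnv_label' column")
    out = cohort.copy()
    scores = [table.lookup(l) for l in out["cnv_label"]]
    out["P_Sz"] = [s[0] for s in scores]
    out["P_DD"] = [s[1] for s in scores]
    out["carrier"] = (out["cnv_label"] != CONTROL_LABEL).astype(int)
    return out
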