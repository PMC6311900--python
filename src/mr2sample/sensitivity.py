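"""Sensitivity analyses: leave-one-out, per-variant estimates, intercept screen.

Leave-one-out re-estimation asks whether any single instrument drives the
pooled causal estimate: each variant is removed in turn and the requested
estimators are re-run on the remaining J-1.  The per-variant (forest-plot)
estimates expose each instrument's own Wald ratio.  The intercept screen
applies the MR-Egger intercept test — the average directional pleiotropy
per variant — to the full set and, optionally, to every leave-one-out
subset, flagging any subset whose intercept p-value falls below a chosen
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientInstrumentsError
from .estimators import (
    MREstimate,
    egger,
    ivw,
    max_likelihood,
    wald_ratio,
    weighted_median,
)
from .summary_io import HarmonizedDataset

__all__ = [
    "LeaveOneOutRow",
    "leave_one_out",
    "leave_one_out_frame",
    "single_snp_estimates",
    "InterceptScreenReport",
    "intercept_screen",
]

#: methods reported by the reference sensitivity table
DEFAULT_LOO_METHODS = ("ivw", "weighted-median", "egger")


@dataclass(frozen=True)
class LeaveOneOutRow:
    """Estimates computed with ``excluded_snp`` removed from the dataset."""

    excluded_snp: str
    estimates: dict[str, MREstimate | None]


def _run_method(method, dataset, model, n_boot, seed):
    if method == "ivw":
        return ivw(dataset, model=model)
    if method == "weighted-median":
        return weighted_median(dataset, n_boot=n_boot, seed=seed)
    if method == "egger":
        return egger(dataset)[0]
    if method == "egger-intercept":
        return egger(dataset)[1]
    if method == "max-likelihood":
        return max_likelihood(dataset)
    if method == "wald":
        if len(dataset) != 1:
            raise InsufficientInstrumentsError("wald needs exactly one variant")
        return wald_ratio(dataset[0])
    raise ValueError(f"unknown method {method!r}")


def leave_one_out(
    dataset: HarmonizedDataset,
    methods=DEFAULT_LOO_METHODS,
    model: str = "default",
    n_boot: int = 1000,
    seed: int = 42,
) -> list[LeaveOneOutRow]:
    """Re-run each estimator with every variant excluded in turn.

    Returns one row per variant, in dataset order.  Within a row every
    method sees the identical J-1 subset; the weighted-median bootstrap uses
    ``seed + row_index`` so rows are independent but reproducible.  A method
    whose minimum size exceeds J-1 yields ``None`` for that cell rather
    than failing the whole analysis.
    """
    rows = []
    for i, snp in enumerate(dataset.snp_ids):
        reduced = dataset.drop(snp)
        cell: dict[str, MREstimate | None] = {}
        for m in methods:
            try:
                cell[m] = _run_method(m, reduced, model, n_boot, seed + i)
            except InsufficientInstrumentsError:
                cell[m] = None
        rows.append(LeaveOneOutRow(excluded_snp=snp, estimates=cell))
    return rows


def leave_one_out_frame(rows, full: bool = False) -> pd.DataFrame:
    """Tabulate leave-one-out rows: p-values only, or full estimates."""
    records = []
    for row in rows:
        rec: dict = {"excluded_snp": row.excluded_snp}
        for method, est in row.estimates.items():
            key = method.replace("-", "_")
            if est is None:
                rec[f"pval_{key}"] = None
                continue
            rec[f"pval_{key}"] = est.pval
            if full:
                rec[f"theta_{key}"] = est.theta
                rec[f"se_{key}"] = est.se
                rec[f"or_{key}"] = est.or_
        records.append(rec)
    return pd.DataFrame(records)


def single_snp_estimates(dataset: HarmonizedDataset) -> list[MREstimate]:
    """One Wald-ratio estimate per variant (delta-method SE); forest data."""
    return [wald_ratio(pair, se_order="second") for pair in dataset]


@dataclass(frozen=True)
class InterceptScreenReport:
    """MR-Egger intercept test on the full set and leave-one-out subsets."""

    full_intercept: MREstimate
    alpha: float
    subsets: dict[str, MREstimate]  # excluded snp -> intercept on the rest
    flagged: tuple[str, ...]  # subset labels with intercept p < alpha

    @property
    def full_significant(self) -> bool:
        return self.full_intercept.pval < self.alpha

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset": "full",
                "intercept": self.full_intercept.theta,
                "se": self.full_intercept.se,
                "pval": self.full_intercept.pval,
                "flagged": self.full_significant,
            }
        ]
        for snp, est in self.subsets.items():
            rows.append(
                {
                    "subset": f"excl:{snp}",
                    "intercept": est.theta,
                    "se": est.se,
                    "pval": est.pval,
                    "flagged": f"excl:{snp}" in self.flagged,
                }
            )
        return pd.DataFrame(rows)


def intercept_screen(
    dataset: HarmonizedDataset, prune: bool = False, alpha: float = 0.05
) -> InterceptScreenReport:
    """Directional-pleiotropy screen via the MR-Egger intercept.

    With ``prune`` the intercept test is repeated on every leave-one-out
    subset (iterative pruning); any subset with intercept p below ``alpha``
    is flagged.
    """
    _, full_intercept = egger(dataset)
    subsets: dict[str, MREstimate] = {}
    flagged: list[str] = []
    if full_intercept.pval < alpha:
        flagged.append("full")
    if prune:
        for snp in dataset.snp_ids:
            try:
                _, sub = egger(dataset.drop(snp))
            except InsufficientInstrumentsError:
                continue
            subsets[snp] = sub
            if sub.pval < alpha:
                flagged.append(f"excl:{snp}")
    return InterceptScreenReport(
        full_intercept=full_intercept,
        alpha=alpha,
        subsets=subsets,
        flagged=tuple(flagged),
    )
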