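"""Instrument selection and pleiotropy screening.

Two selection problems precede estimation:

* **Tag-SNP selection** at a single locus (here SNCA, the alpha-synuclein
  gene): candidate lead SNPs reported by different GWASs are filtered to an
  allowed discovery ancestry, variants in linkage disequilibrium with one
  another are collapsed into one linked group, and the group is represented
  by the member reported by the largest study.  LD r-squared values are
  supplied as data (e.g. read off an LD browser); they are never computed
  here.

* **Confounder screening** of a multi-SNP instrument set: any instrument
  with a sub-threshold association to a potential confounder trait
  (education, diet, alcohol, disease biomarkers, ... staged 1-4) violates
  the independence assumptions and is excluded.  The fifth stage — the
  MR-Egger intercept test — lives in :mod:`mr2sample.sensitivity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptySelectionError, ValidationError
from .summary_io import HarmonizedDataset, VariantAssociation, harmonize

__all__ = [
    "CandidateVariant",
    "ConfounderAssociation",
    "ScreenReport",
    "TagSelection",
    "select_tag_snp",
    "screen_pleiotropy",
    "assemble_instruments",
    "candidates_from_frame",
    "confounders_from_frame",
]


@dataclass(frozen=True)
class CandidateVariant:
    """A locus lead-SNP candidate with its selection metadata.

    ``ld_r2`` is the linkage-disequilibrium r-squared with the locus
    reference variant (``None`` when unknown); ``source_n`` is the sample
    size of the reporting GWAS.
    """

    snp_id: str
    ancestry: str
    source_n: int
    ld_r2: float | None = None
    assoc: VariantAssociation | None = None

    def __post_init__(self):
        if self.ld_r2 is not None and not (0.0 <= self.ld_r2 <= 1.0):
            raise ValidationError(f"{self.snp_id}: ld_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class ConfounderAssociation:
    """One instrument-confounder association from a screening stage (1-4)."""

    snp_id: str
    trait: str
    stage: int
    pval: float

    def __post_init__(self):
        if self.stage not in {1, 2, 3, 4}:
            raise ValidationError(f"{self.snp_id}: stage must be 1-4")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: pval must lie in (0, 1]")


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the confounder screen: retained ids and per-SNP reasons."""

    retained: tuple[str, ...]
    excluded: dict[str, tuple[tuple[int, str, float], ...]]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"snp": s, "status": "retained", "reasons": ""} for s in self.retained]
        for snp, reasons in self.excluded.items():
            rows.append(
                {
                    "snp": snp,
                    "status": "excluded",
                    "reasons": ";".join(
                        f"stage{st}:{trait}:p={p:.3g}" for st, trait, p in reasons
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TagSelection:
    """Result of tag-SNP selection with a per-candidate audit trail."""

    tag: str
    audit: dict[str, str]  # snp_id -> decision ("selected" or removal rule)


def select_tag_snp(
    candidates: Sequence[CandidateVariant],
    ancestry_allow: Iterable[str] = ("European", "Caucasian"),
    r2_link_threshold: float = 0.2,
) -> TagSelection:
    """Pick one tag variant for a locus from reported lead-SNP candidates.

    Candidates outside ``ancestry_allow`` are removed first.  Among the
    rest, candidates whose ``ld_r2`` (to the locus reference) reaches
    ``r2_link_threshold`` form one linked group; candidates with missing or
    sub-threshold r-squared stand alone.  Each group is represented by its
    largest-``source_n`` member, and the tag is the representative with the
    largest ``source_n`` overall (ties broken by snp_id for determinism).
    Every removal is recorded in the audit with the rule that caused it.
    """
    if not candidates:
        raise EmptySelectionError("no candidates supplied")
    audit: dict[str, str] = {}
    allow = set(ancestry_allow)
    surviving = []
    for c in sorted(candidates, key=lambda c: c.snp_id):
        if c.ancestry not in allow:
            audit[c.snp_id] = f"removed: ancestry {c.ancestry} not allowed"
        else:
            surviving.append(c)
    if not surviving:
        raise EmptySelectionError("no candidate from an allowed ancestry")

    linked = [c for c in surviving if c.ld_r2 is not None and c.ld_r2 >= r2_link_threshold]
    singles = [c for c in surviving if c not in linked]
    groups = ([linked] if linked else []) + [[c] for c in singles]

    reps = []
    for group in groups:
        rep = max(group, key=lambda c: (c.source_n, c.snp_id))
        reps.append(rep)
        for c in group:
            if c is not rep:
                audit[c.snp_id] = (
                    f"removed: linked (r2={c.ld_r2}) to larger study tag {rep.snp_id}"
                )
    tag = max(reps, key=lambda c: (c.source_n, c.snp_id))
    for rep in reps:
        if rep is not tag:
            audit[rep.snp_id] = (
                f"removed: separate group, smaller study than {tag.snp_id}"
            )
    audit[tag.snp_id] = "selected"
    return TagSelection(tag=tag.snp_id, audit=audit)


def screen_pleiotropy(
    ivs: Sequence[str],
    confounders: Iterable[ConfounderAssociation],
    threshold: float = 1e-3,
) -> ScreenReport:
    """Exclude instruments with a confounder association below ``threshold``.

    The comparison is strict (``pval < threshold``); a single sub-threshold
    hit suffices for exclusion and every triggering association is listed.
    Confounder records naming an unknown instrument are ignored with a
    warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    iv_set = set(ivs)
    hits: dict[str, list[tuple[int, str, float]]] = {}
    for rec in confounders:
        if rec.snp_id not in iv_set:
            warnings.warn(
                f"confounder record for unknown instrument {rec.snp_id}; ignored",
                stacklevel=2,
            )
            continue
        if rec.pval < threshold:
            hits.setdefault(rec.snp_id, []).append((rec.stage, rec.trait, rec.pval))
    excluded = {snp: tuple(sorted(v)) for snp, v in hits.items()}
    retained = tuple(s for s in ivs if s not in excluded)
    return ScreenReport(retained=retained, excluded=excluded)


def assemble_instruments(
    exposure_table: Sequence[VariantAssociation],
    outcome_table: Sequence[VariantAssociation],
    screen_report: ScreenReport | None = None,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    **harmonize_kwargs,
) -> tuple[HarmonizedDataset, dict[str, int]]:
    """Harmonize, apply a screen report, and emit the analysis-ready dataset.

    Returns the dataset together with a provenance log:
    ``initial`` candidates, ``missing_in_outcome`` (plus any other
    harmonization exclusions, counted separately), ``screened`` and the
    final ``J``.  Counts are conserved:
    ``initial = final + missing_in_outcome + other_harmonization + screened``.
    """
    initial = len(exposure_table)
    dataset = harmonize(
        exposure_table,
        outcome_table,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        **harmonize_kwargs,
    )
    missing = sum(1 for _, why in dataset.excluded if why == "missing-in-outcome")
    other = len(dataset.excluded) - missing

    screened_ids: set[str] = set()
    if screen_report is not None:
        screened_ids = set(screen_report.excluded) & set(dataset.snp_ids)
        keep = [s for s in dataset.snp_ids if s not in screened_ids]
        if not keep:
            raise EmptySelectionError("screening removed every instrument")
        excluded = dataset.excluded + [
            (s, "pleiotropy-screened") for s in sorted(screened_ids)
        ]
        dataset = HarmonizedDataset(
            [p for p in dataset if p.snp_id in set(keep)],
            exposure_label,
            outcome_label,
            excluded,
        )
    provenance = {
        "initial": initial,
        "missing_in_outcome": missing,
        "other_harmonization": other,
        "screened": len(screened_ids),
        "final": len(dataset),
    }
    return dataset, provenance


def candidates_from_frame(df: pd.DataFrame) -> list[CandidateVariant]:
    """Build candidates from a table with snp/ancestry/ld_r2/source_n columns."""
    out = []
    for r in df.itertuples():
        ld = getattr(r, "ld_r2", None)
        out.append(
            CandidateVariant(
                snp_id=r.snp,
                ancestry=str(r.ancestry),
                source_n=int(r.source_n),
                ld_r2=None if ld is None or pd.isna(ld) else float(ld),
            )
        )
    return out


def confounders_from_frame(df: pd.DataFrame) -> list[ConfounderAssociation]:
    """Build confounder records from a snp/trait/stage/pval table."""
    return [
        ConfounderAssociation(
            snp_id=r.snp, trait=str(r.trait), stage=int(r.stage), pval=float(r.pval)
        )
        for r in df.itertuples()
    ]
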