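"""Summary-statistic containers, tabular I/O and allele harmonization.

Two-sample Mendelian randomization starts from two per-variant association
tables — one for the exposure, one for the outcome — each reporting an
additive effect (log odds ratio for binary traits) of the *effect allele*
together with its standard error.  Before any causal estimate can be formed
the two tables have to be placed on a common effect-allele orientation:
where the outcome study reports the other allele the outcome effect is
negated (and the allele frequency complemented), strand flips are resolved
through base complementing, and palindromic variants (A/T, C/G), whose
strand cannot be read off the alleles, are resolved from allele frequency
or dropped.

The module also ships the worked PD→AD dataset used throughout the test
suite: 39 harmonized variants with Parkinson's disease (exposure, Nalls/
Chang-scale GWAS) and Alzheimer's disease (outcome, IGAP stage 1) effects,
plus the seven SNCA candidate variants used for single-instrument analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "VariantAssociation",
    "HarmonizedPair",
    "HarmonizedDataset",
    "SummaryTable",
    "read_summary_table",
    "harmonize",
    "write_harmonized",
    "read_harmonized",
    "load_pd_ad_dataset",
    "load_pd_ad_tables",
    "load_snca_candidates",
    "load_candidate_tables",
    "load_confounder_table",
    "load_reported_results",
    "load_reported_loo_pvalues",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default file-column names; remap via ``column_map``
DEFAULT_COLUMNS = {
    "snp": "snp",
    "chr": "chr",
    "pos": "pos",
    "ea": "ea",
    "nea": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive per-effect-allele effect (log odds for binary
    traits) and refers to allele ``ea``; ``eaf`` is the effect-allele
    frequency and may be ``None`` when the source study did not report it.
    """

    snp_id: str
    ea: str
    nea: str
    beta: float
    se: float
    pval: float | None = None
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        ea, nea = self.ea.upper(), self.nea.upper()
        object.__setattr__(self, "ea", ea)
        object.__setattr__(self, "nea", nea)
        if not ea or not nea or ea == nea:
            raise ValidationError(
                f"{self.snp_id}: alleles must be distinct and non-empty "
                f"(got ea={ea!r}, nea={nea!r})"
            )
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be finite and > 0")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf must lie in [0, 1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: pval must lie in (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants (strand-ambiguous)."""
        return _COMPLEMENT.get(self.ea) == self.nea

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            ea=self.nea,
            nea=self.ea,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class HarmonizedPair:
    """Paired exposure/outcome effects for one variant on a shared effect allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValidationError(f"{self.snp_id}: standard errors must be > 0")


class HarmonizedDataset:
    """An ordered collection of :class:`HarmonizedPair` ready for estimation.

    Exposes the per-variant effect vectors as numpy arrays (``beta_x``,
    ``se_x``, ``beta_y``, ``se_y``) for the estimator layer.  ``excluded``
    records variants that harmonization removed, as ``(snp_id, reason)``.
    """

    def __init__(
        self,
        pairs: Sequence[HarmonizedPair],
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
        excluded: Sequence[tuple[str, str]] = (),
    ):
        pairs = list(pairs)
        if len(pairs) < 1:
            raise ValidationError("a HarmonizedDataset needs at least one variant")
        ids = [p.snp_id for p in pairs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate snp_id in dataset: {', '.join(dup)}")
        self.pairs: list[HarmonizedPair] = pairs
        self.exposure_label = exposure_label
        self.outcome_label = outcome_label
        self.excluded: list[tuple[str, str]] = list(excluded)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, key) -> HarmonizedPair:
        return self.pairs[key]

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([p.beta_x for p in self.pairs], dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return np.array([p.se_x for p in self.pairs], dtype=float)

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([p.beta_y for p in self.pairs], dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return np.array([p.se_y for p in self.pairs], dtype=float)

    def drop(self, snp_id: str) -> "HarmonizedDataset":
        """A copy without the named variant (leave-one-out slicing)."""
        kept = [p for p in self.pairs if p.snp_id != snp_id]
        if len(kept) == len(self.pairs):
            raise KeyError(snp_id)
        return HarmonizedDataset(kept, self.exposure_label, self.outcome_label)

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedDataset":
        keep = set(snp_ids)
        return HarmonizedDataset(
            [p for p in self.pairs if p.snp_id in keep],
            self.exposure_label,
            self.outcome_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "eaf": [p.eaf for p in self.pairs],
                "flags": [";".join(sorted(p.flags)) for p in self.pairs],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HarmonizedDataset({len(self)} variants, "
            f"{self.exposure_label!r} -> {self.outcome_label!r})"
        )


class SummaryTable(list):
    """A list of :class:`VariantAssociation` with a record of rejected rows.

    ``rejected`` holds ``(row_index, reason)`` for every input row that could
    not be parsed into a valid association.
    """

    def __init__(self, records: Iterable[VariantAssociation] = (), rejected=()):
        super().__init__(records)
        self.rejected: list[tuple[int, str]] = list(rejected)


def _parse_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "" or text.upper() in {"NA", "NAN", "."}:
        return None
    try:
        out = float(text)
    except ValueError:
        return None
    return out if math.isfinite(out) else None


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SummaryTable:
    """Read a tab-separated summary-statistic file into associations.

    Parameters
    ----------
    path
        TSV file with a header row.  Default column names are
        ``snp, chr, pos, ea, nea, eaf, beta, se, pval``; pass ``column_map``
        (logical name -> file column) to remap.  Missing values are ``NA``.

    Rows whose beta or se do not parse as finite numbers (se additionally
    must be positive) are rejected, each with a reason, accessible through
    the returned table's ``rejected`` attribute.  ``eaf`` and ``pval`` are
    optional per row.

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is absent from the file.
    ValidationError
        if the same snp identifier appears twice.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = ["snp", "ea", "nea", "beta", "se"]
    missing = [cols[k] for k in mandatory if cols[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    records: list[VariantAssociation] = []
    rejected: list[tuple[int, str]] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        snp = str(row[cols["snp"]]).strip()
        beta = _parse_float(row[cols["beta"]])
        se = _parse_float(row[cols["se"]])
        if beta is None:
            rejected.append((idx, f"{snp}: unparseable beta"))
            continue
        if se is None or se <= 0:
            rejected.append((idx, f"{snp}: unparseable SE"))
            continue
        if snp in seen:
            raise ValidationError(f"{path}: duplicate snp_id {snp}")
        seen.add(snp)
        pos = _parse_float(row[cols["pos"]]) if cols["pos"] in df.columns else None
        records.append(
            VariantAssociation(
                snp_id=snp,
                ea=str(row[cols["ea"]]).strip(),
                nea=str(row[cols["nea"]]).strip(),
                beta=beta,
                se=se,
                pval=_parse_float(row[cols["pval"]]) if cols["pval"] in df.columns else None,
                eaf=_parse_float(row[cols["eaf"]]) if cols["eaf"] in df.columns else None,
                chrom=str(row[cols["chr"]]).strip() if cols["chr"] in df.columns else None,
                pos=None if pos is None else int(pos),
            )
        )
    return SummaryTable(records, rejected)


def _complement_alleles(v: VariantAssociation) -> VariantAssociation | None:
    """The association re-expressed on the opposite strand, if complementable."""
    try:
        return replace(v, ea=_COMPLEMENT[v.ea], nea=_COMPLEMENT[v.nea])
    except KeyError:
        return None


def harmonize(
    exposure: Iterable[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    palindrome_policy: str = "infer-by-eaf",
    eaf_window: float = 0.08,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Matching is by rsID only; genomic coordinates are carried as metadata.
    For each exposure variant:

    * outcome reported on the same alleles -> kept as-is;
    * outcome reported on swapped alleles (or their strand complement) ->
      outcome beta negated, eaf complemented, flag ``allele-flipped``;
    * palindromic variants (A/T, C/G) handled per ``palindrome_policy``:
      ``drop`` excludes them; ``keep`` takes the alleles at face value;
      ``infer-by-eaf`` orients by comparing allele frequencies, and excludes
      the variant (flag ``palindromic-ambiguous``) when both frequencies lie
      within ``eaf_window`` of 0.5, or when either eaf is missing;
    * variants absent from the outcome table are excluded with flag
      ``missing-in-outcome``; irreconcilable allele pairs with
      ``allele-mismatch``.

    The operation is idempotent: harmonizing an already aligned dataset
    changes nothing.
    """
    if palindrome_policy not in {"drop", "infer-by-eaf", "keep"}:
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    exposure = list(exposure)
    outcome_by_id = {v.snp_id: v for v in outcome}
    if not exposure or not outcome_by_id:
        raise ValidationError("exposure and outcome collections must be non-empty")

    pairs: list[HarmonizedPair] = []
    excluded: list[tuple[str, str]] = []

    for ex in exposure:
        out = outcome_by_id.get(ex.snp_id)
        if out is None:
            excluded.append((ex.snp_id, "missing-in-outcome"))
            continue
        flags: set[str] = set()

        if ex.is_palindromic or out.is_palindromic:
            # for palindromes the strand-complement allele set equals the
            # swapped set, so the sets must agree outright
            if {ex.ea, ex.nea} != {out.ea, out.nea}:
                excluded.append((ex.snp_id, "allele-mismatch"))
                continue
            flags.add("palindromic")
            if palindrome_policy == "drop":
                excluded.append((ex.snp_id, "palindromic-dropped"))
                continue
            if palindrome_policy == "keep":
                aligned = out if out.ea == ex.ea else out.flipped()
                if aligned.ea != ex.ea:
                    excluded.append((ex.snp_id, "allele-mismatch"))
                    continue
                if aligned is not out:
                    flags.add("allele-flipped")
            else:  # infer-by-eaf
                if ex.eaf is None or out.eaf is None:
                    excluded.append((ex.snp_id, "palindromic-no-eaf"))
                    continue
                if abs(ex.eaf - 0.5) < eaf_window and abs(out.eaf - 0.5) < eaf_window:
                    excluded.append((ex.snp_id, "palindromic-ambiguous"))
                    continue
                # same side of 0.5 -> frequencies describe the same allele
                same_side = (ex.eaf - 0.5) * (out.eaf - 0.5) >= 0
                aligned = out if same_side else out.flipped()
                if not same_side:
                    flags.add("allele-flipped")
        else:
            aligned = None
            for cand, extra in ((out, None), (_complement_alleles(out), "strand-complemented")):
                if cand is None:
                    continue
                if cand.ea == ex.ea and cand.nea == ex.nea:
                    aligned = cand
                elif cand.ea == ex.nea and cand.nea == ex.ea:
                    aligned = cand.flipped()
                    flags.add("allele-flipped")
                if aligned is not None:
                    if extra:
                        flags.add(extra)
                    break
            if aligned is None:
                excluded.append((ex.snp_id, "allele-mismatch"))
                continue

        pairs.append(
            HarmonizedPair(
                snp_id=ex.snp_id,
                beta_x=ex.beta,
                se_x=ex.se,
                beta_y=aligned.beta,
                se_y=aligned.se,
                eaf=ex.eaf,
                flags=frozenset(flags),
            )
        )

    if not pairs:
        raise ValidationError("harmonization removed every variant")
    return HarmonizedDataset(pairs, exposure_label, outcome_label, excluded)


def write_harmonized(dataset: HarmonizedDataset, path: str | Path) -> None:
    """Write a harmonized dataset as TSV with full float precision."""
    df = dataset.to_frame()
    df.insert(0, "exposure", dataset.exposure_label)
    df.insert(1, "outcome", dataset.outcome_label)
    # pandas' default float repr round-trips exactly
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_harmonized(path: str | Path) -> HarmonizedDataset:
    """Read back a file written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t")
    pairs = [
        HarmonizedPair(
            snp_id=str(r.snp),
            beta_x=float(r.beta_x),
            se_x=float(r.se_x),
            beta_y=float(r.beta_y),
            se_y=float(r.se_y),
            eaf=None if pd.isna(r.eaf) else float(r.eaf),
            flags=frozenset() if pd.isna(r.flags) or not r.flags else frozenset(str(r.flags).split(";")),
        )
        for r in df.itertuples()
    ]
    return HarmonizedDataset(
        pairs,
        exposure_label=str(df["exposure"].iloc[0]),
        outcome_label=str(df["outcome"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_path(name: str) -> Path:
    return Path(resources.files("mr2sample") / "fixtures" / name)


def _pd_ad_frame() -> pd.DataFrame:
    return pd.read_csv(_fixture_path("table2_pd_ad.tsv"), sep="\t")


def load_pd_ad_dataset() -> HarmonizedDataset:
    """The 39-variant harmonized PD (exposure) / AD (outcome) dataset.

    Both traits' effects refer to the same printed effect allele, so the
    table is already harmonized.
    """
    df = _pd_ad_frame()
    pairs = [
        HarmonizedPair(
            snp_id=r.snp,
            beta_x=r.beta_pd,
            se_x=r.se_pd,
            beta_y=r.beta_ad,
            se_y=r.se_ad,
            eaf=r.eaf,
        )
        for r in df.itertuples()
    ]
    return HarmonizedDataset(pairs, "PD", "AD")


def load_pd_ad_tables() -> tuple[SummaryTable, SummaryTable]:
    """The same 39 variants as two single-trait association tables."""
    df = _pd_ad_frame()

    def as_records(beta_col, se_col, p_col):
        return SummaryTable(
            VariantAssociation(
                snp_id=r.snp,
                ea=r.ea,
                nea=r.nea,
                beta=getattr(r, beta_col),
                se=getattr(r, se_col),
                pval=getattr(r, p_col),
                eaf=r.eaf,
                chrom=str(r.chr),
                pos=int(r.pos),
            )
            for r in df.itertuples()
        )

    return (
        as_records("beta_pd", "se_pd", "pval_pd"),
        as_records("beta_ad", "se_ad", "pval_ad"),
    )


def load_snca_candidates() -> pd.DataFrame:
    """The seven SNCA-locus candidate variants (ancestry, LD r2, OR, CI, p).

    ``source_n`` holds approximate total sample sizes of the reporting
    GWASs; only their ordering is used (largest-study wins tag selection).
    """
    return pd.read_csv(_fixture_path("table1_snca.tsv"), sep="\t")


def load_candidate_tables() -> tuple[SummaryTable, SummaryTable]:
    """The full 43-candidate exposure table and 42-variant outcome table.

    Thirty-nine rows per trait are the printed harmonized dataset; the
    remaining four exposure rows (and three outcome rows) cover variants the
    source publication excluded before printing its dataset table
    (rs143918452 absent from the outcome study; rs11343, rs17649553 and
    rs9275326 removed by the pleiotropy screen).  Their effect sizes are
    synthetic placeholders of realistic magnitude — the screening decisions
    they feed depend only on presence/absence and on the genuine confounder
    p-values.
    """
    exposure, outcome = load_pd_ad_tables()
    extra = pd.read_csv(_fixture_path("extra_candidates_synthetic.tsv"), sep="\t")
    for r in extra.itertuples():
        rec = VariantAssociation(
            snp_id=r.snp,
            ea=r.ea,
            nea=r.nea,
            beta=r.beta,
            se=r.se,
            pval=r.pval,
            eaf=r.eaf,
            chrom=str(r.chr),
            pos=int(r.pos),
        )
        (exposure if r.trait == "pd" else outcome).append(rec)
    return exposure, outcome


def load_confounder_table() -> pd.DataFrame:
    """Printed confounder associations driving the pleiotropy screen."""
    return pd.read_csv(_fixture_path("confounders.tsv"), sep="\t")


def load_reported_results() -> pd.DataFrame:
    """Headline estimates as printed by the source study (for comparison)."""
    return pd.read_csv(_fixture_path("reported_results.tsv"), sep="\t")


def load_reported_loo_pvalues() -> pd.DataFrame:
    """Printed leave-one-out p-values (IVW / weighted median / Egger)."""
    return pd.read_csv(_fixture_path("table3_loo_pvalues.tsv"), sep="\t")
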