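"""Ingestion and harmonization of two-sample GWAS summary statistics.

A two-sample Mendelian randomization analysis starts from two per-SNP
association tables — one against the exposure, one against the outcome —
each row carrying an effect allele, the other allele, the effect-allele
frequency (EAF), an additive effect estimate ``beta`` with standard error
``se``, and a p-value.  Before any causal estimation the two tables must be
*harmonized*: every SNP's outcome effect must be expressed for the same
allele as its exposure effect, resolving reversed allele labels, strand
complementation, and the intrinsic ambiguity of palindromic (A/T, G/C)
variants.  This module provides the record types, the table reader, the
harmonization engine, and the mean F-statistic instrument-strength
diagnostic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "SummaryDataError",
    "ACTIONS",
    "DROPPED_ACTIONS",
    "read_summary_table",
    "is_palindromic",
    "complement_allele",
    "harmonize",
    "mean_f_statistic",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT_AS_IS = "kept_as_is"
OUTCOME_FLIPPED = "outcome_flipped"
STRAND_COMPLEMENTED = "strand_complemented"
STRAND_COMPLEMENTED_AND_FLIPPED = "strand_complemented_and_flipped"
DROPPED_AMBIGUOUS = "dropped_ambiguous"
DROPPED_MISSING = "dropped_missing"
DROPPED_IRRECONCILABLE = "dropped_irreconcilable"

ACTIONS = (
    KEPT_AS_IS,
    OUTCOME_FLIPPED,
    STRAND_COMPLEMENTED,
    STRAND_COMPLEMENTED_AND_FLIPPED,
    DROPPED_AMBIGUOUS,
    DROPPED_MISSING,
    DROPPED_IRRECONCILABLE,
)
DROPPED_ACTIONS = (DROPPED_AMBIGUOUS, DROPPED_MISSING, DROPPED_IRRECONCILABLE)

#: default column names, GWAS-catalog style
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
}


class SummaryDataError(ValueError):
    """Raised for malformed summary-statistic inputs."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary statistics in one GWAS.

    ``beta`` is the additive per-effect-allele estimate — log-odds for a
    binary trait, SD units when the source GWAS analysed a standardized
    trait.  ``eaf`` and ``pvalue`` may be ``None`` when the source table
    omits them.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.rsid:
            problems.append("empty rsid")
        if self.effect_allele not in _VALID_ALLELES:
            problems.append(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            problems.append(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            problems.append("effect and other allele identical")
        if not np.isfinite(self.beta):
            problems.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            problems.append(f"se must be > 0, got {self.se!r}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf outside [0, 1]: {self.eaf!r}")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            problems.append(f"pvalue outside (0, 1]: {self.pvalue!r}")
        return problems

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def minor_allele_frequency(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's paired exposure/outcome effects after allele alignment.

    After harmonization ``beta_exposure >= 0`` (the effect allele is the
    exposure-increasing allele) and ``beta_outcome`` refers to that same
    allele.  ``action`` records what harmonization did; records with a
    ``dropped_*`` action carry no estimate downstream.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    palindromic: bool
    action: str
    pvalue_exposure: float | None = None
    pvalue_outcome: float | None = None

    @property
    def dropped(self) -> bool:
        return self.action in DROPPED_ACTIONS


@dataclass
class InstrumentSet:
    """An ordered set of harmonized instruments plus the harmonization audit.

    ``instruments`` holds only the retained records; ``records`` keeps every
    shared rsid with its action flag so drops are auditable.  Numeric arrays
    over the retained instruments are exposed as properties for the
    estimator layer.
    """

    instruments: list[HarmonizedInstrument]
    records: list[HarmonizedInstrument] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            self.records = list(self.instruments)
        rsids = [inst.rsid for inst in self.instruments]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise SummaryDataError(f"duplicate rsids in instrument set: {dupes}")
        if any(inst.dropped for inst in self.instruments):
            raise SummaryDataError("dropped records may not enter an instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [inst.rsid for inst in self.instruments]

    def _array(self, name: str) -> np.ndarray:
        return np.array([getattr(inst, name) for inst in self.instruments], dtype=float)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self._array("beta_exposure")

    @property
    def se_exposure(self) -> np.ndarray:
        return self._array("se_exposure")

    @property
    def beta_outcome(self) -> np.ndarray:
        return self._array("beta_outcome")

    @property
    def se_outcome(self) -> np.ndarray:
        return self._array("se_outcome")

    @property
    def n_palindromic_retained(self) -> int:
        return sum(1 for inst in self.instruments if inst.palindromic)

    @property
    def n_dropped(self) -> int:
        return sum(1 for rec in self.records if rec.dropped)

    def dropped_counts(self) -> dict[str, int]:
        counts = {action: 0 for action in DROPPED_ACTIONS}
        for rec in self.records:
            if rec.dropped:
                counts[rec.action] += 1
        return counts

    def subset(self, rsids: Iterable[str]) -> "InstrumentSet":
        """Instrument set restricted to ``rsids`` (order preserved)."""
        keep = set(rsids)
        return InstrumentSet(
            [inst for inst in self.instruments if inst.rsid in keep],
            records=self.records,
        )

    def drop(self, rsids: Iterable[str]) -> "InstrumentSet":
        omit = set(rsids)
        return InstrumentSet(
            [inst for inst in self.instruments if inst.rsid not in omit],
            records=self.records,
        )

    def to_frame(self, full: bool = False) -> pd.DataFrame:
        rows = self.records if full else self.instruments
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in rows],
                "effect_allele": [r.effect_allele for r in rows],
                "other_allele": [r.other_allele for r in rows],
                "beta_exposure": [r.beta_exposure for r in rows],
                "se_exposure": [r.se_exposure for r in rows],
                "beta_outcome": [r.beta_outcome for r in rows],
                "se_outcome": [r.se_outcome for r in rows],
                "eaf_exposure": [r.eaf_exposure for r in rows],
                "eaf_outcome": [r.eaf_outcome for r in rows],
                "palindromic": [r.palindromic for r in rows],
                "action": [r.action for r in rows],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame(full=True).to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or G/C (strand-ambiguous)."""
    for a in (a1, a2):
        if a not in _VALID_ALLELES:
            raise SummaryDataError(f"invalid allele symbol {a!r}")
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


def complement_allele(a: str) -> str:
    if a not in _COMPLEMENT:
        raise SummaryDataError(f"invalid allele symbol {a!r}")
    return _COMPLEMENT[a]


def _parse_optional(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan", "."):
        return None
    out = float(value)
    return None if np.isnan(out) else out


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as handle:
        sample = handle.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[SnpAssociation]:
    """Read a delimited summary-statistic table into ``SnpAssociation`` records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps the canonical field names (``rsid``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``) to the
        file's column names.  Unmapped fields fall back to GWAS-catalog
        style defaults.  ``eaf`` and ``pvalue`` columns may be absent.
    delimiter
        Field delimiter; auto-detected when omitted.

    Raises
    ------
    SummaryDataError
        On unreadable input, duplicate rsids, or rows violating the record
        invariants (each offender is named — bad rows are never silently
        dropped).
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SummaryDataError(f"cannot read summary table {path}: {exc}") from exc

    required = ["rsid", "effect_allele", "other_allele", "beta", "se"]
    missing = [f for f in required if colmap[f] not in frame.columns]
    if missing:
        raise SummaryDataError(
            f"missing required columns {[colmap[f] for f in missing]} in {path}; "
            f"available: {list(frame.columns)}"
        )

    records: list[SnpAssociation] = []
    problems: list[str] = []
    for idx, row in frame.iterrows():
        rsid = str(row[colmap["rsid"]]).strip()
        try:
            rec = SnpAssociation(
                rsid=rsid,
                effect_allele=str(row[colmap["effect_allele"]]).strip().upper(),
                other_allele=str(row[colmap["other_allele"]]).strip().upper(),
                beta=float(row[colmap["beta"]]),
                se=float(row[colmap["se"]]),
                eaf=_parse_optional(row.get(colmap["eaf"])),
                pvalue=_parse_optional(row.get(colmap["pvalue"])),
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"row {idx} ({rsid}): unparseable value ({exc})")
            continue
        row_problems = rec.validate()
        if row_problems:
            problems.append(f"row {idx} ({rsid}): " + "; ".join(row_problems))
        else:
            records.append(rec)

    if problems:
        raise SummaryDataError(
            "invalid rows in summary table:\n  " + "\n  ".join(problems)
        )
    rsids = [r.rsid for r in records]
    if len(set(rsids)) != len(rsids):
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        raise SummaryDataError(f"duplicate rsids: {dupes}")
    return records


def write_summary_table(records: Sequence[SnpAssociation], path) -> None:
    """Write records in the same TSV dialect ``read_summary_table`` consumes."""
    frame = pd.DataFrame(
        {
            "SNP": [r.rsid for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pvalue for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def _orient_to_exposure_increasing(rec: SnpAssociation) -> SnpAssociation:
    """Flip the record so its beta is >= 0 (effect allele increases exposure)."""
    if rec.beta >= 0:
        return rec
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _flip_outcome(beta, eaf):
    return -beta, (None if eaf is None else 1.0 - eaf)


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindromic_maf_threshold: float = 0.45,
    palindromic_policy: str = "retain_same_strand",
) -> InstrumentSet:
    """Align outcome effects to the exposure-increasing allele of each SNP.

    For each rsid shared between the tables:

    1. the exposure record is oriented so its beta is non-negative (alleles
       swapped, beta negated, EAF complemented when needed);
    2. the outcome record is matched to the oriented exposure alleles —
       directly, with swapped labels (outcome beta negated, EAF
       complemented), or after A<->T / C<->G strand complementation;
    3. palindromic SNPs, for which strand complementation is uninformative,
       are handled per ``palindromic_policy``:

       ``retain_same_strand``
           treat the labels as same-strand reads and align by label only;
       ``drop_above_threshold``
           as above, but drop SNPs whose minor-allele frequency exceeds
           ``palindromic_maf_threshold``;
       ``infer_by_frequency``
           align by EAF concordance across the datasets (compare the
           outcome EAF against the exposure EAF and its complement); drop
           as ambiguous when the MAF exceeds the threshold or the EAF is
           missing on either side.

    SNPs absent from either table are recorded as ``dropped_missing``;
    irreconcilable allele pairs are flagged, never fatal.  Raises
    ``SummaryDataError`` when the rsid intersection is empty.
    """
    if palindromic_policy not in (
        "retain_same_strand",
        "drop_above_threshold",
        "infer_by_frequency",
    ):
        raise SummaryDataError(f"unknown palindromic policy {palindromic_policy!r}")

    outcome_by_rsid = {rec.rsid: rec for rec in outcome}
    exposure_rsids = {rec.rsid for rec in exposure}
    if not exposure_rsids & set(outcome_by_rsid):
        raise SummaryDataError("no rsids shared between exposure and outcome tables")

    records: list[HarmonizedInstrument] = []
    for exp_raw in exposure:
        out = outcome_by_rsid.get(exp_raw.rsid)
        exp = _orient_to_exposure_increasing(exp_raw)
        base = dict(
            rsid=exp.rsid,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            eaf_exposure=exp.eaf,
            palindromic=exp.palindromic,
            pvalue_exposure=exp.pvalue,
        )
        if out is None:
            records.append(
                HarmonizedInstrument(
                    **base,
                    beta_outcome=np.nan,
                    se_outcome=np.nan,
                    eaf_outcome=None,
                    pvalue_outcome=None,
                    action=DROPPED_MISSING,
                )
            )
            continue
        action, beta_out, eaf_out = _align_outcome(
            exp, out, palindromic_maf_threshold, palindromic_policy
        )
        records.append(
            HarmonizedInstrument(
                **base,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf_outcome=eaf_out,
                pvalue_outcome=out.pvalue,
                action=action,
            )
        )

    kept = [rec for rec in records if not rec.dropped]
    return InstrumentSet(kept, records=records)


def _align_outcome(
    exp: SnpAssociation,
    out: SnpAssociation,
    maf_threshold: float,
    policy: str,
) -> tuple[str, float, float | None]:
    """Return (action, aligned outcome beta, aligned outcome eaf)."""
    ea, oa = exp.effect_allele, exp.other_allele

    if exp.palindromic:
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return DROPPED_IRRECONCILABLE, np.nan, None
        maf = exp.minor_allele_frequency()
        if policy == "infer_by_frequency":
            if exp.eaf is None or out.eaf is None or maf is None:
                return DROPPED_AMBIGUOUS, np.nan, None
            if maf > maf_threshold:
                return DROPPED_AMBIGUOUS, np.nan, None
            # the outcome's labels carry no strand information; pick the
            # orientation whose EAF agrees with the exposure EAF
            eaf_as_labelled = out.eaf if out.effect_allele == ea else 1.0 - out.eaf
            if abs(eaf_as_labelled - exp.eaf) <= abs((1.0 - eaf_as_labelled) - exp.eaf):
                beta = out.beta if out.effect_allele == ea else -out.beta
                return (
                    KEPT_AS_IS if out.effect_allele == ea else OUTCOME_FLIPPED,
                    beta,
                    eaf_as_labelled,
                )
            beta = -out.beta if out.effect_allele == ea else out.beta
            return STRAND_COMPLEMENTED_AND_FLIPPED, beta, 1.0 - eaf_as_labelled
        if policy == "drop_above_threshold" and (maf is None or maf > maf_threshold):
            return DROPPED_AMBIGUOUS, np.nan, None
        # retain_same_strand (and low-MAF drop_above_threshold): labels are
        # trusted as same-strand reads
        if out.effect_allele == ea:
            return KEPT_AS_IS, out.beta, out.eaf
        beta, eaf = _flip_outcome(out.beta, out.eaf)
        return OUTCOME_FLIPPED, beta, eaf

    if (out.effect_allele, out.other_allele) == (ea, oa):
        return KEPT_AS_IS, out.beta, out.eaf
    if (out.effect_allele, out.other_allele) == (oa, ea):
        beta, eaf = _flip_outcome(out.beta, out.eaf)
        return OUTCOME_FLIPPED, beta, eaf
    cea, coa = complement_allele(out.effect_allele), complement_allele(out.other_allele)
    if (cea, coa) == (ea, oa):
        return STRAND_COMPLEMENTED, out.beta, out.eaf
    if (cea, coa) == (oa, ea):
        beta, eaf = _flip_outcome(out.beta, out.eaf)
        return STRAND_COMPLEMENTED_AND_FLIPPED, beta, eaf
    return DROPPED_IRRECONCILABLE, np.nan, None


def mean_f_statistic(instruments: InstrumentSet) -> float:
    """Mean F-statistic of the instrument set.

    The per-SNP F-statistic is approximated by the squared exposure z-score
    (beta/se)^2; values above ~10 conventionally indicate instruments strong
    enough to keep weak-instrument bias negligible.
    """
    if len(instruments) == 0:
        raise SummaryDataError("cannot compute mean F on an empty instrument set")
    z = instruments.beta_exposure / instruments.se_exposure
    return float(np.mean(z**2))
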