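"""PSM filtering and decoy-based false-discovery-rate estimation.

Each tandem-MS spectrum assigned to a peptide sequence (a peptide spectral
match, PSM) carries a search-engine expectation value and a target/decoy
flag.  A sample's identifications are accepted only after (1) an e-value
cut, (2) a minimum-support rule requiring at least two PSMs per protein
accession, and (3) a check that the decoy-estimated false-discovery rate at
both the PSM and the protein level stays under configurable ceilings
(defaults: protein FDR < 5%, PSM FDR < 2%).

The FDR estimator is the classical target-decoy one:

    FDR% = 100 * n_decoy / (n_target - n_decoy)

which is undefined when targets do not outnumber decoys; such degenerate
samples fail validation with an explicit reason rather than raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "DECOY_PREFIX",
    "PeptideSpectralMatch",
    "FilterThresholds",
    "FdrReport",
    "ValidationResult",
    "filter_psms",
    "compute_fdr",
    "validate_sample",
    "read_psm_csv",
    "write_psm_csv",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accession prefix conventionally used by search engines for reversed
#: (decoy) database entries; honoured in addition to the explicit flag.
DECOY_PREFIX = "DECOY_"

PSM_COLUMNS = [
    "sample_id",
    "peptide",
    "protein_accession",
    "protein_family",
    "e_value",
    "is_decoy",
    "n_deamidation_mods",
]


@dataclass(frozen=True)
class PeptideSpectralMatch:
    """One spectrum-to-peptide assignment."""

    sample_id: str
    peptide: str
    protein_accession: str
    protein_family: str = "other"
    e_value: float = 1.0
    is_decoy: bool = False
    n_deamidation_mods: int = 0

    def __post_init__(self) -> None:
        if not self.peptide or not set(self.peptide) <= AMINO_ACIDS:
            raise ValueError(f"invalid peptide sequence: {self.peptide!r}")
        if self.e_value <= 0:
            raise ValueError(f"e_value must be > 0, got {self.e_value}")
        n_sites = sum(self.peptide.count(r) for r in "NQ")
        if not 0 <= self.n_deamidation_mods <= n_sites:
            raise ValueError(
                f"n_deamidation_mods={self.n_deamidation_mods} exceeds the "
                f"{n_sites} N/Q residues of {self.peptide!r}"
            )
        if self.protein_accession.startswith(DECOY_PREFIX) and not self.is_decoy:
            object.__setattr__(self, "is_decoy", True)


@dataclass(frozen=True)
class FilterThresholds:
    """Acceptance thresholds; all comparisons are strict ('under' / 'below')."""

    e_value_max: float = 0.01
    min_psms_per_protein: int = 2
    protein_fdr_max_percent: float = 5.0
    psm_fdr_max_percent: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.e_value_max < 1:
            raise ValueError("e_value_max must be in (0, 1)")
        if self.min_psms_per_protein < 1:
            raise ValueError("min_psms_per_protein must be >= 1")
        if self.protein_fdr_max_percent <= 0 or self.psm_fdr_max_percent <= 0:
            raise ValueError("FDR ceilings must be positive")


@dataclass(frozen=True)
class FdrReport:
    """Target/decoy tally and the resulting FDR percentage at one level.

    ``fdr_percent`` is None when the estimator is degenerate
    (n_target - n_decoy <= 0).
    """

    level: Literal["psm", "protein"]
    n_target: int
    n_decoy: int
    fdr_percent: float | None

    @property
    def degenerate(self) -> bool:
        return self.fdr_percent is None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class ValidationResult:
    sample_id: str
    psms: list[PeptideSpectralMatch]
    psm_fdr: FdrReport
    protein_fdr: FdrReport
    passes: bool
    reason: str | None = None


def filter_psms(
    psms: Sequence[PeptideSpectralMatch],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[PeptideSpectralMatch]:
    """Apply the e-value cut, then the minimum protein-support rule.

    The e-value cut (strictly below ``e_value_max``) runs first; protein
    support is then counted on the surviving PSMs, grouped by accession with
    targets and decoys in separate groups, and groups with fewer than
    ``min_psms_per_protein`` PSMs are dropped.  Input order is preserved.
    Idempotent by construction.
    """
    if not psms:
        return []
    sample_ids = {p.sample_id for p in psms}
    if len(sample_ids) > 1:
        raise ValueError(f"mixed sample_ids in one table: {sorted(sample_ids)}")

    passing = [p for p in psms if p.e_value < thresholds.e_value_max]
    support: dict[tuple[str, bool], int] = {}
    for p in passing:
        key = (p.protein_accession, p.is_decoy)
        support[key] = support.get(key, 0) + 1
    return [
        p
        for p in passing
        if support[(p.protein_accession, p.is_decoy)] >= thresholds.min_psms_per_protein
    ]


def compute_fdr(
    psms: Iterable[PeptideSpectralMatch], level: Literal["psm", "protein"]
) -> FdrReport:
    """Decoy-based FDR on already-filtered PSMs.

    At the PSM level targets/decoys are counted per match; at the protein
    level per distinct accession.  FDR% = 100 * decoys / (targets - decoys),
    reported as None when the denominator is not positive.
    """
    psms = list(psms)
    if level == "psm":
        n_target = sum(not p.is_decoy for p in psms)
        n_decoy = sum(p.is_decoy for p in psms)
    elif level == "protein":
        n_target = len({p.protein_accession for p in psms if not p.is_decoy})
        n_decoy = len({p.protein_accession for p in psms if p.is_decoy})
    else:
        raise ValueError(f"unknown FDR level: {level!r}")

    denom = n_target - n_decoy
    fdr = 100.0 * n_decoy / denom if denom > 0 else None
    return FdrReport(level=level, n_target=n_target, n_decoy=n_decoy, fdr_percent=fdr)


def validate_sample(
    psms: Sequence[PeptideSpectralMatch],
    thresholds: FilterThresholds = FilterThresholds(),
) -> ValidationResult:
    """Filter one sample's PSMs and judge it against both FDR ceilings.

    A sample passes iff both FDR estimates are defined and strictly under
    their ceilings.  Failing samples keep their filtered PSMs and carry a
    machine-readable reason; they are flagged, never silently dropped.
    """
    filtered = filter_psms(psms, thresholds)
    sample_id = psms[0].sample_id if psms else ""
    psm_fdr = compute_fdr(filtered, "psm")
    protein_fdr = compute_fdr(filtered, "protein")

    reason = None
    if psm_fdr.degenerate or protein_fdr.degenerate:
        passes = False
        reason = "degenerate_fdr"
    else:
        passes = (
            protein_fdr.fdr_percent < thresholds.protein_fdr_max_percent
            and psm_fdr.fdr_percent < thresholds.psm_fdr_max_percent
        )
        if not passes:
            reason = "fdr_above_threshold"
    return ValidationResult(
        sample_id=sample_id,
        psms=filtered,
        psm_fdr=psm_fdr,
        protein_fdr=protein_fdr,
        passes=passes,
        reason=reason,
    )


def read_psm_csv(path) -> dict[str, list[PeptideSpectralMatch]]:
    """Read a PSM table (one or more samples) from CSV, keyed by sample."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "protein_accession": str},
        float_precision="round_trip",
    )
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    out: dict[str, list[PeptideSpectralMatch]] = {}
    for row in df.itertuples(index=False):
        psm = PeptideSpectralMatch(
            sample_id=row.sample_id,
            peptide=row.peptide,
            protein_accession=row.protein_accession,
            protein_family=row.protein_family,
            e_value=float(row.e_value),
            is_decoy=bool(int(row.is_decoy)),
            n_deamidation_mods=int(row.n_deamidation_mods),
        )
        out.setdefault(psm.sample_id, []).append(psm)
    return out


def write_psm_csv(psms: Iterable[PeptideSpectralMatch], path) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "peptide": p.peptide,
            "protein_accession": p.protein_accession,
            "protein_family": p.protein_family,
            "e_value": p.e_value,
            "is_decoy": int(p.is_decoy),
            "n_deamidation_mods": p.n_deamidation_mods,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, index=False, float_format="%.17g")
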