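"""Synthetic cohorts with known ground truth for every pipeline stage.

Real steppe-calculus datasets live in proteomics repositories and
supplementary tables; this module generates structurally faithful
stand-ins so the whole pipeline runs self-contained and every stage can be
checked against a recorded truth table:

* per-sample PSM tables with target/decoy e-value populations and injected
  milk peptides for ground-truth dairy consumers,
* a milk-protein reference FASTA whose sequences are built from peptide
  blocks shared at chosen clade levels, so each peptide's correct LCA is
  known by construction (plus a bacterial contaminant record mimicking the
  casein-like entries that must be excluded),
* an oral-signature category table and per-sample proteome compositions
  with preset authenticity outcomes,
* bone-collagen δ15N values drawn from the diet-mixing forward model at a
  known freshwater fraction, and
* radiocarbon dates forward-modelled from known calendar ages and known
  reservoir offsets through a synthetic calibration curve.

Every generator is a pure function of (spec, seed): the same seed yields
byte-identical tables.  The default cohort mirrors a three-period steppe
study design (19/17/19 individuals; Eneolithic dairy absent save one
equivocal casein-only individual; Bronze Age dairy nearly ubiquitous,
including two horse-milk consumers in the Early Bronze Age).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import dairy_assignment as da
from . import diet_mixing as dm
from .preservation_screen import DEFAULT_THRESHOLDS, OssdEntry
from .psm_validation import PeptideSpectralMatch, write_psm_csv
from .reservoir_calibration import CalibrationCurve, RadiocarbonDate, write_curve
from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_milk_reference",
    "simulate_psm_table",
    "simulate_isotopes_and_dates",
    "synthetic_curve",
    "write_cohort",
]

PERIOD_ORDER = ("eneolithic", "early_bronze", "middle_late_bronze")

_SITES = {
    "eneolithic": ("Murzikha 2", "Khvalynsk 1", "Khvalynsk 2", "Ekaterinovka Mys"),
    "early_bronze": ("Krivyanskiy 9", "Kutuluk 1", "Mustayevo 5", "Lopatino 1"),
    "middle_late_bronze": ("Kamennyi Ambar 5", "Utevka 6", "Kalinovsky 1", "Potapovka 1"),
}

# residues allowed inside a tryptic block (no internal cleavage sites, no
# proline to keep the cleavage rule trivial)
_BLOCK_ALPHABET = sorted(set("ACDEFGHILMNQSTVWY"))
_PEPTIDE_ALPHABET = sorted(set("ACDEFGHILMNQSTVWY"))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults follow the three-period steppe design: 19 Eneolithic, 17 Early
    Bronze Age and 19 Middle–Late Bronze Age individuals, of whom 11/16/19
    pass preservation screening; dairy prevalence among preserved
    individuals is 0 (plus one equivocal casein-only individual), 15/16 and
    15/19 respectively.
    """

    seed: int
    individuals_per_period: Mapping[str, int] = field(
        default_factory=lambda: {"eneolithic": 19, "early_bronze": 17, "middle_late_bronze": 19}
    )
    preserved_per_period: Mapping[str, int] = field(
        default_factory=lambda: {"eneolithic": 11, "early_bronze": 16, "middle_late_bronze": 19}
    )
    dairy_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "eneolithic": 0.0,
            "early_bronze": 15.0 / 16.0,
            "middle_late_bronze": 15.0 / 19.0,
        }
    )
    equivocal_per_period: Mapping[str, int] = field(
        default_factory=lambda: {"eneolithic": 1, "early_bronze": 0, "middle_late_bronze": 0}
    )
    equus_positives_early_bronze: int = 2
    taxa_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Bos": 0.4, "Ovis": 0.3, "Capra": 0.3}
    )
    decoy_fraction: float = 0.08
    target_evalue_range: tuple[float, float] = (1e-8, 1e-3)
    decoy_evalue_range: tuple[float, float] = (1e-3, 1.0)
    protein_families_range: tuple[int, int] = (25, 196)
    psms_per_protein: tuple[int, int] = (2, 4)
    n_ossd_per_sample: int = 40
    date_sd: float = 20.0
    measurement_sd: float = 0.2
    noiseless: bool = False
    """With noiseless=True decoy e-values all sit above the e-value cut, so
    no decoy survives filtering and every sample's FDR is exactly 0; dairy
    ground truth is then recovered exactly by the pipeline."""

    def __post_init__(self) -> None:
        for period, frac in self.dairy_prevalence.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"prevalence for {period} outside [0,1]")
        for period, n in self.preserved_per_period.items():
            if n > self.individuals_per_period[period]:
                raise ValueError(f"preserved > sampled for {period}")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    taxonomy: Taxonomy
    milk_records: list[da.MilkProteinRecord]
    exclusion_list: set[str]
    block_peptides: dict[tuple[str, str], str]  # (clade-or-taxon, family) -> peptide
    ossd: list[OssdEntry]
    psms: list[PeptideSpectralMatch]
    truth: pd.DataFrame  # one row per individual, truth_ columns
    consumers: list[dm.ConsumerMeasurement]
    dates: list[RadiocarbonDate]
    isotope_truth: pd.DataFrame
    curve: CalibrationCurve


# --------------------------------------------------------------------------
# milk reference

_REFERENCE_DESIGN = {
    # family: (taxa, shared clade levels)
    "BLG": (("Bos", "Bubalus", "Bison", "Ovis", "Capra", "Cervus"), ("Pecora", "subfamily")),
    "alpha-S1-casein": (("Bos", "Bubalus", "Bison", "Ovis", "Capra"), ("Bovinae",)),
    "alpha-S2-casein": (("Bos", "Ovis", "Capra"), ()),
    "alpha-lactalbumin": (("Bos", "Ovis"), ()),
    "BLG-I": (("Equus",), ()),
    "BLG-II": (("Equus",), ()),
}

_SUBFAMILY_OF = {
    "Bos": "Bovinae",
    "Bubalus": "Bovinae",
    "Bison": "Bovinae",
    "Ovis": "Caprinae",
    "Capra": "Caprinae",
}

CONTAMINANT_ACCESSION = "SYN_CONTAM_JEOTGALICOCCUS"


def _draw_block(rng: np.random.Generator, used: set[str], length: int = 9, n_sites=None) -> str:
    """A unique tryptic block: no internal K/R/P, terminal K or R."""
    for _ in range(1000):
        if n_sites is None:
            body = "".join(rng.choice(_BLOCK_ALPHABET, size=length - 1))
        else:
            non_nq = [a for a in _BLOCK_ALPHABET if a not in "NQ"]
            body_list = list(rng.choice(non_nq, size=length - 1))
            positions = rng.choice(length - 1, size=n_sites, replace=False)
            for pos in np.atleast_1d(positions):
                body_list[int(pos)] = str(rng.choice(["N", "Q"]))
            body = "".join(body_list)
        block = body + str(rng.choice(["K", "R"]))
        if block not in used:
            used.add(block)
            return block
    raise RuntimeError("could not draw a unique block")


def simulate_milk_reference(
    tree: Taxonomy, rng: np.random.Generator, block_length: int = 9
) -> tuple[list[da.MilkProteinRecord], set[str], dict[tuple[str, str], str]]:
    """Milk-protein records built from clade-shared and taxon-unique blocks.

    Returns (records, exclusion list, block map).  The block map keys are
    (clade-or-taxon, family); by construction a shared block's peptides have
    the clade as their LCA and a unique block's peptide has the leaf taxon.
    A casein-mimicking bacterial contaminant record carries the shared
    Bovinae casein block and must be excluded via the exclusion list.
    """
    used: set[str] = set()
    blocks: dict[tuple[str, str], str] = {}
    records: list[da.MilkProteinRecord] = []

    for family, (taxa, shared_levels) in _REFERENCE_DESIGN.items():
        if "Pecora" in shared_levels:
            blocks[("Pecora", family)] = _draw_block(rng, used, block_length)
        if "subfamily" in shared_levels:
            for subfam in sorted({_SUBFAMILY_OF[t] for t in taxa if t in _SUBFAMILY_OF}):
                blocks[(subfam, family)] = _draw_block(rng, used, block_length)
        if "Bovinae" in shared_levels:
            # the classic three-taxon casein block carries exactly one
            # possible deamidation site
            blocks[("Bovinae", family)] = _draw_block(rng, used, block_length, n_sites=1)
        for taxon in taxa:
            blocks[(taxon, family)] = _draw_block(rng, used, block_length)

    for family, (taxa, shared_levels) in _REFERENCE_DESIGN.items():
        for taxon in taxa:
            parts = []
            if ("Pecora", family) in blocks:
                parts.append(blocks[("Pecora", family)])
            subfam = _SUBFAMILY_OF.get(taxon)
            if subfam and (subfam, family) in blocks:
                if "subfamily" in shared_levels or (
                    "Bovinae" in shared_levels and subfam == "Bovinae"
                ):
                    parts.append(blocks[(subfam, family)])
            parts.append(blocks[(taxon, family)])
            records.append(
                da.MilkProteinRecord(
                    accession=f"SYN_{family}_{taxon}".upper().replace("-", ""),
                    protein_family=family,
                    taxon=taxon,
                    sequence="".join(parts),
                )
            )

    # bacterial entry nearly identical to ruminant casein: shares the
    # Bovinae block; listed for exclusion, and its taxon is deliberately
    # outside the tree so forgetting the exclusion fails loudly.
    records.append(
        da.MilkProteinRecord(
            accession=CONTAMINANT_ACCESSION,
            protein_family="other-milk",
            taxon="Jeotgalicoccus",
            sequence=blocks[("Bovinae", "alpha-S1-casein")] + _draw_block(rng, used, block_length),
        )
    )
    return records, {CONTAMINANT_ACCESSION}, blocks


# --------------------------------------------------------------------------
# proteome composition / PSM tables


def _build_ossd(rng: np.random.Generator) -> list[OssdEntry]:
    pools = {
        "oral_bacteria": [f"ORAL_{i:03d}" for i in range(120)],
        "human_immune_oral": [f"IMM_{i:03d}" for i in range(40)],
        "handling_contaminant": [f"HAND_{i:03d}" for i in range(30)],
        "lab_contaminant": [f"LAB_{i:03d}" for i in range(30)],
    }
    return [OssdEntry(acc, cat) for cat, accs in pools.items() for acc in accs]


def _loguniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def _random_peptide(rng: np.random.Generator, forbidden: set[str], length: int = 10) -> str:
    while True:
        pep = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length))
        if pep not in forbidden:
            return pep


def simulate_psm_table(
    spec: CohortSpec,
    cohort_plan: pd.DataFrame,
    blocks: dict[tuple[str, str], str],
    milk_peptides: set[str],
    ossd: list[OssdEntry],
    rng: np.random.Generator,
) -> list[PeptideSpectralMatch]:
    """Per-individual PSM rows realizing the planned ground truth.

    Background target proteins (some OSSD-listed, composition fixed by the
    planned authenticity), decoy proteins with diffuse e-values, and — for
    planned dairy consumers — milk peptides drawn from the reference blocks
    with at least two PSMs per milk protein so they survive the support
    rule.
    """
    by_cat: dict[str, list[str]] = {}
    for entry in ossd:
        by_cat.setdefault(entry.category, []).append(entry.match_key)

    target_low, target_high = spec.target_evalue_range
    decoy_low, decoy_high = spec.decoy_evalue_range
    if spec.noiseless:
        decoy_low = max(decoy_low, 0.05)  # everything above the e-value cut

    psms: list[PeptideSpectralMatch] = []
    for row in cohort_plan.itertuples(index=False):
        sid = row.individual_id
        # --- background proteome with preset authenticity ---------------
        n_ossd = spec.n_ossd_per_sample
        n_auth = int(round(row.truth_authenticity_target / 100.0 * n_ossd))
        n_oral = int(round(0.8 * n_auth))
        n_imm = n_auth - n_oral
        n_contam = n_ossd - n_auth
        n_hand = n_contam // 2
        n_lab = n_contam - n_hand
        accessions = (
            list(rng.choice(by_cat["oral_bacteria"], size=n_oral, replace=False))
            + list(rng.choice(by_cat["human_immune_oral"], size=n_imm, replace=False))
            + list(rng.choice(by_cat["handling_contaminant"], size=n_hand, replace=False))
            + list(rng.choice(by_cat["lab_contaminant"], size=n_lab, replace=False))
        )
        n_bg = int(rng.integers(spec.protein_families_range[0], spec.protein_families_range[1] + 1))
        n_misc = max(0, n_bg - n_ossd)
        accessions += [f"{sid}_MISC_{i:03d}" for i in range(n_misc)]

        for accession in accessions:
            n = int(rng.integers(spec.psms_per_protein[0], spec.psms_per_protein[1] + 1))
            evals = _loguniform(rng, target_low, target_high, n)
            for e in evals:
                pep = _random_peptide(rng, milk_peptides)
                psms.append(
                    PeptideSpectralMatch(
                        sample_id=sid,
                        peptide=pep,
                        protein_accession=accession,
                        protein_family="other",
                        e_value=float(e),
                        n_deamidation_mods=int(
                            rng.integers(0, pep.count("N") + pep.count("Q") + 1)
                        ),
                    )
                )

        # --- decoys ------------------------------------------------------
        n_decoy_prot = int(round(spec.decoy_fraction * n_bg))
        for i in range(n_decoy_prot):
            n = int(rng.integers(spec.psms_per_protein[0], spec.psms_per_protein[1] + 1))
            evals = _loguniform(rng, decoy_low, decoy_high, n)
            for e in evals:
                psms.append(
                    PeptideSpectralMatch(
                        sample_id=sid,
                        peptide=_random_peptide(rng, milk_peptides),
                        protein_accession=f"DECOY_{sid}_{i:03d}",
                        protein_family="other",
                        e_value=float(e),
                        is_decoy=True,
                    )
                )

        # --- dairy injection ---------------------------------------------
        plan_peptides: list[tuple[str, str, str]] = []  # (peptide, family, accession)
        if row.truth_dairy_call == "equivocal":
            pep = blocks[("Bovinae", "alpha-S1-casein")]
            plan_peptides.append((pep, "alpha-S1-casein", "SYN_ALPHAS1CASEIN_BOS"))
        elif row.truth_dairy_call == "positive":
            taxa = row.truth_taxa.split("+")
            for taxon in taxa:
                if taxon == "Equus":
                    pep = blocks[("Equus", "BLG-I")]
                    plan_peptides.append((pep, "BLG-I", "SYN_BLGI_EQUUS"))
                    continue
                # one genus-specific and one clade-shared BLG peptide
                plan_peptides.append(
                    (blocks[(taxon, "BLG")], "BLG", f"SYN_BLG_{taxon}".upper())
                )
                plan_peptides.append(
                    (blocks[("Pecora", "BLG")], "BLG", f"SYN_BLG_{taxon}".upper())
                )
                if rng.random() < 0.5 and (taxon, "alpha-S2-casein") in blocks:
                    plan_peptides.append(
                        (
                            blocks[(taxon, "alpha-S2-casein")],
                            "alpha-S2-casein",
                            f"SYN_ALPHAS2CASEIN_{taxon}".upper(),
                        )
                    )
        for pep, family, accession in plan_peptides:
            n = max(2, int(rng.integers(2, 4)))
            evals = _loguniform(rng, target_low, min(target_high, 1e-4), n)
            sites = pep.count("N") + pep.count("Q")
            for e in evals:
                psms.append(
                    PeptideSpectralMatch(
                        sample_id=sid,
                        peptide=pep,
                        protein_accession=accession,
                        protein_family=family,
                        e_value=float(e),
                        n_deamidation_mods=int(rng.integers(0, sites + 1)),
                    )
                )
    return psms


# --------------------------------------------------------------------------
# isotopes, dates, curve


def synthetic_curve(
    cal_min: float = 0.0,
    cal_max: float = 12000.0,
    step: float = 5.0,
    amplitude: float = 20.0,
    period: float = 500.0,
    sd: float = 10.0,
) -> CalibrationCurve:
    """A smooth synthetic calibration curve: 14C age = cal BP + a
    low-amplitude sinusoid, giving realistic local multimodality without
    external data."""
    cal = np.arange(cal_min, cal_max + step / 2, step)
    c14 = cal + amplitude * np.sin(2.0 * np.pi * cal / period)
    return CalibrationCurve(cal, c14, np.full_like(cal, sd))


def simulate_isotopes_and_dates(
    spec: CohortSpec,
    individual_ids: list[str],
    model: dm.MixingModel,
    curve: CalibrationCurve,
    rng: np.random.Generator,
    cal_age_range: tuple[float, float] = (5950.0, 6550.0),
    f_true: Mapping[str, float] | None = None,
    delta_r_true: Mapping[str, float] | None = None,
) -> tuple[list[dm.ConsumerMeasurement], list[RadiocarbonDate], pd.DataFrame]:
    """Forward-simulate δ15N and 14C measurements at known f and ΔR.

    δ15N follows the diet-mixing generative model at the individual's true
    freshwater fraction; the 14C age is the curve value at the true
    calendar age plus the reservoir offset scaled by the true fraction,
    with measurement noise at the stated sd.
    """
    lo, hi = cal_age_range
    if lo < curve.cal_bp.min() or hi > curve.cal_bp.max():
        raise ValueError("true calendar ages outside the calibration curve span")

    t, w = model.terrestrial, model.freshwater
    consumers, dates, rows = [], [], []
    for i, sid in enumerate(individual_ids):
        f_i = float(rng.uniform(0.0, 1.0)) if f_true is None else float(f_true[sid])
        s_t = rng.normal(t.delta15N_mean, t.delta15N_sd) + rng.normal(
            *t.collagen_to_edible_offset
        )
        s_w = rng.normal(w.delta15N_mean, w.delta15N_sd) + rng.normal(
            *w.collagen_to_edible_offset
        )
        y = (
            f_i * s_w
            + (1.0 - f_i) * s_t
            + rng.normal(*model.diet_to_consumer_offset)
            + rng.normal(0.0, spec.measurement_sd)
        )
        cal_true = float(rng.uniform(lo, hi))
        dr_true = (
            float(rng.uniform(0.0, 1000.0))
            if delta_r_true is None
            else float(delta_r_true[sid])
        )
        c14_mu = float(np.interp(cal_true, curve.cal_bp, curve.c14_age))
        c14 = c14_mu + f_i * dr_true + rng.normal(0.0, spec.date_sd)
        lab_code = f"SYN-{i + 1:04d}"
        consumers.append(dm.ConsumerMeasurement(sid, float(y), spec.measurement_sd))
        dates.append(RadiocarbonDate(lab_code, float(c14), spec.date_sd))
        rows.append(
            {
                "individual_id": sid,
                "lab_code": lab_code,
                "truth_f_freshwater": f_i,
                "truth_cal_bp": cal_true,
                "truth_delta_r": dr_true,
                "delta15N": float(y),
                "c14_age": float(c14),
            }
        )
    columns = [
        "individual_id",
        "lab_code",
        "truth_f_freshwater",
        "truth_cal_bp",
        "truth_delta_r",
        "delta15N",
        "c14_age",
    ]
    return consumers, dates, pd.DataFrame(rows, columns=columns)


# --------------------------------------------------------------------------
# cohort assembly


def _plan_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """One row per individual with all ground-truth labels.

    Preservation, dairy status and taxa are assigned deterministically:
    counts are exact (prevalence × n preserved, rounded half-up), with the
    seeded RNG deciding only which individuals carry which label.
    """
    prefixes = {"eneolithic": "ENE", "early_bronze": "EBA", "middle_late_bronze": "MLB"}
    thresholds = DEFAULT_THRESHOLDS
    rows = []
    for period in PERIOD_ORDER:
        n = spec.individuals_per_period[period]
        n_preserved = spec.preserved_per_period[period]
        ids = [f"{prefixes[period]}{i + 1:03d}" for i in range(n)]
        sites = [_SITES[period][i % len(_SITES[period])] for i in range(n)]
        order = rng.permutation(n)
        preserved_ids = {ids[i] for i in order[:n_preserved]}
        preserved_list = [i for i in order[:n_preserved]]
        n_pos = dm.round_half_up(spec.dairy_prevalence[period] * n_preserved)
        n_eq = spec.equivocal_per_period.get(period, 0)
        positive_ids = {ids[i] for i in preserved_list[:n_pos]}
        equivocal_ids = {ids[i] for i in preserved_list[n_pos : n_pos + n_eq]}

        # which positives carry which taxa
        taxa_names = sorted(spec.taxa_weights)
        weights = np.array([spec.taxa_weights[t] for t in taxa_names], dtype=float)
        weights /= weights.sum()
        equus_left = spec.equus_positives_early_bronze if period == "early_bronze" else 0

        threshold = thresholds[period]
        for i, (sid, site) in enumerate(zip(ids, sites)):
            preserved = sid in preserved_ids
            if preserved:
                auth_target = float(rng.uniform(threshold + 10.0, 95.0))
            else:
                auth_target = float(rng.uniform(5.0, max(6.0, threshold - 10.0)))
            if sid in positive_ids:
                call = "positive"
                n_taxa = int(rng.integers(1, 3))
                chosen = list(rng.choice(taxa_names, size=n_taxa, replace=False, p=weights))
                if equus_left > 0:
                    chosen.append("Equus")
                    equus_left -= 1
                taxa = "+".join(sorted(set(chosen)))
            elif sid in equivocal_ids:
                call, taxa = "equivocal", "Bovinae"
            else:
                call, taxa = "negative", ""
            rows.append(
                {
                    "individual_id": sid,
                    "site": site,
                    "period": period,
                    "truth_preserved": preserved,
                    "truth_authenticity_target": auth_target,
                    "truth_dairy_call": call if preserved else "negative",
                    "truth_taxa": taxa if preserved else "",
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate every pipeline input for one cohort; pure in (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    tree = default_taxonomy()
    milk_records, exclusion, blocks = simulate_milk_reference(tree, rng)
    milk_peptides = {
        pep
        for rec in milk_records
        for pep in da.tryptic_digest(rec.sequence, missed_cleavages=2, min_length=6)
    }
    ossd = _build_ossd(rng)
    plan = _plan_cohort(spec, rng)
    psms = simulate_psm_table(spec, plan, blocks, milk_peptides, ossd, rng)

    curve = synthetic_curve()
    eneolithic_preserved = list(
        plan[(plan.period == "eneolithic") & plan.truth_preserved].individual_id
    )
    consumers, dates, isotope_truth = simulate_isotopes_and_dates(
        spec, eneolithic_preserved, dm.default_model(), curve, rng
    )
    return SyntheticCohort(
        spec=spec,
        taxonomy=tree,
        milk_records=milk_records,
        exclusion_list=exclusion,
        block_peptides=blocks,
        ossd=ossd,
        psms=psms,
        truth=plan,
        consumers=consumers,
        dates=dates,
        isotope_truth=isotope_truth,
        curve=curve,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write every input table in the dialect its consuming stage reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": out / "psms.csv",
        "truth": out / "truth.csv",
        "milk_reference": out / "milk_reference.fasta",
        "exclusion": out / "exclusion_list.txt",
        "taxonomy": out / "taxonomy.tsv",
        "ossd": out / "ossd.csv",
        "consumers": out / "consumers.csv",
        "dates": out / "dates.csv",
        "curve": out / "synthetic_curve.14c",
        "isotope_truth": out / "isotope_truth.csv",
    }
    write_psm_csv(cohort.psms, paths["psms"])
    cohort.truth.to_csv(paths["truth"], index=False)
    da.write_milk_fasta(cohort.milk_records, paths["milk_reference"])
    paths["exclusion"].write_text("\n".join(sorted(cohort.exclusion_list)) + "\n")
    cohort.taxonomy.to_tsv(paths["taxonomy"])
    pd.DataFrame(
        [{"match_key": e.match_key, "category": e.category} for e in cohort.ossd]
    ).to_csv(paths["ossd"], index=False)
    pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "delta15N": c.delta15N,
                "measurement_sd": c.measurement_sd,
            }
            for c in cohort.consumers
        ]
    ).to_csv(paths["consumers"], index=False)
    pd.DataFrame(
        [
            {"lab_code": d.lab_code, "c14_age": d.c14_age, "sd": d.sd}
            for d in cohort.dates
        ]
    ).to_csv(paths["dates"], index=False)
    write_curve(cohort.curve, paths["curve"], comment="synthetic calibration curve")
    cohort.isotope_truth.to_csv(paths["isotope_truth"], index=False)
    return paths
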