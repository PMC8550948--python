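"""Ground-truth generators: determinism and recoverability guarantees."""

import numpy as np
import pandas as pd
import pytest

from paleodairy import diet_mixing as dm
from paleodairy import synthetic_data as sd
from paleodairy.dairy_assignment import build_peptide_index
from paleodairy.psm_validation import FilterThresholds, compute_fdr, filter_psms


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path, small_cohort):
        a = sd.simulate_cohort(small_cohort.spec)
        b = sd.simulate_cohort(small_cohort.spec)
        pa = sd.write_cohort(a, tmp_path / "a")
        pb = sd.write_cohort(b, tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes(), name

    def test_different_seed_differs(self, small_cohort):
        import dataclasses

        other = sd.simulate_cohort(dataclasses.replace(small_cohort.spec, seed=8))
        assert other.psms != small_cohort.psms


class TestPsmTable:
    def test_zero_decoy_fraction_gives_zero_fdr(self, tree):
        import dataclasses

        spec = dataclasses.replace(
            sd.CohortSpec(
                seed=3,
                individuals_per_period={"eneolithic": 2, "early_bronze": 2, "middle_late_bronze": 2},
                preserved_per_period={"eneolithic": 2, "early_bronze": 2, "middle_late_bronze": 2},
                protein_families_range=(25, 40),
            ),
            decoy_fraction=0.0,
        )
        cohort = sd.simulate_cohort(spec)
        by_sample = {}
        for p in cohort.psms:
            by_sample.setdefault(p.sample_id, []).append(p)
        for psms in by_sample.values():
            report = compute_fdr(filter_psms(psms, FilterThresholds()), "psm")
            assert report.fdr_percent == 0.0

    def test_filtered_family_count_within_generation_bounds(self, small_cohort):
        lo, hi = small_cohort.spec.protein_families_range
        by_sample = {}
        for p in small_cohort.psms:
            by_sample.setdefault(p.sample_id, []).append(p)
        for psms in by_sample.values():
            filtered = filter_psms(psms, FilterThresholds())
            background = {
                p.protein_accession
                for p in filtered
                if not p.is_decoy and p.protein_family == "other"
            }
            assert lo <= len(background) <= hi

    def test_preserved_counts_exact(self, small_cohort):
        truth = small_cohort.truth
        for period, expected in small_cohort.spec.preserved_per_period.items():
            assert truth[truth.period == period].truth_preserved.sum() == expected


class TestMilkReference:
    def test_blocks_have_known_lca_by_construction(self, small_cohort):
        tree = small_cohort.taxonomy
        index = build_peptide_index(
            small_cohort.milk_records, tree, exclusion=small_cohort.exclusion_list
        )
        blocks = small_cohort.block_peptides
        taxa_of = lambda pep: {t for t, _ in index[pep]}
        assert tree.lca(taxa_of(blocks[("Bovinae", "alpha-S1-casein")])) == "Bovinae"
        assert tree.lca(taxa_of(blocks[("Pecora", "BLG")])) == "Pecora"
        assert taxa_of(blocks[("Equus", "BLG-I")]) == {"Equus"}

    def test_blocks_do_not_collide(self, small_cohort):
        blocks = list(small_cohort.block_peptides.values())
        assert len(blocks) == len(set(blocks))

    def test_shared_casein_block_has_one_deamidation_site(self, small_cohort):
        pep = small_cohort.block_peptides[("Bovinae", "alpha-S1-casein")]
        assert pep.count("N") + pep.count("Q") == 1


class TestIsotopesAndDates:
    def test_terrestrial_end_member_limit(self, rng):
        spec = sd.CohortSpec(seed=1)
        model = dm.default_model()
        curve = sd.synthetic_curve()
        ids = [f"I{i}" for i in range(60)]
        consumers, _, truth = sd.simulate_isotopes_and_dates(
            spec, ids, model, curve, rng, f_true={i: 0.0 for i in ids}
        )
        values = np.array([c.delta15N for c in consumers])
        # pure terrestrial consumers cluster at the terrestrial prediction
        mu, var = model.predictive_moments(0.0, spec.measurement_sd)
        assert abs(values.mean() - mu) < 3 * np.sqrt(var / len(ids))

    def test_full_reservoir_shift(self, rng):
        spec = sd.CohortSpec(seed=1)
        model = dm.default_model()
        curve = sd.synthetic_curve()
        ids = [f"I{i}" for i in range(40)]
        _, dates_shifted, truth = sd.simulate_isotopes_and_dates(
            spec, ids, model, curve, rng,
            f_true={i: 1.0 for i in ids}, delta_r_true={i: 1000.0 for i in ids},
        )
        apparent_offset = np.array(
            [
                d.c14_age - np.interp(t, curve.cal_bp, curve.c14_age)
                for d, t in zip(dates_shifted, truth.truth_cal_bp)
            ]
        )
        assert apparent_offset.mean() == pytest.approx(1000.0, abs=15)

    def test_truth_table_reproducible(self, rng):
        spec = sd.CohortSpec(seed=1)
        model = dm.default_model()
        curve = sd.synthetic_curve()
        ids = ["A", "B", "C"]
        _, _, t1 = sd.simulate_isotopes_and_dates(
            spec, ids, model, curve, np.random.default_rng(5)
        )
        _, _, t2 = sd.simulate_isotopes_and_dates(
            spec, ids, model, curve, np.random.default_rng(5)
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_age_outside_curve_rejected(self, rng):
        spec = sd.CohortSpec(seed=1)
        curve = sd.synthetic_curve(0, 1000)
        with pytest.raises(ValueError, match="outside the calibration curve"):
            sd.simulate_isotopes_and_dates(
                spec, ["A"], dm.default_model(), curve, rng, cal_age_range=(5950, 6550)
            )


def test_prevalence_config_error():
    with pytest.raises(ValueError, match="prevalence"):
        sd.CohortSpec(seed=0, dairy_prevalence={"eneolithic": 1.5, "early_bronze": 0, "middle_late_bronze": 0})
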