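import numpy as np
import pytest

from crss.cohort_io import (
    CANONICAL_DIRECTIONS,
    Cohort,
    CohortValidationError,
    CutoffRule,
    PatientRecord,
    SchemaError,
    assign_iss,
    assign_riss,
    dichotomize,
    egfr_mdrd,
    impute_median,
    load_cutoffs,
    normalize_ldh,
    read_cohort,
    write_cohort,
)

HEADER = ("patient_id,age,albumin,b2m,calcium,hemoglobin,egfr,creatinine,"
          "ldh,ldh_uln,hrca,female,pfs_time,pfs_event,os_time,os_event")


def _write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def _row(pid="P1", **kw):
    base = dict(age=60, albumin=3.6, b2m=4.0, calcium=9.5, hemoglobin=11.0,
                egfr=70, creatinine="", ldh=200, ldh_uln=250, hrca=1, female=0,
                pfs_time=100, pfs_event=1, os_time=150, os_event=0)
    base.update(kw)
    return ",".join([pid] + [str(base[k]) for k in
                             ("age", "albumin", "b2m", "calcium", "hemoglobin",
                              "egfr", "creatinine", "ldh", "ldh_uln", "hrca",
                              "female", "pfs_time", "pfs_event", "os_time",
                              "os_event")])


class TestReadCohort:
    def test_round_trip(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1"), _row("P2"), _row("P3")])
        cohort = read_cohort(path)
        assert len(cohort) == 3
        assert cohort.records[0].patient_id == "P1"
        assert cohort.records[0].age == 60
        assert cohort.records[0].hrca is True
        out = tmp_path / "round.csv"
        write_cohort(cohort, out)
        again = read_cohort(out)
        assert [r.patient_id for r in again] == ["P1", "P2", "P3"]
        assert again.records[1].b2m == cohort.records[1].b2m

    def test_missing_mandatory_column_named(self, tmp_path):
        header = HEADER.replace(",os_event", "")
        rows = [_row("P1").rsplit(",", 1)[0]]
        path = _write_csv(tmp_path, rows, header=header)
        with pytest.raises(SchemaError, match="os_event"):
            read_cohort(path)

    def test_negative_time_cites_row(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1"), _row("P2", pfs_time=-1)])
        with pytest.raises(CohortValidationError, match="row 2"):
            read_cohort(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_cohort(path)

    def test_egfr_derived_from_creatinine(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1", egfr="", creatinine=1.0)])
        rec = read_cohort(path).records[0]
        assert rec.egfr == pytest.approx(egfr_mdrd(1.0, 60, female=False))

    def test_supplied_egfr_wins_over_creatinine(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1", egfr=88.0, creatinine=1.0)])
        assert read_cohort(path).records[0].egfr == 88.0

    def test_neither_creatinine_nor_egfr_rejected(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1", egfr="", creatinine="")])
        with pytest.raises(CohortValidationError, match="creatinine or egfr"):
            read_cohort(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = _write_csv(tmp_path, [_row("P1"), _row("P1")])
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path)


class TestImputeMedian:
    def _cohort(self, b2m_values):
        records = [
            PatientRecord(patient_id=f"P{i}", age=60, albumin=3.5, b2m=v,
                          calcium=9.5, hemoglobin=11.0, egfr=70.0, female=False,
                          pfs_time=10, pfs_event=1, os_time=20, os_event=1)
            for i, v in enumerate(b2m_values)
        ]
        return Cohort(records=records)

    def test_median_of_observed(self):
        cohort = impute_median(self._cohort([1.0, 2.0, None, 4.0]), ["b2m"])
        assert [r.b2m for r in cohort] == [1.0, 2.0, 2.0, 4.0]

    def test_no_missing_is_identity(self):
        base = self._cohort([1.0, 2.0, 3.0])
        out = impute_median(base, ["b2m"])
        assert [r.b2m for r in out] == [r.b2m for r in base]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="b2m"):
            impute_median(self._cohort([None, None]), ["b2m"])

    def test_idempotent(self):
        once = impute_median(self._cohort([1.0, None, 5.0, None]), ["b2m"])
        twice = impute_median(once, ["b2m"])
        assert [r.b2m for r in once] == [r.b2m for r in twice]


class TestEgfrMdrd:
    @pytest.mark.parametrize(
        "creatinine,age,female,expected",
        [
            (1.0, 50, False, 79.1),
            (1.0, 50, True, 58.7),
            (2.0, 50, False, 35.5),
        ],
    )
    def test_reference_values(self, creatinine, age, female, expected):
        assert egfr_mdrd(creatinine, age, female=female) == pytest.approx(expected, abs=0.05)

    def test_matches_formula_on_random_inputs(self, rng):
        for _ in range(100):
            scr = rng.uniform(0.3, 8.0)
            age = rng.uniform(20.0, 90.0)
            female = bool(rng.integers(2))
            black = bool(rng.integers(2))
            expected = (175.0 * scr ** -1.154 * age ** -0.203
                        * (0.742 if female else 1.0) * (1.212 if black else 1.0))
            got = egfr_mdrd(scr, age, female=female, black=black)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_monotone_decreasing(self):
        assert egfr_mdrd(2.0, 50) < egfr_mdrd(1.0, 50)
        assert egfr_mdrd(1.0, 80) < egfr_mdrd(1.0, 50)

    @pytest.mark.parametrize("creatinine,age", [(0, 50), (-1, 50), (1.0, 0)])
    def test_nonpositive_inputs_error(self, creatinine, age):
        with pytest.raises(ValueError):
            egfr_mdrd(creatinine, age)


class TestNormalizeLdh:
    @pytest.mark.parametrize("ldh,uln,expected", [
        (560, 560, 280.0),
        (140, 280, 140.0),
        (300, 250, 336.0),
    ])
    def test_rescaling(self, ldh, uln, expected):
        assert normalize_ldh(ldh, uln) == pytest.approx(expected, rel=1e-9)

    def test_bad_uln(self):
        with pytest.raises(ValueError):
            normalize_ldh(200, 0)


class TestDichotomize:
    def test_age_above_strict_cutoff_is_high_risk(self):
        rule = CutoffRule("age", 67, "high_if_gt")
        assert dichotomize(68, rule) is True
        assert dichotomize(67, rule) is False

    def test_le_direction_includes_boundary(self):
        rule = CutoffRule("albumin", 3.5, "high_if_le")
        assert dichotomize(3.5, rule) is True
        assert dichotomize(3.51, rule) is False

    def test_missing_value_errors(self):
        with pytest.raises(ValueError, match="impute"):
            dichotomize(float("nan"), CutoffRule("b2m", 5.5, "high_if_ge"))

    @pytest.mark.parametrize("direction", ["high_if_gt", "high_if_ge", "high_if_le"])
    def test_monotone_in_value(self, direction, rng):
        rule = CutoffRule("x", 5.0, direction)
        values = np.sort(rng.uniform(0, 10, size=50))
        flags = [dichotomize(v, rule) for v in values]
        if direction == "high_if_le":
            flags = flags[::-1]
        # Once high-risk going up (or down for <=), always high-risk.
        first_high = next((i for i, f in enumerate(flags) if f), len(flags))
        assert all(flags[first_high:])


class TestStagingBaselines:
    @pytest.mark.parametrize("b2m,albumin,expected", [
        (3.0, 3.6, 1),
        (6.0, 4.0, 3),
        (3.0, 3.0, 2),
        (5.5, 4.0, 3),
        (3.5, 4.0, 2),
    ])
    def test_iss(self, b2m, albumin, expected):
        assert assign_iss(b2m, albumin) == expected

    # Exhaustive rule table over ISS x HRCA x high-LDH.
    RISS_TABLE = {
        (1, False, False): 1,
        (1, False, True): 2,
        (1, True, False): 2,
        (1, True, True): 2,
        (2, False, False): 2,
        (2, False, True): 2,
        (2, True, False): 2,
        (2, True, True): 2,
        (3, False, False): 2,
        (3, False, True): 3,
        (3, True, False): 3,
        (3, True, True): 3,
    }

    def test_riss_all_twelve_combinations(self):
        for (iss, hrca, ldh), expected in self.RISS_TABLE.items():
            assert assign_riss(iss, hrca, ldh) == expected

    def test_riss_requires_flags(self):
        with pytest.raises(ValueError):
            assign_riss(1, None, False)


class TestBundledCutoffs:
    def test_presets_load_with_canonical_directions(self):
        for preset in ("established", "proposed_mmin", "proposed_mmrf"):
            rules = load_cutoffs(preset)
            assert set(rules) == {"age", "albumin", "b2m", "calcium", "egfr", "hemoglobin"}
            for p, rule in rules.items():
                assert rule.direction == CANONICAL_DIRECTIONS[p]

    def test_known_thresholds(self):
        mmin = load_cutoffs("proposed_mmin")
        assert mmin["age"].threshold == 67
        assert mmin["egfr"].threshold == 48.2
        mmrf = load_cutoffs("proposed_mmrf")
        assert mmrf["hemoglobin"].threshold == 9.59
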